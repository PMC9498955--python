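import numpy as np
import pandas as pd
import pytest

from countvar.io import CountMatrix, LengthTable


@pytest.fixture
def toy_lengths():
    return LengthTable({f"t{i}": 100 * i for i in range(1, 6)})


@pytest.fixture
def toy_matrix():
    """5 transcripts x 6 samples (3 per condition), mildly variable counts."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.integers(5, 500, size=(5, 6)).astype(float),
        index=pd.Index([f"t{i}" for i in range(1, 6)], name="transcript_id"),
        columns=["a1", "a2", "a3", "b1", "b2", "b3"],
    )
    design = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
    return CountMatrix(data, design)


def make_matrix(counts: np.ndarray, n_a: int, n_b: int) -> CountMatrix:
    """Build a CountMatrix from a (transcripts x samples) array."""
    t, s = counts.shape
    assert s == n_a + n_b
    cols = [f"a{i}" for i in range(1, n_a + 1)] + [f"b{i}" for i in range(1, n_b + 1)]
    data = pd.DataFrame(
        np.asarray(counts, dtype=float),
        index=pd.Index([f"t{i}" for i in range(1, t + 1)], name="transcript_id"),
        columns=cols,
    )
    design = {c: ("A" if c.startswith("a") else "B") for c in cols}
    return CountMatrix(data, design)
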