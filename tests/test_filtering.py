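"""Variance scoring, pooled percentile threshold and filtering.

The scoring oracle reimplements the whole pipeline with explicit Python
loops (normalize per sample, enumerate pairs, population variance) and is
kept independent of the vectorized implementation it checks.
"""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from countvar.filtering import (
    DEFAULT_SWEEP_PERCENTILES,
    VarianceTable,
    apply_filter,
    filter_at_percentile,
    normalize,
    pairwise_difference_variance,
    pooled_threshold,
    score_all,
    sweep,
)
from countvar.io import CountMatrix, LengthTable
from countvar.simulate import SimulationSpec, simulate_experiment

from conftest import make_matrix


# ---------------------------------------------------------------- oracles


def oracle_pairwise_variance(values):
    d = [abs(x - y) for x, y in combinations(values, 2)]
    mean = sum(d) / len(d)
    return sum((x - mean) ** 2 for x in d) / len(d)


def oracle_scores(matrix: CountMatrix, lengths: LengthTable):
    """Loop-based reimplementation of normalize + score_all."""
    totals = {s: sum(matrix.data[s]) for s in matrix.sample_ids}
    norm = {
        t: {s: matrix.data.at[t, s] / (lengths[t] * totals[s]) for s in matrix.sample_ids}
        for t in matrix.transcript_ids
    }
    out = {}
    for t in matrix.transcript_ids:
        per_cond = []
        for cond in ("A", "B"):
            vals = [norm[t][s] for s in matrix.samples_in(cond)]
            per_cond.append(oracle_pairwise_variance(vals))
        out[t] = tuple(per_cond)
    return out


def oracle_nearest_rank(sorted_values, percentile):
    rank = math.ceil(percentile / 100.0 * len(sorted_values))
    return sorted_values[max(rank, 1) - 1]


# ---------------------------------------------------------------- normalize


class TestNormalize:
    def test_direct_formula(self):
        # sample a1: counts (10, 990), total 1000; t1 length 100
        m = make_matrix(
            np.array([[10.0, 20.0, 10.0, 20.0], [990.0, 980.0, 990.0, 980.0]]), 2, 2
        )
        lengths = LengthTable({"t1": 100, "t2": 200})
        norm = normalize(m, lengths)
        assert norm.values.at["t1", "a1"] == pytest.approx(10 / (100 * 1000))

    def test_scale_invariance_per_sample(self, toy_matrix, toy_lengths):
        base = normalize(toy_matrix, toy_lengths).values
        scaled = toy_matrix.data.copy()
        scaled["a1"] *= 7.0
        m2 = CountMatrix(scaled, dict(toy_matrix.design))
        assert np.allclose(normalize(m2, toy_lengths).values, base)

    def test_zero_count_normalizes_to_zero(self):
        m = make_matrix(np.array([[0.0, 0.0, 0.0, 0.0], [10.0, 10.0, 10.0, 10.0]]), 2, 2)
        norm = normalize(m, LengthTable({"t1": 100, "t2": 100}))
        assert (norm.values.loc["t1"] == 0).all()

    def test_zero_total_sample_is_error(self):
        m = make_matrix(np.array([[0.0, 1.0, 1.0, 1.0], [0.0, 1.0, 1.0, 1.0]]), 2, 2)
        with pytest.raises(ValueError, match="zero total"):
            normalize(m, LengthTable({"t1": 100, "t2": 100}))


# ------------------------------------------------- pairwise-difference variance


class TestPairwiseDifferenceVariance:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ((3.0, 3.0, 3.0), 0.0),  # constant replicates
            ((1.0, 2.0, 4.0), 2.0 / 3.0),  # D = {1, 3, 2}: hand-computed
            ((0.0, 5.0), 0.0),  # single pair: population variance of one value
        ],
    )
    def test_known_values(self, values, expected):
        assert pairwise_difference_variance(values) == pytest.approx(expected)

    def test_fewer_than_two_values_is_error(self):
        with pytest.raises(ValueError):
            pairwise_difference_variance([1.0])

    @given(
        st.lists(st.floats(min_value=0, max_value=1e-3, allow_nan=False), min_size=2, max_size=8)
    )
    @settings(deadline=None, max_examples=100)
    def test_matches_bruteforce_oracle(self, values):
        got = pairwise_difference_variance(values)
        want = oracle_pairwise_variance(values)
        assert got == pytest.approx(want, rel=1e-10, abs=1e-30)


# ---------------------------------------------------------------- score_all


@st.composite
def small_count_matrix(draw):
    t = draw(st.integers(2, 10))
    na = draw(st.integers(2, 3))
    nb = draw(st.integers(2, 3))
    counts = draw(
        st.lists(
            st.lists(st.integers(0, 5000), min_size=na + nb, max_size=na + nb),
            min_size=t,
            max_size=t,
        )
    )
    counts = np.asarray(counts, dtype=float)
    # ensure nonzero sample totals
    counts[0, :] += 1
    lengths = LengthTable(
        {f"t{i}": draw(st.integers(100, 5000)) for i in range(1, t + 1)}
    )
    return make_matrix(counts, na, nb), lengths


class TestScoreAll:
    @given(small_count_matrix())
    @settings(deadline=None, max_examples=40)
    def test_matches_bruteforce_oracle(self, mat_lengths):
        matrix, lengths = mat_lengths
        table = score_all(matrix, lengths)
        want = oracle_scores(matrix, lengths)
        for t in matrix.transcript_ids:
            # abs floor sits far below any attainable score (normalized
            # values <= 1e-2 -> scores <= 1e-4) but above cancellation noise
            assert table.scores.at[t, "variance_a"] == pytest.approx(
                want[t][0], rel=1e-12, abs=1e-25
            )
            assert table.scores.at[t, "variance_b"] == pytest.approx(
                want[t][1], rel=1e-12, abs=1e-25
            )

    def test_identical_replicates_score_zero(self):
        col = np.array([[7.0], [13.0], [2.0]])
        m = make_matrix(np.repeat(col, 5, axis=1), 3, 2)
        table = score_all(m, LengthTable({"t1": 100, "t2": 200, "t3": 300}))
        assert (table.pooled == 0).all()

    def test_sample_permutation_invariance(self, toy_matrix, toy_lengths):
        base = score_all(toy_matrix, toy_lengths)
        shuffled = toy_matrix.data[["a3", "a1", "a2", "b2", "b3", "b1"]]
        m2 = CountMatrix(shuffled, dict(toy_matrix.design))
        assert np.allclose(score_all(m2, toy_lengths).scores, base.scores)

    def test_library_size_invariance(self, toy_matrix, toy_lengths):
        base = score_all(toy_matrix, toy_lengths)
        scaled = toy_matrix.data.copy()
        scaled["b2"] *= 3.5
        m2 = CountMatrix(scaled, dict(toy_matrix.design))
        assert np.allclose(score_all(m2, toy_lengths).scores, base.scores)

    def test_single_replicate_condition_rejected(self):
        m = make_matrix(np.ones((3, 3)), 1, 2)
        with pytest.raises(ValueError, match="need >= 2"):
            score_all(m, LengthTable({"t1": 1, "t2": 1, "t3": 1}))


# ---------------------------------------------------------------- threshold


class TestPooledThreshold:
    def test_nearest_rank_on_1_to_20(self):
        scores = np.arange(1.0, 21.0).reshape(10, 2)
        table = VarianceTable(
            __import__("pandas").DataFrame(
                scores, columns=["variance_a", "variance_b"],
                index=[f"t{i}" for i in range(10)],
            )
        )
        # pooled = 1..20; ceil(0.9 * 20) = 18 -> tau = 18
        assert pooled_threshold(table, 90) == 18

    def test_constant_scores(self):
        import pandas as pd

        table = VarianceTable(
            pd.DataFrame({"variance_a": [3.0] * 5, "variance_b": [3.0] * 5})
        )
        for p in (1, 50, 99):
            assert pooled_threshold(table, p) == 3.0

    def test_zero_mass_with_one_high_score(self):
        import pandas as pd

        table = VarianceTable(
            pd.DataFrame({"variance_a": [0.0] * 10, "variance_b": [0.0] * 9 + [5.0]})
        )
        assert pooled_threshold(table, 50) == 0.0

    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=50),
        st.floats(0.1, 99.9),
    )
    @settings(deadline=None, max_examples=100)
    def test_matches_nearest_rank_oracle(self, values, percentile):
        import pandas as pd

        n = len(values)
        table = VarianceTable(
            pd.DataFrame({"variance_a": values, "variance_b": values})
        )
        want = oracle_nearest_rank(sorted(values + values), percentile)
        assert pooled_threshold(table, percentile) == want

    def test_invalid_percentile(self, toy_matrix, toy_lengths):
        table = score_all(toy_matrix, toy_lengths)
        for p in (0, 100, -1):
            with pytest.raises(ValueError):
                pooled_threshold(table, p)


# ---------------------------------------------------------------- filtering


class TestApplyFilter:
    @pytest.fixture
    def table3(self):
        import pandas as pd

        return VarianceTable(
            pd.DataFrame(
                {"variance_a": [0.1, 0.0, 0.0], "variance_b": [0.0, 0.3, 0.0]},
                index=["t1", "t2", "t3"],
            )
        )

    @pytest.fixture
    def matrix3(self):
        return make_matrix(np.arange(12, dtype=float).reshape(3, 4) + 1, 2, 2)

    def test_either_condition_rule(self, table3, matrix3):
        res = apply_filter(matrix3, table3, tau=0.2)
        assert res.removed_ids == {"t2"}
        assert res.kept.transcript_ids == ["t1", "t3"]

    def test_huge_tau_removes_nothing(self, table3, matrix3):
        res = apply_filter(matrix3, table3, tau=1e9)
        assert res.removed_ids == set()
        assert res.kept.data.equals(matrix3.data)

    def test_ties_kept_under_strict_greater(self, table3, matrix3):
        res = apply_filter(matrix3, table3, tau=0.0)
        # zero-score transcript t3 survives a zero threshold
        assert "t3" in res.kept.transcript_ids
        assert res.removed_ids == {"t1", "t2"}

    def test_remove_ties_flag(self, table3, matrix3):
        res = apply_filter(matrix3, table3, tau=0.0, remove_ties=True)
        assert res.removed_ids == {"t1", "t2", "t3"}

    def test_kept_counts_bit_identical(self, toy_matrix, toy_lengths):
        res = filter_at_percentile(toy_matrix, toy_lengths, 60)
        for t in res.kept.transcript_ids:
            assert (res.kept.data.loc[t] == toy_matrix.data.loc[t]).all()

    def test_partition_of_ids(self, toy_matrix, toy_lengths):
        res = filter_at_percentile(toy_matrix, toy_lengths, 60)
        assert res.removed_ids | set(res.kept.transcript_ids) == set(toy_matrix.transcript_ids)
        assert not res.removed_ids & set(res.kept.transcript_ids)


@pytest.fixture(scope="module")
def simulated():
    spec = SimulationSpec(
        n_transcripts=400, fragments_per_replicate=200_000, seed=7,
        background_level=0.05,
    )
    return simulate_experiment(spec)


class TestSweep:
    def test_default_percentile_grid(self):
        assert DEFAULT_SWEEP_PERCENTILES == (70, 75, 80, 85, 90, 91, 92, 93, 94, 95, 96, 97, 98, 99)

    def test_nested_removal_sets(self, simulated):
        _, results = sweep(simulated.matrix, simulated.lengths, [70, 85, 95, 99])
        ps = sorted(results)
        for lo, hi in zip(ps, ps[1:]):
            assert results[hi].removed_ids <= results[lo].removed_ids

    def test_n_removed_non_increasing(self, simulated):
        table, _ = sweep(simulated.matrix, simulated.lengths)
        assert (table.sort_values("percentile")["n_removed"].diff().dropna() <= 0).all()

    def test_removal_fraction_bound(self, simulated):
        # with one pooled list of 2T scores and an either-condition rule,
        # the removed fraction at percentile p lies in [(100-p)%, 2(100-p)%]
        t = simulated.matrix.n_transcripts
        table, _ = sweep(simulated.matrix, simulated.lengths, [70, 80, 90, 95])
        for _, row in table.iterrows():
            frac = row.n_removed / t
            lo = (100 - row.percentile) / 100
            hi = min(1.0, 2 * (100 - row.percentile) / 100)
            assert lo - 0.01 <= frac <= hi + 0.01

    def test_duplicate_percentiles_rejected(self, simulated):
        with pytest.raises(ValueError):
            sweep(simulated.matrix, simulated.lengths, [90, 90])
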