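"""Intra-condition count-variation scoring and percentile-threshold filtering.

The filter scores every reference transcript, within each condition
separately, by the population variance of the absolute pairwise differences
of its normalized counts across the condition's replicates.  Both
conditions' scores are pooled into one ascending list; the variance value at
a user-chosen percentile of that pooled list (nearest-rank) becomes the
threshold, and a transcript is removed when its score in *either* condition
exceeds the threshold.  Raw counts of the surviving transcripts are written
out untouched, ready for any downstream differential-expression tool.

Normalization divides each raw count by the transcript length and by the
sample's total raw count, so scores are invariant both to sequencing depth
and to transcript length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, LengthTable, RunConfig, read_count_file, read_lengths, \
    assemble_matrix, write_count_file

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "VarianceTable",
    "FilterResult",
    "normalize",
    "pairwise_difference_variance",
    "score_all",
    "pooled_threshold",
    "apply_filter",
    "run_filter",
    "sweep",
    "DEFAULT_SWEEP_PERCENTILES",
]

#: 70th-90th in steps of five, then 91st-99th in steps of one.
DEFAULT_SWEEP_PERCENTILES: tuple[float, ...] = (70, 75, 80, 85, 90, 91, 92, 93, 94, 95, 96, 97, 98, 99)


@dataclass
class NormalizedMatrix:
    """Length- and library-size-normalized counts (transcripts x samples)."""

    values: pd.DataFrame
    design: dict[str, str]

    def condition_values(self, condition: str) -> np.ndarray:
        cols = [s for s in self.values.columns if self.design[s] == condition]
        return self.values[cols].to_numpy()


def normalize(matrix: CountMatrix, lengths: LengthTable) -> NormalizedMatrix:
    """value(t, s) = rawcount(t, s) / (length(t) * total_rawcount(s)).

    Totals run over the transcripts present in the matrix.  A sample whose
    counts sum to zero, or a transcript without a length, is an error.
    """
    missing = [t for t in matrix.transcript_ids if t not in lengths]
    if missing:
        raise ValueError(f"transcripts missing from length table: {missing[:3]}")
    totals = matrix.data.sum(axis=0)
    zero = list(totals.index[totals <= 0])
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")
    lens = lengths.as_series(matrix.transcript_ids)
    values = matrix.data.div(lens, axis=0).div(totals, axis=1)
    return NormalizedMatrix(values, dict(matrix.design))


def pairwise_difference_variance(values: Sequence[float]) -> float:
    """Variance of the absolute pairwise differences of one transcript's
    normalized counts within one condition.

    With replicates x_1..x_n the set D = {|x_i - x_j| : i < j} has
    n(n-1)/2 elements; the score is the population variance of D (squared
    deviations from the mean of D, divided by |D|).  For n = 2, |D| = 1 and
    the score is exactly 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values within a condition")
    i, j = np.triu_indices(x.size, k=1)
    d = np.abs(x[i] - x[j])
    return float(d.var(ddof=0))


def _condition_scores(values: np.ndarray) -> np.ndarray:
    """Vectorized pairwise-difference variance per row of (T, n) array."""
    n = values.shape[1]
    i, j = np.triu_indices(n, k=1)
    d = np.abs(values[:, i] - values[:, j])
    return d.var(axis=1, ddof=0)


@dataclass
class VarianceTable:
    """Per-transcript, per-condition variance scores plus the pooled list.

    ``scores`` has columns ``variance_a`` and ``variance_b`` indexed by
    transcript id; ``pooled`` is the ascending-sorted concatenation of both
    columns (length 2T).
    """

    scores: pd.DataFrame
    pooled: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if (self.scores[["variance_a", "variance_b"]].to_numpy() < 0).any():
            raise ValueError("negative variance score")
        self.pooled = np.sort(
            np.concatenate(
                [self.scores["variance_a"].to_numpy(), self.scores["variance_b"].to_numpy()]
            )
        )

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.scores.index)

    def __len__(self) -> int:
        return len(self.scores)


def score_all(matrix: CountMatrix, lengths: LengthTable) -> VarianceTable:
    """Normalize and score every transcript in both conditions."""
    for cond in ("A", "B"):
        n = len(matrix.samples_in(cond))
        if n < 2:
            raise ValueError(f"condition {cond} has {n} sample(s); need >= 2")
        if n < 3:
            logger.warning(
                "condition %s has only 2 replicates; all its variance scores are 0", cond
            )
    norm = normalize(matrix, lengths)
    scores = pd.DataFrame(
        {
            "variance_a": _condition_scores(norm.condition_values("A")),
            "variance_b": _condition_scores(norm.condition_values("B")),
        },
        index=matrix.data.index,
    )
    return VarianceTable(scores)


def pooled_threshold(table: VarianceTable, percentile: float) -> float:
    """Nearest-rank percentile of the pooled ascending score list.

    tau = pooled[ceil(percentile/100 * 2T)] with 1-based indexing.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie strictly between 0 and 100")
    pooled = table.pooled
    if pooled.size == 0:
        raise ValueError("empty variance table")
    rank = math.ceil(percentile / 100.0 * pooled.size)
    rank = min(max(rank, 1), pooled.size)
    return float(pooled[rank - 1])


@dataclass
class FilterResult:
    """Outcome of one filtering run.

    ``kept`` holds the input's raw counts, untouched, for the transcripts
    whose variance scores did not exceed ``threshold`` in either condition.
    """

    percentile: float
    threshold: float
    removed_ids: set[str]
    kept: CountMatrix
    variances: VarianceTable

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)

    @property
    def n_kept(self) -> int:
        return self.kept.n_transcripts

    def report_frame(self) -> pd.DataFrame:
        """Per-transcript report (scores, removed flag, threshold, percentile)."""
        df = self.variances.scores.copy()
        df["removed"] = [t in self.removed_ids for t in df.index]
        df["threshold"] = self.threshold
        df["percentile"] = self.percentile
        df.index.name = "transcript_id"
        return df


def apply_filter(
    matrix: CountMatrix,
    table: VarianceTable,
    tau: float,
    percentile: float = float("nan"),
    remove_ties: bool = False,
) -> FilterResult:
    """Remove every transcript whose score exceeds ``tau`` in either condition.

    The removal test is strictly-greater-than by default, so transcripts
    tied with the threshold are kept; a tau of 0 over a mass of zero-score
    transcripts therefore does not empty the matrix.  ``remove_ties=True``
    switches to >=.
    """
    missing = set(matrix.transcript_ids) - set(table.scores.index)
    if missing:
        raise ValueError(f"variance table does not cover matrix ids: {sorted(missing)[:3]}")
    sub = table.scores.loc[matrix.transcript_ids]
    va = sub["variance_a"].to_numpy()
    vb = sub["variance_b"].to_numpy()
    if remove_ties:
        mask = (va >= tau) | (vb >= tau)
    else:
        mask = (va > tau) | (vb > tau)
    ids = np.asarray(matrix.transcript_ids, dtype=object)
    removed = set(ids[mask])
    kept = matrix.subset(list(ids[~mask]))
    logger.info(
        "filter: tau=%.3e removed %d / %d transcripts", tau, len(removed), len(ids)
    )
    return FilterResult(percentile, float(tau), removed, kept, table)


def filter_at_percentile(
    matrix: CountMatrix,
    lengths: LengthTable,
    percentile: float,
    remove_ties: bool = False,
) -> FilterResult:
    """Score, threshold at the pooled percentile, and filter in one call."""
    table = score_all(matrix, lengths)
    tau = pooled_threshold(table, percentile)
    return apply_filter(matrix, table, tau, percentile=percentile, remove_ties=remove_ties)


def run_filter(config: RunConfig) -> FilterResult:
    """End-to-end run from a :class:`~countvar.io.RunConfig`.

    Reads all count files and the length table, scores and filters at
    ``config.percentile``, writes one filtered count file per input sample
    (output names from the config) and, when configured, a tab-separated
    report with columns (transcript_id, variance_a, variance_b, removed,
    threshold, percentile).
    """
    samples = []
    design: dict[str, str] = {}
    paths: dict[str, str] = {}
    for cond, files in (("A", config.condition_a_files), ("B", config.condition_b_files)):
        for p in files:
            s = read_count_file(p, config.column_spec)
            if s.sample_id in design:
                raise ValueError(f"duplicate sample id {s.sample_id!r} (file {p})")
            samples.append(s)
            design[s.sample_id] = cond
            paths[s.sample_id] = str(p)
    lengths = read_lengths(config.lengths_path, config.column_spec)
    matrix = assemble_matrix(samples, design, lengths, strict=True)
    result = filter_at_percentile(matrix, lengths, config.percentile)
    for sample_id in matrix.sample_ids:
        out = config.output_names[paths[sample_id]]
        write_count_file(result.kept.sample(sample_id), out)
    if config.report_path:
        result.report_frame().to_csv(config.report_path, sep="\t")
    return result


def sweep(
    matrix: CountMatrix,
    lengths: LengthTable,
    percentiles: Sequence[float] = DEFAULT_SWEEP_PERCENTILES,
) -> tuple[pd.DataFrame, dict[float, FilterResult]]:
    """Filter at several percentiles of the same pooled score distribution.

    Returns a summary frame with one row per percentile — (percentile,
    threshold, n_removed, n_kept) — and the per-percentile
    :class:`FilterResult` objects.  Removal sets are nested: a higher
    percentile removes a subset of what a lower percentile removes.
    """
    if len(set(percentiles)) != len(percentiles):
        raise ValueError("percentiles must be distinct")
    table = score_all(matrix, lengths)
    rows = []
    results: dict[float, FilterResult] = {}
    for p in sorted(percentiles):
        tau = pooled_threshold(table, p)
        res = apply_filter(matrix, table, tau, percentile=p)
        results[p] = res
        rows.append(
            {"percentile": p, "threshold": tau, "n_removed": res.n_removed, "n_kept": res.n_kept}
        )
    return pd.DataFrame(rows), results
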