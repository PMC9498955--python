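"""Evaluation metrics for the effect of variance filtering on DE outcomes.

Three complementary views:

* **ambiguous positives** — how many transcripts called differentially
  expressed on *unfiltered* data carry intra-condition variance above a
  pooled-percentile threshold (default the 90th), versus the rate over the
  whole reference;
* **dispersion diagnostics** — the log-log linear fit of gene-wise NB
  dispersion against mean normalized counts (r², RMSE, outlier count), a
  proxy for how well-behaved the mean-dispersion relationship the NB test
  relies on is;
* **discordance** — how the unfiltered significant list decomposes once the
  filtered input's list is computed: maintained, lost directly (removed by
  the filter), lost indirectly (still present but no longer significant),
  plus transcripts newly added.

Also provided: truth-recovery counts for simulations and the pre/post
common-detection ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .diffexpr import DEResultTable
from .filtering import VarianceTable, pooled_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "AmbiguousPositivesReport",
    "DiscordanceReport",
    "DispersionDiagnostics",
    "RecoveryMetrics",
    "ambiguous_positives",
    "discordance",
    "dispersion_diagnostics",
    "recovery_metrics",
    "common_ratio",
]

_EPS = 1e-8


@dataclass
class AmbiguousPositivesReport:
    """DE calls carrying high intra-condition variance.

    ``pct_flagged`` is the percentage of DE-significant transcripts whose
    variance score exceeds the threshold in either condition;
    ``reference_pct`` is the same percentage over the whole reference set.
    """

    percentile: float
    threshold: float
    n_de: int
    n_flagged: int
    flagged_ids: set[str]

    reference_n: int = 0
    reference_flagged: int = 0

    @property
    def pct_flagged(self) -> float:
        return 100.0 * self.n_flagged / self.n_de if self.n_de else 0.0

    @property
    def reference_pct(self) -> float:
        return 100.0 * self.reference_flagged / self.reference_n if self.reference_n else 0.0


def ambiguous_positives(
    de: DEResultTable,
    variances: VarianceTable,
    percentile: float = 90.0,
    alpha: float = 0.05,
) -> AmbiguousPositivesReport:
    """Flag DE-significant transcripts above the pooled variance percentile."""
    tau = pooled_threshold(variances, percentile)
    scores = variances.scores
    high = set(
        scores.index[(scores["variance_a"] > tau) | (scores["variance_b"] > tau)]
    )
    sig = set(de.significant(alpha))
    unknown = sig - set(scores.index)
    if unknown:
        raise ValueError(f"DE ids absent from variance table: {sorted(unknown)[:3]}")
    flagged = sig & high
    if not sig:
        logger.warning("ambiguous_positives: empty DE set; reporting 0%%")
    return AmbiguousPositivesReport(
        percentile=percentile,
        threshold=tau,
        n_de=len(sig),
        n_flagged=len(flagged),
        flagged_ids=flagged,
        reference_n=len(scores),
        reference_flagged=len(high),
    )


@dataclass
class DiscordanceReport:
    """Decomposition of the change between unfiltered and filtered DE lists.

    The unfiltered significant set partitions exactly into
    ``maintained + lost_direct + lost_indirect``; ``added`` counts
    transcripts significant only after filtering.  ``discordance_pct`` =
    100 * (lost_direct + lost_indirect + added) / n_nf.
    """

    n_nf: int
    maintained: int
    lost_direct: int
    lost_indirect: int
    added: int

    def __post_init__(self) -> None:
        assert self.n_nf == self.maintained + self.lost_direct + self.lost_indirect, (
            "partition identity violated"
        )

    @property
    def discordance_pct(self) -> float:
        changed = self.lost_direct + self.lost_indirect + self.added
        return 100.0 * changed / self.n_nf if self.n_nf else 0.0


def discordance(
    de_nf: DEResultTable,
    de_filt: DEResultTable,
    removed_ids: set[str],
    alpha: float = 0.05,
) -> DiscordanceReport:
    """Compare DE lists from unfiltered vs filtered inputs.

    ``de_filt`` must have been computed on the filtered matrix, so its id
    universe excludes ``removed_ids``.
    """
    overlap = removed_ids & set(de_filt.transcript_ids)
    if overlap:
        raise ValueError(
            f"removed ids present in filtered DE universe: {sorted(overlap)[:3]}"
        )
    sig_nf = set(de_nf.significant(alpha))
    sig_f = set(de_filt.significant(alpha))
    lost_direct = sig_nf & removed_ids
    maintained = sig_nf & sig_f
    lost_indirect = sig_nf - lost_direct - maintained
    added = sig_f - sig_nf
    return DiscordanceReport(
        n_nf=len(sig_nf),
        maintained=len(maintained),
        lost_direct=len(lost_direct),
        lost_indirect=len(lost_indirect),
        added=len(added),
    )


@dataclass
class DispersionDiagnostics:
    """Fit quality of log10(dispersion) vs log10(mean normalized counts)."""

    r_squared: float
    rmse: float
    n_outliers: int
    n_genes: int


def dispersion_diagnostics(de: DEResultTable) -> DispersionDiagnostics:
    """Least-squares log-log regression of gene-wise dispersion on base mean.

    Genes at the dispersion floor carry no variance information and are
    excluded along with genes of zero mean; fewer than 3 usable genes is an
    error.
    """
    df = de.results
    if "dispersion_genewise" not in df.columns or df["dispersion_genewise"].isna().all():
        raise ValueError("gene-wise dispersions unavailable in this result table")
    disp = df["dispersion_genewise"].to_numpy(dtype=float)
    mean = df["base_mean"].to_numpy(dtype=float)
    mask = np.isfinite(disp) & np.isfinite(mean) & (disp > _EPS) & (mean > 0)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 genes usable for the dispersion regression")
    x = np.log10(mean[mask])
    y = np.log10(disp[mask])
    fit = stats.linregress(x, y)
    pred = fit.intercept + fit.slope * x
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    n_out = int(df["outlier"].sum()) if "outlier" in df.columns else 0
    return DispersionDiagnostics(
        r_squared=float(fit.rvalue**2), rmse=rmse, n_outliers=n_out, n_genes=int(mask.sum())
    )


@dataclass
class RecoveryMetrics:
    """Truth recovery of a simulated over-expressed set."""

    n_truth: int
    n_detected_true: int
    n_significant: int  # over-expressed calls (padj < alpha, log2fc > 0)
    missing_truth: set[str]  # truth ids absent from the DE universe (filtered out)

    @property
    def full_recovery(self) -> bool:
        return self.n_detected_true == self.n_truth


def recovery_metrics(
    de: DEResultTable, truth: set[str], alpha: float = 0.05
) -> RecoveryMetrics:
    """Count truth transcripts detected as over-expressed (padj < alpha,
    positive log2 fold change).  Truth transcripts absent from the DE
    universe (e.g. removed by the filter) count as undetected and are
    listed in ``missing_truth``."""
    if not truth:
        logger.warning("recovery_metrics: empty truth set; full recovery is vacuous")
    over = set(de.over_expressed(alpha))
    missing = truth - set(de.transcript_ids)
    if missing:
        logger.info("recovery_metrics: %d truth transcripts absent from DE universe", len(missing))
    return RecoveryMetrics(
        n_truth=len(truth),
        n_detected_true=len(truth & over),
        n_significant=len(over),
        missing_truth=missing,
    )


def common_ratio(de_pre: DEResultTable, de_post: DEResultTable, alpha: float = 0.05) -> float:
    """|common over-expressed set| / max(|pre|, |post|); 0/0 defined as 1."""
    pre = set(de_pre.over_expressed(alpha))
    post = set(de_post.over_expressed(alpha))
    denom = max(len(pre), len(post))
    if denom == 0:
        logger.warning("common_ratio: both over-expressed sets empty; defining ratio as 1")
        return 1.0
    return len(pre & post) / denom
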