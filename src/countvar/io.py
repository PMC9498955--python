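"""Reading and writing count files, length tables and run configurations.

The canonical count-file dialect is two-column tab-separated text
(``transcript_id<TAB>count``), one row per transcript, with ``#``-prefixed
comment lines skipped.  Arbitrary column positions are supported through
:class:`ColumnSpec` so that wider coverage-statistics tables (e.g. BBMap
``pileup.sh`` covstats output) can be read without reformatting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnSpec",
    "SampleCounts",
    "LengthTable",
    "CountMatrix",
    "RunConfig",
    "read_count_file",
    "read_lengths",
    "assemble_matrix",
    "merge_technical_replicates",
    "write_count_file",
    "load_config",
]


class CountFileError(ValueError):
    """Malformed count/length file (bad field, duplicate id, no records)."""


@dataclass(frozen=True)
class ColumnSpec:
    """Which columns of a tab-separated file hold the id and the value.

    ``id_column`` and ``value_column`` are 0-based indices; lines starting
    with ``comment_prefix`` are skipped.
    """

    id_column: int = 0
    value_column: int = 1
    comment_prefix: str = "#"


@dataclass
class SampleCounts:
    """Per-transcript read counts for one sample.

    ``counts`` maps transcript id to a non-negative count; insertion order is
    the file order and is preserved on write.  Counts are integers when read
    from raw files but may be fractional after technical-replicate averaging.
    """

    sample_id: str
    counts: dict[str, float]

    def __post_init__(self) -> None:
        bad = [t for t, c in self.counts.items() if c < 0 or not math.isfinite(c)]
        if bad:
            raise ValueError(f"negative or non-finite count for {bad[:3]}")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class LengthTable:
    """Transcript lengths in bp (all >= 1)."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        bad = [t for t, n in self.lengths.items() if n < 1]
        if bad:
            raise ValueError(f"transcript length < 1 for {bad[:3]}")

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.lengths

    def __getitem__(self, transcript_id: str) -> int:
        return self.lengths[transcript_id]

    def __len__(self) -> int:
        return len(self.lengths)

    def as_series(self, ids: Sequence[str] | None = None) -> pd.Series:
        s = pd.Series(self.lengths, dtype=float)
        return s if ids is None else s.reindex(list(ids))


@dataclass
class CountMatrix:
    """Raw counts (transcripts x samples) with a two-condition design.

    ``data`` is indexed by transcript id with one column per sample id;
    ``design`` maps each sample id to condition ``"A"`` or ``"B"``.
    """

    data: pd.DataFrame
    design: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.data.columns) - set(self.design)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)[:3]}")
        extra = set(self.design) - set(self.data.columns)
        if extra:
            raise ValueError(f"design names unknown samples: {sorted(extra)[:3]}")
        bad = {c for c in self.design.values() if c not in ("A", "B")}
        if bad:
            raise ValueError(f"conditions must be 'A' or 'B', got {bad}")
        for cond in ("A", "B"):
            if not self.samples_in(cond):
                raise ValueError(f"condition {cond} has no samples")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate transcript ids in matrix")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.data.columns if self.design[s] == condition]

    @property
    def n_transcripts(self) -> int:
        return self.data.shape[0]

    def subset(self, transcript_ids: Sequence[str]) -> "CountMatrix":
        """Row subset preserving raw counts bit-for-bit."""
        return CountMatrix(self.data.loc[list(transcript_ids)], dict(self.design))

    def sample(self, sample_id: str) -> SampleCounts:
        return SampleCounts(sample_id, self.data[sample_id].to_dict())


def _iter_records(path: str | Path, spec: ColumnSpec):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count file not found: {path}")
    need = max(spec.id_column, spec.value_column) + 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(spec.comment_prefix):
                continue
            fields = line.split("\t")
            if len(fields) < need:
                raise CountFileError(
                    f"{path}:{lineno}: expected >= {need} tab-separated fields, "
                    f"got {len(fields)}"
                )
            yield lineno, fields[spec.id_column], fields[spec.value_column]


def read_count_file(
    path: str | Path,
    column_spec: ColumnSpec = ColumnSpec(),
    sample_id: str | None = None,
) -> SampleCounts:
    """Read one per-sample count file into a :class:`SampleCounts`.

    Raises :class:`CountFileError` (with the offending line number) on an
    unparseable or negative count, a duplicate transcript id, or a file with
    no data records.
    """
    path = Path(path)
    counts: dict[str, float] = {}
    for lineno, tid, raw in _iter_records(path, column_spec):
        try:
            value = float(raw)
        except ValueError:
            raise CountFileError(f"{path}:{lineno}: unparseable count {raw!r}") from None
        if value < 0 or not math.isfinite(value):
            raise CountFileError(f"{path}:{lineno}: negative/non-finite count {raw!r}")
        if tid in counts:
            raise CountFileError(f"{path}:{lineno}: duplicate transcript id {tid!r}")
        counts[tid] = value
    if not counts:
        raise CountFileError(f"{path}: no count records")
    return SampleCounts(sample_id or path.stem, counts)


def read_lengths(path: str | Path, column_spec: ColumnSpec = ColumnSpec()) -> LengthTable:
    """Read a two-column (id, length-in-bp) table; lengths must be >= 1."""
    path = Path(path)
    lengths: dict[str, int] = {}
    for lineno, tid, raw in _iter_records(path, column_spec):
        try:
            value = int(float(raw))
        except ValueError:
            raise CountFileError(f"{path}:{lineno}: unparseable length {raw!r}") from None
        if value < 1:
            raise CountFileError(f"{path}:{lineno}: length must be >= 1, got {raw!r}")
        if tid in lengths:
            raise CountFileError(f"{path}:{lineno}: duplicate transcript id {tid!r}")
        lengths[tid] = value
    if not lengths:
        raise CountFileError(f"{path}: no length records")
    return LengthTable(lengths)


def assemble_matrix(
    samples: Sequence[SampleCounts],
    design: Mapping[str, str],
    lengths: LengthTable,
    strict: bool = True,
) -> CountMatrix:
    """Combine per-sample counts into a :class:`CountMatrix`.

    In strict mode (default) any transcript-id mismatch across samples, or an
    id absent from the length table, is an error.  In non-strict mode the id
    sets are intersected (and intersected with the length table) and the
    number of dropped transcripts is logged.  Strictness is the default
    because a silent intersection can mask upstream mapping errors.
    """
    if not samples:
        raise ValueError("no samples")
    missing_design = [s.sample_id for s in samples if s.sample_id not in design]
    if missing_design:
        raise ValueError(f"design does not cover samples: {missing_design[:3]}")

    first_ids = samples[0].transcript_ids
    universe = set(first_ids)
    common = set(first_ids)
    for s in samples[1:]:
        ids = set(s.counts)
        universe |= ids
        common &= ids
    common &= set(lengths.lengths)

    if strict:
        if len(common) != len(universe):
            raise ValueError(
                f"transcript-id mismatch across samples/length table: "
                f"{len(universe) - len(common)} ids not shared (strict mode)"
            )
        kept_ids = first_ids
    else:
        kept_ids = [t for t in first_ids if t in common]
        dropped = len(universe) - len(common)
        if dropped:
            logger.info("assemble_matrix: dropped %d transcripts not shared by all inputs", dropped)
    if not kept_ids:
        raise ValueError("empty transcript-id intersection")

    data = pd.DataFrame(
        {s.sample_id: [s.counts[t] for t in kept_ids] for s in samples},
        index=pd.Index(kept_ids, name="transcript_id"),
        dtype=float,
    )
    return CountMatrix(data, {s.sample_id: design[s.sample_id] for s in samples})


def merge_technical_replicates(
    replicates: Sequence[SampleCounts], sample_id: str | None = None
) -> SampleCounts:
    """Average technical replicates into one count profile.

    The per-transcript arithmetic mean is rounded half-up to the nearest
    integer so that the merged profile remains count-like for downstream
    negative-binomial testing; the unrounded means are logged at DEBUG level.
    """
    if len(replicates) < 2:
        raise ValueError("need >= 2 technical replicates to merge")
    ids = replicates[0].transcript_ids
    idset = set(ids)
    for r in replicates[1:]:
        if set(r.counts) != idset:
            raise ValueError(
                f"technical replicates disagree on transcript ids "
                f"({replicates[0].sample_id} vs {r.sample_id})"
            )
    n = len(replicates)
    merged: dict[str, float] = {}
    for t in ids:
        mean = sum(r.counts[t] for r in replicates) / n
        merged[t] = float(math.floor(mean + 0.5))  # round half-up
        logger.debug("merge %s: mean %.4f -> %d", t, mean, merged[t])
    return SampleCounts(sample_id or f"{replicates[0].sample_id}_merged", merged)


def write_count_file(sample: SampleCounts, path: str | Path) -> None:
    """Write a two-column tab-separated count file.

    Integer counts round-trip losslessly through :func:`read_count_file`;
    fractional counts (averaged technical replicates) are written at full
    precision via ``repr``.
    """
    path = Path(path)
    if not sample.counts:
        logger.warning("writing empty count file %s", path)
    with open(path, "w") as fh:
        for t, c in sample.counts.items():
            text = str(int(c)) if float(c).is_integer() else repr(c)
            fh.write(f"{t}\t{text}\n")


@dataclass
class RunConfig:
    """Full parameterization of a filtering run, loadable from YAML.

    ``output_names`` maps each input count-file path to the path its filtered
    counterpart is written to; paths may never coincide with an input (the
    original counts are kept untouched).
    """

    condition_a_files: list[str]
    condition_b_files: list[str]
    lengths_path: str
    percentile: float = 95.0
    output_names: dict[str, str] = field(default_factory=dict)
    column_spec: ColumnSpec = field(default_factory=ColumnSpec)
    report_path: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.percentile < 100):
            raise ValueError("percentile must lie strictly between 0 and 100")
        for cond, files in (("A", self.condition_a_files), ("B", self.condition_b_files)):
            if len(files) < 2:
                raise ValueError(f"condition {cond} needs >= 2 count files")
            if len(files) == 2:
                logger.warning(
                    "condition %s has exactly 2 replicates: every pairwise-difference "
                    "set has one element, so all its variance scores are 0", cond,
                )
        inputs = set(map(str, self.condition_a_files + self.condition_b_files))
        if not self.output_names:
            self.output_names = {p: f"{p}.filtered" for p in inputs}
        clashes = set(map(str, self.output_names.values())) & inputs
        if clashes:
            raise ValueError(f"output paths overwrite inputs: {sorted(clashes)[:3]}")

    @property
    def all_input_files(self) -> list[str]:
        return list(self.condition_a_files) + list(self.condition_b_files)


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file.

    Recognised keys: ``conditionA``/``conditionB`` (lists of count-file
    paths), ``lengths`` (path), ``percentile``, ``output_suffix`` or
    ``output_names`` (mapping), ``report`` (path), and ``column_spec`` with
    subkeys ``id_column``, ``value_column``, ``comment_prefix``.  Relative
    paths are resolved against the config file's directory.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key in ("conditionA", "conditionB", "lengths"):
        if key not in raw:
            raise KeyError(f"{path}: missing required config key {key!r}")
    base = path.parent

    def _resolve(p: str) -> str:
        return str((base / p) if not Path(p).is_absolute() else Path(p))

    cond_a = [_resolve(p) for p in raw["conditionA"]]
    cond_b = [_resolve(p) for p in raw["conditionB"]]
    spec = ColumnSpec(**raw.get("column_spec", {}))
    suffix = raw.get("output_suffix", ".filtered")
    if "output_names" in raw:
        out = {_resolve(k): _resolve(v) for k, v in raw["output_names"].items()}
    else:
        out = {p: p + suffix for p in cond_a + cond_b}
    return RunConfig(
        condition_a_files=cond_a,
        condition_b_files=cond_b,
        lengths_path=_resolve(raw["lengths"]),
        percentile=float(raw.get("percentile", 95.0)),
        output_names=out,
        column_spec=spec,
        report_path=_resolve(raw["report"]) if "report" in raw else None,
    )
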