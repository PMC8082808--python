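"""Tabular I/O, run configuration and provenance logging.

The pipeline consumes two plain tab-separated tables:

* a **count table** — integer feature counts (taxa at some rank, or predicted
  metabolic pathways) per stool sample, samples × features after orientation
  normalisation;
* a **cohort table** — one row per sample with subject identifier, ordered
  time-point label, delivery mode, breastfeeding duration, and the two stool
  markers (zonulin in ng/mL, calprotectin in µg/g), either possibly missing.

Missing marker values stay missing (``NaN``) and are removed case-wise by the
downstream analyses; they are never imputed or zero-filled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MARKERS = ("zonulin", "calprotectin")

_COHORT_REQUIRED = (
    "sample_id",
    "subject_id",
    "time_point",
    "delivery_mode",
    "breastfeeding_weeks",
)


@dataclass(frozen=True)
class CountTable:
    """Integer feature counts, samples × features.

    Parameters
    ----------
    sample_ids, feature_ids
        Opaque unique identifiers for the rows and columns of ``counts``.
    counts
        Non-negative integer matrix of shape ``(n_samples, n_features)``.
    """

    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n_s, n_f = counts.shape
        if n_s != len(self.sample_ids) or n_f != len(self.feature_ids):
            raise ValueError("counts shape does not match identifier lists")
        if n_s < 1 or n_f < 2:
            raise ValueError("need at least 1 sample and 2 features")
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} IDs")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        object.__setattr__(self, "counts", np.asarray(counts, dtype=np.int64))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    def select_samples(self, keep: list[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return CountTable(tuple(keep), self.feature_ids, self.counts[idx])


@dataclass(frozen=True)
class RunConfig:
    """Run settings; the defaults reproduce the primary-cohort analysis."""

    rarefaction_depth: int | str = "auto"
    rarefaction_cycles: int = 10
    n_instances: int = 128
    prevalence_min: float = 0.20
    pathway_min_count: int = 3
    fdr_alpha: float = 0.05
    rng_seed: int = 0
    covariates: tuple[str, ...] = ("delivery_mode", "breastfeeding_weeks")
    clip_marker_limits: bool = False

    def __post_init__(self) -> None:
        if self.rarefaction_depth != "auto" and int(self.rarefaction_depth) < 1:
            raise ValueError("rarefaction_depth must be positive or 'auto'")
        if not (0 < self.prevalence_min <= 1):
            raise ValueError("prevalence_min must be in (0, 1]")
        if self.rarefaction_cycles < 1 or self.n_instances < 1:
            raise ValueError("cycles and instance counts must be positive")
        if self.pathway_min_count < 1:
            raise ValueError("pathway_min_count must be >= 1")
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Provenance record: config echo, seed, per-stage counts and outputs."""

    config: dict = field(default_factory=dict)
    seed: int | None = None
    stages: list[dict] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def log(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **info})

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


# assay determination limits (upper): zonulin ng/mL, calprotectin µg/g
MARKER_LIMITS = {"zonulin": 800.0, "calprotectin": 2100.0}


def apply_marker_limits(design: pd.DataFrame, clip: bool) -> pd.DataFrame:
    """Optionally clip marker values at the assay's upper determination limit.

    Whether out-of-range readings were censored or recorded as the limit is
    an acquisition detail the pipeline cannot infer, so both behaviours are
    exposed; with ``clip=False`` values pass through unchanged.
    """
    if not clip:
        return design
    design = design.copy()
    for marker, limit in MARKER_LIMITS.items():
        if marker in design.columns:
            design[marker] = design[marker].clip(upper=limit)
    return design


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a flat-key YAML file; unknown keys raise."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "covariates" in data:
        data["covariates"] = tuple(data["covariates"])
    return RunConfig(**data)


def read_count_table(path: str | Path, orientation: str = "samples-as-rows") -> CountTable:
    """Read a tab-separated count table and normalise to samples × features.

    ``orientation`` declares whether the file's rows are samples
    (``"samples-as-rows"``) or features (``"samples-as-columns"``).
    """
    if orientation not in ("samples-as-rows", "samples-as-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "samples-as-columns":
        df = df.T
    for axis_name, ids in (("sample", df.index), ("feature", df.columns)):
        if ids.duplicated().any():
            dup = ids[ids.duplicated()][0]
            raise ValueError(f"duplicate {axis_name} ID {dup!r} in {path}")
    values = df.to_numpy()
    bad = ~np.isfinite(values.astype(float)) | (values.astype(float) != np.floor(values.astype(float)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer entry at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    neg = values.astype(float) < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"negative count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return CountTable(tuple(df.index.astype(str)), tuple(df.columns.astype(str)), values.astype(np.int64))


def write_count_table(t: CountTable, path: str | Path) -> None:
    t.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_cohort(path: str | Path, timepoint_order: list[str]) -> pd.DataFrame:
    """Read sample metadata; coerce time points to the declared ordered set.

    Returns a DataFrame indexed by ``sample_id`` with ``time_point`` as an
    ordered categorical. Blank marker cells become ``NaN`` and the sample is
    retained. Duplicate ``(subject_id, time_point)`` rows or time labels
    outside ``timepoint_order`` raise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    return validate_cohort(df, timepoint_order)


def validate_cohort(df: pd.DataFrame, timepoint_order: list[str]) -> pd.DataFrame:
    df = df.copy()
    unknown = set(df["time_point"].astype(str)) - set(timepoint_order)
    if unknown:
        raise ValueError(f"unknown time point label(s): {sorted(unknown)}")
    dup = df.duplicated(subset=["subject_id", "time_point"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate (subject, time) pair: ({row['subject_id']}, {row['time_point']})"
        )
    df["time_point"] = pd.Categorical(
        df["time_point"].astype(str), categories=list(timepoint_order), ordered=True
    )
    for m in MARKERS:
        if m in df.columns:
            df[m] = pd.to_numeric(df[m], errors="coerce")
    df["breastfeeding_weeks"] = pd.to_numeric(df["breastfeeding_weeks"])
    return df.set_index("sample_id", drop=False)


def write_cohort(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def filter_prevalence(
    t: CountTable, min_fraction: float, min_count: int = 1, report: RunReport | None = None
) -> CountTable:
    """Drop features detected at < ``min_count`` reads in < ``min_fraction`` of samples.

    A feature is kept when ``count >= min_count`` in at least
    ``ceil(min_fraction * n_samples)`` samples; the sample set is unchanged.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    detected = (t.counts >= min_count).sum(axis=0)
    keep = detected / t.n_samples >= min_fraction
    if not keep.any():
        raise ValueError("prevalence filter removed every feature")
    if report is not None:
        report.log(
            "filter_prevalence",
            min_fraction=min_fraction,
            min_count=min_count,
            removed=int((~keep).sum()),
            kept=int(keep.sum()),
        )
    kept_ids = tuple(f for f, k in zip(t.feature_ids, keep) if k)
    return CountTable(t.sample_ids, kept_ids, t.counts[:, keep])
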