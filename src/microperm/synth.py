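"""Synthetic longitudinal infant-cohort generator with ground truth.

The generator emulates the statistical structure the analysis assumes: a
small cohort of infants sampled at up to five scheduled stool collections
(7 days, 1, 6, 12 and 24 months — labels P2…P6) with realistic missingness;
genus-level counts that are Dirichlet-multinomial around subject- and
time-adjusted expected proportions; a zonulin trajectory that rises to a
plateau around the 6-month visit; a calprotectin trajectory that declines
after it; subject-level random intercepts on both the log-abundances and
the markers; and an optional linear coupling that ties a marker's change to
the CLR change of one feature.

Each sample's *realized* composition is the Dirichlet draw; sequencing is
the multinomial on top of it. Marker couplings act on the realized
composition's CLR, so the coupled signal is recoverable from the counts up
to multinomial noise. All randomness flows from one seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_config import CountTable, validate_cohort

DEFAULT_TIMEPOINTS = ("P2", "P3", "P4", "P5", "P6")
# per-time sampling probability matched to the cohort's visit counts out of 21
DEFAULT_AVAILABILITY = (20 / 21, 19 / 21, 20 / 21, 21 / 21, 13 / 21)
# ng/mL: low in the first month, plateau from the 6-month visit
DEFAULT_ZONULIN_CURVE = (220.0, 280.0, 480.0, 500.0, 510.0)
# µg/g: high through 6 months, declining at 12 and 24 months
DEFAULT_CALPROTECTIN_CURVE = (250.0, 240.0, 220.0, 120.0, 70.0)


@dataclass(frozen=True)
class SimScenario:
    """Study-condition bundle for :func:`simulate_cohort`.

    Trend directions are balanced (half up, half down) so the CLR of
    non-trending features carries no systematic time signal. The default
    coupling strength is sized so the coupled term explains roughly half of
    the marker's residual variance — the "large effect" regime.
    """

    n_subjects: int = 21
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    availability: tuple[float, ...] = DEFAULT_AVAILABILITY
    n_features: int = 47
    n_trending: int = 8
    trend_magnitude: float = 1.5  # natural-log change across the full series
    subject_sd: float = 0.5  # random-intercept SD on log-abundance
    marker_subject_sd: float = 60.0  # random-intercept SD on markers
    library_size_mu: float = 9.0  # lognormal log-mean of reads per sample
    library_size_sigma: float = 0.35
    dm_concentration: float = 200.0  # Dirichlet-multinomial overdispersion
    zonulin_curve: tuple[float, ...] = DEFAULT_ZONULIN_CURVE
    calprotectin_curve: tuple[float, ...] = DEFAULT_CALPROTECTIN_CURVE
    coupling: tuple[tuple[str, str, float], ...] = (("g12", "calprotectin", 150.0),)
    noise_sd: float = 80.0  # marker residual SD
    prevalence_min: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.availability) != len(self.timepoints):
            raise ValueError("availability must match timepoints")
        if not all(0 <= a <= 1 for a in self.availability):
            raise ValueError("availability probabilities must be in [0, 1]")
        if max(self.availability, default=0) == 0:
            raise ValueError("degenerate scenario: all availability zero")
        if self.n_trending > self.n_features:
            raise ValueError("n_trending cannot exceed n_features")
        for f, m, b in self.coupling:
            if not np.isfinite(b):
                raise ValueError("coupling beta must be finite")
        if len(self.zonulin_curve) != len(self.timepoints):
            raise ValueError("zonulin_curve must match timepoints")
        if len(self.calprotectin_curve) != len(self.timepoints):
            raise ValueError("calprotectin_curve must match timepoints")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    trending: dict[str, dict] = field(default_factory=dict)
    coupling: list[dict] = field(default_factory=list)
    subject_intercepts: dict[str, dict] = field(default_factory=dict)
    expected_proportions: dict[str, list] = field(default_factory=dict)
    realized_clr: dict[str, dict] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self)))


def _feature_ids(n: int) -> tuple[str, ...]:
    return tuple(f"g{i + 1:02d}" for i in range(n))


def _trend_assignment(feature_ids, n_trending: int) -> dict[str, float]:
    """Alternating up/down trends on moderately abundant features (indices 2+)."""
    signs = {}
    for k in range(n_trending):
        signs[feature_ids[2 + k]] = 1.0 if k % 2 == 0 else -1.0
    return signs


def simulate_cohort(
    s: SimScenario,
) -> tuple[CountTable, pd.DataFrame, GroundTruth]:
    """Draw one synthetic cohort; fully reproducible under ``s.seed``."""
    rng = np.random.default_rng(s.seed)
    T = len(s.timepoints)
    feats = _feature_ids(s.n_features)
    subjects = tuple(f"S{i + 1:02d}" for i in range(s.n_subjects))

    base_log = -0.15 * np.arange(s.n_features)  # geometric-ish rank-abundance
    trend_sign = _trend_assignment(feats, s.n_trending)
    trend_dir = np.array([trend_sign.get(f, 0.0) for f in feats])
    # linear log-trend, centred so the series-wide change equals trend_magnitude
    t_frac = (np.arange(T) / (T - 1) - 0.5) if T > 1 else np.zeros(1)

    subj_feat = rng.normal(0.0, s.subject_sd, size=(s.n_subjects, s.n_features))
    observed = rng.random((s.n_subjects, T)) < np.asarray(s.availability)

    marker_curves = {"zonulin": s.zonulin_curve, "calprotectin": s.calprotectin_curve}
    marker_int = {
        m: rng.normal(0.0, s.marker_subject_sd, size=s.n_subjects)
        for m in marker_curves
    }
    delivery = rng.choice(["C", "V"], size=s.n_subjects, p=[0.55, 0.45])
    breastfeeding = np.clip(rng.normal(29.0, 20.0, size=s.n_subjects), 0.0, None)

    truth = GroundTruth(
        trending={
            f: {"direction": int(d), "magnitude": s.trend_magnitude}
            for f, d in trend_sign.items()
        },
        coupling=[
            {"feature": f, "marker": m, "beta_true": b} for f, m, b in s.coupling
        ],
        subject_intercepts={
            m: dict(zip(subjects, map(float, marker_int[m]))) for m in marker_curves
        },
    )

    sample_rows, count_rows = [], []
    coupled_feats = {f for f, _, _ in s.coupling}
    clr_store: dict[str, dict[str, float]] = {f: {} for f in coupled_feats}
    baseline_clr: dict[tuple[str, str], float] = {}

    for i, subj in enumerate(subjects):
        for t in range(T):
            if not observed[i, t]:
                continue
            sid = f"{subj}_{s.timepoints[t]}"
            loglat = base_log + trend_dir * s.trend_magnitude * t_frac[t] + subj_feat[i]
            p = np.exp(loglat - loglat.max())
            p /= p.sum()
            truth.expected_proportions[sid] = [round(float(v), 8) for v in p]
            comp = rng.dirichlet(s.dm_concentration * p)
            comp = np.clip(comp, 1e-12, None)
            comp /= comp.sum()
            lib = max(int(np.round(rng.lognormal(s.library_size_mu, s.library_size_sigma))), 1)
            counts = rng.multinomial(lib, comp)
            clr = np.log(comp) - np.log(comp).mean()
            for f in coupled_feats:
                clr_store[f][sid] = float(clr[feats.index(f)])

            row = {
                "sample_id": sid,
                "subject_id": subj,
                "time_point": s.timepoints[t],
                "delivery_mode": delivery[i],
                "breastfeeding_weeks": float(breastfeeding[i]),
            }
            for m, curve in marker_curves.items():
                value = curve[t] + marker_int[m][i]
                for f, cm, beta in s.coupling:
                    if cm != m:
                        continue
                    key = (subj, f)
                    if key not in baseline_clr:  # first available time point
                        baseline_clr[key] = clr[feats.index(f)]
                    value += beta * (clr[feats.index(f)] - baseline_clr[key])
                value += rng.normal(0.0, s.noise_sd)
                row[m] = max(value, 0.0)
            sample_rows.append(row)
            count_rows.append(counts)

    if not sample_rows:
        raise ValueError("no samples generated; availability draws were all empty")
    design = validate_cohort(pd.DataFrame(sample_rows), list(s.timepoints))
    table = CountTable(
        tuple(r["sample_id"] for r in sample_rows), feats, np.array(count_rows)
    )
    truth.realized_clr = clr_store
    return table, design, truth


def scenario_presets(name: str, seed: int = 0) -> SimScenario:
    """Named study conditions: ``pmu-like``, ``hms-like`` or ``null``."""
    if name == "pmu-like":
        return SimScenario(seed=seed)
    if name == "hms-like":
        return SimScenario(
            n_subjects=45,
            timepoints=("P2", "P3", "P4", "P5"),
            availability=(0.85, 0.85, 0.85, 0.85),
            zonulin_curve=DEFAULT_ZONULIN_CURVE[:4],
            calprotectin_curve=DEFAULT_CALPROTECTIN_CURVE[:4],
            prevalence_min=0.10,
            seed=seed,
        )
    if name == "null":
        flat_z = (float(np.mean(DEFAULT_ZONULIN_CURVE)),) * 5
        flat_c = (float(np.mean(DEFAULT_CALPROTECTIN_CURVE)),) * 5
        return SimScenario(
            n_trending=0,
            trend_magnitude=0.0,
            coupling=(),
            zonulin_curve=flat_z,
            calprotectin_curve=flat_c,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")


def synthetic_delta_response(
    feature_change: np.ndarray,
    intervals: pd.Series | np.ndarray,
    beta: float,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Construct a response with a known common slope over interval rows.

    response = beta * feature_change + interval-specific offset + N(0, noise_sd);
    used by slope-recovery checks where the generative coefficient must be
    identified on the raw (un-ranked) scale.
    """
    rng = np.random.default_rng(seed)
    codes, _ = pd.factorize(np.asarray(intervals))
    offsets = rng.normal(0.0, 2.0, size=codes.max() + 1)
    return (
        beta * np.asarray(feature_change, dtype=float)
        + offsets[codes]
        + rng.normal(0.0, noise_sd, size=len(codes))
    )
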