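"""Change-vs-change analysis over all within-subject time-point pairs.

For every subject, every ordered pair of observed time points (P2–P3,
P2–P4, …) contributes one row holding the marker change (later − earlier),
the per-feature CLR change for each Monte-Carlo instance, and the
within-subject Bray–Curtis distance between the two rarefied samples. The
marker change (rank-transformed by default) is then modelled as

    Δmarker ~ Δpredictor + interval + covariates + (1 | subject)

with two nested LRTs: the first drops the predictor from the no-interaction
(common slope) model; the second compares the interaction model
(Δpredictor × interval) against the common slope. The reading rule follows
the two-step convention: interpret per-interval slopes if the interaction
q < alpha, otherwise the common slope if its q < alpha, otherwise nothing.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compositional import ClrInstanceSet
from .diversity import bray_curtis
from .io_config import CountTable
from .models import LmmFit, _fit_mixedlm, bh_fdr, lrt, rank_transform
from scipy import stats


@dataclass
class DeltaTable:
    """All within-subject interval rows plus the per-instance feature changes."""

    frame: pd.DataFrame  # subject, interval, earlier, later, Δmarkers, bray_curtis, covariates
    feature_changes: np.ndarray  # instances × rows × features
    feature_ids: tuple[str, ...]
    interval_levels: tuple[str, ...]

    @property
    def n_rows(self) -> int:
        return len(self.frame)


def interval_labels(timepoints: list[str]) -> tuple[str, ...]:
    return tuple(f"{a}-{b}" for a, b in itertools.combinations(timepoints, 2))


def build_deltas(
    rarefied: CountTable,
    c: ClrInstanceSet,
    design: pd.DataFrame,
    markers: list[str],
    covariates: list[str] = ("delivery_mode", "breastfeeding_weeks"),
) -> DeltaTable:
    """Assemble the interval table; a subject with k time points yields C(k,2) rows.

    Marker changes at intervals with a missing endpoint stay missing (the
    feature columns are still filled). Subjects observed at fewer than two
    time points contribute no rows.
    """
    if tuple(rarefied.sample_ids) != tuple(c.sample_ids):
        raise ValueError("rarefied table and CLR set must cover the same samples")
    design = design.loc[list(c.sample_ids)]
    tp_order = list(design["time_point"].cat.categories)
    levels = interval_labels(tp_order)
    bc = bray_curtis(rarefied)
    pos = {s: i for i, s in enumerate(c.sample_ids)}

    rows, change_idx = [], []
    for subject, g in design.groupby("subject_id", sort=False, observed=True):
        g = g.sort_values("time_point")
        if len(g) < 2:
            warnings.warn(f"subject {subject!r} has <2 time points; no interval rows")
            continue
        for (_, ea), (_, la) in itertools.combinations(g.iterrows(), 2):
            row = {
                "subject_id": subject,
                "interval": f"{ea['time_point']}-{la['time_point']}",
                "earlier": str(ea["time_point"]),
                "later": str(la["time_point"]),
                "bray_curtis": bc.values[pos[ea["sample_id"]], pos[la["sample_id"]]],
            }
            for m in markers:
                row[f"d_{m}"] = la[m] - ea[m]
            for cov in covariates:
                row[cov] = ea[cov]
            rows.append(row)
            change_idx.append((pos[ea["sample_id"]], pos[la["sample_id"]]))
    if not rows:
        raise ValueError("no subject contributed an interval row")
    frame = pd.DataFrame(rows)
    frame["interval"] = pd.Categorical(frame["interval"], categories=levels, ordered=True)
    ei = np.array([e for e, _ in change_idx])
    li = np.array([l for _, l in change_idx])
    changes = c.values[:, li, :] - c.values[:, ei, :]
    return DeltaTable(frame, changes, c.feature_ids, levels)


@dataclass
class SlopeModelResult:
    """Averaged-over-instances output of the two delta models for one predictor."""

    predictor: str
    marker: str
    beta: float
    se: float
    lrt1_stat: float
    lrt1_df: int
    lrt1_p: float
    lrt2_stat: float
    lrt2_df: int
    lrt2_p: float
    n_obs: int
    n_instances: int
    lrt1_q: float = np.nan
    lrt2_q: float = np.nan
    interval_slopes: pd.DataFrame | None = None
    decision: str = "none"

    def decide(self, alpha: float = 0.05) -> str:
        q1 = self.lrt1_q if np.isfinite(self.lrt1_q) else self.lrt1_p
        q2 = self.lrt2_q if np.isfinite(self.lrt2_q) else self.lrt2_p
        if q2 < alpha:
            self.decision = "interaction"
        elif q1 < alpha:
            self.decision = "common-slope"
        else:
            self.decision = "none"
        return self.decision


def _delta_design(
    frame: pd.DataFrame, predictor: np.ndarray, covariates: list[str], which: str
) -> tuple[pd.DataFrame, list[str]]:
    """Fixed-effects matrix for one of the three nested delta models."""
    iv = frame["interval"].cat.remove_unused_categories()
    obs_levels = list(iv.cat.categories)
    parts = [pd.Series(1.0, index=frame.index, name="Intercept")]
    for lv in obs_levels[1:]:
        parts.append(pd.Series((iv == lv).astype(float), name=f"interval[{lv}]"))
    for cov in covariates:
        col = frame[cov]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).rename(cov))
        else:
            for lev in pd.unique(col.dropna().astype(str))[1:]:
                parts.append(((col.astype(str) == lev).astype(float)).rename(f"{cov}[{lev}]"))
    if which in ("common", "interaction"):
        parts.append(pd.Series(predictor, index=frame.index, name="slope"))
    if which == "interaction":
        for lv in obs_levels[1:]:
            parts.append(
                pd.Series(predictor * (iv == lv).astype(float), name=f"slope:interval[{lv}]")
            )
    return pd.concat(parts, axis=1), obs_levels


def _predictor_values(d: DeltaTable, predictor: str, inst: int) -> np.ndarray:
    if predictor in d.feature_ids:
        return d.feature_changes[inst, :, d.feature_ids.index(predictor)]
    if predictor in d.frame.columns:  # bray_curtis or another marker's change
        return d.frame[predictor].to_numpy(dtype=float)
    raise KeyError(f"unknown predictor {predictor!r}")


def fit_delta_model(
    d: DeltaTable,
    marker: str,
    predictor: str,
    covariates: list[str] = ("delivery_mode", "breastfeeding_weeks"),
    rank_response: bool = True,
    alpha: float = 0.05,
    n_instances: int | None = None,
) -> SlopeModelResult:
    """Common-slope and interaction models of Δmarker on one predictor.

    Fitted once per Monte-Carlo instance (for CLR feature predictors) and
    averaged. Rows with a missing response, predictor or covariate are
    dropped; the response is rank-transformed across the retained rows when
    ``rank_response`` is set. Per-interval slopes are always computed from
    the interaction fit (BH across intervals); the decision rule picks which
    reading applies.
    """
    resp = f"d_{marker}" if f"d_{marker}" in d.frame.columns else marker
    per_feature = predictor in d.feature_ids
    k = (n_instances or d.feature_changes.shape[0]) if per_feature else 1
    acc: list[dict] = []
    slope_acc: list[pd.DataFrame] = []
    for inst in range(k):
        pred = _predictor_values(d, predictor, inst)
        frame = d.frame.copy()
        frame["_pred"] = pred
        frame = frame.dropna(subset=[resp, "_pred", *covariates])
        if frame["interval"].nunique() < 2:
            raise ValueError("need data in at least 2 intervals")
        y = frame[resp].to_numpy(dtype=float)
        if rank_response:
            y = rank_transform(y)
        y = pd.Series(y, index=frame.index)
        pv = frame["_pred"].to_numpy(dtype=float)
        if np.ptp(pv) == 0:
            raise ValueError("predictor is constant across interval rows")
        fits: dict[str, LmmFit] = {}
        for which in ("null", "common", "interaction"):
            X, obs_levels = _delta_design(frame, pv, list(covariates), which)
            if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
                raise ValueError(f"rank-deficient design in {which} delta model")
            fits[which] = _fit_mixedlm(y, X, frame["subject_id"], resp, obs_levels)
        l1 = lrt(fits["common"], fits["null"])
        l2 = lrt(fits["interaction"], fits["common"])
        acc.append(
            {
                "beta": fits["common"].params["slope"],
                "se": float(np.sqrt(fits["common"].cov_params.loc["slope", "slope"])),
                "lrt1_stat": l1.statistic, "lrt1_df": l1.df, "lrt1_p": l1.p,
                "lrt2_stat": l2.statistic, "lrt2_df": l2.df, "lrt2_p": l2.p,
                "n_obs": fits["common"].n_obs,
            }
        )
        slope_acc.append(_interval_slopes(fits["interaction"], obs_levels))
    avg = pd.DataFrame(acc).mean()
    slopes = (
        pd.concat(slope_acc)
        .groupby("interval", sort=False)
        .mean()
        .reset_index()
    )
    slopes["q"] = bh_fdr(slopes["p"])
    result = SlopeModelResult(
        predictor=predictor,
        marker=marker,
        beta=float(avg["beta"]),
        se=float(avg["se"]),
        lrt1_stat=float(avg["lrt1_stat"]),
        lrt1_df=int(avg["lrt1_df"]),
        lrt1_p=float(avg["lrt1_p"]),
        lrt2_stat=float(avg["lrt2_stat"]),
        lrt2_df=int(avg["lrt2_df"]),
        lrt2_p=float(avg["lrt2_p"]),
        n_obs=int(avg["n_obs"]),
        n_instances=k,
        interval_slopes=slopes,
    )
    result.decide(alpha)
    return result


def _interval_slopes(fit: LmmFit, obs_levels: list[str]) -> pd.DataFrame:
    """Marginal slope per interval from the interaction fit (emtrends-style)."""
    df_resid = fit.n_obs - fit.n_fixed
    rows = []
    for lv in obs_levels:
        c = pd.Series(0.0, index=fit.params.index)
        c["slope"] = 1.0
        key = f"slope:interval[{lv}]"
        if key in c.index:
            c[key] = 1.0
        est = float(c @ fit.params)
        se = float(np.sqrt(max(c @ fit.cov_params @ c, 0.0)))
        t_ratio = est / se if se > 0 else 0.0
        rows.append(
            {
                "interval": lv,
                "beta": est,
                "se": se,
                "t_ratio": t_ratio,
                "p": float(2 * stats.t.sf(abs(t_ratio), df_resid)),
            }
        )
    return pd.DataFrame(rows)


def delta_screen(
    d: DeltaTable,
    marker: str,
    features: list[str] | None = None,
    covariates: list[str] = ("delivery_mode", "breastfeeding_weeks"),
    rank_response: bool = True,
    alpha: float = 0.05,
    n_instances: int | None = None,
) -> pd.DataFrame:
    """fit_delta_model per feature with FDR across features per LRT family."""
    features = list(features) if features is not None else list(d.feature_ids)
    rows = []
    results: dict[str, SlopeModelResult] = {}
    for feat in features:
        try:
            res = fit_delta_model(
                d, marker, feat, covariates, rank_response, alpha, n_instances
            )
            results[feat] = res
            rows.append(
                {"feature": feat, "beta": res.beta, "se": res.se,
                 "lrt1_p": res.lrt1_p, "lrt2_p": res.lrt2_p, "n_obs": res.n_obs}
            )
        except (ValueError, KeyError) as exc:
            warnings.warn(f"delta fit failed for {feat!r}: {exc}")
            rows.append(
                {"feature": feat, "beta": np.nan, "se": np.nan,
                 "lrt1_p": np.nan, "lrt2_p": np.nan, "n_obs": np.nan}
            )
    out = pd.DataFrame(rows).set_index("feature")
    out["lrt1_q"] = bh_fdr(out["lrt1_p"])
    out["lrt2_q"] = bh_fdr(out["lrt2_p"])
    decisions = []
    for feat in out.index:
        if feat in results:
            res = results[feat]
            res.lrt1_q = float(out.loc[feat, "lrt1_q"])
            res.lrt2_q = float(out.loc[feat, "lrt2_q"])
            decisions.append(res.decide(alpha))
        else:
            decisions.append("failed")
    out["decision"] = decisions
    out["marker"] = marker
    return out


def interval_overlap(
    marker_contrasts: pd.DataFrame,
    feature_contrasts: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Directional co-occurrence of significant interval changes.

    Both inputs carry time-point pair contrasts with ``pair, estimate, q``
    columns (the feature table additionally has ``feature``). A feature is
    labelled "same" when every interval significant for both the feature and
    the marker changes in the same direction, "opposite" when every shared
    significant interval disagrees, "mixed" otherwise, and "" when no
    interval is significant for both.
    """
    m_pairs = set(marker_contrasts["pair"])
    f_pairs = set(feature_contrasts["pair"])
    if not f_pairs <= m_pairs:
        raise ValueError("contrast tables cover different interval sets")
    m_sig = marker_contrasts[marker_contrasts["q"] < alpha].set_index("pair")["estimate"]
    rows = []
    for feat, g in feature_contrasts.groupby("feature", sort=False):
        f_sig = g[g["q"] < alpha].set_index("pair")["estimate"]
        shared = f_sig.index.intersection(m_sig.index)
        same = int(np.sum(np.sign(f_sig[shared]) == np.sign(m_sig[shared])))
        opposite = len(shared) - same
        if same and not opposite:
            label = "same"
        elif opposite and not same:
            label = "opposite"
        elif same and opposite:
            label = "mixed"
        else:
            label = ""
        rows.append(
            {"feature": feat, "label": label, "n_shared": len(shared),
             "n_same": same, "n_opposite": opposite}
        )
    return pd.DataFrame(rows)
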