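"""Mixed-effects time-course machinery: nested LRTs, time-point contrasts,
rank transforms and Benjamini–Hochberg FDR.

Every response (marker level, alpha index, PCo score, or per-feature CLR
value) is modelled as

    y ~ time_point + covariates + (1 | subject)

fitted by maximum likelihood (REML likelihoods are not comparable across
fixed-effect structures, so ML throughout). The effect of time is tested by
a likelihood-ratio test of the full model against the nested model without
the time factor. Pairwise time-point comparisons use estimated marginal
means: with treatment coding the covariate terms cancel, so each contrast is
a linear combination of the time coefficients with a t reference on
``n_obs − n_fixed`` residual degrees of freedom.

For CLR feature stacks the whole analysis runs once per Monte-Carlo
instance; coefficients, standard errors and BH-adjusted q-values are
averaged across instances.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .compositional import ClrInstanceSet


def rank_transform(x: np.ndarray | pd.Series) -> np.ndarray:
    """Average ranks with ties shared; missing values stay missing."""
    arr = np.asarray(x, dtype=float)
    if np.sum(~np.isnan(arr)) < 2:
        raise ValueError("rank transform needs at least 2 non-missing values")
    return stats.rankdata(arr, method="average", nan_policy="omit")


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    if ok.any():
        vals = arr[ok]
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        m = vals.size
        order = np.argsort(vals, kind="stable")
        scaled = vals[order] * m / np.arange(1, m + 1)
        q = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
        adj = np.empty(m)
        adj[order] = q
        out[ok] = adj
    return out


@dataclass
class LmmFit:
    """A fitted random-intercept model plus what the LRT and contrasts need."""

    response: str
    params: pd.Series
    cov_params: pd.DataFrame
    llf: float
    n_obs: int
    n_subjects: int
    n_fixed: int
    re_variance: float
    resid_variance: float
    time_levels: tuple[str, ...]
    row_index: tuple
    converged: bool


def _covariate_matrix(design: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    cols = {}
    for c in covariates:
        col = design[c]
        if pd.api.types.is_numeric_dtype(col):
            cols[c] = col.astype(float)
        else:
            levels = pd.unique(col.dropna().astype(str))
            for lev in levels[1:]:  # first level is the reference
                cols[f"{c}[{lev}]"] = (col.astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=design.index)


def build_design_matrix(
    design: pd.DataFrame, covariates: list[str], include_time: bool = True
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Fixed-effects matrix: intercept, treatment-coded time, covariates.

    Time levels with no observations are dropped with a warning. Returns the
    matrix and the observed (ordered) time levels.
    """
    tp = design["time_point"]
    observed = [lv for lv in tp.cat.categories if (tp == lv).any()]
    if len(observed) < len(tp.cat.categories):
        warnings.warn("dropping time level(s) with no observations")
    parts = [pd.Series(1.0, index=design.index, name="Intercept")]
    if include_time:
        for lv in observed[1:]:
            parts.append(pd.Series((tp == lv).astype(float), name=f"time[{lv}]"))
    X = pd.concat(parts, axis=1)
    cov = _covariate_matrix(design, covariates)
    if not cov.empty:
        X = pd.concat([X, cov], axis=1)
    return X, tuple(observed)


def _fit_mixedlm(
    y: pd.Series, X: pd.DataFrame, groups: pd.Series, response: str, time_levels
) -> LmmFit:
    if np.ptp(y.to_numpy()) == 0:
        # constant response: every nested model is an equally perfect fit
        params = pd.Series(0.0, index=X.columns)
        params.iloc[0] = float(y.iloc[0])
        return LmmFit(
            response=response,
            params=params,
            cov_params=pd.DataFrame(0.0, index=X.columns, columns=X.columns),
            llf=0.0,
            n_obs=len(y),
            n_subjects=int(groups.nunique()),
            n_fixed=X.shape[1],
            re_variance=0.0,
            resid_variance=0.0,
            time_levels=tuple(time_levels),
            row_index=tuple(y.index),
            converged=True,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = sm.MixedLM(y.to_numpy(), X.to_numpy(), groups=groups.to_numpy())
        try:
            res = model.fit(reml=False)
        except Exception:
            res = model.fit(reml=False, method="powell")
    k = X.shape[1]
    params = pd.Series(res.fe_params, index=X.columns)
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[:k, :k], index=X.columns, columns=X.columns
    )
    return LmmFit(
        response=response,
        params=params,
        cov_params=cov,
        llf=float(res.llf),
        n_obs=len(y),
        n_subjects=int(groups.nunique()),
        n_fixed=k,
        re_variance=float(np.asarray(res.cov_re).ravel()[0]),
        resid_variance=float(res.scale),
        time_levels=tuple(time_levels),
        row_index=tuple(y.index),
        converged=bool(res.converged),
    )


def fit_timecourse(
    y: pd.Series | np.ndarray,
    design: pd.DataFrame,
    covariates: list[str] = (),
    include_time: bool = True,
    response: str = "y",
) -> LmmFit:
    """Fit ``y ~ time + covariates + (1 | subject)`` by ML.

    Rows with missing response or covariates are deleted case-wise. Set
    ``include_time=False`` for the nested null model of the time LRT.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=design.index, name=response)
    cov_cols = list(covariates)
    frame = pd.concat([y, design[["subject_id", "time_point", *cov_cols]]], axis=1)
    frame = frame.dropna(subset=[response, *cov_cols])
    if frame["time_point"].nunique() < 2:
        raise ValueError("need at least 2 observed time levels")
    frame = frame.copy()
    frame["time_point"] = frame["time_point"].cat.remove_unused_categories()
    X, levels = build_design_matrix(frame, cov_cols, include_time=include_time)
    return _fit_mixedlm(frame[response], X, frame["subject_id"], response, levels)


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    p: float


def lrt(full: LmmFit, null: LmmFit) -> LrtResult:
    """Chi-square LRT of nested ML fits; negative statistics clamp to 0."""
    if full.n_obs != null.n_obs or full.row_index != null.row_index:
        raise ValueError("full and null models must be fitted on identical rows")
    df = full.n_fixed - null.n_fixed
    if df <= 0:
        raise ValueError("null model is not nested in the full model")
    statistic = max(0.0, 2.0 * (full.llf - null.llf))
    return LrtResult(statistic, df, float(stats.chi2.sf(statistic, df)))


def pairwise_contrasts(fit: LmmFit) -> pd.DataFrame:
    """All pairwise time-point contrasts from estimated marginal means.

    The estimate is earlier-minus-later, so for an increasing response the
    t-ratio is negative. BH adjustment runs across the pair family. Returns
    columns ``pair, earlier, later, estimate, se, t_ratio, p, q``.
    """
    levels = fit.time_levels
    if len(levels) < 2:
        return pd.DataFrame(
            columns=["pair", "earlier", "later", "estimate", "se", "t_ratio", "p", "q"]
        )
    df_resid = fit.n_obs - fit.n_fixed
    rows = []
    for a, b in itertools.combinations(levels, 2):  # a earlier than b
        c = pd.Series(0.0, index=fit.params.index)
        if f"time[{a}]" in c.index:
            c[f"time[{a}]"] += 1.0
        if f"time[{b}]" in c.index:
            c[f"time[{b}]"] -= 1.0
        est = float(c @ fit.params)
        se = float(np.sqrt(max(c @ fit.cov_params @ c, 0.0)))
        t_ratio = est / se if se > 0 else 0.0
        p = float(2 * stats.t.sf(abs(t_ratio), df_resid))
        rows.append(
            {
                "pair": f"{a}-{b}",
                "earlier": a,
                "later": b,
                "estimate": est,
                "se": se,
                "t_ratio": t_ratio,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"])
    return out


def timecourse_lrt(
    y, design: pd.DataFrame, covariates: list[str] = (), response: str = "y"
) -> tuple[LmmFit, LrtResult, pd.DataFrame]:
    """Convenience: full fit, LRT of the time factor, and pairwise contrasts."""
    full = fit_timecourse(y, design, covariates, include_time=True, response=response)
    null = fit_timecourse(y, design, covariates, include_time=False, response=response)
    return full, lrt(full, null), pairwise_contrasts(full)


def per_feature_timecourse(
    c: ClrInstanceSet,
    design: pd.DataFrame,
    covariates: list[str] = (),
    fdr_alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature time-course screen over CLR Monte-Carlo instances.

    For every feature and instance the full/null pair is fitted and the time
    LRT and pairwise contrasts computed. Within each instance, BH runs across
    features (overall LRT family) and across all feature × pair cells
    (contrast family). Coefficients, SEs, p and q are then averaged over
    instances.

    Returns ``(overall, contrasts)``: the overall table is indexed by feature
    with ``lrt_stat, lrt_df, lrt_p, lrt_q, n_instances``; the contrast table
    has one row per feature × pair with averaged ``estimate, se, t_ratio, p, q``.
    """
    design = design.loc[list(c.sample_ids)]
    overall_acc: list[pd.DataFrame] = []
    contrast_acc: list[pd.DataFrame] = []
    for inst in range(c.n_instances):
        o_rows, c_frames = [], []
        for j, feat in enumerate(c.feature_ids):
            y = c.values[inst, :, j]
            try:
                full, res, contr = timecourse_lrt(y, design, covariates, response=feat)
            except Exception as exc:  # propagate as a missing row, not a crash
                warnings.warn(f"fit failed for feature {feat!r}: {exc}")
                o_rows.append(
                    {"feature": feat, "lrt_stat": np.nan, "lrt_df": np.nan, "lrt_p": np.nan}
                )
                continue
            o_rows.append(
                {
                    "feature": feat,
                    "lrt_stat": res.statistic,
                    "lrt_df": res.df,
                    "lrt_p": res.p,
                }
            )
            contr = contr.drop(columns="q")
            contr.insert(0, "feature", feat)
            c_frames.append(contr)
        overall = pd.DataFrame(o_rows).set_index("feature")
        overall["lrt_q"] = bh_fdr(overall["lrt_p"])
        overall_acc.append(overall)
        contrasts = pd.concat(c_frames, ignore_index=True)
        contrasts["q"] = bh_fdr(contrasts["p"])  # one family: all feature × pair cells
        contrast_acc.append(contrasts.set_index(["feature", "pair"]))

    overall_avg = (
        pd.concat(overall_acc).groupby(level=0, sort=False).mean()
    ).loc[list(c.feature_ids)]
    overall_avg["n_instances"] = c.n_instances
    overall_avg["significant"] = overall_avg["lrt_q"] < fdr_alpha
    num_cols = ["estimate", "se", "t_ratio", "p", "q"]
    contrast_avg = (
        pd.concat(contrast_acc)[num_cols + ["earlier", "later"]]
        .groupby(level=[0, 1], sort=False)
        .agg({**{k: "mean" for k in num_cols}, "earlier": "first", "later": "first"})
        .reset_index()
    )
    return overall_avg, contrast_avg
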