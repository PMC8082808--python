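"""Repeated-measures correlation (rmcorr).

rmcorr estimates the common within-subject association between two
repeatedly measured variables via an analysis of covariance with subject as
a factor and one variable as the covariate — equivalent to a random-
intercept mixed model. The correlation is

    r = sign(b) * sqrt(SS_x / (SS_x + SS_error)),  df = n_obs − n_subjects − 1,

where ``b`` is the pooled within-subject slope and SS_x the sum of squares
attributable to the covariate after the subject factor. Significance comes
from F(1, df) = SS_x / (SS_error / df).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .compositional import ClrInstanceSet
from .models import bh_fdr, rank_transform


@dataclass(frozen=True)
class RmcorrResult:
    r: float
    df: int
    p: float
    n_obs: int
    n_subjects: int


def rmcorr(
    subject: np.ndarray | pd.Series,
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    allow_single_subject: bool = False,
) -> RmcorrResult:
    """Repeated-measures correlation of x and y over subjects.

    Incomplete pairs are removed case-wise; subjects left with fewer than two
    complete pairs are dropped. With ``allow_single_subject`` the degenerate
    one-subject case is permitted, where r reduces to the ordinary Pearson
    correlation with df = n − 2.
    """
    frame = pd.DataFrame(
        {
            "subject": np.asarray(subject, dtype=object),
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=float),
        }
    ).dropna()
    frame = frame.groupby("subject").filter(lambda g: len(g) >= 2)
    k = frame["subject"].nunique()
    if k < (1 if allow_single_subject else 2):
        raise ValueError("need at least 2 subjects with >= 2 complete pairs")
    n = len(frame)
    df_error = n - k - 1
    if df_error <= 0:
        raise ValueError(f"non-positive error df ({df_error}); too few observations")

    xc = frame["x"] - frame.groupby("subject")["x"].transform("mean")
    if np.allclose(xc, 0.0):
        raise ValueError("covariate constant within every subject; r undefined")

    dummies = pd.get_dummies(frame["subject"], drop_first=False, dtype=float)
    X_null = dummies.to_numpy()
    X_full = np.column_stack([X_null, frame["x"].to_numpy()])
    yv = frame["y"].to_numpy()
    fit_null = sm.OLS(yv, X_null).fit()
    fit_full = sm.OLS(yv, X_full).fit()
    ss_err = float(fit_full.ssr)
    ss_x = float(fit_null.ssr) - ss_err
    if ss_x + ss_err <= 0 or not np.isfinite(fit_full.params[-1]):
        raise ValueError("covariate constant within every subject; r undefined")
    slope = float(fit_full.params[-1])
    ss_x = max(ss_x, 0.0)
    r = float(np.sign(slope) * np.sqrt(ss_x / (ss_x + ss_err)))
    if slope == 0.0:
        r = 0.0
    f_stat = ss_x / (ss_err / df_error) if ss_err > 0 else np.inf
    p = float(stats.f.sf(f_stat, 1, df_error))
    return RmcorrResult(r=r, df=df_error, p=p, n_obs=n, n_subjects=k)


def rmcorr_screen(
    features: pd.DataFrame,
    design: pd.DataFrame,
    markers: list[str],
    rank: bool = True,
) -> pd.DataFrame:
    """rmcorr of every feature column against every marker, BH per marker.

    ``features`` is samples × features aligned to ``design``; markers are
    rank-transformed when ``rank`` is set. Failed fits become missing rows.
    """
    design = design.loc[features.index]
    rows = []
    for marker in markers:
        m = design[marker].to_numpy(dtype=float)
        if rank:
            m = rank_transform(m)
        for feat in features.columns:
            try:
                res = rmcorr(design["subject_id"], features[feat], m)
                rows.append(
                    {
                        "marker": marker,
                        "feature": feat,
                        "r": res.r,
                        "df": res.df,
                        "p": res.p,
                        "n_obs": res.n_obs,
                        "n_subjects": res.n_subjects,
                    }
                )
            except ValueError:
                rows.append(
                    {"marker": marker, "feature": feat, "r": np.nan, "df": np.nan,
                     "p": np.nan, "n_obs": np.nan, "n_subjects": np.nan}
                )
    out = pd.DataFrame(rows)
    out["q"] = out.groupby("marker")["p"].transform(lambda p: bh_fdr(p))
    return out


def rmcorr_screen_clr(
    c: ClrInstanceSet,
    design: pd.DataFrame,
    markers: list[str],
    rank: bool = True,
) -> pd.DataFrame:
    """Instance-wise rmcorr screen on a CLR stack, averaged over instances."""
    per_instance = []
    for inst in range(c.n_instances):
        features = pd.DataFrame(
            c.values[inst], index=list(c.sample_ids), columns=list(c.feature_ids)
        )
        scr = rmcorr_screen(features, design, markers, rank=rank)
        per_instance.append(scr.set_index(["marker", "feature"]))
    avg = (
        pd.concat(per_instance)
        .groupby(level=[0, 1], sort=False)
        .mean()
        .reset_index()
    )
    avg["n_instances"] = c.n_instances
    return avg
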