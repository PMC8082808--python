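"""Alpha/beta diversity, principal coordinates and the partial Mantel test.

Alpha indices are computed per rarefaction cycle and summarised as the
median across cycles, which stabilises the subsampling noise. Beta
diversity (Bray–Curtis) and its PCoA embedding use the canonical (first,
seeded) rarefied table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as skalpha
from skbio.stats.distance import DistanceMatrix as SkbioDM
from skbio.stats.ordination import pcoa as skbio_pcoa

from .compositional import RarefiedSet
from .io_config import CountTable

ALPHA_INDICES = ("shannon", "simpson", "chao1", "evenness")


@dataclass(frozen=True)
class DistanceMatrix:
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids),) * 2:
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        object.__setattr__(self, "values", v)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class Ordination:
    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # samples × axes, positive eigenvalues only
    eigenvalues: np.ndarray  # all, descending (negatives reported, not corrected)
    proportion_explained: np.ndarray

    def scores(self, axis: int) -> pd.Series:
        return pd.Series(
            self.coordinates[:, axis], index=list(self.sample_ids), name=f"PCo{axis + 1}"
        )


def _alpha_row(counts: np.ndarray) -> dict[str, float]:
    if counts.sum() == 0:
        raise ValueError("sample with zero reads has undefined diversity")
    s_obs = int((counts > 0).sum())
    h = skalpha.shannon(counts, base=np.e)
    return {
        "shannon": h,
        "simpson": skalpha.simpson(counts),  # Gini–Simpson, 1 − Σp²
        "chao1": skalpha.chao1(counts, bias_corrected=True),
        "evenness": h / np.log(s_obs) if s_obs > 1 else np.nan,  # Pielou; undefined at S=1
    }


def alpha_diversity(r: RarefiedSet) -> pd.DataFrame:
    """Median Shannon/Gini–Simpson/Chao1/Pielou evenness across cycles."""
    per_cycle = []
    for table in r.tables:
        rows = [_alpha_row(table.counts[i]) for i in range(table.n_samples)]
        per_cycle.append(pd.DataFrame(rows, index=list(table.sample_ids)))
    med = (
        pd.concat(per_cycle)
        .groupby(level=0, sort=False)
        .median()
        .loc[list(r.sample_ids)]
    )
    med["cycles_used"] = r.cycles
    return med


def bray_curtis(t: CountTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity, d(i,j) = Σ|x−y| / Σ(x+y), on a rarefied table."""
    d = squareform(pdist(t.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(t.sample_ids, d)


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> Ordination:
    """Classical PCoA (Gower centering + eigendecomposition).

    Axes are returned for positive eigenvalues only; negative eigenvalues are
    reported in ``eigenvalues`` without Cailliez/Lingoes correction. Requests
    beyond the positive-eigenvalue count are truncated with a warning.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns on negative eigenvalues
        res = skbio_pcoa(SkbioDM(d.values, ids=list(d.sample_ids)), method="eigh")
    eig = res.eigvals.to_numpy()
    n_pos = int((eig > 1e-10).sum())
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating"
        )
        n_axes = n_pos
    coords = res.samples.to_numpy()[:, :n_axes]
    return Ordination(
        d.sample_ids, coords, eig, res.proportion_explained.to_numpy()
    )


def _offdiag_pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def mantel_partial(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    d3: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Partial Mantel test: correlation of d1 and d2 controlling for d3.

    The statistic is the first-order partial Pearson correlation of the
    off-diagonal entries. The null distribution permutes rows/columns of d1
    jointly; the p-value is one-sided (greater), counting the observed
    statistic itself among the permutations.
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    if not (d1.sample_ids == d2.sample_ids == d3.sample_ids):
        raise ValueError("distance matrices must share the same sample set")
    v1, v2, v3 = d1.condensed(), d2.condensed(), d3.condensed()
    for name, v in (("d1", v1), ("d2", v2), ("d3", v3)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant; Mantel statistic undefined")

    def partial_r(x: np.ndarray) -> float:
        r12 = _offdiag_pearson(x, v2)
        r13 = _offdiag_pearson(x, v3)
        r23 = _offdiag_pearson(v2, v3)
        return (r12 - r13 * r23) / np.sqrt((1 - r13**2) * (1 - r23**2))

    observed = partial_r(v1)
    rng = np.random.default_rng(seed)
    n = len(d1.sample_ids)
    m1 = d1.values
    hits = 1  # the identity permutation
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = squareform(m1[np.ix_(perm, perm)], checks=False)
        if partial_r(vp) >= observed:
            hits += 1
    return observed, hits / (n_perm + 1)


def subject_incongruence(sample_ids: list[str], subjects: pd.Series) -> DistanceMatrix:
    """0/1 matrix: 0 for samples from the same subject, 1 otherwise."""
    subj = subjects.loc[list(sample_ids)].to_numpy()
    mat = (subj[:, None] != subj[None, :]).astype(float)
    return DistanceMatrix(tuple(sample_ids), mat)


def time_interval_matrix(sample_ids: list[str], time_index: pd.Series) -> DistanceMatrix:
    """|Δ time index| between samples, from the ordered time-point codes."""
    t = time_index.loc[list(sample_ids)].to_numpy(dtype=float)
    return DistanceMatrix(tuple(sample_ids), np.abs(t[:, None] - t[None, :]))
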