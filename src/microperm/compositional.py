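"""Rarefaction and Dirichlet Monte-Carlo CLR transformation.

Sequencing counts are compositional: only relative information is
interpretable, and low-count samples carry large uncertainty about the
underlying proportions. Two complementary devices are used here:

* **rarefaction** — repeated subsampling without replacement to a common
  read depth, removing library-size effects before diversity calculations;
* **Dirichlet Monte-Carlo CLR** — for each sample, proportions are drawn
  repeatedly from a Dirichlet posterior centred on the observed counts
  (counts + a uniform pseudo-count prior), and each draw is mapped to the
  centred log-ratio (CLR) scale ``log p_i − mean(log p)``. Downstream models
  are fitted once per instance and averaged, propagating count uncertainty
  into the inference.

The CLR uses the natural log; the base only rescales coefficients by a
constant and cancels in every test statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_config import CountTable


@dataclass(frozen=True)
class RarefiedSet:
    """Per-cycle rarefied tables at a common depth.

    ``tables`` holds one CountTable per cycle over the retained samples;
    ``dropped_samples`` lists samples whose total reads fell below ``depth``.
    """

    depth: int
    cycles: int
    tables: tuple[CountTable, ...]
    dropped_samples: tuple[str, ...]

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.tables[0].sample_ids

    @property
    def canonical(self) -> CountTable:
        """First cycle — the seeded draw used for beta diversity."""
        return self.tables[0]


@dataclass(frozen=True)
class ClrInstanceSet:
    """Stack of Monte-Carlo CLR matrices, ``values[instance, sample, feature]``."""

    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray
    prior: float
    log_base: str = "e"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("values must be instances × samples × features")
        if v.shape[1] != len(self.sample_ids) or v.shape[2] != len(self.feature_ids):
            raise ValueError("values shape does not match identifiers")
        object.__setattr__(self, "values", v)

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]


def auto_depth(t: CountTable, floor: int = 1000) -> int:
    """Depth = smallest per-sample total at or above ``floor``.

    Samples below the floor are treated as failed libraries and excluded from
    the depth computation (they are then dropped by :func:`rarefy`).
    """
    totals = t.counts.sum(axis=1)
    retained = totals[totals >= floor]
    if retained.size == 0:
        raise ValueError(f"no sample reaches the read floor of {floor}")
    return int(retained.min())


def rarefy(t: CountTable, depth: int, cycles: int = 10, seed: int = 0) -> RarefiedSet:
    """Subsample each sample's reads without replacement to exactly ``depth``.

    Samples with fewer than ``depth`` total reads are listed in
    ``dropped_samples`` and excluded from every cycle. Each cycle is an
    independent multivariate-hypergeometric draw from the sample's reads.
    """
    if depth < 1 or cycles < 1:
        raise ValueError("depth and cycles must be positive")
    totals = t.counts.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"rarefaction depth {depth} exceeds every sample's total")
    dropped = tuple(s for s, k in zip(t.sample_ids, keep) if not k)
    kept_ids = tuple(s for s, k in zip(t.sample_ids, keep) if k)
    counts = t.counts[keep]
    rng = np.random.default_rng(seed)
    tables = []
    for _ in range(cycles):
        sub = np.empty_like(counts)
        for i in range(counts.shape[0]):
            sub[i] = rng.multivariate_hypergeometric(counts[i], depth)
        tables.append(CountTable(kept_ids, t.feature_ids, sub))
    return RarefiedSet(depth, cycles, tuple(tables), dropped)


def dirichlet_clr(
    t: CountTable, n_instances: int = 128, prior: float = 0.5, seed: int = 0
) -> ClrInstanceSet:
    """Draw CLR instances from per-sample Dirichlet(counts + prior) posteriors.

    Each instance draws, per sample, a proportion vector from
    Dirichlet(counts + prior) and maps it to ``log p − mean(log p)``. The
    draws use the gamma representation so the whole stack is one vectorised,
    seed-reproducible operation.
    """
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    if prior <= 0:
        raise ValueError("prior must be > 0")
    zero = t.counts.sum(axis=1) == 0
    if zero.any():
        bad = t.sample_ids[int(np.argmax(zero))]
        raise ValueError(f"sample {bad!r} has all-zero counts; composition undefined")
    alpha = t.counts.astype(float) + prior
    rng = np.random.default_rng(seed)
    gammas = rng.standard_gamma(alpha, size=(n_instances, *alpha.shape))
    logp = np.log(gammas) - np.log(gammas.sum(axis=2, keepdims=True))
    clr = logp - logp.mean(axis=2, keepdims=True)
    return ClrInstanceSet(t.sample_ids, t.feature_ids, clr, prior)


def instance_mean(c: ClrInstanceSet) -> np.ndarray:
    """Arithmetic mean over the instance axis; rows still sum to zero."""
    return c.values.mean(axis=0)
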