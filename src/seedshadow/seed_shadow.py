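"""Observation model linking mapped stands to seed-trap counts.

The expected count in a trap is the trap area times the sum, over every
mapped conspecific tree at the site, of that tree's seed shadow evaluated at
the trap: fecundity (proportional to basal area, with a lognormal site-level
multiplier) times the dispersal kernel at the trap-tree distance.  Observed
counts are modelled as negative binomial around this mean with a
second-degree polynomial mean-variance relationship,
``Var = mu (1 + k1) + k2 mu^2``.

Coordinates are planar metres (UTM-like); distances are Euclidean.  All
mapped trees at a site are treated as potential contributors to every trap
at that site; trees outside the mapping radius of the field protocol are
simply absent from the data, an edge-truncation the model inherits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .kernels import KernelSpec, kernel_pdf

__all__ = [
    "ISLANDS",
    "TreeRecord",
    "TrapRecord",
    "FecundityParams",
    "NBDispersion",
    "StandData",
    "basal_area_m2",
    "expected_trap_count",
    "nb_loglik",
    "stand_loglik",
    "simulate_trap_counts",
]

ISLANDS = ("Guam", "Rota", "Saipan", "Tinian")


def basal_area_m2(dbh_cm: float) -> float:
    """Circular-stem basal area in m^2 from diameter at breast height in cm."""
    if dbh_cm <= 0:
        raise ValueError(f"dbh must be positive, got {dbh_cm}")
    return math.pi * (dbh_cm / 200.0) ** 2


@dataclass(frozen=True)
class TreeRecord:
    """A mapped conspecific tree: position, size and site membership."""

    tree_id: str
    site_id: str
    island: str
    x: float
    y: float
    dbh_cm: float

    def __post_init__(self):
        if self.island not in ISLANDS:
            raise ValueError(f"unknown island {self.island!r}")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("tree coordinates must be finite")
        if self.dbh_cm <= 0:
            raise ValueError("dbh must be positive")

    @property
    def basal_area(self) -> float:
        return basal_area_m2(self.dbh_cm)


@dataclass(frozen=True)
class TrapRecord:
    """A seed trap: position, catch area, season-total count, and the
    ingested/flesh-covered classification of its seeds."""

    trap_id: str
    site_id: str
    island: str
    x: float
    y: float
    area_m2: float
    seed_count: int = 0
    ingested_count: int = 0
    total_classified: int = 0

    def __post_init__(self):
        if self.island not in ISLANDS:
            raise ValueError(f"unknown island {self.island!r}")
        if self.area_m2 <= 0:
            raise ValueError("trap area must be positive")
        if self.seed_count < 0:
            raise ValueError("seed count must be nonnegative")
        if not 0 <= self.ingested_count <= self.total_classified:
            raise ValueError("need 0 <= ingested_count <= total_classified")


@dataclass(frozen=True)
class FecundityParams:
    """Lognormal site-level fecundity-per-basal-area multipliers.

    ``beta_s[site]`` has units seeds per m^2 of basal area; across sites
    ``log beta_s ~ Normal(mu_beta, sigma_beta^2)``.
    """

    mu_beta: float
    sigma_beta: float
    beta_s: dict[str, float]

    def __post_init__(self):
        if self.sigma_beta < 0:
            raise ValueError("sigma_beta must be >= 0")
        for site, b in self.beta_s.items():
            if b <= 0:
                raise ValueError(f"beta_s[{site!r}] must be positive")


@dataclass(frozen=True)
class NBDispersion:
    """Negative-binomial overdispersion: ``Var = mu (1 + k1) + k2 mu^2``.

    The NB size parameter is ``n = mu / (k1 + k2 mu)``; as ``(k1, k2) -> 0``
    the distribution tends to Poisson.
    """

    k1: float
    k2: float

    def __post_init__(self):
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("k1 and k2 must be nonnegative")

    def variance(self, mu):
        mu = np.asarray(mu, dtype=float)
        return mu * (1.0 + self.k1) + self.k2 * mu**2


def expected_trap_count(
    trap: TrapRecord,
    trees: Iterable[TreeRecord],
    spec: KernelSpec,
    fec: FecundityParams,
) -> float:
    """Expected seed count in one trap given the mapped trees at its site.

    ``mu = A * sum_i beta_s * b_i * f(r_i)`` with ``r_i`` the Euclidean
    trap-tree distance.  Additive in trees; zero for an empty stand.
    """
    trees = list(trees)
    for t in trees:
        if t.site_id != trap.site_id:
            raise ValueError(
                f"tree {t.tree_id!r} (site {t.site_id!r}) does not share "
                f"a site with trap {trap.trap_id!r} (site {trap.site_id!r})"
            )
    if not trees:
        return 0.0
    beta = fec.beta_s[trap.site_id]
    dist = np.hypot(
        np.array([t.x for t in trees]) - trap.x,
        np.array([t.y for t in trees]) - trap.y,
    )
    b = np.array([t.basal_area for t in trees])
    f = np.asarray(kernel_pdf(spec, dist))
    return float(trap.area_m2 * beta * np.sum(b * f))


def nb_loglik(s, mu, disp: NBDispersion):
    """Negative-binomial log-likelihood of counts ``s`` given means ``mu``.

    Vectorized over ``s`` and ``mu`` (broadcast).  ``mu = 0`` is handled as
    a limit: 0 if ``s = 0`` and -inf otherwise, so samplers can reject
    rather than crash.  Near-zero overdispersion falls back to the Poisson
    log-pmf.
    """
    s = np.asarray(s)
    if np.any(s < 0) or not np.issubdtype(s.dtype, np.integer) and np.any(s != np.floor(s)):
        raise ValueError("counts must be nonnegative integers")
    s = s.astype(float)
    mu = np.asarray(mu, dtype=float)
    s, mu = np.broadcast_arrays(s, mu)
    out = np.empty(s.shape, dtype=float)

    zero_mu = mu <= 0.0
    out[zero_mu] = np.where(s[zero_mu] == 0, 0.0, -np.inf)

    ok = ~zero_mu
    s_, mu_ = s[ok], mu[ok]
    excess = disp.k1 + disp.k2 * mu_  # Var = mu (1 + excess)
    pois = excess < 1e-12
    nb = ~pois
    ll = np.empty(s_.shape, dtype=float)
    # Poisson limit
    ll[pois] = s_[pois] * np.log(mu_[pois]) - mu_[pois] - gammaln(s_[pois] + 1.0)
    # NB with size n and mean mu: p = n / (n + mu)
    n = mu_[nb] / excess[nb]
    m = mu_[nb]
    ll[nb] = (
        gammaln(s_[nb] + n)
        - gammaln(n)
        - gammaln(s_[nb] + 1.0)
        + n * np.log(n / (n + m))
        + s_[nb] * np.log(m / (n + m))
    )
    out[ok] = ll
    if out.ndim == 0:
        return float(out)
    return out


class StandData:
    """Mapped trees plus traps for one species across sites and islands.

    Wraps two DataFrames (schemas below) and precomputes the flat
    (trap, tree) pair arrays that make repeated likelihood evaluation cheap.

    trees columns:  tree_id, site_id, island, x_m, y_m, dbh_cm
    traps columns:  trap_id, site_id, island, x_m, y_m, area_m2, seed_count,
                    ingested_count, total_classified
    """

    def __init__(self, trees: pd.DataFrame, traps: pd.DataFrame):
        self.trees = trees.reset_index(drop=True)
        self.traps = traps.reset_index(drop=True)
        bad = set(self.traps.site_id) - set(self.trees.site_id)
        if bad:
            raise ValueError(f"traps reference sites with no mapped trees: {sorted(bad)}")
        self.sites = sorted(self.traps.site_id.unique())
        self.site_index = {s: i for i, s in enumerate(self.sites)}
        self._build_pairs()

    def _build_pairs(self) -> None:
        """Flatten same-site (trap, tree) pairs, sorted by trap, for
        segment-summed seed-shadow evaluation."""
        traps, trees = self.traps, self.trees
        n_traps = len(traps)
        pair_dist, pair_b, pair_trap = [], [], []
        trees_by_site = dict(tuple(trees.groupby("site_id")))
        for j in range(n_traps):
            row = traps.iloc[j]
            tt = trees_by_site.get(row.site_id)
            if tt is None:
                continue
            d = np.hypot(tt.x_m.to_numpy() - row.x_m, tt.y_m.to_numpy() - row.y_m)
            b = np.pi * (tt.dbh_cm.to_numpy() / 200.0) ** 2
            pair_dist.append(d)
            pair_b.append(b)
            pair_trap.append(np.full(len(d), j))
        self.pair_dist = np.concatenate(pair_dist) if pair_dist else np.empty(0)
        self.pair_b = np.concatenate(pair_b) if pair_b else np.empty(0)
        pair_trap_idx = np.concatenate(pair_trap) if pair_trap else np.empty(0, int)
        self.pair_trap_idx = pair_trap_idx.astype(int)
        # reduceat segment starts: one segment per trap (possibly empty)
        counts = np.bincount(pair_trap_idx.astype(int), minlength=n_traps)
        self.pair_counts = counts
        self.segment_starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.trap_area = traps.area_m2.to_numpy(dtype=float)
        self.trap_site_idx = traps.site_id.map(self.site_index).to_numpy()
        self.trap_island = traps.island.to_numpy()
        self.counts = traps.seed_count.to_numpy(dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def expected_counts(self, spec_per_trap_a: np.ndarray, family: str, p: float,
                        beta_per_site: np.ndarray) -> np.ndarray:
        """Expected counts for all traps given per-trap kernel scales and
        per-site fecundity multipliers (single parameter set)."""
        a_pair = np.repeat(spec_per_trap_a, self.pair_counts)
        f = kernel_pdf(KernelSpec(family, 1.0, p), self.pair_dist / a_pair) / a_pair**2
        shadow = self.pair_b * f
        per_trap = np.add.reduceat(shadow, self.segment_starts) if len(shadow) else np.zeros(len(self.counts))
        per_trap[self.pair_counts == 0] = 0.0
        return self.trap_area * beta_per_site[self.trap_site_idx] * per_trap


def stand_loglik(
    stand: StandData,
    spec_by_island: dict[str, KernelSpec],
    fec: FecundityParams,
    disp: NBDispersion,
) -> float:
    """Total NB log-likelihood of the observed trap counts.

    The total is the sum of pointwise log-likelihoods over all traps at all
    sites (the data are conditionally independent given the parameters).
    """
    fam = next(iter(spec_by_island.values())).family
    p = next(iter(spec_by_island.values())).p
    a_per_trap = np.array([spec_by_island[isl].a for isl in stand.trap_island])
    beta = np.array([fec.beta_s[s] for s in stand.sites])
    mu = stand.expected_counts(a_per_trap, fam, p, beta)
    return float(np.sum(nb_loglik(stand.counts, mu, disp)))


def simulate_trap_counts(
    traps: Sequence[TrapRecord],
    trees: Sequence[TreeRecord],
    spec: KernelSpec,
    fec: FecundityParams,
    disp: NBDispersion,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one NB count per trap from the seed-shadow model (generative
    twin of the likelihood).  Reproducible given the generator state."""
    trees_by_site: dict[str, list[TreeRecord]] = {}
    for t in trees:
        trees_by_site.setdefault(t.site_id, []).append(t)
    counts = np.empty(len(traps), dtype=np.int64)
    for j, trap in enumerate(traps):
        mu = expected_trap_count(trap, trees_by_site.get(trap.site_id, []), spec, fec)
        if mu <= 0:
            counts[j] = 0
            continue
        excess = disp.k1 + disp.k2 * mu
        if excess < 1e-12:
            counts[j] = rng.poisson(mu)
        else:
            n = mu / excess
            counts[j] = rng.negative_binomial(n, n / (n + mu))
    return counts
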