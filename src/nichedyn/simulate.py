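"""Virtual-species scenarios with known niche-change ground truth.

Two rectangular regions carry linear climate gradients with offset extents,
so their climate envelopes overlap but are unequal — the analog climate is
the intersection.  A virtual species occupies climate space with probability
proportional to a truncated Gaussian around its niche optimum; presences are
cells sampled without replacement with those weights (one presence per cell,
as in rasterized range maps).  Niche change is induced by exactly the two
mechanisms the indices are meant to separate:

* unfilling — the alien presences are restricted to a geometric *mask* (a
  subset of the alien region), emulating incomplete colonization;
* expansion — the alien niche optimum is shifted by ``delta``, emulating
  occupation of conditions unused in the native range.

``true_niche_metrics`` integrates the truncated occupancy densities over a
fine climate-space reference grid using the same definitions (and the same
mass-quantile occupancy support) as the empirical pipeline, giving analytic
expansion/unfilling values every downstream estimate can be scored against.

A second generator emits driver tables: 11 species-by-realm covariates with
realistic skew and link-scale linear effects (with realm/order random
intercepts) on a binary expansion response and a beta-distributed unfilling
response, with the true coefficients stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import ClimateGrid, ContractError, RangeSet
from .drivers import (
    DRIVER_NAMES,
    introduction_effort,
    prepare_design,
    specialization_index,
)
from .dynamics import DEFAULT_OCCUPANCY_QUANTILE, mass_quantile_support

__all__ = [
    "VariableGradient",
    "NicheSpec",
    "SyntheticScenario",
    "DriverScenario",
    "generate_climate_region",
    "sample_virtual_presences",
    "true_niche_metrics",
    "make_scenario",
    "generate_driver_table",
]


@dataclass
class VariableGradient:
    """Linear spatial field for one climate variable:
    ``value = base + slope_x * x + slope_y * y + N(0, noise_sd)``."""

    name: str
    base: float = 0.0
    slope_x: float = 0.0
    slope_y: float = 0.0
    noise_sd: float = 0.0


@dataclass
class NicheSpec:
    """Gaussian niche in climate space.

    Occupancy probability is ``p_max * exp(-1/2 (c-mu)' Sigma^-1 (c-mu))``,
    truncated to the climates available in the region (and to the sampling
    mask, if any).
    """

    mean: np.ndarray
    covariance: np.ndarray
    p_max: float = 1.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if not np.allclose(self.covariance, self.covariance.T):
            raise ContractError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.covariance) <= 0):
            raise ContractError("covariance must be positive definite")
        if not 0.0 < self.p_max <= 1.0:
            raise ContractError("p_max must be in (0, 1]")


def generate_climate_region(
    region_id: str,
    extent: tuple[float, float, float, float],
    n_cells: int,
    gradients: list[VariableGradient],
    seed: int,
    cell_id_start: int = 0,
) -> ClimateGrid:
    """Lay ``n_cells`` on a regular lattice over ``extent`` and evaluate
    the climate gradients (deterministic for a fixed seed)."""
    x0, x1, y0, y1 = extent
    if not (x1 > x0 and y1 > y0):
        raise ContractError("degenerate extent")
    if n_cells < 100:
        raise ContractError("need at least 100 cells")
    if len(gradients) < 2:
        raise ContractError("need at least 2 climate variables")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_cells)))
    gx = np.linspace(x0, x1, side)
    gy = np.linspace(y0, y1, side)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    x = X.ravel()[:n_cells]
    y = Y.ravel()[:n_cells]
    climate = np.empty((n_cells, len(gradients)))
    for j, g in enumerate(gradients):
        climate[:, j] = g.base + g.slope_x * x + g.slope_y * y
        if g.noise_sd > 0:
            climate[:, j] += rng.normal(0.0, g.noise_sd, size=n_cells)
    return ClimateGrid(
        region_id=region_id,
        cell_ids=np.arange(cell_id_start, cell_id_start + n_cells),
        xy=np.column_stack([x, y]),
        climate=climate,
        variables=[g.name for g in gradients],
    )


def sample_virtual_presences(
    grid: ClimateGrid,
    niche: NicheSpec,
    n_target: int,
    species_id: str,
    role: str,
    realm_id: str,
    mask: np.ndarray | None = None,
    seed: int = 0,
) -> RangeSet:
    """Sample ``n_target`` distinct presence cells without replacement.

    Cell weights are the truncated-Gaussian occupancy probabilities; the
    optional ``mask`` (an array of cell ids) restricts the candidate cells.
    Sampling uses the Gumbel-top-k trick, which is distributionally
    equivalent to successive weighted draws without replacement.
    """
    if mask is not None:
        mask_ids = np.asarray(mask, dtype=np.int64)
        unknown = set(map(int, mask_ids)) - set(map(int, grid.cell_ids))
        if unknown:
            raise ContractError(f"mask contains unknown cell ids: {sorted(unknown)[:5]}")
        rows = grid.rows_for(mask_ids)
    else:
        mask_ids = grid.cell_ids
        rows = np.arange(grid.n_cells)
    if len(rows) < n_target:
        raise ContractError(
            f"cannot draw {n_target} distinct cells from {len(rows)} candidates"
        )
    C = grid.climate[rows]
    d = C - niche.mean
    inv = np.linalg.inv(niche.covariance)
    logw = -0.5 * np.einsum("ij,jk,ik->i", d, inv, d)
    rng = np.random.default_rng(seed)
    gumbel = rng.gumbel(size=len(rows))
    take = np.argpartition(-(logw + gumbel), n_target - 1)[:n_target]
    cells = frozenset(int(c) for c in np.asarray(mask_ids)[take])
    return RangeSet(species_id, role, realm_id, cells)


# ---------------------------------------------------------------------------
# Analytic truth

Box = tuple[tuple[float, float], tuple[float, float]]


def true_niche_metrics(
    niche: NicheSpec,
    delta: np.ndarray,
    native_box: Box,
    alien_box: Box,
    mask_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    resolution: int = 500,
    occupancy_quantile: float = DEFAULT_OCCUPANCY_QUANTILE,
) -> tuple[float, float, float]:
    """Analytic (expansion, stability, unfilling) for a 2-variable scenario.

    The native occupancy density is the niche Gaussian truncated to the
    native climate envelope ``native_box``; the alien density is the same
    Gaussian shifted by ``delta`` and truncated to the alien envelope
    intersected with the sampling mask (``mask_fn`` maps an (n, 2) climate
    matrix to a boolean vector).  Both densities are integrated on a
    ``resolution`` x ``resolution`` reference grid over the union envelope;
    analog climates are the envelope intersection; the occupied sets use the
    mass-quantile support rule shared with the empirical pipeline.
    """
    if resolution < 400:
        raise ContractError("reference grid must be at least 400 x 400")
    delta = np.asarray(delta, dtype=float)
    (n1lo, n1hi), (n2lo, n2hi) = native_box
    (a1lo, a1hi), (a2lo, a2hi) = alien_box
    lo1, hi1 = min(n1lo, a1lo), max(n1hi, a1hi)
    lo2, hi2 = min(n2lo, a2lo), max(n2hi, a2hi)
    c1 = np.linspace(lo1, hi1, resolution + 1)
    c2 = np.linspace(lo2, hi2, resolution + 1)
    c1 = 0.5 * (c1[:-1] + c1[1:])
    c2 = 0.5 * (c2[:-1] + c2[1:])
    G1, G2 = np.meshgrid(c1, c2, indexing="ij")
    pts = np.column_stack([G1.ravel(), G2.ravel()])

    in_native = (
        (pts[:, 0] >= n1lo) & (pts[:, 0] <= n1hi)
        & (pts[:, 1] >= n2lo) & (pts[:, 1] <= n2hi)
    )
    in_alien = (
        (pts[:, 0] >= a1lo) & (pts[:, 0] <= a1hi)
        & (pts[:, 1] >= a2lo) & (pts[:, 1] <= a2hi)
    )
    in_mask = in_alien if mask_fn is None else (in_alien & mask_fn(pts))

    rv_n = stats.multivariate_normal(niche.mean, niche.covariance)
    rv_a = stats.multivariate_normal(niche.mean + delta, niche.covariance)
    dn = np.where(in_native, rv_n.pdf(pts), 0.0)
    da = np.where(in_mask, rv_a.pdf(pts), 0.0)
    if dn.sum() <= 0 or da.sum() <= 0:
        raise ContractError("a truncated occupancy density has zero mass")
    dn /= dn.sum()
    da /= da.sum()

    occ_n = mass_quantile_support(dn, occupancy_quantile)
    occ_a = mass_quantile_support(da, occupancy_quantile)
    analog = in_native & in_alien

    alien_mass = da[analog & occ_a].sum()
    native_mass = dn[analog & occ_n].sum()
    if alien_mass <= 0 or native_mass <= 0:
        raise ContractError("no occupancy mass inside analog climates")
    E = float(da[analog & occ_a & ~occ_n].sum() / alien_mass)
    U = float(dn[analog & occ_n & ~occ_a].sum() / native_mass)
    return E, 1.0 - E, U


# ---------------------------------------------------------------------------
# Scenario assembly


@dataclass
class SyntheticScenario:
    """A complete virtual-species scenario with analytic truth attached."""

    native_grid: ClimateGrid
    alien_grid: ClimateGrid
    native_range: RangeSet
    alien_range: RangeSet
    niche: NicheSpec
    delta: np.ndarray
    mask_cells: np.ndarray | None
    true_expansion: float
    true_stability: float
    true_unfilling: float
    seed: int


#: default scenario geometry: native envelope [0,10]^2, alien offset to
#: [4,14] x [0,10] (analog climates are var1 in [4,10]); niche optimum
#: (6, 5) with SD 0.8 per axis sits well inside the analog window so both
#: expansion (via delta) and unfilling (via masks) have room to act
_NATIVE_EXTENT = (0.0, 10.0, 0.0, 10.0)
_ALIEN_EXTENT = (4.0, 14.0, 0.0, 10.0)
_NICHE_MEAN = (6.0, 5.0)
_NICHE_SD = 0.8
_NOISE_SD = 0.1


def make_scenario(
    delta: tuple[float, float] = (0.0, 0.0),
    mask_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    n_native: int = 1000,
    n_alien: int = 1000,
    n_cells: int = 40000,
    niche_sd: float = _NICHE_SD,
    seed: int = 0,
    species_id: str = "sp1",
    realm_id: str = "realmA",
) -> SyntheticScenario:
    """Build a two-region virtual-species scenario.

    ``mask_fn`` restricts alien presence sampling (unfilling mechanism);
    ``delta`` shifts the alien niche optimum (expansion mechanism).  The
    analytic truth is computed on a 500 x 500 reference grid.
    """
    ss = np.random.SeedSequence([seed, 20260927])
    s_native, s_alien, s_pn, s_pa = ss.spawn(4)
    gradients = [
        VariableGradient("t1", base=0.0, slope_x=1.0, noise_sd=_NOISE_SD),
        VariableGradient("t2", base=0.0, slope_y=1.0, noise_sd=_NOISE_SD),
    ]
    native_grid = generate_climate_region(
        "native_region", _NATIVE_EXTENT, n_cells, gradients,
        seed=int(s_native.generate_state(1)[0] % 2**31),
    )
    alien_grid = generate_climate_region(
        "alien_region",
        (_ALIEN_EXTENT[0], _ALIEN_EXTENT[1], _ALIEN_EXTENT[2], _ALIEN_EXTENT[3]),
        n_cells, gradients,
        seed=int(s_alien.generate_state(1)[0] % 2**31),
        cell_id_start=n_cells,
    )
    niche = NicheSpec(
        mean=np.array(_NICHE_MEAN),
        covariance=np.diag([niche_sd**2, niche_sd**2]),
    )
    native_range = sample_virtual_presences(
        native_grid, niche, n_native, species_id, "native", "native_realm",
        seed=int(s_pn.generate_state(1)[0] % 2**31),
    )
    delta_v = np.asarray(delta, dtype=float)
    alien_niche = NicheSpec(mean=niche.mean + delta_v, covariance=niche.covariance)
    mask_cells = None
    if mask_fn is not None:
        keep = mask_fn(alien_grid.climate)
        mask_cells = alien_grid.cell_ids[keep]
    alien_range = sample_virtual_presences(
        alien_grid, alien_niche, n_alien, species_id, "alien", realm_id,
        mask=mask_cells, seed=int(s_pa.generate_state(1)[0] % 2**31),
    )
    x0, x1, y0, y1 = _NATIVE_EXTENT
    a0, a1, b0, b1 = _ALIEN_EXTENT
    E, S, U = true_niche_metrics(
        niche, delta_v,
        native_box=((x0, x1), (y0, y1)),
        alien_box=((a0, a1), (b0, b1)),
        mask_fn=mask_fn,
    )
    return SyntheticScenario(
        native_grid=native_grid, alien_grid=alien_grid,
        native_range=native_range, alien_range=alien_range,
        niche=niche, delta=delta_v, mask_cells=mask_cells,
        true_expansion=E, true_stability=S, true_unfilling=U, seed=seed,
    )


def half_mass_mask(niche_mean_1: float = _NICHE_MEAN[0]):
    """Alien sampling mask keeping climates with variable 1 at or above the
    niche optimum — by symmetry it covers half the native occupancy mass."""

    def fn(climate: np.ndarray) -> np.ndarray:
        return climate[:, 0] >= niche_mean_1

    return fn


def patchy_colonization_mask(
    discs: tuple[tuple[float, float, float], ...] = (
        (6.2, 5.0, 1.0),   # well-matched colonized core near the optimum
        (8.4, 5.0, 0.5),   # outlying marginal-climate population
    ),
):
    """Alien sampling mask emulating incomplete, patchy colonization.

    The species occupies a climate-matched core plus a small outlying patch,
    leaving much of the suitable climate (including high-suitability classes
    outside the core) unoccupied — the colonization-lag signature that
    raises suitability-model sensitivity while degrading the Boyce index.
    """

    def fn(climate: np.ndarray) -> np.ndarray:
        out = np.zeros(len(climate), dtype=bool)
        for cx, cy, r in discs:
            out |= (climate[:, 0] - cx) ** 2 + (climate[:, 1] - cy) ** 2 <= r * r
        return out

    return fn


# ---------------------------------------------------------------------------
# Driver tables with known coefficients


@dataclass
class DriverScenario:
    """Generative settings for a species-by-realm driver table.

    Coefficients are on the link scale and apply to the transformed,
    standardized covariates (the same preparation the inference stage
    performs); responses follow a binomial-logit (expansion) and a
    beta-logit with precision ``phi`` (unfilling).
    """

    n: int = 337
    n_realms: int = 11
    n_orders: int = 10
    n_species: int = 200
    beta_expansion: dict[str, float] = field(default_factory=lambda: {
        "native_range_size": -0.8,
        "community_similarity": -0.6,
        "human_disturbance": -0.6,
        "introduction_effort": 0.8,
    })
    beta_unfilling: dict[str, float] = field(default_factory=lambda: {
        "human_disturbance": 0.6,
        "native_range_loss": 0.5,
        "introduction_effort": -0.8,
        "residence_time": -0.5,
    })
    intercept_expansion: float = -0.9
    intercept_unfilling: float = 1.0
    realm_sd_expansion: float = 0.3
    realm_sd_unfilling: float = 0.3
    order_sd_unfilling: float = 0.3
    phi: float = 12.0

    def __post_init__(self) -> None:
        if self.n < 10 * len(DRIVER_NAMES):
            raise ContractError(
                f"n={self.n} violates the 10-observations-per-variable rule "
                f"for {len(DRIVER_NAMES)} covariates"
            )
        if self.phi <= 0:
            raise ContractError("beta precision phi must be positive")


def generate_driver_table(
    spec: DriverScenario | None = None, seed: int = 0
) -> pd.DataFrame:
    """Generate a species-by-realm driver table with known effects.

    Returns a DataFrame with grouping labels (species, order, realm), the 11
    raw covariates (log-normal sizes/counts/rates, Bernoulli insularity,
    bounded community similarity), the binary ``expansion`` response and the
    ``unfilling`` response in [0, 1].  True link-scale coefficients are
    stored in ``df.attrs["beta_expansion"]`` / ``df.attrs["beta_unfilling"]``.
    """
    spec = spec or DriverScenario()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 47]))
    n = spec.n

    species = rng.integers(0, spec.n_species, size=n)
    order_of_species = rng.integers(0, spec.n_orders, size=spec.n_species)
    order = order_of_species[species]
    realm = rng.integers(0, spec.n_realms, size=n)

    z = rng.normal(size=(n, 10))
    # modest realistic correlations: large-ranged species are richer-ranged
    # and better-studied
    z[:, 8] = 0.4 * z[:, 0] + np.sqrt(1 - 0.4**2) * z[:, 8]

    foods = 1 + rng.poisson(6.0 * special.expit(z[:, 4]))
    habitats = 1 + rng.poisson(5.0 * special.expit(0.6 * z[:, 4] + 0.8 * rng.normal(size=n)))
    locations = 1 + rng.poisson(np.exp(0.8 + 0.9 * z[:, 5]))
    pathways = 1 + rng.binomial(4, 0.35, size=n)

    table = pd.DataFrame({
        "species": [f"sp{s:03d}" for s in species],
        "order": [f"order{o}" for o in order],
        "realm": [f"realm{r}" for r in realm],
        "native_range_size": np.exp(12.0 + 1.5 * z[:, 0]),
        "native_range_loss": np.round(np.exp(4.0 + 1.2 * z[:, 1])),
        "dispersal": np.exp(1.0 + 0.8 * z[:, 2]),
        "fast_growth": z[:, 3],
        "specialization": [
            specialization_index(int(f), int(h)) for f, h in zip(foods, habitats)
        ],
        "introduction_effort": [
            introduction_effort(int(l), int(p)) for l, p in zip(locations, pathways)
        ],
        "residence_time": np.clip(np.round(np.exp(3.3 + 1.0 * z[:, 6])), 1, 500),
        "alien_insularity": rng.binomial(1, 0.3, size=n).astype(float),
        "human_disturbance": np.exp(1.5 + 0.8 * z[:, 7]),
        "native_richness": np.maximum(np.round(np.exp(4.0 + 0.9 * z[:, 8])), 1.0),
        "community_similarity": stats.beta.ppf(
            special.ndtr(z[:, 9]), 2.0, 2.0
        ),
    })

    def linear_predictor(response: str, betas: dict[str, float]) -> np.ndarray:
        design = prepare_design(table, response)
        eta = np.zeros(n)
        for name, b in betas.items():
            eta += b * design[name].to_numpy()
        return eta

    realm_u_e = rng.normal(0.0, spec.realm_sd_expansion, size=spec.n_realms)
    eta_e = (spec.intercept_expansion
             + linear_predictor("expansion", spec.beta_expansion)
             + realm_u_e[realm])
    table["expansion"] = rng.binomial(1, special.expit(eta_e)).astype(float)

    realm_u_u = rng.normal(0.0, spec.realm_sd_unfilling, size=spec.n_realms)
    order_u = rng.normal(0.0, spec.order_sd_unfilling, size=spec.n_orders)
    eta_u = (spec.intercept_unfilling
             + linear_predictor("unfilling", spec.beta_unfilling)
             + realm_u_u[realm] + order_u[order])
    mu = special.expit(eta_u)
    v = rng.beta(mu * spec.phi, (1.0 - mu) * spec.phi)
    v = np.clip(v, 1e-9, 1 - 1e-9)
    table["unfilling"] = v**2  # the beta draw is the sqrt-scale response

    table.attrs["beta_expansion"] = dict(spec.beta_expansion)
    table.attrs["beta_unfilling"] = dict(spec.beta_unfilling)
    table.attrs["intercepts"] = (spec.intercept_expansion, spec.intercept_unfilling)
    table.attrs["phi"] = spec.phi
    table.attrs["seed"] = seed
    return table
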