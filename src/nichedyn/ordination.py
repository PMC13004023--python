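"""Shared climate ordination, kernel occupancy grids, and novelty screening.

Native and alien niches are compared inside a common two-dimensional climate
space: a correlation-matrix PCA is calibrated on the pooled environments of
both regions (presences and background cells together), occurrence densities
are kernel-smoothed onto an R x R grid spanning the pooled scores, and all
niche indices are restricted to *analog* climates — conditions available in
both backgrounds.  Novel alien-background climates are additionally screened
with the two extrapolation-detection scores: NT1 (univariate range
extrapolation, always <= 0) and NT2 (multivariate combinational novelty, a
Mahalanobis ratio against the reference's own maximum, computed only where
NT1 = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ContractError

__all__ = [
    "Ordination",
    "OccupancyGrid",
    "AnalogMask",
    "NoveltyReport",
    "fit_scaled_pca",
    "project_scores",
    "variance_check",
    "silverman_bandwidth",
    "estimate_occupancy_grid",
    "compute_analog_mask",
    "exdet_nt1",
    "exdet_nt2",
    "novelty_summary",
]


@dataclass
class Ordination:
    """A fitted correlation-matrix PCA (center + unit scale)."""

    means: np.ndarray          # (k,) variable means of the calibration rows
    sds: np.ndarray            # (k,) sample SDs
    loadings: np.ndarray       # (k, n_axes) eigenvectors of the correlation matrix
    variance_fractions: np.ndarray  # (n_axes,) fraction of total variance per axis
    all_variance_fractions: np.ndarray  # (k,) over all axes; sums to 1

    @property
    def n_axes(self) -> int:
        return self.loadings.shape[1]


def fit_scaled_pca(rows: np.ndarray, n_axes: int = 2) -> Ordination:
    """PCA on the correlation matrix of ``rows``, retaining ``n_axes`` axes.

    Deterministic sign convention: the largest-magnitude element of each
    loading vector is made positive.  Constant columns are rejected because
    unit scaling is undefined for them.
    """
    X = np.asarray(rows, dtype=float)
    if X.ndim != 2:
        raise ContractError("rows must be a 2-D matrix")
    n, k = X.shape
    if n < n_axes + 1:
        raise ContractError(f"need at least {n_axes + 1} rows, got {n}")
    if not 1 <= n_axes <= k:
        raise ContractError("n_axes must be in [1, k]")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ContractError(f"constant column(s) at index {zero.tolist()}")
    Z = (X - means) / sds
    corr = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention
    for j in range(k):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    frac = eigval / eigval.sum()
    return Ordination(
        means=means,
        sds=sds,
        loadings=eigvec[:, :n_axes],
        variance_fractions=frac[:n_axes],
        all_variance_fractions=frac,
    )


def project_scores(ordination: Ordination, rows: np.ndarray) -> np.ndarray:
    """Project climate rows into the ordination: ``(x - mean)/sd @ loadings``."""
    X = np.atleast_2d(np.asarray(rows, dtype=float))
    if X.shape[1] != ordination.means.shape[0]:
        raise ContractError(
            f"row dimension {X.shape[1]} does not match "
            f"{ordination.means.shape[0]} fitted variables"
        )
    return (X - ordination.means) / ordination.sds @ ordination.loadings


def variance_check(ordination: Ordination, threshold: float = 0.75) -> bool:
    """True when the retained axes capture more than ``threshold`` variance."""
    return bool(ordination.variance_fractions.sum() > threshold)


def silverman_bandwidth(values: np.ndarray) -> float:
    """Normal-reference bandwidth for one axis of a 2-D kernel density.

    ``h = sigma * n**(-1/6)``, the d=2 case of Silverman's rule.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    sigma = values.std(ddof=1) if n > 1 else 1.0
    if sigma == 0:
        sigma = 1e-6  # degenerate point cloud; keep the kernel well-defined
    return float(sigma * n ** (-1.0 / 6.0))


@dataclass
class OccupancyGrid:
    """Kernel occupancy and background density on an R x R ordination grid.

    ``z`` is the occupancy density, normalized so that ``z.sum() * cell_area
    == 1``; when availability correction is on, occurrence density is divided
    by background density before normalizing, separating where the species
    sits in climate space from what climate was available.  ``background`` is
    the raw (un-normalized) kernel density of background cells per grid cell.
    """

    edges1: np.ndarray      # (R+1,) bin edges on axis 1
    edges2: np.ndarray      # (R+1,) bin edges on axis 2
    z: np.ndarray           # (R, R) occupancy density, unit mass
    background: np.ndarray  # (R, R) background density (raw)
    corrected: bool
    #: z value of the grid cell containing each presence; the occupancy
    #: support cutoff is a quantile of these (None for hand-built grids,
    #: which then binarize at strict positivity)
    z_at_presences: np.ndarray | None = None
    #: background cell-count histogram; the analog mask uses its support
    background_counts: np.ndarray | None = None

    @property
    def resolution(self) -> int:
        return len(self.edges1) - 1

    @property
    def cell_area(self) -> float:
        return float((self.edges1[1] - self.edges1[0]) * (self.edges2[1] - self.edges2[0]))

    @property
    def centers1(self) -> np.ndarray:
        return 0.5 * (self.edges1[:-1] + self.edges1[1:])

    @property
    def centers2(self) -> np.ndarray:
        return 0.5 * (self.edges2[:-1] + self.edges2[1:])

    def same_edges(self, other: "OccupancyGrid") -> bool:
        return (
            self.edges1.shape == other.edges1.shape
            and np.allclose(self.edges1, other.edges1)
            and np.allclose(self.edges2, other.edges2)
        )


def _kde2d_on_grid(
    points: np.ndarray,
    centers1: np.ndarray,
    centers2: np.ndarray,
    h1: float,
    h2: float,
) -> np.ndarray:
    """Separable Gaussian KDE of 2-D ``points`` evaluated on a grid.

    Returns the density matrix with axis-1 centers as rows.  The Gaussian
    kernel underflows to exact zero beyond ~38 bandwidths, which gives the
    density a numerically compact support — strict positivity of ``z`` is
    therefore a meaningful occupancy criterion.
    """
    d1 = (centers1[:, None] - points[None, :, 0]) / h1
    d2 = (centers2[:, None] - points[None, :, 1]) / h2
    k1 = np.exp(-0.5 * d1 * d1) / (np.sqrt(2 * np.pi) * h1)
    k2 = np.exp(-0.5 * d2 * d2) / (np.sqrt(2 * np.pi) * h2)
    return (k1 @ k2.T) / len(points)


_BACKGROUND_FLOOR = 1e-12  # avoid 0/0 at the edge of the background support

#: kernel bandwidths are this fraction of the per-axis normal-reference
#: (Silverman) value: the reference rule assumes an untruncated Gaussian
#: cloud and oversmooths the sharply bounded occupancy distributions that
#: masked colonization produces, dilating the occupied support
DEFAULT_BANDWIDTH_FACTOR = 0.5


def estimate_occupancy_grid(
    presence_scores: np.ndarray,
    background_scores: np.ndarray,
    resolution: int = 100,
    extent: tuple[float, float, float, float] | None = None,
    correction: bool = True,
    bandwidth_factor: float = DEFAULT_BANDWIDTH_FACTOR,
) -> OccupancyGrid:
    """Kernel occupancy density of one region on the ordination grid.

    Parameters
    ----------
    presence_scores, background_scores : ndarray, shape (n, 2)
        Ordination scores of presences and of all background cells.
    resolution : int
        Grid side length R.
    extent : (min1, max1, min2, max2), optional
        Grid extent.  Pass the pooled extent of both regions so native and
        alien grids share bin edges; defaults to this region's pooled scores
        expanded by one bandwidth per side.
    correction : bool
        Divide occurrence density by background density (where positive)
        before normalizing.
    """
    P = np.atleast_2d(np.asarray(presence_scores, dtype=float))
    B = np.atleast_2d(np.asarray(background_scores, dtype=float))
    if P.shape[0] < 5:
        raise ContractError("need at least 5 presence scores")
    if bandwidth_factor <= 0:
        raise ContractError("bandwidth_factor must be positive")
    h1 = bandwidth_factor * silverman_bandwidth(P[:, 0])
    h2 = bandwidth_factor * silverman_bandwidth(P[:, 1])
    if extent is None:
        allpts = np.vstack([P, B])
        extent = (
            allpts[:, 0].min() - h1,
            allpts[:, 0].max() + h1,
            allpts[:, 1].min() - h2,
            allpts[:, 1].max() + h2,
        )
    lo1, hi1, lo2, hi2 = extent
    if not (P[:, 0].min() >= lo1 and P[:, 0].max() <= hi1
            and P[:, 1].min() >= lo2 and P[:, 1].max() <= hi2):
        raise ContractError("extent does not cover all presence scores")
    edges1 = np.linspace(lo1, hi1, resolution + 1)
    edges2 = np.linspace(lo2, hi2, resolution + 1)
    c1 = 0.5 * (edges1[:-1] + edges1[1:])
    c2 = 0.5 * (edges2[:-1] + edges2[1:])
    # a kernel much narrower than a grid cell underflows between the cell
    # centers; half a cell width is the narrowest representable kernel
    h1 = max(h1, 0.5 * float(edges1[1] - edges1[0]))
    h2 = max(h2, 0.5 * float(edges2[1] - edges2[0]))

    occ = _kde2d_on_grid(P, c1, c2, h1, h2)
    bh1 = bandwidth_factor * silverman_bandwidth(B[:, 0])
    bh2 = bandwidth_factor * silverman_bandwidth(B[:, 1])
    bg = _kde2d_on_grid(B, c1, c2, bh1, bh2)
    counts, _, _ = np.histogram2d(B[:, 0], B[:, 1], bins=[edges1, edges2])

    if correction:
        # clip to the available envelope: dividing the kernel tail of occ by
        # the tail of bg outside the background's own support would turn
        # availability artefacts into occupancy
        avail = counts > 0
        z = np.where(avail & (bg > 0), occ / np.maximum(bg, _BACKGROUND_FLOOR), 0.0)
    else:
        z = occ.copy()
    area = float((edges1[1] - edges1[0]) * (edges2[1] - edges2[0]))
    total = z.sum() * area
    if total <= 0:
        raise ContractError("occupancy density has zero mass on the grid")
    z /= total

    i1 = np.clip(np.searchsorted(edges1, P[:, 0], side="right") - 1, 0, resolution - 1)
    i2 = np.clip(np.searchsorted(edges2, P[:, 1], side="right") - 1, 0, resolution - 1)
    z_at_p = z[i1, i2]
    return OccupancyGrid(edges1=edges1, edges2=edges2, z=z,
                         background=bg, corrected=correction,
                         z_at_presences=z_at_p, background_counts=counts)


@dataclass
class AnalogMask:
    """Grid cells whose climates are available in both backgrounds."""

    mask: np.ndarray       # (R, R) bool
    analog_fraction: float  # fraction of grid cells that are analog


def compute_analog_mask(
    native: OccupancyGrid, alien: OccupancyGrid, quantile: float = 0.0
) -> AnalogMask:
    """Cells where both backgrounds exceed their density quantile cutoff.

    ``quantile = 0`` means strict positivity of both background densities.
    The mask shrinks monotonically as the quantile grows.  Grids built from
    data carry a background cell-count histogram, whose support bounds the
    available envelope sharply; hand-built grids fall back to the stored
    background density field.
    """
    if not native.same_edges(alien):
        raise ContractError("occupancy grids do not share bin edges")
    if not 0.0 <= quantile < 1.0:
        raise ContractError("quantile must be in [0, 1)")

    def support(grid: OccupancyGrid) -> np.ndarray:
        bg = (grid.background_counts
              if grid.background_counts is not None else grid.background)
        if quantile == 0.0:
            return bg > 0
        pos = bg[bg > 0]
        cut = np.quantile(pos, quantile) if pos.size else np.inf
        return bg > cut

    m = support(native) & support(alien)
    return AnalogMask(mask=m, analog_fraction=float(m.mean()))


# ---------------------------------------------------------------------------
# Extrapolation detection (climate novelty)


def exdet_nt1(reference: np.ndarray, point: np.ndarray) -> float:
    """Univariate extrapolation score NT1 (<= 0; 0 iff inside all ranges).

    ``NT1 = sum_i min(x_i - min_i, max_i - x_i, 0) / (max_i - min_i)``.
    """
    R = np.atleast_2d(np.asarray(reference, dtype=float))
    x = np.asarray(point, dtype=float).ravel()
    mins = R.min(axis=0)
    maxs = R.max(axis=0)
    rng = maxs - mins
    if np.any(rng == 0):
        raise ContractError("reference has zero range in some variable")
    ud = np.minimum.reduce([x - mins, maxs - x, np.zeros_like(x)])
    return float(np.sum(ud / rng))


def exdet_nt2(
    reference: np.ndarray,
    point: np.ndarray,
    _cache: dict | None = None,
) -> float:
    """Multivariate novelty NT2: Mahalanobis^2 of the point from the
    reference centroid, divided by the maximum Mahalanobis^2 over the
    reference points themselves.  > 1 flags combinations of climates never
    jointly observed in the reference, even if each variable is in range.
    """
    R = np.atleast_2d(np.asarray(reference, dtype=float))
    x = np.asarray(point, dtype=float).ravel()
    if _cache is not None and "inv" in _cache:
        mu, inv, dmax = _cache["mu"], _cache["inv"], _cache["dmax"]
    else:
        mu = R.mean(axis=0)
        cov = np.cov(R, rowvar=False)
        cov = np.atleast_2d(cov)
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise ContractError(
                "singular reference covariance; reduce correlated variables"
            ) from exc
        dc = R - mu
        dmax = float(np.max(np.einsum("ij,jk,ik->i", dc, inv, dc)))
        if _cache is not None:
            _cache.update(mu=mu, inv=inv, dmax=dmax)
    d2 = float((x - mu) @ inv @ (x - mu))
    return d2 / dmax


@dataclass
class NoveltyReport:
    """Prevalence of novel climates in an alien background."""

    nt1: np.ndarray          # per alien-background cell, <= 0
    nt2: np.ndarray          # per cell; NaN where NT1 < 0 (not computed)
    percent_novel: float     # % of cells with NT1 < 0 or NT2 > 1
    exceeds_5pct: bool


def novelty_summary(
    alien_background: np.ndarray, native_background: np.ndarray
) -> NoveltyReport:
    """ExDet screen of every alien-background cell against the native one.

    A cell is novel iff NT1 < 0 (outside some univariate native range) or
    NT2 > 1 (a climate combination more distant than any native cell).
    """
    A = np.atleast_2d(np.asarray(alien_background, dtype=float))
    N = np.atleast_2d(np.asarray(native_background, dtype=float))
    if A.size == 0 or N.size == 0:
        raise ContractError("both backgrounds must be nonempty")
    mins = N.min(axis=0)
    maxs = N.max(axis=0)
    rng = maxs - mins
    if np.any(rng == 0):
        raise ContractError("native background has zero range in some variable")
    ud = np.minimum(np.minimum(A - mins, maxs - A), 0.0)
    nt1 = (ud / rng).sum(axis=1)

    nt2 = np.full(len(A), np.nan)
    inside = nt1 == 0
    if inside.any():
        cache: dict = {}
        # prime the cache once, then evaluate the batch with it
        exdet_nt2(N, A[np.flatnonzero(inside)[0]], _cache=cache)
        dc = A[inside] - cache["mu"]
        d2 = np.einsum("ij,jk,ik->i", dc, cache["inv"], dc)
        nt2[inside] = d2 / cache["dmax"]

    novel = (nt1 < 0) | (np.nan_to_num(nt2, nan=0.0) > 1)
    pct = 100.0 * novel.mean()
    return NoveltyReport(nt1=nt1, nt2=nt2, percent_novel=float(pct),
                         exceeds_5pct=bool(pct > 5.0))
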