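"""Genetic-divergence landscapes and the climatic-stability regression.

Pairwise genetic distances are mapped to the spherical midpoints of
population pairs, interpolated into a continuous surface with
k-nearest-neighbour inverse-distance weighting (power 2, 12 neighbours
by default — ArcGIS "variable search radius" semantics), clipped to the
convex hull of the sample locations, and regressed on the per-cell
change in climatic suitability with a penalized-spline generalized
additive model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point
from statsmodels.gam.api import BSplines, GLMGam

from .genetics import PopulationSet
from .geo import spherical_midpoint
from .raster import GridSpec, SuitabilityMap

__all__ = [
    "MidpointSample",
    "StabilityRegression",
    "midpoint_distances",
    "idw_interpolate",
    "suitability_change",
    "stability_gam",
]


@dataclass
class MidpointSample:
    """One pairwise genetic distance placed at the pair's midpoint."""

    lon: float
    lat: float
    value: float
    pop_a: str
    pop_b: str


@dataclass
class StabilityRegression:
    """GAM of interpolated genetic distance on suitability change."""

    r2: float
    p_value: float
    n: int
    edf: float
    sign_convention: str
    threshold: float | None
    fitted: np.ndarray
    response: np.ndarray
    predictor: np.ndarray


def midpoint_distances(pops: PopulationSet, D: np.ndarray,
                       labels: list[str] | None = None) -> list[MidpointSample]:
    """n(n-1)/2 midpoint samples from a pairwise distance matrix whose
    label order matches the population set."""
    labels = labels or list(pops.ids)
    if labels != list(pops.ids):
        raise ValueError("distance-matrix labels do not match populations")
    n = len(pops)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            lon, lat = spherical_midpoint(
                pops.lons[i], pops.lats[i], pops.lons[j], pops.lats[j]
            )
            out.append(MidpointSample(lon, lat, float(D[i, j]),
                                      pops.ids[i], pops.ids[j]))
    return out


def idw_interpolate(samples: list[MidpointSample], grid: GridSpec,
                    power: float = 2.0, k_neighbors: int = 12,
                    clip_to_hull: bool = True) -> np.ndarray:
    """Inverse-distance-weighted surface over a grid.

    Cell value = sum(w_j v_j)/sum(w_j) over the k nearest samples with
    w_j = d_j^(-power); a cell whose centre coincides with a sample
    takes that sample's value exactly. Cells outside the convex hull of
    the sample locations are NaN (no extrapolation beyond the sampled
    extent); with fewer than 3 distinct sample points the hull
    degenerates and clipping keeps cells within the samples' bounding
    box buffered by one cell.
    """
    if not samples:
        raise ValueError("no samples to interpolate")
    pts = np.array([[s.lon, s.lat] for s in samples])
    vals = np.array([s.value for s in samples])
    k = min(k_neighbors, len(samples))
    tree = cKDTree(pts)
    lon, lat = grid.centers()
    query = np.column_stack([lon.ravel(), lat.ravel()])
    dist, idx = tree.query(query, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    exact = dist[:, 0] < 1e-12
    with np.errstate(divide="ignore"):
        w = dist ** (-power)
    w[exact] = 0.0
    w[exact, 0] = 1.0
    surface = (w * vals[idx]).sum(axis=1) / w.sum(axis=1)
    if clip_to_hull:
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        if hull.area == 0:  # collinear or single point: buffer instead
            hull = hull.buffer(grid.cellsize)
        inside = np.array([hull.covers(Point(x, y)) for x, y in query])
        surface = np.where(inside, surface, np.nan)
    return surface.reshape(grid.shape)


def suitability_change(current: SuitabilityMap, future: SuitabilityMap
                       ) -> np.ndarray:
    """Signed per-cell suitability change, future minus current
    (positive = gain in suitability)."""
    if current.grid != future.grid:
        raise ValueError("suitability grids differ")
    return future.values - current.values


def _fit_penalized_spline(y: np.ndarray, x: np.ndarray, df: int):
    """Gaussian GAM with the smoothing penalty chosen by generalized
    cross-validation over a log-spaced grid: GCV = n·SSR/(n − edf)²."""
    n = len(y)
    best = None
    best_gcv = np.inf
    for alpha in np.logspace(-8, 4, 13):
        bs = BSplines(x[:, None], df=[df], degree=[3])
        try:
            res = GLMGam(y, np.ones((n, 1)), smoother=bs, alpha=[alpha]).fit()
        except Exception:  # singular / perfectly separated at this penalty
            continue
        ssr = float(((y - res.fittedvalues) ** 2).sum())
        edf = float(res.edf.sum())
        gcv = n * ssr / max(n - edf, 1.0) ** 2
        if gcv < best_gcv:
            best_gcv, best = gcv, res
    if best is None:
        raise ValueError("penalized spline fit failed at every penalty")
    return best


def stability_gam(landscape: np.ndarray, change: np.ndarray, grid: GridSpec,
                  df: int = 10, max_cells: int = 2000, seed: int = 0,
                  threshold: float | None = None) -> StabilityRegression:
    """Penalized cubic-spline GAM of interpolated genetic distance
    (response) on climatic-suitability change (predictor).

    Evaluation points are the cells where both surfaces are defined,
    subsampled to ``max_cells`` (seeded) to keep the fit tractable.
    Reports R², the approximate F-test p-value of the smooth term
    against a constant model, and the effective degrees of freedom.
    """
    if landscape.shape != grid.shape or change.shape != grid.shape:
        raise ValueError("surface shapes do not match grid")
    ok = np.isfinite(landscape) & np.isfinite(change)
    y = landscape[ok]
    x = change[ok]
    if len(y) < 30:
        raise ValueError("fewer than 30 evaluation cells")
    if x.std() < 1e-12:
        raise ValueError("constant predictor: GAM undefined")
    if len(y) > max_cells:
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(y), size=max_cells, replace=False)
        y, x = y[sel], x[sel]
    res = _fit_penalized_spline(y, x, df)
    fitted = np.asarray(res.fittedvalues)
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = max(0.0, 1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0
    edf = float(np.clip(res.edf.sum() - 1.0, 1.0, df)) if hasattr(res, "edf") else float(df)
    n = len(y)
    denom_df = max(n - edf - 1.0, 1.0)
    if ss_res <= 0:
        p_value = 0.0
    else:
        from scipy import stats

        F = ((ss_tot - ss_res) / edf) / (ss_res / denom_df)
        p_value = float(stats.f.sf(F, edf, denom_df))
    return StabilityRegression(
        r2=r2, p_value=p_value, n=n, edf=edf,
        sign_convention="future - current (positive = suitability gain)",
        threshold=threshold, fitted=fitted, response=y, predictor=x,
    )
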