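"""Topographic mapping: 3D channel midpoints -> circular 2D head template.

Channel midpoints are flattened with an azimuthal-equidistant projection about
the vertex (the standard circular template used for scalp topography): the
polar angle from the vertex maps linearly to disk radius, the azimuth is
preserved.  Channel values are then interpolated onto a regular raster inside
the unit disk (piecewise-linear on the Delaunay triangulation, with
nearest-neighbour fill outside the convex hull), giving comparable per-subject
maps from which group means, standard-error-percent maps, split-half
reliability and cross-map correlations are computed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import Delaunay, QhullError
from scipy.stats import pearsonr

from .errors import (
    AlignmentError,
    DegenerateGeometryError,
    ParameterError,
    UndefinedCorrelationError,
)

DEFAULT_THETA_MAX = math.radians(100.0)


@dataclass
class DiskProjection:
    """Projected channel positions on the unit disk."""

    xy: np.ndarray          # (n, 2) disk coordinates
    rho: np.ndarray         # radial coordinate in [0, 1]
    azimuth: np.ndarray     # radians
    clipped: np.ndarray     # True where theta exceeded theta_max
    theta_max: float


def project_to_disk(midpoints_mm: np.ndarray,
                    head_center: np.ndarray = (0.0, 0.0, 0.0),
                    vertex_dir: np.ndarray = (0.0, 0.0, 1.0),
                    theta_max: float = DEFAULT_THETA_MAX) -> DiskProjection:
    """Azimuthal-equidistant flattening about the vertex.

    ``rho = theta / theta_max`` where theta is the polar angle from
    ``vertex_dir``; azimuth is preserved.  Points beyond ``theta_max`` are
    clipped to the rim (``rho = 1``) and flagged — the flattening distorts
    ventral relative to dorsal locations.
    """
    if not 0 < theta_max <= math.pi:
        raise ParameterError("theta_max must lie in (0, pi]")
    v = np.asarray(vertex_dir, dtype=float)
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ParameterError("vertex direction must be non-zero")
    v = v / nv
    p = np.atleast_2d(np.asarray(midpoints_mm, dtype=float)) - np.asarray(head_center, float)
    r = np.linalg.norm(p, axis=1)
    if np.any(r == 0):
        raise ParameterError("midpoint coincides with the head centre")
    u = p / r[:, None]
    cos_t = np.clip(u @ v, -1.0, 1.0)
    theta = np.arccos(cos_t)
    # orthonormal basis in the plane normal to v (deterministic choice)
    a = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = a - v * (a @ v)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    azimuth = np.arctan2(u @ e2, u @ e1)
    clipped = theta > theta_max
    rho = np.minimum(theta / theta_max, 1.0)
    xy = np.column_stack([rho * np.cos(azimuth), rho * np.sin(azimuth)])
    return DiskProjection(xy, rho, azimuth, clipped, theta_max)


def disk_to_sphere(projection: DiskProjection) -> np.ndarray:
    """Inverse mapping for unclipped points: (theta, azimuth) per point."""
    return np.column_stack([projection.rho * projection.theta_max, projection.azimuth])


@dataclass
class GridMap:
    """A raster over the unit disk: values, validity and extrapolation masks."""

    values: np.ndarray
    valid: np.ndarray
    extrapolated: np.ndarray
    grid_n: int

    def same_grid(self, other: "GridMap") -> bool:
        return self.grid_n == other.grid_n

    @property
    def xs(self) -> np.ndarray:
        return np.linspace(-1.0, 1.0, self.grid_n)


def _disk_grid(grid_n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xs = np.linspace(-1.0, 1.0, grid_n)
    gx, gy = np.meshgrid(xs, xs, indexing="xy")
    inside = gx**2 + gy**2 <= 1.0
    return gx, gy, inside


def interpolate_map(projection: DiskProjection, values: np.ndarray,
                    grid_n: int = 64) -> GridMap:
    """Interpolate channel values onto a ``grid_n x grid_n`` disk raster.

    Piecewise-linear inside the convex hull of the projected points (so the
    map reproduces each sample value at its own location and never exceeds the
    input range there); pixels inside the disk but outside the hull are filled
    by nearest neighbour and flagged ``extrapolated``.
    """
    values = np.asarray(values, dtype=float)
    good = np.isfinite(values)
    pts = projection.xy[good]
    vals = values[good]
    if len(vals) < 3:
        raise DegenerateGeometryError("need at least 3 valued points")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point geometry: {exc}") from exc
    lin = LinearNDInterpolator(tri, vals)
    near = NearestNDInterpolator(pts, vals)
    gx, gy, inside = _disk_grid(grid_n)
    z = lin(gx, gy)
    hull_miss = ~np.isfinite(z) & inside
    z[hull_miss] = near(gx[hull_miss], gy[hull_miss])
    z[~inside] = np.nan
    return GridMap(values=z, valid=inside & np.isfinite(z),
                   extrapolated=hull_miss, grid_n=grid_n)


def _check_shared_grid(maps: list[GridMap]) -> None:
    if not maps:
        raise ValueError("no maps given")
    n = maps[0].grid_n
    if any(m.grid_n != n for m in maps):
        raise AlignmentError("maps do not share a common grid")


def group_maps(maps: list[GridMap]) -> tuple[GridMap, GridMap]:
    """Across-subject mean map and SE-percent map (SE as % of the pixel mean).

    ``SE% = 100 * (SD / sqrt(n)) / mean``, undefined (NaN) where the pixel
    mean is non-positive.
    """
    _check_shared_grid(maps)
    if len(maps) < 2:
        raise ValueError("need at least 2 subjects")
    stack = np.stack([m.values for m in maps])
    valid = np.logical_and.reduce([m.valid for m in maps])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    se_pct = np.where(valid & (mean > 0), 100.0 * sd / math.sqrt(len(maps)) / np.where(mean > 0, mean, 1.0), np.nan)
    mean = np.where(valid, mean, np.nan)
    n = maps[0].grid_n
    no_extrap = np.zeros_like(valid)
    return (GridMap(mean, valid, no_extrap, n),
            GridMap(se_pct, valid & np.isfinite(se_pct), no_extrap, n))


def map_correlation(a: GridMap, b: GridMap) -> float:
    """Pearson correlation over jointly valid pixels of two maps."""
    if not a.same_grid(b):
        raise AlignmentError("maps do not share a common grid")
    joint = a.valid & b.valid
    x, y = a.values[joint], b.values[joint]
    tol_x = 1e-12 * max(1.0, float(np.max(np.abs(x), initial=0.0)))
    tol_y = 1e-12 * max(1.0, float(np.max(np.abs(y), initial=0.0)))
    if joint.sum() < 3 or np.std(x) <= tol_x or np.std(y) <= tol_y:
        raise UndefinedCorrelationError("fewer than 3 jointly valid pixels or zero variance")
    return float(pearsonr(x, y)[0])


def split_half_reliability(maps: list[GridMap], strata: pd.DataFrame | list,
                           seed: int = 0) -> float:
    """Pixel-wise correlation between mean maps of two stratified random halves.

    ``strata`` gives one stratification label per subject (e.g. tuples of
    (age decade, sex)); each stratum is split as evenly as possible between
    the halves.  A singleton stratum triggers a warning and random assignment.
    """
    _check_shared_grid(maps)
    labels = [tuple(s) if isinstance(s, (list, tuple, np.ndarray)) else (s,) for s in
              (strata.itertuples(index=False) if isinstance(strata, pd.DataFrame) else strata)]
    if len(labels) != len(maps):
        raise ValueError("one stratum label per subject required")
    rng = np.random.default_rng(seed)
    half = np.zeros(len(maps), dtype=int)
    for lab in set(labels):
        idx = [i for i, l in enumerate(labels) if l == lab]
        if len(idx) == 1:
            warnings.warn(f"stratum {lab!r} has a single subject; assigned at random")
        perm = rng.permutation(idx)
        half[perm[: len(perm) // 2 + len(perm) % 2 * rng.integers(0, 2)]] = 1
        # ensure non-degenerate overall split handled below
    # guard: if a half ended empty (tiny cohorts), rebalance at random
    if half.sum() == 0 or half.sum() == len(maps):
        half = rng.permutation(np.arange(len(maps)) % 2)
    g0, _ = group_maps([m for m, h in zip(maps, half) if h == 0])
    g1, _ = group_maps([m for m, h in zip(maps, half) if h == 1])
    return map_correlation(g0, g1)
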