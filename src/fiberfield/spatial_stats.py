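"""Neuron–fiber spatial statistics.

Distances are 3D Euclidean between a fiber tip center (the center of the
ellipse fit to the electrode tract at its tip) and neuron soma centroids.
Each fiber carries a *tracing radius* — 50 µm, or the tip-to-slice-top
distance when the tip sits shallower than 50 µm — which bounds which
neurons were traced and therefore which positions are measurable.

The hypothetical-fiber grid reproduces the control construction for
unimplanted tissue: a 12.5 µm 3D lattice centered on the volume centroid,
with points discarded when closer than 50 µm to the volume border or when
falling inside a traced soma.  The closed-form mean k-th nearest-neighbor
distance for a homogeneous Poisson process of intensity λ (µm⁻³),

    E[r_k] = Γ(k + 1/3)/Γ(k) · (4πλ/3)^(−1/3),

serves as the independent oracle for the simulation path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from scipy.special import gamma as _gamma
from shapely.geometry import Polygon as _ShapelyPolygon

from .morphometry import Ellipse, NeuronRecord, NeuronScaffold

logger = logging.getLogger(__name__)

MAX_TRACING_RADIUS = 50.0  # µm, the single-unit recording radius

__all__ = [
    "MAX_TRACING_RADIUS",
    "FiberTip",
    "DistanceTable",
    "HypotheticalGrid",
    "tracing_radius",
    "sorted_neuron_distances",
    "build_distance_tables",
    "kth_position_summary",
    "shell_counts",
    "local_density",
    "expected_count_in_sphere",
    "hypothetical_grid",
    "grid_kth_distances",
    "grid_position_summary",
    "poisson_kth_nn_mean",
    "localization_agreement",
]


@dataclass
class FiberTip:
    """A localized electrode tip: 3D center (µm) plus its fitted tip ellipse."""

    fiber_id: str
    center: tuple[float, float, float]
    tip_ellipse: Ellipse | None = None
    tracing_radius: float = MAX_TRACING_RADIUS

    def __post_init__(self) -> None:
        self.center = tuple(float(c) for c in self.center)  # type: ignore[assignment]
        if not (0 < self.tracing_radius <= MAX_TRACING_RADIUS):
            raise ValueError("tracing_radius must lie in (0, 50] µm")


def tracing_radius(tip: FiberTip, slice_top_z: float) -> float:
    """Per-fiber analysis radius: min(50, tip depth below the slice top)."""
    depth = tip.center[2] - slice_top_z
    if depth <= 0:
        raise ValueError(
            f"tip {tip.fiber_id} is at or above the slice top (depth {depth:.2f} µm)"
        )
    return min(MAX_TRACING_RADIUS, depth)


def _centroid_array(
    neurons: Sequence[NeuronRecord] | np.ndarray,
) -> tuple[np.ndarray, list[str]]:
    if isinstance(neurons, np.ndarray):
        pts = np.atleast_2d(np.asarray(neurons, dtype=float))
        ids = [str(i) for i in range(pts.shape[0])]
        return pts, ids
    if hasattr(neurons, "centroids"):  # NeuronPopulation duck type
        pts = np.asarray(neurons.centroids, dtype=float)
        ids = [str(i) for i in getattr(neurons, "ids", range(pts.shape[0]))]
        return pts, ids
    pts = np.array([n.centroid for n in neurons], dtype=float)
    ids = [n.neuron_id for n in neurons]
    return pts.reshape(-1, 3), ids


def sorted_neuron_distances(
    tip: FiberTip, neurons: Sequence[NeuronRecord] | np.ndarray
) -> list[tuple[str, float]]:
    """Ascending (neuron_id, r) for all neurons within the tracing radius.

    Ties in distance are broken by neuron_id for determinism.
    """
    pts, ids = _centroid_array(neurons)
    if pts.size == 0:
        return []
    d = np.linalg.norm(pts - np.asarray(tip.center), axis=1)
    keep = d <= tip.tracing_radius
    entries = [(ids[i], float(d[i])) for i in np.nonzero(keep)[0]]
    entries.sort(key=lambda e: (e[1], e[0]))
    return entries


@dataclass
class DistanceTable:
    """Per-fiber ascending neuron distance lists, with each fiber's radius."""

    entries: dict[str, list[tuple[str, float]]]
    radii: dict[str, float]

    def distances(self, fiber_id: str) -> list[float]:
        return [r for _, r in self.entries[fiber_id]]


def build_distance_tables(
    tips: Sequence[FiberTip], neurons: Sequence[NeuronRecord] | np.ndarray
) -> DistanceTable:
    entries = {t.fiber_id: sorted_neuron_distances(t, neurons) for t in tips}
    radii = {t.fiber_id: t.tracing_radius for t in tips}
    return DistanceTable(entries=entries, radii=radii)


def kth_position_summary(
    table: DistanceTable, k: int
) -> tuple[float, float, int]:
    """Mean ± SD of the k-th nearest-neuron distance over contributing fibers.

    A fiber contributes only when it has >= k neurons inside its tracing
    radius; otherwise the k-th position was never measured (it may lie
    beyond a reduced radius) and the fiber is excluded for that position.
    Returns (mean, sample SD, n_fibers); (nan, nan, 0) when no fiber
    contributes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = [
        entries[k - 1][1]
        for entries in table.entries.values()
        if len(entries) >= k
    ]
    if not vals:
        logger.warning("no fibers contribute to position %d", k)
        return float("nan"), float("nan"), 0
    arr = np.asarray(vals)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return float(arr.mean()), sd, int(arr.size)


def shell_counts(
    tip: FiberTip,
    neurons: Sequence[NeuronRecord] | np.ndarray,
    bin_width: float = 10.0,
    max_radius: float = MAX_TRACING_RADIUS,
) -> pd.DataFrame:
    """Neuron counts per 10 µm spherical shell around a tip, plus cumulative."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pts, _ = _centroid_array(neurons)
    if pts.size:
        d = np.linalg.norm(pts - np.asarray(tip.center), axis=1)
    else:
        d = np.empty(0)
    edges = np.arange(0.0, max_radius + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame(
        {
            "r_inner": edges[:-1],
            "r_outer": edges[1:],
            "count": counts,
            "cumulative": np.cumsum(counts),
        }
    )


def local_density(
    tip: FiberTip, neurons: Sequence[NeuronRecord] | np.ndarray
) -> float:
    """Local neuron density (mm⁻³) in the tip's tracing-radius sphere."""
    if tip.tracing_radius <= 0:
        raise ValueError("tracing radius must be positive")
    n = len(sorted_neuron_distances(tip, neurons))
    volume_um3 = (4.0 / 3.0) * math.pi * tip.tracing_radius ** 3
    return n / volume_um3 * 1e9


def expected_count_in_sphere(density_mm3: float, radius_um: float) -> float:
    """Expected Poisson count in a sphere: λ·(4/3)πr³ (density in mm⁻³)."""
    return density_mm3 * 1e-9 * (4.0 / 3.0) * math.pi * radius_um ** 3


# ---------------------------------------------------------------------------
# Hypothetical-fiber grid
# ---------------------------------------------------------------------------

@dataclass
class HypotheticalGrid:
    """Control grid points used as virtual electrode tips."""

    points: np.ndarray  # (n, 3) µm
    spacing: float
    border_margin: float

    def __len__(self) -> int:
        return self.points.shape[0]


def _grid_candidates(volume, spacing: float, margin: float) -> np.ndarray:
    """Axis-aligned lattice centered on the volume centroid, margin applied."""
    cx, cy, cz = volume.centroid
    if volume.shape == "cylinder":
        radius = volume.dimensions[0] / 2.0 - margin
        height = volume.dimensions[1]
        if radius <= 0:
            raise ValueError("volume too small for the requested margin")
        n = int(math.floor(radius / spacing))
        offs = np.arange(-n, n + 1) * spacing
        gx, gy = np.meshgrid(offs, offs, indexing="ij")
        keep = gx**2 + gy**2 <= radius**2 + 1e-9
        xy = np.column_stack([gx[keep] + cx, gy[keep] + cy])
        z0, z1 = margin, height - margin
    else:
        sx, sy, sz = volume.dimensions
        nx = int(math.floor((sx / 2.0 - margin) / spacing))
        ny = int(math.floor((sy / 2.0 - margin) / spacing))
        if nx < 0 or ny < 0:
            raise ValueError("volume too small for the requested margin")
        ox = np.arange(-nx, nx + 1) * spacing + cx
        oy = np.arange(-ny, ny + 1) * spacing + cy
        gx, gy = np.meshgrid(ox, oy, indexing="ij")
        xy = np.column_stack([gx.ravel(), gy.ravel()])
        height = sz
        z0, z1 = margin, height - margin
    nz = int(math.floor((height / 2.0 - margin) / spacing))
    if z1 < z0 or nz < 0:
        raise ValueError("volume too thin for the requested margin")
    zs = cz + np.arange(-nz, nz + 1) * spacing
    zs = zs[(zs >= z0 - 1e-9) & (zs <= z1 + 1e-9)]
    pts = np.column_stack(
        [
            np.repeat(xy, zs.size, axis=0),
            np.tile(zs, xy.shape[0])[:, None],
        ]
    )
    return pts


def _inside_scaffolds(points: np.ndarray, scaffolds: Sequence[NeuronScaffold]) -> np.ndarray:
    """Point-in-soma test against per-plane traced contours (even-odd rule)."""
    inside = np.zeros(points.shape[0], dtype=bool)
    by_plane: dict[int, list[_ShapelyPolygon]] = {}
    z_step = scaffolds[0].z_step if scaffolds else 1.0
    for s in scaffolds:
        for z_index, poly in s.contours:
            by_plane.setdefault(z_index, []).append(_ShapelyPolygon(poly))
    plane_of_point = np.rint(points[:, 2] / z_step).astype(int)
    for z_index, polys in by_plane.items():
        sel = np.nonzero(plane_of_point == z_index)[0]
        if sel.size == 0:
            continue
        xs, ys = points[sel, 0], points[sel, 1]
        hit = np.zeros(sel.size, dtype=bool)
        for poly in polys:
            hit |= shapely.contains_xy(poly, xs, ys)
        inside[sel] |= hit
    return inside


def hypothetical_grid(
    volume,
    somas=None,
    spacing: float = 12.5,
    margin: float = MAX_TRACING_RADIUS,
) -> HypotheticalGrid:
    """Place virtual-tip grid points in unimplanted tissue.

    ``somas`` may be None, a list of :class:`NeuronScaffold` (membership
    tested against the traced contour at the point's z-plane), or a
    synthetic ``NeuronPopulation`` (membership tested against the analytic
    ellipsoids).  Points inside a soma or within ``margin`` of the volume
    border are excluded.
    """
    pts = _grid_candidates(volume, spacing, margin)
    if pts.shape[0] == 0:
        raise ValueError("no grid points survive the border margin")
    if somas is not None:
        if hasattr(somas, "contains_points"):
            inside = somas.contains_points(pts)
        else:
            inside = _inside_scaffolds(pts, list(somas))
        pts = pts[~inside]
    if pts.shape[0] == 0:
        raise ValueError("no grid points survive soma exclusion")
    logger.info("hypothetical grid: %d points", pts.shape[0])
    return HypotheticalGrid(points=pts, spacing=spacing, border_margin=margin)


def grid_kth_distances(
    grid: HypotheticalGrid | np.ndarray,
    neurons: Sequence[NeuronRecord] | np.ndarray,
    kmax: int = 6,
) -> np.ndarray:
    """(n_points, kmax) distances to the k nearest neuron centroids."""
    pts = grid.points if isinstance(grid, HypotheticalGrid) else np.asarray(grid)
    centroids, _ = _centroid_array(neurons)
    if centroids.shape[0] < kmax:
        raise ValueError("fewer neurons than requested neighbor count")
    tree = cKDTree(centroids)
    d, _ = tree.query(pts, k=kmax)
    return np.atleast_2d(d)


def grid_position_summary(
    grid: HypotheticalGrid,
    neurons,
    kmax: int = 6,
    radius: float = MAX_TRACING_RADIUS,
) -> pd.DataFrame:
    """Mean ± SD k-th nearest-neuron distance over grid points (k = 1..kmax).

    A grid point contributes to position k only when its k-th distance lies
    within ``radius`` — the same measurability rule applied to real fibers.
    """
    d = grid_kth_distances(grid, neurons, kmax=kmax)
    rows = []
    for k in range(1, kmax + 1):
        col = d[:, k - 1]
        ok = col <= radius
        vals = col[ok]
        rows.append(
            {
                "position": k,
                "mean": float(vals.mean()) if vals.size else float("nan"),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                "n_fibers": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def poisson_kth_nn_mean(density_per_um3: float, k: int) -> float:
    """Closed-form mean k-th NN distance for a 3D homogeneous Poisson process."""
    if density_per_um3 <= 0:
        raise ValueError("density must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    lam = density_per_um3
    return float(
        _gamma(k + 1.0 / 3.0)
        / _gamma(k)
        * (4.0 * math.pi * lam / 3.0) ** (-1.0 / 3.0)
    )


# ---------------------------------------------------------------------------
# Inter-reviewer localization agreement
# ---------------------------------------------------------------------------

def localization_agreement(
    localizations: Mapping[str, Sequence[Sequence[float]]],
) -> dict:
    """Pairwise agreement of three independent tip localizations per fiber.

    For each fiber with exactly three localizations the three pairwise
    Euclidean distances are pooled; fibers missing a reviewer are excluded
    and logged.  Reports the pooled median and IQR, plus the median in-plane
    (x, y) and axial (z) components of the pairwise differences.
    """
    dists, inplane, axial = [], [], []
    n_fibers = 0
    for fiber_id, locs in localizations.items():
        pts = np.asarray(locs, dtype=float)
        if pts.shape != (3, 3):
            logger.info("excluding fiber %s: %d localization(s)", fiber_id, pts.shape[0])
            continue
        n_fibers += 1
        for i, j in ((0, 1), (0, 2), (1, 2)):
            diff = pts[i] - pts[j]
            dists.append(float(np.linalg.norm(diff)))
            inplane.append(float(np.hypot(diff[0], diff[1])))
            axial.append(abs(float(diff[2])))
    if not dists:
        raise ValueError("no fibers with three localizations")
    arr = np.asarray(dists)
    q1, q3 = np.percentile(arr, [25, 75])
    return {
        "n_fibers": n_fibers,
        "n_comparisons": len(dists),
        "distances": dists,
        "median": float(np.median(arr)),
        "iqr": float(q3 - q1),
        "median_inplane": float(np.median(inplane)),
        "median_axial": float(np.median(axial)),
    }
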