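"""Radial glial (GFAP/IBA1) intensity profiling around electrode tips.

The profile of a stain channel versus distance from an electrode tip is
measured in the tip's own z-plane with concentric 10 µm rings, restricted
to a *lane* — a strip perpendicular to the fitted electrode axis, centered
on the tip, whose width equals the minimum inter-tip pitch so adjacent
fibers never share pixels.  Ring means are normalized by the plane's
background intensity, the mean over pixels 300–310 µm from any tip/tract
reference point, making the profile invariant to acquisition gain.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .spatial_stats import FiberTip

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "RadialProfile",
    "ElectrodeAxis",
    "background_intensity",
    "background_for_plane",
    "fit_electrode_axis",
    "lane_mask",
    "radial_profile",
    "compare_profiles",
    "write_stack",
    "read_stack",
]


@dataclass
class ImageStack:
    """A multichannel-free (single-channel) confocal stack in (z, y, x) order."""

    intensities: np.ndarray
    pixel_size: float  # µm, XY
    z_step: float  # µm
    channel: str = ""
    tip_coords: np.ndarray | None = None  # (n, 3) µm tip centers

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a (z, y, x) array")
        if self.pixel_size <= 0 or self.z_step <= 0:
            raise ValueError("pixel_size and z_step must be positive")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_planes(self) -> int:
        return self.intensities.shape[0]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane pixel-center coordinate grids (µm), origin at stack center."""
        nz, ny, nx = self.intensities.shape
        xs = (np.arange(nx) + 0.5) * self.pixel_size - nx * self.pixel_size / 2.0
        ys = (np.arange(ny) + 0.5) * self.pixel_size - ny * self.pixel_size / 2.0
        return np.meshgrid(xs, ys, indexing="xy")

    def plane_z(self, z_index: int) -> float:
        return (z_index + 0.5) * self.z_step

    def z_index_of(self, z_um: float) -> int:
        idx = int(np.clip(round(z_um / self.z_step - 0.5), 0, self.n_planes - 1))
        return idx


@dataclass
class RadialProfile:
    """Background-normalized mean intensity per 10 µm ring for one fiber."""

    bin_edges: np.ndarray
    ratio: np.ndarray  # NaN where a ring holds no pixels
    background: float
    n_pixels: np.ndarray
    channel: str = ""
    fiber_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_inner": self.bin_edges[:-1],
                "r_outer": self.bin_edges[1:],
                "ratio": self.ratio,
                "n_pixels": self.n_pixels,
            }
        )


# ---------------------------------------------------------------------------
# Background
# ---------------------------------------------------------------------------

def background_intensity(
    plane: np.ndarray,
    distances: np.ndarray,
    annulus: tuple[float, float] = (300.0, 310.0),
) -> float:
    """Mean intensity over pixels whose reference distance is in [300, 310) µm.

    ``distances`` is the per-pixel minimum distance to the reference points
    (tip centers, or tract centers for planes dorsal to a tip).  If the
    annulus is clipped by the field of view, the mean over the remaining
    pixels is used and the count logged; an empty annulus is an error.
    """
    lo, hi = annulus
    mask = (distances >= lo) & (distances < hi)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            "background annulus is empty: enlarge the field of view beyond "
            f"{hi} µm from the reference points"
        )
    if n < mask.size * 0.001:
        logger.info("background annulus clipped: %d pixels", n)
    return float(plane[mask].mean())


def _plane_distances(stack: ImageStack, z_index: int) -> np.ndarray:
    """Min distance of each pixel to any tip, with the dorsal-plane tract rule."""
    if stack.tip_coords is None or len(stack.tip_coords) == 0:
        raise ValueError("stack has no tip coordinates")
    gx, gy = stack.pixel_centers()
    z = stack.plane_z(z_index)
    d = np.full(gx.shape, np.inf)
    for tx, ty, tz in np.atleast_2d(stack.tip_coords):
        inplane2 = (gx - tx) ** 2 + (gy - ty) ** 2
        if z < tz:  # dorsal to this tip: distance to the tract center line
            dist = np.sqrt(inplane2)
        else:
            dist = np.sqrt(inplane2 + (z - tz) ** 2)
        np.minimum(d, dist, out=d)
    return d


def background_for_plane(stack: ImageStack, z_index: int) -> float:
    """Background intensity of one plane using the stack's tip references."""
    return background_intensity(
        stack.intensities[z_index], _plane_distances(stack, z_index)
    )


# ---------------------------------------------------------------------------
# Electrode axis and lanes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeAxis:
    """Total-least-squares line through the coplanar tip (x, y) positions."""

    point: tuple[float, float]
    direction: tuple[float, float]  # unit vector
    residual: float  # RMS perpendicular distance of tips to the line

    def project(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Signed coordinate along the axis."""
        return (x - self.point[0]) * self.direction[0] + (
            y - self.point[1]
        ) * self.direction[1]


def fit_electrode_axis(tips: Sequence[FiberTip]) -> ElectrodeAxis:
    """Fit the electrode-array axis to the tip in-plane positions (TLS/PCA)."""
    pts = np.array([(t.center[0], t.center[1]) for t in tips], dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least two tips to fit the electrode axis")
    mean = pts.mean(axis=0)
    centered = pts - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    perp = centered @ vt[1] if vt.shape[0] > 1 else np.zeros(pts.shape[0])
    residual = float(np.sqrt(np.mean(perp**2)))
    return ElectrodeAxis(
        point=(float(mean[0]), float(mean[1])),
        direction=(float(direction[0]), float(direction[1])),
        residual=residual,
    )


def minimum_pitch(tips: Sequence[FiberTip], axis: ElectrodeAxis) -> float:
    """Smallest along-axis spacing between adjacent tip projections."""
    proj = np.sort(
        axis.project(
            np.array([t.center[0] for t in tips]),
            np.array([t.center[1] for t in tips]),
        )
    )
    if proj.size < 2:
        raise ValueError("need at least two tips for a pitch")
    return float(np.diff(proj).min())


def lane_mask(
    stack: ImageStack,
    tip: FiberTip,
    axis: ElectrodeAxis,
    lane_width: float,
    all_tips: Sequence[FiberTip] | None = None,
) -> np.ndarray:
    """Boolean in-plane mask of the lane belonging to one tip.

    A pixel lies in the lane when its along-axis projection is within
    ±lane_width/2 of the tip's projection.  When ``all_tips`` is given, a
    pixel on a shared boundary goes to the tip with the nearer projection,
    ties to the lower fiber_id — so adjacent lanes are disjoint by
    construction.
    """
    if lane_width <= 0:
        raise ValueError("lane_width must be positive")
    gx, gy = stack.pixel_centers()
    proj = axis.project(gx, gy)
    tip_proj = axis.project(np.array([tip.center[0]]), np.array([tip.center[1]]))[0]
    offset = np.abs(proj - tip_proj)
    mask = offset <= lane_width / 2.0 + 1e-9
    if all_tips:
        order = sorted(all_tips, key=lambda t: t.fiber_id)
        best = np.full(gx.shape, np.inf)
        owner = np.full(gx.shape, -1, dtype=int)
        for rank, other in enumerate(order):
            op = axis.project(
                np.array([other.center[0]]), np.array([other.center[1]])
            )[0]
            dist = np.abs(proj - op)
            closer = dist < best - 1e-9  # strict: ties keep the lower fiber_id
            best = np.where(closer, dist, best)
            owner = np.where(closer, rank, owner)
        my_rank = next(
            i for i, t in enumerate(order) if t.fiber_id == tip.fiber_id
        )
        mask &= owner == my_rank
    return mask


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def radial_profile(
    stack: ImageStack,
    tip: FiberTip,
    lane: np.ndarray | None = None,
    bin_width: float = 10.0,
    max_radius: float = 300.0,
    background: float | None = None,
) -> RadialProfile:
    """Ring profile of one tip at its own z-plane, normalized by background.

    Distances are in-plane (2D), consistent with per-plane rings.  Rings
    with no in-lane pixels report NaN rather than 0.
    """
    z_index = stack.z_index_of(tip.center[2])
    if not (0 <= z_index < stack.n_planes):
        raise ValueError(f"tip {tip.fiber_id} z-plane outside the stack")
    plane = stack.intensities[z_index]
    gx, gy = stack.pixel_centers()
    d = np.hypot(gx - tip.center[0], gy - tip.center[1])
    if background is None:
        background = background_for_plane(stack, z_index)
    sel = lane if lane is not None else np.ones_like(d, dtype=bool)
    edges = np.arange(0.0, max_radius + bin_width, bin_width)
    ratio = np.full(edges.size - 1, np.nan)
    n_pixels = np.zeros(edges.size - 1, dtype=int)
    for i in range(edges.size - 1):
        ring = sel & (d >= edges[i]) & (d < edges[i + 1])
        n = int(ring.sum())
        n_pixels[i] = n
        if n:
            ratio[i] = float(plane[ring].mean()) / background
    return RadialProfile(
        bin_edges=edges,
        ratio=ratio,
        background=float(background),
        n_pixels=n_pixels,
        channel=stack.channel,
        fiber_id=tip.fiber_id,
    )


def compare_profiles(
    implant: Sequence[RadialProfile],
    control: Sequence[RadialProfile],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-bin two-sided two-sample t-tests of implant vs control ratios.

    Bins missing (NaN or absent) in either group are skipped and logged.
    No multiple-testing correction is applied across bins.
    """
    if len(implant) < 2 or len(control) < 2:
        raise ValueError("need at least two profiles per group")
    edges = implant[0].bin_edges
    rows = []
    for i in range(edges.size - 1):
        a = np.array(
            [p.ratio[i] for p in implant if i < p.ratio.size], dtype=float
        )
        b = np.array(
            [p.ratio[i] for p in control if i < p.ratio.size], dtype=float
        )
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            logger.info("skipping bin [%g, %g): insufficient data", edges[i], edges[i + 1])
            continue
        t, p = sstats.ttest_ind(a, b, equal_var=True)
        rows.append(
            {
                "r_inner": edges[i],
                "r_outer": edges[i + 1],
                "mean_implant": a.mean(),
                "mean_control": b.mean(),
                "t": float(t),
                "p": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TIFF + JSON-sidecar IO
# ---------------------------------------------------------------------------

def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as multi-page TIFF with a JSON sidecar of metadata."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.intensities, dtype=np.float32))
    sidecar = {
        "pixel_size": stack.pixel_size,
        "z_step": stack.z_step,
        "channel": stack.channel,
        "tip_coords": (
            np.atleast_2d(stack.tip_coords).tolist()
            if stack.tip_coords is not None
            else []
        ),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_stack(path: str | Path) -> ImageStack:
    import tifffile

    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    tips = np.asarray(meta.get("tip_coords", []), dtype=float)
    return ImageStack(
        intensities=np.atleast_3d(data) if data.ndim == 3 else data[None],
        pixel_size=float(meta["pixel_size"]),
        z_step=float(meta["z_step"]),
        channel=meta.get("channel", ""),
        tip_coords=tips if tips.size else None,
    )
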