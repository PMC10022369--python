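"""Point-source extracellular spike-amplitude model and discriminability.

A firing neuron is treated as a point current source in a homogeneous,
isotropic medium, so the peak–peak potential seen by an electrode at
distance r is

    V_pp(r) = I_pp / (4 π σ r),

with the unit convention fixed here as V[µV] = I[nA] · 10³ / (4π · σ[S/m] ·
r[µm]).  I_pp is the peak–peak extracellular current of a spike and σ the
tissue conductivity (default 0.27 S/m, a standard cortical value).  The
model assumes every neuron has the same spiking output, so amplitude is a
function of distance alone.

The module provides the forward model, three fitting routes (I_pp with σ
fixed against mean rank-wise amplitude/position pairs; I_pp and σ jointly;
I_pp with σ fixed against per-cluster pairs), cluster ranking and pairing
with nearest-neuron positions, a discriminability analysis that finds the
neuron rank at which consecutive predicted amplitudes fall below a noise
threshold, and predicted-waveform scaling.

Note on the two-parameter fit: V_pp depends on I_pp and σ only through the
ratio I_pp/σ, so the joint fit is structurally non-identifiable — the
returned pair depends on the (documented) initialization, and only the
ratio is meaningful.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

SAMPLING_RATE_HZ = 24_414.1
DEFAULT_SIGMA = 0.27  # S/m

__all__ = [
    "SAMPLING_RATE_HZ",
    "DEFAULT_SIGMA",
    "PointSourceParams",
    "SpikeCluster",
    "AmplitudeDistancePair",
    "DiscriminabilityResult",
    "predict_vpp",
    "peak_to_peak",
    "summarize_and_rank_clusters",
    "pair_amplitudes_with_positions",
    "fit_ipp_fixed_sigma",
    "fit_ipp_and_sigma",
    "discriminability",
    "scale_waveforms",
]


@dataclass(frozen=True)
class PointSourceParams:
    """Model parameters: I_pp in nA, sigma in S/m."""

    i_pp: float
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        if self.i_pp <= 0:
            raise ValueError("I_pp must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def ratio(self) -> float:
        """The identifiable quantity I_pp/σ (nA·m/S)."""
        return self.i_pp / self.sigma


def predict_vpp(r, params: PointSourceParams):
    """Predicted peak–peak amplitude in µV at distance(s) r in µm."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance r must be positive")
    out = params.i_pp * 1e3 / (4.0 * math.pi * params.sigma * r)
    return float(out) if out.ndim == 0 else out


def peak_to_peak(waveforms: np.ndarray) -> np.ndarray:
    """Per-spike peak–peak amplitude (max − min over samples)."""
    w = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if w.size == 0:
        raise ValueError("empty waveform array")
    return w.max(axis=1) - w.min(axis=1)


@dataclass
class SpikeCluster:
    """A sorted spike cluster: (spike × sample) waveforms in µV at 24 414.1 Hz."""

    channel_id: str
    waveforms: np.ndarray
    rank: int | None = None
    mean_vpp: float = field(init=False)

    def __post_init__(self) -> None:
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=float))
        if self.waveforms.size == 0:
            raise ValueError(f"cluster on channel {self.channel_id} has no spikes")
        self.mean_vpp = float(peak_to_peak(self.waveforms).mean())


@dataclass(frozen=True)
class AmplitudeDistancePair:
    """A cluster amplitude matched with the same-rank nearest-neuron distance."""

    v_pp: float
    r: float
    channel_id: str
    rank: int

    def __post_init__(self) -> None:
        if self.v_pp <= 0 or self.r <= 0:
            raise ValueError("V_pp and r must be positive")


def summarize_and_rank_clusters(
    clusters: Sequence[SpikeCluster],
) -> list[SpikeCluster]:
    """Sort one channel's clusters by descending mean V_pp; stable on ties.

    Rank 1 is the largest cluster.
    """
    if not clusters:
        raise ValueError("no clusters to rank")
    order = sorted(
        range(len(clusters)), key=lambda i: (-clusters[i].mean_vpp, i)
    )
    ranked = []
    for rank, i in enumerate(order, start=1):
        c = clusters[i]
        c.rank = rank
        ranked.append(c)
    return ranked


def pair_amplitudes_with_positions(
    ranked_by_channel: Mapping[str, Sequence[SpikeCluster]],
    distances_by_fiber: Mapping[str, Sequence[float]],
    channel_to_fiber: Mapping[str, str],
) -> list[AmplitudeDistancePair]:
    """Match each channel's rank-k cluster with its fiber's k-th nearest neuron.

    ``distances_by_fiber`` holds each fiber's ascending neuron distances
    inside its tracing radius.  A pair is dropped (with a log record) when
    the k-th position was not measured for that fiber — e.g. a tip too close
    to the top of the slice truncated the tracing radius.
    """
    pairs: list[AmplitudeDistancePair] = []
    for channel_id, clusters in ranked_by_channel.items():
        if channel_id not in channel_to_fiber:
            raise KeyError(f"channel {channel_id!r} has no fiber mapping")
        fiber_id = channel_to_fiber[channel_id]
        distances = list(distances_by_fiber.get(fiber_id, []))
        for cluster in clusters:
            k = cluster.rank
            if k is None:
                raise ValueError("clusters must be ranked before pairing")
            if k > len(distances):
                logger.info(
                    "dropping cluster rank %d on channel %s: position %d "
                    "not measured for fiber %s",
                    k, channel_id, k, fiber_id,
                )
                continue
            pairs.append(
                AmplitudeDistancePair(
                    v_pp=cluster.mean_vpp,
                    r=float(distances[k - 1]),
                    channel_id=channel_id,
                    rank=k,
                )
            )
    return pairs


def _as_arrays(
    pairs_or_amplitudes, positions=None
) -> tuple[np.ndarray, np.ndarray]:
    if positions is None:
        pairs: Iterable[AmplitudeDistancePair] = pairs_or_amplitudes
        v = np.array([p.v_pp for p in pairs], dtype=float)
        r = np.array([p.r for p in pairs], dtype=float)
    else:
        v = np.asarray(pairs_or_amplitudes, dtype=float)
        r = np.asarray(positions, dtype=float)
    if v.size == 0:
        raise ValueError("no amplitude/distance pairs to fit")
    return v, r


def fit_ipp_fixed_sigma(
    pairs_or_amplitudes, positions=None, sigma: float = DEFAULT_SIGMA
) -> float:
    """Least-squares I_pp (nA) for V = I_pp·10³/(4πσr) with σ fixed.

    Accepts either a sequence of :class:`AmplitudeDistancePair` or parallel
    (amplitudes, positions) arrays.  The model is linear in I_pp, so the
    solution is the closed form Σ(V_i x_i)/Σ(x_i²) with x_i = 10³/(4πσr_i).
    """
    v, r = _as_arrays(pairs_or_amplitudes, positions)
    x = 1e3 / (4.0 * math.pi * sigma * r)
    return float(np.dot(v, x) / np.dot(x, x))


def fit_ipp_and_sigma(
    pairs_or_amplitudes,
    positions=None,
    init: tuple[float, float] = (10.0, DEFAULT_SIGMA),
) -> tuple[PointSourceParams, float]:
    """Jointly fit (I_pp, σ) by nonlinear least squares.

    Returns the fitted parameters and the converged residual norm.  Because
    the model depends only on I_pp/σ, the individual values inherit the
    initialization scale; interpret ``params.ratio``.
    """
    v, r = _as_arrays(pairs_or_amplitudes, positions)
    if np.unique(r).size < 2:
        raise ValueError("need >=2 pairs with distinct r")

    def resid(theta):
        i_pp, sigma = theta
        return i_pp * 1e3 / (4.0 * math.pi * sigma * r) - v

    sol = least_squares(resid, x0=np.asarray(init, dtype=float),
                        bounds=([1e-9, 1e-9], [np.inf, np.inf]))
    if not sol.success:
        raise RuntimeError(f"joint (I_pp, sigma) fit did not converge: {sol.message}")
    residual = float(np.linalg.norm(sol.fun))
    return PointSourceParams(i_pp=float(sol.x[0]), sigma=float(sol.x[1])), residual


@dataclass(frozen=True)
class DiscriminabilityResult:
    """Predicted amplitudes per neuron rank and the sortability boundary."""

    positions: tuple[float, ...]
    predicted: tuple[float, ...]
    consecutive_diffs: tuple[float, ...]
    boundary_rank: dict[float, int]
    thresholds: tuple[float, ...]


def discriminability(
    positions: Sequence[float],
    params: PointSourceParams,
    thresholds: Sequence[float] = (15.0, 10.0),
) -> DiscriminabilityResult:
    """Find the neuron rank where consecutive amplitudes sink into the noise.

    ``positions`` are the mean distances of the 1st..n-th nearest neurons
    (strictly increasing).  With predicted amplitudes V(k), the consecutive
    differences are d_k = V(k) − V(k+1); for threshold θ the boundary rank is
    the smallest k such that d_j < θ for all j >= k — the k-th neuron sits on
    the boundary of the easy sorting zone (ranks 1..k).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size < 2:
        raise ValueError("need at least two positions")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    predicted = predict_vpp(pos, params)
    diffs = -np.diff(predicted)  # V(k) - V(k+1) > 0
    boundary: dict[float, int] = {}
    for theta in thresholds:
        below = diffs < theta
        # smallest k (1-based) with all diffs from k on below theta
        k = diffs.size + 1
        for j in range(diffs.size - 1, -1, -1):
            if below[j]:
                k = j + 1
            else:
                break
        boundary[float(theta)] = int(k)
    return DiscriminabilityResult(
        positions=tuple(pos),
        predicted=tuple(float(x) for x in predicted),
        consecutive_diffs=tuple(float(x) for x in diffs),
        boundary_rank=boundary,
        thresholds=tuple(float(t) for t in thresholds),
    )


def scale_waveforms(
    spikes: np.ndarray,
    positions: Sequence[float],
    params: PointSourceParams,
    tol: float = 1e-6,
) -> list[dict]:
    """Scale unit peak–peak spikes to the predicted amplitude per position.

    ``spikes`` is (n_spikes, n_samples) with every spike normalized to a
    peak–peak amplitude of 1.  For each position r_k, all spikes are scaled
    by predict_vpp(r_k); the mean and SD waveform of the scaled bundle are
    returned.  The mean waveform's peak–peak is <= the predicted amplitude,
    with equality only when the spikes are peak-aligned.
    """
    spikes = np.atleast_2d(np.asarray(spikes, dtype=float))
    pp = peak_to_peak(spikes)
    if np.any(np.abs(pp - 1.0) > tol):
        raise ValueError("spikes must be normalized to unit peak-peak amplitude")
    out = []
    for k, r in enumerate(positions, start=1):
        amp = predict_vpp(float(r), params)
        scaled = spikes * amp
        out.append(
            {
                "rank": k,
                "r": float(r),
                "predicted_vpp": amp,
                "mean_waveform": scaled.mean(axis=0),
                "sd_waveform": scaled.std(axis=0, ddof=0),
            }
        )
    return out
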