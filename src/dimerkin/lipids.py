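"""Persistence/exchange-time analysis of lipid tracers (CTRW view).

The lipid motion is coarse-grained as a sequence of displacements of
length *d* (default 10 Å).  From a time origin t₀ the *persistence time*
t_P is the first time the in-plane displacement from x(t₀) exceeds d; the
*exchange times* t_X,i are then defined recursively as the waiting times
between successive displacements of length d.  ⟨t_X⟩ sets the local
diffusion coefficient D ≈ d²/⟨t_X⟩ while ⟨t_P⟩ tracks the local effective
viscosity; their ratio exceeds 1 in dynamically heterogeneous ("jammed")
regions where the Stokes–Einstein coupling breaks down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trajectory import A2_PER_NS_TO_CM2_PER_S

__all__ = [
    "ResidenceSample",
    "SpatialMap",
    "compute_residence_times",
    "build_spatial_maps",
    "diffusion_from_exchange",
    "KramersParams",
    "kramers_rate",
]


@dataclass
class ResidenceSample:
    """Residence statistics from one time origin of one tracer.

    ``t_P`` is None when the tracer never left the d-neighborhood of its
    origin before the trajectory ended (censored); ``t_X`` is the ordered
    sequence of exchange times observed after the first displacement.
    """

    tracer_id: int
    origin_xy: np.ndarray  # receptor-frame position of the origin, Å
    t_P: float | None
    t_X: np.ndarray
    leaflet: str = "upper"

    @property
    def censored(self) -> bool:
        return self.t_P is None


def _next_crossing(
    xy: np.ndarray,
    times: np.ndarray,
    ref_xy: np.ndarray,
    ref_time: float,
    start: int,
    d: float,
    chunk: int = 512,
) -> tuple[float, int] | None:
    """First index ≥ start with |xy - ref_xy| > d, with interpolated time.

    Returns ``(crossing_time, frame_index)`` or None if no crossing occurs
    before the trajectory ends.  The crossing time is refined by linear
    interpolation of the displacement magnitude between the bracketing
    frames (exact for uniform motion, unbiased for jump processes).
    """
    n = len(times)
    d2 = d * d
    s = start
    while s < n:
        e = min(s + chunk, n)
        dd = xy[s:e] - ref_xy
        r2 = dd[:, 0] ** 2 + dd[:, 1] ** 2
        hits = np.nonzero(r2 > d2)[0]
        if hits.size:
            idx = s + int(hits[0])
            r1 = float(np.sqrt(r2[hits[0]]))
            if idx == 0:
                return float(times[0]), 0
            prev = xy[idx - 1] - ref_xy
            r0 = float(np.hypot(prev[0], prev[1]))
            t_lo = max(float(times[idx - 1]), ref_time)
            frac = (d - r0) / (r1 - r0) if r1 > r0 else 1.0
            frac = min(max(frac, 0.0), 1.0)
            return t_lo + frac * (float(times[idx]) - t_lo), idx
        s = e
    return None


def compute_residence_times(
    positions: np.ndarray,
    times: np.ndarray,
    d: float = 10.0,
    origin_stride: int = 10,
    max_exchanges: int | None = None,
    tracer_id: int = 0,
    leaflet: str = "upper",
    origin_frames: Sequence[int] | None = None,
) -> list[ResidenceSample]:
    """Persistence and exchange times of one unwrapped tracer trajectory.

    Parameters
    ----------
    positions : (n_frames, 2) or (n_frames, 3) array, Å, **unwrapped**;
        only the in-plane (x, y) components are used.
    times : (n_frames,) array, ns.
    d : coarse-graining length, Å (default 10).
    origin_stride : take every ``origin_stride``-th frame as a time origin
        (origins decorrelate at roughly the exchange time).
    max_exchanges : optional cap on the exchange-time sequence per origin.
    origin_frames : explicit origin frame indices (overrides the stride).

    Returns one :class:`ResidenceSample` per origin; origins whose
    displacement never exceeds ``d`` are censored.
    """
    positions = np.asarray(positions, dtype=float)
    times = np.asarray(times, dtype=float)
    if positions.ndim != 2 or len(positions) != len(times):
        raise ValueError("positions must be (n_frames, 2 or 3) matching times")
    if len(times) < 2:
        raise ValueError("need at least 2 frames")
    if d <= 0:
        raise ValueError("coarse-graining length d must be positive")
    xy = np.ascontiguousarray(positions[:, :2])
    origins = (
        list(origin_frames)
        if origin_frames is not None
        else list(range(0, len(times) - 1, max(origin_stride, 1)))
    )
    out: list[ResidenceSample] = []
    for o in origins:
        t0 = float(times[o])
        hit = _next_crossing(xy, times, xy[o], t0, o + 1, d)
        if hit is None:
            out.append(ResidenceSample(tracer_id, xy[o].copy(), None, np.empty(0), leaflet))
            continue
        t_cross, idx = hit
        t_P = t_cross - t0
        # the renewal reference resets to the first sampled frame past each
        # crossing; time and position are taken at that same frame so the
        # chain of exchange times is self-consistent (exact for uniform motion)
        ref_time = float(times[idx])
        t_X: list[float] = []
        while True:
            if max_exchanges is not None and len(t_X) >= max_exchanges:
                break
            hit = _next_crossing(xy, times, xy[idx], ref_time, idx + 1, d)
            if hit is None:
                break
            t_next, idx_next = hit
            t_X.append(t_next - ref_time)
            idx = idx_next
            ref_time = float(times[idx])
        out.append(ResidenceSample(tracer_id, xy[o].copy(), t_P, np.array(t_X), leaflet))
    return out


@dataclass
class SpatialMap:
    """2D map of ⟨t_P⟩, ⟨t_X⟩ and their ratio in the receptor frame.

    Bins of ``bin_size`` Å (default 1 Å) keyed to the origin position of
    each residence sample.  ``ratio`` is defined only where both means have
    at least ``min_occupancy`` samples; other bins are NaN-masked.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    mean_t_P: np.ndarray
    mean_t_X: np.ndarray
    count_t_P: np.ndarray
    count_t_X: np.ndarray
    censored_fraction: np.ndarray
    bin_size: float

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.mean_t_P / self.mean_t_X

    def to_frame(self) -> pd.DataFrame:
        """Gridded text layout: x, y, t_P, t_X, ratio, counts."""
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "t_P": self.mean_t_P.ravel(),
                "t_X": self.mean_t_X.ravel(),
                "ratio": self.ratio.ravel(),
                "n_t_P": self.count_t_P.ravel(),
                "n_t_X": self.count_t_X.ravel(),
                "censored_fraction": self.censored_fraction.ravel(),
            }
        )

    def render(self, path: str | Path, quantity: str = "ratio") -> None:
        """Write a PNG heat map of t_P, t_X or their ratio."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        data = {"t_P": self.mean_t_P, "t_X": self.mean_t_X, "ratio": self.ratio}[quantity]
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.pcolormesh(self.x_edges, self.y_edges, data.T, shading="auto")
        fig.colorbar(im, ax=ax, label=quantity)
        ax.set_xlabel("x (Å)")
        ax.set_ylabel("y (Å)")
        ax.set_aspect("equal")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def build_spatial_maps(
    samples: Iterable[ResidenceSample],
    bin_size: float = 1.0,
    min_occupancy: int = 1,
    extent: tuple[float, float, float, float] | None = None,
    transforms: dict | None = None,
) -> SpatialMap:
    """Bin residence samples by origin position and average per bin.

    Censored t_P values are excluded from the t_P mean (their fraction is
    reported per bin); every exchange time contributes to the t_X mean of
    its origin's bin.  ``transforms`` optionally maps a key
    ``(tracer_id, leaflet)`` to a receptor-frame ``(R, t)`` pair applied to
    the origin before binning (lower-leaflet mirroring, protomer alignment).
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    samples = list(samples)
    if not samples:
        raise ValueError("no samples")

    origins = np.empty((len(samples), 2))
    for i, s in enumerate(samples):
        xy = s.origin_xy
        if transforms is not None:
            R, t = transforms.get((s.tracer_id, s.leaflet), (np.eye(2), np.zeros(2)))
            xy = R @ xy + t
        origins[i] = xy

    if extent is None:
        x0, x1 = origins[:, 0].min(), origins[:, 0].max() + 1e-9
        y0, y1 = origins[:, 1].min(), origins[:, 1].max() + 1e-9
    else:
        x0, x1, y0, y1 = extent
    x_edges = np.arange(x0, x1 + bin_size, bin_size)
    y_edges = np.arange(y0, y1 + bin_size, bin_size)
    nx, ny = len(x_edges) - 1, len(y_edges) - 1

    ix = np.clip(np.digitize(origins[:, 0], x_edges) - 1, 0, nx - 1)
    iy = np.clip(np.digitize(origins[:, 1], y_edges) - 1, 0, ny - 1)

    sum_tp = np.zeros((nx, ny))
    n_tp = np.zeros((nx, ny))
    n_cens = np.zeros((nx, ny))
    sum_tx = np.zeros((nx, ny))
    n_tx = np.zeros((nx, ny))
    for i, s in enumerate(samples):
        bx, by = ix[i], iy[i]
        if s.censored:
            n_cens[bx, by] += 1
        else:
            sum_tp[bx, by] += s.t_P
            n_tp[bx, by] += 1
        if len(s.t_X):
            sum_tx[bx, by] += s.t_X.sum()
            n_tx[bx, by] += len(s.t_X)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_tp = np.where(n_tp >= min_occupancy, sum_tp / n_tp, np.nan)
        mean_tx = np.where(n_tx >= min_occupancy, sum_tx / n_tx, np.nan)
        cens = np.where(n_tp + n_cens > 0, n_cens / (n_tp + n_cens), np.nan)
    return SpatialMap(x_edges, y_edges, mean_tp, mean_tx, n_tp, n_tx, cens, bin_size)


def diffusion_from_exchange(
    mean_t_X: float, d: float = 10.0, effective_factor: float | None = None
) -> float:
    """Diffusion coefficient D = d²/⟨t_X⟩ in cm²/s.

    ``effective_factor`` applies the CG effective-time correction (divide
    by the ×4 scaling so that D refers to effective time).
    """
    if mean_t_X <= 0 or d <= 0:
        raise ValueError("mean exchange time and d must be positive")
    D = d * d / mean_t_X * A2_PER_NS_TO_CM2_PER_S
    if effective_factor is not None:
        if effective_factor < 1:
            raise ValueError("effective factor must be >= 1")
        D /= effective_factor
    return D


@dataclass(frozen=True)
class KramersParams:
    """Inputs to the Kramers barrier-crossing rate in the high-friction form."""

    m: float  # effective mass
    omega_well: float  # well curvature frequency
    omega_barrier: float  # barrier curvature frequency
    barrier_height: float  # G†, same units as kBT
    eta: float  # effective viscosity (friction)
    kBT: float

    def __post_init__(self) -> None:
        if min(self.omega_well, self.omega_barrier, self.eta, self.kBT) <= 0:
            raise ValueError("curvatures, viscosity and kBT must be positive")


def kramers_rate(params: KramersParams) -> float:
    """Barrier-crossing rate k = m ω† ω / (2πη) · exp(−G†/kBT)."""
    pre = params.m * params.omega_barrier * params.omega_well / (2 * np.pi * params.eta)
    return pre * np.exp(-params.barrier_height / params.kBT)
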