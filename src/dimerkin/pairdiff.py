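"""Position-dependent pair diffusion and free-energy barriers.

The approach distance of a protomer pair is modelled as a 1D birth–death
Markov process over distance bins (default 30–90 Å).  Given lagged
transition counts N_jj', the posterior over the nearest-neighbor generator
K is p(K|X) ∝ exp(Σ N_jj' ln(e^{τK})_jj') with a flat prior on log-rates,
and the position-dependent diffusion profile follows from

    D_j ≈ (Δd)² K_{j,j+1} (P_j / P_{j+1})^{1/2}

with P the stationary distribution of K.  Free-energy barriers along a
steered angular coordinate are estimated with the Jarzynski equality
applied to sets of work traces (mean over sets, set scatter as the error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm, null_space

from .mcmc import McmcResult, McmcSettings, sample_posterior
from .synthetic import KBT_300K, WorkTrace
from .trajectory import A2_PER_NS_TO_CM2_PER_S, BeadTrajectory, minimum_image_displacement

__all__ = [
    "PairGeometry",
    "BinnedPairTrajectory",
    "extract_pair_trajectories",
    "RateMatrixModel",
    "RateMatrixResults",
    "build_tridiagonal_generator",
    "stationary_distribution",
    "diffusion_profile",
    "PmfProfile",
    "jarzynski_pmf",
]


@dataclass
class PairGeometry:
    """Per-frame relative geometry of one protomer pair.

    ``d`` is the in-plane center-of-mass distance (Å); ``phi1``/``phi2``
    are the angles between the COM–COM direction and each protomer's TM4
    axis, wrapped to [0, 2π).
    """

    times: np.ndarray
    d: np.ndarray
    phi1: np.ndarray
    phi2: np.ndarray
    pair: tuple[int, int]
    valid: np.ndarray  # third-protomer exclusion mask


@dataclass
class BinnedPairTrajectory:
    """Distance-binned pair trajectories with lagged transition counts."""

    bin_edges: np.ndarray  # Å
    tau: float  # ns
    counts: np.ndarray  # N_jj'
    segments: list[np.ndarray] = field(default_factory=list)  # bin-index series

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("transition counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def delta_d(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def is_connected(self) -> bool:
        """All bins with any observation reachable through observed hops."""
        m = self.n_bins
        touched = np.nonzero(self.counts.sum(axis=0) + self.counts.sum(axis=1))[0]
        if len(touched) == 0:
            return False
        adj = (self.counts + self.counts.T) > 0
        seen = {int(touched[0])}
        stack = [int(touched[0])]
        while stack:
            j = stack.pop()
            for j2 in np.nonzero(adj[j])[0]:
                if int(j2) not in seen:
                    seen.add(int(j2))
                    stack.append(int(j2))
        return all(int(j) in seen for j in touched)


def _tm4_axis(traj: BeadTrajectory, protomer: int, frame: int) -> np.ndarray:
    """In-plane unit vector from the protomer centroid to its TM4 beads."""
    top = traj.topologies[protomer]
    beads = traj.positions[frame, top.bead_indices, :2]
    centroid = beads.mean(axis=0)
    tm4_res = [r for r, h in ((r, top.tm.helix_of(r)) for r in top.residues) if h == "TM4"]
    if not tm4_res:
        raise ValueError("protomer has no TM4 residues")
    lo = top.residue_range[0]
    idx = [top.bead_indices[r - lo] for r in tm4_res]
    v = traj.positions[frame, idx, :2].mean(axis=0) - centroid
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate TM4 axis")
    return v / n


def compute_pair_geometry(traj: BeadTrajectory, i: int, j: int) -> PairGeometry:
    """COM distance and TM4 angles (ϕ1, ϕ2) for a protomer pair, all frames.

    Frames in which the pair is in contact with a third protomer — any
    third centroid closer to either partner than the pair distance — are
    flagged invalid (``valid`` mask), never bridged.
    """
    n_prot = len(traj.topologies)
    if n_prot < 2:
        raise ValueError("need at least two protomers")
    cents = np.stack(
        [traj.positions[:, top.bead_indices, :2].mean(axis=1) for top in traj.topologies],
        axis=1,
    )  # (n_frames, n_prot, 2)
    box2 = traj.box[:, :2]
    dij = minimum_image_displacement(cents[:, i], cents[:, j], box2)
    d = np.hypot(dij[:, 0], dij[:, 1])
    valid = np.ones(traj.n_frames, dtype=bool)
    for k in range(n_prot):
        if k in (i, j):
            continue
        dik = minimum_image_displacement(cents[:, i], cents[:, k], box2)
        djk = minimum_image_displacement(cents[:, j], cents[:, k], box2)
        near = np.minimum(np.hypot(dik[:, 0], dik[:, 1]), np.hypot(djk[:, 0], djk[:, 1]))
        valid &= d < near
    phi1 = np.empty(traj.n_frames)
    phi2 = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        u = dij[f] / max(d[f], 1e-12)
        a1 = _tm4_axis(traj, i, f)
        a2 = _tm4_axis(traj, j, f)
        phi1[f] = np.arctan2(u[1], u[0]) - np.arctan2(a1[1], a1[0])
        phi2[f] = np.arctan2(-u[1], -u[0]) - np.arctan2(a2[1], a2[0])
    return PairGeometry(
        traj.times.copy(), d, phi1 % (2 * np.pi), phi2 % (2 * np.pi), (i, j), valid
    )


def extract_pair_trajectories(
    traj: BeadTrajectory,
    bin_edges: np.ndarray | None = None,
    tau_frames: int = 1,
    window: tuple[tuple[float, float], tuple[float, float]] | None = None,
    pairs: Sequence[tuple[int, int]] | None = None,
) -> BinnedPairTrajectory:
    """Binned pair-distance trajectories with third-protomer exclusion.

    ``bin_edges`` defaults to 30–90 Å in 10 Å bins.  ``window`` optionally
    restricts to an angular region {α1≤ϕ1≤β1, α2≤ϕ2≤β2}.  Frames failing
    the third-protomer rule or leaving the distance range split the series
    into segments; lagged transitions (lag ``tau_frames`` stored frames)
    are only counted within contiguous segments.
    """
    if bin_edges is None:
        bin_edges = np.arange(30.0, 90.0 + 10.0, 10.0)
    bin_edges = np.asarray(bin_edges, dtype=float)
    n_bins = len(bin_edges) - 1
    if pairs is None:
        n_prot = len(traj.topologies)
        pairs = [(i, j) for i in range(n_prot) for j in range(i + 1, n_prot)]
    counts = np.zeros((n_bins, n_bins))
    segments: list[np.ndarray] = []
    for i, j in pairs:
        geo = compute_pair_geometry(traj, i, j)
        ok = geo.valid & (geo.d >= bin_edges[0]) & (geo.d <= bin_edges[-1])
        if window is not None:
            (a1, b1), (a2, b2) = window
            ok &= (geo.phi1 >= a1) & (geo.phi1 <= b1) & (geo.phi2 >= a2) & (geo.phi2 <= b2)
            if not ok.any():
                raise ValueError("empty window selection")
        bins = np.clip(np.digitize(geo.d, bin_edges) - 1, 0, n_bins - 1)
        # split into contiguous valid segments
        edges = np.nonzero(np.diff(ok.astype(int)))[0] + 1
        for seg in np.split(np.arange(traj.n_frames), edges):
            if len(seg) == 0 or not ok[seg[0]]:
                continue
            series = bins[seg]
            segments.append(series)
            if len(series) > tau_frames:
                np.add.at(counts, (series[:-tau_frames], series[tau_frames:]), 1.0)
    tau = float(np.median(np.diff(traj.times))) * tau_frames
    return BinnedPairTrajectory(bin_edges, tau, counts, segments)


def build_tridiagonal_generator(log_up: np.ndarray, log_down: np.ndarray) -> np.ndarray:
    """Nearest-neighbor generator from log up/down rates (reflecting ends)."""
    m = len(log_up) + 1
    K = np.zeros((m, m))
    up = np.exp(log_up)
    down = np.exp(log_down)
    for j in range(m - 1):
        K[j, j + 1] = up[j]
        K[j + 1, j] = down[j]
    np.fill_diagonal(K, 0.0)
    np.fill_diagonal(K, -K.sum(axis=1))
    return K


def stationary_distribution(K: np.ndarray) -> np.ndarray:
    """Stationary probability vector (null left-eigenvector of K).

    For a tridiagonal generator the stationary weights satisfy the
    birth–death recursion P_{j+1} = P_j K_{j,j+1}/K_{j+1,j}; the general
    null-space solution is used as a fallback.
    """
    m = K.shape[0]
    off_ok = all(K[j + 1, j] > 0 for j in range(m - 1))
    if off_ok:
        logP = np.zeros(m)
        for j in range(m - 1):
            logP[j + 1] = logP[j] + np.log(K[j, j + 1]) - np.log(K[j + 1, j])
        P = np.exp(logP - logP.max())
    else:
        ns = null_space(K.T)
        if ns.shape[1] == 0:
            raise ValueError("no stationary distribution")
        P = np.abs(ns[:, 0])
    return P / P.sum()


class RateMatrixModel:
    """Bayesian nearest-neighbor rate-matrix model for binned distances.

    The likelihood is ln p(X|K) = Σ_jj' N_jj' ln(e^{τK})_jj'; the prior is
    flat on the log up/down rates within ``log_rate_bounds`` (a proper
    surrogate for a uniform prior on K).  ``fit`` samples the posterior by
    Metropolis-within-Gibbs and derives stationary weights and the
    diffusion profile per draw.
    """

    def __init__(
        self,
        binned: BinnedPairTrajectory,
        log_rate_bounds: tuple[float, float] = (-10.0, 10.0),
    ) -> None:
        if binned.counts.sum() == 0:
            raise ValueError("empty count matrix")
        if binned.tau <= 0:
            raise ValueError("lag must be positive")
        if not binned.is_connected():
            raise ValueError("disconnected bin graph: some bin unreachable")
        self.binned = binned
        self.log_rate_bounds = log_rate_bounds
        self._N = binned.counts
        self._m = binned.n_bins

    def loglike(self, theta: np.ndarray) -> float:
        """Σ N_jj' ln(e^{τK})_jj' at log-rates theta = [log_up, log_down]."""
        m = self._m
        K = build_tridiagonal_generator(theta[: m - 1], theta[m - 1 :])
        T = expm(self.binned.tau * K)
        with np.errstate(divide="ignore"):
            logT = np.log(np.clip(T, 1e-300, None))
        return float((self._N * logT).sum())

    def logpost(self, theta: np.ndarray) -> float:
        lo, hi = self.log_rate_bounds
        if np.any(theta < lo) or np.any(theta > hi):
            return -np.inf
        return self.loglike(theta)

    def _initial_rates(self) -> np.ndarray:
        """Crude rate guesses from the row-normalized transition counts."""
        N = self._N
        tau = self.binned.tau
        tot = np.maximum(N.sum(axis=1), 1.0)
        up = np.array([max(N[j, j + 1], 0.5) / tot[j] / tau for j in range(self._m - 1)])
        down = np.array([max(N[j + 1, j], 0.5) / tot[j + 1] / tau for j in range(self._m - 1)])
        lo, hi = self.log_rate_bounds
        return np.clip(np.log(np.concatenate([up, down])), lo + 1.0, hi - 1.0)

    def fit(self, settings: McmcSettings | None = None) -> "RateMatrixResults":
        settings = settings or McmcSettings()
        res = sample_posterior(self.logpost, self._initial_rates(), settings, scales=None)
        return RateMatrixResults(self, res)


@dataclass
class RateMatrixResults:
    """Posterior over the generator K with derived D_j profile."""

    model: RateMatrixModel
    mcmc: McmcResult
    ci: tuple[float, float] = (25.0, 95.0)

    def __post_init__(self) -> None:
        m = self.model._m
        th = self.mcmc.samples
        n = th.shape[0]
        self.K_samples = np.empty((n, m, m))
        self.P_samples = np.empty((n, m))
        for s in range(n):
            K = build_tridiagonal_generator(th[s, : m - 1], th[s, m - 1 :])
            self.K_samples[s] = K
            self.P_samples[s] = stationary_distribution(K)

    @property
    def K_mean(self) -> np.ndarray:
        return self.K_samples.mean(axis=0)

    def diffusion_samples(self) -> np.ndarray:
        """Per-draw D_j = (Δd)² K_{j,j+1} (P_j/P_{j+1})^{1/2}, in cm²/s."""
        return diffusion_profile_samples(
            self.K_samples, self.P_samples, self.model.binned.delta_d
        )

    def summary(self) -> pd.DataFrame:
        """Per-edge diffusion profile with mean and credible interval."""
        D = self.diffusion_samples()
        lo, hi = np.percentile(D, self.ci, axis=0)
        edges = self.model.binned.bin_edges
        centers = 0.5 * (edges[:-1] + edges[1:])
        return pd.DataFrame(
            {
                "d_A": 0.5 * (centers[:-1] + centers[1:]),
                "D_mean_cm2_s": D.mean(axis=0),
                f"ci_{self.ci[0]}%": lo,
                f"ci_{self.ci[1]}%": hi,
            }
        )


def diffusion_profile_samples(
    K_samples: np.ndarray, P_samples: np.ndarray, delta_d: float
) -> np.ndarray:
    """D_j per posterior draw (Å²/ns converted to cm²/s)."""
    if np.any(P_samples <= 0):
        raise ValueError("zero stationary weight in a bin")
    m = K_samples.shape[1]
    j = np.arange(m - 1)
    Kup = K_samples[:, j, j + 1]
    ratio = np.sqrt(P_samples[:, :-1] / P_samples[:, 1:])
    return delta_d**2 * Kup * ratio * A2_PER_NS_TO_CM2_PER_S


def diffusion_profile(K: np.ndarray, delta_d: float, P: np.ndarray | None = None) -> np.ndarray:
    """Diffusion profile of a single generator, in cm²/s."""
    P = stationary_distribution(K) if P is None else np.asarray(P, dtype=float)
    return diffusion_profile_samples(K[None], P[None], delta_d)[0]


# ---------------------------------------------------------------------------
# Jarzynski PMF
# ---------------------------------------------------------------------------

@dataclass
class PmfProfile:
    """PMF along the steering coordinate with set-to-set errors."""

    lam: np.ndarray  # rad
    pmf: np.ndarray  # kcal/mol, anchored to 0 at lam[0]
    error: np.ndarray  # across-set standard deviation
    set_pmfs: np.ndarray  # (n_sets, n_points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda_rad": self.lam, "pmf_kcal_mol": self.pmf, "error": self.error})


def jarzynski_pmf(trace_sets: Sequence[Sequence[WorkTrace]], kBT: float = KBT_300K) -> PmfProfile:
    """Jarzynski free-energy profile from grouped work traces.

    Per set, PMF(λ) = −kBT ln⟨exp(−W(λ)/kBT)⟩ over the set's traces; the
    returned curve is the across-set mean with the across-set standard
    deviation as the error, anchored to zero at the schedule start.  All
    traces must share one steering schedule.
    """
    if not trace_sets or not trace_sets[0]:
        raise ValueError("need at least one set with at least one trace")
    sched = trace_sets[0][0].schedule
    for s in trace_sets:
        for tr in s:
            if tr.schedule != sched:
                raise ValueError("inconsistent steering schedules")
    lam = sched.lam
    set_pmfs = []
    for s in trace_sets:
        W = np.stack([tr.work for tr in s])  # (n_traces, n_points)
        # log-sum-exp for numerical stability
        a = (-W / kBT).max(axis=0)
        lnavg = a + np.log(np.mean(np.exp(-W / kBT - a), axis=0))
        pmf = -kBT * lnavg
        set_pmfs.append(pmf - pmf[0])
    set_pmfs = np.stack(set_pmfs)
    mean = set_pmfs.mean(axis=0)
    err = set_pmfs.std(axis=0, ddof=1) if len(trace_sets) > 1 else np.zeros_like(mean)
    return PmfProfile(lam, mean, err, set_pmfs)
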