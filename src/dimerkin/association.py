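"""Bayesian pooling of dimerization events across trajectories.

Two models share the event-count table:

* :class:`PrevalenceModel` — the per-trajectory interface counts N_iC are
  multinomial with cluster probabilities p_C = w_C / Σ w_C, w_C = exp(a_C),
  and weak N(0, sd²) priors on the a_C.  The posterior mean of p_C is close
  to the pooled fraction; the credible interval carries the pooling
  uncertainty.
* :class:`OnRateModel` — the number of interface-specific events in
  trajectory *i* is Poisson with intensity t_i·k_on(C)·c_i = exp(b_Ci),
  with a weak normal prior on ln k_on(C).  k_on is reported in μm²/s.

Both are fitted by Metropolis-within-Gibbs (:mod:`dimerkin.mcmc`) with
10⁴ retained samples after a 5×10³ burn-in by default, and report the
posterior mean with a (2.5%, 97.5%) interval per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .mcmc import McmcResult, McmcSettings, sample_posterior
from .trajectory import SimulationMetadata

__all__ = [
    "EventCounts",
    "PrevalenceModel",
    "PrevalenceResults",
    "OnRateModel",
    "OnRateResults",
    "counts_from_events",
]


@dataclass
class EventCounts:
    """Dimerization counts N_iC with per-trajectory time and concentration.

    ``counts`` has shape (n_trajectories, n_clusters); ``times_s`` are the
    per-trajectory observation times in seconds (simulated or effective,
    recorded in ``time_basis``); ``conc_um2`` the monomer surface densities
    in μm⁻² (for heterodimers the geometric mean of the two species).
    """

    counts: np.ndarray
    labels: Sequence[str]
    times_s: np.ndarray
    conc_um2: np.ndarray
    time_basis: str = "simulated"

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=int))
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.conc_um2 = np.asarray(self.conc_um2, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape[1] != len(self.labels):
            raise ValueError("labels must match the number of clusters")
        if self.times_s.shape != (self.counts.shape[0],) or np.any(self.times_s <= 0):
            raise ValueError("need one positive time per trajectory")
        if self.conc_um2.shape != (self.counts.shape[0],) or np.any(self.conc_um2 <= 0):
            raise ValueError("need one positive concentration per trajectory")

    @property
    def n_trajectories(self) -> int:
        return self.counts.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.counts.shape[1]

    def observed(self) -> "EventCounts":
        """Restrict to clusters observed at least once (dash convention)."""
        keep = self.counts.sum(axis=0) > 0
        return EventCounts(
            self.counts[:, keep],
            [l for l, k in zip(self.labels, keep) if k],
            self.times_s,
            self.conc_um2,
            self.time_basis,
        )


def counts_from_events(
    events: pd.DataFrame,
    metadata: Sequence[SimulationMetadata],
    species: tuple[str, str] | None = None,
    time_basis: str = "simulated",
) -> EventCounts:
    """Build an :class:`EventCounts` table from a tidy events frame.

    ``events`` needs columns ``trajectory`` and ``label``.  ``metadata``
    supplies, per trajectory, the membrane area, monomer counts and the
    simulated time; concentrations are initial monomer surface densities
    (geometric mean across the two species for heterodimers).
    """
    labels = sorted(events["label"].dropna().unique())
    meta = {m.trajectory_id: m for m in metadata}
    traj_ids = [m.trajectory_id for m in metadata]
    counts = np.zeros((len(traj_ids), len(labels)), dtype=int)
    for (tid, lab), grp in events.groupby(["trajectory", "label"]):
        counts[traj_ids.index(tid), labels.index(lab)] = len(grp)
    times, conc = [], []
    for m in metadata:
        t_us = m.effective_time_us if time_basis == "effective" else m.simulated_time_us
        times.append(t_us * 1e-6)  # μs -> s
        if species is not None:
            c = np.sqrt(
                (m.monomer_counts[species[0]] / m.area_um2)
                * (m.monomer_counts[species[1]] / m.area_um2)
            )
        else:
            c = sum(m.monomer_counts.values()) / m.area_um2
        conc.append(c)
    return EventCounts(counts, labels, np.array(times), np.array(conc), time_basis)


def _summary_frame(
    labels: Sequence[str], samples: np.ndarray, ci: tuple[float, float], unit: str
) -> pd.DataFrame:
    lo, hi = np.percentile(samples, ci, axis=0)
    return pd.DataFrame(
        {
            "interface": list(labels),
            f"mean_{unit}": samples.mean(axis=0),
            f"ci_{ci[0]}%": lo,
            f"ci_{ci[1]}%": hi,
        }
    )


class PrevalenceModel:
    """Multinomial interface-prevalence model with log-weight parameters.

    Parameters
    ----------
    counts : event-count table; clusters never observed are dropped
        (the dash convention of the output tables).
    trajectory_effects : when True, adds per-trajectory log-weight offsets
        η_iC with a half-normal hyperprior on their scale, so that
        trajectory-to-trajectory variability widens the population
        intervals.  The default (False) is the plain shared-weight model.
    """

    def __init__(self, counts: EventCounts, trajectory_effects: bool = False) -> None:
        counts = counts.observed()
        if counts.n_clusters == 0:
            raise ValueError("all-zero counts")
        self.counts = counts
        self.trajectory_effects = trajectory_effects

    def loglike(self, a: np.ndarray, eta: np.ndarray | None = None) -> float:
        """Multinomial log-likelihood at log-weights ``a`` (+ offsets)."""
        N = self.counts.counts
        if eta is None:
            logits = np.broadcast_to(a, N.shape)
        else:
            logits = a[None, :] + eta
        logz = np.log(np.exp(logits - logits.max(axis=1, keepdims=True)).sum(axis=1))
        logp = logits - logits.max(axis=1, keepdims=True) - logz[:, None]
        return float((N * logp).sum())

    def fit(self, settings: McmcSettings | None = None) -> "PrevalenceResults":
        settings = settings or McmcSettings()
        C = self.counts.n_clusters
        n_traj = self.counts.n_trajectories
        pooled = self.counts.counts.sum(axis=0).astype(float)
        a0 = np.log(pooled / pooled.sum()) - np.log(pooled.max() / pooled.sum())

        if not self.trajectory_effects:
            def logpost(theta: np.ndarray) -> float:
                prior = -0.5 * np.sum(theta**2) / settings.prior_sd**2
                return prior + self.loglike(theta)

            res = sample_posterior(logpost, a0, settings)
            a_samples = res.samples
        else:
            # params: [a_C ... , eta_iC ..., log_sigma]
            def unpack(theta: np.ndarray):
                a = theta[:C]
                eta = theta[C : C + n_traj * C].reshape(n_traj, C)
                log_sig = theta[-1]
                return a, eta, log_sig

            def logpost(theta: np.ndarray) -> float:
                a, eta, log_sig = unpack(theta)
                sig = np.exp(log_sig)
                prior = -0.5 * np.sum(a**2) / settings.prior_sd**2
                # half-normal(1) hyperprior on sigma, Jacobian for log param
                prior += -0.5 * sig**2 + log_sig
                prior += -0.5 * np.sum(eta**2) / sig**2 - eta.size * log_sig
                return prior + self.loglike(a, eta)

            theta0 = np.concatenate([a0, np.zeros(n_traj * C), [np.log(0.5)]])
            res = sample_posterior(logpost, theta0, settings)
            a_samples = res.samples[:, :C]

        w = np.exp(a_samples - a_samples.max(axis=1, keepdims=True))
        p_samples = w / w.sum(axis=1, keepdims=True)
        return PrevalenceResults(self, res, a_samples, p_samples)


@dataclass
class PrevalenceResults:
    """Posterior prevalences p_C with (2.5%, 97.5%) intervals."""

    model: PrevalenceModel
    mcmc: McmcResult
    a_samples: np.ndarray
    p_samples: np.ndarray
    ci: tuple[float, float] = (2.5, 97.5)

    @property
    def labels(self) -> Sequence[str]:
        return self.model.counts.labels

    @property
    def mean(self) -> np.ndarray:
        return self.p_samples.mean(axis=0)

    @property
    def interval(self) -> np.ndarray:
        return np.percentile(self.p_samples, self.ci, axis=0).T

    def summary(self, percent: bool = True) -> pd.DataFrame:
        """One row per observed interface: mean and credible interval."""
        scale = 100.0 if percent else 1.0
        unit = "percent" if percent else "fraction"
        return _summary_frame(self.labels, self.p_samples * scale, self.ci, unit)


class OnRateModel:
    """Poisson model for interface-specific 2D association rates.

    Each cluster C is independent: N_iC ~ Poisson(t_i · k_on(C) · c_i),
    parameterized by b_C = ln k_on(C) with a weak N(0, sd²) prior.
    """

    def __init__(self, counts: EventCounts) -> None:
        if counts.n_clusters == 0:
            raise ValueError("no clusters")
        self.counts = counts.observed() if counts.counts.sum() else counts
        if self.counts.times_s is None or self.counts.conc_um2 is None:
            raise ValueError("missing metadata")

    def loglike_cluster(self, b: float, c_idx: int) -> float:
        """Poisson log-likelihood of cluster ``c_idx`` at ln k_on = b."""
        n = self.counts.counts[:, c_idx]
        tc = self.counts.times_s * self.counts.conc_um2
        lam = tc * np.exp(b)
        return float(np.sum(n * np.log(lam) - lam - gammaln(n + 1)))

    def fit(self, settings: McmcSettings | None = None) -> "OnRateResults":
        settings = settings or McmcSettings()
        C = self.counts.n_clusters
        tc_total = float(np.sum(self.counts.times_s * self.counts.conc_um2))
        all_samples = []
        all_res = []
        for c in range(C):
            n_total = int(self.counts.counts[:, c].sum())
            b0 = np.log(max(n_total, 0.5) / tc_total)

            def logpost(theta: np.ndarray, c=c) -> float:
                return (
                    -0.5 * theta[0] ** 2 / settings.prior_sd**2
                    + self.loglike_cluster(theta[0], c)
                )

            sub = McmcSettings(
                n_samples=settings.n_samples,
                burn_in=settings.burn_in,
                prior_sd=settings.prior_sd,
                seed=settings.seed + c,
                proposal_scale=settings.proposal_scale,
                adapt_interval=settings.adapt_interval,
            )
            res = sample_posterior(logpost, np.array([b0]), sub)
            all_res.append(res)
            all_samples.append(np.exp(res.samples[:, 0]))
        return OnRateResults(self, all_res, np.column_stack(all_samples))


@dataclass
class OnRateResults:
    """Posterior k_on(C) in μm²/s with (2.5%, 97.5%) intervals."""

    model: OnRateModel
    mcmc: list[McmcResult]
    kon_samples: np.ndarray  # (n_samples, n_clusters), μm²/s

    ci: tuple[float, float] = (2.5, 97.5)

    @property
    def labels(self) -> Sequence[str]:
        return self.model.counts.labels

    @property
    def mean(self) -> np.ndarray:
        return self.kon_samples.mean(axis=0)

    @property
    def interval(self) -> np.ndarray:
        return np.percentile(self.kon_samples, self.ci, axis=0).T

    def summary(self) -> pd.DataFrame:
        """One row per interface: k_on mean and credible interval (μm²/s)."""
        df = _summary_frame(self.labels, self.kon_samples, self.ci, "kon_um2_per_s")
        df.attrs["time_basis"] = self.model.counts.time_basis
        return df
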