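# dimerkin

Analysis of membrane-receptor self-association from coarse-grained (CG)
molecular-dynamics trajectories, written for people who study GPCR
di-/oligomerization (e.g. opioid-receptor subtypes in a POPC/cholesterol
bilayer) and want the full post-simulation pipeline — from raw bead
trajectories to interface-resolved association rates and lipid
dynamical-heterogeneity maps — as tested, reusable code.  A synthetic-data
module generates membrane systems with the exact statistical structure
each estimator assumes, so every stage can be verified against known
ground truth without access to the original MD data.

## What it computes

**Interface detection and clustering.**  For every protomer pair a binary
residue–residue contact map δ_ij is built from backbone-bead distances
(contact iff d < 8 Å, minimum image).  A pair is *dimeric* when ≥ 10
residues on each protomer carry cross-contacts, sustained over a
persistence window.  Interfaces are clustered by k-means under the
Frobenius distance ‖δ^(k1) − δ^(k2)‖, using for homodimers the symmetrized
form min(‖δ^(k1) − δ^(k2)‖, ‖δ^(k1) − δ^(k2)ᵀ‖) to respect protomer-swap
equivalence, and labelled by the TM helices contributing ≥ 3 involved
residues per side (e.g. `TM1,2/TM4,5`).

**Bayesian prevalence and association rates.**  Event counts N_iC pooled
over trajectories follow a multinomial with p_C = w_C/Σw_C, w_C = exp(a_C);
interface-specific counts follow a Poisson with intensity
t·k_on(C)·c_i = exp(b_Ci).  Weak N(0, 10²) priors, Metropolis-within-Gibbs
with 10⁴ retained samples after 5×10³ burn-in, posterior means with
(2.5%, 97.5%) intervals; k_on in μm²/s.

**Lipid CTRW dynamics.**  Lipid motion is coarse-grained as displacements
of length d = 10 Å.  The persistence time t_P (first displacement beyond d
from a time origin) tracks local viscosity η ∝ ⟨t_P⟩; the exchange time
t_X (waiting time between successive displacements) sets diffusion
D ≈ d²/⟨t_X⟩.  The two distributions obey the renewal identity
p_P(t) = ⟨t_X⟩⁻¹ ∫_t^∞ p_X(s) ds, so ⟨t_P⟩/⟨t_X⟩ = 1 for Poissonian
dynamics and > 1 in "jammed" regions where the Stokes–Einstein coupling
breaks down.  Maps of both quantities are built in 1 Å × 1 Å bins in the
receptor-aligned frame.

**Position-dependent pair diffusion.**  Protomer-pair distances (3–9 nm,
third-protomer contacts excluded) are binned and modelled as a
nearest-neighbor rate matrix K with likelihood
ln p(X|K) = Σ N_jj′ ln(e^{τK})_jj′; the posterior yields
D_j ≈ (Δd)² K_j,j+1 (P_j/P_j+1)^{1/2} with (25%, 95%) credible intervals.

**Free-energy barriers.**  The Jarzynski equality
ΔG = −k_BT ln⟨e^{−W/k_BT}⟩ applied to 5 sets of 5 steered work traces
(default schedule: 1.2 → 2.1 rad at 0.05 rad/ns, k = 800 (kcal/mol)/rad²)
gives the PMF with set-to-set scatter as the error.

## Worked example

Simulate a 16-protomer membrane patch with two association rules, detect
and label the dimerization events, and estimate prevalences and on-rates:

```python
import numpy as np
from dimerkin import (AssociationRule, simulate_protomer_bd, detect_dimer_events,
                      auto_cluster, assign_tm_regions, EventCounts,
                      PrevalenceModel, OnRateModel, McmcSettings, summarize_tables)

rules = [AssociationRule(("TM1", "TM2"), ("TM4", "TM5")),
         AssociationRule(("TM5",), ("TM5",))]
traj, log = simulate_protomer_bd(16, box=600.0, D_t=1.0, D_r=0.01, rules=rules,
                                 duration=4000.0, dt=2.0, seed=11, save_stride=5)
events, maps = detect_dimer_events(traj, cutoff=8.0, min_residues=6, min_persist_frames=3)
top = traj.topologies[0]
tm_map = {r - top.residue_range[0]: h for r, h in assign_tm_regions(top).items()}
clusters, assign = auto_cluster(maps, tm_map, homodimer=True, seed=0)
for ev, a in zip(events, assign):
    ev.label = clusters[a].label

labels = sorted({e.label for e in events})
counts = [[sum(e.label == l for e in events) for l in labels]]
ec = EventCounts(counts, labels, times_s=[4e-6], conc_um2=[16 / 0.0036])
prev = PrevalenceModel(ec).fit(McmcSettings(seed=1))
kon = OnRateModel(ec).fit(McmcSettings(seed=1))
print(summarize_tables(prev, kon).round(2).to_string(index=False))
```

prints

```
  interface  mean_percent  percent_ci_2.5  percent_ci_97.5  mean_kon_um2_per_s  kon_ci_2.5  kon_ci_97.5
TM1,2/TM4,5          59.9           19.29            93.10              163.90       33.24       408.49
    TM5/TM5          40.1            6.90            80.71              109.08       11.75       302.56
```

Five dimerization events formed in this 4 μs patch, three at the
`TM1,2/TM4,5` interface and two at `TM5/TM5`; every event was detected at
the generator's ground-truth binding time and assigned the label of the
rule that produced it.  With so few events the 95% intervals are wide —
exactly the behavior the Bayesian pooling is there to expose.  The rates
are per-interface 2D association constants: ~10²  μm²/s for a membrane
patch of 0.0036 μm² holding 16 monomers observed for 4 μs of simulated
time.

The same estimators apply unchanged to real CG trajectories loaded with
`load_trajectory(("system.gro", "run.xtc"), topologies)`.

A quick analytic check of the lipid observables:

```python
>>> from dimerkin import diffusion_from_exchange
>>> diffusion_from_exchange(10.0, d=10.0)      # bulk: <t_X> = 10 ns
1e-06
>>> diffusion_from_exchange(40.0, d=10.0)      # near the receptor surface
2.5e-07
```

in cm²/s — bulk lipid diffusion is ~10⁻⁶ cm²/s and drops fourfold where
exchange times stretch to ~40 ns near the protein.

There is also a CLI (`dimerkin all --config pipeline.yml`) that runs the
configured stages end to end and writes CSV/JSON outputs plus a manifest
with checksums for byte-level reproducibility; see `dimerkin --help`.

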