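# Methods

This note records the models behind each stage of `dimerkin`, the defaults
and their units, what the synthetic generators do and do not emulate, and
the numerical choices made where the design was genuinely open.

## Units and geometry

Lengths are Å and times ns everywhere inside the package; conversions
(1 Å²/ns = 10⁻⁷ cm²/s; μm²/s for rates) happen only in reporting code.
The membrane plane is x–y and the normal z.  Positions are stored
unwrapped per molecule so displacement-based observables never jump across
periodic images; `BeadTrajectory.wrapped()` provides wrapped coordinates
for density bookkeeping.  Minimum-image displacements assume an
orthorhombic box.  Rigid superposition uses the Kabsch SVD solution, in
two flavours: full 3D (crystal comparison) and in-plane (rotation about z
plus x–y translation, for receptor-frame map building).  Residues carry
Ballesteros–Weinstein labels derived from per-helix anchor residues
(position 50).

The CG effective-time convention is a multiplicative factor (default 4)
applied at reporting boundaries; `effective_time` and the `time_basis`
switch on the rate tables record which basis a number uses, since a rate
on the effective basis is 4× smaller than on the simulated basis.

## Interface detection and clustering

Contact maps are binary: δ_ij = 1 iff the backbone-bead distance of
residue i (protomer A) and j (protomer B) is strictly below the cutoff
(default 8 Å).  A pair becomes dimeric at the first frame where at least
`min_residues` (default 10) residues **per protomer** carry cross-contacts,
sustained for `min_persist_frames` consecutive stored frames; the
persistence gate exists to drop glancing touches, since the data model
assumes no complex ever dissociates.  The event's representative map is
the time-average over the sustained window binarized at 0.5.

Clustering is k-means in contact-map space under the Frobenius norm, with
real-valued centroids.  For homodimers each member enters assignment and
the centroid update in its distance-minimizing orientation (identity vs
transpose), with ties broken toward the identity — a deterministic,
monotone variant of symmetrized k-means.  Initialization is
farthest-point seeding from an explicit seed, so runs are reproducible.
The number of clusters is chosen by scanning k = 2…12 and taking the
smallest k whose merged label set equals that of k+1; clusters with equal
labels are merged post hoc.  A residue is *involved* on a side when it
carries a contact in more than `involvement_threshold` (default 0.5, i.e.
a majority) of the member maps; a helix enters the label with ≥ 3 involved
residues.  Two per-residue profiles are kept: the participation fraction
(in [0, 1], used for labelling) and the mean contact count per residue
(centroid row/column sums), which can exceed 1 for residues touching
several partners.

Crystal comparison superposes each simulated protomer *independently*
onto its assigned chain — deliberately ignoring internal monomer
deformation, since the CG protomers are elastic-network rigid while
crystal monomers are not — then scores the whole dimer and reports the
minimum over the anchoring protomer and (for homodimers) the two chain
assignments.

## Prevalence and on-rate models

Counts N_iC of events of interface C in trajectory i are multinomial with
shared cluster weights p_C = exp(a_C)/Σ exp(a_C); interface-specific event
counts are Poisson with intensity t_i·k_on(C)·c_i, parameterized by
ln k_on(C).  Priors are proper but weak, N(0, 10²) on the log-scale
parameters; with total counts ≳ 50 the posterior means move by < 1% when
the prior SD is tripled.  The concentration c_i is the initial monomer
surface density (μm⁻²); monomer depletion during a run is ignored, and for
heterodimers c_i is the geometric mean of the two species' densities
(recorded in the output metadata, as this is a convention choice).

Sampling is component-wise Metropolis-within-Gibbs: Gaussian proposals
per coordinate, scales adapted every 100 burn-in sweeps toward a 20–50%
acceptance band and frozen afterwards; defaults are 10⁴ retained draws
after 5×10³ burn-in.  Diagnostics: per-component acceptance rate,
split-chain R-hat, and an autocorrelation-sum effective sample size.  The
sampler raises if nothing is accepted during burn-in.

In the shared-weight model the pooled counts are sufficient, so splitting
the same totals over more trajectories cannot change the posterior.  To
let trajectory-to-trajectory variability widen the population intervals,
`PrevalenceModel(trajectory_effects=True)` adds per-trajectory log-weight
offsets η_iC with a half-normal(1) hyperprior on their scale: with several
trajectories the offsets average out, with a single trajectory they
inflate the population uncertainty.  The default is the plain shared
model.

## Lipid persistence and exchange times

The lipid (phosphate bead) and cholesterol (head-group bead) motion is
viewed as a continuous-time random walk with coarse-graining length d
(default 10 Å).  From a time origin t₀, the persistence time t_P is the
first time the in-plane displacement from x(t₀) exceeds d; exchange times
t_X,i follow recursively between successive displacements of length d.
Time origins are every 10th stored frame by default (origins decorrelate
at about one exchange time); origins whose displacement never exceeds d
before the trajectory ends are censored and excluded from ⟨t_P⟩ (the
censored fraction is reported per bin).  Only in-plane displacements
count, matching the 2D membrane-projected maps; samples are binned by
their origin-time position ("lipids starting here"); when receptors must
be treated as isolated, only the first third of each trajectory should be
fed in (configurable, not enforced).

Two numerical details matter at finite frame spacing.  First, threshold
crossings are located by linear interpolation of the displacement
magnitude between the bracketing frames — exact for uniform motion, and
removing most of the O(Δt/2) upward bias that taking the first
super-threshold frame would introduce.  Second, the renewal reference
resets to the first *sampled* frame past each crossing, with time and
position taken at that same frame, so the exchange-time chain is
self-consistent.  For jump processes whose steps are exactly length d
(the CTRW generator), the strict `> d` criterion would never fire in
floating point; analyses of such data use a threshold marginally below
the jump length (0.999 d), which identifies jump epochs exactly.

Derived indicators: D = d²/⟨t_X⟩ (optionally divided by the ×4
effective-time factor) and the local viscosity proxy ⟨t_P⟩; their ratio
⟨t_P⟩/⟨t_X⟩ equals 1 for Poissonian dynamics (Stokes–Einstein regime) and
exceeds 1 where jump events cluster in time.  The Kramers high-friction
rate k = m ω† ω/(2πη)·exp(−G†/k_BT) is provided for translating barrier
heights and local viscosity into association-rate estimates.

## Pair diffusion from a Bayesian rate matrix

Pair distances are analysed only on frames passing the third-protomer
rule (the pair distance must be smaller than either partner's distance to
any other protomer); failing frames split the series into segments that
are never bridged, and lagged transitions are counted within segments
only.  Orientation angles ϕ₁, ϕ₂ measure each protomer's TM4 axis against
the center-to-center direction, supporting interface-specific angular
windows (derived in practice from cluster centroids ± one circular
standard deviation).  The distance range is 30–90 Å in Δd = 10 Å bins by
default; the lag τ defaults to the frame-storage interval, and halving or
doubling τ is the recommended robustness check since the discrete-lag
likelihood is exact for any τ.

The generator K is restricted to tridiagonal (birth–death) form with
reflecting ends — the diffusion formula uses only K_j,j+1, implying
nearest-neighbor structure — and parameterized by log-rates to enforce
positivity.  The prior is flat on log-rates within [−10, 10] (units
1/ns), a proper surrogate for the improper uniform-on-K choice.  The
likelihood Σ N_jj′ ln(e^{τK})_jj′ is evaluated with a dense matrix
exponential (scipy `expm`, machine precision at these sizes).  Stationary
weights come from the birth–death recursion
P_j+1 = P_j K_j,j+1/K_j+1,j (null left-eigenvector in degenerate cases),
and D_j = (Δd)² K_j,j+1 (P_j/P_j+1)^{1/2} per posterior draw.  Intervals
default to (25%, 95%), with (2.5%, 97.5%) available via the results'
`ci` field.

## Jarzynski PMF

Work traces along a common steering schedule (default 1.2 → 2.1 rad at
0.05 rad/ns with k = 800 (kcal/mol)/rad²; the coordinate is treated as
radians throughout) are grouped into sets; per set
PMF(λ) = −k_BT ln⟨e^{−W(λ)/k_BT}⟩, and the reported curve is the across-set
mean with the across-set standard deviation as error, anchored at zero at
the schedule start.  The exponential average is computed with
log-sum-exp.  By Jensen's inequality the PMF never exceeds the mean-work
profile; this is asserted in tests.  For externally supplied steered
trajectories the stiff-spring convention W(λ) = ∫ k(λ(t) − ϕ(t)) dλ is
the intended work definition.

## Synthetic generators: what they emulate, and what they do not

All generators take an explicit seed and are bit-reproducible; identical
seeds give identical outputs.

*Patchy-protomer Brownian dynamics* emulates the 16-receptor membrane
systems: rigid 2D discs (radius 20 Å) with 8 labelled boundary patches
(TM1–TM7, H8) at fixed angular offsets, translational/rotational Brownian
motion (slowed 1/size for aggregates), soft rigid-body repulsion, and
irreversible patch-specific association.  Unbound protomers rest at a
rim-to-rim distance of 10 Å (above the 8 Å contact cutoff), so only bound
pairs register as dimeric; a firing rule snaps the partner's aggregate
into the ideal contact geometry (rim gap 3 Å), giving each rule a
reproducible contact-map signature whose involved helices are exactly the
rule's patch sets.  Ground-truth k_on for recovery tests is the empirical
MLE n/(t·c) over replicate simulations, not a claimed closed form.  The
model omits membrane deformation, hydrodynamics, internal protomer
flexibility and any energetics; with 5 beads per helix the snapped
interface carries ~6–7 contacting residues per side, so synthetic
detection runs use `min_residues=6` rather than the default 10 used for
real receptors (~300 residues).  Passing tests therefore demonstrate the
correctness of the detection/clustering/labelling machinery, not the
realism of CG force-field contacts.

*CTRW tracers* wait at their position for a time drawn from the local law
and jump exactly d in a uniform random direction.  Waiting laws are
exponential or Pareto with shape α > 2 (default 2.2) so the second moment
needed by the forward-recurrence identity ⟨t_P⟩ = ⟨t_X²⟩/2⟨t_X⟩ exists.
With α < 1+√2 the coefficient of variation exceeds 1 and the asymptotic
ratio ⟨t_P⟩/⟨t_X⟩ is above 1; note that for such tails the empirical
second moment converges slowly (the fourth moment is infinite), so
finite-sample checks compare the measured ratio against the *empirical*
moment prediction rather than the asymptotic value.  An optional slow
annulus (longer waits within a radius of a point) mimics jammed lipid
regions for map-contrast tests.  Real lipid motion is not a pure jump
process — frames are sampled at dt = (bulk mean)/40 by default and the
estimator's interpolation handles the in-between motion.

*Distance chains* are exact discrete skeletons of a CTMC: states sampled
at lag τ from expm(τK).  *Work traces* are Gaussian with mean
G(λ) + s(λ)²/2k_BT and Brownian variance s(λ)² = f(λ)σ_W², which satisfies
the Gaussian fluctuation relation at every schedule point, so the
Jarzynski average recovers G(λ) pointwise and terminal works are
N(ΔG + σ_W²/2k_BT, σ_W²).

## Problem sizes and tolerances

Test and acceptance runs use desk-scale sizes chosen to make the
stochastic tolerances comfortable: CTRW ensembles of 60 tracers × 4 μs
(≈ 2×10⁵ exchange samples; 2% on means, KS < 0.02), distance chains of
4×10⁴ steps (D_j flat within 10%), 20 BD replicates for interval
coverage, and 4 μs 16-protomer patches for detection/labelling (a handful
of events each, matched 1:1 against the ground-truth log).  MCMC defaults
(10⁴ draws) are used for headline estimates; recovery loops use 2–4×10³
draws, which R-hat shows is ample for these 1–6 parameter posteriors.

## Known limitations

Event detection assumes irreversible association (at most one event per
pair); k_off estimation is out of scope.  The diffusion model is 1D in
distance — no (d, ϕ₁, ϕ₂) tensor.  Censored persistence times are
excluded rather than Kaplan–Meier-corrected.  The prevalence model's
trajectory-effects extension is a modelling choice, not a fitted
necessity; with a single trajectory its hyperprior drives the extra
width.  Heterodimer concentration uses the geometric-mean convention.
The GRO/XTC path converts nm→Å and ps→ns on load and assumes MDAnalysis
selections identify one backbone bead per residue.
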