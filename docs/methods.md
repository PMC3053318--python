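# Methods

## The kinetic model

The circuit couples four processes: operator repression, inducer–repressor
binding, expression of the permease LacY, and inducer transport.

**Repression.**  One operator copy and R_tot = 10 repressor dimers (held
constant; repressor expression noise is out of scope).  Association rates
are molar constants converted to stochastic propensities as k/(N_A·V).
The three dimer species bind the operator at k_rb = 2.43×10⁶ M⁻¹s⁻¹ (R2),
C·k_rb with C = 0.5 (IR2) and C2·k_rb with C2 = 0.01 (I2R2); dissociation
at 6.3×10⁻⁴ s⁻¹ from RO and IRO and 0.315 s⁻¹ from I2RO (inducer-driven
"knock-off").

**Inducer binding.**  Each dimer has two identical, independent inducer
sites (non-cooperative).  Stored rates carry the statistical factors: the
first association is twice the per-site rate, the second dissociation
twice the per-site dissociation.  The per-site dissociation constants
implied by the table are 17.6 µM (TMG, free repressor), 4.1 µM (IPTG,
free), 3 mM (TMG, operator-bound) and 89 µM (IPTG, operator-bound).

**Expression.**  Single rate-limiting steps: transcription k_ts = 0.126
s⁻¹ from the free operator, translation k_tl = 0.0444 s⁻¹ per transcript,
mRNA decay k_mdeg = 0.0111 s⁻¹ (90 s lifetime, so four proteins per
transcript on average), protein dilution k_pdeg = ln 2 / 55 min.

**Transport (PFB only).**  Passive diffusion in/out at 2.33×10⁻³ s⁻¹ and
LacY-mediated import expanded into bind/unbind/catalysis with
k_cat = 12 s⁻¹, k_off chosen as 1% of k_cat to suppress unproductive
binding events, and k_on fixed by K_M = 400 µM (the value that yields the
observed ~70-fold steady-state enrichment of internal inducer).  External
inducer is clamped (infinite reservoir); internal and external volumes are
equal.

**Reaction volume.**  The well-stirred volume is not an observable of the
rate table; we use V = 8×10⁻¹⁶ L, consistent with the fast-growth
spherocylinder (0.87 µm³) and reproducing a single-repressor operator
search time of ~200 s.  V is configurable and recorded in serialized
outputs; concentrations, not counts, are the invariant inputs.

## Burst theory and calibration

When bound episodes are long compared with free intervals, transcription
is a competition at the free operator between initiation (k_ts) and
repressor rebinding (λ).  Episodes yield geometric transcript counts;
since zero-transcript episodes are unobservable, the mean observed burst
size is B = 1/(1−p) = 1 + k_ts/λ with p = k_ts/(k_ts+λ).  The free dimer
pool partitions binomially over inducer occupancy, and with C = 1/2 the
aggregate binding rate collapses to λ(I) = λ₀/(1 + I/K_ID), making B(I)
and the burst duration 1/λ(I) exactly affine in I.  Calibration inverts
this: a linear fit of protein burst size (4B) against I gives
K_ID = (intercept − 4)/slope (the −4 removes the unobservable-burst
offset); k_rb is set so the burst duration at a reference concentration
(200 µM) equals 5% of the protein lifetime — the longest duration for
which stationary-distribution burst inference is reliable (see the
validity study below); k_ts follows from the intercept; and
k_ro_off = a·k_pdeg from the observed burst frequency a ≈ 3.

## Exact solvers

**Operator subsystem.**  For clamped internal inducer (NPF), the joint
chain over operator state × free-dimer composition is finite: 66 + 3×55 =
231 states for 10 dimers.  We solve πQ = 0 by least squares with a
normalization row, and compute burst frequency (stationary release flux ×
protein lifetime), mean repressed-complex lifetime and mean free interval
by first-passage solves with stationary entry distributions.

**Moment closure.**  Transcription depends only on the subsystem state,
never on transcript or protein counts, so the conditional moments
E[m·1_s], E[Y·1_s], E[m²·1_s], E[mY·1_s], E[Y²·1_s] obey closed linear
systems (five dense solves of size 231 per concentration).  This gives
exact stationary means, variances, covariance and Fano factors — no
truncation, no sampling.  The closure is exact only without feedback;
requesting it for the PFB variant is an error.

**Telegraph stationary law.**  The two-state model's stationary protein
PMF is hypergeometric; we evaluate it through the Euler-integral
representation P(n) = E_t[NB(n; α, t·b)] with t ~ Beta(β, κ₀+κ₁−β), where
α ≥ β are the roots of x² − (a+κ₀+κ₁)x + aκ₀ = 0.  A Gauss–Jacobi rule
with the Beta weight (200 nodes; 128 inside fit loops) integrates this to
machine precision for any count — verified at ≲10⁻¹² total variation
against an independent truncated master-equation linear solve, including
the negative-binomial limit κ₁ → 0 and endpoint-singular shapes β < 1.
This representation was chosen over hypergeometric series recurrences
because it has no cancellation or convergence failures at large counts,
so no high-precision fallback is needed.

## Maximum-likelihood fitting

Both model classes minimize the negative log-likelihood over unique
observed counts (weighted by multiplicity) with Nelder–Mead in
log-parameter space (positivity by construction; NLL tolerance 10⁻⁸, 2000
iterations, multi-starts around moment estimates).  The telegraph fit is
two-stage: (a, b) from a negative-binomial fit to a fully induced
reference (where the law reduces to NB), then the switching rates with
(a, b) allowed ±5%.  An unconstrained four-parameter comparison fit is
available but off by default: the free likelihood has a
weak-identifiability ridge (a → ∞, b → 0 at fixed a·b — the Poisson-Beta
corner) along which likelihood gains are fractions of a unit per 10⁴
cells while the burst interpretation of (a, b) is destroyed; the staged
constraint exists to keep estimates off that ridge.  Confidence intervals
come from refitting random subsets (default 1000 resamples; the central
95% of estimates per parameter).

## Synthetic data

Generators draw exactly from the analytic laws: negative-binomial counts
via the Gamma–Poisson mixture, telegraph counts by inverse CDF over the
tabulated PMF (truncation mass deficit checked against 10⁻⁶).  The
titration study emulates reporter-based single-molecule datasets: burst
frequency constant at 3 per protein lifetime and protein burst size
affine in inducer with intercept 13.99 and slope 5.677×10⁵ M⁻¹ — the line
implied by the packaged rate table, whose corrected intercept-to-slope
ratio is K_ID = 17.6 µM.  Default ladder {0, 20, 40, 50, 75, 100, 200}
µM, 500 cells per condition.  What these generators deliberately lack:
extrinsic noise, measurement error in count calibration, and
concentration-dependent burst frequency — so closed-loop recovery tests
certify the estimators, not the realism of any particular experiment.

## Stochastic simulation

Direct-method Gillespie with a numba-compiled inner loop; clamped species
(constant-concentration pools) enter propensities but have zero net
stoichiometry.  Ensembles derive per-cell 31-bit seeds from the master
seed via `numpy.random.SeedSequence`, making results bit-reproducible and
independent of execution order.  Event logging is opt-in and restricted
to watched reactions (operator binding/release and transcription) to
bound memory; burst statistics drop zero-transcript episodes, mirroring
their invisibility in fluorescence data.  Stationary sampling burns in
ten protein lifetimes by default (minimum five); the initial condition is
the naive state (operator free, no protein), which burn-in makes
immaterial.

## Lattice reaction-diffusion

Space is voxelized (2–32 nm) with typed sites; particles live as
per-species count grids.  Each step alternates a diffusion sweep — every
particle moves to one of six neighbors with total probability
6·D·dt/λ², rejected into obstacles, disallowed site types, or sites at
capacity (default 8) — and a per-site reaction sweep with site-restricted
rates (bimolecular molar rates become k/(N_A·V_site) between
co-occupants).  The bound D ≤ λ²/(6·dt) is enforced per species and site
type.  This is a behavior-level emulation of multiparticle RDME
operators: exact in the well-mixed fast-diffusion limit (verified against
the SSA and mass-action kinetics) and diffusion-limited otherwise.

Cell models: the fast-growth spherocylinder (2 × 0.8 µm, operator
central, chromosome diffuse) and a synthetic slow-growth cell (3 × 0.4
µm) assembled the way a model is built from a partial tomographic
reconstruction — one pole third of ribosome positions drawn at the
measured density outside the condensed nucleoid, mirrored to the other
pole, middle third density-sampled; 3021 ribosomes total; operator on the
nucleoid surface ~32 nm from the membrane near a pole.  The chromosome is
a 31,000-segment random walk of 50 nm persistence-length cylinders
confined to the nucleoid, successive angles ≤ 90°, with
unwind-10-and-restart on boundary exit (direction proposals are retried
30 times before unwinding; the restart direction is unconstrained).
Obstacles follow the in-vivo census (12 classes, 1.7–10.4 nm radius) and
are packed by largest-first random sequential addition to 50% volume
fraction (achieved within 1%).

**Rebinding experiment.**  A 160 nm box at 2 nm spacing and 5 ns steps;
one repressor starts a site away from the central operator site
(obstacles are excluded from a 2-spacing ball there — the repressor
occupied that space an instant earlier) and walks until it either reacts
at the operator (per-visit rate k_rb/(N_A·V_site)) or crosses the 64 nm
escape radius.  The free repressor diffusion coefficient defaults to
1 µm²/s; because the in-vitro value behind the published experiment is
not printed, absolute rebinding probabilities are configuration-matched
rather than asserted — the tested claims are the monotone increase with
packing, escape-time broadening, and the transient sub-unity MSD exponent
in the 1–100 µs window at 50% packing.  MSD controls start at random
free sites so α(t) reflects the percolating void space.

**mRNA localization.**  Transcripts released at the operator walk at 0.1
µm²/s (excluded from the nucleoid in slow growth) until first standing on
a membrane site; the dispersion of axial contact positions is compared
between phenotypes.

## Problem sizes in the test suite

The published study ran 10,000-cell well-stirred ensembles for 24 h of
biological time and 100-cell whole-cell RDME simulations; the test suite
exercises the same code paths at sizes a workstation handles in minutes:
SSA/exact cross-validation at 250–500 cells over 8 protein lifetimes at
three concentrations; feedback switching with 32 cells × 13 h at 15 µM
(bimodality develops after ~10 h in this parameterization) and 16 cells
× 5 h at 50 µM; rebinding with 2,500 walkers per packing fraction;
resampling confidence intervals from 60–200 refits.  The library defaults
remain the larger study sizes (e.g. 200 cells × 8 h for the scaled
switching preset, 1000 resamples, 5000 walkers), and full-scale presets
are a parameter away; nothing in the scientific claims tested depends on
the reduced sizes beyond wider Monte-Carlo tolerances.

## Known limitations

* No DNA looping, LacI tetramerization, or repressor expression noise;
  no global extrinsic noise.  Measured distributions of highly expressed
  proteins stay over-dispersed where this model approaches Poisson.
* The moment solver and subsystem solver require the no-feedback variant;
  feedback statistics come from simulation only.
* The RDME diffusion operator emulates observable behavior (MSD,
  occupancy statistics) rather than reproducing any particular published
  implementation bit-for-bit; site capacity and the per-site bimolecular
  convention are stated, configurable approximations.
* Facilitated search (1D sliding / 3D hopping) and electrostatic or
  non-specific interactions are not modeled; crowding effects on
  rebinding are therefore lower bounds.
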