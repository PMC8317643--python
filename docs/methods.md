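# Methods

This note documents the models, protocols, numerical choices and known
limitations of the package; it is the design record a maintainer should
read before changing defaults.

## Minimal ventricular model

The cell model is the four-variable minimal ventricular ("phenomenological")
model: a transmembrane variable u and three gates (v, w, s) driving a fast
inward, slow outward and slow inward current with Heaviside switches and
tanh-shaped gate kinetics; the endocardial parameter column (28 named
parameters, `restforge.params.PARAM_NAMES`) is the baseline.  Voltage is
reported through the model's published affine map V = 85.7·u − 84 mV, so
the resting potential is −84.0 mV.

The true resting state is (u_o, 1, 1, s_inf(u_o)) with
s_inf(u) = (1 + tanh(k_s(u − u_s)))/2 ≈ 0.0215 at u_o = 0: the s-gate's
steady state is a smooth sigmoid and does not vanish at rest.  All four
derivatives are exactly zero there, which the test suite asserts.

### Stimulation

Rectangular pulses of 1 ms.  The amplitude is calibrated once, by
bisection on the base model, so that a rested beat's peak equals the
baseline model's published peak voltage of 53.8 mV (amplitude ≈ 0.937
dimensionless units/ms, about 2.9× the diastolic threshold).  Peak
voltage and maximal upstroke velocity are the two biomarkers that depend
directly on stimulus specification; pinning the stimulus to the printed
peak makes the remaining biomarkers reproducible.  dV/dt_max remains
stimulus-shape sensitive and is reported but not used as a calibration
anchor.

### Biomarker protocols

Two pacing contexts are distinguished deliberately:

* `rested_biomarkers` — one beat from rest at CL 500 ms.  This is the
  protocol that reproduces the published baseline biomarker row
  (APD30/50/90 = 123.7/226.5/276.3 ms) to within a fraction of a
  percent.  Steady-state pacing of the endocardial base model at 500 ms
  yields APD90 ≈ 237 ms — inconsistent with that row — so the table
  values evidently describe a fully rested beat, and the package adopts
  that reading for baseline biomarkers.
* `steady_biomarkers` — the final beat of a 20-beat train, used for the
  GA-calibrated cohort models, whose published APD90 values (256.8 and
  242.5 ms) coincide with the cohorts' measured steady 500 ms ARIs.

APD_x is measured from the maximum-dV/dt point of the upstroke to
recovery through RMP + (1 − x/100)·(Vmax − RMP), linearly interpolated
between samples.  DI runs from the APD90 endpoint of one beat to the
next activation.

### Numerics

Explicit forward Euler at dt = 0.02 ms (default) resolves the stiff
upstroke (tau_fi = 0.1 ms); halving dt moves APD90 by well under 0.5 ms.
Two acceleration devices keep desk-scale studies fast without changing
the model:

* The three smooth u-dependent nonlinearities (tau_w^-, tau_so, s_inf)
  are tabulated per parameter set on a 16384-point grid over
  u ∈ [−2, 4] and linearly interpolated inside the integrators; the
  interpolation error is orders of magnitude below the time-stepping
  error (base APD90 shifts by < 0.01 ms).
* Inside the GA fitness only, an adaptive-step Euler variant takes
  steps of err_tol/|du/dt| clipped to [0.02, 0.1] ms, resolving the
  upstroke at 0.02 ms while striding through plateau and diastole.
  Per-beat APD90 agrees with the fixed-step integrator to < 1 ms
  (asserted in the test suite); final reported biomarkers always use
  the fixed-step integrator.

Numerical blow-up (|u| > 25) is detected and signalled; inside the GA it
becomes a large finite penalty instead of an exception.

## Synthetic electrograms

The generator emulates the clinical acquisition: decremental bursts
(20 beats at 600→350 ms by 50 ms), 977 Hz sampling, unipolar morphology.
Cohort restitution structure is calibrated to the published per-CL
(DI, ARI) anchor tables: the mean curve is the OLS log fit
ARI = α + β ln(DI), plus a small cohort-level per-CL offset absorbing
the log model's structural residual at each anchor (up to ~9 ms for the
ICMP 350 ms point) so that simulated cohort means land on the anchors.
Slope variability is hierarchical — patient slopes drawn with the
between-subject SD (13.9 SNLV / 29.1 ICMP), electrode slopes perturbed
with the within-subject SD (6.4 / 29.1) — and per-electrode curves pivot
on the 600 ms steady-state DI, so cohorts agree at slow pacing and fan
out at short cycle lengths, as observed.  Intercept variance components
are not published; they are exposed as free parameters and default to
the pivot construction.

Beat dynamics follow the pacing recursion DI_n = CL − ARI_{n−1} seeded
from the 600 ms fixed point, so early-burst rate-adaptation transients
exist for the exclusion rule to remove.  Each beat renders as a fast
derivative-of-Gaussian activation wavelet (σ = 4 ms) and a slower
opposite-polarity repolarization wave (σ = 20 ms) positioned so the
signal's derivative extrema fall exactly on the ground-truth AT and RT —
the property the Wyatt method measures.  White noise, baseline wander,
50/60 Hz interference and pacing artifacts are available but default to
zero.

What the generator does **not** emulate: far-field forward modelling,
fractionated/scar electrograms, catheter contact variation, and any
coupling between morphology and restitution.  Passing the round-trip
tests therefore demonstrates correctness of the measurement chain on
Wyatt-ideal signals, not robustness to every clinical artifact.

## ARI extraction and restitution fitting

The Wyatt detector is deterministic and windowed: activation is the
minimum-derivative point in [stimulus + 2 ms, stimulus + 0.4·CL];
repolarization is the maximum-derivative point in
[AT + 0.25·CL, next stimulus − 5 ms].  Derivatives are centred
differences after Savitzky–Golay smoothing (window 11 samples, order 3).
A window whose deflection stays below 4× the robust (MAD-based) noise
floor marks the beat "no-detection".  The clinical exclusion rule
removes the first three and last beats of each burst.

Restitution curves are fitted as ARI = α + β ln(DI) (natural log) by
iteratively reweighted least squares with Tukey's bisquare
(c = 4.685, coefficient-change convergence at 1e−8, ≤ 50 iterations),
via statsmodels RLM.  R² is computed with the final robust weights —
robust-fit R² has no unique definition, and this one reduces to ordinary
R² when all weights are 1 — and recordings with R² ≤ 50% are rejected.
The cohort contrast (`compare_cohorts`) resamples whole patients
(cluster bootstrap) because electrodes are nested within patients.

## GA calibration

Real-coded genetic algorithm over the 28 parameters: log-space
representation, tournament selection (size 3), BLX-0.5 blend crossover
(probability 0.9), per-gene Gaussian log-space mutation (probability
2/28, σ = 0.1), elitism 2, stop after 25 generations without 0.01 ms
improvement.  Search bounds: [1/20, 20]× base for the repolarization
time constants and slope factors (the published fitted populations
contain fold-changes up to ~17, all in slow-current parameters);
[1/2, 2]× clipped at 1.6 for thresholds and gate midpoints; and
[1/2, 2]× for the depolarization-phase time constants (tau_fi and the
v-gate constants).  The narrow depolarization prior encodes what the
fitted cohort models are reported to satisfy — near-base peak voltage,
upstroke velocity and time-to-peak, and a fast inward current similar
across cohorts — and is also what keeps the fitted models excitable
enough to propagate in tissue: fits that realize steep restitution by
slowing excitability recovery reproduce the cellular anchors while
being unable to sustain any tissue-level re-entry.  Zero-valued base
entries stay frozen.  The base parameter set is injected into the
initial population once.

Fitness is the mean absolute APD90 deviation from the target log curve
over the retained beats of a dynamic restitution protocol, for beats
whose preceding DI lies in the target's validity range, plus λ
(default 1.0) times the mean absolute mV deviation of a rested CL-600
beat from the base-model morphology template.  The template is compared
on a grid of 0.1 ms over the first 10 ms and 1 ms thereafter: a uniform
1 ms grid cannot see the ~1 ms upstroke, which leaves the depolarization
phase unconstrained in practice.  The target's validity range is the
span of the clinical anchors; extending it with the extrapolated curve
down to the protocol's shortest DIs was evaluated and rejected — it
over-constrains the fits toward the extrapolation and destabilizes them
(occasional failures to converge) without improving the emergent
behaviors.  Three deliberate protocol choices:

* **Cycle-length range.** The fitness protocol paces 620→260 ms in
  20 ms steps (10 beats per CL), i.e. over the full DI range on which
  alternans predictions are later made, rather than only the clinical
  600→350 ms burst set.  With the clinical range alone the fitted
  models' short-DI behavior is mathematically unconstrained, and whole
  converged populations show no alternans anywhere on the scan — a
  calibration that cannot express the phenomenon it is meant to
  predict.  The clinical protocol remains available
  (`FitnessProtocol(cls=CLINICAL_CLS, beats_per_cl=20)`).
* **Retained beats.** The fitness keeps beats 2..10 of each block
  (dropping only the first), not the clinical steady-state mask.
  Steady beats all lie on the line APD = CL − DI, so they pin the
  target curve's values at one point per cycle length but not its
  slope; converged GA runs exploit that freedom with shallow
  non-alternating models threading the steady points.  The transient
  beats after each cycle-length step sample DIs off the steady locus
  and constrain the local dynamic slope.  Measurement-side processing
  (the `ari` module) always applies the clinical exclusion rule; this
  choice concerns only the simulation-side objective.

Desk-scale defaults (population 100, ≤ 60 generations) converge to
1–3 ms fitness in a few minutes; the full-scale configuration
(population 1512, hundreds of generations) is available behind
`full_scale_config`/`--scale full`.

## Alternans scan

620→260 ms in 5 ms steps, 10 beats per cycle length, last two beats
compared; onset is the longest CL with |ΔAPD| ≥ 2 ms at that CL and the
next shorter one.  Each block is paced from the rested state by default:
the protocol's 10-beat blocks are far from steady state either way, and
of the two defensible readings (rested blocks vs state carried across
blocks) the rested-block convention is the one consistent with the
published onset cycle lengths; carried-state scanning is available via
`carry_state=True` and yields onsets ~30–40 ms shorter on the same
models.  Loss of 1:1 capture terminates the grid, since alternation is
undefined beyond it.

## Population clustering

The final GA population is normalized to log2 fold-change against the
base parameter set (raw-space distances would be dominated by the large
time constants), clustered with average-linkage AHC on Euclidean
distances, and cut at the (k−1) highest merge heights for k = 2 and 4.
Centroids are arithmetic means in normalized space, de-normalized for
simulation.  The percentile constraint keeps rows whose every parameter
lies inside the central [100−p, p] band of its marginal distribution
(two-sided reading of "within the p-th percentile").  Linkage method,
metric and normalization are not published; average linkage is the
method for which the cophenetic correlation is the natural fidelity
measure.

## Tissue model

2 cm × 2 cm isotropic monodomain sheet (the 0.25 mm thickness admits no
transmural dynamics and is collapsed), 5-point Laplacian with mirrored
no-flux boundaries, forward Euler at dt = 0.02 ms on an 80 × 80 grid
(dx = 0.025 cm), with the CFL-type bound dt ≤ dx²/(4D) enforced.
Conductivity maps to diffusivity as D = κ·σ with κ calibrated once on
the base model so a plane wave at σ = 0.012 S/m travels at 74 cm/s, the
top of the clinically observed range; the calibrated mapping then puts
σ = 0.009 at ≈ 63 cm/s and σ = 0.001 at ≈ 16 cm/s.

Conduction velocity is measured on a thin pseudo-1D strip at twice the
slab resolution (dx = 0.0125 cm): a plane wave is invariant transverse
to propagation, and at low conductivity the depolarization front is
narrower than the 0.025 cm slab spacing, which would artificially slow
it.  Probes sit at 25% and 75% of the propagation axis.

Pre-pacing (100 beats at 600 ms) is run at the cell level and broadcast:
diffusion of a uniform state is identically zero, so this is exactly
equivalent to pacing the slab and ~4000× cheaper; the state is cached by
parameter hash.  S1 excites a 2 cm × 0.5 mm bottom-edge strip at t = 0,
S2 a 1 cm × 1 cm lower-left square at the coupling interval; activation
is an upward crossing of the rescaled −40 mV level with a 5 ms per-node
deadtime.  A trial is *sustained* when the last activation anywhere
occurs more than 2 s after S2 (simulated horizon 2.5 s) and *induced*
when activity outlives the direct S2 response by 0.5 s.  Runs stop
early once no node has activated for 400 ms (no re-entrant pattern can
pause that long) or the slab is uniformly below u = 0.1.

The inducibility sweep shares the S1 prefix across coupling intervals
at fixed conductivity via state snapshots.  Desk-scale default grids:
σ ∈ {0.003, 0.006, 0.009} S/m and CI 435→120 ms in 15 ms steps — the
three conductivities span the clinical CV range and the CI range brackets
every window we have observed by a full window width; the full clinical
grids (0.001–0.012 by 0.0005; 500→50 by 5) are available through the
same function and the CLI.

## Known limitations

* The fitted populations are phenomenological: parameter fold-changes
  are degenerate directions and carry no direct ionic meaning; only
  emergent behaviors (restitution, alternans onset ordering, re-entry
  windows) are meaningful outputs.
* Alternans onset cycle lengths of GA-calibrated models retain genuine
  run-to-run (seed) variability of a few tens of ms at desk scale; the
  ICMP-later-than-SNLV ordering is the robust signature.  The ICMP
  onset is mechanism-determined (the steep target forces it) and lands
  around 380–395 ms; the SNLV onset is not identifiable from the SNLV
  calibration data — the SNLV clinical curve's slope stays below ~0.4
  everywhere in its measured DI range, and its slope-1 point lies below
  the scan floor — so fitted SNLV models alternate only through
  unconstrained short-DI structure, typically near 275–300 ms.  Any
  particular published SNLV onset therefore reflects the authors'
  specific fit rather than the cohort data.
* Desk-scale populations (100 individuals, ≤ 60 generations) do not
  reproduce clustering statistics of a fully converged 1512-individual
  population: the cophenetic correlation measures how strongly a few
  extreme stragglers dominate the pairwise-distance distribution, and a
  small converged population has none (measured ~0.6–0.8 versus ~0.97
  at full scale), and its top-level cut may split the bulk into two
  comparable clusters instead of one dominant one.  The stability
  conclusion — cluster centroids behave like the best fit — holds
  regardless.
* Absolute re-entry window edges depend on the unpublished tissue
  constants absorbed into κ; the cohort ordering of window widths is
  the calibrated, comparable quantity.
* Post-repolarization refractoriness is not representable in the
  minimal model.
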