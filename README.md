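# restforge

Characterizing electrophysiologic remodeling of the human left ventricle
from clinical pacing data, end to end: from unipolar electrograms to
disease-specific action-potential models to tissue-level re-entry
inducibility.

Patients with ischemic cardiomyopathy (ICMP) have a steeper
action-potential-duration restitution (APDR) — the dependence of APD on
the preceding diastolic interval (DI) — than patients with structurally
normal left ventricles (SNLV), and steep restitution promotes APD
alternans and re-entrant arrhythmias.  This package implements the full
computational methodology for quantifying that remodeling and its
arrhythmogenic consequences:

1. **Electrogram synthesis** (`restforge.egm`) — unipolar electrograms
   sampled at 977 Hz under the clinical decremental pacing protocol
   (20 beats per burst, cycle lengths 600→350 ms in 50 ms steps), with
   known activation/repolarization ground truth and cohort-calibrated
   restitution statistics, so the signal-processing chain is testable
   without patient data.
2. **ARI extraction** (`restforge.ari`) — activation–recovery intervals
   by the Wyatt method (steepest negative slope of the activation
   deflection to steepest positive slope of the repolarization wave),
   the clinical beat-exclusion rule, logarithmic restitution fits
   `ARI = α + β ln(DI)` by Tukey-bisquare robust regression with an
   R² > 50% acceptance filter, and a patient-level cluster bootstrap for
   cohort contrasts.
3. **Model calibration** (`restforge.ga`) — a real-coded genetic
   algorithm fitting the 28 parameters of the four-variable minimal
   ventricular action-potential model (endocardial base) so its
   dynamic restitution matches a cohort APDR target, with mean-absolute-
   error fitness and an action-potential morphology constraint.
4. **Calibration uncertainty** (`restforge.clustering`) — agglomerative
   hierarchical clustering of the final GA population in log2
   fold-change space; cophenetic correlation, top-2/top-4 cuts, cluster
   centroids, and percentile-constrained sensitivity analyses.
5. **Pro-arrhythmia assessment** (`restforge.cell`, `restforge.tissue`)
   — single-cell alternans scans (620→260 ms, 5 ms steps, ≥2 ms APD
   difference at two consecutive cycle lengths) and 2-D isotropic
   monodomain simulations on a 2 cm × 2 cm slab with an S1S2 cross-field
   protocol, conduction-velocity calibration (17–74 cm/s over
   conductivities 0.001–0.012 S/m) and sustained-re-entry (>2 s)
   inducibility maps.

The model core is the minimal ventricular model: four state variables
(u, v, w, s) and three phenomenological currents

    du/dt = -(J_fi + J_so + J_si) + I_stim

with a fast inward current J_fi gated by v, a slow outward current J_so,
and a slow inward current J_si gated by w·s; voltage is reported in mV
through the published affine map V = 85.7·u − 84.

## Worked example

```python
from restforge import make_base_params, rested_biomarkers
from restforge.ga import GACalibrator
from restforge.cell import alternans_scan, steady_biomarkers

# baseline endocardial model: biomarkers of a rested beat at CL 500 ms
b = rested_biomarkers(make_base_params())
print(f"RMP {b.RMP:.1f} mV  APD30 {b.APD30:.1f}  APD50 {b.APD50:.1f}  APD90 {b.APD90:.1f} ms")
# RMP -84.0 mV  APD30 124.3  APD50 227.0  APD90 276.8 ms

# calibrate the model to the ICMP cohort restitution target (desk scale)
cal = GACalibrator(seed=1, population_size=100, max_generations=60).fit("icmp")
print(f"fitness {cal.best_fitness_:.2f} ms after {cal.n_generations_} generations")
# fitness 3.26 ms after 60 generations
apd = steady_biomarkers(cal.best_params_, cl=500).APD90
onset = alternans_scan(cal.best_params_).onset_cl
print(f"APD90 at 500 ms pacing: {apd:.1f} ms; alternans onset: {onset} ms")
# APD90 at 500 ms pacing: 243.4 ms; alternans onset: 380.0 ms
```

The first block reproduces the published baseline biomarker row (resting
potential −84.0 mV, APD90 276.3 ms).  The calibration takes a few
minutes on one CPU and returns a best-fit ICMP model whose steady APD90
at 500 ms pacing lands on the cohort's measured 500 ms ARI (≈243 ms) and
whose alternans onset (380 ms here) is at a longer cycle length than the
SNLV fit's — the in-silico signature of the ICMP cohort's steeper
restitution and its greater arrhythmogenic propensity.

A command-line interface mirrors the library:

```bash
restforge biomarkers --protocol rested
restforge synth-egm --cohort icmp --patients 5 --electrodes 4 --seed 1 --out egm/
restforge ga-fit --cohort snlv --seed 1 --out ga_snlv/
restforge cluster --population ga_snlv --k 4
restforge tissue-sweep --params ga_snlv/best_params.json --out sweep.csv
restforge pipeline --seed 1 --out run1/
```

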