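# Methods

This note documents the models, numerical choices and known limitations of
`pdcest`.  It is written for a reader who wants to know exactly what the
package computes and what passing its tests does and does not demonstrate.

## Saturation-transfer model

The simulator propagates the coupled Bloch-McConnell equations for a set of
magnetization pools in the rotating frame of the saturation pulse.  Water
and every chemically shifted solute pool carry three components
(Mx, My, Mz); semisolid magnetization-transfer (MT) pools are
longitudinal-only, with RF saturation entering through a Lorentzian
absorption rate `π·ω1²·g(Δω)`, `g(Δω) = (T2/π)/(1+(Δω·T2)²)`.  Exchange
between a solute pool and water uses the pool-to-water rate `k` with the
reverse rate `k·f` (`f` the pool fraction), preserving thermal equilibrium.
A super-Lorentzian MT lineshape is deliberately not offered: close to
water, where this package evaluates the MT pool, the super-Lorentzian
diverges and standard practice interpolates it anyway; the Lorentzian keeps
the model self-contained.

Irradiation is pseudo-continuous-wave: `n_pulses` rectangular pulses of
`pulse_duration` seconds separated by `interpulse_delay` of free evolution
(defaults 4 × 200 ms, 10 ms, B1 = 2 μT, 3 T).  Because the RF amplitude is
piecewise constant, each segment is propagated *exactly* with one matrix
exponential of the augmented (affine) evolution matrix; the per-offset
block propagator is raised to the pulse count.  There is no step size to
tune, and the propagator agrees with an independent fixed-step RK4
integration of the same ODE system to ~1e-10 relative (tested).

The readout is the water Mz at the end of the train normalized by its
equilibrium value — the Z-spectrum point `Ssat/S0` at that offset.

### Default pools and calibration

Four pools: water (T1 1.3 s, T2 80 ms), amide (+3.5 ppm, k = 30 s⁻¹,
T2 30 ms), aliphatic NOE (−3.5 ppm, f = 0.004, k = 20 s⁻¹, T2 5 ms), and a
semisolid MT pool (f = 0.08, k = 25 s⁻¹, T2 = 10 μs, centered on water).
These are generic 3 T gray-matter figures, not measurements of any specific
tissue.  The amide pool fraction is the free parameter: per region it is
calibrated, by inverting the simulated APT-weighted response curve, so each
region's healthy baseline lands on configured targets in the ~0.7–1.3 %
range typical of deep gray matter (`defaults.REGION_APT_BASELINE`).

An important structural property of this model: the APT-weighted value is
*offset-linear* in the amide fraction — the NOE pool contributes a
near-constant negative asymmetry (~−2.5 % at 3.5 ppm here) that the amide
effect must first cancel.  Relative changes in amide content therefore
produce much larger relative changes in APTw.  All disease-effect
calibration goes through the response curve inverse rather than assuming
proportionality.

## Phantom

Two 64×64 slices (configurable): substantia nigra on the lower slice;
globus pallidus, putamen and caudate on the upper, each as bilateral
ellipses on a uniform tissue background.  Geometry is specified in
fractions of the grid so it scales to smaller test images.  Each voxel's
spectrum is its region's simulated spectrum evaluated at
`offset − B0(voxel)`, scaled by S0 (constant 1000), with independent
Gaussian noise per acquisition (relative SD `noise_sigma`, default 0.005).
The B0 map is a smooth tilt-plus-bump field with configurable amplitude
(default 0.1 ppm).

Gaussian noise rather than Rician is a documented simplification: at these
saturation levels the signal stays far from zero, where the Rician
distribution is well approximated by a Gaussian.

**Intravoxel line broadening.**  The raw finite-train Bloch-McConnell
spectrum carries coherent ripples (~0.003 in Z near the water dip) from
Rabi oscillation phases at readout.  No voxel-scale measurement retains
these: static-field dispersion across a 6 mm slice dephases them.  The
phantom therefore convolves each region's dense-grid spectrum with a
Gaussian of `intravoxel_sigma` = 0.04 ppm before sampling.  Setting it to 0
reproduces raw simulator output bit-exactly (used by the exactness tests).
Without this physically real dispersion, no estimator working from the
31 scheduled samples can localize the water center to 0.01 ppm.

DWI synthesis is a single-tensor forward model `S0·exp(−b gᵀ D g)` per
region with ground-truth tensors built from (FA, MD) pairs via the
axially-symmetric closed form; 1 b=0 volume plus 31 Fibonacci-sphere
directions at b = 1000 s/mm², Gaussian noise at a configurable b=0 SNR
(default 30).  No eddy-current distortion, motion, or skull is simulated,
so no preprocessing (eddy correction, brain extraction) is re-implemented.

## CEST quantification

* **Normalization**: repeats averaged per offset first, then divided by S0
  (equivalent to the reverse with a single S0; averaging first is the
  better-conditioned order under noise).  Voxels with S0 ≤ 0 are NaN and
  flagged, never zero-filled.
* **B0 correction**: the water center is found by exhaustive grid search
  (±1 ppm, 0.01 ppm steps) minimizing the *mirror residual*
  `mean[(Z(2c−x) − Z(x))²]` over the samples within 0.65 ppm of the
  candidate center `c`, with `Z` cubic-spline interpolated.  The plain
  spline minimum is available as `method="minimum"`, but at 2 μT the water
  line is saturated flat over ±0.2 ppm and its interpolated minimum
  localizes no better than ~0.02–0.07 ppm from 0.25-ppm-spaced samples;
  the symmetry center uses the steep, well-sampled flanks and recovers
  injected shifts to ≤0.01 ppm over ±0.5 ppm (tested).  A center on the
  search-window boundary invalidates the voxel rather than clamping.
* **Resampling**: the corrected spectrum is the measured spectrum linearly
  interpolated at `nominal + shift`.  Linear is a deliberate choice: cubic
  splines ring at the schedule's 0.25→0.5 ppm sampling-density transitions
  and triple the metric-level error.  Whole-spectrum round-trip fidelity is
  bounded by interpolation of the 0.25/0.5 ppm sampling (~`f″h²/8`, up to
  a few 1e-2 on the steep direct-saturation flank); what the pipeline
  guarantees, and tests, is metric-level fidelity — region-mean APTw within
  0.05 % of the uncorrupted value under the default 0.1 ppm field.
* **Asymmetry**: `100·[Z(−x) − Z(+x)]` on the non-negative offsets covered
  on both sides, 0 at x = 0 by definition; APTw by linear interpolation at
  3.5 ppm; total CEST by trapezoid on a uniform 0.125 ppm grid over
  0–4 ppm.  The two algebraic forms of the asymmetry definition are
  verified identical to 1e-14.

## Diffusion metrics

Ordinary least squares on `log S` against the 7-column b-matrix design
(6 tensor components + log S0), per voxel; exact on noiseless data (tested
to 1e-10).  WLS is not fitted by default — at the SNR used here OLS matches
the standard single-shell practice.  Negative eigenvalues are clamped to
zero with the voxel flagged; FA is clipped to [0,1]; a tensor with
eigenvalue norm below 1e-8 (in 10⁻³ mm²/s units) is treated as zero and
assigned FA 0, so roundoff-scale fits cannot produce arbitrary anisotropy.
MD is reported in 10⁻³ mm²/s so healthy gray matter sits near 0.7.

## Cohort model

Subjects: 23 controls, 12 early-stage and 11 advanced-stage patients by
default.  Disease multiplies each region's amide fraction (protein/peptide
content proxy — an exchange-rate mode is deliberately not the default) and
the mean / anisotropic part of its tensor.  The amide multipliers are
derived by inverting the APT response so the stage group means land on
configured stage targets (nigra: 1.25 → 0.96 → 0.81 %; caudate:
0.84 → 1.35 → 0.91 %; etc.); the diffusion multipliers implement the
progressive nigral FA decline with essentially null striatal effects.

Between-subject biology is a unit-mean lognormal deviate per subject and
region: CV 0.04 on the amide fraction (the response gain makes this
~0.12 CV in APTw), CV/3 on the tensor scalings.  Hemisphere samples add
independent Gaussian measurement noise (APTw 0.06 %, total CEST
0.2 %·ppm, FA 0.008, MD 0.01).  This dispersion is deliberately *below*
what the clinical tables imply (sample CV ≈ 0.3): the phantom is a
well-powered validation cohort whose purpose is to verify that the
pipeline recovers the injected effect structure, not to emulate clinical
power.  Consequently some striatal DTI contrasts reach significance here
that are null in patients; the direction pattern, not the significance
pattern, is what the cohort reproduces.  The null configuration
(`null_config`) sets all multipliers to 1 *and* CV to 0, leaving iid
measurement noise — with subject-level biology present, bilateral samples
from one subject are correlated and the hemisphere-as-sample convention
makes the two-group t-test anti-conservative (design effect 1 + ICC); this
is a real property of the sampling convention, documented rather than
hidden.

Two generation paths share the parameter structure: the imaging path
(phantom + DWI per subject through the full voxelwise pipeline) and a
table path that draws ROI values directly through the response splines, for
calibration studies needing hundreds of replicate cohorts.  Both are
deterministic in the seed.

## Statistics

Summaries use the t-based 95 % CI half-width `t(0.975, n−1)·sd/√n`.  The
two-group test defaults to Student's pooled t (the equal-variances-assumed
convention of mainstream statistics packages), with Welch available.  The
summary-statistics bridge (reconstructing t and F from published
"mean ± CI" rows) uses Welch with Welch–Satterthwaite df, because two
separate CIs cannot recover a pooled SD; it is verified against raw-sample
Welch tests and reproduces the published nigral (p = 0.003) and putaminal
(p = 0.010) comparisons under both the bilateral-sample (n = 46) and
per-subject (n = 23) reading of the group sizes — the source tables are
ambiguous on this point, so both modes ship and neither is asserted.

Levene's test uses mean centering.  Tukey HSD uses pooled variance,
`df = N − k`, and simultaneous CIs from the studentized-range quantile;
Games-Howell uses per-pair `SE = √(s_i²/n_i + s_j²/n_j)`,
Welch–Satterthwaite df, and `q = |diff|·√2/SE`.  The studentized-range
CDF/quantiles come from `scipy.stats.studentized_range` (numerical
integration; validated against the published table value
q(0.95; 3, 10) = 3.88).  Our Tukey matches `scipy.stats.tukey_hsd` to
1e-8 and our Games-Howell matches both a from-definition hand computation
and `pingouin.pairwise_gameshowell`.  The post hoc gate is exactly
`Levene p ≥ 0.05 → Tukey, else Games-Howell`, at the fixed α = 0.05.  No
multiple-testing correction is applied across region × metric cells — the
emulated analysis applies none — and this is a known limitation.

Degenerate inputs follow explicit conventions: identical groups give
p = 1 with a warning (detected by zero range, not sample SD, which is
~1e-16 on bit-identical values), and constant-group Levene returns
W = 0, p = 1.

## Problem sizes

The shipped configurations are sized for a single CPU: the demo pipeline
uses 6+4+4 subjects on 32×32 slices (~10 s), tests use 16–24 voxel grids,
the type-I simulation uses 500 table-path replicates and the sign-pattern
check 100 seeds.  All sizes are configuration, not code.

## Known limitations

* Gaussian (not Rician) noise; no scanner artifacts, motion, eddy currents,
  ghosting, or realistic anatomy.
* Lorentzian MT lineshape only.
* Whole-spectrum B0 round-trip fidelity is interpolation-limited on the
  steep direct-saturation flank (see above); metrics are unaffected beyond
  the tested 0.05 % bound.
* Total-CEST magnitudes run below clinical values: the 4-pool model has no
  amine/guanidinium pools in the 1.5–3 ppm band, so the 0–4 ppm integral
  accumulates less positive asymmetry than tissue does.  Group *contrasts*
  in total CEST still follow the amide effect.
* The cohort's dispersion is validation-grade, not clinical-grade (see
  above); absolute p-values from the synthetic cohort are not comparable
  to patient-study p-values, only the recovered effect structure is.
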