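# pdcest

Quantification and group-comparison pipeline for CEST/APT and diffusion-tensor
MRI of the substantia nigra and striatum, with a Bloch-McConnell synthetic
brain-phantom cohort for end-to-end validation.

## The problem

Amide proton transfer (APT) imaging, a variant of chemical exchange
saturation transfer (CEST) MRI, saturates the backbone amide protons of
mobile proteins and peptides 3.5 ppm downfield of water and reads out the
transferred saturation as a drop in the water signal.  In Parkinson's
disease, APT-weighted signal falls in the substantia nigra (neuronal and
protein loss) and rises in the striatum early in the disease, while
diffusion-tensor metrics (FA, MD) change little outside the nigra — which
makes CEST an attractive early marker and motivates a careful, testable
re-implementation of the quantification chain that produces those numbers.

This package implements that chain for people who want to study or stress
the analysis itself: simulation of the acquisition, the two CEST metrics,
the tensor metrics, and the exact inference procedure applied to ROI
samples.

## What it computes

For each voxel of a saturation stack acquired at offsets `x` (ppm) with an
unsaturated reference `S0`:

* **Z-spectrum** `Z(x) = S_sat(x) / S0`, repeats averaged per offset;
* **B0 correction** — the water center is found per voxel by an exhaustive
  symmetry-center search on a cubic-spline interpolation of `Z` (default
  window ±1 ppm, step 0.01 ppm) and the spectrum is resampled so the center
  sits at 0 ppm;
* **MTR asymmetry** `MTRasym(x) = MTR(+x) − MTR(−x) = [Z(−x) − Z(+x)]`,
  reported in percent; the APT-weighted value is `MTRasym(3.5 ppm)`;
* **Total CEST** — the trapezoidal integral of `MTRasym` over 0–4 ppm
  (percent·ppm);
* **Diffusion tensor** by per-voxel ordinary least squares on
  `log(S/S0) = −b gᵀ D g`, with `MD = (λ1+λ2+λ3)/3` and
  `FA = √(3/2)·‖λ − MD‖ / ‖λ‖` (units 10⁻³ mm²/s).

ROI samples (left and right hemispheres kept as separate records) feed the
inference chain: mean ± 95 % CI summaries, independent-samples t-tests
(control vs patients), one-way ANOVA over control / early-stage /
advanced-stage, and a Levene homogeneity gate that selects Tukey HSD
(Levene p ≥ 0.05) or Games-Howell (p < 0.05) pairwise post hoc tests, both
built on the studentized-range distribution.

Because no patient images are distributable, the package ships a
first-class synthetic-data module: a pulsed-saturation Bloch-McConnell
simulator (water, amide at +3.5 ppm, aliphatic NOE at −3.5 ppm, and a
Lorentzian semisolid MT pool; exact matrix-exponential propagation), a
two-slice bilateral-ROI phantom with a smooth B0 field and seeded noise,
single-tensor DWI synthesis, and a cohort generator whose stage effects are
calibrated against published group means.

## Worked example

```python
from pdcest.pipeline import RunConfig, run_all
from pdcest.schedule import DEFAULT_SCHEDULE_TEXT

cfg = RunConfig(schedule=DEFAULT_SCHEDULE_TEXT, out_dir="demo", seed=1,
                image_shape=(32, 32, 2),
                n_control=6, n_early_pd=4, n_advanced_pd=4)
run_dir = run_all(cfg)

import pandas as pd
tt = pd.read_csv(run_dir / "stats" / "ttests.csv").set_index(["region", "metric"])
print(tt.loc[("substantia_nigra", "apt_weighted"), "p"])
```

With seed 1 this 14-subject demo prints `0.0070780331901276`: the nigral
APT-weighted signal of the simulated patients (group mean 0.93 %) is
significantly below the controls (1.09 %), while the same table shows the
striatal APT-weighted values running higher in patients — the expected
disease pattern, recovered from raw simulated images by the full chain.
The run directory also contains per-subject NIfTI maps (`apt_weighted`,
`total_cest`, `b0_fitted`, `fa`, `md`), the ROI sample CSV, ANOVA/post hoc
tables, and a rendered markdown report.

The same pipeline is available from the shell:

```bash
pd-cest run-all --config run.yaml
pd-cest cest-quant --stack s.nii.gz --s0 s0.nii.gz --schedule schedule.json \
    --mask labels.nii.gz --out maps/
pd-cest dti-fit --dwi dwi.nii.gz --bvals dwi.bval --bvecs dwi.bvec --out maps/
pd-cest group-stats --samples roi.csv --out report/
```

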