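# vertemech

Cross-species prediction of vertebral compressive stiffness from
micro-CT-style image volumes, using bone volume fraction (BV/TV) as the
single material driver.

Vertebral finite-element models are usually calibrated per species from
image greyscale, which breaks down whenever density calibration is
unavailable — dry or fossil bone, archived scans, or comparisons across
species with very different tissue mineralization (e.g. elderly human
versus juvenile porcine vertebrae). This package implements a pipeline that
needs only the *geometry* of the bone phase:

1. fit a two-normal mixture (trabecular fluid + bone) to the greyscale
   histogram of a trabecular region of interest, and select a
   bone/background threshold by the *clear-minimum* rule where the mixture
   is bimodal or the *equal-misclassification* rule
   A₁·Φ̄((t−μ₁)/σ₁) = A₂·Φ((t−μ₂)/σ₂) where it is not — per species, or
   globally as the mean of the species thresholds;
2. binarize and homogenize to a 1 mm element grid whose values are exact
   partial-volume bone fractions, and label bone / PMMA cement / void;
3. map BV/TV to elastic modulus, E = k·(BV/TV)^p with p ∈ {1, 2} and
   cement fixed at 2.45 GPa;
4. solve a voxel-hexahedral linear-elastic model of the potted specimen:
   fixed base, tied bone–cement interfaces, and an axial point load applied
   through a rigid plate that is free to tilt (ball-joint loading);
   stiffness = load / load-point displacement (kN/mm), apparent modulus =
   stiffness × height / area (MPa);
5. calibrate k against measured stiffness by minimizing the mean absolute
   percentage error over the specimen set, for the 2×2 variant matrix
   {species-specific, global threshold} × {linear, square law};
6. sweep the load over five equally spaced anterior→posterior positions
   (with the upper cement cap rebuilt at 40% of body height) to quantify
   the growing role of the posterior neural arch.

A synthetic-phantom generator (`vertemech.phantom`) produces vertebra-like
volumes with full ground truth — trabecular texture at a target BV/TV,
cortical rim, posterior arch, PMMA caps, and two greyscale regimes
("human-like": separated mixture, low BV/TV; "porcine-like": overlapped
mixture, high BV/TV) — plus pseudo-experimental stiffness with controlled
noise, so the whole pipeline is testable without any scan data.

## Worked example

```python
import numpy as np
from vertemech import *
from vertemech.phantom import trabecular_roi

spec = human_like_spec(seed=1)
volume, truth = make_vertebra_phantom(spec)

hist = compute_histogram(volume, roi=trabecular_roi(spec), n_bins=128)
fit = fit_bimodal(hist)
res = select_species_threshold(fit)
print(f"mixture fit: mu1={fit.mu1:.1f}, mu2={fit.mu2:.1f}, "
      f"sigma1={fit.sigma1:.1f}, sigma2={fit.sigma2:.1f}")
print(f"threshold = {res.threshold:.2f} (rule: {res.rule})")

params = MaterialParams(k=0.33, exponent=1)
rec, s_true = pseudo_experiment(truth, params, specimen_id="demo")
print(f"forward FE stiffness at k=0.33 GPa: {s_true:.3f} kN/mm")

bv2, lab2, _ = configure_endcap(truth.bvtv_coarse, truth.labels_coarse,
                                truth.height_mm)
pos = load_positions(truth.body_labels_coarse)
sweep = position_sweep(bv2, lab2, params, pos, truth.height_mm, truth.area_mm2)
print("A->P sweep stiffness (kN/mm):", np.round(sweep.stiffness_kN_per_mm, 3))
print("change vs anterior (%):      ", np.round(sweep.change_pct, 1))
```

prints

```
mixture fit: mu1=100.0, mu2=219.9, sigma1=14.9, sigma2=24.8
threshold = 151.50 (rule: clear_minimum)
forward FE stiffness at k=0.33 GPa: 2.166 kN/mm
A->P sweep stiffness (kN/mm): [0.454 0.685 1.098 1.797 2.519]
change vs anterior (%):       [  0.   51.  142.  296.2 455.5]
```

The fitted component means land on the generator's background (100) and
bone (220) intensities and the clear-minimum rule fires, as it should for a
strongly mineralized ("human-like") distribution. The sweep rises
monotonically from the anterior to the posterior of the vertebral body: as
the load point moves back, the stiff posterior arch carries an increasing
share of the load.

The same workflow is available from the shell:

```bash
vertemech phantom --regime human_like --seed 1 --outdir ph/
vertemech threshold ph/volume.mhd
vertemech bvtv ph/volume.mhd --threshold 151.5 --outdir fields/
vertemech solve fields/bvtv.mhd fields/labels.mhd --k 0.33
vertemech run-part1 manifest.csv --outdir report/   # 4-variant calibration
vertemech run-part2 manifest.csv --outdir sweeps/   # 5-position sweeps
```

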