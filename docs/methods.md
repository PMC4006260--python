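# Methods

`vertemech` predicts the axial compressive stiffness of vertebral specimens
from micro-CT-style greyscale volumes, across species with very different
bone volume fraction and mineralization, and probes how stiffness depends on
where the load is applied. This note records the models, the numerical
choices, and what the synthetic phantoms do and do not establish.

## The modelling chain

1. **Threshold selection.** A greyscale histogram is extracted from a
   cuboidal region of interest inside the trabecular centrum and modelled as
   the sum of two normal components — trabecular-space fluid (mean μ₁,
   variance σ₁²) and mineralized bone (μ₂, σ₂²) — with free masses A₁, A₂
   in voxel counts. The masses are a necessary extension: a count histogram
   cannot be fitted by two density curves without amplitude terms. The model
   curve, evaluated at bin centres and scaled by bin width, is fitted to the
   binned counts by least squares with a bounded quasi-Newton optimizer
   (L-BFGS-B, numerical gradients, σ bounded below by one bin width) from
   three deterministic quantile-based starts; the best final objective wins.
   Two rules then pick the bone/background threshold:
   * *clear minimum*: the interior local minimum of the mixture density on
     (μ₁, μ₂), accepted when its density is ≤ 0.8 × the density at the
     nearer mean (the relative-depth factor is configurable; ties go to the
     deeper minimum, then the one nearer the midpoint). Typical of strongly
     mineralized, well-separated distributions.
   * *equal misclassification*: the root of
     A₁·Φ̄((t−μ₁)/σ₁) = A₂·Φ((t−μ₂)/σ₂), i.e. the intensity at which the
     expected count of background voxels called bone equals the expected
     count of bone voxels called background; solved by bracketed Brent
     iteration to 10⁻⁶ intensity units. Used when no clear minimum exists
     (heavily overlapping distributions).
   A *global* threshold across two groups is the arithmetic mean of the two
   group thresholds. Group fits use the group-average histogram on shared
   bin edges (128 bins by default; the bin count is configurable and the
   method is insensitive to it at these sample sizes).

2. **BV/TV homogenization.** The volume is binarized (bone ⇔ intensity ≥
   threshold; the tie goes to bone for determinism) and downsampled onto a
   coarse grid of 1×1×1 mm elements. Each coarse value is the exact bone
   volume fraction of the cell computed with separable fractional-overlap
   weights, so the non-integer spacing ratio (1 mm over 0.074 mm scanner
   voxels, ≈13.5) introduces no blocking error and total bone volume is
   conserved to rounding. Cells truncated by the image boundary are
   normalized by their intersected volume and flagged. Region labels
   (bone / PMMA cement / void) come from thresholding + largest
   26-connected component + morphological closing (radius 1 element) with
   small interior cavities filled; the cement caps are split off by a high
   intensity threshold before bone binarization. Body height is the axial
   voxel-layer extent of the bone label; average cross-sectional area is the
   mean occupied-slice area. The measured label includes the posterior
   elements; on phantoms, the generator also emits a centrum-only mask.

3. **Material mapping.** Bone elements follow E = k·(BV/TV)^p with p = 1
   (linear) or p = 2 (square); cement takes 2.45 GPa; a single Poisson ratio
   ν = 0.3 applies to all materials (standard for continuum bone/PMMA
   models; configurable). Bone elements retained for connectivity are
   floored at E ≥ k·10⁻⁶ to avoid singular systems without affecting
   stiffness.

4. **Voxel micro-FE.** Each retained cell is one 8-node trilinear hexahedron
   (2×2×2 Gauss quadrature, isotropic linear elasticity). Only the largest
   face-connected component is meshed (corner-linked elements would hinge).
   Units are mm / GPa / kN, so assembled stiffness is kN/mm directly. The
   lowest-z face is fully fixed; the top-surface nodes are condensed into a
   single 6-degree-of-freedom rigid plate whose reference sits at the load
   point, reproducing a compression test through a ball joint: the plate
   translates and tilts freely while an axial point load acts through the
   reference. Bone–cement interfaces are tied by shared lattice nodes. The
   reduced symmetric positive-definite system is solved by preconditioned
   conjugate gradients to relative residual 10⁻⁸ (Jacobi preconditioner in
   the general solver; the calibration loop factorizes each specimen's
   matrix once with sparse LU and reuses it as a preconditioner for every
   trial k, which is spectrally exact up to the ratio k/k₀). Load magnitude
   defaults to 1000 N; the model is linear, so stiffness is independent of
   it. Specimen stiffness is load over the axial displacement of the plate
   at the load point (kN/mm); apparent modulus is stiffness × height / area
   (MPa).

5. **Calibration of k.** k is a pure prefactor of the bone stiffness for
   both laws, so K(k) = k·K_bone + K_cement is assembled once per specimen
   and recombined per trial. The conversion factor minimizes the mean
   absolute percentage stiffness error over the specimen set ("mean error"
   is read as mean |error|: a signed mean could be driven to zero by
   cancellation). The search is bounded derivative-free Brent in log k over
   [0.01, 10] GPa to a relative tolerance of 10⁻³, with per-k predictions
   cached; predictions are independent of the measured values, so noise
   replicates can share one problem object and its cache. k is optimized
   jointly across species (the per-group option exists).

6. **Load sweep.** The upper cement cap is rebuilt at 40% of the body
   height, rounded to the nearest whole element layer. Five load positions
   are spaced equally from the anterior to the posterior voxel-centre
   extent of the centrum (endpoints inclusive), all at its mid-lateral x.
   One solve per position yields stiffness and apparent-modulus profiles;
   the change metric is 100·(value_i − value_1)/value_1 against the most
   anterior position.

## The phantom generator

Phantoms emulate a potted vertebral specimen: an elliptic-cylinder centrum
(default semi-axes 7 × 5.5 mm, height 12 mm) with a dense 0.6 mm cortical
rim and Gaussian-random-field trabecular texture thresholded at the exact
empirical quantile for the target BV/TV (correlation length 0.9 mm ≈
trabecular feature scale at the phantom's 0.3 mm voxels); an optional
posterior neural arch (two pedicles plus a lamina bar, fully dense); and
PMMA caps rendered at a fixed high intensity so fixture segmentation is
unambiguous. Greyscale is drawn per voxel from the two-normal model:

* **human-like** — background N(100, 15²), bone N(220, 25²), body BV/TV
  0.20, arch members 3.6 mm: strongly mineralized, osteoporotic centrum;
  the mixture has a clear interior minimum.
* **porcine-like** — background N(100, 20²), bone N(150, 35²), body BV/TV
  0.45, arch members 3.4 mm: immature mineralization, dense juvenile
  centrum; the mixture is effectively unimodal and triggers the
  equal-misclassification rule.

Air outside the specimen renders dark (N(20, 10²)), as in a real scan;
without this, overlapped-regime thresholds would classify a noticeable
fraction of air as bone, a failure mode real pipelines exclude via the
specimen-region floodfill. The arch member sizes are fixture design: they
give the arch a load share comparable to real posterior elements, so the
phantom class exhibits the anatomy-driven behaviour real specimens show —
a monotone anterior-to-posterior stiffness rise in both regimes, with the
larger relative change in the human-like regime because its compliant
centrum leaves the arch a larger share. Coarse ground-truth labels are
produced by the package's own segmentation applied to the exact
(noise-free) downsampled bone field, so truth and derived models differ
only through greyscale misclassification.

Pseudo-experiments produce "measured" stiffness as the forward FE
prediction at a known k_true times multiplicative lognormal noise of a
given CV, optionally wrapped in a synthetic toe-plus-linear
load–displacement curve whose gradient over a 0.6 mm window equals the
stiffness.

What phantom-based results do **not** show: scanner physics (beam
hardening, noise correlation, calibration units), anatomical realism beyond
body/arch/caps, cortical-shell anatomy beyond high local BV/TV, and any
claim about absolute stiffness of real vertebrae. They validate the
*pipeline*: that each stage recovers what the previous stage encoded, and
that the method's comparative claims (species-specific vs global
thresholds; anterior vs posterior loading) follow from the stated
mechanisms.

## Problem sizes and numerical choices

The standard study set is four phantoms (two per regime) at 0.3 mm fine
voxels (grids ≈ 55×65×55) homogenized to 1 mm elements (≈ 3–4 k elements,
≈ 10–14 k constrained degrees of freedom per model), which keeps a full
four-variant calibration plus sweeps within minutes on one CPU while
preserving every qualitative regime contrast. Mixture fits at this scale
see ~2×10⁴ ROI voxels rather than the ~5×10⁶ of a full-resolution scan, so
single-specimen thresholds for the overlapped regime wobble by a few
intensity units; species-average fits (the method's own definition) are
correspondingly tighter. Other defaults: solver tolerance 10⁻⁸ (stiffness
reproducible to ≥ 6 significant figures), calibration bracket [0.01, 10]
GPa, clear-minimum depth factor 0.8, closing radius 1 element, bone-label
floor BV/TV ≥ 0.005.

## Known limitations

* A freely tilting loading plate makes load-point stiffness drop sharply at
  positions near the section edge of any uniform column (compliance grows
  with the squared offset from the stiffness centroid, I/A = a²/4 for an
  ellipse). An archless control therefore shows a strongly peaked, fore-aft
  symmetric profile rather than a literally flat one; the arch's causal
  role is instead demonstrated by the posterior/anterior stiffness ratio,
  which the arch raises several-fold over the archless control.
* Stiffness only: no strength, nonlinearity, contact, or rate effects.
* One tissue modulus per model: differences in tissue mineralization across
  species are absorbed into k, which is exactly why cross-species errors
  exceed single-species ones.
* Pure voxel hexahedra; no smoothed-surface meshing. This preserves the
  per-element BV/TV mapping exactly and is the standard micro-FE idiom.
* The equal-misclassification equation can lose its bracket for fits whose
  mass ratio is extreme; the operation then refuses with a diagnostic
  rather than extrapolating.
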