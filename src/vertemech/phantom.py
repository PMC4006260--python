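"""Synthetic vertebra phantoms with ground truth.

A phantom is a greyscale volume emulating a potted vertebral specimen in a
micro-CT scan: an elliptic-cylinder vertebral body with a dense cortical rim
and Gaussian-random-field trabecular texture at a target BV/TV, an optional
posterior neural arch (two pedicles plus a lamina bar), and PMMA end-caps
above and below.  Greyscale is a two-component normal mixture — background
(fluid in the trabecular space) and bone — whose component separation
defines two regimes:

* "human-like": well-separated components with a high bone mean
  (heavily mineralized elderly bone; the mixture density has a clear
  interior minimum), low trabecular BV/TV;
* "porcine-like": overlapping components (juvenile, less mineralized bone;
  no clear minimum, the equal-misclassification rule applies), high BV/TV.

Caps render at a fixed intensity far above the bone mean so the fixture's
region segmentation is unambiguous.  Everything is deterministic per seed.

A pseudo-experiment turns a phantom into a "measured" specimen: the forward
FE stiffness at a known conversion factor ``k_true``, times multiplicative
lognormal noise, optionally wrapped in a synthetic load-displacement curve
whose gradient over a 0.6 mm interval is the stiffness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .bvtv_map import (LABEL_BONE, LABEL_VOID, BVTVVolume,
                       RegionLabelVolume, downsample_bvtv, segment_regions)
from .core_io import BinaryVolume, GreyscaleVolume, SpecimenRecord
from .material_map import MaterialParams
from .calibrate import SpecimenModel, predict_stiffness

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "human_like_spec",
    "porcine_like_spec",
    "trabecular_texture",
    "make_vertebra_phantom",
    "pseudo_experiment",
    "synthesize_load_displacement",
    "stiffness_from_curve",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters (lengths mm, intensities in arbitrary units)."""

    body_semi_axes: tuple = (7.0, 5.5)     # lateral, A-P semi-axes
    body_height: float = 12.0
    shell_thickness: float = 0.6           # dense cortical rim
    arch: bool = True
    pedicle_width: float = 2.4             # lateral extent of each pedicle
    arch_thickness: float = 2.4            # A-P extent of pedicles/lamina bar
    arch_bvtv: float = 1.0                 # density of arch bone (its modulus share)
    target_bvtv: float = 0.25              # trabecular interior
    correlation_length: float = 0.9        # texture feature size
    bg_mean: float = 100.0
    bg_sd: float = 15.0
    bone_mean: float = 220.0
    bone_sd: float = 25.0
    air_mean: float = 20.0                 # empty space outside the specimen
    air_sd: float = 10.0
    cap_thickness: float = 2.0
    cap_intensity: float = 500.0
    fine_spacing: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.target_bvtv < 1):
            raise ValueError("target BV/TV must be in (0, 1)")
        if not self.bg_mean < self.bone_mean:
            raise ValueError("need background mean < bone mean")
        if self.correlation_length < self.fine_spacing:
            raise ValueError("texture correlation length must be >= voxel spacing")


def human_like_spec(**overrides) -> PhantomSpec:
    """Well-separated greyscale mixture (heavily mineralized), low body BV/TV
    (elderly trabecular bone), stout arch: the arch carries a large share of
    posteriorly applied load."""
    kw = dict(bg_mean=100.0, bg_sd=15.0, bone_mean=220.0, bone_sd=25.0,
              target_bvtv=0.20, pedicle_width=3.6, arch_thickness=3.6)
    kw.update(overrides)
    return PhantomSpec(**kw)


def porcine_like_spec(**overrides) -> PhantomSpec:
    """Overlapping greyscale mixture (immature mineralization), dense juvenile
    body BV/TV, slightly slighter arch: the dense centrum keeps the arch's
    share of posterior load smaller than in the human-like regime."""
    kw = dict(bg_mean=100.0, bg_sd=20.0, bone_mean=150.0, bone_sd=35.0,
              target_bvtv=0.45, pedicle_width=3.4, arch_thickness=3.4)
    kw.update(overrides)
    return PhantomSpec(**kw)


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside the greyscale volume."""

    bone: BinaryVolume                 # fine binary bone (shell + trabeculae + arch)
    cap_mask: np.ndarray               # fine boolean PMMA mask
    body_mask: np.ndarray              # fine boolean centrum envelope (no arch)
    labels_coarse: RegionLabelVolume
    body_labels_coarse: RegionLabelVolume   # bone label = centrum only
    bvtv_coarse: BVTVVolume
    height_mm: float
    area_mm2: float
    k_true: float | None = None


def trabecular_texture(shape, target_bvtv: float, correlation_length: float,
                       spacing: float, seed: int) -> BinaryVolume:
    """Gaussian-random-field binary texture at an exact empirical quantile.

    White noise is smoothed at the correlation length and thresholded at the
    (1 - target) quantile, so the achieved bone fraction matches the target
    to within one voxel count.  Deterministic per seed.
    """
    if not (0 < target_bvtv < 1):
        raise ValueError("target BV/TV must be in (0, 1)")
    if correlation_length < spacing:
        raise ValueError("correlation length must be >= voxel spacing")
    rng = np.random.default_rng(seed)
    f = ndimage.gaussian_filter(rng.standard_normal(shape),
                                sigma=correlation_length / spacing)
    thr = np.quantile(f, 1.0 - target_bvtv)
    return BinaryVolume(data=(f >= thr).astype(np.uint8),
                        spacing=np.full(3, float(spacing)))


def _centre_coords(n, h):
    return (np.arange(n) + 0.5) * h


def trabecular_roi(spec: PhantomSpec, margin_mm: float = 0.2):
    """Largest axis-aligned square-section box (mm) inscribed in the
    phantom's trabecular interior — the analogue of the largest possible
    central cuboidal region of interest cut from a scanned vertebral body
    for histogram extraction."""
    h = spec.fine_spacing
    ax, ay = spec.body_semi_axes
    margin = 2.0 * h
    Lx = 2 * ax + 2 * margin
    nx = int(np.ceil(Lx / h))
    cx, cy = nx * h / 2, margin + ay
    # square inscribed in the interior ellipse (semi-axes minus the shell):
    # corner (half, half) lies on the ellipse when
    # half = a' b' / sqrt(a'^2 + b'^2)
    a_in = ax - spec.shell_thickness
    b_in = ay - spec.shell_thickness
    half = a_in * b_in / np.hypot(a_in, b_in) - margin_mm
    if half <= h:
        raise ValueError("body too small for an interior ROI")
    z0 = spec.cap_thickness + 1.0
    z1 = spec.cap_thickness + spec.body_height - 1.0
    return ((cx - half, cx + half), (cy - half, cy + half), (z0, z1))


def make_vertebra_phantom(spec: PhantomSpec, coarse_spacing: float = 1.0
                          ) -> tuple[GreyscaleVolume, PhantomTruth]:
    """Build the greyscale phantom and its ground truth.

    Grid layout (mm): caps occupy the full specimen footprint at the bottom
    and top; the body is centred laterally with the arch to the posterior
    (+y).  The arch spans the body's z range only (arch overlapping a cap is
    a spec error).
    """
    h = spec.fine_spacing
    ax, ay = spec.body_semi_axes
    margin = 2.0 * h
    arch_extent = (spec.arch_thickness * 2 + 1.0) if spec.arch else 0.0
    Lx = 2 * ax + 2 * margin
    Ly = 2 * ay + arch_extent + 2 * margin
    Lz = spec.body_height + 2 * spec.cap_thickness
    nx, ny, nz = (int(np.ceil(L / h)) for L in (Lx, Ly, Lz))
    X, Y, Z = np.meshgrid(_centre_coords(nx, h), _centre_coords(ny, h),
                          _centre_coords(nz, h), indexing="ij")
    cx, cy = nx * h / 2, margin + ay
    z0, z1 = spec.cap_thickness, spec.cap_thickness + spec.body_height
    if spec.arch and (z0 < spec.cap_thickness - 1e-12):
        raise ValueError("arch would overlap the caps")

    in_body_z = (Z >= z0) & (Z < z1)
    r2 = ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2
    body = (r2 <= 1.0) & in_body_z
    shell = body & (((X - cx) / (ax - spec.shell_thickness)) ** 2
                    + ((Y - cy) / (ay - spec.shell_thickness)) ** 2 > 1.0)

    arch_mask = np.zeros_like(body)
    if spec.arch:
        t = spec.arch_thickness
        y_ped0 = cy + ay * np.sqrt(max(1 - (0.45) ** 2, 0.0)) - h  # join the rim
        y_ped1 = cy + ay + t
        y_lam0, y_lam1 = y_ped1, y_ped1 + t
        for sgn in (-1, 1):
            x0 = cx + sgn * 0.45 * ax - spec.pedicle_width / 2
            ped = ((X >= x0) & (X < x0 + spec.pedicle_width)
                   & (Y >= y_ped0) & (Y < y_ped1) & in_body_z)
            arch_mask |= ped
        x_lam0 = cx - 0.45 * ax - spec.pedicle_width / 2
        x_lam1 = cx + 0.45 * ax + spec.pedicle_width / 2
        lam = ((X >= x_lam0) & (X < x_lam1) & (Y >= y_lam0) & (Y < y_lam1)
               & in_body_z)
        arch_mask |= lam
        arch_mask &= ~body
        if (y_lam1 + margin) > Ly + 1e-9:
            raise ValueError("arch exceeds the grid; enlarge the domain")

    caps = (Z < z0) | (Z >= z1)
    footprint = (body | arch_mask).any(axis=2)
    caps &= footprint[:, :, None]

    # trabecular interior texture; arch at its own (denser) quantile
    tex = trabecular_texture((nx, ny, nz), spec.target_bvtv,
                             spec.correlation_length, h, spec.seed)
    interior = body & ~shell
    bone = np.zeros((nx, ny, nz), dtype=bool)
    bone[interior] = tex.data[interior] == 1
    bone |= shell
    if spec.arch:
        rng_a = np.random.default_rng(spec.seed + 1)
        arch_field = ndimage.gaussian_filter(rng_a.standard_normal((nx, ny, nz)),
                                             sigma=spec.correlation_length / h)
        vals = arch_field[arch_mask]
        if vals.size:
            thr = np.quantile(vals, 1.0 - spec.arch_bvtv)
            sel = np.zeros_like(bone)
            sel[arch_mask] = arch_field[arch_mask] >= thr
            bone |= sel

    # air outside the specimen, trabecular fluid inside, bone on the network
    rng = np.random.default_rng(spec.seed + 2)
    grey = rng.normal(spec.air_mean, spec.air_sd, size=(nx, ny, nz))
    envelope = body | arch_mask
    fluid = envelope & ~bone
    grey[fluid] = rng.normal(spec.bg_mean, spec.bg_sd, size=int(fluid.sum()))
    grey[bone] = rng.normal(spec.bone_mean, spec.bone_sd, size=int(bone.sum()))
    grey[caps] = spec.cap_intensity

    spacing = np.full(3, h)
    volume = GreyscaleVolume(data=grey, spacing=spacing)
    bone_vol = BinaryVolume(data=bone.astype(np.uint8), spacing=spacing)

    # coarse ground truth on the analysis grid
    bvtv_coarse = downsample_bvtv(bone_vol, coarse_spacing)
    cap_frac = downsample_bvtv(BinaryVolume(data=caps.astype(np.uint8),
                                            spacing=spacing), coarse_spacing)
    # truth labels go through the same segmentation path the pipeline uses,
    # applied to the exact (unthresholded) bone field
    labels_coarse = segment_regions(bvtv_coarse, cement_mask=cap_frac.data >= 0.5)
    body_frac = downsample_bvtv(BinaryVolume(data=body.astype(np.uint8),
                                             spacing=spacing), coarse_spacing)
    blab = np.full(bvtv_coarse.shape, LABEL_VOID, dtype=np.uint8)
    blab[body_frac.data >= 0.5] = LABEL_BONE
    body_labels = RegionLabelVolume(data=blab, spacing=bvtv_coarse.spacing,
                                    origin=bvtv_coarse.origin)
    # zero BV/TV outside the labelled bone so materials see a clean field
    bvtv_clean = bvtv_coarse.data.copy()
    bvtv_clean[labels_coarse.data != LABEL_BONE] = 0.0
    bvtv_coarse = BVTVVolume(data=bvtv_clean, spacing=bvtv_coarse.spacing,
                             origin=bvtv_coarse.origin,
                             cell_fraction=bvtv_coarse.cell_fraction)

    truth = PhantomTruth(
        bone=bone_vol,
        cap_mask=caps,
        body_mask=body,
        labels_coarse=labels_coarse,
        body_labels_coarse=body_labels,
        bvtv_coarse=bvtv_coarse,
        height_mm=spec.body_height,
        area_mm2=float(np.pi * ax * ay),
    )
    return volume, truth


def synthesize_load_displacement(stiffness_kN_per_mm: float, toe_mm: float = 0.15,
                                 max_disp_mm: float = 1.2, n: int = 241
                                 ) -> np.ndarray:
    """Synthetic load-displacement curve: a quadratic toe region blending
    into a linear branch of slope ``stiffness``.  Returns (n, 2) columns
    (displacement mm, load kN)."""
    u = np.linspace(0.0, max_disp_mm, n)
    S = stiffness_kN_per_mm
    load = np.where(u < toe_mm, S * u ** 2 / (2 * toe_mm),
                    S * (u - toe_mm / 2))
    return np.stack([u, load], axis=1)


def stiffness_from_curve(curve: np.ndarray, interval_mm: float = 0.6) -> float:
    """Stiffness as the load-displacement gradient over a sliding window of
    the given length (mm); the steepest window is taken as the linear region."""
    u, f = np.asarray(curve).T
    du = u[1] - u[0]
    w = max(2, int(round(interval_mm / du)) + 1)
    best = -np.inf
    for i in range(len(u) - w + 1):
        slope = np.polyfit(u[i:i + w], f[i:i + w], 1)[0]
        best = max(best, slope)
    return float(best)


def pseudo_experiment(truth: PhantomTruth, params: MaterialParams,
                      noise_cv: float = 0.0, seed: int = 0,
                      specimen_id: str = "phantom", species: str = "synthetic",
                      with_curve: bool = False, stiffness_true: float | None = None):
    """Measured stiffness for a phantom: forward FE prediction at the given
    (true) material parameters, times multiplicative lognormal noise of the
    given coefficient of variation.

    ``stiffness_true`` short-circuits the forward solve when the caller has
    already computed it (e.g. noise replicates over one phantom).

    Returns ``(SpecimenRecord, stiffness_true)`` or, with ``with_curve``,
    ``(SpecimenRecord, stiffness_true, curve)``.
    """
    if noise_cv < 0:
        raise ValueError("noise CV must be >= 0")
    if stiffness_true is None:
        spec_model = SpecimenModel(
            id=specimen_id, bvtv=truth.bvtv_coarse, labels=truth.labels_coarse,
            measured_stiffness=1.0, height_mm=truth.height_mm,
            area_mm2=truth.area_mm2,
        )
        s_true, _ = predict_stiffness(spec_model, params)
    else:
        s_true = float(stiffness_true)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log(1.0 + noise_cv ** 2))
        noise = np.exp(rng.normal(-sigma ** 2 / 2, sigma))
    else:
        noise = 1.0
    s_meas = s_true * noise
    rec = SpecimenRecord(id=specimen_id, species=species,
                         stiffness_kN_per_mm=s_meas,
                         height_mm=truth.height_mm, area_mm2=truth.area_mm2)
    truth.k_true = params.k
    if with_curve:
        return rec, s_true, synthesize_load_displacement(s_meas)
    return rec, s_true
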