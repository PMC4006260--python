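"""Virtual anterior-to-posterior loading sweep.

Protocol: the upper cement end-cap is first adjusted to 40% of the vertebral
body height so the loading point sits at the same relative distance from the
vertebra in every model; the axial point load is then applied at five
positions equally spaced between the anterior and posterior extents of the
vertebral body (centrum), and each model is solved for stiffness (load over
displacement at the load point) and apparent modulus.  Posterior positions
engage the neural arch, so stiffness rises from anterior to posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bvtv_map import LABEL_BONE, LABEL_CEMENT, LABEL_VOID, BVTVVolume, RegionLabelVolume
from .material_map import MaterialParams, assign_materials
from .voxfem import apply_rigid_plate_load, build_model, solve, stiffness_from_solution

__all__ = ["SweepResult", "configure_endcap", "load_positions", "position_sweep"]


@dataclass
class SweepResult:
    """Five-position sweep output.  ``change_pct`` is relative to the most
    anterior position (index 0)."""

    positions_mm: np.ndarray          # (5, 2) x, y of each load point
    stiffness_kN_per_mm: np.ndarray   # (5,)
    apparent_modulus_MPa: np.ndarray  # (5,)
    change_pct: np.ndarray            # (5,), 100 * (S_i - S_1) / S_1
    modulus_change_pct: np.ndarray    # (5,), same metric on apparent modulus
    specimen_id: str = ""

    def __post_init__(self):
        if len(self.stiffness_kN_per_mm) != 5:
            raise ValueError("a sweep has exactly 5 positions")


def configure_endcap(bvtv: BVTVVolume, labels: RegionLabelVolume,
                     body_height_mm: float) -> tuple[BVTVVolume, RegionLabelVolume, int]:
    """Rebuild the upper cement end-cap at 40% of the body height.

    The cap thickness is 0.40 * height rounded to the nearest whole element
    layer (at least 1); existing cement above the bone is replaced by a slab
    of that thickness over the upper cap's footprint (or, absent an upper
    cap, the specimen footprint).  Returns the adjusted fields and the layer
    count; the z extent of the grid grows or shrinks as needed.
    """
    if not body_height_mm > 0:
        raise ValueError("body height must be > 0")
    dz = float(labels.spacing[2])
    n_layers = int(round(0.4 * body_height_mm / dz))
    if n_layers < 1:
        raise ValueError(
            f"40% of height {body_height_mm} mm is below one {dz} mm element layer"
        )
    lab = labels.data
    bone_z = np.nonzero((lab == LABEL_BONE).any(axis=(0, 1)))[0]
    if bone_z.size == 0:
        raise ValueError("no bone in the label volume")
    top = int(bone_z[-1])
    upper_cem = lab == LABEL_CEMENT
    upper_cem[:, :, : top + 1] = False
    if upper_cem.any():
        footprint = upper_cem.any(axis=2)
    else:
        footprint = (lab != LABEL_VOID).any(axis=2)

    nz_new = top + 1 + n_layers
    nx, ny = lab.shape[:2]
    new_lab = np.full((nx, ny, nz_new), LABEL_VOID, dtype=np.uint8)
    new_bvtv = np.zeros((nx, ny, nz_new))
    nz_keep = min(top + 1, lab.shape[2])
    new_lab[:, :, :nz_keep] = lab[:, :, :nz_keep]
    new_bvtv[:, :, :nz_keep] = bvtv.data[:, :, :nz_keep]
    new_lab[:, :, top + 1:][footprint] = LABEL_CEMENT
    out_labels = RegionLabelVolume(data=new_lab, spacing=labels.spacing.copy(),
                                   origin=labels.origin.copy())
    out_bvtv = BVTVVolume(data=new_bvtv, spacing=bvtv.spacing.copy(),
                          origin=bvtv.origin.copy())
    return out_bvtv, out_labels, n_layers


def load_positions(body_mask, spacing=None, origin=None, n: int = 5) -> np.ndarray:
    """Equally spaced load points along the A-P axis of the vertebral body.

    ``body_mask`` is a RegionLabelVolume (its bone label is taken as the
    body/centrum) or a boolean array with explicit ``spacing``/``origin``.
    Returns an (n, 2) array of (x, y) in mm: all points share the body's
    mid-lateral x; y runs from the anterior to the posterior voxel-centre
    extent of the body inclusive.
    """
    if isinstance(body_mask, RegionLabelVolume):
        mask = body_mask.data == LABEL_BONE
        spacing, origin = body_mask.spacing, body_mask.origin
    else:
        mask = np.asarray(body_mask, dtype=bool)
        if spacing is None or origin is None:
            raise ValueError("boolean masks need explicit spacing and origin")
        spacing, origin = np.asarray(spacing, float), np.asarray(origin, float)
    if not mask.any():
        raise ValueError("empty body mask")
    xs = np.nonzero(mask.any(axis=(1, 2)))[0]
    ys = np.nonzero(mask.any(axis=(0, 2)))[0]
    if ys[0] == ys[-1]:
        raise ValueError("degenerate anterior-posterior extent")
    centre = lambda ax, i: origin[ax] + (i + 0.5) * spacing[ax]
    x_mid = 0.5 * (centre(0, xs[0]) + centre(0, xs[-1]))
    y_ant, y_post = centre(1, ys[0]), centre(1, ys[-1])
    frac = np.arange(n) / (n - 1)
    return np.stack([np.full(n, x_mid), y_ant + frac * (y_post - y_ant)], axis=1)


def position_sweep(bvtv: BVTVVolume, labels: RegionLabelVolume,
                   params: MaterialParams, positions: np.ndarray,
                   height_mm: float, area_mm2: float,
                   specimen_id: str = "", solver_tol: float = 1e-8) -> SweepResult:
    """One FE solve per load position; stiffness, apparent modulus and the
    percentage change relative to the most anterior position."""
    positions = np.asarray(positions, dtype=float)
    materials = assign_materials(bvtv, labels, params)
    model = build_model(materials)
    stiff = np.empty(len(positions))
    app = np.empty(len(positions))
    warm = None
    for i, pos in enumerate(positions):
        m = apply_rigid_plate_load(model, pos)
        try:
            sol = solve(m, tol=solver_tol, x0=warm)
        except Exception as exc:
            raise RuntimeError(f"solve failed at position {i} ({pos}): {exc}") from exc
        warm = sol._reduced
        res = stiffness_from_solution(m, sol, height_mm, area_mm2,
                                      model_id=specimen_id)
        stiff[i] = res.stiffness_kN_per_mm
        app[i] = res.apparent_modulus_MPa
    change = 100.0 * (stiff - stiff[0]) / stiff[0]
    mchange = 100.0 * (app - app[0]) / app[0]
    return SweepResult(positions_mm=positions, stiffness_kN_per_mm=stiff,
                       apparent_modulus_MPa=app, change_pct=change,
                       modulus_change_pct=mchange, specimen_id=specimen_id)
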