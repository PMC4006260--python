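"""BV/TV to elastic-modulus conversion and per-element material assignment.

Bone elements follow a power law in bone volume fraction,

    E = k * (BV/TV)^p,     p in {1, 2},

with the conversion factor ``k`` (GPa) calibrated against measured stiffness.
Cement (PMMA) elements take a fixed modulus (2.45 GPa by default); void
elements take modulus 0 and are dropped at meshing.  A single Poisson's
ratio is applied to all materials (0.3 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bvtv_map import LABEL_BONE, LABEL_CEMENT, BVTVVolume, RegionLabelVolume

__all__ = ["MaterialParams", "MaterialField", "modulus_from_bvtv", "assign_materials"]


@dataclass(frozen=True)
class MaterialParams:
    """Conversion-law parameters.

    k : conversion factor, GPa (modulus of fully dense bone, BV/TV = 1)
    exponent : power p of the law, 1 (linear) or 2 (square)
    E_cement : PMMA modulus, GPa
    nu : Poisson's ratio applied to every material
    E_floor : minimum modulus retained for meshed bone elements, GPa
        (guards against singular systems from near-zero-modulus elements)
    """

    k: float
    exponent: int = 1
    E_cement: float = 2.45
    nu: float = 0.3
    E_floor: float | None = None

    def __post_init__(self):
        if not self.k > 0:
            raise ValueError(f"k must be > 0 GPa, got {self.k}")
        if self.exponent not in (1, 2):
            raise ValueError(f"exponent must be 1 or 2, got {self.exponent}")
        if not self.E_cement > 0:
            raise ValueError("E_cement must be > 0")
        if not (0 <= self.nu < 0.5):
            raise ValueError(f"need 0 <= nu < 0.5, got {self.nu}")
        if self.E_floor is None:
            object.__setattr__(self, "E_floor", self.k * 1e-6)
        if not (0 <= self.E_floor < self.k):
            raise ValueError("need 0 <= E_floor < k")

    def with_k(self, k: float) -> "MaterialParams":
        """Same law at a different conversion factor (floor rescales with k)."""
        return replace(self, k=k, E_floor=self.E_floor * (k / self.k))


@dataclass
class MaterialField:
    """Per-element modulus (GPa) and Poisson's ratio on the coarse grid,
    with the region labels carried along."""

    modulus: np.ndarray
    nu: np.ndarray
    labels: RegionLabelVolume
    params: MaterialParams

    def __post_init__(self):
        self.modulus = np.asarray(self.modulus, dtype=np.float64)
        self.nu = np.asarray(self.nu, dtype=np.float64)
        if self.modulus.shape != self.labels.data.shape or self.nu.shape != self.modulus.shape:
            raise ValueError("modulus, nu and labels must share one grid")
        if np.any(self.modulus < 0):
            raise ValueError("modulus must be >= 0 everywhere")

    @property
    def spacing(self):
        return self.labels.spacing

    @property
    def origin(self):
        return self.labels.origin


def modulus_from_bvtv(bvtv, params: MaterialParams, floor: bool = True):
    """E = k * bvtv^p (GPa), optionally floored at ``params.E_floor``.

    Accepts scalars or arrays; ``bvtv`` must lie in [0, 1].
    """
    b = np.asarray(bvtv, dtype=float)
    if np.any(b < 0) or np.any(b > 1):
        raise ValueError("BV/TV values must lie in [0, 1]")
    E = params.k * b ** params.exponent
    if floor:
        E = np.maximum(E, params.E_floor)
    return float(E) if np.isscalar(bvtv) else E


def assign_materials(bvtv: BVTVVolume, labels: RegionLabelVolume,
                     params: MaterialParams) -> MaterialField:
    """Element-wise material assignment.

    Bone elements get ``modulus_from_bvtv`` (floored); cement elements get
    ``E_cement``; void elements get 0 and are dropped by model building.
    """
    if bvtv.data.shape != labels.data.shape:
        raise ValueError(
            f"BV/TV grid {bvtv.data.shape} and label grid {labels.data.shape} differ"
        )
    E = np.zeros(bvtv.data.shape, dtype=np.float64)
    bone = labels.data == LABEL_BONE
    E[bone] = modulus_from_bvtv(bvtv.data[bone], params)
    E[labels.data == LABEL_CEMENT] = params.E_cement
    nu = np.full(bvtv.data.shape, params.nu, dtype=np.float64)
    return MaterialField(modulus=E, nu=nu, labels=labels, params=params)
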