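"""Volume and table I/O, spacing metadata, and FE mesh export.

Volumes are 3D scalar images with per-axis voxel spacing in millimetres.
The axis convention used throughout the package is

    axis 0 = x (lateral), axis 1 = y (anterior -> posterior), axis 2 = z (axial,
    inferior -> superior),

so ``data[i, j, k]`` is the voxel at lateral index ``i``, A-P index ``j`` and
axial index ``k``.  Physical voxel-centre positions are
``origin + (index + 0.5) * spacing`` (0-based indices).

Supported on-disk formats: MetaImage (MHD/RAW, via SimpleITK) and TIFF stacks
(multi-page, via tifffile).  Specimen tables are plain CSV.  FE meshes export
to Abaqus INP (C3D8) and legacy-ASCII VTK with cell-data moduli.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

__all__ = [
    "GreyscaleVolume",
    "BinaryVolume",
    "SpecimenRecord",
    "read_volume",
    "write_volume",
    "read_specimen_table",
    "write_specimen_table",
    "export_fe_mesh",
]


def _validate_grid(data: np.ndarray, spacing, origin) -> tuple[np.ndarray, np.ndarray]:
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"volume data must be 3D, got ndim={data.ndim}")
    if any(s < 2 for s in data.shape):
        raise ValueError(f"volume must have shape >= 2 on each axis, got {data.shape}")
    if spacing.shape != (3,) or not np.all(np.isfinite(spacing)) or np.any(spacing <= 0):
        raise ValueError(f"spacing must be 3 positive finite values in mm, got {spacing}")
    if origin.shape != (3,) or not np.all(np.isfinite(origin)):
        raise ValueError(f"origin must be 3 finite values in mm, got {origin}")
    if not np.all(np.isfinite(data)):
        raise ValueError("volume data contains non-finite values")
    return spacing, origin


@dataclass
class GreyscaleVolume:
    """3D greyscale image with voxel spacing (mm).  Intensities are arbitrary
    scanner units, stored as float64 internally."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing, self.origin = _validate_grid(self.data, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def voxel_centres(self, axis: int) -> np.ndarray:
        """Physical centre coordinates (mm) of voxels along one axis."""
        n = self.data.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]


@dataclass
class BinaryVolume:
    """3D binary (0/1) segmentation on the same grid conventions."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        data = np.asarray(self.data)
        vals = np.unique(data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("binary volume must contain only values {0, 1}")
        self.data = data.astype(np.uint8)
        self.spacing, self.origin = _validate_grid(self.data, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class SpecimenRecord:
    """One physically tested specimen: measured stiffness plus morphometrics."""

    id: str
    species: str
    stiffness_kN_per_mm: float
    height_mm: float
    area_mm2: float

    def __post_init__(self):
        if not self.stiffness_kN_per_mm > 0:
            raise ValueError(f"stiffness must be > 0, got {self.stiffness_kN_per_mm}")
        if not self.height_mm > 0:
            raise ValueError(f"height must be > 0, got {self.height_mm}")
        if not self.area_mm2 > 0:
            raise ValueError(f"area must be > 0, got {self.area_mm2}")


_SPECIMEN_COLUMNS = ["id", "species", "stiffness_kN_per_mm", "height_mm", "area_mm2"]


def read_specimen_table(path) -> list[SpecimenRecord]:
    df = pd.read_csv(path)
    missing = set(_SPECIMEN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"specimen CSV {path} missing columns: {sorted(missing)}")
    return [
        SpecimenRecord(
            id=str(r.id),
            species=str(r.species),
            stiffness_kN_per_mm=float(r.stiffness_kN_per_mm),
            height_mm=float(r.height_mm),
            area_mm2=float(r.area_mm2),
        )
        for r in df.itertuples()
    ]


def write_specimen_table(records, path) -> None:
    pd.DataFrame(
        [
            {
                "id": r.id,
                "species": r.species,
                "stiffness_kN_per_mm": r.stiffness_kN_per_mm,
                "height_mm": r.height_mm,
                "area_mm2": r.area_mm2,
            }
            for r in records
        ],
        columns=_SPECIMEN_COLUMNS,
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Volume I/O.
#
# SimpleITK images index as (x, y, z) through GetPixel but convert to numpy as
# (z, y, x); we transpose so the in-memory layout matches the package's
# (x, y, z) convention.
# ---------------------------------------------------------------------------


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".mhd":
        return "mhd"
    if ext in (".tif", ".tiff"):
        return "tiff_stack"
    raise ValueError(f"cannot infer volume format from extension {ext!r}; pass format=")


def read_volume(path, format: str | None = None, spacing=None, origin=None,
                binary: bool = False):
    """Read a 3D volume from MHD/RAW or a multi-page TIFF stack.

    Parameters
    ----------
    path : str or Path
    format : {"mhd", "tiff_stack"}, optional
        Inferred from the extension when omitted.
    spacing : length-3 sequence of float, optional
        Voxel spacing in mm.  Required for TIFF stacks (the format carries no
        reliable 3D spacing); if given for MHD it overrides the header.
    origin : length-3 sequence of float, optional
    binary : bool
        Return a :class:`BinaryVolume` (data must be 0/1).

    Raises
    ------
    ValueError
        If spacing is unavailable: spacing is never silently assumed.
    """
    fmt = _infer_format(path, format)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "mhd":
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        if spacing is None:
            # SimpleITK silently defaults absent spacing to 1 mm; reject that
            with open(path) as f:
                header_keys = {line.split("=")[0].strip() for line in f
                               if "=" in line}
            if "ElementSpacing" not in header_keys and \
                    "ElementSize" not in header_keys:
                raise ValueError(
                    f"{path} has no ElementSpacing in its header; pass spacing= "
                    "explicitly (voxel size is never assumed)"
                )
            spacing = img.GetSpacing()
        if origin is None:
            origin = img.GetOrigin()
    elif fmt == "tiff_stack":
        # pages are axial (z) slices of shape (ny, nx) -> (x, y, z)
        arr = tifffile.imread(str(path))
        if arr.ndim != 3:
            raise ValueError(f"TIFF stack must hold >= 2 slices, got ndim={arr.ndim}")
        data = arr.transpose(2, 1, 0)
        if spacing is None:
            raise ValueError(
                "TIFF stacks carry no trusted 3D voxel spacing; pass spacing= in mm"
            )
        if origin is None:
            origin = (0.0, 0.0, 0.0)
    else:
        raise ValueError(f"unknown volume format {fmt!r}")
    cls = BinaryVolume if binary else GreyscaleVolume
    return cls(data=np.asarray(data), spacing=np.asarray(spacing, float),
               origin=np.asarray(origin, float))


def write_volume(volume, path, format: str | None = None, dtype=None) -> None:
    """Write a volume to MHD/RAW or a multi-page TIFF stack.

    Binary volumes are written as uint8; greyscale as float32 unless ``dtype``
    is given.  Round-trips are bit-exact for integer data.
    """
    fmt = _infer_format(path, format)
    ext = os.path.splitext(str(path))[1].lower()
    if fmt == "mhd" and ext != ".mhd":
        raise ValueError(f"format 'mhd' requires a .mhd path, got {path}")
    if fmt == "tiff_stack" and ext not in (".tif", ".tiff"):
        raise ValueError(f"format 'tiff_stack' requires a .tif/.tiff path, got {path}")
    if dtype is None:
        dtype = np.uint8 if isinstance(volume, BinaryVolume) else np.float32
    data = volume.data.astype(dtype)
    if fmt == "mhd":
        img = sitk.GetImageFromArray(data.transpose(2, 1, 0))
        img.SetSpacing(tuple(float(s) for s in volume.spacing))
        img.SetOrigin(tuple(float(o) for o in volume.origin))
        sitk.WriteImage(img, str(path))
    elif fmt == "tiff_stack":
        tifffile.imwrite(str(path), data.transpose(2, 1, 0),
                         photometric="minisblack")
    else:
        raise ValueError(f"unknown volume format {fmt!r}")


# ---------------------------------------------------------------------------
# FE mesh export
# ---------------------------------------------------------------------------


def export_fe_mesh(model, path, format: str | None = None) -> None:
    """Export a voxel-hexahedral FE model to Abaqus INP or legacy-ASCII VTK.

    Node coordinates are written in mm; per-element modulus is preserved
    (INP: one *SOLID SECTION/*ELASTIC block per distinct modulus; VTK: a
    ``modulus_GPa`` cell-data array).
    """
    if model.n_elements == 0:
        raise ValueError("cannot export an empty FE model")
    if format is None:
        ext = os.path.splitext(str(path))[1].lower()
        format = {"inp": "inp", ".inp": "inp", ".vtk": "vtk"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer mesh format from {path}")
    if format == "inp":
        _write_inp(model, path)
    elif format == "vtk":
        _write_vtk(model, path)
    else:
        raise ValueError(f"unknown mesh format {format!r}")


def _write_inp(model, path) -> None:
    coords = model.node_coords
    conn = model.connectivity
    E = model.element_modulus
    nu = model.element_nu
    with open(path, "w") as f:
        f.write("*HEADING\nvertemech voxel hexahedral mesh\n")
        f.write("*NODE\n")
        for i, (x, y, z) in enumerate(coords, start=1):
            f.write(f"{i}, {x:.9g}, {y:.9g}, {z:.9g}\n")
        f.write("*ELEMENT, TYPE=C3D8\n")
        for e, nodes in enumerate(conn, start=1):
            f.write(f"{e}, " + ", ".join(str(n + 1) for n in nodes) + "\n")
        # group elements by (E, nu) so the modulus round-trips exactly
        keys = {}
        for e, (Ee, nue) in enumerate(zip(E, nu), start=1):
            keys.setdefault((float(Ee), float(nue)), []).append(e)
        for m, ((Ee, nue), elems) in enumerate(sorted(keys.items()), start=1):
            f.write(f"*ELSET, ELSET=MAT{m}\n")
            for i in range(0, len(elems), 8):
                f.write(", ".join(str(e) for e in elems[i:i + 8]) + "\n")
            f.write(f"*SOLID SECTION, ELSET=MAT{m}, MATERIAL=MAT{m}\n")
        for m, ((Ee, nue), _) in enumerate(sorted(keys.items()), start=1):
            f.write(f"*MATERIAL, NAME=MAT{m}\n*ELASTIC\n{Ee:.9g}, {nue:.9g}\n")


def _write_vtk(model, path) -> None:
    coords = model.node_coords
    conn = model.connectivity
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("vertemech voxel hexahedral mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(coords)} double\n")
        for x, y, z in coords:
            f.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
        n_el = len(conn)
        f.write(f"CELLS {n_el} {n_el * 9}\n")
        for nodes in conn:
            f.write("8 " + " ".join(str(n) for n in nodes) + "\n")
        f.write(f"CELL_TYPES {n_el}\n")
        f.write("\n".join(["12"] * n_el) + "\n")  # VTK_HEXAHEDRON
        f.write(f"CELL_DATA {n_el}\nSCALARS modulus_GPa double 1\nLOOKUP_TABLE default\n")
        for Ee in model.element_modulus:
            f.write(f"{Ee:.12g}\n")
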