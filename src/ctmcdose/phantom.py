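"""Voxel phantoms: HU calibration to density/composition, fixtures, couch merge.

The Hounsfield scale is split into contiguous integer ranges, each carrying
elemental weight fractions; mass density follows a separate piecewise-linear
curve anchored at air (-1000) and water (0).  Both calibrations are packaged
as CSV and user-overridable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from . import dicomio
from .spectrum import ConfigurationError

__all__ = [
    "DensityCalibration",
    "CompositionTable",
    "VoxelPhantom",
    "GeometryError",
    "hu_to_density",
    "hu_to_composition",
    "voxelize_dicom",
    "merge_couch",
    "make_fixture",
    "save_phantom",
    "load_phantom",
]

logger = logging.getLogger(__name__)

HU_MIN, HU_MAX = -1500, 2000

# HU value that maps to PMMA density (1.19 g/cm3) through the default
# density calibration; used by the CTDI fixture.
PMMA_EQUIVALENT_HU = 290

ELEMENTS = (
    "hydrogen",
    "oxygen",
    "carbon",
    "nitrogen",
    "chlorine",
    "calcium",
    "phosphorus",
    "magnesium",
)


class GeometryError(ValueError):
    pass


def _round_half_away(hu) -> np.ndarray:
    """Round half away from zero (np.rint rounds half to even)."""
    hu = np.asarray(hu, dtype=float)
    return (np.sign(hu) * np.floor(np.abs(hu) + 0.5)).astype(np.int32)


@dataclass
class DensityCalibration:
    """Piecewise-linear HU -> mass density (g/cm^3) curve."""

    hu_nodes: np.ndarray
    density_nodes: np.ndarray

    def __post_init__(self):
        self.hu_nodes = np.asarray(self.hu_nodes, dtype=float)
        self.density_nodes = np.asarray(self.density_nodes, dtype=float)
        if self.hu_nodes.size != self.density_nodes.size or self.hu_nodes.size < 2:
            raise ConfigurationError("need >= 2 calibration nodes of equal length")
        if np.any(np.diff(self.hu_nodes) <= 0):
            raise ConfigurationError("HU nodes must be strictly increasing")
        if np.any(self.density_nodes < 0):
            raise ConfigurationError("densities must be non-negative")

    def __call__(self, hu) -> np.ndarray:
        hu = np.clip(np.asarray(hu, dtype=float), HU_MIN, HU_MAX)
        return np.interp(hu, self.hu_nodes, self.density_nodes)

    @classmethod
    def from_csv(cls, path) -> "DensityCalibration":
        rows = np.loadtxt(path, delimiter=",", skiprows=2, ndmin=2)
        return cls(rows[:, 0], rows[:, 1])

    @classmethod
    def load_default(cls) -> "DensityCalibration":
        with resources.as_file(
            resources.files("ctmcdose").joinpath("data/hu_density.csv")
        ) as path:
            return cls.from_csv(path)


@dataclass
class CompositionTable:
    """Inclusive HU ranges mapping to elemental weight fractions."""

    hu_min: np.ndarray
    hu_max: np.ndarray
    fractions: np.ndarray  # (n_rows, len(ELEMENTS))
    elements: tuple = ELEMENTS

    def __post_init__(self):
        self.hu_min = np.asarray(self.hu_min, dtype=int)
        self.hu_max = np.asarray(self.hu_max, dtype=int)
        self.fractions = np.asarray(self.fractions, dtype=float)
        n = self.hu_min.size
        if self.hu_max.size != n or self.fractions.shape != (n, len(self.elements)):
            raise ConfigurationError("composition table shape mismatch")
        if np.any(self.fractions < 0):
            raise ConfigurationError("weight fractions must be non-negative")
        sums = self.fractions.sum(axis=1)
        # published calibration rows round as low as 0.988, so the window is
        # wider than the nominal +-0.005
        bad = (sums < 0.985 - 1e-9) | (sums > 1.005 + 1e-9)
        if bad.any():
            raise ConfigurationError(
                f"composition row sums outside [0.985, 1.005]: rows {np.where(bad)[0]}"
            )
        if np.any(self.hu_max < self.hu_min):
            raise ConfigurationError("row hu_max < hu_min")
        if np.any(self.hu_min[1:] != self.hu_max[:-1] + 1):
            raise ConfigurationError("composition HU ranges must be contiguous and ordered")
        if self.hu_min[0] != HU_MIN or self.hu_max[-1] != HU_MAX:
            raise ConfigurationError(f"table must cover [{HU_MIN}, {HU_MAX}]")

    @property
    def n_rows(self) -> int:
        return self.hu_min.size

    def row_index(self, hu) -> np.ndarray:
        """Row lookup with clamping and half-away-from-zero rounding."""
        hu_int = np.clip(_round_half_away(hu), HU_MIN, HU_MAX)
        idx = np.searchsorted(self.hu_min, hu_int, side="right") - 1
        return idx.astype(np.int16)

    def row_fractions(self, hu):
        return self.fractions[self.row_index(hu)]

    @classmethod
    def from_csv(cls, path) -> "CompositionTable":
        with open(path) as fh:
            header = fh.readline().strip().split(",")
        cols = [h.strip().lower() for h in header[2:]]
        rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        order = [cols.index(e) for e in ELEMENTS]
        return cls(rows[:, 0], rows[:, 1], rows[:, 2:][:, order])

    @classmethod
    def load_default(cls) -> "CompositionTable":
        with resources.as_file(
            resources.files("ctmcdose").joinpath("data/hu_composition.csv")
        ) as path:
            return cls.from_csv(path)


def hu_to_density(hu, calibration: Optional[DensityCalibration] = None):
    """Piecewise-linear HU -> g/cm^3; out-of-range HU are clamped."""
    cal = calibration or DensityCalibration.load_default()
    return cal(hu)


def hu_to_composition(hu, table: Optional[CompositionTable] = None) -> dict:
    """Weight fractions (element -> fraction) for a single HU value."""
    tab = table or CompositionTable.load_default()
    fr = tab.fractions[int(tab.row_index(hu))]
    return {e: float(f) for e, f in zip(tab.elements, fr) if f > 0}


@dataclass
class VoxelPhantom:
    """Rectilinear HU grid with derived density and material-row indices.

    Arrays are indexed ``[ix, iy, iz]``; ``origin_mm`` is the world position
    of voxel (0, 0, 0)'s center; the grid extent is half-open
    ``[origin - spacing/2, origin + (dims - 1/2) * spacing)``.
    """

    hu: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    density: np.ndarray = field(default=None, repr=False)
    material_index: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.hu = np.asarray(self.hu)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.hu.ndim != 3:
            raise GeometryError("hu grid must be 3-D")
        if self.spacing_mm.shape != (3,) or np.any(self.spacing_mm <= 0):
            raise GeometryError("spacing must be 3 positive values")
        if self.density is not None and self.density.shape != self.hu.shape:
            raise GeometryError("density grid shape mismatch")
        if self.material_index is not None and self.material_index.shape != self.hu.shape:
            raise GeometryError("material grid shape mismatch")

    @property
    def dims(self) -> tuple:
        return self.hu.shape

    @property
    def grid_min_mm(self) -> np.ndarray:
        return self.origin_mm - self.spacing_mm / 2

    @property
    def grid_max_mm(self) -> np.ndarray:
        return self.grid_min_mm + np.array(self.dims) * self.spacing_mm

    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing_mm) / 1000.0)

    def voxel_centers(self, axis: int) -> np.ndarray:
        return self.origin_mm[axis] + np.arange(self.dims[axis]) * self.spacing_mm[axis]

    @classmethod
    def from_hu(
        cls,
        hu: np.ndarray,
        spacing_mm,
        origin_mm=(0.0, 0.0, 0.0),
        density_cal: Optional[DensityCalibration] = None,
        composition: Optional[CompositionTable] = None,
    ) -> "VoxelPhantom":
        hu = np.asarray(hu)
        clipped = int(np.sum((hu < HU_MIN) | (hu > HU_MAX)))
        if clipped:
            logger.warning("clamped %d voxels outside HU [%d, %d]", clipped, HU_MIN, HU_MAX)
        cal = density_cal or DensityCalibration.load_default()
        tab = composition or CompositionTable.load_default()
        hu = np.clip(hu, HU_MIN, HU_MAX).astype(np.int16)
        return cls(
            hu=hu,
            spacing_mm=spacing_mm,
            origin_mm=origin_mm,
            density=cal(hu).astype(np.float32),
            material_index=tab.row_index(hu),
        )


def voxelize_dicom(
    series_path,
    density_cal: Optional[DensityCalibration] = None,
    composition: Optional[CompositionTable] = None,
) -> VoxelPhantom:
    """Load a single-frame CT series into a calibrated voxel phantom."""
    slices = dicomio.read_series(series_path)
    first = slices[0]
    hu = np.stack([s.hu for s in slices], axis=-1)  # (rows=y, cols=x, z)
    hu = np.transpose(hu, (1, 0, 2))  # -> (x, y, z)
    hu = _round_half_away(hu)
    row_sp, col_sp = first.pixel_spacing_mm
    dz = (
        slices[1].position_mm[2] - slices[0].position_mm[2]
        if len(slices) > 1
        else first.slice_thickness_mm
    )
    spacing = (col_sp, row_sp, dz)
    return VoxelPhantom.from_hu(
        hu, spacing, first.position_mm, density_cal=density_cal, composition=composition
    )


def merge_couch(
    patient: VoxelPhantom,
    couch: VoxelPhantom,
    vertical_offset_mm: float = 0.0,
    air_threshold_hu: int = -950,
    density_cal: Optional[DensityCalibration] = None,
    composition: Optional[CompositionTable] = None,
) -> VoxelPhantom:
    """Superimpose a couch grid under a patient grid.

    Patient voxels keep their HU wherever they are above the air threshold;
    air voxels take the couch HU sampled (nearest neighbor) at the patient
    voxel center shifted down by ``vertical_offset_mm`` along +y.
    """
    maps = []
    in_bounds = []
    offset = np.array([0.0, vertical_offset_mm, 0.0])
    for ax in range(3):
        centers = patient.voxel_centers(ax) + offset[ax]
        idx = np.rint((centers - couch.origin_mm[ax]) / couch.spacing_mm[ax]).astype(int)
        ok = (idx >= 0) & (idx < couch.dims[ax])
        maps.append(np.clip(idx, 0, couch.dims[ax] - 1))
        in_bounds.append(ok)
    overlap = (
        in_bounds[0][:, None, None] & in_bounds[1][None, :, None] & in_bounds[2][None, None, :]
    )
    if not overlap.any():
        raise GeometryError("couch grid does not overlap the patient grid")
    couch_hu = couch.hu[np.ix_(maps[0], maps[1], maps[2])]
    merged = np.where(
        (patient.hu > air_threshold_hu) | ~overlap, patient.hu, couch_hu
    )
    return VoxelPhantom.from_hu(
        merged,
        patient.spacing_mm,
        patient.origin_mm,
        density_cal=density_cal,
        composition=composition,
    )


def _cylinder_mask(phantom_shape, spacing, origin, radius_mm, length_mm, axis=2):
    coords = [origin[a] + np.arange(phantom_shape[a]) * spacing[a] for a in range(3)]
    trans = [a for a in range(3) if a != axis]
    grids = []
    for a in trans:
        s = [1, 1, 1]
        s[a] = phantom_shape[a]
        grids.append(coords[a].reshape(s))
    radial2 = grids[0] ** 2 + grids[1] ** 2
    s = [1, 1, 1]
    s[axis] = phantom_shape[axis]
    axial = np.abs(coords[axis].reshape(s))
    return (radial2 <= radius_mm**2) & (axial <= length_mm / 2)


def make_fixture(name: str, **params) -> VoxelPhantom:
    """Generate a named test phantom as an HU grid run through the calibration.

    Names: ``ctdi_body``, ``air_chamber``, ``water_cylinder``, ``couch``,
    ``block_phantom``.
    """
    density_cal = params.pop("density_cal", None)
    composition = params.pop("composition", None)

    def build(hu, spacing, origin):
        return VoxelPhantom.from_hu(
            hu, spacing, origin, density_cal=density_cal, composition=composition
        )

    if name == "ctdi_body":
        voxel = params.pop("voxel_mm", 2.0)
        diameter = params.pop("diameter_mm", 320.0)
        length = params.pop("length_mm", 150.0)
        hole_d = params.pop("hole_diameter_mm", 13.0)
        pad = params.pop("pad_mm", 20.0)
        _reject_extras(name, params)
        ext_xy = diameter + 2 * pad
        dims = (
            int(round(ext_xy / voxel)),
            int(round(ext_xy / voxel)),
            int(round(length / voxel)),
        )
        spacing = np.array([voxel] * 3)
        origin = -(np.array(dims) - 1) * spacing / 2
        hu = np.full(dims, -1000, dtype=np.int16)
        body = _cylinder_mask(dims, spacing, origin, diameter / 2, length)
        hu[body] = PMMA_EQUIVALENT_HU
        hole = _cylinder_mask(dims, spacing, origin, hole_d / 2, length)
        hu[hole] = -1000
        return build(hu, spacing, origin)

    if name == "air_chamber":
        voxel = params.pop("voxel_mm", 4.0)
        extent = params.pop("extent_mm", (120.0, 120.0, 200.0))
        _reject_extras(name, params)
        dims = tuple(int(round(e / voxel)) for e in extent)
        spacing = np.array([voxel] * 3)
        origin = -(np.array(dims) - 1) * spacing / 2
        hu = np.full(dims, -1000, dtype=np.int16)
        return build(hu, spacing, origin)

    if name == "water_cylinder":
        voxel = params.pop("voxel_mm", 2.0)
        diameter = params.pop("diameter_mm", 200.0)
        length = params.pop("length_mm", 150.0)
        pad = params.pop("pad_mm", 20.0)
        _reject_extras(name, params)
        ext_xy = diameter + 2 * pad
        dims = (
            int(round(ext_xy / voxel)),
            int(round(ext_xy / voxel)),
            int(round(length / voxel)),
        )
        spacing = np.array([voxel] * 3)
        origin = -(np.array(dims) - 1) * spacing / 2
        hu = np.full(dims, -1000, dtype=np.int16)
        hu[_cylinder_mask(dims, spacing, origin, diameter / 2, length)] = 0
        return build(hu, spacing, origin)

    if name == "couch":
        voxel = params.pop("voxel_mm", 4.0)
        width = params.pop("width_mm", 480.0)
        thickness = params.pop("thickness_mm", 80.0)
        length = params.pop("length_mm", 300.0)
        shell = params.pop("shell_mm", 8.0)
        shell_hu = params.pop("shell_hu", -80)
        foam_hu = params.pop("foam_hu", -900)
        _reject_extras(name, params)
        dims = (
            int(round(width / voxel)),
            int(round(thickness / voxel)),
            int(round(length / voxel)),
        )
        spacing = np.array([voxel] * 3)
        origin = -(np.array(dims) - 1) * spacing / 2
        hu = np.full(dims, foam_hu, dtype=np.int16)
        n_shell = max(1, int(round(shell / voxel)))
        hu[:n_shell, :, :] = shell_hu
        hu[-n_shell:, :, :] = shell_hu
        hu[:, :n_shell, :] = shell_hu
        hu[:, -n_shell:, :] = shell_hu
        return build(hu, spacing, origin)

    if name == "block_phantom":
        voxel = params.pop("voxel_mm", 4.0)
        extent = params.pop("extent_mm", (200.0, 120.0, 160.0))
        _reject_extras(name, params)
        dims = tuple(int(round(e / voxel)) for e in extent)
        spacing = np.array([voxel] * 3)
        origin = -(np.array(dims) - 1) * spacing / 2
        hu = np.full(dims, -1000, dtype=np.int16)
        # layered slabs along y: lung / soft tissue / bone
        ny = dims[1]
        hu[:, : ny // 3, :] = -700
        hu[:, ny // 3 : 2 * ny // 3, :] = 0
        hu[:, 2 * ny // 3 :, :] = 800
        return build(hu, spacing, origin)

    raise ConfigurationError(f"unknown fixture name {name!r}")


def _reject_extras(name, params):
    if params:
        raise ConfigurationError(f"unknown parameters for fixture {name!r}: {sorted(params)}")


def save_phantom(phantom: VoxelPhantom, directory) -> None:
    """Serialize as a binary HU grid plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "hu.npy", phantom.hu)
    meta = {
        "dims": list(phantom.dims),
        "spacing_mm": phantom.spacing_mm.tolist(),
        "origin_mm": phantom.origin_mm.tolist(),
        "hu_dtype": str(phantom.hu.dtype),
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_phantom(
    directory,
    density_cal: Optional[DensityCalibration] = None,
    composition: Optional[CompositionTable] = None,
) -> VoxelPhantom:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    hu = np.load(directory / "hu.npy")
    if list(hu.shape) != meta["dims"]:
        raise GeometryError("sidecar dims disagree with the stored grid")
    return VoxelPhantom.from_hu(
        hu,
        meta["spacing_mm"],
        meta["origin_mm"],
        density_cal=density_cal,
        composition=composition,
    )
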