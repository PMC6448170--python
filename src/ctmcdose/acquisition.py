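"""Tube trajectory and photon emission for axial, helical and TCM scans.

The phantom stays fixed; helical table motion is modeled by translating the
tube along z.  The tube angle advances deterministically with z (one full
rotation per pitch x collimation of travel), and all emission sampling is
vectorized over photons drawn from one seeded generator per batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .scanner_model import ScannerModel, sample_bowtie_exit, sample_heel_z
from .spectrum import ConfigurationError

__all__ = [
    "ScanProtocol",
    "TCMTable",
    "TubeState",
    "SourcePhotonBatch",
    "table_travel",
    "build_tcm_pdf",
    "sample_tube_state",
    "emit_photons",
    "batch_rng",
]

TWO_PI = 2.0 * np.pi


@dataclass
class TCMTable:
    """Per-reconstructed-slice average tube current along z."""

    slice_z_mm: np.ndarray
    ma: np.ndarray

    def __post_init__(self):
        self.slice_z_mm = np.asarray(self.slice_z_mm, dtype=float)
        self.ma = np.asarray(self.ma, dtype=float)
        if self.slice_z_mm.size == 0:
            raise ConfigurationError("empty TCM table")
        if self.slice_z_mm.size != self.ma.size:
            raise ConfigurationError("TCM z/mA arrays must be equal length")
        if np.any(np.diff(self.slice_z_mm) <= 0):
            raise ConfigurationError("TCM slice positions must be sorted increasing")
        if np.any(self.ma <= 0):
            raise ConfigurationError("TCM currents must be positive")

    @property
    def bin_edges_mm(self) -> np.ndarray:
        z = self.slice_z_mm
        if z.size == 1:
            return np.array([z[0] - 0.5, z[0] + 0.5])
        mids = 0.5 * (z[:-1] + z[1:])
        first = z[0] - (mids[0] - z[0])
        last = z[-1] + (z[-1] - mids[-1])
        return np.concatenate([[first], mids, [last]])

    @classmethod
    def from_csv(cls, path) -> "TCMTable":
        rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(rows[:, 0], rows[:, 1])

    @property
    def mean_ma(self) -> float:
        return float(self.ma.mean())


@dataclass
class ScanProtocol:
    """Acquisition parameters for one scan."""

    mode: str  # 'axial' | 'helical' | 'static'
    kv: float
    ma: float = 300.0
    tcm: Optional[TCMTable] = None
    rotation_time_s: float = 1.0
    exposure_time_s: float = 1.0
    pitch: float = 1.0
    collimation_mm: float = 80.0
    start_angle_rad: float = 0.0  # from +y axis
    start_z_mm: float = 0.0
    direction: int = 1  # +1 head-first, -1 feet-first
    tube_to_iso_mm: float = 625.6

    def __post_init__(self):
        if self.mode not in ("axial", "helical", "static"):
            raise ConfigurationError(f"unknown scan mode {self.mode!r}")
        if self.mode == "helical" and self.pitch <= 0:
            raise ConfigurationError("helical pitch must be positive")
        if self.collimation_mm <= 0:
            raise ConfigurationError("collimation must be positive")
        if self.rotation_time_s <= 0 or self.exposure_time_s <= 0:
            raise ConfigurationError("times must be positive")
        if self.direction not in (1, -1):
            raise ConfigurationError("direction must be +1 or -1")

    @property
    def mAs(self) -> float:
        current = self.tcm.mean_ma if self.tcm is not None else self.ma
        return current * self.exposure_time_s

    @classmethod
    def from_config(cls, path) -> "ScanProtocol":
        """Flat ``key = value`` protocol file (``#`` comments allowed)."""
        values = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            values[key.strip().lower()] = val.strip()
        tcm = None
        if "tcm_file" in values:
            tcm_path = Path(values.pop("tcm_file"))
            if not tcm_path.is_absolute():
                tcm_path = Path(path).parent / tcm_path
            tcm = TCMTable.from_csv(tcm_path)
        kwargs = dict(
            mode=values["mode"],
            kv=float(values["kv"]),
            tcm=tcm,
        )
        if "ma" in values:
            kwargs["ma"] = float(values["ma"])
        for key, cast in (
            ("rotation_time_s", float),
            ("exposure_time_s", float),
            ("pitch", float),
            ("collimation_mm", float),
            ("start_z_mm", float),
            ("tube_to_iso_mm", float),
            ("direction", int),
        ):
            if key in values:
                kwargs[key] = cast(values[key])
        if "start_angle_deg" in values:
            kwargs["start_angle_rad"] = np.deg2rad(float(values["start_angle_deg"]))
        return cls(**kwargs)


@dataclass
class TubeState:
    """Sampled tube position(s); arrays for a batch of emissions."""

    z_mm: np.ndarray
    beta_rad: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray


@dataclass
class SourcePhotonBatch:
    """Struct-of-arrays source photons ready for transport."""

    position_mm: np.ndarray  # (n, 3)
    direction: np.ndarray  # (n, 3) unit vectors
    energy_kev: np.ndarray  # (n,)
    weight: np.ndarray  # (n,)

    @property
    def n(self) -> int:
        return self.energy_kev.size


def batch_rng(master_seed: int, batch_index: int) -> np.random.Generator:
    """Stated splitting rule: stream seeded by the (master seed, batch index)
    entropy pair; batches are reproducible and order-independent."""
    return np.random.default_rng([int(master_seed), int(batch_index)])


def table_travel(protocol: ScanProtocol) -> float:
    """Helical table travel T_z = pitch * collimation * t_exp / t_rot (mm)."""
    if protocol.mode != "helical":
        warnings.warn("table travel is zero for non-helical modes")
        return 0.0
    return (
        protocol.pitch
        * protocol.collimation_mm
        * protocol.exposure_time_s
        / protocol.rotation_time_s
    )


def build_tcm_pdf(tcm: TCMTable, scan_range_mm: tuple[float, float]) -> np.ndarray:
    """Slice-bin sampling probabilities proportional to the slice mA."""
    z0, z1 = min(scan_range_mm), max(scan_range_mm)
    edges = tcm.bin_edges_mm
    if z0 < edges[0] - 1e-9 or z1 > edges[-1] + 1e-9:
        raise ConfigurationError(
            f"TCM table [{edges[0]:.1f}, {edges[-1]:.1f}] mm does not cover the "
            f"scan range [{z0:.1f}, {z1:.1f}] mm"
        )
    pdf = tcm.ma / tcm.ma.sum()
    return pdf


def _helix_angle(protocol: ScanProtocol, z_mm: np.ndarray) -> np.ndarray:
    return protocol.start_angle_rad + np.abs(z_mm - protocol.start_z_mm) * TWO_PI / (
        protocol.pitch * protocol.collimation_mm
    )


def sample_tube_state(
    protocol: ScanProtocol, rng: np.random.Generator, n: int = 1
) -> TubeState:
    """Sample tube z/angle per scan mode and project onto the gantry circle."""
    if protocol.mode == "static":
        z = np.full(n, protocol.start_z_mm)
        beta = np.full(n, protocol.start_angle_rad)
    elif protocol.mode == "axial":
        z = np.full(n, protocol.start_z_mm)
        beta = rng.random(n) * TWO_PI
    else:  # helical
        if protocol.tcm is not None:
            t_z = table_travel(protocol)
            lo = min(protocol.start_z_mm, protocol.start_z_mm + protocol.direction * t_z)
            hi = max(protocol.start_z_mm, protocol.start_z_mm + protocol.direction * t_z)
            pdf = build_tcm_pdf(protocol.tcm, (lo, hi))
            edges = protocol.tcm.bin_edges_mm
            idx = rng.choice(pdf.size, size=n, p=pdf)
            z = edges[idx] + (edges[idx + 1] - edges[idx]) * rng.random(n)
            z = np.clip(z, lo, hi)
        else:
            eps = rng.random(n)
            z = protocol.start_z_mm + protocol.direction * table_travel(protocol) * eps
        beta = _helix_angle(protocol, z)
    r = protocol.tube_to_iso_mm
    return TubeState(z_mm=z, beta_rad=beta, x_mm=r * np.sin(beta), y_mm=r * np.cos(beta))


class _EnergySampler:
    """Discrete energy sampling from each bowtie bin's filtered spectrum."""

    def __init__(self, bowtie):
        self.edges = [s.energy_edges for s in bowtie.per_bin_spectrum]
        self.cdfs = []
        for s in bowtie.per_bin_spectrum:
            total = s.fluence.sum()
            if total <= 0:
                raise ConfigurationError("bowtie bin spectrum has no photons")
            self.cdfs.append(np.cumsum(s.fluence) / total)

    def sample(self, bin_idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        energies = np.empty(bin_idx.size)
        for b in np.unique(bin_idx):
            sel = bin_idx == b
            m = int(sel.sum())
            k = np.searchsorted(self.cdfs[b], rng.random(m), side="right")
            edges = self.edges[b]
            energies[sel] = edges[k] + (edges[k + 1] - edges[k]) * rng.random(m)
        return energies


def emit_photons(
    protocol: ScanProtocol,
    model: ScannerModel,
    rng: np.random.Generator,
    n: int,
) -> SourcePhotonBatch:
    """Compose tube-state, bowtie, heel and energy sampling into source photons.

    Photons start at the focal spot and head through their sampled exit point
    in the isocenter plane (lateral fan offset + z cone offset).
    """
    if model.bowtie.pdf is None:
        raise ConfigurationError("scanner model bowtie pdf not populated; fit it first")
    state = sample_tube_state(protocol, rng, n)
    r_iso = protocol.tube_to_iso_mm
    x_off, _, bin_idx = sample_bowtie_exit(model.bowtie, r_iso, rng, n)
    z_off, _ = sample_heel_z(model.beam, r_iso, rng, n)
    energies = _EnergySampler(model.bowtie).sample(bin_idx, rng)

    sin_b, cos_b = np.sin(state.beta_rad), np.cos(state.beta_rad)
    pos = np.stack([state.x_mm, state.y_mm, state.z_mm], axis=1)
    # tube-to-isocenter unit vector and the in-plane lateral unit vector
    toward = np.stack([-sin_b, -cos_b, np.zeros(n)], axis=1)
    lateral = np.stack([cos_b, -sin_b, np.zeros(n)], axis=1)
    vec = (
        r_iso * toward
        + x_off[:, None] * lateral
        + np.stack([np.zeros(n), np.zeros(n), z_off], axis=1)
    )
    direction = vec / np.linalg.norm(vec, axis=1, keepdims=True)
    return SourcePhotonBatch(
        position_mm=pos,
        direction=direction,
        energy_kev=energies,
        weight=np.ones(n),
    )
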