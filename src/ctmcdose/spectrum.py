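"""X-ray spectrum handling: filtration, air kerma, HVL, equivalent-filter fit.

Spectra are binned photon fluences (photons/mm^2/mAs in contiguous 1 keV
bins) at a stated reference distance from the focal spot.  All beam-quality
computations (kerma, HVL) run through the packaged attenuation tables, so a
single set of physical constants feeds both the source characterization and
the transport engine.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "EnergySpectrum",
    "FilterLayer",
    "AttenuationTable",
    "ConfigurationError",
    "FitFailureError",
    "apply_filtration",
    "rescale_distance",
    "air_kerma",
    "half_value_layer",
    "fit_equivalent_filter",
    "fallback_spectrum",
]

# photons/mm^2 * keV * cm^2/g -> uGy  (1 keV = 1.602176634e-16 J, mm^-2 ->
# cm^-2 is x100, g^-1 -> kg^-1 is x1000, Gy -> uGy is x1e6)
_KERMA_UGY = 100.0 * 1.602176634e-16 * 1000.0 * 1e6

_ELEMENT_ALIASES = {
    "h": "hydrogen",
    "c": "carbon",
    "n": "nitrogen",
    "o": "oxygen",
    "mg": "magnesium",
    "al": "aluminum",
    "p": "phosphorus",
    "cl": "chlorine",
    "ca": "calcium",
    "graphite": "carbon",
}


class ConfigurationError(ValueError):
    """Raised for unknown materials or malformed configuration inputs."""


class FitFailureError(RuntimeError):
    """Raised when an optimization cannot meet its targets."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class EnergySpectrum:
    """Binned photon fluence per mAs at ``reference_distance`` cm."""

    energy_edges: np.ndarray  # keV, length n_bins + 1, strictly increasing
    fluence: np.ndarray  # photons/mm^2/mAs per bin
    reference_distance: float  # cm from focal spot

    def __post_init__(self):
        edges = np.asarray(self.energy_edges, dtype=float)
        flu = np.asarray(self.fluence, dtype=float)
        object.__setattr__(self, "energy_edges", edges)
        object.__setattr__(self, "fluence", flu)
        if edges.ndim != 1 or flu.ndim != 1 or edges.size != flu.size + 1:
            raise ConfigurationError("energy_edges must have one more entry than fluence")
        if not np.all(np.diff(edges) > 0):
            raise ConfigurationError("energy edges must be strictly increasing")
        if np.any(flu < 0):
            raise ConfigurationError("fluence must be non-negative")
        if self.reference_distance <= 0:
            raise ConfigurationError("reference distance must be positive")

    @property
    def energies(self) -> np.ndarray:
        """Bin-center energies in keV."""
        return 0.5 * (self.energy_edges[:-1] + self.energy_edges[1:])

    @property
    def n_bins(self) -> int:
        return self.fluence.size

    @property
    def total_fluence(self) -> float:
        return float(self.fluence.sum())

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write(f"# reference_distance_cm={self.reference_distance:.6g}\n")
            fh.write("energy_keV,fluence_per_mm2_per_mAs\n")
            for e, f in zip(self.energies, self.fluence):
                fh.write(f"{e:.6g},{f:.10g}\n")

    @classmethod
    def from_csv(cls, path) -> "EnergySpectrum":
        ref = None
        energies, fluence = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "reference_distance_cm" in line:
                        ref = float(line.split("=", 1)[1])
                    continue
                if line.lower().startswith("energy"):
                    continue
                e, f = line.split(",")
                energies.append(float(e))
                fluence.append(float(f))
        if ref is None:
            raise ConfigurationError("spectrum CSV missing reference_distance_cm metadata")
        energies = np.asarray(energies)
        widths = np.diff(energies)
        width = widths[0] if widths.size else 1.0
        edges = np.concatenate([[energies[0] - width / 2], energies + width / 2])
        return cls(edges, np.asarray(fluence), ref)


@dataclass(frozen=True)
class FilterLayer:
    """A homogeneous attenuating layer of ``thickness_mm`` millimetres."""

    material: str
    thickness_mm: float

    def __post_init__(self):
        if self.thickness_mm < 0:
            raise ConfigurationError("filter thickness must be non-negative")


class AttenuationTable:
    """Mass attenuation/energy-absorption coefficients per material.

    Channels: ``pe`` (photoelectric), ``incoh``, ``coh``, ``total`` and ``en``
    (mass energy-absorption), all in cm^2/g on a common per-material energy
    grid.  Lookups interpolate log-log.
    """

    CHANNELS = ("pe", "incoh", "coh", "total", "en")

    def __init__(self):
        self._materials: dict[str, dict] = {}

    @staticmethod
    def _canonical(name: str) -> str:
        key = name.strip().lower()
        return _ELEMENT_ALIASES.get(key, key)

    def add_material(self, name, energy_keV, channels: Mapping[str, np.ndarray], density):
        name = self._canonical(name)
        energy = np.asarray(energy_keV, dtype=float)
        if not np.all(np.diff(energy) > 0):
            raise ConfigurationError(f"{name}: energy grid must be monotone increasing")
        rec = {"energy": energy, "density": float(density)}
        for ch in self.CHANNELS:
            arr = np.asarray(channels[ch], dtype=float)
            if np.any(arr <= 0):
                raise ConfigurationError(f"{name}: channel {ch} must be positive")
            rec[ch] = arr
        self._materials[name] = rec

    def materials(self) -> list[str]:
        return sorted(self._materials)

    def __contains__(self, name) -> bool:
        return self._canonical(name) in self._materials

    def _record(self, material):
        key = self._canonical(material)
        if key not in self._materials:
            raise ConfigurationError(f"unknown material {material!r}")
        return self._materials[key]

    def density(self, material) -> float:
        return self._record(material)["density"]

    def mass_coefficient(self, material, energy_keV, channel="total") -> np.ndarray:
        """Log-log interpolated mass coefficient (cm^2/g)."""
        if channel not in self.CHANNELS:
            raise ConfigurationError(f"unknown channel {channel!r}")
        rec = self._record(material)
        e = np.atleast_1d(np.asarray(energy_keV, dtype=float))
        e = np.clip(e, rec["energy"][0], rec["energy"][-1])
        out = np.exp(np.interp(np.log(e), np.log(rec["energy"]), np.log(rec[channel])))
        return out if np.ndim(energy_keV) else float(out[0])

    def linear_mu(self, material, energy_keV, channel="total") -> np.ndarray:
        """Linear attenuation coefficient in 1/cm at the tabulated density."""
        return self.mass_coefficient(material, energy_keV, channel) * self.density(material)

    @classmethod
    def from_directory(cls, directory) -> "AttenuationTable":
        table = cls()
        for path in sorted(Path(directory).glob("*.csv")):
            density = None
            with open(path) as fh:
                first = fh.readline()
                if first.startswith("#") and "density_g_cm3" in first:
                    density = float(first.split("=", 1)[1])
                reader = csv.DictReader(fh)
                rows = list(reader)
            if density is None:
                raise ConfigurationError(f"{path}: missing density metadata line")
            energy = np.array([float(r["energy_keV"]) for r in rows])
            channels = {
                "pe": np.array([float(r["mu_pe"]) for r in rows]),
                "incoh": np.array([float(r["mu_incoh"]) for r in rows]),
                "coh": np.array([float(r["mu_coh"]) for r in rows]),
                "total": np.array([float(r["mu_total"]) for r in rows]),
                "en": np.array([float(r["mu_en"]) for r in rows]),
            }
            table.add_material(path.stem, energy, channels, density)
        return table

    @classmethod
    def load_default(cls) -> "AttenuationTable":
        root = resources.files("ctmcdose").joinpath("data/xs")
        with resources.as_file(root) as directory:
            return cls.from_directory(directory)


def apply_filtration(
    spec: EnergySpectrum, layers: Iterable[FilterLayer], xs: AttenuationTable
) -> EnergySpectrum:
    """Beer-Lambert attenuation of every bin through a stack of layers."""
    energies = spec.energies
    optical_depth = np.zeros_like(energies)
    for layer in layers:
        mu = xs.linear_mu(layer.material, energies)  # 1/cm
        optical_depth += mu * layer.thickness_mm / 10.0
    return replace(spec, fluence=spec.fluence * np.exp(-optical_depth))


def rescale_distance(spec: EnergySpectrum, new_distance_cm: float) -> EnergySpectrum:
    """Inverse-square rescaling of the fluence to a new distance."""
    if new_distance_cm <= 0:
        raise ConfigurationError("distance must be positive")
    ratio = (spec.reference_distance / new_distance_cm) ** 2
    return replace(spec, fluence=spec.fluence * ratio, reference_distance=new_distance_cm)


def air_kerma(spec: EnergySpectrum, xs: AttenuationTable, material="air") -> float:
    """Air kerma in uGy/mAs at the spectrum's reference distance."""
    mu_en = xs.mass_coefficient(material, spec.energies, channel="en")
    return float(np.sum(spec.fluence * spec.energies * mu_en) * _KERMA_UGY)


def half_value_layer(
    spec: EnergySpectrum, xs: AttenuationTable, material: str = "aluminum"
) -> float:
    """Thickness (mm) of ``material`` halving the spectrum's air kerma."""
    if spec.total_fluence <= 0:
        raise ConfigurationError("cannot compute HVL of an empty spectrum")
    k0 = air_kerma(spec, xs)

    def ratio(t_mm):
        return air_kerma(apply_filtration(spec, [FilterLayer(material, t_mm)], xs), xs) / k0 - 0.5

    hi = 1.0
    while ratio(hi) > 0:
        hi *= 2.0
        if hi > 1e4:
            raise FitFailureError("no HVL bracket found for this spectrum")
    return float(brentq(ratio, 0.0, hi, rtol=1e-9, xtol=1e-9))


def fit_equivalent_filter(
    unfiltered: EnergySpectrum,
    target_kerma: float,
    target_hvl: float,
    xs: AttenuationTable,
    materials: Sequence[str] = ("carbon", "aluminum"),
    rel_tol: float = 5e-3,
    starts: Sequence[Sequence[float]] = ((0.0, 0.0), (5.0, 10.0)),
) -> tuple[float, float]:
    """Fit two filter thicknesses (mm) matching a kerma and an HVL target.

    Returns the thickness pair for ``materials``; raises
    :class:`FitFailureError` with residuals when the targets cannot be met
    within ``rel_tol`` relative.
    """
    if target_kerma <= 0 or target_hvl <= 0:
        raise ConfigurationError("targets must be positive")
    base_hvl = half_value_layer(unfiltered, xs)
    if target_hvl < base_hvl * (1.0 - rel_tol):
        raise FitFailureError(
            f"target HVL {target_hvl:.3g} mm below the unfiltered spectrum's "
            f"{base_hvl:.3g} mm; filtration can only harden the beam",
            residuals=(np.nan, np.nan),
        )

    def residual(thicknesses):
        layers = [FilterLayer(m, t) for m, t in zip(materials, thicknesses)]
        filtered = apply_filtration(unfiltered, layers, xs)
        return np.array(
            [
                air_kerma(filtered, xs) / target_kerma - 1.0,
                half_value_layer(filtered, xs) / target_hvl - 1.0,
            ]
        )

    best = None
    for x0 in starts:
        result = least_squares(
            residual, x0, bounds=([0.0, 0.0], [np.inf, np.inf]), xtol=1e-12, ftol=1e-12
        )
        if best is None or result.cost < best.cost:
            best = result
    res = residual(best.x)
    if np.max(np.abs(res)) > rel_tol:
        raise FitFailureError(
            f"equivalent-filter fit did not converge (residuals {res})", residuals=res
        )
    return float(best.x[0]), float(best.x[1])


def fallback_spectrum(
    kv: float = 120.0,
    min_energy: float = 10.0,
    reference_distance: float = 100.0,
    characteristic_lines: bool = True,
    scale: float = 2.0e4,
) -> EnergySpectrum:
    """Analytic bremsstrahlung test spectrum in 1 keV bins up to ``kv``.

    Kramers-law shape ``phi(E) ~ (E_max - E)/E`` with optional tungsten
    K-line spikes; a stand-in for measured/tabulated tube spectra so the
    whole pipeline runs without external data.
    """
    edges = np.arange(float(min_energy), float(kv) + 1.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fluence = scale * np.clip(kv - centers, 0.0, None) / centers
    if characteristic_lines and kv > 69.5:
        # tungsten K lines: K-alpha2/K-alpha1/K-beta3+1/K-beta2
        for line_e, strength in ((58.0, 0.6), (59.3, 1.0), (67.2, 0.35), (69.1, 0.1)):
            idx = np.searchsorted(edges, line_e) - 1
            if 0 <= idx < fluence.size:
                fluence[idx] += strength * 0.12 * scale * kv / line_e
    return EnergySpectrum(edges, fluence, reference_distance)
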