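"""Packaged example data and the default fitted scanner model.

The packaged bowtie/beam measurement CSVs are synthetic but generated through
the same physics as the fitting path, so the full characterization pipeline
(filter fit, bowtie fit, profile discretization) can run without any external
measurement files.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .scanner_model import (
    ScannerModel,
    SourceGeometry,
    build_beam_profile,
    build_bowtie_pdf,
    fit_bowtie_thickness,
)
from .spectrum import (
    AttenuationTable,
    EnergySpectrum,
    FilterLayer,
    apply_filtration,
    fallback_spectrum,
    rescale_distance,
)

__all__ = [
    "ISO_DISTANCE_CM",
    "EQUIVALENT_FILTER_MM",
    "default_filtered_spectrum",
    "load_bowtie_measurement",
    "load_beam_profile_measurement",
    "build_default_scanner_model",
]

ISO_DISTANCE_CM = 62.56
TUBE_TO_ISO_MM = 625.6

# carbon + aluminum equivalent inherent filtration (mm)
EQUIVALENT_FILTER_MM = (3.6, 9.3)


def default_filtered_spectrum(
    kv: float = 120.0, xs: AttenuationTable | None = None
) -> EnergySpectrum:
    """Fallback tube spectrum behind the equivalent filter, at the isocenter."""
    xs = xs or AttenuationTable.load_default()
    t_c, t_al = EQUIVALENT_FILTER_MM
    spec = fallback_spectrum(kv=kv)
    spec = apply_filtration(
        spec, [FilterLayer("carbon", t_c), FilterLayer("aluminum", t_al)], xs
    )
    return rescale_distance(spec, ISO_DISTANCE_CM)


def _load_csv(name: str) -> np.ndarray:
    with resources.as_file(resources.files("ctmcdose").joinpath(f"data/{name}")) as path:
        return np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)


def load_bowtie_measurement() -> tuple[np.ndarray, np.ndarray]:
    """(distance_cm, normalized_exposure) bowtie characterization points."""
    rows = _load_csv("bowtie_measurement.csv")
    return rows[:, 0], rows[:, 1]


def load_beam_profile_measurement() -> tuple[np.ndarray, np.ndarray]:
    """(z_mm, normalized_intensity) beam-profile scan for 80 mm collimation."""
    rows = _load_csv("beam_profile_80mm.csv")
    return rows[:, 0], rows[:, 1]


def build_default_scanner_model(
    kv: float = 120.0,
    collimation_mm: float = 80.0,
    xs: AttenuationTable | None = None,
) -> ScannerModel:
    """Fit bowtie and beam profiles from the packaged measurement data.

    The packaged profile was taken at 80 mm collimation; other collimations
    stretch the z axis proportionally.
    """
    xs = xs or AttenuationTable.load_default()
    base = default_filtered_spectrum(kv=kv, xs=xs)
    dist_cm, ratios = load_bowtie_measurement()
    bowtie = fit_bowtie_thickness(dist_cm, ratios, base, "aluminum", xs)
    bowtie = build_bowtie_pdf(bowtie)
    z_mm, intensity = load_beam_profile_measurement()
    z_mm = z_mm * (collimation_mm / 80.0)
    beam = build_beam_profile(z_mm, intensity)
    geometry = SourceGeometry.from_profiles(bowtie, beam, TUBE_TO_ISO_MM)
    return ScannerModel(bowtie=bowtie, beam=beam, geometry=geometry)
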