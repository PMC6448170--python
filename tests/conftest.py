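import numpy as np
import pytest

from ctmcdose.datasets import build_default_scanner_model
from ctmcdose.phantom import CompositionTable, DensityCalibration
from ctmcdose.scanner_model import (
    BeamProfile,
    BowtieProfile,
    ScannerModel,
    SourceGeometry,
    build_bowtie_pdf,
)
from ctmcdose.spectrum import AttenuationTable, EnergySpectrum, fallback_spectrum


@pytest.fixture(scope="session")
def xs():
    return AttenuationTable.load_default()


@pytest.fixture(scope="session")
def composition():
    return CompositionTable.load_default()


@pytest.fixture(scope="session")
def density_cal():
    return DensityCalibration.load_default()


@pytest.fixture(scope="session")
def spectrum_120():
    return fallback_spectrum(kv=120.0)


@pytest.fixture(scope="session")
def default_model(xs):
    """Scanner model fitted from the packaged measurement data (slow-ish)."""
    return build_default_scanner_model(xs=xs)


def with_row_air(xs):
    """Clone of the attenuation table plus a ``row_air`` material matching the
    HU-calibration air row (N 0.765 / O 0.237, no argon), so fluence-to-kerma
    conversions can be made consistent with what the voxel grid contains."""
    table = AttenuationTable.load_default()
    grid = np.arange(1.0, 161.0)
    channels = {
        ch: 0.765 * xs.mass_coefficient("nitrogen", grid, ch)
        + 0.237 * xs.mass_coefficient("oxygen", grid, ch)
        for ch in AttenuationTable.CHANNELS
    }
    table.add_material("row_air", grid, channels, 1.20479e-3)
    return table


def single_bin_spectrum(energy_kev=60.0, fluence=1.0e4, distance_cm=100.0):
    edges = np.array([energy_kev - 0.5, energy_kev + 0.5])
    return EnergySpectrum(edges, np.array([fluence]), distance_cm)


@pytest.fixture
def mono60():
    return single_bin_spectrum(60.0)


def pencil_scanner_model(spectrum, tube_to_iso_mm=625.6, half_width_cm=5e-7):
    """Degenerate single-bin bowtie/beam model: every ray goes through the
    isocenter axis (to within the vanishing bin width)."""
    bowtie = BowtieProfile(
        bin_edges=np.array([-half_width_cm, half_width_cm]),
        thickness_mm=np.array([0.0]),
        material="aluminum",
        per_bin_spectrum=[spectrum],
    )
    bowtie = build_bowtie_pdf(bowtie)
    beam = BeamProfile(
        z_edges=np.array([-half_width_cm, half_width_cm]),
        intensity=np.array([1.0]),
        fwhm_mm=max(2 * half_width_cm * 10.0, 1e-6),
    )
    geometry = SourceGeometry.from_profiles(bowtie, beam, tube_to_iso_mm)
    return ScannerModel(bowtie=bowtie, beam=beam, geometry=geometry)


@pytest.fixture
def pencil_model(spectrum_120, xs):
    from ctmcdose.spectrum import FilterLayer, apply_filtration

    filtered = apply_filtration(
        spectrum_120,
        [FilterLayer("carbon", 3.6), FilterLayer("aluminum", 9.3)],
        xs,
    )
    return pencil_scanner_model(filtered)
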