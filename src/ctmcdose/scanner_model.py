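"""Scanner characterization: bowtie filter, z beam profile, source strength.

The bowtie is described by a thickness per 1 cm radial bin fitted to
normalized exposure measurements; the z beam profile (heel effect) by
normalized intensities per 1 cm bin.  Both carry discrete sampling PDFs used
by the photon source, and together with the tube geometry they determine the
total emitted photon count Q used to scale per-photon tallies to absolute
dose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .spectrum import (
    AttenuationTable,
    ConfigurationError,
    EnergySpectrum,
    FilterLayer,
    air_kerma,
    apply_filtration,
)

__all__ = [
    "BowtieProfile",
    "BeamProfile",
    "SourceGeometry",
    "ScannerModel",
    "fit_bowtie_thickness",
    "build_bowtie_pdf",
    "sample_bowtie_exit",
    "sample_heel_z",
    "fwhm",
    "source_strength",
]

_PDF_TOL = 1e-12


@dataclass
class BowtieProfile:
    """Radial bowtie description: thickness, filtered spectra and sampling PDF.

    ``bin_edges`` are cm along the radial (fan) axis measured from the
    isocenter projection; bins are expected to be 1 cm wide and symmetric
    about zero when built from one-sided measurements.
    """

    bin_edges: np.ndarray  # cm, length n_bins + 1
    thickness_mm: np.ndarray  # bowtie material per bin
    material: str
    per_bin_spectrum: list = field(default_factory=list)
    pdf: Optional[np.ndarray] = None

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.thickness_mm = np.asarray(self.thickness_mm, dtype=float)
        if self.bin_edges.size != self.thickness_mm.size + 1:
            raise ConfigurationError("bowtie bin_edges/thickness size mismatch")
        if np.any(self.thickness_mm < 0):
            raise ConfigurationError("bowtie thickness must be non-negative")
        if self.pdf is not None:
            self.pdf = np.asarray(self.pdf, dtype=float)
            if abs(self.pdf.sum() - 1.0) > _PDF_TOL:
                raise ConfigurationError("bowtie pdf must sum to 1")

    @property
    def n_bins(self) -> int:
        return self.thickness_mm.size

    @property
    def bin_centers_cm(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class BeamProfile:
    """z-axis beam intensity profile (heel effect) with sampling PDF."""

    z_edges: np.ndarray  # cm, length n_bins + 1
    intensity: np.ndarray  # normalized H_j in [0, 1]
    fwhm_mm: float
    pdf: Optional[np.ndarray] = None

    def __post_init__(self):
        self.z_edges = np.asarray(self.z_edges, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.z_edges.size != self.intensity.size + 1:
            raise ConfigurationError("beam profile z_edges/intensity size mismatch")
        if np.any(self.intensity < 0) or np.any(self.intensity > 1 + 1e-9):
            raise ConfigurationError("beam intensities must be normalized to [0, 1]")
        if self.fwhm_mm <= 0:
            raise ConfigurationError("fwhm must be positive")
        if self.pdf is None:
            total = self.intensity.sum()
            if total <= 0:
                raise ConfigurationError("degenerate beam profile")
            self.pdf = self.intensity / total
        else:
            self.pdf = np.asarray(self.pdf, dtype=float)
        if abs(self.pdf.sum() - 1.0) > _PDF_TOL:
            raise ConfigurationError("beam pdf must sum to 1")

    @property
    def n_bins(self) -> int:
        return self.intensity.size

    @property
    def bin_centers_cm(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])


@dataclass
class SourceGeometry:
    """Tube geometry and the per-(bowtie, profile)-bin area/distance factors."""

    tube_to_iso_mm: float
    bin_area_mm2: np.ndarray  # A_ij, shape (n_bowtie, n_profile)
    distance_mm: np.ndarray  # D_ij, same shape

    def __post_init__(self):
        if self.tube_to_iso_mm <= 0:
            raise ConfigurationError("tube-to-isocenter distance must be positive")
        self.bin_area_mm2 = np.asarray(self.bin_area_mm2, dtype=float)
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)
        if self.bin_area_mm2.shape != self.distance_mm.shape:
            raise ConfigurationError("area/distance grids must share shape")
        if np.any(self.bin_area_mm2 <= 0):
            raise ConfigurationError("bin areas must be positive")

    @classmethod
    def from_profiles(
        cls, bowtie: BowtieProfile, beam: BeamProfile, tube_to_iso_mm: float
    ) -> "SourceGeometry":
        """Rectangular bin areas in the isocenter plane and focal-spot distances."""
        x = bowtie.bin_centers_cm * 10.0  # mm
        z = beam.bin_centers_cm * 10.0
        wx = np.diff(bowtie.bin_edges) * 10.0
        wz = np.diff(beam.z_edges) * 10.0
        area = np.outer(wx, wz)
        dist = np.sqrt(
            tube_to_iso_mm**2 + x[:, None] ** 2 + z[None, :] ** 2
        )
        return cls(tube_to_iso_mm, area, dist)


def fit_bowtie_thickness(
    distances_cm: Sequence[float],
    normalized_kerma: Sequence[float],
    base_spectrum: EnergySpectrum,
    material: str,
    xs: AttenuationTable,
    mirror: bool = True,
) -> BowtieProfile:
    """Per-bin 1-D root find for the bowtie thickness reproducing measured
    kerma ratios; measurements are one-sided from the isocenter and mirrored
    by default."""
    dist = np.asarray(distances_cm, dtype=float)
    ratios = np.asarray(normalized_kerma, dtype=float)
    if dist.size != ratios.size or dist.size == 0:
        raise ConfigurationError("distance/ratio arrays must be equal-length, non-empty")
    if np.any(ratios <= 0) or np.any(ratios > 1.0 + 1e-9):
        raise ConfigurationError("normalized kerma ratios must lie in (0, 1]")
    order = np.argsort(dist)
    dist, ratios = dist[order], ratios[order]

    k0 = air_kerma(base_spectrum, xs)

    def thickness_for(ratio):
        if ratio >= 1.0:
            return 0.0

        def f(t_mm):
            filtered = apply_filtration(base_spectrum, [FilterLayer(material, t_mm)], xs)
            return air_kerma(filtered, xs) / k0 - ratio

        hi = 1.0
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e5:
                raise ConfigurationError("bowtie ratio unreachable with this material")
        return brentq(f, 0.0, hi, rtol=1e-10, xtol=1e-10)

    thickness = np.array([thickness_for(r) for r in ratios])

    width = np.diff(dist)
    step = width[0] if width.size else 1.0
    if mirror:
        centers = np.concatenate([-dist[::-1][:-1], dist]) if dist[0] == 0 else np.concatenate(
            [-dist[::-1], dist]
        )
        thickness = (
            np.concatenate([thickness[::-1][:-1], thickness])
            if dist[0] == 0
            else np.concatenate([thickness[::-1], thickness])
        )
    else:
        centers = dist
    edges = np.concatenate([centers - step / 2, [centers[-1] + step / 2]])

    per_bin = [
        apply_filtration(base_spectrum, [FilterLayer(material, t)], xs) for t in thickness
    ]
    return BowtieProfile(edges, thickness, material, per_bin_spectrum=per_bin)


def build_bowtie_pdf(profile: BowtieProfile) -> BowtieProfile:
    """Populate the sampling PDF from the total photons exiting each bin."""
    if not profile.per_bin_spectrum:
        raise ConfigurationError("per-bin spectra required to build the bowtie pdf")
    widths_mm = np.diff(profile.bin_edges) * 10.0
    counts = np.array(
        [s.total_fluence for s in profile.per_bin_spectrum]
    ) * widths_mm  # photons per mm of bin height, per bin
    total = counts.sum()
    if total <= 0:
        raise ConfigurationError("degenerate bowtie pdf: no photons in any bin")
    pdf = counts / total
    pdf = pdf / pdf.sum()
    return BowtieProfile(
        profile.bin_edges,
        profile.thickness_mm,
        profile.material,
        per_bin_spectrum=profile.per_bin_spectrum,
        pdf=pdf,
    )


def sample_bowtie_exit(
    profile: BowtieProfile,
    tube_to_iso_mm: float,
    rng: np.random.Generator,
    n: int = 1,
):
    """Sample bowtie bins from the PDF and uniform offsets within each bin.

    Returns ``(x_offset_mm, fan_angle_rad, bin_index)``; the fan angle is the
    in-rotation-plane angle of the exit coordinate seen from the focal spot.
    """
    if profile.pdf is None:
        raise ConfigurationError("bowtie pdf not populated")
    idx = rng.choice(profile.n_bins, size=n, p=profile.pdf)
    lo = profile.bin_edges[idx]
    hi = profile.bin_edges[idx + 1]
    x_cm = lo + (hi - lo) * rng.random(n)
    x_mm = x_cm * 10.0
    fan = np.arctan2(x_mm, tube_to_iso_mm)
    return x_mm, fan, idx


def sample_heel_z(
    profile: BeamProfile,
    tube_to_iso_mm: float,
    rng: np.random.Generator,
    n: int = 1,
):
    """Sample z offsets from the beam-profile PDF; returns ``(z_mm, cone_rad)``."""
    if profile.pdf is None:
        raise ConfigurationError("beam pdf not populated")
    idx = rng.choice(profile.n_bins, size=n, p=profile.pdf)
    lo = profile.z_edges[idx]
    hi = profile.z_edges[idx + 1]
    z_mm = (lo + (hi - lo) * rng.random(n)) * 10.0
    cone = np.arctan2(z_mm, tube_to_iso_mm)
    return z_mm, cone


def fwhm(z_positions_mm: Sequence[float], intensities: Sequence[float]) -> float:
    """Full width at half maximum by linear interpolation of the crossings."""
    z = np.asarray(z_positions_mm, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if z.size < 3:
        raise ConfigurationError("need at least 3 profile samples")
    order = np.argsort(z)
    z, y = z[order], y[order]
    half = y.max() / 2.0
    above = y >= half
    if not above.any():
        raise ConfigurationError("profile has no region above half maximum")
    first = int(np.argmax(above))
    last = int(y.size - 1 - np.argmax(above[::-1]))
    if first == 0 or last == y.size - 1:
        raise ConfigurationError("profile never falls below half maximum on one side")

    def cross(i0, i1):
        z0, z1, y0, y1 = z[i0], z[i1], y[i0], y[i1]
        return z0 + (half - y0) * (z1 - z0) / (y1 - y0)

    left = cross(first - 1, first)
    right = cross(last, last + 1)
    return float(right - left)


def build_beam_profile(
    z_positions_mm: Sequence[float],
    intensities: Sequence[float],
    bin_width_cm: float = 1.0,
) -> BeamProfile:
    """Discretize a measured z profile into 1 cm bins over its FWHM extent.

    The FWHM is taken as the effective collimation; bins are centered on the
    half-maximum midpoint and intensities are normalized to a unit maximum.
    """
    z = np.asarray(z_positions_mm, dtype=float)
    y = np.asarray(intensities, dtype=float)
    width_mm = fwhm(z, y)
    order = np.argsort(z)
    z, y = z[order], y[order]
    half = y.max() / 2.0
    above = np.where(y >= half)[0]
    center = 0.5 * (z[above[0]] + z[above[-1]])
    n_bins = max(1, int(round(width_mm / (bin_width_cm * 10.0))))
    edges_cm = (center / 10.0) + bin_width_cm * (np.arange(n_bins + 1) - n_bins / 2.0)
    centers_mm = 10.0 * 0.5 * (edges_cm[:-1] + edges_cm[1:])
    h = np.interp(centers_mm, z, y)
    h = np.clip(h / h.max(), 0.0, 1.0)
    return BeamProfile(edges_cm, h, fwhm_mm=width_mm)


def source_strength(
    bowtie: BowtieProfile,
    beam: BeamProfile,
    geometry: SourceGeometry,
    mAs: float,
) -> float:
    """Total emitted photons Q = sum_ij H_j (A_ij D_ij / SDD^2) sum_k phi_ik.

    ``phi_ik`` is the per-mm^2 photon fluence at the isocenter behind bowtie
    bin i in energy group k, scaled linearly by mAs; the printed area-distance
    weighting is evaluated verbatim.
    """
    if mAs <= 0:
        raise ConfigurationError("mAs must be positive")
    if not bowtie.per_bin_spectrum:
        raise ConfigurationError("bowtie spectra required for source strength")
    if geometry.bin_area_mm2.shape != (bowtie.n_bins, beam.n_bins):
        raise ConfigurationError("geometry grid does not match profile binning")
    phi_i = np.array([s.total_fluence for s in bowtie.per_bin_spectrum])  # sum over k
    sdd2 = geometry.tube_to_iso_mm**2
    weights = geometry.bin_area_mm2 * geometry.distance_mm / sdd2  # (i, j)
    # H_j enters Q as the raw normalized intensity, not the renormalized pdf
    q = np.sum(weights * beam.intensity[None, :] * phi_i[:, None]) * mAs
    return float(q)


@dataclass
class ScannerModel:
    """Fitted scanner description bundling bowtie, beam profile and geometry."""

    bowtie: BowtieProfile
    beam: BeamProfile
    geometry: SourceGeometry

    def to_json(self, path=None) -> str:
        doc = {
            "bowtie": {
                "bin_edges_cm": self.bowtie.bin_edges.tolist(),
                "thickness_mm": self.bowtie.thickness_mm.tolist(),
                "material": self.bowtie.material,
                "pdf": None if self.bowtie.pdf is None else self.bowtie.pdf.tolist(),
                "per_bin_spectrum": [
                    {
                        "energy_edges": s.energy_edges.tolist(),
                        "fluence": s.fluence.tolist(),
                        "reference_distance": s.reference_distance,
                    }
                    for s in self.bowtie.per_bin_spectrum
                ],
            },
            "beam": {
                "z_edges_cm": self.beam.z_edges.tolist(),
                "intensity": self.beam.intensity.tolist(),
                "fwhm_mm": self.beam.fwhm_mm,
                "pdf": self.beam.pdf.tolist(),
            },
            "geometry": {
                "tube_to_iso_mm": self.geometry.tube_to_iso_mm,
                "bin_area_mm2": self.geometry.bin_area_mm2.tolist(),
                "distance_mm": self.geometry.distance_mm.tolist(),
            },
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ScannerModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        b = doc["bowtie"]
        spectra = [
            EnergySpectrum(
                np.asarray(s["energy_edges"]),
                np.asarray(s["fluence"]),
                s["reference_distance"],
            )
            for s in b["per_bin_spectrum"]
        ]
        bowtie = BowtieProfile(
            np.asarray(b["bin_edges_cm"]),
            np.asarray(b["thickness_mm"]),
            b["material"],
            per_bin_spectrum=spectra,
            pdf=None if b["pdf"] is None else np.asarray(b["pdf"]),
        )
        m = doc["beam"]
        beam = BeamProfile(
            np.asarray(m["z_edges_cm"]),
            np.asarray(m["intensity"]),
            m["fwhm_mm"],
            pdf=np.asarray(m["pdf"]),
        )
        g = doc["geometry"]
        geometry = SourceGeometry(
            g["tube_to_iso_mm"],
            np.asarray(g["bin_area_mm2"]),
            np.asarray(g["distance_mm"]),
        )
        return cls(bowtie, beam, geometry)
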