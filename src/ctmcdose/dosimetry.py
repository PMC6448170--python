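"""Dose reporting: correction factors, start-angle averaging, error propagation."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .spectrum import ConfigurationError

__all__ = [
    "DoseReport",
    "MeasurementSet",
    "ctdi_correction_factor",
    "table_attenuation_factor",
    "average_over_start_angles",
    "average_measured_dose",
]

DEFAULT_START_ANGLES_DEG = (0.0, 90.0, 180.0, 270.0)


@dataclass
class DoseReport:
    """Per-tally absorbed doses (cGy) with standard errors and provenance."""

    doses_cgy: dict  # name -> dose
    sigmas_cgy: dict  # name -> standard error
    protocol: Optional[dict] = None
    seed: Optional[int] = None
    n_histories: Optional[int] = None
    model_hash: Optional[str] = None
    corrections: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(v < 0 for v in self.doses_cgy.values()):
            raise ConfigurationError("doses must be non-negative")

    def apply_factor(self, name: str, factor: float) -> "DoseReport":
        """Multiplicative correction; applying the same factor twice is rejected."""
        if name in self.corrections:
            raise ConfigurationError(f"correction {name!r} already applied")
        doses = {k: v * factor for k, v in self.doses_cgy.items()}
        sigmas = {k: v * factor for k, v in self.sigmas_cgy.items()}
        corrections = dict(self.corrections)
        corrections[name] = factor
        return replace(self, doses_cgy=doses, sigmas_cgy=sigmas, corrections=corrections)

    def rounded(self, decimals: int = 2) -> dict:
        """Two-decimal display values; machine output keeps full precision."""
        return {
            k: (round(v, decimals), round(self.sigmas_cgy[k], decimals))
            for k, v in self.doses_cgy.items()
        }

    def to_json(self, path=None) -> str:
        doc = {
            "doses_cGy": self.doses_cgy,
            "sigmas_cGy": self.sigmas_cgy,
            "corrections": self.corrections,
            "protocol": self.protocol,
            "seed": self.seed,
            "n_histories": self.n_histories,
            "model_hash": self.model_hash,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class MeasurementSet:
    """Repeated dose measurements with a detector calibration error."""

    doses_cgy: Sequence[float]
    relative_calibration_error: float

    def __post_init__(self):
        if len(self.doses_cgy) < 1:
            raise ConfigurationError("need at least one measurement")
        if self.relative_calibration_error < 0:
            raise ConfigurationError("calibration error must be non-negative")


def ctdi_correction_factor(measured_cgy: float, simulated_cgy: float) -> float:
    """Measured over simulated center-hole air kerma."""
    if simulated_cgy <= 0:
        raise ConfigurationError("simulated dose must be positive")
    return measured_cgy / simulated_cgy


def table_attenuation_factor(sim_with_table_cgy: float, sim_without_table_cgy: float) -> float:
    """Ratio of the simulated detector signal with and without the couch."""
    if sim_with_table_cgy <= 0 or sim_without_table_cgy <= 0:
        raise ConfigurationError("simulated doses must be positive")
    return sim_with_table_cgy / sim_without_table_cgy


def average_over_start_angles(
    protocol,
    runner: Callable,
    angles_deg: Sequence[float] = DEFAULT_START_ANGLES_DEG,
) -> DoseReport:
    """Average per-tally doses over tube start angles (helical scans).

    ``runner(protocol)`` must return a :class:`DoseReport`.  The combined
    sigma propagates the per-run statistical errors:
    ``sigma = sqrt(sum sigma_i^2) / n``.
    """
    if protocol.mode != "helical":
        warnings.warn("start-angle averaging applies to helical scans; single run used")
        return runner(protocol)
    reports = []
    for angle in angles_deg:
        p = replace(protocol, start_angle_rad=float(np.deg2rad(angle)))
        reports.append(runner(p))
    names = sorted(reports[0].doses_cgy)
    n = len(reports)
    doses = {k: sum(r.doses_cgy[k] for r in reports) / n for k in names}
    sigmas = {
        k: float(np.sqrt(sum(r.sigmas_cgy[k] ** 2 for r in reports))) / n for k in names
    }
    return DoseReport(
        doses_cgy=doses,
        sigmas_cgy=sigmas,
        protocol=reports[0].protocol,
        seed=reports[0].seed,
        n_histories=sum(r.n_histories or 0 for r in reports) or None,
        model_hash=reports[0].model_hash,
    )


def average_measured_dose(measurements: MeasurementSet) -> tuple[float, float]:
    """(D_avg, sigma_avg) with the calibration error propagated per reading:
    ``sigma_avg = (1/n) sqrt(sum (D_i * r_cf)^2)``."""
    d = np.asarray(measurements.doses_cgy, dtype=float)
    r = measurements.relative_calibration_error
    n = d.size
    return float(d.mean()), float(np.sqrt(np.sum((d * r) ** 2)) / n)
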