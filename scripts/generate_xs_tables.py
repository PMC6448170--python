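"""Bake the packaged photon cross-section tables.

Requires the ``xraylib`` bindings (conda-forge), which are only needed at
table-generation time -- the package itself reads the committed CSVs.

Columns are mass coefficients in cm^2/g on a 1 keV grid:
``energy_keV,mu_pe,mu_incoh,mu_coh,mu_total,mu_en``.

``mu_en`` is computed as ``mu_pe + mu_incoh * f_KN(E)`` where ``f_KN`` is the
Klein-Nishina mean energy-transfer fraction (radiative losses and fluorescence
escape are negligible for the low-Z materials at the energies covered here).
This makes the packaged energy-absorption channel exactly consistent with the
collision-kerma transport approximation used by the simulation engine.
"""

from __future__ import annotations

import pathlib

import numpy as np
import xraylib as xl
from scipy.integrate import quad

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "ctmcdose" / "data" / "xs"

ENERGY_KEV = np.arange(1.0, 161.0)  # 1..160 keV inclusive

ELECTRON_REST_KEV = 510.998950

# name -> (element Z, density) or (mass-fraction dict, density)
MATERIALS = {
    "hydrogen": (1, None),
    "carbon": (6, None),
    "nitrogen": (7, None),
    "oxygen": (8, None),
    "magnesium": (12, None),
    "aluminum": (13, None),
    "phosphorus": (15, None),
    "chlorine": (17, None),
    "calcium": (20, None),
    "air": ({6: 0.000124, 7: 0.755267, 8: 0.231781, 18: 0.012827}, 1.20479e-3),
    "water": ({1: 0.111898, 8: 0.888102}, 1.000),
    "pmma": ({1: 0.080538, 6: 0.599848, 8: 0.319614}, 1.190),
    "carbon_fiber": ({6: 1.0}, 1.550),
    # polystyrene-like closed-cell couch foam
    "foam": ({1: 0.077418, 6: 0.922582}, 0.050),
}


def kn_transfer_fraction(energy_kev: float) -> float:
    """Mean fraction of photon energy given to the electron per KN scatter."""
    alpha = energy_kev / ELECTRON_REST_KEV

    def x_of_mu(mu):
        return 1.0 / (1.0 + alpha * (1.0 - mu))

    def dsdmu(mu):
        x = x_of_mu(mu)
        return x * x * (x + 1.0 / x - 1.0 + mu * mu)

    def dsdmu_x(mu):
        return dsdmu(mu) * x_of_mu(mu)

    num, _ = quad(dsdmu_x, -1.0, 1.0, limit=200)
    den, _ = quad(dsdmu, -1.0, 1.0, limit=200)
    return 1.0 - num / den


def bake(name, spec, density):
    if isinstance(spec, int):
        fractions = {spec: 1.0}
        if density is None:
            density = xl.ElementDensity(spec)
    else:
        fractions = spec
    f_kn = np.array([kn_transfer_fraction(e) for e in ENERGY_KEV])
    pe = np.zeros_like(ENERGY_KEV)
    incoh = np.zeros_like(ENERGY_KEV)
    coh = np.zeros_like(ENERGY_KEV)
    for z, w in fractions.items():
        pe += w * np.array([xl.CS_Photo(z, e) for e in ENERGY_KEV])
        incoh += w * np.array([xl.CS_Compt(z, e) for e in ENERGY_KEV])
        coh += w * np.array([xl.CS_Rayl(z, e) for e in ENERGY_KEV])
    total = pe + incoh + coh
    mu_en = pe + incoh * f_kn
    path = OUT / f"{name}.csv"
    with open(path, "w") as fh:
        fh.write(f"# density_g_cm3={density:.6g}\n")
        fh.write("energy_keV,mu_pe,mu_incoh,mu_coh,mu_total,mu_en\n")
        for row in zip(ENERGY_KEV, pe, incoh, coh, total, mu_en):
            fh.write(",".join(f"{v:.8g}" for v in row) + "\n")
    print(f"wrote {path} (rho={density})")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for name, (spec, density) in MATERIALS.items():
        bake(name, spec, density)


if __name__ == "__main__":
    main()
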