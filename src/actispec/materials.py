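"""Materials and photon cross sections for the detector model.

Mass attenuation coefficients (cm^2/g) for photoelectric absorption,
incoherent (Compton) and coherent (Rayleigh) scattering are evaluated
per element and combined by Bragg additivity:

* incoherent — exact integrated Klein-Nishina cross section per
  electron times Z/A (free-electron approximation; binding corrections
  are a few percent below ~50 keV and neglected),
* photoelectric — a Z^3.8 / E^3 power law anchored to iodine at
  100 keV, with K-edge jump discontinuities for iodine (33.2 keV) and
  lead (88.0 keV); accurate to a few tens of percent, which sets the
  photopeak/continuum balance but cancels from every self-consistent
  transport check,
* coherent — a Z^2.5 / E^2 power law anchored to water at 100 keV
  (a small correction at these energies).

Each material caches the partials on a logarithmic 10-800 keV grid
(:class:`CrossSectionTable`) and interpolates log-log between grid
points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

AVOGADRO = 6.02214076e23
ELECTRON_RADIUS_CM = 2.8179403e-13
ELECTRON_REST_KEV = 510.99895

# element: (Z, A, K-edge keV or None, K-jump factor)
_ELEMENTS = {
    "H": (1, 1.008, None, 1.0),
    "C": (6, 12.011, None, 1.0),
    "N": (7, 14.007, None, 1.0),
    "O": (8, 15.999, None, 1.0),
    "Na": (11, 22.990, None, 1.0),
    "Mg": (12, 24.305, None, 1.0),
    "Al": (13, 26.982, None, 1.0),
    "I": (53, 126.904, 33.17, 5.9),
    "Pb": (82, 207.2, 88.0, 5.0),
}

# photoelectric anchor: iodine tau/rho = 1.70 cm^2/g at 100 keV
_PE_EXPONENT_Z = 3.8
_PE_EXPONENT_E = 3.0
_PE_CONST = 1.70 * 126.904 / 53.0**_PE_EXPONENT_Z
# coherent anchor: water sigma_coh/rho = 0.0037 cm^2/g at 100 keV
_COH_EXPONENT_Z = 2.5
_COH_CONST = 0.0037 / (
    0.1119 * 1.0**_COH_EXPONENT_Z / 1.008 + 0.8881 * 8.0**_COH_EXPONENT_Z / 15.999
)


def klein_nishina_total(energy_kev: np.ndarray) -> np.ndarray:
    """Integrated Klein-Nishina cross section per electron, cm^2."""
    k = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    pre = 2.0 * math.pi * ELECTRON_RADIUS_CM**2
    t1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log1p(2 * k) / k)
    t2 = np.log1p(2 * k) / (2 * k)
    t3 = -(1 + 3 * k) / (1 + 2 * k) ** 2
    return pre * (t1 + t2 + t3)


def _element_partials(symbol: str, energy_kev: np.ndarray):
    z, a, k_edge, jump = _ELEMENTS[symbol]
    e = np.asarray(energy_kev, dtype=float)
    incoh = (z / a) * AVOGADRO * klein_nishina_total(e)
    pe = _PE_CONST * z**_PE_EXPONENT_Z / a * (100.0 / e) ** _PE_EXPONENT_E
    if k_edge is not None:
        pe = np.where(e < k_edge, pe / jump, pe)
    coh = _COH_CONST * z**_COH_EXPONENT_Z / a * (100.0 / e) ** 2
    return pe, incoh, coh


@dataclass(frozen=True)
class Material:
    """Named material with density (g/cm^3) and elemental mass fractions."""

    name: str
    density: float
    composition: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        total = sum(f for _, f in self.composition)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{self.name}: mass fractions sum to {total}, not 1")
        for sym, _ in self.composition:
            if sym not in _ELEMENTS:
                raise ValueError(f"{self.name}: no cross-section data for {sym!r}")


BUILTIN_MATERIALS = {
    "NaI": Material("NaI", 3.667, (("Na", 0.1534), ("I", 0.8466))),
    "MgO": Material("MgO", 3.58, (("Mg", 0.6030), ("O", 0.3970))),
    "Al": Material("Al", 2.699, (("Al", 1.0),)),
    "Pb": Material("Pb", 11.35, (("Pb", 1.0),)),
    "polyethylene": Material("polyethylene", 0.94, (("H", 0.1437), ("C", 0.8563))),
    "water": Material("water", 1.0, (("H", 0.1119), ("O", 0.8881))),
    # Ar folded into N for simplicity; air is nearly transparent here anyway
    "air": Material("air", 1.205e-3, (("N", 0.7552), ("O", 0.2448))),
}


@dataclass
class CrossSectionTable:
    """Log-log tabulated partial mass attenuation coefficients for one material.

    ``interp(energies)`` returns linear attenuation coefficients (1/cm)
    for (photoelectric, incoherent, coherent) at the given keV energies.
    """

    material: Material
    energy_kev: np.ndarray = field(default=None)  # type: ignore[assignment]
    photoelectric: np.ndarray = field(default=None)  # type: ignore[assignment]
    incoherent: np.ndarray = field(default=None)  # type: ignore[assignment]
    coherent: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.energy_kev is None:
            grid = np.geomspace(10.0, 800.0, 160)
            # place points just on both sides of K-edges so the jump survives
            for sym, frac in self.material.composition:
                edge = _ELEMENTS[sym][2]
                if edge is not None and frac > 0:
                    grid = np.append(grid, [edge * (1 - 1e-6), edge * (1 + 1e-6)])
            self.energy_kev = np.unique(grid)
            pe = np.zeros_like(self.energy_kev)
            inc = np.zeros_like(self.energy_kev)
            coh = np.zeros_like(self.energy_kev)
            for sym, frac in self.material.composition:
                p, i, c = _element_partials(sym, self.energy_kev)
                pe += frac * p
                inc += frac * i
                coh += frac * c
            self.photoelectric, self.incoherent, self.coherent = pe, inc, coh
        self._log_e = np.log(self.energy_kev)
        self._logs = [
            np.log(np.maximum(arr, 1e-300))
            for arr in (self.photoelectric, self.incoherent, self.coherent)
        ]

    @property
    def total(self) -> np.ndarray:
        return self.photoelectric + self.incoherent + self.coherent

    def mass_attenuation(self, energy_kev) -> tuple[np.ndarray, ...]:
        """Partial mass attenuation coefficients (cm^2/g) at given energies."""
        loge = np.log(np.clip(energy_kev, self.energy_kev[0], self.energy_kev[-1]))
        return tuple(np.exp(np.interp(loge, self._log_e, ls)) for ls in self._logs)

    def interp(self, energy_kev) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Partial linear attenuation coefficients (1/cm) at given energies."""
        pe, inc, coh = self.mass_attenuation(energy_kev)
        rho = self.material.density
        return pe * rho, inc * rho, coh * rho

    def mu_total(self, energy_kev) -> np.ndarray:
        pe, inc, coh = self.interp(energy_kev)
        return pe + inc + coh


class CrossSectionLibrary:
    """Cache of cross-section tables keyed by material name."""

    def __init__(self, materials: dict[str, Material] | None = None) -> None:
        self.materials = dict(materials or BUILTIN_MATERIALS)
        self._tables: dict[str, CrossSectionTable] = {}

    def table(self, name: str) -> CrossSectionTable:
        if name not in self._tables:
            self._tables[name] = CrossSectionTable(self.materials[name])
        return self._tables[name]
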