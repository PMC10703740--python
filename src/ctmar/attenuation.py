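"""X-ray attenuation physics: material tables and source spectra.

Mass attenuation coefficients (mu/rho, cm^2/g) are embedded as sparse energy
knots transcribed from the public NIST XCOM/ICRU tabulations and interpolated
log-log in energy — adequate for simulation because mu/rho of the body
materials is smooth (no K-edges between 20 and 150 keV).  Lead has its K-edge
at 88 keV, so its knots bracket the edge and the piezoceramic average
inherits the discontinuity there.

The transducer's piezoelectric ceramic (PZT, lead zirconate titanate) is
modelled by the unweighted mean of the elemental lead, zirconium and titanium
coefficients at each knot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AttenuationTable",
    "Spectrum",
    "filtered_kramers_spectrum",
    "monochromatic_spectrum",
    "effective_energy",
    "DEFAULT_TABLE",
]

# mu/rho in cm^2/g on a common 20-150 keV grid (NIST XCOM / ICRU-44 values,
# rounded to 4 significant figures).  Lead carries extra knots at the 88 keV
# K-edge.
_GRID_KEV = np.array([20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0])

_WATER = np.array([0.8096, 0.3756, 0.2683, 0.2269, 0.2059,
                   0.1837, 0.1707, 0.1505])
# ICRU-44 lung tissue: composition close to soft tissue (density differs).
_LUNG = np.array([0.7943, 0.3707, 0.2659, 0.2254, 0.2048,
                  0.1831, 0.1703, 0.1505])
_BONE = np.array([4.001, 1.331, 0.6655, 0.4242, 0.3148,
                  0.2229, 0.1855, 0.1480])
_TITANIUM = np.array([2.214, 0.7661, 0.3837, 0.2413, 0.1951,
                      0.1570, 0.1378, 0.1166])
_ZIRCONIUM = np.array([15.78, 5.577, 2.601, 1.450, 0.9148,
                       0.4731, 0.2992, 0.1659])

_PB_KEV = np.array([20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 87.99, 88.01,
                    100.0, 150.0])
_PB = np.array([86.36, 30.32, 14.36, 8.041, 5.021, 2.419, 1.910, 7.683,
                5.549, 2.014])

# Aluminium, used only for beam filtration of the source spectrum.
_AL = np.array([3.441, 1.128, 0.5685, 0.3681, 0.2778,
                0.2018, 0.1704, 0.1378])


def _loglog_interp(e: np.ndarray, grid_kev: np.ndarray,
                   mu_rho: np.ndarray) -> np.ndarray:
    e = np.asarray(e, dtype=np.float64)
    lo, hi = grid_kev[0], grid_kev[-1]
    if np.any(e < lo) or np.any(e > hi):
        raise ValueError(
            f"energy outside attenuation table range [{lo}, {hi}] keV")
    out = np.interp(np.log(e), np.log(grid_kev), np.log(mu_rho))
    return np.exp(out)


@dataclass
class AttenuationTable:
    """Per-material mass attenuation coefficients with reference densities.

    ``materials`` maps a class name to ``(energies_keV, mu_rho, density)``.
    The ``pzt_metal`` entry is the unweighted mean of lead, zirconium and
    titanium evaluated on the common grid.
    """

    materials: dict = field(default_factory=dict)

    @classmethod
    def default(cls) -> "AttenuationTable":
        pzt = (_loglog_interp(_GRID_KEV, _PB_KEV, _PB)
               + _TITANIUM + _ZIRCONIUM) / 3.0
        mats = {
            "water": (_GRID_KEV, _WATER, 1.0),
            "lung": (_GRID_KEV, _LUNG, 0.30),
            "cortical_bone": (_GRID_KEV, _BONE, 1.92),
            "lead": (_PB_KEV, _PB, 11.35),
            "zirconium": (_GRID_KEV, _ZIRCONIUM, 6.51),
            "titanium": (_GRID_KEV, _TITANIUM, 4.51),
            "pzt_metal": (_GRID_KEV, pzt, 7.5),
            "aluminium": (_GRID_KEV, _AL, 2.699),
        }
        return cls(materials=mats)

    def mu_over_rho(self, material: str, energy_keV) -> np.ndarray:
        """mu/rho (cm^2/g) of ``material`` at ``energy_keV`` (scalar or array)."""
        if material not in self.materials:
            raise KeyError(f"unknown material {material!r}")
        grid, table, _ = self.materials[material]
        return _loglog_interp(energy_keV, grid, table)

    def density(self, material: str) -> float:
        return self.materials[material][2]

    def mu(self, material: str, energy_keV) -> np.ndarray:
        """Linear attenuation (1/cm) at the material's reference density."""
        return self.mu_over_rho(material, energy_keV) * self.density(material)

    @property
    def energy_range(self) -> tuple:
        return float(_GRID_KEV[0]), float(_GRID_KEV[-1])


DEFAULT_TABLE = AttenuationTable.default()


@dataclass
class Spectrum:
    """Discretized polychromatic X-ray source.

    energies_keV : ascending bin centres.
    weights : relative photon fluence per bin, normalized to sum 1.
    i0 : incident photons per detector element per view.
    """

    energies_keV: np.ndarray
    weights: np.ndarray
    i0: float = 2.0e5

    def __post_init__(self) -> None:
        self.energies_keV = np.asarray(self.energies_keV, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.energies_keV.ndim != 1 or self.energies_keV.size == 0:
            raise ValueError("spectrum needs at least one energy bin")
        if np.any(np.diff(self.energies_keV) <= 0):
            raise ValueError("energies must be strictly ascending")
        if self.weights.shape != self.energies_keV.shape:
            raise ValueError("weights must match energies")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        s = self.weights.sum()
        if s <= 0:
            raise ValueError("weights must have positive sum")
        if abs(s - 1.0) > 1e-12:
            self.weights = self.weights / s
        if self.i0 <= 0:
            raise ValueError("i0 must be positive")

    @property
    def n_bins(self) -> int:
        return self.energies_keV.size

    @property
    def mean_energy_keV(self) -> float:
        return float(np.sum(self.energies_keV * self.weights))


def filtered_kramers_spectrum(kvp: float = 120.0, bin_width_keV: float = 5.0,
                              e_min_keV: float = 20.0,
                              filtration_mm_al: float = 2.5,
                              i0: float = 2.0e5,
                              table: AttenuationTable | None = None,
                              ) -> Spectrum:
    """Bremsstrahlung tube spectrum: Kramers shape hardened by Al filtration.

    Photon-number Kramers law N(E) ∝ (E_max − E)/E, attenuated by a slab of
    aluminium of the given thickness.  The default (120 kVp, 2.5 mm Al,
    5 keV bins over 20–120 keV) activates both beam hardening and, behind
    thick metal, photon starvation.
    """
    table = table or DEFAULT_TABLE
    edges = np.arange(e_min_keV, kvp + 1e-9, bin_width_keV)
    centers = (edges[:-1] + edges[1:]) / 2.0
    n = (kvp - centers) / centers
    mu_al = table.mu("aluminium", centers)  # 1/cm
    w = n * np.exp(-mu_al * (filtration_mm_al / 10.0))
    return Spectrum(energies_keV=centers, weights=w / w.sum(), i0=i0)


def monochromatic_spectrum(energy_keV: float = 70.0,
                           i0: float = 2.0e5) -> Spectrum:
    return Spectrum(energies_keV=np.array([energy_keV]),
                    weights=np.array([1.0]), i0=i0)


def effective_energy(spectrum: Spectrum,
                     table: AttenuationTable | None = None,
                     water_path_cm: float = 20.0) -> float:
    """Water-calibrated effective energy of a spectrum.

    The monochromatic energy whose water attenuation matches the spectrum's
    effective attenuation through ``water_path_cm`` of water — the scanner
    water calibration that puts water at 0 HU for a body-sized object.
    For a monochromatic spectrum this returns its energy.
    """
    from scipy.optimize import brentq

    table = table or DEFAULT_TABLE
    if spectrum.n_bins == 1:
        return float(spectrum.energies_keV[0])
    mu_w = table.mu("water", spectrum.energies_keV)
    L = water_path_cm
    mu_eff = -np.log(np.sum(spectrum.weights * np.exp(-mu_w * L))) / L
    lo, hi = table.energy_range
    return float(brentq(lambda e: table.mu("water", e) - mu_eff, lo, hi))
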