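"""Materials database, X-ray spectrum model, and HU-to-material mapping.

The dose engine works on a small set of named materials (air, water, soft
tissue, lung, PMMA, cortical bone, aluminum, tungsten, lead).  Each material
carries energy-dependent mass attenuation ``mu/rho`` and mass energy-absorption
``mu_en/rho`` tables bundled as CSV inside the package, interpolated log-log.

The tube spectrum is a semi-empirical Kramers bremsstrahlung continuum plus
tungsten K fluorescence lines, filtered through aluminum by Beer-Lambert.  A
measured spectrum can be substituted from a two-column CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Hounsfield-unit range accepted by the HU mapping (12-bit CT convention).
HU_MIN, HU_MAX = -1024, 3071

# Tungsten K fluorescence: (energy keV, relative intensity).  Only emitted
# above the K-edge binding energy.
_W_K_EDGE_KEV = 69.525
_W_K_LINES = ((57.98, 0.50), (59.32, 1.00), (67.24, 0.30), (69.10, 0.08))
_K_LINE_FRACTION = 0.07  # fraction of unfiltered fluence carried by K lines


class EnergyRangeError(ValueError):
    """Photon energy outside the bundled cross-section tables."""


@dataclass(frozen=True)
class Material:
    """A named medium with nominal density and photon cross-section tables."""

    name: str
    density: float  # g/cm^3, nominal
    z_over_a: float  # mean Z/A (electrons per amu)
    energies_kev: np.ndarray = field(repr=False)
    mu_over_rho: np.ndarray = field(repr=False)  # cm^2/g
    mu_en_over_rho: np.ndarray = field(repr=False)  # cm^2/g

    def _interp(self, table: np.ndarray, energy_kev) -> np.ndarray:
        e = np.asarray(energy_kev, dtype=float)
        lo, hi = self.energies_kev[0], self.energies_kev[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise EnergyRangeError(
                f"energy outside [{lo}, {hi}] keV table range for {self.name!r}"
            )
        return np.exp(
            np.interp(np.log(e), np.log(self.energies_kev), np.log(table))
        )

    def mass_attenuation(self, energy_kev) -> np.ndarray:
        """mu/rho in cm^2/g at the given energy (log-log interpolation)."""
        return self._interp(self.mu_over_rho, energy_kev)

    def mass_energy_absorption(self, energy_kev) -> np.ndarray:
        """mu_en/rho in cm^2/g at the given energy."""
        return self._interp(self.mu_en_over_rho, energy_kev)


@lru_cache(maxsize=1)
def _load_tables() -> dict[str, Material]:
    data = resources.files("mrtplan") / "data"
    props = pd.read_csv(data / "materials.csv", comment="#")
    atten = pd.read_csv(data / "attenuation.csv", comment="#")
    out: dict[str, Material] = {}
    for _, row in props.iterrows():
        tab = atten[atten["material"] == row["name"]].sort_values("energy_kev")
        out[row["name"]] = Material(
            name=row["name"],
            density=float(row["density"]),
            z_over_a=float(row["z_over_a"]),
            energies_kev=tab["energy_kev"].to_numpy(float),
            mu_over_rho=tab["mu_over_rho"].to_numpy(float),
            mu_en_over_rho=tab["mu_en_over_rho"].to_numpy(float),
        )
    return out


def get_material(name: str) -> Material:
    """Look up a bundled material by name."""
    try:
        return _load_tables()[name]
    except KeyError:
        known = ", ".join(sorted(_load_tables()))
        raise KeyError(f"unknown material {name!r}; bundled: {known}") from None


def material_names() -> tuple[str, ...]:
    return tuple(_load_tables())


def attenuation_coefficient(material, density: float, energy_kev) -> np.ndarray:
    """Linear attenuation coefficient in 1/mm.

    Parameters
    ----------
    material : Material or str
    density : float
        Mass density in g/cm^3 (overrides the nominal density).
    energy_kev : float or array
    """
    if isinstance(material, str):
        material = get_material(material)
    # cm^2/g * g/cm^3 = 1/cm -> 1/mm
    return material.mass_attenuation(energy_kev) * density / 10.0


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Spectrum:
    """Relative photon fluence per energy bin, normalized to sum 1."""

    energies_kev: np.ndarray
    fluence: np.ndarray

    def __post_init__(self):
        if np.any(self.fluence < 0):
            raise ValueError("spectrum fluence must be non-negative")
        total = float(self.fluence.sum())
        if total <= 0:
            raise ValueError("spectrum carries no fluence")
        object.__setattr__(self, "fluence", self.fluence / total)

    @property
    def mean_energy_kev(self) -> float:
        """Fluence-weighted mean photon energy."""
        return float(np.sum(self.energies_kev * self.fluence))

    def effective_energy_kev(self) -> float:
        """Alias for the fluence-weighted mean (single-value spectrum proxy)."""
        return self.mean_energy_kev

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"energy_kev": self.energies_kev, "relative_fluence": self.fluence}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Spectrum":
        df = pd.read_csv(path, comment="#")
        cols = list(df.columns)
        return cls(df[cols[0]].to_numpy(float), df[cols[1]].to_numpy(float))


def generate_spectrum(
    kvp: float, filtration_mm_al: float = 1.0, e_min_kev: float = 10.0
) -> Spectrum:
    """Model a tungsten-anode tube spectrum at the given peak voltage.

    Kramers-type bremsstrahlung, ``N(E) ∝ (kvp − E)/E``, plus tungsten K
    fluorescence lines when the tube potential exceeds the K edge, hardened by
    aluminum filtration via Beer-Lambert.  Bins are 1 keV wide.
    """
    if not 40.0 <= kvp <= 300.0:
        raise ValueError(f"tube potential {kvp} kVp outside supported 40-300 kVp")
    if filtration_mm_al < 0:
        raise ValueError("filtration must be non-negative")
    energies = np.arange(e_min_kev, np.floor(kvp) + 1.0)
    fluence = np.clip(kvp - energies, 0.0, None) / energies
    if kvp > _W_K_EDGE_KEV:
        line_total = _K_LINE_FRACTION * fluence.sum()
        weight_sum = sum(w for _, w in _W_K_LINES)
        for e_line, w in _W_K_LINES:
            idx = int(np.argmin(np.abs(energies - e_line)))
            fluence[idx] += line_total * w / weight_sum
    if filtration_mm_al > 0:
        mu_al = attenuation_coefficient(
            "aluminum", get_material("aluminum").density, energies
        )  # 1/mm
        fluence = fluence * np.exp(-mu_al * filtration_mm_al)
    return Spectrum(energies, fluence)


# ---------------------------------------------------------------------------
# HU mapping
# ---------------------------------------------------------------------------

# 4-segment Hounsfield scheme: thresholds (upper edge, material) and a
# continuous piecewise-linear density ramp.  The ramp slope of 1e-3 g/cm^3 per
# HU reproduces the water convention (HU 0 -> 1.00 g/cm^3); the bone segment
# flattens to 5e-4 per HU, continuous at HU 120.
_HU_AIR_UPPER = -850.0
_HU_LUNG_UPPER = -100.0
_HU_SOFT_UPPER = 120.0
_BONE_SLOPE = 5.0e-4


def hu_to_material(hu):
    """Map Hounsfield units to (material name(s), density g/cm^3).

    Scalar in, scalar out; array in, (array of names, array of densities).
    Values outside [-1024, 3071] are clamped with a warning.
    """
    arr = np.asarray(hu, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any(arr < HU_MIN) or np.any(arr > HU_MAX):
        logger.warning("HU values outside [%d, %d] clamped", HU_MIN, HU_MAX)
        arr = np.clip(arr, HU_MIN, HU_MAX)

    names = np.empty(arr.shape, dtype=object)
    dens = np.empty(arr.shape, dtype=float)

    m_air = arr < _HU_AIR_UPPER
    m_lung = (arr >= _HU_AIR_UPPER) & (arr < _HU_LUNG_UPPER)
    m_soft = (arr >= _HU_LUNG_UPPER) & (arr < _HU_SOFT_UPPER)
    m_bone = arr >= _HU_SOFT_UPPER

    names[m_air] = "air"
    dens[m_air] = get_material("air").density
    names[m_lung] = "lung"
    dens[m_lung] = 1.0 + arr[m_lung] / 1000.0
    names[m_soft] = "soft_tissue"
    dens[m_soft] = 1.0 + arr[m_soft] / 1000.0
    names[m_bone] = "bone_cortical"
    dens[m_bone] = (1.0 + _HU_SOFT_UPPER / 1000.0) + _BONE_SLOPE * (
        arr[m_bone] - _HU_SOFT_UPPER
    )

    if scalar:
        return str(names[0]), float(dens[0])
    return names, dens


def material_to_hu(name: str, density: float) -> float:
    """Inverse of :func:`hu_to_material` for HU-representable materials."""
    if name == "air":
        return -1000.0
    if name in ("lung", "soft_tissue"):
        return (density - 1.0) * 1000.0
    if name == "bone_cortical":
        return _HU_SOFT_UPPER + (density - (1.0 + _HU_SOFT_UPPER / 1000.0)) / _BONE_SLOPE
    raise ValueError(f"material {name!r} has no Hounsfield representation")
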