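"""Cross-section preparation for the photon transport engine.

Builds, on a uniform 1 keV grid, per-material linear-attenuation data and
Klein-Nishina sampling tables shared by the Monte Carlo kernel and the
deterministic primary ray-trace:

* ``mu_rho``      — total mass attenuation (cm^2/g), from the bundled tables
* ``p_compton``   — probability that an interaction is incoherent scattering
  (Klein-Nishina free-electron cross section over the total); the remainder
  is treated as local absorption (photoelectric, with coherent folded in)
* ``invcdf_cost`` — inverse CDF of the KN scattering-angle distribution
* ``mean_eps``    — mean scattered-energy fraction per Compton event

Using one shared table set guarantees that the deterministic primary path
converges to the Monte Carlo primary estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import Spectrum, get_material

ELECTRON_REST_KEV = 511.0
R_E_SQ_CM2 = 7.94079e-26  # classical electron radius squared
N_AVOGADRO = 6.02214076e23

E_GRID_MIN_KEV = 10.0
E_GRID_MAX_KEV = 300.0
N_COST_QUANTILES = 256


def _kn_angular(k: float, cost: np.ndarray) -> np.ndarray:
    """Unnormalized Klein-Nishina dsigma/dcos(theta) at reduced energy k."""
    eps = 1.0 / (1.0 + k * (1.0 - cost))
    return eps * eps * (eps + 1.0 / eps - (1.0 - cost * cost))


@dataclass(frozen=True)
class CrossSections:
    """Per-material tables on a uniform 1 keV energy grid."""

    e0_kev: float
    energies_kev: np.ndarray  # (n_e,)
    materials: tuple[str, ...]
    mu_rho: np.ndarray  # (n_mat, n_e) cm^2/g, total
    p_compton: np.ndarray  # (n_mat, n_e)
    invcdf_cost: np.ndarray  # (n_e, N_COST_QUANTILES)
    mean_eps: np.ndarray  # (n_e,) mean E'/E per Compton event
    transfer_frac: np.ndarray  # (n_mat, n_e) expected dE/E per interaction

    def energy_index(self, energy_kev) -> np.ndarray:
        idx = np.asarray(energy_kev) - self.e0_kev
        return np.clip(idx.astype(int), 0, self.energies_kev.size - 1)


def build_cross_sections(material_names: tuple[str, ...]) -> CrossSections:
    e = np.arange(E_GRID_MIN_KEV, E_GRID_MAX_KEV + 1.0)
    n_e = e.size
    n_mat = len(material_names)

    # KN per-electron total cross section, angular inverse CDF, mean eps
    cost = np.linspace(-1.0, 1.0, 2001)
    sigma_kn = np.empty(n_e)
    mean_eps = np.empty(n_e)
    invcdf = np.empty((n_e, N_COST_QUANTILES))
    q = np.linspace(0.0, 1.0, N_COST_QUANTILES)
    for i, ek in enumerate(e):
        k = ek / ELECTRON_REST_KEV
        pdf = _kn_angular(k, cost)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(cost))])
        total = cdf[-1]
        sigma_kn[i] = np.pi * R_E_SQ_CM2 * total
        eps = 1.0 / (1.0 + k * (1.0 - cost))
        w = pdf / total
        mean_eps[i] = np.trapezoid(eps * w, cost)
        invcdf[i] = np.interp(q, cdf / total, cost)

    mu_rho = np.empty((n_mat, n_e))
    p_comp = np.empty((n_mat, n_e))
    for m, name in enumerate(material_names):
        mat = get_material(name)
        mu_rho[m] = mat.mass_attenuation(e)
        kn_mass = sigma_kn * N_AVOGADRO * mat.z_over_a  # cm^2/g
        p_comp[m] = np.clip(kn_mass / mu_rho[m], 0.0, 1.0)

    transfer = p_comp * (1.0 - mean_eps)[None, :] + (1.0 - p_comp) * 1.0
    return CrossSections(
        e0_kev=E_GRID_MIN_KEV,
        energies_kev=e,
        materials=tuple(material_names),
        mu_rho=mu_rho,
        p_compton=p_comp,
        invcdf_cost=invcdf,
        mean_eps=mean_eps,
        transfer_frac=transfer,
    )


def spectrum_sampling_tables(spectrum: Spectrum) -> tuple[np.ndarray, np.ndarray]:
    """(cumulative fluence, energies) for inverse-CDF spectrum sampling."""
    cdf = np.cumsum(spectrum.fluence)
    cdf = cdf / cdf[-1]
    return cdf, np.asarray(spectrum.energies_kev, dtype=np.float64)
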