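"""Macroscopic photon dose on the voxel grid, split into primary and scatter.

The Monte Carlo stage scores the energy transferred at photon interaction
sites locally (kerma approximation) — electron transport is deferred to the
micrometer-scale convolution stage.  First interactions score to
``d_primary``, all later ones to ``d_scatter``.  The microbeam structure is
not simulated here: the fluence is scaled by the field-averaged collimator
transmittance, matching the unit-period-mean normalization of the fluence
pattern, so ``d_primary`` is the period-averaged primary dose per voxel.

Doses are reported in keV/g per unit primary fluence at the collimator plane
(photons/cm^2), which makes results comparable across field sizes at fixed
tube output; the absolute Gy/min scale enters later through a single machine
output factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._mc import transport
from ._xs import CrossSections, build_cross_sections, spectrum_sampling_tables
from .beam_geometry import BeamGeometry
from .materials import Spectrum
from .phantom import VoxelPhantom

#: default collimator-to-phantom air gap (mm); the bed design constrains >= 4
DEFAULT_GAP_MM = 4.0

_CUTOFF_KEV = 10.0


@dataclass
class PhotonDoseGrid:
    """Per-voxel dose split into primary and scatter components."""

    d_primary: np.ndarray  # keV/g per unit collimator-plane fluence
    d_scatter: np.ndarray
    n_histories: int
    seed: int | None
    voxel_size_mm: float
    gap_mm: float
    statistical_uncertainty: np.ndarray | None = None  # relative sigma
    meta: dict = field(default_factory=dict)

    @property
    def d_total(self) -> np.ndarray:
        return self.d_primary + self.d_scatter

    def entrance_distance_mm(self, geometry: BeamGeometry) -> float:
        return geometry.sd_mm + self.gap_mm

    def plane_distance_mm(self, geometry: BeamGeometry, iz: int) -> float:
        """Source distance of slice ``iz``'s center."""
        return self.entrance_distance_mm(geometry) + (iz + 0.5) * self.voxel_size_mm


def _phantom_xs(phantom: VoxelPhantom) -> CrossSections:
    if not phantom.materials:
        raise ValueError("phantom declares no materials")
    return build_cross_sections(tuple(phantom.materials))


def _majorant(phantom: VoxelPhantom, xs: CrossSections) -> np.ndarray:
    """Per-energy majorant linear attenuation over the phantom (1/mm)."""
    mu_max = np.zeros(xs.energies_kev.size)
    for m in range(len(xs.materials)):
        mask = phantom.material_id == m
        if not mask.any():
            continue
        rho_max = float(phantom.density[mask].max())
        mu_max = np.maximum(mu_max, rho_max * xs.mu_rho[m] * 0.1)
    return mu_max


def _voxel_mass_g(phantom: VoxelPhantom) -> np.ndarray:
    v_cm3 = (phantom.voxel_size_mm / 10.0) ** 3
    return np.maximum(phantom.density, 1e-12) * v_cm3


def simulate_photon_dose(
    phantom: VoxelPhantom,
    geometry: BeamGeometry,
    spectrum: Spectrum,
    n_histories: int,
    seed: int,
    gap_mm: float = DEFAULT_GAP_MM,
    n_batches: int = 1,
) -> PhotonDoseGrid:
    """Monte Carlo photon dose with a primary/scatter split.

    Reproducibility contract: identical inputs and seed give bit-identical
    grids.  With ``n_batches > 1`` the run is split into equal batches with
    derived seeds and a per-voxel relative standard error of the total dose
    is estimated from the batch spread.
    """
    if phantom.material_id.size == 0:
        raise ValueError("empty phantom")
    if n_histories < 1:
        raise ValueError("need at least one history")
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")

    xs = _phantom_xs(phantom)
    mu_max = _majorant(phantom, xs)
    spec_cdf, spec_e = spectrum_sampling_tables(spectrum)
    nz, ny, nx = phantom.shape
    v = phantom.voxel_size_mm
    z0 = geometry.sd_mm + gap_mm
    y0 = -0.5 * ny * v
    x0 = -0.5 * nx * v

    w0 = geometry.mean_transmittance(spectrum.effective_energy_kev())
    mass = _voxel_mass_g(phantom)

    density = np.ascontiguousarray(phantom.density, dtype=np.float64)
    mat_id = np.ascontiguousarray(phantom.material_id, dtype=np.int16)

    def _run(n, s):
        ep = np.zeros(phantom.shape)
        es = np.zeros(phantom.shape)
        totals = transport(
            density,
            mat_id,
            v,
            z0,
            y0,
            x0,
            geometry.focal_spot.sigma,
            geometry.sd_mm,
            geometry.field_mm[0],
            geometry.field_mm[1],
            spec_cdf,
            spec_e,
            xs.e0_kev,
            xs.mu_rho,
            xs.p_compton,
            xs.invcdf_cost,
            mu_max,
            n,
            s,
            _CUTOFF_KEV,
            ep,
            es,
        )
        return ep, es, totals

    if n_batches <= 1:
        edep_p, edep_s, totals = _run(n_histories, seed)
        rel_sigma = None
    else:
        per = n_histories // n_batches
        batch_tot = []
        edep_p = np.zeros(phantom.shape)
        edep_s = np.zeros(phantom.shape)
        totals = (0.0, 0.0, 0.0, 0.0)
        for b in range(n_batches):
            # derived batch seeds, kept below 2**31
            ep, es, t = _run(per, (seed * 1000003 + b) % (2**31 - 1))
            edep_p += ep
            edep_s += es
            totals = tuple(a + x for a, x in zip(totals, t))
            batch_tot.append((ep + es) / max(per, 1))
        n_histories = per * n_batches
        stack = np.stack(batch_tot)
        mean = stack.mean(axis=0)
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n_batches)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_sigma = np.where(mean > 0, sem / mean, 0.0)

    # per unit primary fluence at the collimator plane (1/cm^2): one history
    # is one photon through the aperture, so multiply by the aperture area.
    # This makes doses comparable across field sizes at fixed machine output.
    aperture_cm2 = (geometry.field_mm[0] / 10.0) * (geometry.field_mm[1] / 10.0)
    scale = w0 * aperture_cm2 / (mass * n_histories)
    d_primary = edep_p * scale
    d_scatter = edep_s * scale
    e_emitted, e_entered, e_dep, e_exit = totals
    return PhotonDoseGrid(
        d_primary=d_primary,
        d_scatter=d_scatter,
        n_histories=n_histories,
        seed=seed,
        voxel_size_mm=v,
        gap_mm=gap_mm,
        statistical_uncertainty=rel_sigma,
        meta={
            "engine": "mc",
            "mean_transmittance": w0,
            "energy_emitted_kev": e_emitted,
            "energy_entered_kev": e_entered,
            "energy_deposited_kev": e_dep,
            "energy_exited_kev": e_exit,
        },
    )


def primary_dose_deterministic(
    phantom: VoxelPhantom,
    geometry: BeamGeometry,
    spectrum: Spectrum,
    gap_mm: float = DEFAULT_GAP_MM,
) -> np.ndarray:
    """Noise-free primary dose: polyenergetic Beer-Lambert ray trace.

    Attenuation along depth, inverse-square fluence weighting, and the same
    expected energy-transfer coefficient the Monte Carlo engine uses, so the
    two converge as the history count grows.  Returns keV/g per history.
    """
    xs = _phantom_xs(phantom)
    nz, ny, nx = phantom.shape
    v = phantom.voxel_size_mm
    z0 = geometry.sd_mm + gap_mm
    z_center = z0 + (np.arange(nz) + 0.5) * v  # (nz,)
    yc = (np.arange(ny) + 0.5 - ny / 2.0) * v
    xc = (np.arange(nx) + 0.5 - nx / 2.0) * v

    # per-material radiological depth to each voxel center, g/cm^2
    n_mat = len(xs.materials)
    radio = np.zeros((n_mat, nz, ny, nx))
    for m in range(n_mat):
        w = phantom.density * (phantom.material_id == m)
        c = np.cumsum(w, axis=0)
        radio[m] = (c - 0.5 * w) * v * 0.1  # mm -> cm

    # aperture mask (field magnified to each depth) and inverse square
    fx, fy = geometry.field_mm
    mag = z_center / geometry.sd_mm  # (nz,)
    in_x = np.abs(xc)[None, :] <= 0.5 * fx * mag[:, None]  # (nz, nx)
    in_y = np.abs(yc)[None, :] <= 0.5 * fy * mag[:, None]  # (nz, ny)
    aperture = in_y[:, :, None] & in_x[:, None, :]  # (nz, ny, nx)
    inv_sq = (geometry.sd_mm / z_center) ** 2  # (nz,)

    w0 = geometry.mean_transmittance(spectrum.effective_energy_kev())

    e_idx = xs.energy_index(spectrum.energies_kev)
    dose = np.zeros(phantom.shape)
    mat = phantom.material_id
    for w_e, ie in zip(spectrum.fluence, e_idx):
        if w_e == 0.0:
            continue
        e_kev = xs.energies_kev[ie]
        tau = np.zeros(phantom.shape)
        for m in range(n_mat):
            tau += xs.mu_rho[m, ie] * radio[m]
        # interaction coefficient x expected transferred fraction, per voxel
        mu_tr = xs.mu_rho[:, ie][mat] * xs.transfer_frac[:, ie][mat]  # cm^2/g
        dose += w_e * e_kev * mu_tr * np.exp(-tau)
    dose *= aperture * inv_sq[:, None, None] * w0
    return dose


def scatter_kernel_estimate(
    phantom: VoxelPhantom,
    geometry: BeamGeometry,
    spectrum: Spectrum,
    gap_mm: float = DEFAULT_GAP_MM,
) -> tuple[np.ndarray, dict]:
    """Deterministic single-scatter surrogate for the scatter dose.

    A depth-resolved estimate: the scattered energy released per slice
    (Compton events on the attenuated primary beam) is transported along the
    beam axis with a two-sided exponential deposition kernel at a
    representative scattered-photon energy, and spread uniformly over the
    beam cross-section.  Lower fidelity than the Monte Carlo path; the
    returned metadata flags it as approximate.
    """
    xs = _phantom_xs(phantom)
    nz, ny, nx = phantom.shape
    v = phantom.voxel_size_mm
    z0 = geometry.sd_mm + gap_mm
    z_center = z0 + (np.arange(nz) + 0.5) * v
    mat = phantom.material_id
    rho = phantom.density

    e_idx = xs.energy_index(spectrum.energies_kev)

    # mean density/material along the axis for the transport surrogate
    mean_rho = float(rho.mean())
    if mean_rho <= 0:
        return np.zeros(phantom.shape), {"engine": "scatter-kernel", "approximate": True}

    # scattered energy released per slice, keV per history entering the beam
    w0 = geometry.mean_transmittance(spectrum.effective_energy_kev())
    # slice-mean linear attenuation and Compton coefficients (1/mm)
    release = np.zeros(nz)
    e_scat_weighted = 0.0
    e_scat_norm = 0.0
    for w_e, ie in zip(spectrum.fluence, e_idx):
        if w_e == 0.0:
            continue
        e_kev = xs.energies_kev[ie]
        mu_slice = (rho * xs.mu_rho[:, ie][mat]).mean(axis=(1, 2)) * 0.1  # 1/mm
        mu_c_slice = (
            rho * (xs.mu_rho[:, ie] * xs.p_compton[:, ie])[mat]
        ).mean(axis=(1, 2)) * 0.1
        c = np.cumsum(mu_slice) - 0.5 * mu_slice
        attn = np.exp(-c * v)
        eps_mean = xs.mean_eps[ie]
        release += w_e * e_kev * eps_mean * attn * mu_c_slice * v
        e_scat_weighted += w_e * e_kev * eps_mean
        e_scat_norm += w_e
    # representative scattered-photon energy for re-absorption
    e_rep = max(e_scat_weighted / max(e_scat_norm, 1e-30), xs.e0_kev)
    ie_rep = int(np.clip(e_rep - xs.e0_kev, 0, xs.energies_kev.size - 1))
    mu_rho_mean = float(np.mean(xs.mu_rho[:, ie_rep][mat]))
    tf_mean = float(np.mean(xs.transfer_frac[:, ie_rep][mat]))
    mu_att = mean_rho * mu_rho_mean * 0.1  # 1/mm
    mu_ab = mu_att * tf_mean

    # two-sided exponential deposition along z; integral mu_ab/mu_att <= 1
    dz = (np.arange(nz)[:, None] - np.arange(nz)[None, :]) * v
    kern = 0.5 * mu_ab * np.exp(-mu_att * np.abs(dz)) * v
    edep_slice = kern @ release  # keV deposited per slice per history

    # spread uniformly over the magnified beam footprint
    fx, fy = geometry.field_mm
    mag = z_center / geometry.sd_mm
    dose = np.zeros(phantom.shape)
    yc = (np.arange(ny) + 0.5 - ny / 2.0) * v
    xc = (np.arange(nx) + 0.5 - nx / 2.0) * v
    for k in range(nz):
        in_x = np.abs(xc) <= 0.5 * fx * mag[k]
        in_y = np.abs(yc) <= 0.5 * fy * mag[k]
        area_mm2 = fx * mag[k] * fy * mag[k]
        sl = np.outer(in_y, in_x)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(
                sl & (rho[k] > 0),
                edep_slice[k] / np.maximum(rho[k] * area_mm2 * v * 1e-3, 1e-30),
                0.0,
            )
        dose[k] = d
    dose *= w0 * (fx / 10.0) * (fy / 10.0)  # per unit collimator-plane fluence
    meta = {
        "engine": "scatter-kernel",
        "approximate": True,
        "representative_scatter_energy_kev": e_rep,
    }
    return dose, meta
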