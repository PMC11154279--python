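"""End-to-end treatment planning: dose stages, ROI statistics, plan report.

``compute_plan`` runs the macroscopic photon stage over the phantom,
reconstructs the micrometer-scale profile per ROI slice, and aggregates
peak/valley statistics over the ROI.  Within one slice the reconstructed
profile is linear in the voxel's (primary, scatter) pair, so per-voxel peak
and valley doses follow exactly from the slice's normalized profile shape;
FWHM and measured ctc are evaluated at the slice level.

The absolute time scale enters through a single machine output factor
(Gy/min per engine dose unit), calibrated once against a measured reference
dose rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .beam_geometry import BeamGeometry
from .materials import Spectrum
from .microbeam import (
    Kernel1D,
    electron_kernel,
    profile_metrics,
    reconstruct_profile,
)
from .phantom import VoxelPhantom
from .photon_dose import (
    DEFAULT_GAP_MM,
    PhotonDoseGrid,
    primary_dose_deterministic,
    scatter_kernel_estimate,
    simulate_photon_dose,
)
from .radiobiology import equivalent_short_dose, lea_catcheside_g

#: motorized-stage travel range perpendicular to the beam, mm
STAGE_TRAVEL_MM = 50.0

#: exposures longer than this get a protraction (Lea-Catcheside) annotation
PROTRACTION_THRESHOLD_S = 600.0


class PlanningError(ValueError):
    pass


class StageTravelError(PlanningError):
    """Requested positioning offset exceeds the stage travel range."""


@dataclass
class Plan:
    """A treatment plan: geometry, target, prescription, and positioning."""

    geometry: BeamGeometry
    prescription_peak_dose_gy: float
    roi: str = "brain"
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    beam_offset_mm: tuple[float, float] = (0.0, 0.0)
    collimator_angle_deg: float = 0.0
    couch_angle_deg: float = 0.0
    gantry_angle_deg: float = 0.0

    def __post_init__(self):
        if self.prescription_peak_dose_gy <= 0:
            raise PlanningError("prescription must be positive")


@dataclass
class PlanReport:
    """ROI-averaged plan quantities and the derived irradiation time."""

    mean_peak_dose_rate: float  # Gy/min
    mean_valley_dose_rate: float  # Gy/min
    mean_pvdr: float  # mean of per-voxel ratios
    pvdr_of_means: float  # ratio of ROI-mean peak to ROI-mean valley
    mean_fwhm_um: float
    mean_ctc_um: float
    irradiation_time_s: float
    accumulated_valley_dose_gy: float
    prescription_peak_dose_gy: float
    positioning_offset_mm: tuple[float, float] = (0.0, 0.0)
    positioning_rotation_deg: float = 0.0
    n_roi_voxels: int = 0
    depth_table: pd.DataFrame | None = field(default=None, repr=False)
    protraction: dict | None = None
    output_factor: float = 1.0
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {
            "mean_peak_dose_rate_gy_per_min": self.mean_peak_dose_rate,
            "mean_valley_dose_rate_gy_per_min": self.mean_valley_dose_rate,
            "mean_pvdr": self.mean_pvdr,
            "pvdr_of_means": self.pvdr_of_means,
            "mean_fwhm_um": self.mean_fwhm_um,
            "mean_ctc_um": self.mean_ctc_um,
            "irradiation_time_s": self.irradiation_time_s,
            "irradiation_time_rounded_s": round(self.irradiation_time_s),
            "accumulated_valley_dose_gy": self.accumulated_valley_dose_gy,
            "prescription_peak_dose_gy": self.prescription_peak_dose_gy,
            "positioning_offset_mm": list(self.positioning_offset_mm),
            "positioning_rotation_deg": self.positioning_rotation_deg,
            "n_roi_voxels": self.n_roi_voxels,
            "protraction": self.protraction,
            "seed": self.seed,
        }
        return d


def report_from_rates(
    peak_rate_gy_min: float,
    valley_rate_gy_min: float,
    prescription_gy: float,
    **kwargs,
) -> PlanReport:
    """Build the derived plan quantities from given ROI-mean dose rates.

    Encapsulates the report arithmetic: irradiation time from the
    prescription and peak rate, accumulated valley dose from the valley rate
    over that time, and the PVDR of the means.
    """
    if peak_rate_gy_min <= 0:
        raise PlanningError("peak dose rate must be positive")
    time_s = prescription_gy / peak_rate_gy_min * 60.0
    valley_dose = valley_rate_gy_min * time_s / 60.0
    return PlanReport(
        mean_peak_dose_rate=peak_rate_gy_min,
        mean_valley_dose_rate=valley_rate_gy_min,
        mean_pvdr=kwargs.pop("mean_pvdr", peak_rate_gy_min / valley_rate_gy_min),
        pvdr_of_means=peak_rate_gy_min / valley_rate_gy_min,
        mean_fwhm_um=kwargs.pop("mean_fwhm_um", float("nan")),
        mean_ctc_um=kwargs.pop("mean_ctc_um", float("nan")),
        irradiation_time_s=time_s,
        accumulated_valley_dose_gy=valley_dose,
        prescription_peak_dose_gy=prescription_gy,
        **kwargs,
    )


def _slice_profile_shape(geometry, kernel, y_mm, energy_kev):
    """Normalized profile shape A(x) (unit period mean) and its metrics."""
    prof = reconstruct_profile(
        1.0, 0.0, geometry, kernel, y_mm, energy_kev=energy_kev
    )
    return prof


def compute_plan(
    phantom: VoxelPhantom,
    plan: Plan,
    spectrum: Spectrum,
    kernel: Kernel1D | None = None,
    n_histories: int = 200_000,
    seed: int = 1,
    gap_mm: float = DEFAULT_GAP_MM,
    engine: str = "mc",
    output_factor: float = 1.0,
    home_point_mm: tuple[float, float] = (0.0, 0.0),
) -> PlanReport:
    """Run both dose stages over the phantom and aggregate ROI statistics.

    ``output_factor`` converts engine dose units (keV/g per history) to
    Gy/min — the machine calibration constant.
    """
    geometry = plan.geometry
    if plan.roi not in phantom.roi:
        raise PlanningError(
            f"ROI {plan.roi!r} not defined on phantom; has {list(phantom.roi)}"
        )
    if plan.couch_angle_deg % 360.0 or plan.gantry_angle_deg % 360.0:
        from .phantom import resample_rotated

        phantom = resample_rotated(
            phantom, plan.couch_angle_deg, plan.gantry_angle_deg
        )
    roi_mask = np.asarray(phantom.roi[plan.roi], bool)
    if not roi_mask.any():
        raise PlanningError("ROI is empty")

    dose = compute_dose(
        phantom, geometry, spectrum, n_histories=n_histories, seed=seed,
        gap_mm=gap_mm, engine=engine,
    )
    _check_roi_in_beam(phantom, geometry, roi_mask, plan.beam_offset_mm, gap_mm)

    if kernel is None:
        roi_density = float(phantom.density[roi_mask].mean())
        kernel = electron_kernel(spectrum, roi_density)
    e_eff = spectrum.effective_energy_kev()

    peaks, valleys, fwhms, ctcs, pvdrs = [], [], [], [], []
    for iz in np.unique(np.nonzero(roi_mask)[0]):
        sl = roi_mask[iz]
        y = dose.plane_distance_mm(geometry, int(iz))
        shape = _slice_profile_shape(geometry, kernel, y, e_eff)
        m = profile_metrics(shape, expected_period_um=geometry.projected_ctc_um(y))
        dp = dose.d_primary[iz][sl]
        # scatter is laterally smooth within a slice; use the slice-ROI mean
        # so Monte Carlo noise does not leak into per-voxel valley doses
        ds = float(dose.d_scatter[iz][sl].mean())
        pk = dp * m.peak_dose + ds
        vl = dp * m.valley_dose + ds
        peaks.extend(pk)
        valleys.extend(vl)
        pvdrs.extend(pk / vl)
        fwhms.extend([m.fwhm_um] * dp.size)
        ctcs.extend([m.ctc_measured_um] * dp.size)

    mean_peak = float(np.mean(peaks)) * output_factor
    mean_valley = float(np.mean(valleys)) * output_factor
    report = report_from_rates(
        mean_peak,
        mean_valley,
        plan.prescription_peak_dose_gy,
        mean_pvdr=float(np.mean(pvdrs)),
        mean_fwhm_um=float(np.mean(fwhms)),
        mean_ctc_um=float(np.mean(ctcs)),
        n_roi_voxels=int(roi_mask.sum()),
        output_factor=output_factor,
        seed=seed,
    )
    off = positioning_offsets(plan, home_point_mm)
    report.positioning_offset_mm = (off[0], off[1])
    report.positioning_rotation_deg = off[2]
    if report.irradiation_time_s > PROTRACTION_THRESHOLD_S:
        t_h = report.irradiation_time_s / 3600.0
        g = lea_catcheside_g(0.5, t_h)
        report.protraction = {
            "exposure_time_h": t_h,
            "repair_rate_per_h": 0.5,
            "lea_catcheside_g": g,
            "equivalent_short_peak_dose_gy": equivalent_short_dose(
                plan.prescription_peak_dose_gy, g, 2.0
            ),
            "equivalent_short_valley_dose_gy": equivalent_short_dose(
                report.accumulated_valley_dose_gy, g, 2.0
            ),
        }
    return report


def compute_dose(
    phantom: VoxelPhantom,
    geometry: BeamGeometry,
    spectrum: Spectrum,
    n_histories: int = 200_000,
    seed: int = 1,
    gap_mm: float = DEFAULT_GAP_MM,
    engine: str = "mc",
) -> PhotonDoseGrid:
    """Run the macroscopic stage with the chosen engine."""
    if engine == "mc":
        return simulate_photon_dose(
            phantom, geometry, spectrum, n_histories, seed, gap_mm=gap_mm
        )
    if engine == "deterministic":
        dp = primary_dose_deterministic(phantom, geometry, spectrum, gap_mm=gap_mm)
        ds, meta = scatter_kernel_estimate(phantom, geometry, spectrum, gap_mm=gap_mm)
        return PhotonDoseGrid(
            d_primary=dp,
            d_scatter=ds,
            n_histories=0,
            seed=seed,
            voxel_size_mm=phantom.voxel_size_mm,
            gap_mm=gap_mm,
            meta={"engine": "deterministic", "scatter": meta},
        )
    raise ValueError(f"unknown engine {engine!r}")


def _check_roi_in_beam(phantom, geometry, roi_mask, beam_offset, gap_mm):
    v = phantom.voxel_size_mm
    nz, ny, nx = phantom.shape
    izs, iys, ixs = np.nonzero(roi_mask)
    yc = (iys + 0.5 - ny / 2.0) * v - beam_offset[1]
    xc = (ixs + 0.5 - nx / 2.0) * v - beam_offset[0]
    z = geometry.sd_mm + gap_mm + (izs + 0.5) * v
    mag = z / geometry.sd_mm
    fx, fy = geometry.field_mm
    bad = (np.abs(xc) > 0.5 * fx * mag) | (np.abs(yc) > 0.5 * fy * mag)
    if bad.any():
        i = int(np.argmax(bad))
        raise PlanningError(
            f"ROI extends outside the beam: voxel {(izs[i], iys[i], ixs[i])} at "
            f"lateral ({xc[i]:.1f}, {yc[i]:.1f}) mm vs field "
            f"{0.5 * fx * mag[i]:.1f} x {0.5 * fy * mag[i]:.1f} mm half-aperture"
        )


def depth_dose_report(
    dose: PhotonDoseGrid,
    geometry: BeamGeometry,
    phantom: VoxelPhantom,
    kernel: Kernel1D | None = None,
    spectrum: Spectrum | None = None,
    central_fraction: float = 0.5,
    smooth_slices: int = 3,
) -> pd.DataFrame:
    """Per-depth peak/valley/PVDR/FWHM/ctc table along the beam axis.

    The macroscopic components are averaged over the central
    ``central_fraction`` of the beam footprint in each slice (suppressing
    Monte Carlo noise), the profile is reconstructed at the slice's source
    distance, and valley local maxima are annotated in
    ``df.attrs["valley_maxima_depth_mm"]``.
    """
    nz, ny, nx = dose.d_primary.shape
    v = dose.voxel_size_mm
    if kernel is None:
        kernel = electron_kernel(spectrum, float(phantom.density.mean()))
    e_eff = spectrum.effective_energy_kev() if spectrum is not None else None

    yc = (np.arange(ny) + 0.5 - ny / 2.0) * v
    xc = (np.arange(nx) + 0.5 - nx / 2.0) * v
    fx, fy = geometry.field_mm

    rows = []
    for iz in range(nz):
        y = dose.plane_distance_mm(geometry, iz)
        mag = y / geometry.sd_mm
        half_x = 0.5 * fx * mag * central_fraction
        half_y = 0.5 * fy * mag * central_fraction
        sel = np.outer(np.abs(yc) <= half_y, np.abs(xc) <= half_x)
        if not sel.any():
            continue
        dp = float(dose.d_primary[iz][sel].mean())
        ds = float(dose.d_scatter[iz][sel].mean())
        shape = _slice_profile_shape(geometry, kernel, y, e_eff)
        m = profile_metrics(shape, expected_period_um=geometry.projected_ctc_um(y))
        peak = dp * m.peak_dose + ds
        valley = dp * m.valley_dose + ds
        rows.append(
            {
                "depth_mm": (iz + 0.5) * v,
                "peak": peak,
                "valley": valley,
                "pvdr": peak / valley if valley > 0 else math.inf,
                "fwhm_um": m.fwhm_um,
                "ctc_um": m.ctc_measured_um,
            }
        )
    df = pd.DataFrame(rows)
    valley = df["valley"].to_numpy()
    if smooth_slices > 1:
        k = np.ones(smooth_slices) / smooth_slices
        pad = smooth_slices // 2
        padded = np.concatenate(
            [np.full(pad, valley[0]), valley, np.full(pad, valley[-1])]
        )
        valley_s = np.convolve(padded, k, mode="valid")
    else:
        valley_s = valley
    df["valley_smoothed"] = valley_s
    # interior local maxima, ranked by prominence against residual MC noise
    maxima, _ = find_peaks(valley_s, prominence=0.05 * float(np.ptp(valley_s)))
    interior = maxima[(maxima > 0) & (maxima < len(df) - 1)]
    df.attrs["valley_maxima_depth_mm"] = [
        float(df["depth_mm"].iloc[i]) for i in interior
    ]
    return df


def positioning_offsets(
    plan: Plan, home_point_mm: tuple[float, float] = (0.0, 0.0)
) -> tuple[float, float, float]:
    """Stage shifts (dx, dy) in mm and rotation (deg) mapping the planned
    beam center onto the home point (the laser cross).

    Raises :class:`StageTravelError` beyond the 50 mm stage travel.
    """
    dx = plan.beam_offset_mm[0] + plan.isocenter_mm[0] - home_point_mm[0]
    dy = plan.beam_offset_mm[1] + plan.isocenter_mm[1] - home_point_mm[1]
    rot = plan.couch_angle_deg % 360.0
    if abs(dx) > STAGE_TRAVEL_MM or abs(dy) > STAGE_TRAVEL_MM:
        raise StageTravelError(
            f"offset ({dx:.1f}, {dy:.1f}) mm exceeds the {STAGE_TRAVEL_MM:.0f} mm "
            "stage travel"
        )
    return (dx, dy, rot)
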