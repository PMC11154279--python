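"""Source and film calibration.

Two fits live here:

* the effective focal-spot width ``sigma`` — adjusted until calculated
  micrometer-scale dose profiles match measured ones (radiochromic film).
  Per-profile amplitude scaling decouples the shape calibration from the
  absolute dose scale, which is carried by the machine output factor.
* the radiochromic film response ``D(gv) = a + b/(gv + c)`` mapping scanner
  gray values to dose over the fitted 0-10 Gy range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .beam_geometry import BeamGeometry
from .microbeam import Kernel1D, reconstruct_profile

SIGMA_BOUNDS_MM = (0.05, 3.0)


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MeasuredProfile:
    """A measured lateral dose profile at one depth."""

    positions_um: np.ndarray
    values: np.ndarray  # dose (Gy) or film gray value
    depth_mm: float
    label: str = ""

    def __post_init__(self):
        x = np.asarray(self.positions_um, float)
        if np.any(np.diff(x) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass(frozen=True)
class SigmaFit:
    sigma_mm: float
    sigma_interval_mm: tuple[float, float]
    residual_rms: float
    objective_trace: tuple  # (sigma, objective) pairs visited


def _profile_residual(
    sigma: float,
    measured: list[MeasuredProfile],
    geometry: BeamGeometry,
    kernel: Kernel1D,
    dose_pairs: list[tuple[float, float]],
    gap_mm: float,
) -> float:
    geom = geometry.with_sigma(sigma)
    total = 0.0
    for prof, (dp, ds) in zip(measured, dose_pairs):
        y = geometry.sd_mm + gap_mm + prof.depth_mm
        span = (prof.positions_um[-1] - prof.positions_um[0]) / 1000.0
        sim = reconstruct_profile(
            dp, ds, geom, kernel, y, x_span_mm=span * 1.05
        )
        model = np.interp(prof.positions_um, sim.positions_um, sim.dose)
        meas = np.asarray(prof.values, float)
        # per-profile amplitude scaling (least-squares optimal)
        denom = float(model @ model)
        if denom == 0:
            return np.inf
        scale = float(model @ meas) / denom
        total += float(np.sum((scale * model - meas) ** 2))
    return total


def fit_focal_spot_sigma(
    measured: list[MeasuredProfile],
    geometry: BeamGeometry,
    kernel: Kernel1D,
    dose_pairs: list[tuple[float, float]] | None = None,
    gap_mm: float = 4.0,
) -> SigmaFit:
    """Bounded 1D least-squares fit of the effective focal-spot sigma.

    ``dose_pairs`` supplies (d_primary, d_scatter) per profile from the
    macroscopic dose engine; when omitted, a pure-primary shape fit is done
    (adequate because of the per-profile amplitude scaling).

    Returns the argmin with a curvature-based confidence interval.
    """
    if not measured:
        raise ValueError("need at least one measured profile")
    if dose_pairs is None:
        dose_pairs = [(1.0, 0.0)] * len(measured)

    trace: list[tuple[float, float]] = []

    def obj(s: float) -> float:
        val = _profile_residual(s, measured, geometry, kernel, dose_pairs, gap_mm)
        trace.append((s, val))
        return val

    res = minimize_scalar(
        obj, bounds=SIGMA_BOUNDS_MM, method="bounded", options={"xatol": 1e-4}
    )
    if not res.success:
        raise CalibrationError(
            f"sigma fit failed: {res.message}; trace={trace}"
        )
    sigma = float(res.x)
    n_pts = sum(len(p.values) for p in measured)
    rms = float(np.sqrt(res.fun / n_pts))

    # curvature-based interval: f(s) ~ f0 + 0.5 f'' (s - s0)^2, the 1-sigma
    # parameter scale is where the residual grows by one mean-squared unit
    h = max(0.02 * sigma, 1e-3)
    f0 = res.fun
    fp = obj(min(sigma + h, SIGMA_BOUNDS_MM[1]))
    fm = obj(max(sigma - h, SIGMA_BOUNDS_MM[0]))
    curv = (fp - 2 * f0 + fm) / h**2
    if curv > 0:
        half_width = float(np.sqrt(2.0 * max(f0, 1e-30) / n_pts / curv))
    else:
        half_width = float("nan")
    return SigmaFit(
        sigma_mm=sigma,
        sigma_interval_mm=(sigma - half_width, sigma + half_width),
        residual_rms=rms,
        objective_trace=tuple(trace),
    )


# ---------------------------------------------------------------------------
# Film calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilmCalibration:
    """Fitted film response D(gv) = a + b/(gv + c)."""

    a: float
    b: float
    c: float
    gray_range: tuple[float, float]
    dose_range: tuple[float, float] = (0.0, 10.0)
    fit_residual_rms: float = 0.0

    def dose(self, gray_values, clamp: bool = True):
        """Evaluate the calibration; out-of-range inputs are flagged.

        Returns ``(doses, out_of_range_mask)``.
        """
        gv = np.asarray(gray_values, float)
        lo, hi = self.gray_range
        out = (gv < lo) | (gv > hi)
        if clamp:
            gv = np.clip(gv, lo, hi)
        elif out.any():
            raise ValueError("gray values outside the fitted range")
        return self.a + self.b / (gv + self.c), out


def _film_model(gv, a, b, c):
    return a + b / (gv + c)


def fit_film_calibration(
    doses_gy: np.ndarray, gray_values: np.ndarray
) -> FilmCalibration:
    """Nonlinear least-squares fit of the film gray-value-to-dose curve."""
    d = np.asarray(doses_gy, float)
    gv = np.asarray(gray_values, float)
    if d.size < 4:
        raise ValueError("need at least 4 calibration points")
    if np.ptp(gv) == 0:
        raise CalibrationError("degenerate calibration: constant gray values")
    if np.any(d < 0) or np.any(d > 10.0):
        raise ValueError("calibration doses must lie in the fitted (0-10) Gy range")

    # initial guess: dose decreases with gray value, hyperbolic in gv
    c0 = -gv.min() + 0.5 * np.ptp(gv)
    b0 = (d.max() - d.min()) * np.ptp(gv)
    a0 = d.min()
    popt, _ = curve_fit(
        _film_model, gv, d, p0=(a0, b0, c0), maxfev=20000
    )
    resid = d - _film_model(gv, *popt)
    cal = FilmCalibration(
        a=float(popt[0]),
        b=float(popt[1]),
        c=float(popt[2]),
        gray_range=(float(gv.min()), float(gv.max())),
        fit_residual_rms=float(np.sqrt(np.mean(resid**2))),
    )
    # monotonicity over the fitted range (dose must decrease with gray value)
    span = np.linspace(cal.gray_range[0], cal.gray_range[1], 101)
    vals, _ = cal.dose(span)
    if not (np.all(np.diff(vals) < 0) or np.all(np.diff(vals) > 0)):
        raise CalibrationError("fitted film curve is not monotone over range")
    return cal


def apply_film_calibration(calibration: FilmCalibration, gray_values):
    """Vectorized evaluation of the fitted curve; flags out-of-range input."""
    return calibration.dose(gray_values, clamp=True)
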