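"""Divergent-source beam model: focal spot, multislit collimator, fluence.

The geometry is a point/extended source at the origin, a multislit collimator
at distance ``sd`` along the beam axis, and target planes at distances
``y > sd``.  Lateral coordinates are in mm: ``x'`` in the source plane, ``x''``
in the collimator plane, ``x`` in the target plane.

The primary-fluence pattern at a target plane is the integral over the focal
spot of the collimator transmittance seen along each ray,

    theta(x) = ∫ f_s(x') f_c(x''(x, x')) dx' ,

with x''(x, x') = x' (1 − sd/y) + x sd/y.  Equivalently it is the convolution
of a magnified transmittance ``f_c(x sd/y)`` with a rescaled focal-spot
function ``f_s(x / (1 − y/sd))`` — for ``y > sd`` the rescaling factor is
negative, i.e. the source is projected mirrored and stretched by
``(y − sd)/sd``.  Both code paths are provided and must agree.

Fluence patterns are normalized to unit mean over one projected period, so the
period-averaged primary dose in a voxel equals ``D_primary`` and the
period-mean of the reconstructed microbeam profile is ``D_primary +
D_scatter``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .materials import attenuation_coefficient, get_material

#: FWTM of a unit-sigma Gaussian: full width at 10% of maximum.
FWTM_FACTOR = math.sqrt(8.0 * math.log(10.0))

#: No-overlap sentinel returned by :func:`penumbra_overlap_depth`.
NO_OVERLAP = math.inf


class GeometryError(ValueError):
    """Invalid beam-geometry parameter."""


@dataclass(frozen=True)
class FocalSpot:
    """Gaussian focal spot; ``sigma`` is the standard deviation in mm."""

    sigma: float = 0.58

    def __post_init__(self):
        if self.sigma < 0:
            raise GeometryError("focal-spot sigma must be non-negative")

    @property
    def fwtm_mm(self) -> float:
        return fwtm_from_sigma(self.sigma)


@dataclass(frozen=True)
class Collimator:
    """Multislit collimator: periodic slits in a thick absorber.

    ``leakage`` is the transmitted fraction through a septum; ``None`` means
    "compute from the bundled absorber attenuation table at use time".
    """

    slit_width_um: float = 30.0
    ctc_um: float = 400.0
    septum_thickness_mm: float = 7.0
    septum_material: str = "tungsten"
    leakage: float | None = None

    def __post_init__(self):
        if not 0 < self.slit_width_um < self.ctc_um:
            raise GeometryError("need 0 < slit width < ctc")
        if self.leakage is not None and not 0 <= self.leakage < 1:
            raise GeometryError("leakage must lie in [0, 1)")

    @property
    def duty_cycle(self) -> float:
        return self.slit_width_um / self.ctc_um

    def septum_transmission(self, energy_kev: float) -> float:
        """Beer-Lambert transmission through one septum at ``energy_kev``."""
        mat = get_material(self.septum_material)
        mu = attenuation_coefficient(mat, mat.density, energy_kev)  # 1/mm
        return float(np.exp(-mu * self.septum_thickness_mm))

    def effective_leakage(self, energy_kev: float | None = None) -> float:
        if self.leakage is not None:
            return self.leakage
        if energy_kev is None:
            # without an energy the septa are treated as opaque — for 7 mm of
            # tungsten this is indistinguishable from the table value
            return 0.0
        return self.septum_transmission(energy_kev)


@dataclass(frozen=True)
class BeamGeometry:
    """Source, collimator, and field parameters of the divergent beam."""

    sd_mm: float = 212.0
    tilt_deg: float = 8.0  # metadata only; absorbed into the calibrated sigma
    field_mm: tuple[float, float] = (20.0, 20.0)  # at the collimator plane
    focal_spot: FocalSpot = field(default_factory=FocalSpot)
    collimator: Collimator = field(default_factory=Collimator)

    def __post_init__(self):
        if self.sd_mm <= 0:
            raise GeometryError("source-to-collimator distance must be positive")
        if any(f <= 0 for f in self.field_mm):
            raise GeometryError("field size must be positive")

    def with_sigma(self, sigma: float) -> "BeamGeometry":
        return replace(self, focal_spot=FocalSpot(sigma))

    def with_field(self, fx: float, fy: float) -> "BeamGeometry":
        return replace(self, field_mm=(fx, fy))

    def projected_ctc_um(self, y_mm: float) -> float:
        """Microbeam period at target distance ``y_mm`` from the source."""
        return self.collimator.ctc_um * magnification(self.sd_mm, y_mm - self.sd_mm)

    def mean_transmittance(self, energy_kev: float | None = None) -> float:
        """Field-averaged collimator transmittance (duty cycle + leakage)."""
        duty = self.collimator.duty_cycle
        leak = self.collimator.effective_leakage(energy_kev)
        return duty + (1.0 - duty) * leak


# ---------------------------------------------------------------------------
# Scalar geometric relations
# ---------------------------------------------------------------------------


def fwtm_from_sigma(sigma_mm: float) -> float:
    """Full width at 10% of maximum of a Gaussian with std ``sigma_mm``."""
    if sigma_mm < 0:
        raise GeometryError("sigma must be non-negative")
    return sigma_mm * FWTM_FACTOR


def sigma_from_fwtm(fwtm_mm: float) -> float:
    if fwtm_mm < 0:
        raise GeometryError("width must be non-negative")
    return fwtm_mm / FWTM_FACTOR


def magnification(sd_mm: float, delta_mm: float) -> float:
    """Projection factor (sd + delta)/sd by the intersecting-lines theorem.

    ``delta_mm`` is distance beyond the collimator plane; structures with
    period p at the collimator appear with period p * magnification at the
    plane ``delta_mm`` deeper.
    """
    if sd_mm <= 0:
        raise GeometryError("source-to-collimator distance must be positive")
    if delta_mm < -sd_mm:
        raise GeometryError("plane lies behind the source")
    return (sd_mm + delta_mm) / sd_mm


def source_profile(x_mm, focal_spot: FocalSpot) -> np.ndarray:
    """Normalized Gaussian intensity density of the focal spot (1/mm)."""
    if focal_spot.sigma == 0:
        raise GeometryError(
            "point source (sigma = 0) has no density; use the point-source path"
        )
    x = np.asarray(x_mm, dtype=float)
    s = focal_spot.sigma
    return np.exp(-0.5 * (x / s) ** 2) / (s * math.sqrt(2.0 * math.pi))


def _slit_cumulative(x: np.ndarray, slit: float, ctc: float) -> np.ndarray:
    """Total slit-open length on (-inf, x] for slits centered at k*ctc."""
    n = np.floor((x + 0.5 * ctc) / ctc)
    pos = x - n * ctc  # position within the period, in [-ctc/2, ctc/2)
    partial = np.clip(pos, -0.5 * slit, 0.5 * slit) + 0.5 * slit
    return n * slit + partial


def collimator_transmittance(
    x_mm,
    collimator: Collimator,
    field_width_mm: float,
    energy_kev: float | None = None,
    averaging_width_mm: float | None = None,
) -> np.ndarray:
    """Transmittance at collimator-plane coordinate ``x_mm``.

    1 inside a slit, the septum leakage inside a septum, 0 outside the field
    aperture.  Slit centers sit at integer multiples of ctc (one slit centered
    on the beam axis).

    With ``averaging_width_mm`` the exact mean transmittance over the cell
    ``[x - w/2, x + w/2]`` is returned (analytic slit-coverage fraction), which
    removes edge aliasing when the pattern is sampled on a discrete grid.
    """
    x = np.asarray(x_mm, dtype=float)
    ctc = collimator.ctc_um / 1000.0
    slit = collimator.slit_width_um / 1000.0
    leak = collimator.effective_leakage(energy_kev)
    half_ap = 0.5 * field_width_mm
    if averaging_width_mm is None or averaging_width_mm <= 0:
        phase = np.abs((x + 0.5 * ctc) % ctc - 0.5 * ctc)
        t = np.where(phase <= 0.5 * slit, 1.0, leak)
        return np.where(np.abs(x) <= half_ap, t, 0.0)
    h = 0.5 * averaging_width_mm
    cov_slit = (
        _slit_cumulative(x + h, slit, ctc) - _slit_cumulative(x - h, slit, ctc)
    ) / (2 * h)
    cov_ap = (
        np.minimum(x + h, half_ap) - np.maximum(x - h, -half_ap)
    ).clip(0.0) / (2 * h)
    # slit and aperture edges almost never share a cell; treat as independent
    return cov_ap * (leak + (1.0 - leak) * cov_slit)


def penumbra_overlap_depth(geometry: BeamGeometry) -> float:
    """Distance beyond the collimator where adjacent penumbras first meet.

    Solves  slit*(y/sd) + d*(y - sd)/sd = ctc*(y/sd)  for y, where ``d`` is
    the focal-spot FWTM: the projected slit plus the geometric penumbra first
    fills the projected period, after which valley dose rises from direct
    beam overlap.  Returns ``NO_OVERLAP`` (inf) when the focal spot is too
    small for a finite solution.
    """
    d = geometry.focal_spot.fwtm_mm
    ctc = geometry.collimator.ctc_um / 1000.0
    slit = geometry.collimator.slit_width_um / 1000.0
    if d <= ctc - slit:
        return NO_OVERLAP
    y_star = d * geometry.sd_mm / (d - ctc + slit)
    return y_star - geometry.sd_mm


# ---------------------------------------------------------------------------
# Fluence pattern at depth
# ---------------------------------------------------------------------------


def _normalize_period_mean(
    x_mm: np.ndarray,
    theta: np.ndarray,
    period_mm: float,
    half_window_mm: float | None = None,
) -> np.ndarray:
    """Scale so the mean over the central whole number of periods is 1.

    The averaging window never extends beyond ``half_window_mm`` (the
    projected aperture interior), so dark regions outside the field cannot
    bias the normalization.
    """
    half_span = 0.5 * (x_mm[-1] - x_mm[0])
    if half_window_mm is not None:
        half_span = min(half_span, half_window_mm)
    n_per = max(int(2.0 * half_span / period_mm), 1)
    half = 0.5 * n_per * period_mm
    mask = (x_mm >= -half) & (x_mm <= half)
    mean = theta[mask].mean()
    if mean <= 0:
        raise GeometryError("fluence pattern has non-positive period mean")
    return theta / mean


def fluence_pattern(
    x_mm,
    y_mm: float,
    geometry: BeamGeometry,
    energy_kev: float | None = None,
    method: str = "convolution",
    normalize: bool = True,
) -> np.ndarray:
    """Relative primary-fluence pattern theta(x) at target distance ``y_mm``.

    Parameters
    ----------
    x_mm : array
        Uniform target-plane lateral grid, pitch at most ~1 um recommended.
    y_mm : float
        Source-to-target distance; must be >= sd.  At ``y == sd`` the source
        blur vanishes and the pattern equals the aperture transmittance.
    method : "convolution" or "quadrature"
        Fast rescaled-convolution path, or direct numerical evaluation of the
        source-integral (slow; used as an independent cross-check).
    normalize : bool
        Scale to unit mean over the central whole number of projected periods.
    """
    x = np.asarray(x_mm, dtype=float)
    sd = geometry.sd_mm
    sigma = geometry.focal_spot.sigma
    fx = geometry.field_mm[0]
    coll = geometry.collimator
    if y_mm < sd:
        raise GeometryError("target plane must lie at or beyond the collimator")

    period = geometry.projected_ctc_um(y_mm) / 1000.0
    # keep the normalization window inside the magnified aperture, clear of
    # the source-blurred field edges
    sigma_proj = sigma * abs(y_mm - sd) / sd
    half_aperture = 0.5 * fx * (y_mm / sd) - 6.0 * sigma_proj - period

    def _finish(theta):
        if not normalize:
            return theta
        return _normalize_period_mean(x, theta, period, half_aperture)

    grid_pitch = float(x[1] - x[0]) if x.size > 1 else 1e-3

    if y_mm == sd or sigma == 0:
        # exact limits: at the collimator plane the blur vanishes; a point
        # source projects the pure transmittance magnified by y/sd
        theta = collimator_transmittance(
            x * sd / y_mm, coll, fx, energy_kev,
            averaging_width_mm=grid_pitch * sd / y_mm,
        )
        return _finish(theta.astype(float))

    if method == "quadrature":
        # direct integral over the source plane; the transmittance is
        # cell-averaged at the source-grid's footprint in the collimator plane
        xp = np.linspace(-6 * sigma, 6 * sigma, 4001)
        fs = source_profile(xp, geometry.focal_spot)
        scale_cm = 1.0 - sd / y_mm
        avg_w = abs(scale_cm) * (xp[1] - xp[0])
        # x''(x, x') = x' (1 - sd/y) + x sd/y
        xcm = xp[None, :] * scale_cm + x[:, None] * (sd / y_mm)
        fc = collimator_transmittance(
            xcm.ravel(), coll, fx, energy_kev, averaging_width_mm=avg_w
        )
        theta = np.trapezoid(fc.reshape(xcm.shape) * fs[None, :], xp, axis=1)
        return _finish(theta)

    if method != "convolution":
        raise ValueError(f"unknown method {method!r}")

    pitch = float(x[1] - x[0])
    # rescaled source: f_s(x / (1 - y/sd)) is a Gaussian of std
    # sigma * (y - sd)/sd, mirrored for y > sd (symmetric here, but the
    # reflection is kept so asymmetric focal spots project correctly)
    scale = 1.0 - y_mm / sd  # negative beyond the collimator
    sigma_proj = sigma * abs(scale)
    margin = 6.0 * sigma_proj
    n_pad = int(np.ceil(margin / pitch))
    x_ext = np.concatenate(
        [
            x[0] + pitch * np.arange(-n_pad, 0),
            x,
            x[-1] + pitch * np.arange(1, n_pad + 1),
        ]
    )
    fc = collimator_transmittance(
        x_ext * sd / y_mm, coll, fx, energy_kev,
        averaging_width_mm=pitch * sd / y_mm,
    )
    ks = np.arange(-n_pad, n_pad + 1) * pitch
    fs = np.exp(-0.5 * ((ks / scale) / sigma) ** 2)
    if scale < 0:
        fs = fs[::-1]  # mirror; no-op for the symmetric Gaussian
    fs /= fs.sum()
    theta = np.convolve(fc, fs, mode="same")[n_pad : n_pad + x.size]
    return _finish(theta)


def export_fluence_csv(path, x_mm: np.ndarray, theta: np.ndarray) -> None:
    """Two-column CSV export (position_um, relative_fluence)."""
    import pandas as pd

    pd.DataFrame(
        {"position_um": np.asarray(x_mm) * 1000.0, "relative_fluence": theta}
    ).to_csv(path, index=False)
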