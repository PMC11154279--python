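# Methods

This note documents the models in `mrtplan`, the parameters that matter, the
numerical choices, and what the synthetic fixtures do and do not show.

## Geometry and the divergent-beam fluence model

The beam frame puts the source at the origin with the beam axis along +z.
Lateral coordinates are millimeters; profiles are sampled on uniform grids
with a default pitch of 1 µm (at least 30 samples across the 30 µm slit —
the reconstruction refuses pitches coarser than slit/10).  Voxel indexing is
0-based with half-open extents, arrays ordered `[z, y, x]` with z the depth
axis.

Default setup constants: source-to-collimator distance `sd = 212 mm`; 7 mm
tungsten multislit collimator with 30 µm slit openings at a fixed 400 µm
period; field sizes 20×20, 10×10, 5×5 mm² defined at the collimator plane
(the field-size reference plane is a modeling choice; the alternative exit
plane differs by much less than the penumbra); 225 kVp spectrum with 1 mm
aluminum filtration; collimator-to-phantom air gap 4 mm (the smallest the
bed design allows — the exact calibration gap is exposed as a parameter
because it is not fixed by the setup).

The focal spot is a normalized Gaussian of standard deviation σ.  The
effective σ = 0.58 mm default corresponds to a 2.5 mm full width at 10% of
maximum (`σ·√(8 ln 10)`), the width convention used for X-ray tube focal
spots.  The physical tube focal spot is larger; the collimator is tilted by
8° about the source, which foreshortens the projected spot.  That tilt is
*not* modeled geometrically — its entire effect is absorbed into the
calibrated σ, which is why σ is a fitted, effective quantity.  `tilt_deg`
is carried as metadata only.

The primary-fluence pattern at a plane y is the source-plane integral of the
collimator transmittance along each ray.  Two implementations exist and are
held to <0.1% of each other in tests: a direct quadrature of the integral,
and the fast path that convolves the magnified transmittance `f_c(x·sd/y)`
with the rescaled source `f_s(x/(1 − y/sd))` — a Gaussian of width
σ·(y−sd)/sd, mirrored through the rescaling's negative sign (a no-op for a
symmetric spot, kept for generality).  Transmittance is evaluated as the
*exact cell-average* over each sample's footprint (analytic slit-coverage
fraction) rather than point-sampled; point sampling aliases the slit edges
at the percent level, which would dominate the path-agreement budget.

Normalization convention: ϑ has unit mean over the central whole number of
projected periods, with the averaging window kept inside the magnified
aperture and clear of the source-blurred field edges.  Consequence:
`D_primary` is the period-averaged primary dose in a voxel, and the period
mean of the reconstructed profile equals `D_primary + D_scatter` — a
conservation identity the tests enforce to ±0.1%.

Septum leakage defaults to the Beer–Lambert transmission of 7 mm of
tungsten at the spectrum's mean energy (≈10⁻²⁰ at 64 keV — effectively
opaque; when no energy is available the septa are simply treated as
opaque).  A constant leakage can be set explicitly to model thinner or
lower-Z collimators.

Penumbral overlap: the projected slit plus the focal-spot penumbra first
fills the projected period at `y* = d·sd/(d − ctc + slit)` (d = focal-spot
FWTM), i.e. ≈37 mm beyond the collimator for the default geometry.  Beyond
that depth direct beam overlap raises the valley dose; the closed form
returns infinity when `d ≤ ctc − slit` (no overlap for a near-parallel
beam).

## Materials, spectrum, phantoms

Photon cross sections (mass attenuation and mass energy-absorption, 10–300
keV) ship as CSV for air, water, ICRU-style soft tissue, lung, PMMA,
cortical bone, aluminum, tungsten, and lead, log-log interpolated; the
tables are transcriptions of the standard compilations, rounded to four
significant figures, with extra grid points bracketing the tungsten and
lead K edges.  The tungsten/lead energy-absorption columns are nominal —
those materials only ever act as absorbers here.

The tube spectrum is a Kramers continuum `(kVp − E)/E` plus tungsten K
lines (7% of unfiltered fluence, only above the 69.5 keV K edge), hardened
through the aluminum filtration and renormalized.  It is a shape model, not
a tube simulation; a measured spectrum can be substituted from CSV and
bypasses the model entirely.

The HU mapping is a standard four-segment scheme (air below −850 HU,
lung-like to −100, soft tissue to +120, bone above) with a continuous
piecewise-linear density ramp (1 mg/cm³ per HU through the water point,
flattening to 0.5 mg/cm³ per HU in bone).  It is a documented stand-in for
a scanner-specific stoichiometric calibration, and every threshold is a
module constant.

Synthetic phantoms: homogeneous slabs (the 100×54×54 mm³ calibration
phantom and the 20×40×20 mm³ validation phantom are the canonical sizes),
and a layered mouse-head stand-in — 3 mm PMMA bed, 1 mm skin, 1 mm skull,
soft-tissue brain — with the treatment target tagged at 9–15 mm depth so
the brain ROI sits where a real plan would put it.  The layered head
reproduces depth-dependent attenuation and the bone/soft-tissue contrast;
it has no anatomy, no air cavities, and no CT noise, so passing plan tests
demonstrate engine behavior, not registration or segmentation robustness.

## Photon transport

The Monte Carlo stage samples photon energies from the spectrum, source
positions from the focal-spot Gaussian, and aims each photon uniformly into
the field aperture; it then delta-tracks (Woodcock) the photon through the
voxel grid against a per-energy majorant.  Physics: photoelectric-like
local absorption and incoherent (Klein–Nishina, free-electron) scattering.
The KN scattering angle is sampled from a per-energy tabulated inverse CDF
(256 quantiles, built by numerical inversion); the recoil-electron energy
is deposited locally (kerma approximation — correct by construction here
because electron transport belongs to the convolution stage).  Photons are
terminated below 10 keV with local deposition.  First interactions score to
`d_primary`, all later ones to `d_scatter`.

Coherent (Rayleigh) scattering is not a separate channel: the bundled
attenuation totals include it, and the residual after subtracting the KN
cross section is treated as local absorption.  At 30–225 keV in low-Z media
this misassigns a few percent of interactions from "small-angle deflection"
to "absorption"; the effect on the primary depth curve is nil (attenuation
uses the same totals) and on the scatter fraction is at the few-percent
level, below the engine's 10% accuracy goal.

The microbeam structure is *not* simulated in the Monte Carlo: the fluence
is scaled by the field-averaged collimator transmittance (duty cycle plus
leakage), matching ϑ's unit-mean normalization.  Doses are reported in
keV/g per unit primary fluence at the collimator plane, which makes doses
comparable across field sizes at fixed tube output.  The absolute scale is
one machine output factor (Gy/min per engine unit, 3.404 for the reference
setup) calibrated once against a measured reference dose rate — the one
constant the engine cannot derive from first principles.

Reproducibility: the transport kernel is seeded explicitly and identical
inputs give bit-identical grids; batch runs derive sub-seeds from the main
seed and provide per-voxel relative standard errors.

A deterministic primary path (polyenergetic Beer–Lambert ray trace with
inverse-square weighting) uses the *same* cross-section tables and the same
expected energy-transfer coefficient `(μ_pe·E + μ_KN·⟨E_t⟩)` as the Monte
Carlo scoring, so the two converge (verified to 2% at 2×10⁶ histories); it
backs calibration loops where Monte Carlo noise would swamp the fit.  A
deterministic scatter surrogate (slice-resolved Compton release transported
along the axis with a two-sided exponential kernel at a representative
scattered-photon energy, spread uniformly over the beam footprint) is
provided for fast previews and is flagged `approximate` in its metadata; it
reproduces build-up and the conservation bound but not lateral scatter
gradients.

## Profile reconstruction and metrics

The electron scatter kernel is a two-exponential mixture (65% short range,
2 µm; 35% long range, 25 µm at unit density and a 100 keV reference
spectrum), with ranges scaled by 1/density and by (E_mean/100 keV)^1.6.
This is a deliberately simple parameterization of lateral secondary-electron
transport: unit integral, symmetric, width ∝ 1/ρ.  Any measured or
simulated kernel can replace it via two-column CSV.  At this setup the
profile width is dominated by the geometric penumbra (projected σ tens of
µm), so metric-level results are insensitive to the kernel's exact shape.

Convolutions run on grids padded by four kernel half-widths plus two
periods, so wrap-around cannot reach the reported span.  Peak finding uses
local maxima with 20%-of-range prominence and parabolic refinement; edge
peaks are excluded from averages.  Because "valley dose" has no unique
operational definition, two estimators are computed: the profile value at
inter-peak midpoints (default) and the mean over the central 50% of each
inter-peak interval; both are reported.  FWHM is measured per peak at half
height above the valley level, by linear interpolation of the crossings;
it is NaN when valleys rise above half peak (deep penumbral overlap).
Within one voxel slice the profile is linear in (D_primary, D_scatter), so
per-voxel peak and valley doses follow exactly from the slice's normalized
profile shape; the slice-ROI mean of the scattered dose is used for the
pedestal because scatter is laterally smooth and per-voxel Monte Carlo
noise would otherwise leak into valley doses and PVDRs.

## Calibration

σ fitting: bounded scalar least squares over σ ∈ [0.05, 3] mm against
measured profiles, with a per-profile free amplitude (shape calibration is
decoupled from absolute dosimetry, which the output factor owns).  The
objective is unimodal over the bracket on synthetic fixtures; the reported
interval comes from the quadratic curvature at the minimum.  Synthetic
recovery: <0.5% error noiseless, <5% at 2% multiplicative noise.

Film calibration implements the rational response `D(gv) = a + b/(gv + c)`
fitted by nonlinear least squares over the (0–10) Gy range; the linear
reading of the same three symbols is degenerate (two parameters collinear)
and was rejected.  The fit enforces monotonicity over the fitted gray-value
range; evaluation outside that range is clamped and flagged rather than
extrapolated.

## Planning and radiobiology

Plan reports average per-voxel metrics over the ROI without weighting (no
weighting is canonical); PVDR is reported both as the mean of per-voxel
ratios and the ratio of ROI means, which differ when the dose varies across
the ROI.  Irradiation time is prescription ÷ mean peak dose rate;
accumulated valley dose is the valley rate over that time; both identities
hold to machine precision by construction.  Human-readable output rounds
times to whole seconds, JSON keeps full precision.  Positioning offsets map
the planned beam center onto the laser-cross home point and are checked
against the 50 mm stage travel.

For exposures longer than 10 minutes the report annotates protraction: the
Lea–Catcheside factor `G = (2/λT)(1 − (1 − e^{−λT})/λT)` for constant dose
rate with mono-exponential repair (λ = 0.5 h⁻¹ default, a typical
late-responding-tissue value; series expansion below λT = 10⁻⁴ so the
instantaneous limit is exactly 1), and the BED-equivalent acute dose — the
positive root of `D_s² + (α/β)·D_s = (α/β)·D_p + G·D_p²`, the unique
reading that satisfies the BED equality and reduces to `D_s = D_p` at
G = 1.  For α/β = 2 Gy, G = 0.852, D_p = 10 Gy this root is 9.31 Gy.

## Problem sizes and numerical defaults

The test suite and the acceptance script run the full engine at 1–2×10⁶
histories on millimeter grids (the 100×54×54 mm³ slab and the mouse head),
sizes at which the slice-averaged Monte Carlo noise sits well below the
effects being measured; depth curves are additionally smoothed over 5
slices before extrema are located (local maxima ranked by ≥5%-of-range
prominence).  Monte Carlo consistency checks use tolerances set from the
estimated batch standard errors (3σ), not fixed percentages, except where a
property is stated as a bound.

## Known limitations

* 1D lateral treatment: no 2D/3D electron kernels, no kernel tilting within
  the diverging fan, no collimator ray-tracing through slanted septa, no
  heel effect or polarization.
* Kerma approximation at interfaces: dose within ~an electron range of
  bone/soft-tissue boundaries is approximate.
* The scatter surrogate is 1D along the axis; use the Monte Carlo path for
  anything quantitative about valleys.
* The spectrum is a shape model; absolute dosimetry always passes through
  the measured output factor.
* The HU mapping is generic, not scanner-calibrated; gantry/couch rotations
  resample the phantom rather than tilting the engine's beam axis.
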