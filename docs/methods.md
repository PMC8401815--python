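# Methods

## Physical model

A micron-scale sphere in a quiescent liquid experiences two passive
transports. Perpendicular to gravity, displacement is purely Brownian
with Einstein–Stokes diffusivity

    D = k_B T / (6 π η r)

(`k_B` Boltzmann's constant, `T` absolute temperature, `η` dynamic
viscosity, `r` hydrodynamic radius). Parallel to gravity, Brownian
motion is superposed on the Stokes terminal velocity

    v = 2 (ρ_p − ρ_f) g r² / (9 η)

(positive = sinking; the internal z axis increases downward). Inverting
the first relation sizes a particle from its measured lateral
diffusivity; inverting the second gives its density contrast from its
measured axial velocity. Both inversions are exact and round-trip to
machine precision.

The particle Strouhal number compares the time to sediment one particle
radius with the time to diffuse the same distance:

    Sr_p = 3 k_B T / (4 π |ρ_p − ρ_f| g r⁴)

It is independent of viscosity (η cancels between the two timescales),
linear in T, and steeply (r⁻⁴) size-dependent — which is why all
estimation here is per-particle rather than population-pooled. The
regime labels use a decade of margin around Sr_p = 1 (gravity-dominated
below 0.1, Brownian-dominated above 10, mixed between); both thresholds
are configurable since the underlying physics only singles out
Sr_p ≈ 1. The constant 3/(4π) is regression-locked in the tests:
substituting the two timescales with distance set to r actually yields
3/(2π), a factor 2 larger, but the 3/(4π) form is the established
definition this package follows, and no conclusion here depends on the
convention since classification uses the density estimate, not Sr_p.

Overdamped (inertia-free) dynamics are assumed throughout, as
appropriate at these Reynolds numbers; no shape, hindered-settling or
wall-drag corrections are applied.

### Water properties

`water_viscosity` implements the IAPWS 2008 correlation for liquid
water (dilute-gas and residual terms; the critical enhancement is
negligible far from the critical point), evaluated at the
atmospheric-pressure liquid density from Kell's polynomial. It
reproduces 1.0016 mPa·s at 20 °C and 0.31417 mPa·s at 90 °C and is
restricted to 263–373 K. This 3-fold viscosity drop between 20 °C and
90 °C is operationally important: heating a sample accelerates
sedimentation and shortens the observation time needed to resolve small
density contrasts.

### Material and environment libraries

The packaged density library spans typical aquatic biology
(bacterial cells 1100 kg/m³, diatoms — tabulated as 1150 kg/m³, the
midpoint of the commonly quoted 1100–1200 range — and gas-vesicle
clusters at 119 kg/m³), a reference polymer (polystyrene, 1050 kg/m³)
and the light end of the mineral spectrum (carnalite 1570 through
alumina 2930 kg/m³). Every density contrast equals the density minus
998 kg/m³ (water at 20 °C), a consistency the tests enforce. Gravity
environments ship with conventional values: Earth 9.81, Mars 3.71,
Europa 1.315, Enceladus 0.113 m/s².

## Synthetic recordings

The generator emulates the output geometry of a volumetric (digital
holographic) microscope rather than its optics: 15 frames/s, a
356 µm × 365 µm lateral field, a 1 mm deep chamber, and localization
noise of σ_xy = 0.2 µm / σ_z = 1.0 µm by default — a few-fold below the
0.8 µm lateral / 2 µm axial optical resolutions, as typical for
centroid localization of resolved spots (instrument localization
precision is otherwise unspecified, so these are the package's
defaults). The default recording duration is 30 s, which suffices on
Earth to separate bacteria from neutrally buoyant beads.

Trajectories use exact per-frame Gaussian increments
(`√(2 D Δt)·ξ` per axis, plus `v_Stokes Δt` in z and any uniform
lateral drift) — Brownian motion is exactly discretizable, so there is
no time-step bias at any frame rate. All randomness flows through
seeded NumPy generators; named pipeline stages draw independent
substreams of one global seed (stage name CRC-hashed into the seed
sequence), so identical seeds give bit-identical outputs and stages can
be rerun independently.

**Chamber boundaries.** By default a track *ends* when the particle
reaches the chamber floor or ceiling (`boundary="absorb"`): a particle
settled onto a wall stops moving ballistically and drops out of the
tracked ensemble in a real recording, and keeping the pre-wall segment
leaves per-track velocity fits unbiased. Reflecting walls
(`boundary="reflect"`, path folding) and unbounded motion
(`boundary="none"`) are available; reflection is unphysical for strong
sinkers — it would fold sedimentation back into the chamber and bias
ensemble velocity estimates toward zero — and is intended for
confined-diffusion studies. Lateral excursions are not bounded: over
the durations simulated, diffusion covers ~10 µm against a ~360 µm
field, so field-exit is negligible.

Size models: fixed radius (monodisperse beads), lognormal (median and
log-sigma), and monomer clusters whose diameters are integer multiples
of a monomer diameter (streptavidin-linked gas-vesicle aggregates show
exactly such 0.8 µm-increment size peaks).

The optional volume renderer places an anisotropic Gaussian blob
(σ from the optical resolutions interpreted as FWHM) per in-bounds
particle over a constant background with Poisson shot noise, written as
one 16-bit multi-page TIFF per time point. It exists to exercise the
detection/linking path end-to-end; rendering a full
2048² × 500-plane field is deliberately not the default — tests use
coarse grids (~1 µm voxels over tens of µm).

What the generator does **not** emulate: holographic reconstruction
artifacts (speckle, twin images, axially elongated point-spread
sidelobes), hydrodynamic particle–particle and particle–wall coupling,
polydisperse aggregation dynamics, convection, and active motility.
Passing recovery tests therefore validate the estimator chain under the
model's own assumptions — unbiasedness and correctly propagated
uncertainty — not robustness to every real-world artifact.

## Tracking

Volumes are maximum-intensity projected per time point (along z for
lateral motion; along y, after reslicing, for axial motion). Detection
thresholds each projected frame (Otsu by default, or absolute),
labels connected components and takes background-subtracted
intensity-weighted centroids, giving sub-pixel positions in µm; blank
frames yield zero detections rather than errors. Linking is greedy
nearest-neighbour: candidate pairs within `max_disp` accepted in order
of increasing distance, ties broken by lowest track id, unmatched
detections seeding new tracks, and gap closing across up to 2 missed
frames. Greedy suffices at the target densities (50–100 particles per
~350 µm field ≈ a few per 1000 µm²); the tests verify it against
exhaustive minimum-cost assignment on small fixtures, which is kept as
an oracle only.

Ensemble lateral drift (stage/bulk-flow motion) is the mean concurrent
per-frame displacement; it is subtracted before diffusivity estimation.
Axial drift is **never** subtracted — for a homogeneous population the
shared axial motion *is* the sedimentation signal.

## Estimation

- **Diffusivity**: unweighted straight-line fit through the origin of
  MSD versus lag over lags 1–3 (divided by 2·dims). Short lags are the
  standard bias–variance compromise; with localization noise the MSD
  gains a +2σ² offset per axis, so sizing from noisy tracks is biased
  for slow diffusers — size recovery tests use noise-free tracks, and
  the offset itself is verified against theory.
- **Sizing (step-length MLE)**: for 2D Brownian motion the squared
  single-frame step is exponential with mean 4DΔt, so the per-track MLE
  is the mean squared step over 4Δt; diameters `k_B T/(3 π η D̂)` are
  histogrammed in 0.1 µm bins. This is a per-track MLE + histogram
  realization of step-length-distribution sizing; full histogram
  deconvolution is deliberately out of scope.
- **Axial velocity**: OLS slope of z on t per track. For
  Brownian-dominated tracks the endpoint difference is marginally more
  efficient (variance 2D/T versus 2.4D/T), but OLS degrades far more
  gracefully when localization noise dominates and is kept uniformly.
- **Density**: inverse Stokes at the per-track radius (measured, or
  externally known for calibration beads).
- **Population axial drift**: track-length-weighted mean of per-track
  OLS velocities.
- **Outlier filter**: estimates with D̂ > 1.20 µm²/s (configurable
  quantity/cutoff) are removed before summaries — such values exceed
  any plausible particle in the tracked size range and indicate linking
  errors.
- **Summaries**: mean, median (the more representative statistic for
  the skewed size/diffusivity distributions), Student-t 95% CI of the
  mean, and histogram.

Per-track velocity estimates in the recovery benchmarks require ≥ 10
points (0.7 s at 15 fps) — shorter fragments, e.g. from particles that
start next to a chamber wall, carry meaninglessly noisy slopes, and a
minimum spot count is standard tracking practice.

Recovery benchmarks run at the study conditions: 15 alumina-density
tracks over 78 s; 1000 bacterial-density and 1000 polystyrene tracks
over 60 s; 100 gas-vesicle clusters over 54 s — small enough to run in
seconds, large enough that ensemble means sit within a few standard
errors of the Stokes/Einstein truth.

## Classification and planning

ρ̂ = Δρ̂ + ρ_fluid is compared against the density gap: below
1300 kg/m³ → cell-like; above 1500 → mineral-like; inside the gap →
ambiguous (an explicit output, not a forced call — a ±10% density error
still cannot carry a particle across the gap); below the fluid
density → buoyant-biological, since no mineral floats in water.
Thresholds are configurable. With exact densities injected, every
packaged biological material classifies cell-like/buoyant-biological
and every mineral mineral-like; polystyrene (1050 kg/m³) reads
cell-like by density alone, which is exactly the ambiguity the method
is honest about for near-neutral polymers.

Planning inverts Stokes' law for time: the observation needed for the
axial drift of contrast Δρ at radius r to cross one axial resolution
element d is `t = 9 η d / (2 |Δρ| g r²)`, exactly ∝ 1/g — resolving
0.1 g/cm³ at r = 0.75 µm with d = 2 µm takes ~16 s on Earth and ~100×
longer at 1% of Earth's gravity. The planning table also reports the
smallest contrast resolvable in a fixed duration and the Strouhal
regime per environment.

## Numerical and interface choices

- SI units internally; µm, µm/s, mPa·s only at I/O boundaries
  (CSV/JSON columns carry unit suffixes).
- Neutral buoyancy returns `inf` sentinels (gravity time, Strouhal,
  observation time) instead of raising, so density sweeps crossing the
  fluid density stay total.
- Estimation stages that cannot run leave NaN plus a machine-readable
  reason code; classification of such tracks is `unclassifiable`.
- CSV dialect: comma-separated UTF-8, '.' decimal, mandatory header;
  tracks carry 0-based frames with z_um increasing downward (an ingest
  flag flips upward-z tables).
- Config is a flat YAML file that round-trips losslessly; unknown keys
  are rejected.

## Known limitations

Stokes' law assumes rigid spheres: shape, porosity and surface effects
bias density estimates (porous aggregates such as vesicle clusters read
lighter than their bulk material). Diffusivity-based sizing from noisy
tracks inherits the static-noise MSD offset. Greedy linking will switch
identities in dense fields. The classifier encodes terrestrial
mineralogy and cell composition; the density gap is an assumption, not
a law of nature, for other worlds' chemistry.
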