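# Methods

`fluidwalls` models the physics and the quantification pipeline of
fluid-walled "dumbbell" micro-circuits: two millimetre-scale chambers of
culture medium pinned to a Petri dish under an immiscible fluorocarbon
(FC40), joined by a shallow conduit through which only axons grow.  This
note records the models, their assumptions, the defaults, and the
numerical choices.

## Chamber pressure model (`fluidwalls.geometry`)

A chamber is a sessile drop whose contact line is pinned at a fixed
footprint of effective radius *a*.  Below the depinning limit the
medium:FC40 interface is a spherical cap, giving closed forms for the cap
volume V(h) = (πh/6)(3a² + h²), curvature radius R = (a² + h²)/2h,
Laplace pressure P_L = 2γ/R, and the gauge pressure at the dish floor

P = 2γ/R + ρ_med g h + ρ_FC40 g (h_FC40 − h),

where h_FC40 is the FC40 free surface height above the floor.  In the
difference between two chambers the FC40 term cancels exactly:

ΔP = P_R − P_L = 2γ(1/R_R − 1/R_L) + (ρ_med − ρ_FC40) g (h_R − h_L).

Assumptions and choices:

* **Square footprints → effective circle.**  The printed chambers are
  3 mm squares but the cap model needs a circular contact line.  The
  default maps a square of side *s* to the equal-area circle
  a = s/√π ≈ 1.693 mm, preserving the footprint area that the volume
  integral actually fills; the inscribed-circle alternative (a = s/2) is
  available as `radius_mode="inscribed"`.
* **Pinning is binary.**  The contact line is fixed for all volumes up to
  `max_pinned_volume(a, θ_adv)` (cap angle = advancing angle); exceeding
  it raises `DepinningError` rather than simulating contact-line motion.
  The helper supports θ_adv ≤ 90° — caps taller than a hemisphere leave
  the regime where the pinned-footprint model is meaningful.
* **Sphericity.**  The cap shape ignores gravitational flattening.  The
  Bond number (ρ_FC40 − ρ_med) g a²/γ ≈ 1.8 at the default scale, so
  pressures are order-of-magnitude faithful but not interferometric; all
  downstream conclusions depend only on signs and ratios of ΔP.
* **Default fluid constants** (all configurable, none measured here):
  γ = 0.013 N/m (serum-containing medium against FC40),
  ρ_med = 1007 kg/m³, ρ_FC40 = 1855 kg/m³, g = 9.81 m/s²,
  μ_med = 0.89 mPa·s (water-like, 25 °C), θ_adv = 70°.
* **Units.**  SI internally; mm/µm/µl/degrees at the config, CLI and
  export boundaries.  `cap_height_from_volume` inverts the monotone cubic
  by Brent's method with relative tolerance at machine precision
  (round-trip error < 1e−12 relative over the tested range).

## Two-chamber equilibration (`fluidwalls.equilibration`)

Unequal filling drives Poiseuille flow through the conduit until the cap
pressures equalise:

dV_L/dt = ΔP/R_h,  dV_R/dt = −ΔP/R_h,
R_h = 12 μ L / (w h_c³ (1 − 0.63 h_c/w)),

the lubrication-theory resistance of a shallow rectangular channel
(default 1 mm × 200 µm × 10 µm).  Flow is reported signed, positive for
right → left — the direction that keeps freshly seeded cells in the left
chamber.  Deposition events are instantaneous and perfectly mixed; the
conduit is rigid and its ~2 nl dead volume is excluded from the chamber
mass balance (≪ 1 µl).  Integration uses LSODA (stiff-safe) per
inter-event segment with dense output on a 30-minute grid, the cadence of
side-view imaging; volume is a linear invariant of the ODE and is
conserved to < 1e−12 relative.

The standard seeding protocol (4 µl into the right chamber, then 1 µl
into the left) gives ΔP ≈ +3.1 Pa initially, so flow through the conduit
is leftward from t = 0 and `assert_no_backflow` verifies it never
reverses; the reversed protocol fails the same check at t = 0.  With the
defaults the volume imbalance decays 90 % in ≈ 17 h at h_c = 10 µm,
consistent with near-equalisation on the bench by 24 h.  The conduit
height is only printed as "< 10 µm"; since R_h ∝ 1/h_c³, a 5 µm conduit
is ~8× slower (≈ 130 h).  The package therefore treats the 24-h
observation as evidence for an effective height near the top of that
range and checks the hours-to-a-day timescale at the default 10 µm, with
the h³ scaling asserted separately — an order-of-magnitude consistency
check, not a fit.

## Conduit solute gradients (`fluidwalls.transport`)

With equal chamber volumes there is no pressure-driven flow and solute
moves only by diffusion.  The conduit is discretised into N finite-volume
cells (default 41) flux-coupled at each end to a well-mixed chamber
reservoir; media changes are instantaneous mixed dilutions (removing
volume v takes mass C·v; adding v at concentration c mixes linearly).
The discrete series resistance telescopes to exactly L/(D·A), so the
clamped steady state reproduces the continuum linear profile and flux
D·w·h_c·(C_R − C_L)/L identically.

The pure-diffusion system is linear, so the default propagator is a
dense matrix exponential per inter-event segment: unconditionally stable,
no step-size constraint, and total mass (a left eigenvector of the
generator) conserved to roundoff (< 1e−12 relative between events).  An
optional advective coupling — a conduit flow Q(t) taken e.g. from an
equilibration trajectory — switches to an implicit BDF solver with
first-order upwinding and moves chamber volume along with the flow; an
explicit-Euler path with a hard diffusive-CFL check exists for
cross-validation.  Grid-refinement changes chamber series by < 1e−4
relative at the default N.

BDNF parameters: the diffusion coefficient defaults to
D = 1.0 × 10⁻¹⁰ m²/s, typical of a ~27 kDa globular protein in water at
room temperature — an assumption, clearly flagged, since no measured
value is available here.  The CN-medium baseline is 10 ng/ml BDNF and
the enriched distal medium 100 ng/ml (10×).  Cellular uptake or
secretion of BDNF is not modelled (no rates available), so simulated
exposures are upper bounds on the passive-transport contribution.  Under
the 20-day protocol (d 0 start at 10/100 ng/ml, full change at d 2,
half-changes every 48 h) the CN chamber peaks at ≈ 11.4 ng/ml — the
chamber turnover time V·L/(D·w·h_c) ≈ 230 days dwarfs the 48-h
media-change period, so distal BDNF barely accumulates proximally.

## Coverage metrics (`fluidwalls.quantify`)

Inputs are binary neurite masks with pixel size and a physical origin;
upstream segmentation of raw fluorescence is out of scope (a fixed
threshold helper exists for convenience only, and is not the reference
segmentation pipeline).  Conventions, chosen for unambiguity: physical
coordinates in µm with the origin at the left chamber/conduit junction
and x increasing distally; ROI rectangles are half-open [min, max); a
pixel belongs to an ROI iff its centre falls inside.  `covered_area`
equals a brute-force per-pixel loop exactly and is additive over ROI
partitions.

* Outgrowth index: (A_d20 − A_d0)/A_d0 of conduit coverage — the A_d0
  normalisation decouples the index from how many cells were seeded.  It
  is the only cell-number correction applied.
* Fold difference: each value divided by the mean of its own batch's
  control group (so the control group itself averages exactly 1).
* Regeneration zone: abuts the proximal damage line, shares the
  conduit's 200 µm width, extends 300 µm distally (6 × 10⁴ µm²).
* Regrowth fraction: zone coverage at each timepoint divided by the
  pre-axotomy (d 20) zone coverage.  Preparations whose immediate
  post-axotomy residual exceeds `severance_threshold` (default 5 % of
  reference — a configurable choice, since no published cut-off exists)
  are flagged "incomplete severing" and excluded, as are those with zero
  reference coverage.

## Synthetic data (`fluidwalls.synthetic`)

The generators exist to make every stage testable without experimental
data; all are deterministic under a mandatory seed and ship ground-truth
tables alongside rasters.

* **Side views** (`gen_sideview`/`measure_height`): orthographic render
  of the circular-segment cap profile on a substrate line, with a
  dispensing needle of known outer diameter (210 µm) as the scale
  reference, plus Gaussian pixel noise.  Measurement median-filters,
  thresholds, calibrates µm/px from the needle width, and reads the
  apex-to-substrate distance.  Noiseless recovery is exact to one pixel;
  at the default noise (σ = 0.03) the recovery bias over 100 random
  heights is < 2 %.  Lens and meniscus optics are not modelled.
* **Neurite growth** (`gen_neurite_series`): axons are biased random
  walks launched near the conduit mouth, elongating at per-axon normal
  rates and rasterised at a stated thickness (default 2 µm/px over the
  conduit ± 300 µm).  No biological realism is claimed — fascicles,
  branching, contact guidance and density saturation are all absent —
  so green tests show the *metrics* are correct, not that real conduits
  behave this way.
* **Axotomy series** (`gen_axotomy_series`): clears a band (default
  400 µm wide) from a pre-grown mask, optionally leaving a residual
  pixel fraction to exercise the exclusion path, then restores the
  original coverage column-by-column from the proximal line at a
  programmed front speed after a delay.
* **Protocols** (`gen_protocol`): the d −6 → d 25 bench timeline per
  condition (CNs-CN, CNs-BDNF, CNs-MSN): 4 µl/1 µl seeding order,
  washes at d −2, condition media at d 0, full change at d 2,
  half-changes every 48 h, MSN medium switch at d 8.
  `bdnf_exposure_schedule` windows this to the d 0–20 transport run.

## Layout and toolpath (`fluidwalls.layout`, CLI)

The default dish is 60 mm with a 3 × 7 grid (21 dumbbells) at
7.5 × 7.0 mm pitch and a 2 mm rim margin — the pitch is a package choice
(no published spacing) that packs the array with every footprint corner
inside the margin circle.  The axotomy toolpath makes one cut per
conduit, perpendicular to the conduit axis, of length
conduit width + 2 × 1.4 mm margin, with serpentine travel and
nearest-end cut alternation; at 960 mm/min the full pass takes ≈ 13 s,
comfortably inside the < 90 s envelope even allowing for the hardware
overheads (acceleration, jet switching) that the constant-speed,
zero-dwell default ignores (both are configurable).  Rebuilt dumbbells
(3.5 mm chambers, 0.5 mm × ~400 µm conduit) are placed concentric with
the originals and must strictly contain them without touching
neighbours.

The CLI (`fluidwalls`) is a thin wrapper over these functions; every run
writes a provenance JSON (config hash, seed, versions).

## Problem sizes and limitations

Default problem sizes — 41 transport cells, 30-minute equilibration
sampling, ~800 × 400 px mask windows, 100-image recovery studies — were
chosen so each stage runs in seconds on one CPU while the refinement
tests above bound the discretisation error.  Known limitations: no
contact-line dynamics or cap asphericity; rigid conduit ceiling (the
FC40 ceiling's compliance is unmodelled, which is why h_c is exposed as
a parameter); no cellular BDNF kinetics; no fluorescence realism in the
mask generator; toolpath kinematics ignore acceleration.
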