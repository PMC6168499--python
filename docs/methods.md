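# Methods

## Device model

The gradient device is modelled as a hydraulic RC network. Each open,
cylindrical reservoir of cross-section A stores volume against hydrostatic
pressure with capacitance C = A/(ρg); each rectangular channel of width w,
height h ≤ w and length L carries laminar flow against resistance

R = 12µL / (w·h³·(1 − 0.63·h/w + 0.052·(h/w)⁵)),

the refined lubrication closure, within ~0.1 % of the exact eigenfunction
series at every aspect ratio (the bare 1 − 0.63 h/w form errs by ~14 % for
a square duct, which is why the refined form is used; the tests validate it
against the series solution directly). Default fluid parameters are medium
at 37 °C (ρ = 1000 kg m⁻³, µ = 0.7 mPa·s).

The standard device has six reservoirs: two 8 mm drug wells and two 8 mm
medium wells (one pair per side channel) and two 4 mm central wells with
overflow ports. With all four side reservoirs lumped (capacitance 4C_S)
facing the two central reservoirs (2C_C) through the effective network
resistance R_T, the circuit reduces to closed-form pressures. With the
overflow clamp active the central pressure is pinned and the side pressure
decays with time constant R_T·4C_S; without it both levels relax toward the
volume-weighted mean height with the shorter constant
R_T·4C_S/(1 + 2A_S/A_C). The 4C_S grouping is used exactly as the lumped
model implies (four identical side reservoirs in parallel); the network
integrator reproduces both closed forms to <1 %, which is the consistency
check that the six-reservoir topology and the lumped forms describe the
same device.

`simulate_network` integrates the volume balance dV_i/dt = Σ_j (P_j −
P_i)/R_ij with explicit 1–5 s steps (the pressure time constants are
hundreds of hours, so explicit stepping is >10⁴× inside its stability
limit), a recursive step-halving guard against negative volumes, and a hard
overflow clamp: volume above a reservoir's overflow level moves to a
monotone cumulative-discharge ledger. Meniscus effects and evaporation are
deliberately outside the model — they are exactly what the end-of-run
volume QC screens for: an experiment is discarded iff any reservoir's
measured volume deviates from the model expectation by strictly more than
10 % (a deviation of exactly 10 % is accepted).

### Default geometry (where the hardware description stops)

Channel cross-sections (35 µm side channels, 7 µm connecting channels,
150 × 150 × 180 µm wells, 4/8 mm punched reservoirs) are hardware facts;
connecting-channel count and length, and the pipetted volumes, are free
design parameters of any such device. The defaults — 75 connecting
channels per side of 10 × 7 µm section and 3.5 mm length, side wells filled
to 4.6 mm (231 µL), central wells at the 0.6 mm overflow level — were
chosen once so that the simulated device sits in the operating regime the
platform is designed for: R_T ≈ 1.0 × 10¹⁴ Pa s m⁻³, initial head 4 mm,
cross-flow ≈ 1.4 µL/h, decay constant ≈ 580 h. In this regime the gradient
establishes within the first hour, stays monotone and nearly linear across
the rows, and drifts by ≲10 % per row over 24 h across the whole compound
diffusivity window. These defaults were frozen before the acceptance suite
was written and are not tuned per experiment.

## Gradient simulation

The culture channel is thin (35 µm flow layer over a ~7 × 1.9 mm
footprint), so transport is depth-averaged to 2D. Fluid enters uniformly
along both long walls over the connecting-channel span (the array region),
converges toward the mid-line and leaves axially:

v_y(y) = v_in(t)·(1 − 2y/L_y) inside the span (0 in the end margins),
v_x(x) = (2v_in/L_y)·(clip(x, span) − L_x/2),  v_in = Q(t)/(2·L_span·h).

The span is snapped to grid faces so the discrete field is exactly
divergence-free. Boundary conditions: drug-side wall at the source
concentration c₀, medium-side wall at 0 (both side channels are
continuously refreshed), walls elsewhere no-flux, channel ends outflow.
Restricting the held-concentration walls to the array span is what creates
the fringe effects near the first and last columns that motivate the
edge-column exclusion; with walls held along the whole channel the field
would be exactly x-uniform and the exclusion meaningless.

The solver is conservative finite-volume with a hybrid advection scheme
(central averaging below cell-Péclet 2, upwind beyond — at the default
operating point cell-Péclet is ≈0.03–0.5, so the scheme is effectively the
second-order central one; pure upwind would add numerical diffusion
comparable to the physical D at affordable grids) and explicit stepping at
a CFL safety factor of 0.4, with the step fixed once per run for
determinism. Default grid spacing is 50 µm (3 nodes per well, the minimum
the per-well averaging accepts); halving it changes row means by <1 %.

Diffusivities follow D = a·MW^(−1/3) anchored at cisplatin
(D(300) = 0.75 × 10⁻⁹ m² s⁻¹), placing the screened panel at
0.54–0.75 × 10⁻⁹ m² s⁻¹ inside the working window 0.2–0.8 × 10⁻⁹ m² s⁻¹ —
free-solution values for small molecules in aqueous medium at 37 °C. This
window is the package's own calibration: it is the unique decade in which
a gradient across the 1.9 mm row span can both establish within a 1 h
window (L²/π²D ≈ 10–50 min) and afterwards hold every printed behavioural
property of the platform at once — monotone near-linear row profile with
row1/row8 ≈ 5–10, >15 h stability, ≲10 % worst-case drift per 24 h and
<1 % within-row spread in most rows. An order of magnitude lower, the
diffusion time across the span alone exceeds the establishment window and
no flow regime recovers those properties simultaneously. MW outside
100–2000 g/mol is refused (the scaling is not trusted there); an explicit
D always takes precedence.

"Stable" is operationalised as: row means strictly ordered (row 1 highest)
and each within 10 % of its value at the establishment snapshot (default
1 h, matching a 1 h establishment + 12 h incubation protocol). The
assigned per-row dose is the mean of the row profile over the incubation
window; the within-row spread is (max − min)/mean over the retained wells
of the row (first and last 3 columns excluded).

## Synthetic data generator

The generator emulates the study conditions, not arbitrary microscopy:

* **Layout** — 8 × 30 wells of 150 µm (240 wells) at 200 µm pitch;
  a 5-row/250 µm variant is supported.
* **Seeding sizes** — truncated normals around a U-shaped column-mean
  profile (85 µm at the channel ends falling to 65 µm mid-channel, SD
  7.5 µm): cells sediment preferentially near both inlets, and with these
  defaults ≥90 % of diameters land in 50–100 µm.
* **Contours** — star-convex outlines r(θ) = R(1 + a·g(θ)) with g a band of
  Fourier modes k = 2…9, fixed 1/k energy spectrum, random phases,
  normalised so a is the RMS fractional perturbation. The fixed spectrum
  makes roughness map ~deterministically onto shape factor, so equal doses
  give equal disaggregation readouts up to imaging noise; the polygon's
  shoelace area and edge-sum perimeter are exact ground truth.
* **Response model** — per-well effect e = c^H/(c^H + EC50^H), ramping
  linearly over the 3 days after drug application. Disaggregation mode
  maps e to boundary roughness (0.04 → 0.28) and a dead rim (viable core
  area fraction 1 − e); shrinkage mode maps e to radius reduction (up to
  55 %) with an intact smooth contour. The two modes reproduce the two
  phenotypes real screens show and the resulting S_F/V_F dissociation.
* **Rendering** — 1 µm/px crops (configurable; <10 px spheroids get a
  low-resolution flag): dark textured spheroid on bright background in
  brightfield, FDA over the viable region and PI over the dead rim on the
  final day only (viability dyes are end-point-only because they are
  cytotoxic). Speckle (SD 0.05) plus Gaussian background noise (SD 0.03)
  on a 0–1 intensity scale. No optics simulation (PSF, vignetting,
  z-structure) — passing tests therefore demonstrate correctness of the
  measurement chain on idealised images, not robustness to real optical
  artefacts, debris or out-of-focus frames.

All draws descend from `SeedSequence(seed, row, col, purpose)`, so any
well re-renders identically in isolation.

## Image analysis

Segmentation is a global threshold (Otsu by default), binary opening
(2 px) to remove threshold speckle, hole filling, then the largest
component above 300 µm². The measurement contour is marching squares at
the 0.5 level of the lightly smoothed (σ = 1 px) mask: pixel-edge
perimeter counting overestimates a circle's perimeter by up to ~27 % and
would destroy the S_F ≈ 1 reference for healthy spheroids; with the
sub-pixel contour a rendered circle of radius ≥32 px measures S_F ≤ 1.02.
Brightfield is segmented inverted (dark object); fluorescence channels at
native polarity with the same parameters. V_F uses the thresholded FDA
mask area over the brightfield area of the last pre-drug day; PI is
rendered and ingested but not used quantitatively, matching the V_F
definition. Equivalent diameter is 2·√(A/π) of the baseline frame.

## Dose–response

Row aggregation reports mean, SEM (sd/√n across spheroids within the
device; SEM is undefined for n = 1 and flagged rather than invented) and
n. Size groups are inclusive integer bands (75 µm belongs to Group 1).
The 4PL model y = bottom + (top − bottom)/(1 + (c/EC50)^hill) is fitted on
log-concentration with quantile-based initialisation, EC50 bounded to
[min dose/10, max dose·10], and a flat-response guard: no EC50 is reported
when the dynamic range of the means is below twice the pooled SEM. EC50
rescales exactly with a global concentration rescaling. Pearson r(S_F,
V_F) is computed across end-point spheroids; fewer than 3 pairs or zero
variance yields an explicit "undefined" flag. No multiple-testing
machinery is included: the package reports descriptive fits and
correlations.

## Problem sizes and numerical defaults

The validation computations run the full 8 × 30 array: EC50 recovery uses
20 independent screens (three imaging days each — baseline, drug day,
end-point — the minimum the readouts need); the stability run simulates
17 h of transport (so a 16 h stable window is demonstrable) and the drift
sweep 25.5 h at both diffusivity endpoints, all at the default 50 µm grid
and with the device trace integrated at 5 s steps. Tolerances used in
tests mirror the character of each claim: exact identities at solver
precision, discretisation-limited checks at 1–2 %, behavioural claims from
scaled simulations at the stated ~10 %/15 h/1 % levels.

## Known limitations

* The transport model is depth-averaged; wells are treated as part of the
  2D footprint, so intra-well vertical gradients and the well-equilibration
  lag (~minutes) are not represented.
* No PDMS absorption, solute binding or uptake by spheroids; the medium
  side is an ideal sink, the drug side an ideal source at c₀.
* The generator's disaggregation is purely geometric (roughness + rim); it
  does not scatter debris into neighbouring wells or merge spheroids, so
  the multi-object path is exercised synthetically rather than by realistic
  failure modes.
* Fits are per-device; replicate-device variance components are out of
  scope (SEM across spheroids within a device is reported, and separate
  runs can be pooled externally).
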