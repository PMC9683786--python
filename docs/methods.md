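# Methods

`swimtrap` models and analyses the swimming behaviour of single micro-algae
confined to circular, quasi-2D arenas: a biflagellate CR-type swimmer
(*Chlamydomonas*-like, run/stop/tumble gait, ~80 µm/s runs, ~50–60 Hz ciliary
beat) and an octoflagellate PO-type swimmer (*Pyramimonas*-like,
run/stop/shock gait, 300–400 µm/s runs, millisecond backward "shocks"
exceeding 1 mm/s). This note records the models, the parameter choices that
matter, and the limits of what the synthetic tests demonstrate.

## The chiral active-dumbbell swimmer

The simulator (`swimtrap.dumbbell`) represents the cell as two rigid spheres:
a body sphere of radius a2 at the tracked position **x** and a larger front
sphere of radius a1 — the envelope swept by the beating cilia — whose centre
sits at **x** + ℓ·ê(φ+θ). Propulsion acts along the body axis ê(φ) at
constant speed v0. The offset angle θ (degrees, counter-clockwise positive
viewed from above in the lab frame) misaligns the cilia envelope from the
propulsion direction; it is the model's only broken mirror symmetry and
stands in for the bilateral asymmetry of the two flagella ("flagellar
dominance").

Overdamped Langevin dynamics, integrated with fixed-step Euler–Maruyama:

    dx = [v0 ê(φ) + µ_t (F1 + F2)] dt + √(2 D_t dt) ξ_xy
    dφ = µ_r τ dt + √(2 D_r dt) ξ_φ

Each sphere overlapping the trap wall feels a radially inward harmonic
(linear-in-overlap) steric force F_i = k_wall · max(0, |c_i| + a_i − R) ·
(−ĉ_i); the torque τ is taken about the midpoint of the two sphere centres.
In the bulk the swimmer is force- and torque-free, so chirality is expressed
exclusively through wall contacts: a swimmer sliding along the wall with the
cilia envelope tilted into (or away from) the wall experiences an asymmetric
restoring torque, which makes one circulation sense more stable than the
other. With θ = 0 the dynamics are exactly mirror-symmetric (the test suite
checks this step-by-step), so no ensemble circulation can arise in a circular
trap — a chiral flux requires the internal asymmetry θ ≠ 0.

Defaults (all overridable): a1 = 7 µm, a2 = 5 µm, ℓ = 7.5 µm, v0 = 80 µm/s
(red-light preset; the white-light preset uses v0 = 100 µm/s, θ = −1°),
D_r = 0.4 rad²/s, D_t = 0, k_wall·µ_t = 100 s⁻¹, µ_r = 0.05 µm⁻²·µ_t,
dt = 10⁻⁴ s, output subsampled to 2 ms (500 fps). Rationale:

- **Geometry.** The body sphere matches a ~10 µm cell; 2·a1 = 14 µm equals
  the diameter of the tracked blob (cell plus cilia). The head-to-tail reach
  ℓ + a1 = 14.5 µm leaves clearance even in the smallest (Ø 40 µm) arena. A
  longer dumbbell (reach ≳ trap radius) wedges at the centre of the Ø 40
  trap and never circulates, which contradicts the observed phenomenology;
  "cell diameter" in wall-proximity checks means 2·a1.
- **Mobilities.** µ_r sets how fast wall-contact torques reorient the
  swimmer. µ_r = 0.05 gives a reorientation time of ~0.1 s at typical
  contact forces, placing the model firmly in the curvature-guided
  wall-sliding regime: in the Ø 40 µm trap, θ = +1.5° yields a strongly
  positive (CCW) mean tangential flux, θ = −1° a negative one, and θ = 0 is
  statistically unbiased. Chiral bias per unit time weakens with trap size;
  within 60 s recordings the circulation direction in Ø 120–200 µm traps is
  set by the initial condition rather than by θ, consistent with chiral
  fluxes being most prominent under strong confinement. The stiffness
  k_wall·µ_t = 100 s⁻¹ keeps steady-state wall overlaps below ~1 µm and is
  stable at dt = 10⁻⁴ s (relaxation per step 10⁻²); a dt-halving check in
  the suite confirms summary statistics are integration-step independent.
- **Noise.** D_r = 0.4 rad²/s gives a bulk persistence time of 2.5 s
  (persistence length ~200 µm at 80 µm/s), so trap crossings are nearly
  straight, as observed for runs. Translational diffusion is negligible for
  a self-propelled 10 µm swimmer and defaults to 0, which also makes the
  bulk speed exactly v0 at every step — a sharp contract the tests exploit.

## Trajectory analysis

**Kinematics.** Positions are smoothed with a centred moving average (default
10 ms = 5 samples at 500 fps — wide enough to suppress tracker jitter,
narrow enough to resolve 20 ms shocks); speed v and heading come from central
differences of the smoothed positions, and Ω = dφ/dt and dΩ/dt from further
central differences of the unwrapped heading. Below 0.1 µm/s the heading is
ill-defined and held at its last valid value (a causal hold; interpolation
would use future data). Series ends replicate the nearest valid value.

**Gait segmentation.** A per-sample threshold rule followed by dwell-time
debouncing. CR: stop if v < v_c (10 µm/s), else tumble if |Ω| > Ω_c
(12 rad/s), else run — tumbling is scored on angular speed alone once the
stop test has passed, since the defining feature of a tumble is loss of
synchrony, not a particular speed. PO: stop if v < v_c (20 µm/s), else shock
if v > 500 µm/s **and** |dΩ/dt| > 300 rad/s² (both are elevated during a
shock), else run. Any interior segment shorter than min_dwell (default
20 ms, one nominal shock duration) is merged into its longer neighbour (ties
to the preceding segment), conserving total duration; the censored first and
last segments are exempt. Thresholds sit in the wide gaps between the state
speed scales (runs 300–400 µm/s vs shocks > 1000 µm/s for PO) and are all
configurable.

Millisecond shock events are at the resolution limit of a 10 ms smoother:
the detected shock segment is widened by roughly the smoothing stencil on
each side, which biases the shock exit-rate estimate downward. When shock
timing matters (e.g. rate recovery on synthetic PO data), the analysis
config should use `smoothing_window = min_dwell = 6 ms`; with those
settings the full pipeline recovers all generator rates within sampling
error. The 10 ms/20 ms defaults remain appropriate for CR, whose tumbles
last ~200 ms.

**Transition networks.** From a state sequence: occupancies p_i (time
fractions), sojourn lists T_i from maximal constant segments (first/last
excluded as censored — standard survival-analysis practice — but counted in
occupancy), transition counts n_ij, transition probabilities
p_ij = n_ij/Σ_j n_ij, and rates q_ij = n_ij / (time in state i). The
per-time-in-state normalisation makes Q the generator of a continuous-time
Markov chain, directly comparable to simulation inputs; "transitions per
unit total time" is available via `rate_norm="total"`. Empirical survival
curves P(T_i > τ) are right-continuous step functions on the sojourn grid.
`network_timecourse` estimates one network per recording interval and
reports across-interval means and standard errors (sd/√N), mirroring
repeated 5-min recordings.

**Spatial statistics.** The probability-flux field partitions the
trap-centred square (trap-size-scaled coordinates) into n×n bins (default 15
per diameter for readable arrow fields; 30 for occupancy maps). Occupancy is
the fraction of observation time per bin; the flux vector in a bin is the sum
of single-step displacements starting there divided by the time spent there
— a conditional mean velocity. This was chosen over the modal ("most
probable") step direction, which is noisy at finite sampling; the
occupancy-weighted flux telescopes *exactly* to (final − initial
position)/total time, an identity asserted on every estimate. Tangential
projection onto (−sin φ, cos φ) (CCW positive) gives circulation profiles
per annulus and the trap-wide mean tangential flux used as the chirality
statistic. P(r) is line-density normalised (∫P dr = 1), so uniform disk
occupancy reads P ∝ r. MSD is time-averaged over all start times (FFT
implementation), with lags capped at 25% of the duration to bound estimator
variance.

**Beat-frequency spectra.** The analysed signal is the detrended transverse
displacement: velocity is projected onto the perpendicular of a windowed
(0.25 s) mean heading and integrated. Per run segment ≥ 0.25 s, a Welch
periodogram (256-sample segments, 50% overlap, linear detrend; ~2 Hz
resolution at 500 fps, enough to separate the 52 and 62 Hz beat bands) is
computed and length-weighted averaged. Because heading diffusion gives the
background a red (∝ f⁻⁴-like) tail, peaks are detected on the spectrum
divided by a running-median baseline (9 bins) with a prominence threshold of
4, then ranked by raw-spectrum prominence; candidates below 5 Hz (path
meander, not beating) or beneath a 10⁻⁵-of-maximum leakage floor are
discarded. Alternatives to transverse displacement (speed, curvature) would
carry the same beat line; displacement was chosen as the most direct
positional signature.

## The synthetic-behaviour generator

`swimtrap.behaviour` produces labelled test data with exactly the structure
the pipeline assumes: a 3-state continuous-time Markov chain (exponential
sojourns, configurable rate matrix Q) driving state-specific kinematics at
500 Hz inside a circular arena.

- **Runs**: per-sample speed N(80, 8) µm/s for CR (N(350, 25) for PO, the
  centre of the observed 300–400 µm/s band), heading diffusion 0.1 (CR) /
  0.2 (PO) rad²/s, plus a transverse sinusoid at 52 Hz emulating the beat
  signature. Its default amplitude is 5 nm — deliberately far below the
  ~0.1–1 µm wobble of real cells — because at 52 Hz any larger amplitude
  drives the smoothed |Ω| above the 12 rad/s tumble threshold and the
  default CR classifier would shred runs into spurious tumbles; 5 nm keeps
  the beat detectable spectrally while leaving gait classification clean.
- **Stops**: frozen position with 5 nm Gaussian jitter.
- **CR tumbles**: rotation at ±25 rad/s with slow (25 µm/s) translation;
  mean duration 200 ms (exit rate 5 s⁻¹).
- **PO shocks**: backward swimming at N(1300, 150) µm/s with strong heading
  erraticity (20 rad²/s), followed by an instantaneous reorientation drawn
  uniformly from (90°, 270°) relative to the pre-shock heading (random
  sign). The exit rate is 25 s⁻¹ (mean ~40 ms) with a 100 ms safety cap:
  the printed "up to 20 ms" refers to the symmetric undulation phase, while
  the backward displacement visible in a centroid track persists somewhat
  longer; a slower exit also keeps shock sojourns approximately exponential
  (the cap rarely binds), so configured rates remain recoverable. Shock
  speeds comfortably exceed the 1 mm/s benchmark in every seed.
- **Default rate matrices** (s⁻¹), chosen to give CR mostly-continuous
  swimming with occasional stops/tumbles and PO episodic run–stop–shock
  dynamics, with enough events in a 300–600 s recording for rate estimation
  while keeping debounce losses below sampling error:
  CR: q01=1.0, q02=0.1, q10=0.05, q12=0.15, q20=0.5, q21=4.5.
  PO: q01=0.5, q02=0.05, q10=0.2, q12=0.2, q20=2.0, q21=23.0.

Wall handling is a specular reflection of the heading with the position
clamped 1 µm inside the wall. This is intentional: the generator validates
the *statistics* pipeline, and boundary physics (wall-following, chirality)
belongs to the dumbbell simulator. Two consequences matter for
interpretation: (i) generator trajectories show no boundary accumulation or
chiral circulation, so spatial-statistics physics is only tested against the
simulator; (ii) the instantaneous heading jump at each reflection injects
broadband transients into the transverse-displacement spectrum, so
beat-frequency recovery tests run in an effectively unconfined arena
(trap radius 4 mm) where reflections are absent — with real boundary-gliding
cells this artifact does not arise. With the 5 nm default amplitude the beat
line clears the heading-diffusion background for frequencies ≳ 45 Hz
(covering the 52/62 Hz bands); at much lower frequencies it would require a
larger amplitude.

Cohorts (`generate_cohort`) emulate the assay design — N cells × M recording
intervals — with per-interval rate multipliers ("drift", e.g. run→stop
switching becoming more likely over time) and per-(cell, interval) seeds
spawned deterministically from a master seed.

## Droplet-fusion chemistry

`swimtrap.chemistry` predicts post-fusion ion concentrations for
paired-droplet fusion by volume-weighted averaging (default equal volumes,
c_post = (c_cell + c_perturbant)/2), conserving solute exactly. Reported
values round to 3 significant figures with half-up ties (9.165 → 9.17;
banker's rounding would give 9.16) and concentrations below 0.075 mM render
as "negligible". No activity coefficients, osmolarity or speciation — the
assay interpretation needs only conservative dilution arithmetic.

## Numerical and testing notes

- Problem sizes: simulator checks use 60 s runs at dt = 10⁻⁴ s (20-seed
  ensembles for sign tests); pipeline rate-recovery uses single 600 s
  recordings at 500 Hz per phenotype; distributional identities use 10⁶
  samples. These sizes put sampling error well below the tested tolerances
  while keeping the whole suite interactive.
- Determinism: every stochastic component takes a seed; identical seeds give
  bit-identical output (numpy `default_rng`, noise drawn up front for the
  simulator kernel).
- Rate-recovery tolerances are ±3 standard errors with SE = √n_ij / (time in
  state i), the Poisson sampling error of a count-based rate estimate.
- Degenerate inputs: stationary tracks yield v = 0 with held heading; states
  with zero occupancy produce zero (not NaN) network rows with a logged
  warning; empty annuli in tangential profiles are NaN-flagged; an
  all-too-short run list yields an explicitly flagged empty spectrum.
- Known limitations: segmentation timing of ms-scale events is biased by the
  smoothing stencil (see above); the generator's specular walls are
  unphysical near boundaries; the dumbbell model omits hydrodynamic wall
  coupling and 3D motion, and PO's excitable gait is not represented in the
  physical model (the generator owns it).
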