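# swimtrap

Single-cell motility phenotyping in circular microfluidic confinement.

Micron-scale algae trapped one-per-droplet in circular arenas can be tracked
at 500 frames per second for an hour — long enough to phenotype an
*individual* cell's swimming repertoire. `swimtrap` provides the
computational core of such an assay for two contrasting phenotypes: a
biflagellate CR-type swimmer (continuous runs at ~80 µm/s with a ~52 Hz
ciliary beat, interrupted by stops and tumbles) and an octoflagellate
PO-type swimmer (episodic 300–400 µm/s runs, long quiescent stops, and
millisecond backward "shocks" exceeding 1 mm/s). The package is aimed at
behavioural biophysicists who want to simulate, generate and analyse such
trajectories without the microscopy.

## What it computes

**Physical model.** A chiral active dumbbell in a circular trap: body sphere
(radius a₂) at **x**, cilia-envelope sphere (radius a₁ > a₂) at
**x** + ℓ·ê(φ+θ), propulsion v₀·ê(φ), overdamped Langevin dynamics

  dx = [v₀ ê(φ) + µ_t ΣF_wall] dt + √(2D_t dt) ξ,
  dφ = µ_r τ dt + √(2D_r dt) ξ_φ,

with harmonic steric wall forces and the torque about the sphere-centre
midpoint. The offset angle θ (CCW positive, viewed from above in the lab
frame) is the only broken mirror symmetry: θ > 0 produces counter-clockwise
boundary circulation, θ < 0 clockwise, θ = 0 none — a non-equilibrium chiral
steady state from a purely internal asymmetry.

**Trajectory analysis.**

- per-sample kinematics v, heading, Ω = dφ/dt, dΩ/dt (`kinematics`);
- three-macrostate gait segmentation S(t) ∈ {stop 0, run 1, tumble/shock 2}
  by thresholds + dwell-time debouncing (`segmentation`);
- the gait reaction network: state probabilities p_i, sojourn times T_i,
  survival curves P(T_i > τ), transition probabilities p_ij and rates
  q_ij = n_ij / (time in i) (`network`);
- spatial statistics over the trap disk: occupancy heatmaps, time-averaged
  probability-flux vector fields (per-bin conditional mean velocity, with an
  exact telescoping-conservation identity), radial densities P(r),
  tangential-flux profiles and MSD (`spatial`);
- prominent beat frequencies from the transverse displacement of helical run
  segments, by baseline-whitened Welch spectra (`kinematics`);
- a labelled synthetic-behaviour generator — CTMC gait switching with
  state-specific kinematics — so the whole pipeline is testable end to end
  (`behaviour`);
- post-fusion ion arithmetic for paired-droplet chemical perturbation
  (`chemistry`).

See `docs/methods.md` for models, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from swimtrap import (SwimmerConfig, SimRun, simulate, occupancy_flux,
                      mean_tangential_flux, radial_density, BehaviourConfig,
                      generate, compute_kinematics, classify_states,
                      estimate_network, AnalysisConfig)

# 1. Chiral dumbbell in a 40 um trap, red-light config (v0=80 um/s, theta=+1.5deg)
traj = simulate(SwimmerConfig.rl_defaults(),
                SimRun(duration=60.0, seed=1, trap_radius=20.0))
field = occupancy_flux(traj)
print(f"mean tangential flux: {mean_tangential_flux(field):+.2f} um/s")
print(f"radial density peak: {radial_density(traj).peak_radius():.1f} um")

# 2. Synthetic CR-type cell -> segmentation -> gait network
lt = generate(BehaviourConfig.cr_defaults(), 600.0, seed=8)
kin = compute_kinematics(lt.trajectory)
states = classify_states(kin, AnalysisConfig.cr_defaults())
net = estimate_network(states)
print("state probabilities p =", np.round(net.p, 3))
print("q12 = %.3f /s   q21 = %.3f /s" % (net.Q[1, 2], net.Q[2, 1]))
```

prints

```
mean tangential flux: +18.30 um/s
radial density peak: 7.0 um
state probabilities p = [0.045 0.936 0.019]
q12 = 0.119 /s   q21 = 5.432 /s
```

The positive tangential flux is the counter-clockwise chiral circulation
induced by θ = +1.5° under strong confinement; the density peak sits half a
cell diameter from the Ø 40 µm trap wall (boundary accumulation). The
recovered network says the synthetic cell spends 94% of its time running,
switches run→tumble about every 8 s, and leaves a tumble at ~5 s⁻¹ —
matching the generator's configured rates (q12 = 0.15, q21 = 4.5 s⁻¹)
within sampling error.

A command-line interface mirrors the library:

```
swimtrap --seed 7 simulate --trap-diameter 120 --theta 1.5 --v0 80 \
         --duration 300 --out traj.csv
swimtrap segment traj.csv --mode CR --trap-diameter 120
swimtrap network states.csv
swimtrap fuse --pre medium.csv --add kcl.csv --ratio 0.5
```

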