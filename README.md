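# csmkinetics

Quantitative analysis of how the type III-A CRISPR–Cas effector (the Csm
complex) retains the ends of its cleaved target RNA, and how that retention
gates the single-stranded DNase activity of its Cas10 subunit.

Type III CRISPR effectors cleave a recognized target RNA within seconds, yet
their downstream activities — ssDNA cleavage and cyclic-oligoadenylate
synthesis — persist for roughly an hour.  The resolution of this apparent
paradox is kinetic: the short internal RNA fragments leave quickly, but the
terminal RNA fragments stay bound to the complex for tens of minutes and keep
Cas10 switched on.  This package implements the complete analysis chain used
to measure and model that behaviour:

* **Fluorescence (cross-)correlation spectroscopy** (`csmkinetics.correlate`,
  `csmkinetics.fcs`).  Intensity traces are correlated on a multi-tau lag
  grid, G<sub>ij</sub>(τ) = ⟨F<sub>i</sub>(t)F<sub>j</sub>(t+τ)⟩ /
  (⟨F<sub>i</sub>⟩⟨F<sub>j</sub>⟩) − 1, and fitted with the 3D-Gaussian
  confocal diffusion model
  g(τ) = (1+τ/τ_D)⁻¹ (1+τ/(κ²τ_D))^(−1/2), optionally with two diffusing
  species and a triplet term.  Sliding-window correlation turns a reaction
  time course into amplitude / mean-diffusion-time kinetics, which are fitted
  with R(t) = (1−R₀)e^(−t/⟨t⟩) + R₀ or a constrained bi-exponential decay.
* **TIRF survival analysis** (`csmkinetics.tirf`).  Per-spot intensity
  trajectories are smoothed, normalized, scored for disappearance below 10 %
  of the initial intensity, aggregated into survival curves, and corrected for
  photobleaching by dividing by a no-enzyme control.
* **DNase kinetics** (`csmkinetics.dnase`).  A fluorophore-quencher reporter
  assay is calibrated to cleaved-DNA concentration; activation bursts are
  fitted with A(1−e^(−t/⟨t⟩)) (+ c·t); and a six-species mass-action ODE
  model of RNA-gated ssDNA cleavage (non-activated/activated complex, free
  and bound reporter, product) is simulated and globally fitted across a
  ± RNA ssDNA titration, yielding k_bind±, k_cleave^N, k_cleave^A and the
  deactivation rate k_RNA⁻ (RNA-end release), plus the derived
  K_d = k_bind⁻/k_bind⁺.
* **Synthetic data** (`csmkinetics.synthetic`).  Brownian-dynamics FCS traces
  (point emitters in a periodic box, 3D-Gaussian detection, Poisson shot
  noise, optional dark-state blinking), TIRF spot cohorts with exponential
  release/bleaching, and forward-simulated titrations — so every stage of the
  analysis is testable by parameter recovery without any external data.
* **Workflows** (`csmkinetics.workflow`).  Scenario presets (activating /
  non-activating / RNase-dead / no-metal / competitor …) and end-to-end
  pipelines with cross-assay consistency checks.

## Worked example

```python
import numpy as np
from csmkinetics import (
    DecaySimConfig, simulate_decay_series, fit_exp_plateau, joint_release_time,
)

# normalized cross-correlation amplitude decaying with the measured
# release kinetics (mean time 84 min, 8.7 % residual amplitude)
cfg = DecaySimConfig(
    model="exp_plateau",
    true_params={"mean_time": 84.0, "plateau": 0.087},
    sampling_interval=1.0, duration=180.0, noise_sd=0.02, rng_seed=1,
)
fit = fit_exp_plateau(simulate_decay_series(cfg))
print(f"mean release time: {fit.mean_time:.1f} min, plateau: {fit.plateau:.3f}")
print(f"independence prediction: {joint_release_time(84.0, 119.0):.1f} min")
```

prints

```
mean release time: 83.2 min, plateau: 0.088
independence prediction: 49.2 min
```

The first line is the release timescale recovered from a noisy synthetic
amplitude series; the second is the decay time the cross-correlation *would*
show if the two RNA ends released independently (1/(1/t_a+1/t_b) of the
single-end times 84 and 119 min).  The measured cross-correlation decay
(~84 min) is much slower than this ~49-min prediction — the signature of
cooperative release of the two ends.

A full scenario reproduction, from the command line:

```bash
csmkinetics run release --scenario activating --seed 1
csmkinetics run dnase --scenario activating --seed 1
```

## Acceptance script

`scripts/acceptance.py` regenerates every headline quantity from scratch:
the analytic independence prediction, exponential / bi-exponential /
activation fit recoveries on synthetic series generated from the published
fit values, and the mean deactivation time 1/k_RNA⁻ from the global ODE fit
of a synthetic ± RNA ssDNA titration.  Run it as

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It writes one JSON object per target id with the recovered value (in the
units used in the study) and the problem size; the global-fit stage takes a
few minutes on one CPU.

See `docs/methods.md` for the model definitions, parameter conventions,
numerical choices and known limitations.
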