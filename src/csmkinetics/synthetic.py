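"""Synthetic data generators for every analysis stage.

All generators are deterministic given their ``rng_seed`` and produce data
with the statistical structure the analysis models assume:

* :func:`simulate_fcs_trace` — Brownian dynamics of point emitters in a
  periodic box, detected through a 3D-Gaussian molecular detection function
  (MDF) with Poisson shot noise; exercises the correlator and the diffusion
  models.  The analytic ground truth of a species is tau_D = w0^2 / 4 D.
* :func:`simulate_release_experiment` — a sequence of such traces in which
  the fraction of dual-labeled (both-ends-bound) complexes decays
  exponentially window by window, emulating a time-resolved release
  measurement (optionally with compressed time: one analysis window per
  reaction minute).
* :func:`simulate_decay_series` — closed-form decay/activation models plus
  i.i.d. Gaussian noise.
* :func:`simulate_spot_trajectories` — TIRF spots with independent
  exponential release and photobleaching times and Gaussian intensity noise.
* :func:`simulate_titration` — forward ODE simulation of the DNase scheme
  across a ssDNA titration with additive Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .correlate import IntensityTrace
from .dnase import DnaseTrace, KineticParams, TitrationDataset, simulate_kinetics
from .errors import InvalidConfigError
from .fcs import KineticsSeries
from .models import DECAY_MODELS, exp_plateau
from .tirf import SpotTrajectory

__all__ = [
    "FcsSpecies",
    "FcsSimConfig",
    "DecaySimConfig",
    "TirfSimConfig",
    "TitrationSimConfig",
    "simulate_fcs_trace",
    "simulate_release_experiment",
    "simulate_decay_series",
    "simulate_spot_trajectories",
    "simulate_titration",
]


@dataclass(frozen=True)
class FcsSpecies:
    """One diffusing emitter species.

    ``brightness`` is the molecular brightness at the focus center in
    counts/s per detection channel (length 1 or 2; a dual-labeled species
    emits in both).  Optional dark-state blinking is a two-state telegraph
    process with equilibrium dark fraction ``triplet_fraction`` and
    relaxation time ``triplet_time``.
    """

    n_particles: int
    diffusion_coefficient: float  # um^2/s
    brightness: tuple  # counts/s per channel at focus center
    triplet_fraction: float = 0.0
    triplet_time: float = 0.0

    def tau_d(self, w0: float) -> float:
        """Analytic diffusion time w0^2 / 4D."""
        return w0**2 / (4.0 * self.diffusion_coefficient)


@dataclass(frozen=True)
class FcsSimConfig:
    """Brownian-dynamics FCS simulation parameters (lengths in um, times in s)."""

    species: tuple  # of FcsSpecies
    focus_waist_xy: float = 0.25  # w0
    focus_waist_z: float = 1.25  # z0 (default structure factor kappa = 5)
    box_size: float | None = None  # periodic box edge; default max(10 w0, 4 z0)
    timestep: float = 2e-5
    duration: float = 10.0
    bin_width: float = 4e-5
    background_rate: tuple = (0.0, 0.0)  # counts/s per channel
    rng_seed: int = 0

    def __post_init__(self):
        if self.timestep <= 0 or self.duration <= 0 or self.bin_width <= 0:
            raise InvalidConfigError("timestep, duration and bin_width must be positive")
        if self.timestep > self.bin_width:
            raise InvalidConfigError("timestep must not exceed bin_width")
        steps = self.bin_width / self.timestep
        if abs(steps - round(steps)) > 1e-9:
            raise InvalidConfigError("bin_width must be an integer multiple of timestep")
        if any(r < 0 for r in self.background_rate):
            raise InvalidConfigError("background rates must be non-negative")
        for sp in self.species:
            if any(b < 0 for b in sp.brightness):
                raise InvalidConfigError("brightness must be non-negative")
        if self.effective_box_size < 10.0 * self.focus_waist_xy:
            raise InvalidConfigError("box_size must be at least 10 * focus_waist_xy")

    @property
    def effective_box_size(self) -> float:
        if self.box_size is not None:
            return self.box_size
        return max(10.0 * self.focus_waist_xy, 4.0 * self.focus_waist_z)

    @property
    def kappa(self) -> float:
        return self.focus_waist_z / self.focus_waist_xy

    @property
    def n_channels(self) -> int:
        return max([len(self.background_rate)] + [len(s.brightness) for s in self.species])


def _blink_switch_times(rng, dark_fraction, relax_time, duration):
    """Alternating bright/dark switch times of a two-state telegraph process.

    Returns (initial_bright, switch_times).  Transition rates follow from the
    equilibrium dark fraction T and the relaxation time tau:
    bright->dark rate T/tau, dark->bright rate (1-T)/tau.
    """
    k_bd = dark_fraction / relax_time
    k_db = (1.0 - dark_fraction) / relax_time
    bright = rng.random() >= dark_fraction
    times = []
    t = 0.0
    state = bright
    while t < duration:
        rate = k_bd if state else k_db
        t += rng.exponential(1.0 / rate)
        times.append(t)
        state = not state
    return bright, np.array(times)


def simulate_fcs_trace(config: FcsSimConfig, chunk_steps: int = 20000) -> IntensityTrace:
    """Brownian-dynamics simulation of a binned two-channel intensity trace.

    Particles take Gaussian steps of standard deviation sqrt(2 D dt) per axis
    in a periodic cubic box; the expected count rate of a particle at offset
    (dx, dy, dz) from the focus center is
    brightness * exp(-2 (dx^2+dy^2)/w0^2 - 2 dz^2/z0^2).  Expected counts are
    accumulated per time step, summed into bins, and Poisson-sampled together
    with the uniform background.
    """
    rng = np.random.default_rng(config.rng_seed)
    steps_per_bin = int(round(config.bin_width / config.timestep))
    n_bins = int(round(config.duration / config.bin_width))
    n_steps = n_bins * steps_per_bin
    if n_bins < 1:
        raise InvalidConfigError("duration shorter than one bin")
    box = config.effective_box_size
    w0, z0 = config.focus_waist_xy, config.focus_waist_z
    n_ch = config.n_channels
    center = box / 2.0

    expected = np.zeros((n_ch, n_steps))
    for sp in config.species:
        if sp.n_particles == 0 or not any(sp.brightness):
            continue
        # single precision throughout the Brownian core: position error is
        # far below the focus scale and it roughly halves the runtime
        pos = rng.uniform(0.0, box, size=(sp.n_particles, 3)).astype(np.float32)
        step_sd = np.float32(math.sqrt(2.0 * sp.diffusion_coefficient * config.timestep))
        blink = sp.triplet_fraction > 0.0 and sp.triplet_time > 0.0
        if blink:
            switch = [
                _blink_switch_times(
                    rng, sp.triplet_fraction, sp.triplet_time, n_steps * config.timestep
                )
                for _ in range(sp.n_particles)
            ]
        mdf_sum = np.empty(n_steps)
        for start in range(0, n_steps, chunk_steps):
            stop = min(start + chunk_steps, n_steps)
            m = stop - start
            disp = rng.standard_normal((m, sp.n_particles, 3), dtype=np.float32)
            disp *= step_sd
            traj = (pos[None, :, :] + np.cumsum(disp, axis=0, dtype=np.float32)) % np.float32(box)
            pos = traj[-1]
            d = traj - np.float32(center)
            arg = (d[:, :, 0] ** 2 + d[:, :, 1] ** 2) / np.float32(w0**2) + d[
                :, :, 2
            ] ** 2 / np.float32(z0**2)
            mdf = np.exp(np.float32(-2.0) * arg)
            if blink:
                t_steps = (np.arange(start, stop) + 0.5) * config.timestep
                for p, (bright0, times) in enumerate(switch):
                    n_switch = np.searchsorted(times, t_steps)
                    bright = (n_switch % 2 == 0) == bright0
                    mdf[:, p] *= bright
            mdf_sum[start:stop] = mdf.sum(axis=1)
        for c in range(n_ch):
            b = sp.brightness[c] if c < len(sp.brightness) else 0.0
            if b > 0:
                expected[c] += b * config.timestep * mdf_sum

    counts = np.empty((n_ch, n_bins))
    for c in range(n_ch):
        per_bin = expected[c].reshape(n_bins, steps_per_bin).sum(axis=1)
        bg = config.background_rate[c] if c < len(config.background_rate) else 0.0
        counts[c] = rng.poisson(per_bin + bg * config.bin_width)
    return IntensityTrace(counts, config.bin_width)


def simulate_release_experiment(
    n_windows: int,
    window_duration: float,
    release_mean_windows: float,
    plateau: float = 0.0,
    n_complexes: int = 100,
    diffusion_bound: float = 100.0,
    diffusion_free: float = 400.0,
    brightness: tuple = (1.5e5, 1.5e5),
    base: FcsSimConfig | None = None,
    rng_seed: int = 0,
) -> IntensityTrace:
    """Dual-color trace whose dual-labeled fraction decays window by window.

    For analysis window k (reaction time t_k = k in window units) the bound
    fraction is (1 - plateau) exp(-t_k / release_mean_windows) + plateau; that
    share of the complexes still carries both labels and diffuses slowly,
    while released complexes are replaced by two independent single-labeled
    fast species.  Each window is simulated as a stationary trace and the
    windows are concatenated, emulating a time-compressed release measurement
    (one window per reaction minute).
    """
    if n_windows < 2:
        raise InvalidConfigError("need at least 2 windows")
    if base is None:
        base = FcsSimConfig(species=(), duration=window_duration)
    rng = np.random.default_rng(rng_seed)
    chunks = []
    for k in range(n_windows):
        frac = exp_plateau(float(k), release_mean_windows, plateau)
        n_bound = int(round(frac * n_complexes))
        n_free = n_complexes - n_bound
        species = (
            FcsSpecies(n_bound, diffusion_bound, brightness),
            FcsSpecies(n_free, diffusion_free, (brightness[0], 0.0)),
            FcsSpecies(n_free, diffusion_free, (0.0, brightness[1])),
        )
        cfg = replace(
            base,
            species=species,
            duration=window_duration,
            rng_seed=int(rng.integers(2**31)),
        )
        chunks.append(simulate_fcs_trace(cfg).counts)
    return IntensityTrace(np.concatenate(chunks, axis=1), base.bin_width)


# ---------------------------------------------------------------------------
# closed-form decay series


@dataclass(frozen=True)
class DecaySimConfig:
    """Closed-form decay/activation series plus homoscedastic Gaussian noise.

    ``model`` is one of ``exp_plateau``, ``biexp``, ``activation``,
    ``activation_bg`` (see :mod:`csmkinetics.models`); ``true_params`` maps
    that model's parameter names to generating values.
    """

    model: str
    true_params: dict
    sampling_interval: float = 60.0
    duration: float = 10800.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.model not in DECAY_MODELS:
            raise InvalidConfigError(
                f"unknown model {self.model!r}; choose from {sorted(DECAY_MODELS)}"
            )
        if self.sampling_interval <= 0 or self.duration <= 0:
            raise InvalidConfigError("sampling_interval and duration must be positive")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        func, names = DECAY_MODELS[self.model]
        missing = set(names) - set(self.true_params)
        if missing:
            raise InvalidConfigError(f"missing parameters for {self.model}: {sorted(missing)}")
        for name in names:
            if name.startswith("mean_time") and self.true_params[name] <= 0:
                raise InvalidConfigError(f"{name} must be positive")


def simulate_decay_series(config: DecaySimConfig) -> KineticsSeries:
    """Evaluate the chosen model on a uniform grid and add Gaussian noise."""
    func, names = DECAY_MODELS[config.model]
    t = np.arange(0.0, config.duration + 0.5 * config.sampling_interval,
                  config.sampling_interval)
    y = func(t, *(config.true_params[name] for name in names))
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.rng_seed)
        y = y + rng.normal(0.0, config.noise_sd, size=t.size)
    return KineticsSeries(t, y, window_width=config.sampling_interval,
                          observable=config.model)


# ---------------------------------------------------------------------------
# TIRF spot trajectories


@dataclass(frozen=True)
class TirfSimConfig:
    """Spot trajectories with exponential release and photobleaching.

    Frame interval defaults to the experimental 20 s; mean times may be
    ``inf`` (event never occurs, e.g. release in a no-enzyme control).
    """

    n_spots: int
    mean_release_time: float = math.inf
    mean_bleach_time: float = math.inf
    frame_interval: float = 20.0
    n_frames: int = 180
    intensity_noise_sd: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_spots < 1:
            raise InvalidConfigError("n_spots must be >= 1")
        if self.n_frames < 1:
            raise InvalidConfigError("n_frames must be >= 1")
        if self.frame_interval <= 0:
            raise InvalidConfigError("frame_interval must be positive")
        if self.mean_release_time <= 0 or self.mean_bleach_time <= 0:
            raise InvalidConfigError("mean times must be positive (inf allowed)")


def simulate_spot_trajectories(config: TirfSimConfig) -> list:
    """Each spot is at unit intensity (plus noise) until the earlier of its
    release and bleach time, then at zero (plus noise)."""
    rng = np.random.default_rng(config.rng_seed)
    times = np.arange(config.n_frames) * config.frame_interval
    out = []
    for spot in range(config.n_spots):
        t_rel = (
            rng.exponential(config.mean_release_time)
            if math.isfinite(config.mean_release_time)
            else math.inf
        )
        t_bleach = (
            rng.exponential(config.mean_bleach_time)
            if math.isfinite(config.mean_bleach_time)
            else math.inf
        )
        dark_at = min(t_rel, t_bleach)
        intensity = np.where(times < dark_at, 1.0, 0.0)
        if config.intensity_noise_sd > 0:
            intensity = intensity + rng.normal(
                0.0, config.intensity_noise_sd, size=times.size
            )
        out.append(SpotTrajectory(spot, intensity, config.frame_interval))
    return out


# ---------------------------------------------------------------------------
# DNase titration


@dataclass(frozen=True)
class TitrationSimConfig:
    """Forward-simulated DNase traces across a ssDNA titration.

    Defaults follow the published assay: 2 nM complex, 2 nM activating target
    RNA (or 0 for background traces), 300 min of 1-s-interval recording
    starting ~10 s after mixing, over a range of reporter-DNA concentrations.
    ``noise_sd`` is in the cleaved-DNA (nM-equivalent) scale.
    """

    kinetic_params: KineticParams
    csm_total: float = 2.0
    rna_total: float = 2.0
    dna_concentrations: tuple = (12.5, 25.0, 50.0, 100.0)
    duration: float = 18000.0
    sampling_interval: float = 1.0
    first_time: float = 10.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if not self.dna_concentrations:
            raise InvalidConfigError("dna_concentrations must be non-empty")
        if min(self.dna_concentrations) < 0 or self.csm_total < 0 or self.rna_total < 0:
            raise InvalidConfigError("concentrations must be non-negative")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")


def simulate_titration(config: TitrationSimConfig) -> TitrationDataset:
    """Integrate the kinetic scheme for each DNA concentration and add noise."""
    rng = np.random.default_rng(config.rng_seed)
    times = np.arange(config.first_time, config.duration + 0.5 * config.sampling_interval,
                      config.sampling_interval)
    traces = []
    for dna in config.dna_concentrations:
        trace = simulate_kinetics(
            config.kinetic_params,
            {"csm_total": config.csm_total, "rna_total": config.rna_total,
             "dna_total": dna},
            times,
        )
        signal = trace.signal
        if config.noise_sd > 0:
            signal = signal + rng.normal(0.0, config.noise_sd, size=times.size)
        traces.append(
            DnaseTrace(
                times, signal,
                csm_total=config.csm_total, rna_total=config.rna_total, dna_total=dna,
                rna_type="activating" if config.rna_total > 0 else "none",
                calibrated=True,
            )
        )
    return TitrationDataset(traces)
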