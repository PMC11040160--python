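"""Survival analysis of surface-immobilized spot trajectories.

Each fluorescent spot reports one immobilized, labeled RNA 3'-end; a sudden
intensity drop marks either release of the RNA end by the enzyme or
photobleaching.  Trajectories are smoothed (3-point moving average),
normalized to the mean of their first 10 smoothed frames, and scored as
"disappeared" at the first frame below 10% of the initial intensity.  The
population survival curve measured with enzyme is divided by a no-enzyme
control (bleaching only) to isolate the release kinetics: for independent
exponential release and bleaching the expectation of the ratio is
exp(-t / T_release).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InvalidConfigError

__all__ = [
    "SpotTrajectory",
    "SurvivalCurve",
    "preprocess_trajectory",
    "disappearance_time",
    "survival_curve",
    "correct_survival",
    "fit_release_time",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.10
NORMALIZATION_FRAMES = 10


@dataclass
class SpotTrajectory:
    """Per-spot intensity versus frame; frame k is at time k * frame_interval."""

    spot_id: int
    intensities: np.ndarray
    frame_interval: float = 20.0
    normalized: bool = False

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.frame_interval <= 0:
            raise InvalidConfigError("frame_interval must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.intensities.size) * self.frame_interval


@dataclass
class SurvivalCurve:
    """Fraction of spots still fluorescent versus time since reaction start."""

    times: np.ndarray
    surviving_fraction: np.ndarray
    n_at_risk: int
    corrected: bool = False
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.surviving_fraction = np.asarray(self.surviving_fraction, dtype=float)


def _moving_average_3(x: np.ndarray) -> np.ndarray:
    """Centered 3-point moving average, shrinking to 2 points at the ends."""
    if x.size < 2:
        return x.copy()
    out = np.empty_like(x)
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    out[0] = (x[0] + x[1]) / 2.0
    out[-1] = (x[-2] + x[-1]) / 2.0
    return out


def preprocess_trajectory(traj: SpotTrajectory) -> SpotTrajectory:
    """Smooth with a 3-point moving average and normalize to the mean of the
    first 10 smoothed frames."""
    if traj.intensities.size < NORMALIZATION_FRAMES:
        raise InvalidConfigError(
            f"trajectory too short: {traj.intensities.size} < {NORMALIZATION_FRAMES} frames"
        )
    smoothed = _moving_average_3(traj.intensities)
    ref = smoothed[:NORMALIZATION_FRAMES].mean()
    if ref <= 0:
        raise InvalidConfigError("non-positive normalization reference intensity")
    return SpotTrajectory(traj.spot_id, smoothed / ref, traj.frame_interval, normalized=True)


def disappearance_time(
    traj: SpotTrajectory, threshold: float = DEFAULT_THRESHOLD
) -> float | None:
    """Time of the first smoothed, normalized frame below ``threshold``;
    ``None`` if the spot survives the recording (right-censored)."""
    if not traj.normalized:
        traj = preprocess_trajectory(traj)
    below = np.nonzero(traj.intensities < threshold)[0]
    if below.size == 0:
        return None
    return float(below[0] * traj.frame_interval)


def survival_curve(disappearance_times, time_grid) -> SurvivalCurve:
    """Empirical survival from per-spot disappearance times.

    ``disappearance_times`` is a sequence of times, with ``None`` (or inf) for
    censored spots; censored spots count as surviving through the recording.
    The survival at grid time t is the fraction of spots that had not
    disappeared by t (disappearance exactly at t counts as gone)."""
    times = np.array(
        [np.inf if t is None else float(t) for t in disappearance_times], dtype=float
    )
    if times.size == 0:
        raise InvalidConfigError("no spots supplied")
    grid = np.asarray(time_grid, dtype=float)
    surviving = (times[None, :] > grid[:, None]).mean(axis=1)
    return SurvivalCurve(grid, surviving, n_at_risk=times.size)


def correct_survival(sample: SurvivalCurve, control: SurvivalCurve) -> SurvivalCurve:
    """Bleaching correction: pointwise ratio sample / control, clipped to [0, 1].

    The control is interpolated onto the sample grid if the grids differ.  The
    curve is truncated (with a warning record) from the first time the control
    reaches zero.  The corrected curve is not forced to be monotonic."""
    ctrl = np.interp(sample.times, control.times, control.surviving_fraction)
    warnings = []
    valid = ctrl > 0
    if not valid.all():
        first_zero = int(np.argmin(valid))
        warnings.append(
            f"control survival reached 0 at t={sample.times[first_zero]:g}; curve truncated"
        )
        times = sample.times[:first_zero]
        ratio = sample.surviving_fraction[:first_zero] / ctrl[:first_zero]
    else:
        times = sample.times
        ratio = sample.surviving_fraction / ctrl
    if np.any(ratio > 1.0):
        warnings.append("corrected survival exceeded 1 at some times; clipped")
    ratio = np.clip(ratio, 0.0, 1.0)
    return SurvivalCurve(
        times, ratio, n_at_risk=sample.n_at_risk, corrected=True, warnings=warnings
    )


def fit_release_time(curve: SurvivalCurve, with_plateau: bool = False):
    """Fit S(t) = exp(-t/T) (optionally (1-R0) exp(-t/T) + R0) to a survival
    curve; returns (T, stderr) or (T, R0, stderr dict)."""
    t = curve.times
    y = curve.surviving_fraction
    span = max(t[-1] - t[0], 1e-9)
    try:
        if with_plateau:
            popt, pcov = curve_fit(
                lambda t, T, r0: (1 - r0) * np.exp(-t / T) + r0,
                t,
                y,
                p0=(span / 2.0, 0.0),
                bounds=([1e-12, 0.0], [np.inf, 1.0]),
                maxfev=20000,
            )
            perr = np.sqrt(np.diag(pcov))
            return popt[0], popt[1], {"mean_time": perr[0], "plateau": perr[1]}
        popt, pcov = curve_fit(
            lambda t, T: np.exp(-t / T), t, y, p0=(span / 2.0,), maxfev=20000
        )
    except RuntimeError as exc:
        raise FitFailureError(f"survival fit did not converge: {exc}") from exc
    return float(popt[0]), float(np.sqrt(pcov[0, 0]))
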