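"""Diffusion-model fitting of correlation curves and release kinetics.

Workflow, mirroring a dual-color FCS release experiment: an intensity trace is
cut into consecutive short windows (default 60 s); each window is correlated
(:func:`csmkinetics.correlate.correlate`) and fitted with the 3D-Gaussian
diffusion model; the per-window cross-correlation amplitude (proportional to
the concentration of complexes still carrying both labels) or the mean
diffusion time (shifting as bound label is released as faster free label)
forms a kinetics series; after normalization against a no-enzyme control the
series is fitted with an exponential-plus-plateau or a constrained
bi-exponential decay to extract release timescales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .correlate import CorrelationCurve, IntensityTrace, correlate
from .errors import (
    DegenerateControlError,
    DegenerateTraceError,
    FitFailureError,
    InvalidConfigError,
    InvalidParameterError,
)
from .models import biexp_decay, exp_plateau, g_diffusion_3d

__all__ = [
    "DiffusionModelSpec",
    "DiffusionFit",
    "ReleaseFit",
    "KineticsSeries",
    "fit_correlation",
    "sliding_window_kinetics",
    "normalize_series",
    "fit_exp_plateau",
    "fit_biexponential",
    "joint_release_time",
]


@dataclass(frozen=True)
class DiffusionModelSpec:
    """Which variant of the 3D diffusion model to fit.

    ``kappa`` (structure factor z0/w0) is held fixed unless ``fit_kappa``;
    freeing kappa together with two diffusion times is refused unless
    ``allow_unidentifiable`` because the two are strongly degenerate on a
    single curve.
    """

    n_species: int = 1
    triplet: bool = False
    kappa: float = 5.0
    fit_kappa: bool = False
    fit_offset: bool = False
    allow_unidentifiable: bool = False
    #: optional fixed values, e.g. {"tau_d1": 5e-3} or {"triplet_time": 2e-5}
    fixed: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_species not in (1, 2):
            raise InvalidConfigError("n_species must be 1 or 2")
        if self.fit_kappa and self.n_species == 2 and not self.allow_unidentifiable:
            raise InvalidConfigError(
                "freeing kappa and two diffusion times together is not identifiable; "
                "set allow_unidentifiable=True to override"
            )


@dataclass
class DiffusionFit:
    """Best-fit parameters of the 3D confocal diffusion model."""

    amplitude: float
    tau_d1: float
    offset: float = 0.0
    tau_d2: float | None = None
    fraction_1: float = 1.0
    triplet_fraction: float = 0.0
    triplet_time: float = 1.0
    kappa: float = 5.0
    stderr: dict = field(default_factory=dict)
    covariance: np.ndarray | None = None
    param_names: tuple = ()

    @property
    def mean_diffusion_time(self) -> float:
        """Fraction-weighted mean diffusion time of the fitted species."""
        if self.tau_d2 is None:
            return self.tau_d1
        return self.fraction_1 * self.tau_d1 + (1.0 - self.fraction_1) * self.tau_d2

    def __call__(self, tau):
        return g_diffusion_3d(
            tau,
            self.amplitude,
            self.tau_d1,
            offset=self.offset,
            tau_d2=self.tau_d2,
            fraction_1=self.fraction_1,
            triplet_fraction=self.triplet_fraction,
            triplet_time=self.triplet_time,
            kappa=self.kappa,
        )


@dataclass
class ReleaseFit:
    """Fitted release kinetics (single exponential + plateau or constrained
    bi-exponential).  ``mean_time_identifiable`` is cleared when the data do
    not constrain the corresponding timescale (flat series, vanishing
    amplitude)."""

    mean_time: float
    plateau: float | None = None
    mean_time_2: float | None = None
    a1: float | None = None
    a2: float | None = None
    offset: float | None = None
    stderr: dict = field(default_factory=dict)
    mean_time_identifiable: bool = True
    mean_time_2_identifiable: bool | None = None


@dataclass
class KineticsSeries:
    """An observable (cross amplitude or mean diffusion time) versus reaction
    time, one value per analysis window; NaN marks failed windows."""

    times: np.ndarray
    values: np.ndarray
    window_width: float = 60.0
    observable: str = ""
    normalized: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise InvalidConfigError("times and values must have equal length")


# ---------------------------------------------------------------------------
# correlation-curve fitting


def _initial_tau_d(curve: CorrelationCurve, amplitude: float) -> float:
    """Lag at which the curve first falls to half its zero-lag amplitude."""
    half = amplitude / 2.0
    below = np.nonzero(curve.values < half)[0]
    if below.size:
        return float(curve.lags[below[0]])
    return float(curve.lags[-1] / 2.0)


def fit_correlation(
    curve: CorrelationCurve, spec: DiffusionModelSpec = DiffusionModelSpec()
) -> DiffusionFit:
    """Weighted nonlinear least-squares fit of the 3D diffusion model.

    Needs at least 8 lag points.  Lag bins are weighted by the square root of
    the number of averaged products per lag when available (an approximate
    inverse-variance weighting), else uniformly.  Fixed parameters are taken
    from ``spec.fixed``; everything else is free within physical bounds.
    """
    if curve.lags.size < 8:
        raise DegenerateTraceError(f"need >= 8 lag points, got {curve.lags.size}")

    g0_guess = max(float(np.max(curve.values[:4])), 1e-6)
    tau_guess = spec.fixed.get("tau_d1", _initial_tau_d(curve, g0_guess))

    # (name, initial, lower, upper, free?)
    defs = [
        ("amplitude", g0_guess, 0.0, np.inf, True),
        ("tau_d1", tau_guess, 1e-12, np.inf, True),
    ]
    if spec.n_species == 2:
        defs += [
            ("tau_d2", tau_guess / 5.0, 1e-12, np.inf, True),
            ("fraction_1", 0.5, 0.0, 1.0, True),
        ]
    if spec.triplet:
        defs += [
            ("triplet_fraction", 0.1, 0.0, 0.999, True),
            ("triplet_time", curve.lags[0] * 2.0, 1e-12, np.inf, True),
        ]
    defs += [("kappa", spec.kappa, 1.0, 100.0, spec.fit_kappa)]
    defs += [("offset", 0.0, -np.inf, np.inf, spec.fit_offset)]

    fixed = dict(spec.fixed)
    free_names, p0, lo, hi = [], [], [], []
    values = {}
    for name, init, lower, upper, is_free in defs:
        if name in fixed:
            values[name] = float(fixed[name])
        elif is_free:
            free_names.append(name)
            p0.append(init)
            lo.append(lower)
            hi.append(upper)
        else:
            values[name] = init

    def model(tau, *params):
        kw = dict(values)
        kw.update(zip(free_names, params))
        return g_diffusion_3d(
            tau,
            kw["amplitude"],
            kw["tau_d1"],
            offset=kw.get("offset", 0.0),
            tau_d2=kw.get("tau_d2"),
            fraction_1=kw.get("fraction_1", 1.0),
            triplet_fraction=kw.get("triplet_fraction", 0.0),
            triplet_time=kw.get("triplet_time", 1.0),
            kappa=kw["kappa"],
        )

    sigma = None
    if curve.n_samples_per_lag is not None:
        sigma = 1.0 / np.sqrt(np.asarray(curve.n_samples_per_lag, dtype=float))

    try:
        popt, pcov = curve_fit(
            model,
            curve.lags,
            curve.values,
            p0=p0,
            sigma=sigma,
            bounds=(lo, hi),
            maxfev=20000,
        )
    except RuntimeError as exc:
        resid = float(np.linalg.norm(model(curve.lags, *p0) - curve.values))
        raise FitFailureError(f"diffusion fit did not converge: {exc}", resid) from exc

    values.update(zip(free_names, popt))
    perr = np.sqrt(np.diag(pcov))
    stderr = dict(zip(free_names, perr))
    fit = DiffusionFit(
        amplitude=values["amplitude"],
        tau_d1=values["tau_d1"],
        offset=values.get("offset", 0.0),
        tau_d2=values.get("tau_d2"),
        fraction_1=values.get("fraction_1", 1.0),
        triplet_fraction=values.get("triplet_fraction", 0.0),
        triplet_time=values.get("triplet_time", 1.0),
        kappa=values["kappa"],
        stderr=stderr,
        covariance=pcov,
        param_names=tuple(free_names),
    )
    # keep species 1 the slow (bound-like) species
    if fit.tau_d2 is not None and fit.tau_d2 > fit.tau_d1:
        fit = replace(
            fit, tau_d1=fit.tau_d2, tau_d2=fit.tau_d1, fraction_1=1.0 - fit.fraction_1
        )
    return fit


# ---------------------------------------------------------------------------
# sliding-window kinetics


def sliding_window_kinetics(
    trace: IntensityTrace,
    window: float = 60.0,
    observable: str = "cross_amplitude",
    spec: DiffusionModelSpec = DiffusionModelSpec(),
    pair: tuple[int, int] | None = None,
) -> KineticsSeries:
    """Correlate and fit consecutive windows of a trace.

    ``observable`` is ``"cross_amplitude"`` (zero-lag amplitude G0 of the
    cross-correlation, default channel pair (0, 1)) or
    ``"mean_diffusion_time"`` (fraction-weighted mean diffusion time from an
    autocorrelation fit, default channel (0, 0)).  Windows whose correlation
    or fit fails are reported as NaN, never dropped.
    """
    if observable not in ("cross_amplitude", "mean_diffusion_time"):
        raise InvalidConfigError(f"unknown observable {observable!r}")
    if pair is None:
        pair = (0, 1) if observable == "cross_amplitude" else (0, 0)
    n_windows = int(trace.duration / window + 1e-9)
    if n_windows < 2:
        raise InvalidConfigError("trace must cover at least 2 windows")

    times = np.empty(n_windows)
    values = np.empty(n_windows)
    for w in range(n_windows):
        times[w] = trace.start_time + (w + 0.5) * window
        try:
            curve = correlate(trace.slice_time(w * window, (w + 1) * window), pair)
            fit = fit_correlation(curve, spec)
        except (DegenerateTraceError, FitFailureError):
            values[w] = np.nan
            continue
        if observable == "cross_amplitude":
            # an extrapolated zero-lag amplitude far above the measured curve
            # marks a diverged window fit
            blown_up = fit.amplitude > 3.0 * max(float(np.max(curve.values)), 1e-12)
            values[w] = np.nan if blown_up else fit.amplitude
        else:
            # a diffusion time outside the measured lag span is unresolvable
            resolvable = curve.lags[0] / 2 <= fit.mean_diffusion_time <= curve.lags[-1] * 2
            values[w] = fit.mean_diffusion_time if resolvable else np.nan
    return KineticsSeries(times, values, window, observable)


def normalize_series(
    sample: KineticsSeries, control: KineticsSeries | None = None
) -> KineticsSeries:
    """Divide by a control series (linearly interpolated onto the sample time
    grid) and rescale so the first finite value is 1."""
    values = sample.values.copy()
    if control is not None:
        good = np.isfinite(control.values)
        if good.sum() < 2:
            raise DegenerateControlError("control series has fewer than 2 finite values")
        ctrl = np.interp(sample.times, control.times[good], control.values[good])
        if np.any(ctrl[np.isfinite(values)] <= 0):
            raise DegenerateControlError("control series non-positive at needed times")
        values = values / ctrl
    finite = np.nonzero(np.isfinite(values))[0]
    if finite.size == 0:
        raise DegenerateControlError("sample series has no finite values")
    first = values[finite[0]]
    if first <= 0:
        raise DegenerateControlError("first sample value non-positive; cannot normalize")
    return KineticsSeries(
        sample.times, values / first, sample.window_width, sample.observable, normalized=True
    )


# ---------------------------------------------------------------------------
# release-model fits


def _finite(series: KineticsSeries):
    good = np.isfinite(series.values)
    return series.times[good], series.values[good]


def fit_exp_plateau(series: KineticsSeries) -> ReleaseFit:
    """Fit R(t) = (1 - R0) exp(-t/<t>) + R0 to a normalized kinetics series.

    The mean time is flagged unidentifiable when the decaying amplitude is
    negligible or its relative standard error exceeds 1 (flat series or
    recording much shorter than the decay)."""
    t, y = _finite(series)
    if t.size < 5:
        raise InvalidConfigError(f"need >= 5 finite points, got {t.size}")
    span = t[-1] - t[0]
    p0 = (max(span / 3.0, 1e-9), max(min(float(y[-1]), 0.999), 0.0))
    try:
        popt, pcov = curve_fit(
            exp_plateau,
            t,
            y,
            p0=p0,
            # plateau of a normalized decay; slack above 1 tolerates noisy
            # normalization of a flat series
            bounds=([1e-12, 0.0], [np.inf, 1.5]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"exp-plateau fit did not converge: {exc}") from exc
    mean_time, plateau = popt
    perr = np.sqrt(np.diag(pcov))
    stderr = {"mean_time": perr[0], "plateau": perr[1]}
    amp = 1.0 - plateau
    resid_sd = float(np.std(y - exp_plateau(t, *popt)))
    # a decay is identifiable only if its amplitude clears the noise floor
    # and the timescale is constrained by the data
    identifiable = abs(amp) > max(1e-3, 3.0 * resid_sd) and (
        math.isfinite(stderr["mean_time"]) and stderr["mean_time"] < mean_time
    )
    return ReleaseFit(
        mean_time=mean_time,
        plateau=plateau,
        stderr=stderr,
        mean_time_identifiable=bool(identifiable),
    )


def fit_biexponential(series: KineticsSeries) -> ReleaseFit:
    """Fit the constrained bi-exponential decay
    tau(t) = A1 exp(-t/<t>1) + A2 exp(-t/<t>2) + tau0 with A1 = 1 - A2 - tau0.

    Timescales are returned ordered <t>1 < <t>2; the slow timescale is flagged
    unidentifiable when its amplitude is negligible."""
    t, y = _finite(series)
    if t.size < 8:
        raise InvalidConfigError(f"need >= 8 finite points, got {t.size}")
    span = t[-1] - t[0]
    p0 = (span / 20.0, span / 2.0, 0.3, max(min(float(y[-1]), 0.9), 0.0))
    try:
        popt, pcov = curve_fit(
            biexp_decay,
            t,
            y,
            p0=p0,
            bounds=([1e-12, 1e-12, 0.0, 0.0], [np.inf, np.inf, 1.0, 1.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"bi-exponential fit did not converge: {exc}") from exc
    t1, t2, a2, offset = popt
    perr = np.sqrt(np.diag(pcov))
    a1 = 1.0 - a2 - offset
    if t1 > t2:  # order fast < slow; amplitudes follow their timescales
        t1, t2 = t2, t1
        a1, a2 = a2, a1
        perr[[0, 1]] = perr[[1, 0]]
    stderr = {"mean_time_1": perr[0], "mean_time_2": perr[1], "a2": perr[2], "offset": perr[3]}
    # the slow component is meaningful only if it carries amplitude, is
    # constrained, and is actually separated from the fast timescale
    slow_ok = (
        abs(a2) > 1e-3 and math.isfinite(perr[1]) and perr[1] < t2 and t2 > 1.5 * t1
    )
    return ReleaseFit(
        mean_time=t1,
        mean_time_2=t2,
        a1=a1,
        a2=a2,
        offset=offset,
        stderr=stderr,
        mean_time_identifiable=abs(a1) > 1e-3,
        mean_time_2_identifiable=bool(slow_ok),
    )


def joint_release_time(t_a: float, t_b: float) -> float:
    """Mean time of the earlier of two independent exponential events.

    For two RNA ends releasing independently with mean times ``t_a`` and
    ``t_b``, the cross-correlation (which requires both ends bound) is
    predicted to decay with mean time 1/(1/t_a + 1/t_b).  Infinite inputs are
    allowed (a channel that never releases)."""
    if not (t_a > 0 and t_b > 0):
        raise InvalidParameterError("release times must be positive (inf allowed)")
    if math.isinf(t_a) and math.isinf(t_b):
        return math.inf
    return 1.0 / (1.0 / t_a + 1.0 / t_b)
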