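"""Fluorophore-quencher ssDNase assay analysis and the RNA-gated kinetic model.

The Cas10 subunit of the Csm effector cleaves single-stranded DNA; a
fluorophore-quencher labeled ssDNA reporter converts cleavage into a
fluorescence increase.  The minimal reaction scheme has six species, all in
nM:

    N   non-activated free complex        A   activated free complex
    NS  non-activated complex . ssDNA     AS  activated complex . ssDNA
    S   free reporter ssDNA               P   cleaved reporter ssDNA

Both complex forms share the same reversible DNA binding step (rate constants
``k_bind_plus`` in /(M s) and ``k_bind_minus`` in /s) and cleave-and-release
the bound DNA irreversibly (``k_cleave_n`` for the non-activated background,
``k_cleave_a`` for the activated complex).  The activated state is gated by
retained RNA ends: their release deactivates the complex (A -> N and
AS -> NS) with rate ``k_deact`` (the RNA-end release rate).  RNA binding is
treated as instantaneous at t = 0, so the initial activated pool is
min(RNA_total, Csm_total).  Two totals are conserved exactly:
N + A + NS + AS = Csm_total and S + NS + AS + P = DNA_total.

The fluorescence observable is signal_scale * (P + beta * (NS + AS)): bound
but uncleaved reporter already separates dye and quencher, which produces the
fast initial signal rise before any cleavage (``beta``, the bound-signal
fraction, defaults to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit, least_squares
from scipy.stats import linregress

from .errors import (
    CalibrationError,
    FitFailureError,
    IdentifiabilityError,
    InvalidConfigError,
    InvalidParameterError,
    SimulationError,
)
from .models import activation, activation_bg

__all__ = [
    "DnaseTrace",
    "TitrationDataset",
    "Calibration",
    "ActivationFit",
    "KineticParams",
    "ReactionState",
    "calibrate",
    "fit_activation",
    "kinetic_derivatives",
    "simulate_kinetics",
    "global_fit",
    "GlobalFitResult",
    "RATE_SEARCH_BOUNDS",
]

SPECIES = ("N", "A", "NS", "AS", "S", "P")


@dataclass
class DnaseTrace:
    """One fluorometer time series with its reaction composition."""

    times: np.ndarray
    signal: np.ndarray
    csm_total: float = 0.0
    rna_total: float = 0.0
    dna_total: float = 0.0
    rna_type: str = "none"  # activating | non_activating | nonspecific | none | split
    calibrated: bool = False
    states: np.ndarray | None = None  # (n_times, 6) species concentrations, if simulated

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise InvalidConfigError("times must be strictly increasing")
        if min(self.csm_total, self.rna_total, self.dna_total) < 0:
            raise InvalidConfigError("concentrations must be non-negative")


@dataclass
class TitrationDataset:
    """A set of traces sharing one enzyme preparation across a DNA titration."""

    traces: list

    def __iter__(self):
        return iter(self.traces)

    def __len__(self):
        return len(self.traces)


@dataclass
class Calibration:
    """Linear map between fluorescence units and cleaved DNA (nM)."""

    scale: float  # nM per fluorescence unit
    intercept: float  # fluorescence units at zero cleaved DNA
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_concentration(self, signal) -> np.ndarray:
        return (np.asarray(signal, dtype=float) - self.intercept) * self.scale

    def apply(self, trace: DnaseTrace) -> DnaseTrace:
        return replace(trace, signal=self.to_concentration(trace.signal), calibrated=True)


@dataclass
class ActivationFit:
    """Parameters of the saturating-exponential cleavage fit."""

    amplitude: float
    mean_time: float
    background_rate: float | None = None
    stderr: dict = field(default_factory=dict)


@dataclass
class KineticParams:
    """Rate constants of the six-species scheme plus signal parameters.

    ``k_bind_plus`` is in /(M s) at the interface (converted to /(nM s)
    internally); all other rates are /s.
    """

    k_bind_plus: float
    k_bind_minus: float
    k_cleave_n: float
    k_cleave_a: float
    k_deact: float
    signal_scale: float = 1.0
    bound_signal_fraction: float = 1.0

    def __post_init__(self):
        rates = (self.k_bind_plus, self.k_bind_minus, self.k_cleave_n, self.k_cleave_a,
                 self.k_deact)
        if any(k < 0 for k in rates):
            raise InvalidParameterError("rate constants must be non-negative")
        if not 0.0 <= self.bound_signal_fraction <= 1.0:
            raise InvalidParameterError("bound_signal_fraction must be in [0, 1]")

    @property
    def kd(self) -> float:
        """Dissociation constant k_bind_minus / k_bind_plus, in M."""
        return self.k_bind_minus / self.k_bind_plus


#: rate constants fitted from the published titration; time base seconds
PUBLISHED_RATES = KineticParams(
    k_bind_plus=6.6e3,  # /(M s)
    k_bind_minus=1.1e-2,  # /s
    k_cleave_n=1.9e-4,  # /s
    k_cleave_a=8.5e-3,  # /s
    k_deact=1.9e-4,  # /s  (RNA-end release; 1/k ~ 88 min)
)

RATE_NAMES = ("k_bind_plus", "k_bind_minus", "k_cleave_n", "k_cleave_a", "k_deact")

#: log-uniform multi-start search bounds for the global fit
RATE_SEARCH_BOUNDS = {
    "k_bind_plus": (1e2, 1e6),
    "k_bind_minus": (1e-4, 1e0),
    "k_cleave_n": (1e-6, 1e-1),
    "k_cleave_a": (1e-5, 1e0),
    "k_deact": (1e-6, 1e-2),
}


@dataclass
class ReactionState:
    """Instantaneous species concentrations (nM)."""

    n: float
    a: float
    ns: float
    as_: float
    s: float
    p: float

    def to_array(self) -> np.ndarray:
        return np.array([self.n, self.a, self.ns, self.as_, self.s, self.p])

    @classmethod
    def from_array(cls, y) -> "ReactionState":
        return cls(*map(float, y))


def _rhs(y, kp_nm, km, kcn, kca, kd):
    n, a, ns, as_, s, p = y
    bind_n = kp_nm * n * s
    bind_a = kp_nm * a * s
    return np.array(
        [
            -bind_n + km * ns + kcn * ns + kd * a,
            -bind_a + km * as_ + kca * as_ - kd * a,
            bind_n - km * ns - kcn * ns + kd * as_,
            bind_a - km * as_ - kca * as_ - kd * as_,
            -(bind_n + bind_a) + km * (ns + as_),
            kcn * ns + kca * as_,
        ]
    )


def kinetic_derivatives(state: ReactionState, params: KineticParams) -> ReactionState:
    """Mass-action time derivatives of the six-species scheme (nM/s).

    By construction d(N+A+NS+AS)/dt = 0 and d(S+NS+AS+P)/dt = 0.
    """
    y = state.to_array()
    if np.any(y < -1e-9):
        raise InvalidParameterError("state concentrations must be non-negative")
    dy = _rhs(
        y,
        params.k_bind_plus * 1e-9,
        params.k_bind_minus,
        params.k_cleave_n,
        params.k_cleave_a,
        params.k_deact,
    )
    return ReactionState.from_array(dy)


def _jacobian(y, kp_nm, km, kcn, kca, kd):
    n, a, ns, as_, s, _ = y
    J = np.zeros((6, 6))
    # columns: d/dN, d/dA, d/dNS, d/dAS, d/dS, d/dP
    J[0] = [-kp_nm * s, kd, km + kcn, 0.0, -kp_nm * n, 0.0]
    J[1] = [0.0, -kp_nm * s - kd, 0.0, km + kca, -kp_nm * a, 0.0]
    J[2] = [kp_nm * s, 0.0, -km - kcn, kd, kp_nm * n, 0.0]
    J[3] = [0.0, kp_nm * s, 0.0, -km - kca - kd, kp_nm * a, 0.0]
    J[4] = [-kp_nm * s, -kp_nm * s, km, km, -kp_nm * (n + a), 0.0]
    J[5] = [0.0, 0.0, kcn, kca, 0.0, 0.0]
    return J


def simulate_kinetics(
    params: KineticParams,
    init: dict,
    times,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> DnaseTrace:
    """Integrate the scheme and return the fluorescence observable.

    ``init`` holds ``csm_total``, ``rna_total`` and ``dna_total`` in nM.  RNA
    binding is instantaneous: A(0) = min(rna_total, csm_total),
    N(0) = csm_total - A(0), S(0) = dna_total, all other species 0.  The
    returned trace carries the full species matrix in ``states``.
    """
    times = np.asarray(times, dtype=float)
    csm = float(init["csm_total"])
    rna = float(init.get("rna_total", 0.0))
    dna = float(init["dna_total"])
    if min(csm, rna, dna) < 0:
        raise InvalidConfigError("concentrations must be non-negative")
    a0 = min(rna, csm)
    y0 = np.array([csm - a0, a0, 0.0, 0.0, dna, 0.0])
    args = (
        params.k_bind_plus * 1e-9,
        params.k_bind_minus,
        params.k_cleave_n,
        params.k_cleave_a,
        params.k_deact,
    )
    t0 = min(0.0, times[0])
    sol = solve_ivp(
        lambda t, y: _rhs(y, *args),
        (t0, times[-1]),
        y0,
        t_eval=times,
        method=method,
        jac=lambda t, y: _jacobian(y, *args),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"ODE integration failed: {sol.message}")
    states = sol.y.T
    ns, as_, p = states[:, 2], states[:, 3], states[:, 5]
    signal = params.signal_scale * (p + params.bound_signal_fraction * (ns + as_))
    return DnaseTrace(
        times,
        signal,
        csm_total=csm,
        rna_total=rna,
        dna_total=dna,
        rna_type="activating" if rna > 0 else "none",
        calibrated=True,
        states=states,
    )


# ---------------------------------------------------------------------------
# calibration and single-trace fits


def calibrate(plateau_points) -> Calibration:
    """Fit the linear signal calibration from saturated endpoints.

    ``plateau_points`` is a sequence of (known fully-cleaved DNA amount in nM,
    saturated fluorescence signal); at least 2 points spanning a >= 2-fold
    range in amount are required.  Fits signal = amount / scale + intercept.
    """
    pts = np.asarray(plateau_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise CalibrationError("need at least 2 calibration points")
    amounts, signals = pts[:, 0], pts[:, 1]
    if amounts.min() <= 0 or amounts.max() / amounts.min() < 2.0:
        raise CalibrationError("calibration amounts must span at least a 2-fold range")
    res = linregress(amounts, signals)
    if res.slope <= 0:
        raise CalibrationError(f"non-positive calibration slope {res.slope:g}")
    scale = 1.0 / res.slope
    predicted = res.slope * amounts + res.intercept
    return Calibration(scale=scale, intercept=res.intercept, residuals=signals - predicted)


def fit_activation(trace: DnaseTrace, with_background: bool = False) -> ActivationFit:
    """Fit F(t) = A (1 - exp(-t/<t>)) (+ c t with background) to a calibrated
    cleavage trace."""
    if trace.times.size < 20:
        raise InvalidConfigError(f"need >= 20 points, got {trace.times.size}")
    t, y = trace.times, trace.signal
    a0 = max(float(y[-1]), 1e-9)
    t0 = max((t[-1] - t[0]) / 3.0, 1e-9)
    try:
        if with_background:
            slope0 = max(float(y[-1] - y[len(y) // 2]) / (t[-1] - t[len(y) // 2]), 0.0)
            popt, pcov = curve_fit(
                activation_bg,
                t,
                y,
                p0=(a0, t0, slope0),
                bounds=([0.0, 1e-12, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            perr = np.sqrt(np.diag(pcov))
            return ActivationFit(
                amplitude=popt[0],
                mean_time=popt[1],
                background_rate=popt[2],
                stderr={"amplitude": perr[0], "mean_time": perr[1], "background_rate": perr[2]},
            )
        popt, pcov = curve_fit(
            activation, t, y, p0=(a0, t0),
            bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"activation fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    return ActivationFit(
        amplitude=popt[0], mean_time=popt[1],
        stderr={"amplitude": perr[0], "mean_time": perr[1]},
    )


# ---------------------------------------------------------------------------
# global fit


@dataclass
class GlobalFitResult:
    params: KineticParams
    stderr: dict
    cost: float
    unidentifiable: list
    flat_directions: list
    n_starts: int

    @property
    def kd(self) -> float:
        return self.params.kd

    @property
    def deactivation_mean_time(self) -> float:
        """1 / k_deact in seconds."""
        return 1.0 / self.params.k_deact


def _estimate_noise_sd(trace: DnaseTrace) -> float:
    """Point noise level from the median absolute successive difference.

    Robust to the smooth kinetic trend (which contributes little to
    first differences at the assay's sampling rate)."""
    diffs = np.abs(np.diff(trace.signal))
    sd = float(np.median(diffs)) / (np.sqrt(2.0) * 0.6745)
    return max(sd, 1e-4 * max(float(np.ptp(trace.signal)), 1e-12))


def global_fit(
    dataset: TitrationDataset,
    free: tuple = RATE_NAMES,
    initial: KineticParams | None = None,
    bounds: dict | None = None,
    n_starts: int = 10,
    seed: int = 0,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> GlobalFitResult:
    """Simultaneous least-squares fit of one parameter set to all traces.

    All traces share a single :class:`KineticParams`; residuals are weighted
    per trace by the noise level estimated from its first 30 s.  The optimizer
    is multi-started from ``n_starts`` log-uniform draws within ``bounds``
    (seeded, so the fit is reproducible); the draws are pre-screened by their
    objective value and the best few are polished with trust-region least
    squares in log-parameter space.

    Raises :class:`IdentifiabilityError` for an under-determined configuration
    (fewer than 2 traces or fewer than 2 distinct DNA concentrations).
    Activation-specific parameters (``k_cleave_a``, ``k_deact``) cannot be
    constrained without any RNA-containing trace; they are dropped from the
    free set and reported in ``unidentifiable``.
    """
    traces = list(dataset)
    if len(traces) < 2:
        raise IdentifiabilityError("global fit needs at least 2 traces")
    dna_levels = {round(tr.dna_total, 9) for tr in traces}
    if len(dna_levels) < 2:
        raise IdentifiabilityError("global fit needs at least 2 DNA concentrations")
    has_rna = any(tr.rna_total > 0 for tr in traces)

    free = list(free)
    unidentifiable = []
    if not has_rna:
        for name in ("k_cleave_a", "k_deact"):
            if name in free:
                free.remove(name)
                unidentifiable.append(name)
    if not free:
        raise IdentifiabilityError("no identifiable free parameters")

    if initial is None:
        initial = KineticParams(
            k_bind_plus=1e4, k_bind_minus=1e-2, k_cleave_n=1e-4,
            k_cleave_a=1e-3, k_deact=2e-4,
        )
    search = dict(RATE_SEARCH_BOUNDS)
    if bounds:
        search.update(bounds)

    weights = np.array([1.0 / _estimate_noise_sd(tr) for tr in traces])

    def make_residuals(solver_rtol, solver_atol):
        def residuals(logx):
            values = {name: v for name, v in zip(free, 10.0**logx)}
            p = replace(initial, **values)
            out = []
            for tr, w in zip(traces, weights):
                try:
                    sim = simulate_kinetics(
                        p,
                        {"csm_total": tr.csm_total, "rna_total": tr.rna_total,
                         "dna_total": tr.dna_total},
                        tr.times,
                        rtol=solver_rtol,
                        atol=solver_atol,
                    )
                except SimulationError:
                    out.append(np.full(tr.times.size, 1e6))
                    continue
                out.append(w * (sim.signal - tr.signal))
            return np.concatenate(out)

        return residuals

    residuals = make_residuals(rtol, atol)

    lo = np.array([np.log10(search[name][0]) for name in free])
    hi = np.array([np.log10(search[name][1]) for name in free])
    rng = np.random.default_rng(seed)
    starts = [lo + rng.random(len(free)) * (hi - lo) for _ in range(n_starts)]
    # include the supplied initial guess as one start
    starts.append(
        np.clip([np.log10(getattr(initial, name)) for name in free], lo, hi)
    )

    screened = sorted(starts, key=lambda x: float(np.sum(residuals(x) ** 2)))
    best = None
    for x0 in screened[:3]:
        # finite-difference step must dominate the integrator noise floor
        sol = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf", diff_step=1e-3,
            xtol=1e-10, ftol=1e-10, gtol=1e-10,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitFailureError("global fit failed to converge", None)
    # polish the winner with a tighter integration tolerance
    best = least_squares(
        make_residuals(min(rtol, 1e-8), min(atol, 1e-10)), best.x,
        bounds=(lo, hi), method="trf", diff_step=1e-4,
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )

    values = {name: v for name, v in zip(free, 10.0**best.x)}
    fitted = replace(initial, **values)

    # uncertainty and identifiability from the Jacobian at the optimum
    J = best.jac
    n_obs = J.shape[0]
    dof = max(n_obs - len(free), 1)
    s2 = 2.0 * best.cost / dof
    u, sv, vt = np.linalg.svd(J, full_matrices=False)
    flat = []
    for k, s in enumerate(sv):
        if s < 1e-6 * sv[0]:
            direction = {name: float(vt[k, i]) for i, name in enumerate(free)}
            flat.append(direction)
    sv_safe = np.where(sv > 1e-12 * sv[0], sv, np.inf)
    cov_log = (vt.T / sv_safe**2) @ vt * s2
    stderr = {}
    for i, name in enumerate(free):
        # delta method: param = 10^logx
        stderr[name] = float(
            np.sqrt(cov_log[i, i]) * np.log(10.0) * getattr(fitted, name)
        )
    return GlobalFitResult(
        params=fitted,
        stderr=stderr,
        cost=float(best.cost),
        unidentifiable=unidentifiable,
        flat_directions=flat,
        n_starts=len(starts),
    )
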