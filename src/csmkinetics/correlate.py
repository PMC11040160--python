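"""Intensity traces and (cross-)correlation on a multi-tau lag grid.

The fluctuation correlation between detection channels i and j is

    G_ij(tau) = <F_i(t) F_j(t + tau)> / (<F_i> <F_j>)  -  1,

i.e. the textbook FCS correlation minus its uncorrelated baseline of 1, so
that independent signals give G = 0 and the zero-lag value is the fluctuation
amplitude.  Symmetric normalization is used: the denominator means are taken
over the overlapping segments that actually enter the numerator at each lag,
which removes most of the bias from slow drifts over the trace.

Two estimators are provided:

* ``multitau`` — the standard multi-tau scheme (16 lags in the first cascade,
  8 new lags per subsequent cascade, bin width doubling between cascades),
  implemented as a cascade of pairwise re-binning steps;
* ``direct`` — a brute-force O(N*L) correlator evaluated on the same lag
  grid, used as an independent validation oracle.

Both compute the same mathematical estimator, so they agree to floating-point
round-off on any trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateTraceError, InvalidConfigError

__all__ = ["IntensityTrace", "CorrelationCurve", "correlate", "multitau_lag_grid"]

#: lags in the first multi-tau cascade; subsequent cascades add half as many
LAGS_PER_CASCADE = 16


@dataclass
class IntensityTrace:
    """Uniformly binned photon counts / intensities for 1 or 2 channels.

    ``counts`` has shape (n_channels, n_bins); ``bin_width`` is the sampling
    interval in seconds.
    """

    counts: np.ndarray
    bin_width: float
    start_time: float = 0.0

    def __post_init__(self):
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if self.bin_width <= 0:
            raise InvalidConfigError(f"bin_width must be positive, got {self.bin_width}")
        if self.counts.ndim != 2 or self.counts.shape[0] not in (1, 2):
            raise InvalidConfigError("counts must have shape (1 or 2 channels, n_bins)")

    @property
    def n_channels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    def slice_time(self, t_start: float, t_stop: float) -> "IntensityTrace":
        """Sub-trace covering [t_start, t_stop) relative to ``start_time``."""
        i0 = int(round(t_start / self.bin_width))
        i1 = int(round(t_stop / self.bin_width))
        return IntensityTrace(
            self.counts[:, i0:i1], self.bin_width, self.start_time + i0 * self.bin_width
        )


@dataclass
class CorrelationCurve:
    """G(tau) on a strictly increasing quasi-logarithmic lag grid."""

    lags: np.ndarray
    values: np.ndarray
    channel_pair: tuple[int, int]
    n_samples_per_lag: np.ndarray = field(default=None)

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise InvalidConfigError("lag grid must be strictly increasing")

    @property
    def is_auto(self) -> bool:
        return self.channel_pair[0] == self.channel_pair[1]


def multitau_lag_grid(n_bins: int, bin_width: float, n_cascades: int | None = None):
    """Lag grid of the multi-tau scheme as (integer lag, cascade) pairs.

    Cascade 0 holds integer lags 1..16 of the native bin width; cascade c >= 1
    holds coarse lags 9..16 of bin width 2^c * bin_width.  Cascades stop when
    the coarsened trace is too short to estimate the largest lag from at least
    32 products, or when ``n_cascades`` is reached.
    """
    grid = []
    cascade = 0
    while n_cascades is None or cascade < n_cascades:
        n = n_bins >> cascade  # coarse trace length at this cascade
        if n - LAGS_PER_CASCADE < 32:
            break
        if cascade == 0:
            ks = range(1, LAGS_PER_CASCADE + 1)
        else:
            ks = range(LAGS_PER_CASCADE // 2 + 1, LAGS_PER_CASCADE + 1)
        for k in ks:
            grid.append((k, cascade))
        cascade += 1
    if not grid:
        raise DegenerateTraceError(f"trace too short to correlate ({n_bins} bins)")
    return grid


def _corr_at_lag(a: np.ndarray, b: np.ndarray, k: int) -> tuple[float, int]:
    """Symmetric-normalized fluctuation correlation of a, b at integer lag k."""
    n = a.size - k
    left = a[:n]
    right = b[k:]
    mean_l = left.mean()
    mean_r = right.mean()
    if mean_l <= 0 or mean_r <= 0:
        raise DegenerateTraceError("zero-mean channel segment; cannot normalize correlation")
    g = float(np.dot(left, right) / n / (mean_l * mean_r) - 1.0)
    return g, n


def _coarsen(a: np.ndarray) -> np.ndarray:
    n = a.size // 2 * 2
    return a[:n].reshape(-1, 2).sum(axis=1)


def correlate(
    trace: IntensityTrace,
    pair: tuple[int, int] = (0, 0),
    n_cascades: int | None = None,
    method: str = "multitau",
) -> CorrelationCurve:
    """Correlate two channels of a trace on a multi-tau lag grid.

    Parameters
    ----------
    trace
        The binned intensity trace (>= 2 bins, positive mean in the channels
        being correlated).
    pair
        Channel indices (i, j); i == j gives the autocorrelation, i != j the
        cross-correlation.
    n_cascades
        Optional cap on the number of cascades (limits the maximum lag).
    method
        ``"multitau"`` (cascaded re-binning) or ``"direct"`` (brute-force
        oracle on the identical lag grid).
    """
    i, j = pair
    if trace.n_bins < 2:
        raise DegenerateTraceError("need at least 2 bins to correlate")
    a0 = trace.counts[i]
    b0 = trace.counts[j]
    if a0.mean() <= 0 or b0.mean() <= 0:
        raise DegenerateTraceError(f"channel pair {pair} has a zero-mean channel")

    grid = multitau_lag_grid(trace.n_bins, trace.bin_width, n_cascades)
    lags = np.empty(len(grid))
    values = np.empty(len(grid))
    counts = np.empty(len(grid), dtype=int)

    if method == "multitau":
        a, b = a0, b0
        width = trace.bin_width
        cur_cascade = 0
        for idx, (k, cascade) in enumerate(grid):
            while cascade > cur_cascade:
                a = _coarsen(a)
                b = _coarsen(b)
                width *= 2.0
                cur_cascade += 1
            g, n = _corr_at_lag(a, b, k)
            lags[idx] = k * width
            values[idx] = g
            counts[idx] = n
    elif method == "direct":
        for idx, (k, cascade) in enumerate(grid):
            factor = 2**cascade
            width = trace.bin_width * factor
            n_groups = a0.size // factor
            a = a0[: n_groups * factor].reshape(n_groups, factor).sum(axis=1)
            b = b0[: n_groups * factor].reshape(n_groups, factor).sum(axis=1)
            g, n = _corr_at_lag(a, b, k)
            lags[idx] = k * width
            values[idx] = g
            counts[idx] = n
    else:
        raise InvalidConfigError(f"unknown correlation method {method!r}")

    return CorrelationCurve(lags, values, (i, j), counts)
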