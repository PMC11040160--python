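"""Closed-form model functions shared by the simulators and the fitting routines.

Decay / activation models
-------------------------
``exp_plateau``    R(t) = (1 - R0) exp(-t/<t>) + R0
                   normalized cross-correlation amplitude of complexes retaining
                   both RNA ends; R0 is the residual amplitude at infinite time.
``biexp``          tau(t) = A1 exp(-t/<t>1) + A2 exp(-t/<t>2) + tau0,
                   with A1 = 1 - A2 - tau0 so tau(0) = 1; normalized mean
                   diffusion time of an internally labeled substrate.
``activation``     F(t) = A (1 - exp(-t/<t>)); cleaved ssDNA during a single
                   activation burst.
``activation_bg``  F(t) = A (1 - exp(-t/<t>)) + c t; same plus a constant-rate
                   background from the non-activated complex.

Correlation model
-----------------
``g_diffusion_3d`` is the standard FCS model for free 3D diffusion through a
3D-Gaussian detection volume with lateral waist w0 and axial extension
z0 = kappa * w0, optionally with one or two diffusing species and a triplet
(dark-state) relaxation term.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "exp_plateau",
    "biexp_decay",
    "activation",
    "activation_bg",
    "g_diffusion_3d",
    "DECAY_MODELS",
]


def exp_plateau(t, mean_time, plateau):
    """Single-exponential decay from 1 to a residual plateau."""
    t = np.asarray(t, dtype=float)
    return (1.0 - plateau) * np.exp(-t / mean_time) + plateau


def biexp_decay(t, mean_time_1, mean_time_2, a2, offset):
    """Constrained bi-exponential decay: amplitude of the fast component is
    ``1 - a2 - offset`` so the curve starts at 1."""
    t = np.asarray(t, dtype=float)
    a1 = 1.0 - a2 - offset
    return a1 * np.exp(-t / mean_time_1) + a2 * np.exp(-t / mean_time_2) + offset


def activation(t, amplitude, mean_time):
    """Saturating exponential rise of cleaved product during activation."""
    t = np.asarray(t, dtype=float)
    return amplitude * (1.0 - np.exp(-t / mean_time))


def activation_bg(t, amplitude, mean_time, background_rate):
    """Activation rise plus a linear background of constant rate."""
    return activation(t, amplitude, mean_time) + background_rate * np.asarray(t, dtype=float)


#: model tag -> (callable, ordered parameter names)
DECAY_MODELS = {
    "exp_plateau": (exp_plateau, ("mean_time", "plateau")),
    "biexp": (biexp_decay, ("mean_time_1", "mean_time_2", "a2", "offset")),
    "activation": (activation, ("amplitude", "mean_time")),
    "activation_bg": (activation_bg, ("amplitude", "mean_time", "background_rate")),
}


def _g_single(tau, tau_d, kappa):
    tau = np.asarray(tau, dtype=float)
    return 1.0 / ((1.0 + tau / tau_d) * np.sqrt(1.0 + tau / (kappa**2 * tau_d)))


def g_diffusion_3d(
    tau,
    amplitude,
    tau_d1,
    *,
    offset=0.0,
    tau_d2=None,
    fraction_1=1.0,
    triplet_fraction=0.0,
    triplet_time=1.0,
    kappa=5.0,
):
    """Fluctuation autocorrelation of free 3D diffusion through a 3D-Gaussian focus.

    G(tau) = offset + amplitude * triplet(tau)
             * [ f * g(tau; tau_d1) + (1 - f) * g(tau; tau_d2) ]

    with g(tau; tau_d) = (1 + tau/tau_d)^-1 (1 + tau/(kappa^2 tau_d))^-1/2 and
    triplet(tau) = 1 + T/(1-T) * exp(-tau/tau_T).  G(0) = offset + amplitude
    when the triplet fraction is zero.

    Parameters
    ----------
    tau
        Lag time(s), same units as the diffusion times; tau >= 0.
    amplitude
        Fluctuation amplitude G0 (inverse mean number of particles in the
        effective volume for an ideal single-species measurement).
    tau_d1, tau_d2
        Diffusion time(s) w0^2/4D through the lateral waist; ``tau_d2`` only
        for a two-species model.
    fraction_1
        Amplitude fraction of species 1 (ignored for a single species).
    triplet_fraction, triplet_time
        Dark-state population T in [0, 1) and its relaxation time.
    kappa
        Structure factor z0/w0 of the detection volume.
    """
    if not 0.0 <= triplet_fraction < 1.0:
        raise ValueError(f"triplet_fraction must be in [0, 1), got {triplet_fraction}")
    if tau_d1 <= 0 or (tau_d2 is not None and tau_d2 <= 0):
        raise ValueError("diffusion times must be positive")
    tau = np.asarray(tau, dtype=float)
    if tau_d2 is None:
        diff = _g_single(tau, tau_d1, kappa)
    else:
        diff = fraction_1 * _g_single(tau, tau_d1, kappa) + (1.0 - fraction_1) * _g_single(
            tau, tau_d2, kappa
        )
    if triplet_fraction > 0.0:
        trip = 1.0 + triplet_fraction / (1.0 - triplet_fraction) * np.exp(-tau / triplet_time)
    else:
        trip = 1.0
    return offset + amplitude * trip * diff
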