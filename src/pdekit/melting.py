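"""Thermal denaturation midpoints from circular-dichroism melts.

The ellipticity at 222 nm is followed while the sample is heated; the profile
is modelled as a native plateau followed by a single exponential decay,

    Y(T) = Y0                                   for T <  X0
    Y(T) = P + (Y0 - P) · exp(-K · (T - X0))    for T >= X0,

and the melting temperature is the point where the fitted curve crosses the
midpoint between the two extrapolated baselines, which for this model has the
closed form Tm = X0 + ln(2)/K.

A symmetric two-baseline logistic (sigmoid in T with midpoint Tm) is provided
as an alternative for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import InputError


@dataclass(frozen=True)
class MeltDataset:
    """Ellipticity-vs-temperature profile (temperatures strictly increasing)."""

    temperature: np.ndarray  # degC
    signal: np.ndarray  # mean residue ellipticity at 222 nm, a.u.

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", y)
        if t.shape != y.shape or t.ndim != 1 or t.size < 6:
            raise InputError("need equal-length 1-D arrays of >= 6 points")
        if np.any(np.diff(t) <= 0):
            raise InputError("temperatures must be strictly increasing")


@dataclass(frozen=True)
class MeltFit:
    Tm: float  # degC
    X0: float  # onset of decay, degC
    K: float  # decay rate, 1/degC
    native_baseline: float  # Y0
    denatured_plateau: float  # P
    converged: bool


def plateau_decay(t, Y0, P, X0, K):
    """Plateau followed by one-phase exponential decay."""
    t = np.asarray(t, dtype=float)
    y = np.full_like(t, Y0, dtype=float)
    past = t >= X0
    y[past] = P + (Y0 - P) * np.exp(-K * (t[past] - X0))
    return y


def melt_midpoint(X0: float, K: float) -> float:
    """Temperature where the fitted decay crosses (Y0+P)/2: X0 + ln2/K."""
    return X0 + math.log(2.0) / K


def fit_melt(data: MeltDataset, model: str = "plateau_decay") -> MeltFit:
    """Fit a melting profile and locate its midpoint Tm.

    Flat profiles (no transition between the extrapolated baselines) are
    returned with ``converged=False`` and Tm = nan rather than raising.
    ``model`` may be ``plateau_decay`` (default) or ``logistic`` for the
    two-baseline sigmoid sensitivity check (its Tm is the sigmoid midpoint).
    """
    t, y = data.temperature, data.signal
    span = float(np.ptp(y))
    scale = max(float(np.max(np.abs(y))), 1.0)
    y0_init = float(np.mean(y[:3]))
    p_init = float(np.mean(y[-3:]))
    if span <= 1e-12 * scale or abs(y0_init - p_init) <= 1e-9 * scale:
        return MeltFit(math.nan, math.nan, math.nan, y0_init, p_init, False)

    tmin, tmax = float(t[0]), float(t[-1])
    # onset guess: first temperature where the signal departs 10% of the way
    # from the native baseline towards the final plateau
    dep = np.abs(y - y0_init) >= 0.1 * abs(p_init - y0_init)
    x0_init = float(t[np.argmax(dep)]) if np.any(dep) else 0.5 * (tmin + tmax)
    x0_init = float(np.clip(x0_init, tmin, tmax - 1e-6))
    if np.count_nonzero(t >= x0_init) < 2:
        raise InputError("fewer than 2 points past the candidate decay onset")
    k_init = math.log(2.0) / max((tmax - x0_init) / 4.0, 1e-3)

    if model == "plateau_decay":
        def residuals(theta):
            return plateau_decay(t, *theta) - y

        lo = [-np.inf, -np.inf, tmin, 1e-6]
        hi = [np.inf, np.inf, tmax, 10.0]
        x0 = np.clip([y0_init, p_init, x0_init, k_init],
                     [-np.inf, -np.inf, tmin, 1e-6], hi)
        res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                            ftol=1e-12, xtol=1e-12)
        Y0, P, X0, K = res.x
        tm = melt_midpoint(X0, K)
        ok = bool(res.success and np.isfinite(tm)
                  and abs(Y0 - P) > 1e-9 * scale
                  and tmin <= X0 <= tmax and tm <= tmax)
        return MeltFit(float(tm), float(X0), float(K), float(Y0), float(P), ok)

    if model == "logistic":
        def logistic(theta):
            Y0, P, tm, k = theta
            return P + (Y0 - P) / (1 + np.exp(k * (t - tm))) - y

        x0 = [y0_init, p_init, 0.5 * (tmin + tmax), 0.5]
        res = least_squares(logistic, x0, method="lm", ftol=1e-12, xtol=1e-12)
        Y0, P, tm, k = res.x
        ok = bool(res.success and np.isfinite(tm) and abs(Y0 - P) > 1e-9 * scale
                  and tmin <= tm <= tmax)
        return MeltFit(float(tm), float(tm), float(k), float(Y0), float(P), ok)

    raise InputError(f"unknown melt model {model!r}")
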