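"""Metal-binding titrations followed by intrinsic tryptophan fluorescence.

Adding Mn²⁺ quenches the protein's intrinsic fluorescence at 340 nm; the
fractional quench (F₀−F)/F₀ saturates with ligand concentration and is fit to
a one-site specific-binding model with Hill slope,

    Y(X) = Bmax · Xʰ / (Kdʰ + Xʰ),

with Bmax free (the accessible fraction of the fluorescence need not be 1).
A Hill coefficient h < 1 indicates negative cooperativity between the two
metal sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, InputError

#: fit bounds: Kd in mM, dimensionless Hill slope and Bmax
KD_BOUNDS = (1e-4, 100.0)
HILL_BOUNDS = (0.05, 4.0)
BMAX_BOUNDS = (1e-6, 1.2)


@dataclass(frozen=True)
class QuenchDataset:
    """Fluorescence titration: ligand concentrations (mM, including 0) and
    raw fluorescence F at 340 nm; F0 is the zero-ligand fluorescence."""

    ligand_conc: np.ndarray
    F: np.ndarray
    F0: float

    def __post_init__(self) -> None:
        c = np.asarray(self.ligand_conc, dtype=float)
        f = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "ligand_conc", c)
        object.__setattr__(self, "F", f)
        if c.shape != f.shape or c.ndim != 1 or c.size < 5:
            raise InputError("need equal-length 1-D arrays of >= 5 points")
        if self.F0 <= 0:
            raise InputError("F0 must be strictly positive")
        if np.any(c < 0):
            raise InputError("ligand concentrations must be non-negative")


def quench_transform(data: QuenchDataset) -> np.ndarray:
    """Fractional quench (F0 - F)/F0 per titration point."""
    return (data.F0 - data.F) / data.F0


def hill_binding(x, Kd, hill, Bmax):
    """One-site specific binding with Hill slope; Y(0) = 0, Y(Kd) = Bmax/2."""
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x)
    pos = x > 0
    xh = x[pos] ** hill
    y[pos] = Bmax * xh / (Kd**hill + xh)
    return y


@dataclass(frozen=True)
class BindingFit:
    Kd: float  # mM
    hill: float
    Bmax: float
    rss: float
    converged: bool

    @property
    def cooperativity(self) -> str:
        if self.hill < 1.0:
            return "negative"
        if self.hill > 1.0:
            return "positive"
        return "none"


def fit_binding(conc, quench, fix_bmax: float | None = None) -> BindingFit:
    """Least-squares Hill fit of fractional quench against concentration.

    Requires >= 5 points with >= 4 distinct positive concentrations.  The
    initial Kd guess is the concentration nearest half-maximal quench.

    By default Bmax is a free parameter (the quencher-accessible fraction of
    the fluorescence need not be 1).  On a titration far from saturation,
    Bmax and Kd are nearly collinear and the free-Bmax estimate of Kd has
    very large variance; pass ``fix_bmax`` (typically 1.0, complete quench at
    saturation) to pin it, which is how the reported sub-percent precision on
    Kd from such titrations is obtained in practice.
    """
    x = np.asarray(conc, dtype=float)
    y = np.asarray(quench, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 5:
        raise InputError("need equal-length 1-D arrays of >= 5 points")
    if np.unique(x[x > 0]).size < 4:
        raise InputError("need at least 4 distinct positive concentrations")
    if np.allclose(y, 0):
        raise InputError("all-zero quench: nothing to fit")

    bmax0 = float(np.clip(np.max(y), 0.05, BMAX_BOUNDS[1]))
    if fix_bmax is not None and not BMAX_BOUNDS[0] <= fix_bmax <= BMAX_BOUNDS[1]:
        raise InputError(f"fix_bmax must be within {BMAX_BOUNDS}")
    half = (fix_bmax if fix_bmax is not None else bmax0) / 2
    pos = x > 0
    kd0 = float(x[pos][np.argmin(np.abs(y[pos] - half))])
    kd0 = float(np.clip(kd0, *KD_BOUNDS))

    if fix_bmax is None:
        x0 = np.array([kd0, 1.0, bmax0])
        lo = np.array([KD_BOUNDS[0], HILL_BOUNDS[0], BMAX_BOUNDS[0]])
        hi = np.array([KD_BOUNDS[1], HILL_BOUNDS[1], BMAX_BOUNDS[1]])

        def residuals(theta):
            return hill_binding(x, *theta) - y
    else:
        x0 = np.array([kd0, 1.0])
        lo = np.array([KD_BOUNDS[0], HILL_BOUNDS[0]])
        hi = np.array([KD_BOUNDS[1], HILL_BOUNDS[1]])

        def residuals(theta):
            return hill_binding(x, theta[0], theta[1], fix_bmax) - y

    res = least_squares(
        residuals, x0, bounds=(lo, hi), method="trf", ftol=1e-12, xtol=1e-12
    )
    kd, hill = res.x[0], res.x[1]
    bmax = fix_bmax if fix_bmax is not None else res.x[2]
    converged = bool(res.success and np.all(np.isfinite(res.x)))
    return BindingFit(float(kd), float(hill), float(bmax),
                      float(2 * res.cost), converged)
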