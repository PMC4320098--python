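"""Saturation kinetics: specific activity, Michaelis-Menten fits and
catalytic constants.

Rates are expressed throughout in the assay's reporting units,
μmol p-nitrophenol min⁻¹ (mg protein)⁻¹, and substrate concentrations in mM.
Catalytic constants convert to molar units only at the last step:
kcat (min⁻¹) = Vmax × molar mass (kDa), since μmol min⁻¹ mg⁻¹ equals
mmol min⁻¹ g⁻¹ and kDa equals g mmol⁻¹; efficiency = kcat / Km with Km in M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, InputError

#: molar extinction coefficient of p-nitrophenol at 405 nm, M^-1 cm^-1
PNP_EXTINCTION = 18450.0

#: default molar mass (kDa) used for turnover numbers; configurable
DEFAULT_MOLAR_MASS_KDA = 29.5


@dataclass(frozen=True)
class ActivityMeasurement:
    """One endpoint absorbance reading of p-nitrophenol release."""

    absorbance_405: float
    extinction_coeff: float = PNP_EXTINCTION  # M^-1 cm^-1
    path_length: float = 1.0  # cm
    reaction_volume: float = 1e-3  # L
    time: float = 10.0  # min
    protein_mass: float = 1e-3  # mg

    def __post_init__(self) -> None:
        if self.absorbance_405 < 0:
            raise InputError("absorbance must be >= 0")
        for name in ("extinction_coeff", "path_length", "reaction_volume",
                     "time", "protein_mass"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be strictly positive")


def specific_activity(m: ActivityMeasurement) -> float:
    """Specific activity in μmol min⁻¹ mg⁻¹ via Beer-Lambert.

    A405/(ε·l) gives the product concentration in M; times reaction volume
    gives moles, ×10⁶ μmol, divided by incubation time and protein mass.
    """
    conc_molar = m.absorbance_405 / (m.extinction_coeff * m.path_length)
    micromoles = conc_molar * m.reaction_volume * 1e6
    return micromoles / (m.time * m.protein_mass)


def fold_change(reference_rate: float, treated_rate: float) -> float:
    """Activity ratio reference/treated (e.g. ~6-fold EDTA inhibition)."""
    if treated_rate <= 0:
        raise InputError("treated rate must be strictly positive")
    return reference_rate / treated_rate


@dataclass(frozen=True)
class KineticDataset:
    """Initial-rate measurements across substrate concentrations."""

    substrate_conc: np.ndarray  # mM
    rate: np.ndarray  # umol min^-1 mg^-1
    substrate_name: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate_conc, dtype=float)
        v = np.asarray(self.rate, dtype=float)
        object.__setattr__(self, "substrate_conc", s)
        object.__setattr__(self, "rate", v)
        if s.shape != v.shape or s.ndim != 1:
            raise InputError("substrate_conc and rate must be equal-length 1-D")
        if s.size < 4:
            raise InputError("need at least 4 data points")
        if np.any(s < 0):
            raise InputError("substrate concentrations must be non-negative")
        if np.unique(s).size < 3:
            raise InputError("need at least 3 distinct substrate concentrations")


@dataclass(frozen=True)
class MMFit:
    Km: float  # mM
    Km_se: float
    Vmax: float  # umol min^-1 mg^-1
    Vmax_se: float
    rss: float
    converged: bool


def michaelis_menten(s, Km, Vmax):
    s = np.asarray(s, dtype=float)
    return Vmax * s / (Km + s)


def _log_param_fit(residual_fn, x0_log, n_obs, ftol=1e-10):
    """Least squares over log-transformed positive parameters.

    Returns (params, ses, rss, converged); standard errors come from the
    Gauss-Newton covariance in log space mapped back by the delta method.
    """
    res = least_squares(residual_fn, x0_log, method="lm", ftol=ftol, xtol=1e-12)
    params = np.exp(res.x)
    rss = float(2 * res.cost)
    dof = max(n_obs - len(params), 1)
    try:
        jtj_inv = np.linalg.inv(res.jac.T @ res.jac)
        sigma2 = rss / dof
        se_log = np.sqrt(np.clip(np.diag(jtj_inv) * sigma2, 0, np.inf))
        ses = params * se_log  # d(exp x) = exp(x) dx
    except np.linalg.LinAlgError:
        ses = np.full_like(params, np.nan)
    converged = bool(res.success and np.all(np.isfinite(params)))
    return params, ses, rss, converged


def fit_mm(
    data: KineticDataset, init: tuple[float, float] | None = None
) -> MMFit:
    """Nonlinear least-squares fit of v = Vmax·S/(Km+S).

    Parameters are log-transformed to enforce positivity.  Defaults for the
    initial guess are Km = median(S) and Vmax = max(v).
    """
    s, v = data.substrate_conc, data.rate
    if init is None:
        km0 = float(np.median(s[s > 0])) if np.any(s > 0) else 1.0
        vmax0 = float(np.max(v)) if np.max(v) > 0 else 1.0
        init = (km0, vmax0)
    if init[0] <= 0 or init[1] <= 0:
        raise FitError("initial Km and Vmax must be positive")

    def residuals(theta_log):
        km, vmax = np.exp(theta_log)
        return michaelis_menten(s, km, vmax) - v

    (km, vmax), (km_se, vmax_se), rss, ok = _log_param_fit(
        residuals, np.log(init), s.size
    )
    return MMFit(km, km_se, vmax, vmax_se, rss, ok)


@dataclass(frozen=True)
class CatalyticConstants:
    molar_mass: float  # kDa
    kcat: float  # min^-1
    efficiency: float  # M^-1 min^-1


def derive_constants(
    fit: MMFit, molar_mass: float = DEFAULT_MOLAR_MASS_KDA
) -> CatalyticConstants:
    """Turnover number and catalytic efficiency from a converged fit.

    kcat = Vmax × molar_mass (unit identity: μmol min⁻¹ mg⁻¹ × kDa = min⁻¹);
    efficiency = kcat / (Km in M), Km being carried in mM.
    """
    if not fit.converged:
        raise FitError("refusing to derive constants from a non-converged fit")
    if molar_mass <= 0:
        raise InputError("molar mass must be strictly positive")
    kcat = fit.Vmax * molar_mass
    efficiency = kcat / (fit.Km * 1e-3)
    return CatalyticConstants(molar_mass, kcat, efficiency)
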