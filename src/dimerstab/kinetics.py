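"""Irreversible aggregation kinetics: decay fits, Arrhenius and Eyring analysis.

The folded monomer is lost to an aggregate with first-order rate k_Ag, so
the CD signal at constant temperature relaxes as a single exponential

    θ(t) = θ_∞ + (θ_0 − θ_∞) exp(−k_Ag t).

The temperature dependence of k_Ag follows the Arrhenius law
ln k = ln A − E_a/(R T); transition-state theory then converts any rate
into a free-energy barrier ΔG‡ = RT [ln(k_B T/h) − ln k] (transmission
coefficient κ = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._fitting import multistart_curve_fit
from .constants import BOLTZMANN_SI, PLANCK_SI, R_KCAL
from .exceptions import InvalidInputError, InvalidParameterError, NoDecayError


@dataclass
class KineticTrace:
    """Isothermal CD decay: time (s), signal, temperature (K), C_T (μM)."""

    time: np.ndarray
    ellipticity: np.ndarray
    temperature: float = float("nan")
    c_total: float = float("nan")

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.time.size < 10:
            raise InvalidInputError("kinetic trace needs >= 10 points")
        if np.any(np.diff(self.time) <= 0):
            raise InvalidInputError("time must be strictly increasing")


@dataclass(frozen=True)
class AggregationFit:
    """Single-exponential decay parameters: rate, amplitude, offset."""

    k_ag: float
    amplitude: float
    offset: float
    k_ag_err: float = float("nan")
    short_trace: bool = False


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius regression: Ea (kcal/mol), ln A, residuals of ln k."""

    ea: float
    ln_a: float
    ea_err: float
    ln_a_err: float
    residuals: np.ndarray


class ExponentialDecayEstimator(BaseEstimator, RegressorMixin):
    """Least-squares single-exponential decay fit.

    The rate is invariant to affine transforms of the signal; amplitude
    and offset absorb scale and sign.

    Attributes
    ----------
    k_ag_, amplitude_, offset_ : fitted parameters with ``k_ag_err_``.
    short_trace_ : True when the trace spans < 3/k_Ag.
    """

    def __init__(self, n_starts=5, seed=0):
        self.n_starts = n_starts
        self.seed = seed

    @staticmethod
    def _model(t, k, amp, off):
        return off + amp * np.exp(-k * t)

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        theta = np.asarray(y, dtype=float).ravel()
        span = np.ptp(theta)
        # noise floor from first differences (decay contributes little there)
        sigma = float(np.std(np.diff(theta)) / np.sqrt(2.0)) if theta.size > 2 else 0.0
        if span <= max(3.0 * sigma * 1e-3, 1e-12 * max(np.max(np.abs(theta)), 1e-30)):
            raise NoDecayError("signal is constant: no decay to fit")
        duration = t[-1] - t[0]
        k0 = 2.0 / max(duration, 1e-30)
        p0 = [k0, theta[0] - theta[-1], theta[-1]]
        lo = [0.0, -np.inf, -np.inf]
        hi = [np.inf, np.inf, np.inf]
        popt, perr, diag = multistart_curve_fit(
            self._model, t, theta, p0, bounds=(lo, hi),
            n_starts=self.n_starts, seed=self.seed)
        k, amp, off = popt
        resolved = abs(amp) * (1.0 - np.exp(-k * duration))
        if resolved < 3.0 * sigma:
            raise NoDecayError(
                "signal change over the trace is below 3x the noise floor: "
                "no resolvable decay", diagnostics=diag)
        self.k_ag_, self.amplitude_, self.offset_ = map(float, popt)
        self.k_ag_err_ = float(perr[0])
        self.diagnostics_ = diag
        self.short_trace_ = duration < 3.0 / k if k > 0 else True
        if self.short_trace_:
            warnings.warn("trace shorter than 3/k_Ag: rate weakly "
                          "constrained", stacklevel=2)
        return self

    def predict(self, X):
        check_is_fitted(self, "k_ag_")
        return self._model(np.asarray(X, dtype=float).ravel(),
                           self.k_ag_, self.amplitude_, self.offset_)

    def params_(self) -> AggregationFit:
        check_is_fitted(self, "k_ag_")
        return AggregationFit(k_ag=self.k_ag_, amplitude=self.amplitude_,
                              offset=self.offset_, k_ag_err=self.k_ag_err_,
                              short_trace=self.short_trace_)


class ArrheniusEstimator(BaseEstimator, RegressorMixin):
    """(Optionally weighted) linear regression of ln k on 1/T.

    Attributes
    ----------
    ea_, ln_a_ : activation energy (kcal/mol) and log pre-exponential,
        with ``ea_err_``, ``ln_a_err_`` 1σ errors (NaN with only 2 points).
    residuals_ : per-point ln k residuals.
    """

    def __init__(self, weights=None):
        self.weights = weights

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        k = np.asarray(y, dtype=float).ravel()
        if t.size < 2:
            raise InvalidInputError("need >= 2 temperatures")
        if np.any(k <= 0):
            raise InvalidInputError("all rate constants must be > 0")
        x = 1.0 / t
        lnk = np.log(k)
        w = (np.ones_like(x) if self.weights is None
             else np.asarray(self.weights, dtype=float).ravel())
        sw = np.sqrt(w)
        a = np.column_stack([x, np.ones_like(x)]) * sw[:, None]
        b = lnk * sw
        beta, rss, rank, _ = np.linalg.lstsq(a, b, rcond=None)
        slope, intercept = beta
        fitted = slope * x + intercept
        resid = lnk - fitted
        n = t.size
        if n > 2 and rank == 2:
            s2 = float(np.sum(w * resid**2)) / (n - 2)
            cov = s2 * np.linalg.inv(a.T @ a)
            slope_err, int_err = np.sqrt(np.diag(cov))
        else:
            slope_err = int_err = float("nan")
        self.ea_ = float(-slope * R_KCAL)
        self.ln_a_ = float(intercept)
        self.ea_err_ = float(slope_err * R_KCAL)
        self.ln_a_err_ = float(int_err)
        self.residuals_ = resid
        return self

    def predict(self, X):
        """Predicted rate constants at the given temperatures (K)."""
        check_is_fitted(self, "ea_")
        t = np.asarray(X, dtype=float).ravel()
        return np.exp(self.ln_a_ - self.ea_ / (R_KCAL * t))

    def params_(self) -> ArrheniusFit:
        check_is_fitted(self, "ea_")
        return ArrheniusFit(ea=self.ea_, ln_a=self.ln_a_, ea_err=self.ea_err_,
                            ln_a_err=self.ln_a_err_, residuals=self.residuals_)


# ---------------------------------------------------------------------------
# transition-state theory closed forms
# ---------------------------------------------------------------------------

def eyring_prefactor(temperature: float) -> float:
    """ln(k_B T / h), the Eyring attempt frequency relative to 1 s⁻¹."""
    if temperature <= 0:
        raise InvalidParameterError("temperature must be > 0 K")
    return float(np.log(BOLTZMANN_SI * temperature / PLANCK_SI))


def barrier_free_energy(k: float, temperature: float) -> float:
    """Free-energy barrier ΔG‡ (kcal/mol) for a rate k (s⁻¹) at T (K)."""
    if k <= 0:
        raise InvalidInputError("rate constant must be > 0")
    return R_KCAL * temperature * (eyring_prefactor(temperature) - np.log(k))


def eyring_rate(dg_barrier: float, temperature: float) -> float:
    """Inverse of :func:`barrier_free_energy`: rate from a barrier height."""
    return float(BOLTZMANN_SI * temperature / PLANCK_SI
                 * np.exp(-dg_barrier / (R_KCAL * temperature)))


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_decay(trace: KineticTrace, **kwargs) -> ExponentialDecayEstimator:
    """Fit one isothermal decay trace; see :class:`ExponentialDecayEstimator`."""
    return ExponentialDecayEstimator(**kwargs).fit(trace.time,
                                                   trace.ellipticity)


def fit_arrhenius(temperatures, rates, weights=None) -> ArrheniusEstimator:
    """Regress ln k_Ag on 1/T; see :class:`ArrheniusEstimator`."""
    t = np.asarray(temperatures, dtype=float)
    if t.size < 3:
        raise InvalidInputError("need >= 3 temperatures for an Arrhenius fit")
    return ArrheniusEstimator(weights=weights).fit(t, rates)
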