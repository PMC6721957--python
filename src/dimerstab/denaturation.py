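"""Linear-extrapolation-model fits of CD denaturation data.

Thermal melts followed at 222 nm are modelled as a two-state transition
with linear folded/unfolded baselines and a van't Hoff free energy

    ΔG(T) = ΔH (1 − T/Tm)          (ΔCp = 0)
    θ(T)  = [θ_F(T) + θ_U(T) K(T)] / [1 + K(T)],   K = exp(−ΔG/RT)

Chemical denaturation uses the same construction with ΔG(c) = ΔG0 − m·c.

Concentration-dependent melts of an aggregation-prone dimer are bimodal:
a fraction χ_A of the protein (the pool destined for the aggregate)
melts through a first apparent transition at Tm1 while the remainder
unfolds at Tm2, giving the mixture

    θ(T) = χ_A θ1(T; Tm1, ΔH1) + (1 − χ_A) θ2(T; Tm2, ΔH2)

with baselines and both transitions shared across a concentration series
and one χ_A per curve.  The fitted χ_A(C_T) trend feeds the aggregation
phase diagram [M] = (1 − χ_A) C_T with 1 − χ_A ≈ exp(−C_T/C*).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._fitting import multistart_curve_fit, polish_least_squares
from .constants import R_KCAL, celsius_to_kelvin
from .exceptions import FitFailureError, InvalidInputError

# temperatures below this are taken to be Celsius at I/O boundaries
_CELSIUS_CUTOFF = 150.0


def _as_kelvin(temperature):
    t = np.asarray(temperature, dtype=float)
    if np.max(t) < _CELSIUS_CUTOFF:
        t = celsius_to_kelvin(t)
    return t


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MeltCurve:
    """One thermal melt: temperature (K or °C, auto-converted), signal, C_T."""

    temperature: np.ndarray
    ellipticity: np.ndarray
    c_total: float = float("nan")
    label: str = ""

    def __post_init__(self):
        self.temperature = _as_kelvin(self.temperature)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.temperature.size != self.ellipticity.size:
            raise InvalidInputError("temperature and ellipticity lengths differ")
        if self.temperature.size < 20:
            raise InvalidInputError("melt curve needs >= 20 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise InvalidInputError("temperature must be strictly increasing")
        if np.ptp(self.temperature) < 30.0:
            raise InvalidInputError("melt curve must span >= 30 K")
        if np.any(~np.isfinite(self.ellipticity)):
            raise InvalidInputError("ellipticity contains missing values")


@dataclass(frozen=True)
class TwoStateThermoParams:
    """Fitted two-state thermal parameters.

    ``dg(T)`` evaluates ΔG_MU(T) = ΔH (1 − T/Tm); it is exactly zero at Tm.
    Baselines are (intercept, slope-per-K) pairs on the raw signal scale.
    """

    tm: float
    dh_vh: float
    baseline_folded: tuple
    baseline_unfolded: tuple
    tm_err: float = float("nan")
    dh_err: float = float("nan")

    def dg(self, temperature):
        t = _as_kelvin(temperature)
        return self.dh_vh * (1.0 - t / self.tm)


@dataclass(frozen=True)
class ChemDenatFit:
    """Chemical-denaturation LEM parameters: ΔG0, m-value, midpoint Cm."""

    dg0: float
    m_value: float
    cm: float
    baseline_folded: tuple
    baseline_unfolded: tuple
    dg0_err: float = float("nan")
    m_err: float = float("nan")


@dataclass(frozen=True)
class PhaseDiagramFit:
    """Exponential monomer-depletion fit: 1 − χ_A = exp(−C_T/C*)."""

    c_star: float
    c_total: np.ndarray
    chi_a: np.ndarray
    monomer: np.ndarray           # (1 − χ_A)·C_T
    deviation: np.ndarray         # 1 − [M]/C_T, distance below the diagonal
    c_star_err: float = float("nan")
    diagonal: bool = False        # True when all χ_A = 0 (C* unbounded)


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------

def _two_state_theta(t, tm, dh, bf0, bf1, bu0, bu1):
    """Two-state LEM signal with linear baselines; t in Kelvin."""
    dg = dh * (1.0 - t / tm)
    k = np.exp(np.clip(-dg / (R_KCAL * t), -500, 500))
    theta_f = bf0 + bf1 * t
    theta_u = bu0 + bu1 * t
    return (theta_f + theta_u * k) / (1.0 + k)


def _transition_fraction(t, tm, dh):
    """Unfolded fraction of a single two-state transition."""
    dg = dh * (1.0 - t / tm)
    k = np.exp(np.clip(-dg / (R_KCAL * t), -500, 500))
    return k / (1.0 + k)


def bimodal_theta(t, chi_a, tm1, dh1, tm2, dh2, bf0, bf1, bu0, bu1):
    """Mixture of two shared-baseline LEM transitions weighted by χ_A."""
    f1 = _transition_fraction(t, tm1, dh1)
    f2 = _transition_fraction(t, tm2, dh2)
    unfolded = chi_a * f1 + (1.0 - chi_a) * f2
    theta_f = bf0 + bf1 * t
    theta_u = bu0 + bu1 * t
    return theta_f + (theta_u - theta_f) * unfolded


def _baseline_guesses(t, y, edge_frac=0.15):
    n = max(3, int(edge_frac * t.size))
    bf = np.polyfit(t[:n], y[:n], 1)
    bu = np.polyfit(t[-n:], y[-n:], 1)
    return (bf[1], bf[0]), (bu[1], bu[0])  # (intercept, slope)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class TwoStateMeltEstimator(BaseEstimator, RegressorMixin):
    """Two-state LEM fit of a single thermal melt.

    Attributes
    ----------
    tm_, dh_ : melting temperature (K) and van't Hoff enthalpy (kcal/mol)
        with ``tm_err_``, ``dh_err_`` 1σ errors.
    baseline_folded_, baseline_unfolded_ : (intercept, slope per K).
    baseline_overlap_ : True when either baseline has < 10 K of data.
    """

    def __init__(self, n_starts=5, seed=0):
        self.n_starts = n_starts
        self.seed = seed

    def fit(self, X, y):
        t = _as_kelvin(np.asarray(X, dtype=float).ravel())
        theta = np.asarray(y, dtype=float).ravel()
        span = np.ptp(theta)
        if span <= 1e-12 * max(np.max(np.abs(theta)), 1e-30):
            raise FitFailureError("signal is flat: no unfolding transition")
        (bf0, bf1), (bu0, bu1) = _baseline_guesses(t, theta)
        # midpoint guess: temperature where the signal crosses half-span
        mid = 0.5 * (theta[:5].mean() + theta[-5:].mean())
        tm0 = float(t[np.argmin(np.abs(theta - mid))])
        p0 = [tm0, 75.0, bf0, bf1, bu0, bu1]
        lo = [t[0] - 20.0, 1.0, -np.inf, -np.inf, -np.inf, -np.inf]
        hi = [t[-1] + 20.0, 1000.0, np.inf, np.inf, np.inf, np.inf]
        popt, perr, diag = multistart_curve_fit(
            _two_state_theta, t, theta, p0, bounds=(lo, hi),
            n_starts=self.n_starts, seed=self.seed)
        tm, dh = popt[0], popt[1]
        if not (t[0] <= tm <= t[-1]):
            raise FitFailureError(
                f"fitted midpoint {tm:.1f} K falls outside the scanned "
                f"range [{t[0]:.1f}, {t[-1]:.1f}] K", diagnostics=diag)
        self.tm_, self.dh_ = float(tm), float(dh)
        self.tm_err_, self.dh_err_ = float(perr[0]), float(perr[1])
        self.baseline_folded_ = (float(popt[2]), float(popt[3]))
        self.baseline_unfolded_ = (float(popt[4]), float(popt[5]))
        self.diagnostics_ = diag
        self.baseline_overlap_ = (tm - t[0] < 10.0) or (t[-1] - tm < 10.0)
        if self.baseline_overlap_:
            warnings.warn("less than 10 K of baseline on one side of Tm",
                          stacklevel=2)
        return self

    def predict(self, X):
        check_is_fitted(self, "tm_")
        t = _as_kelvin(np.asarray(X, dtype=float).ravel())
        return _two_state_theta(t, self.tm_, self.dh_,
                                *self.baseline_folded_,
                                *self.baseline_unfolded_)

    def params_(self) -> TwoStateThermoParams:
        check_is_fitted(self, "tm_")
        return TwoStateThermoParams(
            tm=self.tm_, dh_vh=self.dh_,
            baseline_folded=self.baseline_folded_,
            baseline_unfolded=self.baseline_unfolded_,
            tm_err=self.tm_err_, dh_err=self.dh_err_)


class BimodalMeltEstimator(BaseEstimator):
    """Global bimodal LEM fit of a concentration series of melts.

    Tm1, Tm2, ΔH1, ΔH2 and both baselines are shared across curves; one
    aggregate fraction χ_A ∈ [0, 1] is fitted per curve (Tm2 > Tm1 is
    enforced by parameterizing the gap).  ``fix_chi_a`` pins every χ_A to
    a constant, collapsing the model to a single two-state transition.

    Attributes
    ----------
    tm1_, tm2_, dh1_, dh2_ : shared transition parameters with ``*_err_``.
    chi_a_ : per-curve aggregate fractions, ordered as the input curves.
    c_totals_ : the per-curve total concentrations, for the phase diagram.
    """

    def __init__(self, fix_chi_a=None, seed=0):
        self.fix_chi_a = fix_chi_a
        self.seed = seed

    def fit(self, curves):
        if isinstance(curves, MeltCurve):
            curves = [curves]
        curves = list(curves)
        if len(curves) == 0:
            raise InvalidInputError("no melt curves supplied")
        if len(curves) == 1 and self.fix_chi_a is None:
            warnings.warn("single curve supplied: the χ_A(C_T) trend is not "
                          "constrained", stacklevel=2)

        t_all = np.concatenate([c.temperature for c in curves])
        y_all = np.concatenate([c.ellipticity for c in curves])
        (bf0, bf1), (bu0, bu1) = _baseline_guesses(
            curves[0].temperature, curves[0].ellipticity)
        tmin, tmax = t_all.min(), t_all.max()

        params = lmfit.Parameters()
        params.add("tm1", value=tmin + 0.3 * (tmax - tmin),
                   min=tmin - 10, max=tmax + 10)
        params.add("dtm", value=0.35 * (tmax - tmin), min=0.5, max=200.0)
        params.add("tm2", expr="tm1 + dtm")
        params.add("dh1", value=60.0, min=1.0, max=1000.0)
        params.add("dh2", value=75.0, min=1.0, max=1000.0)
        params.add("bf0", value=bf0)
        params.add("bf1", value=bf1)
        params.add("bu0", value=bu0)
        params.add("bu1", value=bu1)
        for i, _ in enumerate(curves):
            if self.fix_chi_a is not None:
                params.add(f"chi{i}", value=float(self.fix_chi_a), vary=False)
            else:
                params.add(f"chi{i}", value=0.3, min=0.0, max=1.0)

        def residual(p):
            res = []
            for i, c in enumerate(curves):
                model = bimodal_theta(
                    c.temperature, p[f"chi{i}"].value,
                    p["tm1"].value, p["dh1"].value,
                    p["tm2"].value, p["dh2"].value,
                    p["bf0"].value, p["bf1"].value,
                    p["bu0"].value, p["bu1"].value)
                res.append(model - c.ellipticity)
            return np.concatenate(res)

        out = lmfit.minimize(residual, params, method="leastsq",
                             xtol=1e-12, ftol=1e-12, max_nfev=50000)
        if not out.success:
            raise FitFailureError(
                f"global bimodal fit did not converge: {out.message}",
                diagnostics=[{"message": out.message, "nfev": out.nfev}])
        p = out.params
        # high-precision polish of the free parameters (see _fitting)
        free = [name for name in p if p[name].vary]
        if free:
            def vec_residual(vals):
                trial = p.copy()
                for name, v in zip(free, vals):
                    trial[name].set(value=v, min=-np.inf, max=np.inf)
                return residual(trial)
            polished = polish_least_squares(
                vec_residual, np.array([p[name].value for name in free]))
            ok = all(params[name].min <= v <= params[name].max
                     for name, v in zip(free, polished))
            if ok:
                for name, v in zip(free, polished):
                    p[name].set(value=v)
        self.tm1_, self.tm2_ = p["tm1"].value, p["tm2"].value
        self.dh1_, self.dh2_ = p["dh1"].value, p["dh2"].value
        self.tm1_err_ = p["tm1"].stderr or float("nan")
        self.tm2_err_ = p["tm2"].stderr or float("nan")
        self.baseline_folded_ = (p["bf0"].value, p["bf1"].value)
        self.baseline_unfolded_ = (p["bu0"].value, p["bu1"].value)
        self.chi_a_ = np.array([p[f"chi{i}"].value for i in range(len(curves))])
        self.chi_a_err_ = np.array(
            [p[f"chi{i}"].stderr or float("nan") for i in range(len(curves))])
        self.c_totals_ = np.array([c.c_total for c in curves])
        self.result_ = out
        return self

    def predict(self, curve_index, temperature):
        check_is_fitted(self, "tm1_")
        t = _as_kelvin(np.asarray(temperature, dtype=float))
        return bimodal_theta(t, self.chi_a_[curve_index],
                             self.tm1_, self.dh1_, self.tm2_, self.dh2_,
                             *self.baseline_folded_, *self.baseline_unfolded_)


class ChemicalDenaturationEstimator(BaseEstimator, RegressorMixin):
    """Two-state LEM fit of a chemical-denaturation curve.

    ΔG(c) = ΔG0 − m·c with linear baselines; works for either signal
    direction (ascending or descending ellipticity).

    Attributes
    ----------
    dg0_, m_, cm_ : unfolding free energy (kcal/mol), m-value
        (kcal/mol/M), and midpoint ΔG0/m (M), with ``dg0_err_``, ``m_err_``.
    """

    def __init__(self, temperature=310.15, n_starts=5, seed=0):
        self.temperature = temperature
        self.n_starts = n_starts
        self.seed = seed

    def _model(self, c, dg0, m, bf0, bf1, bu0, bu1):
        t = _as_kelvin(self.temperature)
        dg = dg0 - m * c
        k = np.exp(np.clip(-dg / (R_KCAL * t), -500, 500))
        return (bf0 + bf1 * c + (bu0 + bu1 * c) * k) / (1.0 + k)

    def fit(self, X, y):
        c = np.asarray(X, dtype=float).ravel()
        theta = np.asarray(y, dtype=float).ravel()
        if c.size < 15:
            raise FitFailureError("need >= 15 denaturant concentrations")
        if np.ptp(theta) <= 1e-12 * max(np.max(np.abs(theta)), 1e-30):
            raise FitFailureError("signal is flat: no unfolding transition")
        (bf0, bf1), (bu0, bu1) = _baseline_guesses(c, theta)
        mid = 0.5 * (theta[:3].mean() + theta[-3:].mean())
        cm0 = float(c[np.argmin(np.abs(theta - mid))])
        m0 = 2.5
        p0 = [m0 * max(cm0, 0.5), m0, bf0, bf1, bu0, bu1]
        lo = [0.0, 0.01, -np.inf, -np.inf, -np.inf, -np.inf]
        hi = [100.0, 50.0, np.inf, np.inf, np.inf, np.inf]
        popt, perr, diag = multistart_curve_fit(
            self._model, c, theta, p0, bounds=(lo, hi),
            n_starts=self.n_starts, seed=self.seed)
        cm = popt[0] / popt[1]
        if not (c.min() <= cm <= c.max()):
            raise FitFailureError(
                f"fitted midpoint {cm:.2f} M outside the denaturant range",
                diagnostics=diag)
        self.dg0_, self.m_ = float(popt[0]), float(popt[1])
        self.cm_ = float(cm)
        self.dg0_err_, self.m_err_ = float(perr[0]), float(perr[1])
        self.baseline_folded_ = (float(popt[2]), float(popt[3]))
        self.baseline_unfolded_ = (float(popt[4]), float(popt[5]))
        self.diagnostics_ = diag
        return self

    def predict(self, X):
        check_is_fitted(self, "dg0_")
        c = np.asarray(X, dtype=float).ravel()
        return self._model(c, self.dg0_, self.m_,
                           *self.baseline_folded_, *self.baseline_unfolded_)

    def params_(self) -> ChemDenatFit:
        check_is_fitted(self, "dg0_")
        return ChemDenatFit(dg0=self.dg0_, m_value=self.m_, cm=self.cm_,
                            baseline_folded=self.baseline_folded_,
                            baseline_unfolded=self.baseline_unfolded_,
                            dg0_err=self.dg0_err_, m_err=self.m_err_)


class PhaseDiagramEstimator(BaseEstimator):
    """Exponential fit of the aggregation phase diagram.

    Fits 1 − χ_A = exp(−C_T/C*) to (C_T, χ_A) pairs and exposes the
    monomer line [M] = (1 − χ_A) C_T against the diagonal [M] = C_T.
    """

    def __init__(self, n_starts=5, seed=0):
        self.n_starts = n_starts
        self.seed = seed

    def fit(self, X, y):
        ct = np.asarray(X, dtype=float).ravel()
        chi = np.asarray(y, dtype=float).ravel()
        if ct.size < 3:
            raise InvalidInputError("need >= 3 (C_T, χ_A) pairs")
        if np.any((chi < 0) | (chi > 1)):
            raise InvalidInputError("χ_A values must lie in [0, 1]")
        if np.allclose(chi, 0.0):
            self.c_star_ = float("inf")
            self.c_star_err_ = float("nan")
            self.diagonal_ = True
            warnings.warn("all χ_A = 0: species is effectively monomeric, "
                          "C* unbounded", stacklevel=2)
        else:
            model = lambda c, cstar: np.exp(-c / cstar)  # noqa: E731
            with np.errstate(divide="ignore"):
                est = -ct[chi > 0] / np.log(np.clip(1 - chi[chi > 0], 1e-12, 1))
            p0 = [float(np.median(est))]
            popt, perr, _ = multistart_curve_fit(
                model, ct, 1.0 - chi, p0, bounds=([1e-12], [np.inf]),
                n_starts=self.n_starts, seed=self.seed)
            self.c_star_ = float(popt[0])
            self.c_star_err_ = float(perr[0])
            self.diagonal_ = False
        self.c_total_ = ct
        self.chi_a_ = chi
        self.monomer_ = (1.0 - chi) * ct
        self.deviation_ = chi.copy()   # 1 − [M]/C_T
        return self

    def result_(self) -> PhaseDiagramFit:
        check_is_fitted(self, "c_star_")
        return PhaseDiagramFit(
            c_star=self.c_star_, c_total=self.c_total_, chi_a=self.chi_a_,
            monomer=self.monomer_, deviation=self.deviation_,
            c_star_err=self.c_star_err_, diagonal=self.diagonal_)


# ---------------------------------------------------------------------------
# functional wrappers and closed forms
# ---------------------------------------------------------------------------

def fit_two_state_melt(curve: MeltCurve, **kwargs) -> TwoStateMeltEstimator:
    """Fit one melt curve; see :class:`TwoStateMeltEstimator`."""
    return TwoStateMeltEstimator(**kwargs).fit(curve.temperature,
                                               curve.ellipticity)


def fit_bimodal_melts(curves, **kwargs) -> BimodalMeltEstimator:
    """Globally fit a melt family; see :class:`BimodalMeltEstimator`."""
    return BimodalMeltEstimator(**kwargs).fit(curves)


def fit_chemical_denaturation(denaturant, ellipticity, temperature=310.15,
                              **kwargs) -> ChemicalDenaturationEstimator:
    """Fit a chemical-denaturation curve; see
    :class:`ChemicalDenaturationEstimator`."""
    return ChemicalDenaturationEstimator(temperature=temperature,
                                         **kwargs).fit(denaturant, ellipticity)


def ddg_from_tm_shift(dh_tm: float, tm_wt: float, tm_mut: float) -> float:
    """Destabilization free energy from a melting-temperature shift.

    ΔΔG = ΔH·(Tm_wt − Tm_mut)/Tm_wt, positive when the variant melts lower
    than the reference.  Temperatures in K (°C auto-converted).
    """
    tm_wt_k = float(_as_kelvin(tm_wt))
    tm_mut_k = float(_as_kelvin(tm_mut))
    if tm_wt_k <= 0 or tm_mut_k <= 0:
        raise InvalidInputError("melting temperatures must be positive")
    return dh_tm * (tm_wt_k - tm_mut_k) / tm_wt_k


def phase_diagram(c_total, chi_a, **kwargs) -> PhaseDiagramFit:
    """Fit the aggregation phase diagram; see :class:`PhaseDiagramEstimator`."""
    return PhaseDiagramEstimator(**kwargs).fit(c_total, chi_a).result_()
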