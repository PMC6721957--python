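"""Monomer-dimer equilibrium, two-state populations, and dimer-only enzymology.

The core model is a homodimeric enzyme whose subunits partition between
free monomer M and dimer D according to a dissociation constant

    K_D = [M]^2 / [D],        C_T = [M] + 2 [D]

with C_T the total subunit concentration.  Only subunits assembled in the
dimer carry an active site, so initial rates follow Michaelis-Menten
kinetics with an active-site concentration of 2[D]:

    v = kcat * 2[D](C_T; K_D) * S / (Km + S)

The monomer is additionally in a two-state folding equilibrium (folded
fraction set by ΔG_MU) and can be lost irreversibly to an aggregate with
first-order rate k_Ag; :func:`simulate_scheme1_timecourse` integrates that
loss under a rapid dimer-monomer pre-equilibrium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._fitting import multistart_curve_fit
from .constants import C_STANDARD_UM, R_KCAL
from .exceptions import FitFailureError, InvalidParameterError


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquilibriumSpec:
    """Total subunit concentration, dimer K_D (both μM) and temperature (K)."""

    c_total: float
    k_d: float
    temperature: float = 298.15

    def __post_init__(self):
        if self.c_total < 0:
            raise InvalidParameterError(f"c_total must be >= 0, got {self.c_total}")
        if self.k_d <= 0:
            raise InvalidParameterError(f"k_d must be > 0, got {self.k_d}")
        if self.temperature <= 0:
            raise InvalidParameterError(
                f"temperature must be > 0 K, got {self.temperature}")


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium concentrations and the dimer dissociation free energy.

    ``monomer`` is in subunit μM, ``dimer`` in dimer μM; ``dg_dm`` is
    −RT ln(K_D / 1 M) in kcal/mol, positive for a sub-molar K_D.
    """

    monomer: float
    dimer: float
    fraction_dimer: float
    dg_dm: float


@dataclass(frozen=True)
class EnzymeKinetics:
    """Michaelis constant (μM) and per-subunit turnover number (s⁻¹)."""

    km: float
    kcat: float
    km_err: float = float("nan")
    kcat_err: float = float("nan")

    def __post_init__(self):
        if self.km <= 0:
            raise InvalidParameterError(f"km must be > 0, got {self.km}")
        if self.kcat <= 0:
            raise InvalidParameterError(f"kcat must be > 0, got {self.kcat}")


# ---------------------------------------------------------------------------
# closed-form operations
# ---------------------------------------------------------------------------

def monomer_dimer_partition(spec: EquilibriumSpec) -> EquilibriumState:
    """Partition C_T subunits between monomer and dimer.

    The mass balance 2[M]²/K_D + [M] − C_T = 0 has the unique non-negative
    root [M] = (K_D/4)(−1 + sqrt(1 + 8 C_T/K_D)).
    """
    ct, kd = spec.c_total, spec.k_d
    m = 0.25 * kd * (-1.0 + np.sqrt(1.0 + 8.0 * ct / kd))
    d = 0.5 * (ct - m)
    frac = 2.0 * d / ct if ct > 0 else 0.0
    dg = -R_KCAL * spec.temperature * np.log(kd / C_STANDARD_UM)
    return EquilibriumState(monomer=float(m), dimer=float(d),
                            fraction_dimer=float(frac), dg_dm=float(dg))


def folded_fraction(dg_mu: float, temperature: float) -> float:
    """Two-state Boltzmann folded population from ΔG_MU (kcal/mol)."""
    if temperature <= 0:
        raise InvalidParameterError("temperature must be > 0 K")
    return float(1.0 / (1.0 + np.exp(-dg_mu / (R_KCAL * temperature))))


def dimer_activity_rate(spec: EquilibriumSpec, kinetics: EnzymeKinetics,
                        substrate) -> np.ndarray | float:
    """Initial rate (μM/s) with only dimer-borne subunits active."""
    s = np.asarray(substrate, dtype=float)
    if np.any(s < 0):
        raise InvalidParameterError("substrate concentration must be >= 0")
    state = monomer_dimer_partition(spec)
    v = kinetics.kcat * 2.0 * state.dimer * s / (kinetics.km + s)
    return float(v) if np.isscalar(substrate) else v


def simulate_scheme1_timecourse(spec: EquilibriumSpec, k_ag: float, t_grid):
    """Integrate irreversible monomer aggregation under rapid D⇌M pre-equilibrium.

    d[Ag]/dt = k_Ag [M](t), with [M], [D] re-partitioned at every instant
    from the remaining soluble pool C_T(0) − [Ag](t).  Returns a dict of
    arrays ``{"t", "monomer", "dimer", "aggregate"}``; mass
    [M] + 2[D] + [Ag] is conserved to integrator tolerance.
    """
    if k_ag < 0:
        raise InvalidParameterError(f"k_ag must be >= 0, got {k_ag}")
    t = np.asarray(t_grid, dtype=float)
    ct0 = spec.c_total

    def monomer_of(soluble):
        soluble = max(soluble, 0.0)
        return 0.25 * spec.k_d * (-1.0 + np.sqrt(1.0 + 8.0 * soluble / spec.k_d))

    def rhs(_t, y):
        ag = min(y[0], ct0)
        return [k_ag * monomer_of(ct0 - ag)]

    if k_ag == 0 or ct0 == 0:
        ag = np.zeros_like(t)
    else:
        sol = solve_ivp(rhs, (t[0], t[-1]), [0.0], t_eval=t,
                        method="LSODA", rtol=1e-10, atol=1e-12 * max(ct0, 1.0))
        ag = np.clip(sol.y[0], 0.0, ct0)
    soluble = ct0 - ag
    monomer = np.array([monomer_of(c) for c in soluble])
    dimer = 0.5 * (soluble - monomer)
    return {"t": t, "monomer": monomer, "dimer": dimer, "aggregate": ag}


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _proportional_sigma(v):
    """Per-point σ ∝ |rate| for proportional measurement noise.

    Floored at 5% of the median rate so near-zero points keep finite
    weight.
    """
    av = np.abs(np.asarray(v, dtype=float))
    floor = 0.05 * np.median(av[av > 0]) if np.any(av > 0) else 1.0
    return np.maximum(av, floor)


class MichaelisMentenEstimator(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares fit of v = Vmax S/(Km + S).

    When ``enzyme_total_uM`` and ``k_d_uM`` are supplied, the fitted Vmax is
    converted to a per-subunit kcat via the dimer-partitioned active-site
    concentration 2[D]; with ``correct_for_monomer=False`` the naive
    normalization by the total subunit concentration is used instead.

    Parameters
    ----------
    enzyme_total_uM, k_d_uM : float, optional
        Total enzyme subunit concentration and dimer K_D used for the kcat
        normalization.
    correct_for_monomer : bool, default True
        Divide Vmax by 2[D] (monomer-corrected) rather than by C_T.
    weighting : "proportional" (default) or None
        Initial-rate noise scales with the rate, so the fit weights
        residuals by 1/rate by default; None gives ordinary least squares.
    n_starts, seed : multi-start control.

    Attributes
    ----------
    km_, vmax_ : fitted parameters (μM, μM/s) with ``*_err_`` 1σ errors.
    kcat_, kcat_err_ : per-subunit turnover (s⁻¹), when normalization
        inputs were given.
    at_bound_ : True when Km ran into its lower bound (degenerate,
        saturation-only data).
    """

    _KM_LOWER = 1e-6

    def __init__(self, enzyme_total_uM=None, k_d_uM=None,
                 correct_for_monomer=True, weighting="proportional",
                 n_starts=5, seed=0):
        self.enzyme_total_uM = enzyme_total_uM
        self.k_d_uM = k_d_uM
        self.correct_for_monomer = correct_for_monomer
        self.weighting = weighting
        self.n_starts = n_starts
        self.seed = seed

    @staticmethod
    def _model(s, km, vmax):
        return vmax * s / (km + s)

    def fit(self, X, y):
        s = np.asarray(X, dtype=float).ravel()
        v = np.asarray(y, dtype=float).ravel()
        if s.size < 4 or np.unique(s).size < 4:
            raise FitFailureError(
                "need >= 4 distinct substrate concentrations for a "
                "Michaelis-Menten fit")
        if np.ptp(v) <= 1e-12 * max(np.max(np.abs(v)), 1e-30):
            raise FitFailureError("rates are constant over all substrate "
                                  "concentrations; Km is unidentifiable")
        p0 = [np.median(s), float(np.max(v)) * 1.2]
        sigma = (_proportional_sigma(v) if self.weighting == "proportional"
                 else None)
        popt, perr, diag = multistart_curve_fit(
            self._model, s, v, p0,
            bounds=([self._KM_LOWER, 0.0], [np.inf, np.inf]),
            n_starts=self.n_starts, seed=self.seed, sigma=sigma)
        self.km_, self.vmax_ = map(float, popt)
        self.km_err_, self.vmax_err_ = map(float, perr)
        self.diagnostics_ = diag
        self.at_bound_ = self.km_ <= self._KM_LOWER * 10
        if self.at_bound_:
            warnings.warn("Km estimate at lower bound: data contain no "
                          "sub-saturating information", stacklevel=2)
        if self.enzyme_total_uM is not None and self.k_d_uM is not None:
            state = monomer_dimer_partition(
                EquilibriumSpec(self.enzyme_total_uM, self.k_d_uM))
            sites = (2.0 * state.dimer if self.correct_for_monomer
                     else self.enzyme_total_uM)
            self.kcat_ = self.vmax_ / sites
            self.kcat_err_ = self.vmax_err_ / sites
        return self

    def predict(self, X):
        check_is_fitted(self, "km_")
        return self._model(np.asarray(X, dtype=float).ravel(),
                           self.km_, self.vmax_)

    def kinetics_(self) -> EnzymeKinetics:
        check_is_fitted(self, "kcat_")
        return EnzymeKinetics(km=self.km_, kcat=self.kcat_,
                              km_err=self.km_err_, kcat_err=self.kcat_err_)


class ActivityTitrationEstimator(BaseEstimator, RegressorMixin):
    """Fit the activity-vs-total-concentration curve for the dimer K_D.

    The model is v(C_T) = kcat · 2[D](C_T; K_D) · S/(Km + S) with fixed
    substrate concentration; K_D is always free and kcat optionally so.

    Attributes
    ----------
    kd_, kd_err_ : fitted dissociation constant (μM) and 1σ error.
    kcat_, kcat_err_ : fitted (or echoed) turnover number.
    unidentifiable_ : True when the sampled C_T range does not bracket the
        fitted K_D, so the estimate rests on extrapolation.
    """

    def __init__(self, s_fixed_uM=2000.0, km_uM=25.2, kcat_per_s=0.10,
                 fit_kcat=False, weighting="proportional", n_starts=5,
                 seed=0):
        self.s_fixed_uM = s_fixed_uM
        self.km_uM = km_uM
        self.kcat_per_s = kcat_per_s
        self.fit_kcat = fit_kcat
        self.weighting = weighting
        self.n_starts = n_starts
        self.seed = seed

    def _rate(self, ct, kd, kcat):
        ct = np.asarray(ct, dtype=float)
        m = 0.25 * kd * (-1.0 + np.sqrt(1.0 + 8.0 * ct / kd))
        d = 0.5 * (ct - m)
        sat = self.s_fixed_uM / (self.km_uM + self.s_fixed_uM)
        return kcat * 2.0 * d * sat

    def fit(self, X, y):
        ct = np.asarray(X, dtype=float).ravel()
        v = np.asarray(y, dtype=float).ravel()
        if ct.size < 5:
            raise FitFailureError("need >= 5 total-concentration points")
        if self.fit_kcat:
            model = lambda c, kd, kcat: self._rate(c, kd, kcat)  # noqa: E731
            p0 = [np.median(ct), self.kcat_per_s]
            lo, hi = [1e-9, 1e-9], [np.inf, np.inf]
        else:
            model = lambda c, kd: self._rate(c, kd, self.kcat_per_s)  # noqa: E731
            p0 = [np.median(ct)]
            lo, hi = [1e-9], [np.inf]
        sigma = (_proportional_sigma(v) if self.weighting == "proportional"
                 else None)
        popt, perr, diag = multistart_curve_fit(
            model, ct, v, p0, bounds=(lo, hi),
            n_starts=self.n_starts, seed=self.seed, sigma=sigma)
        self.kd_ = float(popt[0])
        self.kd_err_ = float(perr[0])
        if self.fit_kcat:
            self.kcat_, self.kcat_err_ = float(popt[1]), float(perr[1])
        else:
            self.kcat_, self.kcat_err_ = self.kcat_per_s, float("nan")
        self.diagnostics_ = diag
        self.unidentifiable_ = not (ct.min() < self.kd_ * 50 and
                                    ct.max() > self.kd_ / 50)
        if self.unidentifiable_:
            warnings.warn("C_T grid does not bracket the fitted K_D; the "
                          "estimate is poorly identified", stacklevel=2)
        return self

    def predict(self, X):
        check_is_fitted(self, "kd_")
        return self._rate(np.asarray(X, dtype=float).ravel(),
                          self.kd_, self.kcat_)


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def fit_michaelis_menten(substrate, rates, enzyme_total_uM=None, k_d_uM=None,
                         **kwargs) -> MichaelisMentenEstimator:
    """Fit initial rates vs substrate; see :class:`MichaelisMentenEstimator`."""
    return MichaelisMentenEstimator(
        enzyme_total_uM=enzyme_total_uM, k_d_uM=k_d_uM, **kwargs
    ).fit(substrate, rates)


def fit_activity_vs_concentration(c_total, rates, s_fixed_uM,
                                  kinetics: EnzymeKinetics | None = None,
                                  fit_kcat=False, **kwargs
                                  ) -> ActivityTitrationEstimator:
    """Fit v(C_T) for K_D; see :class:`ActivityTitrationEstimator`."""
    km = kinetics.km if kinetics is not None else 25.2
    kcat = kinetics.kcat if kinetics is not None else 0.10
    return ActivityTitrationEstimator(
        s_fixed_uM=s_fixed_uM, km_uM=km, kcat_per_s=kcat,
        fit_kcat=fit_kcat, **kwargs
    ).fit(c_total, rates)
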