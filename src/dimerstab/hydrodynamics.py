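"""Translational diffusion from DOSY gradient decays and Stokes-Einstein sizing.

Pulsed-field-gradient signal attenuation follows the Stejskal-Tanner
relation I(g) = I0 exp(−D γ² g² δ² (Δ − δ/3)); the fitted diffusion
coefficient converts to a hydrodynamic diameter via d = k_B T / (3π η D).
Under fast monomer-dimer exchange the single observed D is the
population-weighted average of the two species' coefficients, which can
be inverted for the dimer fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._fitting import multistart_curve_fit
from .constants import BOLTZMANN_SI
from .exceptions import InvalidInputError, InvalidParameterError, NoDecayError

#: ¹H gyromagnetic ratio, rad s⁻¹ T⁻¹
GAMMA_1H = 2.6752218744e8


@dataclass
class GradientDecay:
    """DOSY attenuation curve plus acquisition calibration.

    gradient_fraction is the fraction of g_max (T/m) applied; δ (s) is the
    encoding-pulse length and Δ (s) the diffusion time.
    """

    gradient_fraction: np.ndarray
    intensity: np.ndarray
    g_max: float
    delta: float = 3e-3
    big_delta: float = 0.2
    gamma: float = GAMMA_1H

    def __post_init__(self):
        self.gradient_fraction = np.asarray(self.gradient_fraction, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.gradient_fraction.size < 8:
            raise InvalidInputError("need >= 8 gradient steps")
        if np.any(self.intensity <= 0):
            raise InvalidInputError("intensities must be positive")

    @property
    def b_values(self):
        """Stejskal-Tanner b = γ² g² δ² (Δ − δ/3), s m⁻²."""
        g = self.gradient_fraction * self.g_max
        return (self.gamma * g * self.delta) ** 2 * (self.big_delta - self.delta / 3.0)


@dataclass(frozen=True)
class DiffusionResult:
    """Fitted diffusion coefficient and optional size conversion."""

    d: float
    log_d: float
    d_err: float = float("nan")
    hydrodynamic_diameter: float = float("nan")  # Å
    temperature: float = float("nan")
    viscosity: float = float("nan")


class StejskalTannerEstimator(BaseEstimator, RegressorMixin):
    """Exponential fit of gradient-attenuated intensities for D.

    The fit is invariant to overall intensity rescaling (I0 is free).

    Attributes
    ----------
    d_, d_err_ : diffusion coefficient (m²/s) and 1σ error; ``log_d_``.
    i0_ : fitted zero-gradient intensity.
    """

    def __init__(self, n_starts=5, seed=0):
        self.n_starts = n_starts
        self.seed = seed

    def fit(self, decay: GradientDecay):
        b = decay.b_values
        i = decay.intensity
        if np.ptp(i) <= 1e-12 * np.max(i):
            raise NoDecayError("intensities do not attenuate with gradient")
        # nondimensionalize: fit β = D·b_max so the optimizer sees O(1) scales
        b_max = float(np.max(b))
        u = b / b_max
        slope, intercept = np.polyfit(u, np.log(i), 1)
        if slope >= 0:
            raise NoDecayError("intensities increase with gradient strength")
        model = lambda uu, beta, i0: i0 * np.exp(-beta * uu)  # noqa: E731
        p0 = [-slope, float(np.exp(intercept))]
        popt, perr, diag = multistart_curve_fit(
            model, u, i, p0, bounds=([0.0, 0.0], [np.inf, np.inf]),
            n_starts=self.n_starts, seed=self.seed)
        self.d_, self.i0_ = float(popt[0] / b_max), float(popt[1])
        self.d_err_ = float(perr[0] / b_max)
        self.log_d_ = float(np.log10(self.d_))
        self.b_values_ = b
        self.diagnostics_ = diag
        return self

    def predict(self, b_values):
        check_is_fitted(self, "d_")
        return self.i0_ * np.exp(-self.d_ * np.asarray(b_values, dtype=float))

    def result_(self, temperature=float("nan"), viscosity=float("nan")
                ) -> DiffusionResult:
        check_is_fitted(self, "d_")
        diameter = float("nan")
        if np.isfinite(temperature) and np.isfinite(viscosity):
            diameter = stokes_einstein_diameter(self.d_, temperature, viscosity)
        return DiffusionResult(d=self.d_, log_d=self.log_d_, d_err=self.d_err_,
                               hydrodynamic_diameter=diameter,
                               temperature=temperature, viscosity=viscosity)


def fit_stejskal_tanner(decay: GradientDecay, temperature=float("nan"),
                        viscosity=float("nan"), **kwargs) -> DiffusionResult:
    """Fit a DOSY decay and convert to a :class:`DiffusionResult`."""
    est = StejskalTannerEstimator(**kwargs).fit(decay)
    return est.result_(temperature=temperature, viscosity=viscosity)


def stokes_einstein_diameter(d: float, temperature: float,
                             viscosity: float) -> float:
    """Hydrodynamic diameter (Å) from D (m²/s), T (K) and η (Pa·s)."""
    if d <= 0 or temperature <= 0 or viscosity <= 0:
        raise InvalidParameterError("D, T and η must all be positive")
    return BOLTZMANN_SI * temperature / (3.0 * np.pi * viscosity * d) * 1e10


def diameter_to_diffusion(diameter_angstrom: float, temperature: float,
                          viscosity: float) -> float:
    """Inverse of :func:`stokes_einstein_diameter`."""
    if diameter_angstrom <= 0 or temperature <= 0 or viscosity <= 0:
        raise InvalidParameterError("d, T and η must all be positive")
    return BOLTZMANN_SI * temperature / (3.0 * np.pi * viscosity
                                         * diameter_angstrom * 1e-10)


def two_species_population(d_obs: float, d_monomer: float,
                           d_dimer: float) -> float:
    """Dimer subunit fraction from a fast-exchange averaged D.

    D_obs = f_M D_monomer + (1 − f_M) D_dimer; values outside the
    [D_dimer, D_monomer] window are clipped with a warning.
    """
    if d_monomer <= d_dimer or d_dimer <= 0:
        raise InvalidInputError("require D_monomer > D_dimer > 0")
    if not (d_dimer <= d_obs <= d_monomer):
        warnings.warn("observed D outside the two-species window; clipping",
                      stacklevel=2)
        d_obs = float(np.clip(d_obs, d_dimer, d_monomer))
    f_mono = (d_obs - d_dimer) / (d_monomer - d_dimer)
    return 1.0 - f_mono
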