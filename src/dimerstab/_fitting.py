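"""Shared multi-start nonlinear least-squares machinery.

All estimators in the package funnel their optimization through
:func:`multistart_curve_fit`: a seeded set of jittered starting points is
tried, each with :func:`scipy.optimize.curve_fit`, and the best converged
solution (lowest residual sum of squares) wins.  Per-start diagnostics are
retained so fit failures can report what was attempted.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .exceptions import FitFailureError

#: Convergence tolerance on parameters for all nonlinear fits.
PARAM_TOL = 1e-12

DEFAULT_N_STARTS = 5


def polish_least_squares(residual, p, max_nfev=10000):
    """Unbounded Levenberg-Marquardt polish at machine-precision tolerances.

    Nearly flat directions (e.g. van't Hoff enthalpy against baselines)
    leave bounded trust-region solvers parked ~1e-6 from the minimum;
    a final LM pass with gtol-driven stopping removes that ambiguity.
    Returns the polished point, or ``p`` when the polish fails or does
    not improve the cost.
    """
    p = np.asarray(p, dtype=float)
    cost0 = float(np.sum(residual(p) ** 2))
    try:
        sol = least_squares(residual, p, method="lm", xtol=1e-15, ftol=1e-15,
                            gtol=1e-15, max_nfev=max_nfev)
    except Exception:
        return p
    if sol.success and 2.0 * sol.cost <= cost0:
        return sol.x
    return p


def _polish(model, x, y, popt, pcov, lo, hi, sigma):
    sig = None if sigma is None else np.asarray(sigma, dtype=float)

    def residual(p):
        r = model(x, *p) - y
        return r if sig is None else r / sig

    polished = polish_least_squares(residual, popt)
    if np.any(polished < lo) or np.any(polished > hi):
        return popt, pcov
    # refresh the covariance from the polished jacobian (curve_fit convention)
    try:
        sol = least_squares(residual, polished, method="lm", max_nfev=1)
        jac = sol.jac
        _, s, vt = np.linalg.svd(jac, full_matrices=False)
        threshold = np.finfo(float).eps * max(jac.shape) * s[0]
        s = s[s > threshold]
        vt = vt[: s.size]
        pcov_new = np.dot(vt.T / s**2, vt)
        dof = max(y.size - polished.size, 1)
        pcov_new *= 2.0 * sol.cost / dof
        return polished, pcov_new
    except Exception:
        return polished, pcov


def multistart_curve_fit(
    model,
    x,
    y,
    p0,
    bounds=(-np.inf, np.inf),
    n_starts: int = DEFAULT_N_STARTS,
    jitter: float = 0.25,
    seed: int = 0,
    maxfev: int = 20000,
    sigma=None,
):
    """Fit ``model(x, *params)`` to ``y`` from several jittered starts.

    Returns ``(popt, perr, diagnostics)`` where ``perr`` is the 1σ standard
    error from the fit covariance (NaN where the covariance is singular).
    Raises :class:`FitFailureError` when no start converges.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    lo = np.broadcast_to(np.asarray(lo, dtype=float), p0.shape)
    hi = np.broadcast_to(np.asarray(hi, dtype=float), p0.shape)

    best = None
    diagnostics = []
    for i in range(max(1, n_starts)):
        if i == 0:
            start = p0.copy()
        else:
            scale = np.where(np.abs(p0) > 0, np.abs(p0), 1.0)
            start = p0 + rng.normal(0.0, jitter, size=p0.shape) * scale
        start = np.clip(start, lo, hi)
        # keep strictly inside open bounds where curve_fit requires it
        eps = 1e-12
        start = np.where(start <= lo, np.where(np.isfinite(lo), lo + eps, start), start)
        start = np.where(start >= hi, np.where(np.isfinite(hi), hi - eps, start), start)
        try:
            popt, pcov = curve_fit(
                model, x, y, p0=start, bounds=(lo, hi), sigma=sigma,
                maxfev=maxfev, xtol=PARAM_TOL, ftol=PARAM_TOL,
            )
        except (RuntimeError, ValueError) as exc:
            diagnostics.append({"start": start.tolist(), "status": "failed",
                                "message": str(exc)})
            continue
        resid = model(x, *popt) - y
        if sigma is not None:
            resid = resid / np.asarray(sigma, dtype=float)
        rss = float(np.sum(resid ** 2))
        diagnostics.append({"start": start.tolist(), "status": "converged",
                            "rss": rss})
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)

    if best is None:
        raise FitFailureError(
            "nonlinear fit failed to converge from any starting point",
            diagnostics=diagnostics,
        )
    popt, pcov, _ = best
    popt, pcov = _polish(model, x, y, popt, pcov, lo, hi, sigma)
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov)) if pcov is not None else np.full_like(popt, np.nan)
    return popt, perr, diagnostics
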