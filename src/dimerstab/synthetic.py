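"""Synthetic experimental data with the statistical structure the fits assume.

Every input class the pipeline consumes can be generated here from the
forward model its paired fit inverts: two-state and bimodal LEM melts,
chemical denaturation, single-exponential aggregation decays, Arrhenius
rate series, dimer-partitioned Michaelis-Menten titrations,
activity-vs-total-concentration scans, and Stejskal-Tanner DOSY decays.

Defaults are the wild-type parameter set of the dimeric enzyme under
study (Tm → 68.3 °C in the monomer regime with ΔH = 75 kcal/mol, bimodal
dimer-regime melts at Tm1 ≈ 48 °C / Tm2 ≈ 70 °C, ΔG_MU = 9.5 kcal/mol
with m = 3 kcal/mol/M, E_a = 20.9 kcal/mol with ln A = 26, Km = 25.2 μM,
kcat = 0.10 s⁻¹, K_D = 0.5 μM).  Noise models: additive Gaussian scaled
to the signal span for ellipticities, proportional for rates, lognormal
for rate constants (keeping them positive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import celsius_to_kelvin
from .denaturation import MeltCurve, _two_state_theta, bimodal_theta
from .equilibrium import EquilibriumSpec, EnzymeKinetics, dimer_activity_rate
from .exceptions import InvalidInputError, InvalidParameterError
from .hydrodynamics import GradientDecay
from .kinetics import KineticTrace
from .constants import R_KCAL

#: Wild-type generating parameters; every scenario defaults to these.
WT_PARAMS = {
    "tm_C": 68.3,            # monomer-regime melting temperature
    "dh": 75.0,              # van't Hoff enthalpy, kcal/mol
    "tm1_C": 48.0,           # aggregation-coupled apparent transition
    "tm2_C": 70.0,           # monomer unfolding transition
    "dh1": 60.0,
    "dh2": 75.0,
    "dg0": 9.5,              # unfolding free energy at 37 °C, kcal/mol
    "m_value": 3.0,          # kcal/mol/M
    "chem_temperature_K": 310.15,
    "ea": 20.9,              # aggregation activation energy, kcal/mol
    "ln_a": 26.0,
    "km": 25.2,              # μM
    "kcat": 0.10,            # s⁻¹ per subunit in the dimer
    "k_d": 0.5,              # μM
    "c_star": 5.0,           # phase-diagram exponential scale, μM
    # shared signal baselines (intercept at 0 K, slope per K), mdeg-like
    "bf0": -26.0, "bf1": 0.02,
    "bu0": -7.0, "bu1": 0.01,
}

SCENARIOS = ("monomer_melt", "dimer_melt_family", "chem_denat",
             "decay_series", "arrhenius_series", "mm_titration",
             "ctotal_scan", "dosy_decay")


def _merged(params):
    out = dict(WT_PARAMS)
    out.update(params or {})
    return out


def temperature_grid_C(start=25.0, stop=90.0, step=0.5):
    """Default thermal scan: 25–90 °C in 0.5 K steps."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def denaturant_grid_M(start=0.0, stop=7.0, step=0.1):
    """Default chemical-denaturation grid: 0–7 M in 0.1 M steps."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def _span_noise(rng, clean, frac):
    return rng.normal(0.0, frac * np.ptp(clean), size=clean.shape)


def arrhenius_rate(temperature_K, ea, ln_a):
    return np.exp(ln_a - ea / (R_KCAL * np.asarray(temperature_K, dtype=float)))


# ---------------------------------------------------------------------------
# per-scenario generators (in-memory)
# ---------------------------------------------------------------------------

def melt_curve_monomer(seed=0, noise=0.02, c_total=0.1, params=None,
                       temps_C=None) -> MeltCurve:
    """One monomer-regime melt with additive Gaussian noise (span fraction)."""
    p = _merged(params)
    rng = np.random.default_rng(seed)
    t_c = temperature_grid_C() if temps_C is None else np.asarray(temps_C, float)
    t_k = celsius_to_kelvin(t_c)
    clean = _two_state_theta(t_k, celsius_to_kelvin(p["tm_C"]), p["dh"],
                             p["bf0"], p["bf1"], p["bu0"], p["bu1"])
    return MeltCurve(temperature=t_k,
                     ellipticity=clean + _span_noise(rng, clean, noise),
                     c_total=c_total, label="monomer_melt")


def melt_family_dimer(seed=0, noise=0.02, c_totals=(2.5, 5.0, 10.0, 25.0),
                      params=None):
    """Dimer-regime melt family; χ_A(C_T) = 1 − exp(−C_T/C*).

    Returns ``(curves, chi_a_truth)``.
    """
    p = _merged(params)
    rng = np.random.default_rng(seed)
    t_c = temperature_grid_C()
    t_k = celsius_to_kelvin(t_c)
    chi_truth = 1.0 - np.exp(-np.asarray(c_totals, float) / p["c_star"])
    curves = []
    for ct, chi in zip(c_totals, chi_truth):
        clean = bimodal_theta(t_k, chi,
                              celsius_to_kelvin(p["tm1_C"]), p["dh1"],
                              celsius_to_kelvin(p["tm2_C"]), p["dh2"],
                              p["bf0"], p["bf1"], p["bu0"], p["bu1"])
        curves.append(MeltCurve(
            temperature=t_k,
            ellipticity=clean + _span_noise(rng, clean, noise),
            c_total=float(ct), label=f"dimer_melt_{ct:g}uM"))
    return curves, chi_truth


def chem_denat_curve(seed=0, noise=0.02, params=None):
    """Chemical denaturation (denaturant M, ellipticity) at 37 °C."""
    p = _merged(params)
    rng = np.random.default_rng(seed)
    c = denaturant_grid_M()
    t = p["chem_temperature_K"]
    dg = p["dg0"] - p["m_value"] * c
    k = np.exp(-dg / (R_KCAL * t))
    theta_f = p["bf0"] + p["bf1"] * t + 0.15 * c   # gentle baseline drift in c
    theta_u = p["bu0"] + p["bu1"] * t + 0.05 * c
    clean = (theta_f + theta_u * k) / (1.0 + k)
    return c, clean + _span_noise(rng, clean, noise)


def decay_trace(seed=0, noise=0.02, temperature_K=310.15, c_total=0.1,
                k_ag=None, n_points=100, params=None) -> KineticTrace:
    """Isothermal aggregation decay; k_Ag defaults to the Arrhenius value."""
    p = _merged(params)
    rng = np.random.default_rng(seed)
    if k_ag is None:
        k_ag = float(arrhenius_rate(temperature_K, p["ea"], p["ln_a"]))
    if k_ag <= 0:
        raise InvalidParameterError("k_ag must be positive")
    t = np.linspace(0.0, 5.0 / k_ag, n_points)
    amp = (p["bf0"] + p["bf1"] * temperature_K) - (p["bu0"] + p["bu1"] * temperature_K)
    clean = (p["bu0"] + p["bu1"] * temperature_K) + amp * np.exp(-k_ag * t)
    return KineticTrace(time=t,
                        ellipticity=clean + _span_noise(rng, clean, noise),
                        temperature=temperature_K, c_total=c_total)


def arrhenius_rates(seed=0, cv=0.10, temperatures_K=None, params=None):
    """Rate constants at several temperatures with lognormal noise.

    Returns ``(temperatures_K, k_ag)``; default grid is 5 equally spaced
    temperatures over 302–318 K.
    """
    p = _merged(params)
    rng = np.random.default_rng(seed)
    t = (np.linspace(302.0, 318.0, 5) if temperatures_K is None
         else np.asarray(temperatures_K, float))
    k = arrhenius_rate(t, p["ea"], p["ln_a"])
    sigma = np.sqrt(np.log(1.0 + cv**2))
    noisy = k * rng.lognormal(-0.5 * sigma**2, sigma, size=k.shape)
    return t, noisy


def mm_rates(seed=0, cv=0.05, enzyme_total=5.0, substrate_uM=None,
             params=None):
    """Initial rates vs substrate under the dimer-only-active model.

    Returns ``(substrate_uM, rates)``; default 10 log-spaced substrate
    concentrations over 5–500 μM at 5 μM total enzyme.
    """
    p = _merged(params)
    rng = np.random.default_rng(seed)
    s = (np.geomspace(5.0, 500.0, 10) if substrate_uM is None
         else np.asarray(substrate_uM, float))
    spec = EquilibriumSpec(c_total=enzyme_total, k_d=p["k_d"])
    kin = EnzymeKinetics(km=p["km"], kcat=p["kcat"])
    v = dimer_activity_rate(spec, kin, s)
    return s, v * (1.0 + rng.normal(0.0, cv, size=v.shape))


def ctotal_rates(seed=0, cv=0.10, s_fixed=2000.0,
                 c_totals=(0.1, 0.25, 0.5, 1.0, 2.5, 5.0, 10.0), params=None):
    """Initial rates vs total enzyme concentration at fixed substrate."""
    p = _merged(params)
    rng = np.random.default_rng(seed)
    ct = np.asarray(c_totals, float)
    kin = EnzymeKinetics(km=p["km"], kcat=p["kcat"])
    v = np.array([dimer_activity_rate(EquilibriumSpec(c, p["k_d"]), kin, s_fixed)
                  for c in ct])
    return ct, v * (1.0 + rng.normal(0.0, cv, size=v.shape))


def dosy_curve(seed=0, noise=0.01, d=4.55e-11, g_max=0.5, n_steps=32,
               params=None) -> GradientDecay:
    """Stejskal-Tanner gradient decay over the 2–95 % gradient ramp."""
    rng = np.random.default_rng(seed)
    frac = np.linspace(0.02, 0.95, n_steps)
    decay = GradientDecay(gradient_fraction=frac,
                          intensity=np.ones_like(frac), g_max=g_max)
    clean = np.exp(-d * decay.b_values)
    noisy = np.clip(clean + rng.normal(0.0, noise, size=clean.shape), 1e-6, None)
    return GradientDecay(gradient_fraction=frac, intensity=noisy, g_max=g_max)


# ---------------------------------------------------------------------------
# design object / file emission
# ---------------------------------------------------------------------------

@dataclass
class SimulationDesign:
    """A named scenario plus generating parameters, noise level and seed."""

    scenario: str
    params: dict = field(default_factory=dict)
    noise: float = 0.02
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise InvalidInputError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.noise < 0:
            raise InvalidParameterError("noise must be >= 0")


def replicate_seeds(seed, n):
    """Deterministic child seeds (< 2^31) for replicate noise draws."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def generate(design: SimulationDesign, outdir=None):
    """Generate one realization of a scenario; optionally write CSV + truth.

    Returns ``{"tables": {name: DataFrame}, "truth": dict}``; with
    ``outdir`` the tables are written as CSV alongside ``truth.json``.
    Deterministic given (design, seed).
    """
    p = _merged(design.params)
    s, noise = design.seed, design.noise
    tables, truth = {}, {"scenario": design.scenario, "seed": s,
                         "noise": noise}

    if design.scenario == "monomer_melt":
        curve = melt_curve_monomer(seed=s, noise=noise, params=design.params)
        tables["melt"] = pd.DataFrame({
            "temperature_C": curve.temperature - 273.15,
            "ellipticity": curve.ellipticity})
        truth.update(tm_C=p["tm_C"], dh=p["dh"])
    elif design.scenario == "dimer_melt_family":
        curves, chi = melt_family_dimer(seed=s, noise=noise,
                                        params=design.params)
        for c in curves:
            tables[c.label] = pd.DataFrame({
                "temperature_C": c.temperature - 273.15,
                "ellipticity": c.ellipticity})
        truth.update(tm1_C=p["tm1_C"], tm2_C=p["tm2_C"], dh1=p["dh1"],
                     dh2=p["dh2"], c_star=p["c_star"],
                     chi_a=list(map(float, chi)),
                     c_totals=[c.c_total for c in curves])
    elif design.scenario == "chem_denat":
        c, theta = chem_denat_curve(seed=s, noise=noise, params=design.params)
        tables["chem_denat"] = pd.DataFrame(
            {"denaturant_M": c, "ellipticity": theta})
        truth.update(dg0=p["dg0"], m_value=p["m_value"])
    elif design.scenario == "decay_series":
        trace = decay_trace(seed=s, noise=noise, params=design.params)
        tables["decay"] = pd.DataFrame(
            {"time_s": trace.time, "ellipticity": trace.ellipticity})
        truth.update(k_ag=float(arrhenius_rate(trace.temperature,
                                               p["ea"], p["ln_a"])),
                     temperature_K=trace.temperature)
    elif design.scenario == "arrhenius_series":
        t, k = arrhenius_rates(seed=s, cv=noise if noise else 0.10,
                               params=design.params)
        tables["rates"] = pd.DataFrame(
            {"temperature_C": t - 273.15, "k_ag_per_s": k})
        truth.update(ea=p["ea"], ln_a=p["ln_a"])
    elif design.scenario == "mm_titration":
        sub, v = mm_rates(seed=s, cv=noise if noise else 0.05,
                          params=design.params)
        tables["rates"] = pd.DataFrame(
            {"substrate_uM": sub, "rate_uM_per_s": v})
        truth.update(km=p["km"], kcat=p["kcat"], k_d=p["k_d"],
                     enzyme_total=5.0)
    elif design.scenario == "ctotal_scan":
        ct, v = ctotal_rates(seed=s, cv=noise if noise else 0.10,
                             params=design.params)
        tables["rates"] = pd.DataFrame(
            {"ctotal_uM": ct, "rate_uM_per_s": v})
        truth.update(k_d=p["k_d"], km=p["km"], kcat=p["kcat"],
                     s_fixed=2000.0)
    elif design.scenario == "dosy_decay":
        decay = dosy_curve(seed=s, noise=noise if noise else 0.01)
        tables["dosy"] = pd.DataFrame(
            {"gradient_fraction": decay.gradient_fraction,
             "intensity": decay.intensity})
        truth.update(d=4.55e-11, g_max=decay.g_max, delta_s=decay.delta,
                     Delta_s=decay.big_delta)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {"tables": tables, "truth": truth}


# ---------------------------------------------------------------------------
# variant panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSpec:
    """Perturbation of the wild-type parameter set defining one variant.

    ``kd_mult`` scales K_D (interface destabilization), ``kag_mult``
    scales k_Ag (monomer kinetic destabilization), ``dtm_C`` shifts the
    monomer-regime Tm downward by that many degrees.
    """

    label: str
    kd_mult: float = 1.0
    kag_mult: float = 1.0
    dtm_C: float = 0.0

    def __post_init__(self):
        if self.kd_mult <= 0 or self.kag_mult <= 0:
            raise InvalidParameterError("multipliers must be positive")


def mutant_panel(variant_specs, seed=0, noise_rates=0.05, noise_melt=0.02,
                 outdir=None):
    """Generate per-variant datasets for a panel of perturbation specs.

    The wild type (all multipliers 1) is always included first as the
    reference.  For each variant, an activity-vs-C_T scan, an isothermal
    decay trace and a monomer-regime melt are produced along with a truth
    record.  Returns ``{label: {"ctotal": (ct, v), "decay": trace,
    "melt": curve, "truth": dict}}``.
    """
    specs = list(variant_specs)
    if not any(v.label == "WT" for v in specs):
        specs = [VariantSpec("WT")] + specs
    seeds = replicate_seeds(seed, 3 * len(specs))
    wt = WT_PARAMS
    panel = {}
    for i, v in enumerate(specs):
        kd = wt["k_d"] * v.kd_mult
        k_ag_base = float(arrhenius_rate(310.15, wt["ea"], wt["ln_a"]))
        k_ag = k_ag_base * v.kag_mult
        tm_c = wt["tm_C"] - v.dtm_C
        par = {"k_d": kd, "tm_C": tm_c}
        ct, rates = ctotal_rates(seed=int(seeds[3 * i]), cv=noise_rates,
                                 params=par)
        trace = decay_trace(seed=int(seeds[3 * i + 1]), noise=noise_melt,
                            k_ag=k_ag, params=par)
        melt = melt_curve_monomer(seed=int(seeds[3 * i + 2]),
                                  noise=noise_melt, params=par)
        truth = {"label": v.label, "k_d": kd, "k_ag": k_ag, "tm_C": tm_c,
                 "kd_mult": v.kd_mult, "kag_mult": v.kag_mult,
                 "dtm_C": v.dtm_C, "seed": int(seed)}
        panel[v.label] = {"ctotal": (ct, rates), "decay": trace,
                          "melt": melt, "truth": truth}

    if outdir is not None:
        outdir = Path(outdir)
        for label, data in panel.items():
            vdir = outdir / label
            vdir.mkdir(parents=True, exist_ok=True)
            ct, rates = data["ctotal"]
            pd.DataFrame({"ctotal_uM": ct, "rate_uM_per_s": rates}).to_csv(
                vdir / "activity_scan.csv", index=False)
            pd.DataFrame({"time_s": data["decay"].time,
                          "ellipticity": data["decay"].ellipticity}).to_csv(
                vdir / "decay.csv", index=False)
            pd.DataFrame({"temperature_C": data["melt"].temperature - 273.15,
                          "ellipticity": data["melt"].ellipticity}).to_csv(
                vdir / "melt.csv", index=False)
            (vdir / "truth.json").write_text(
                json.dumps(data["truth"], indent=2, sort_keys=True) + "\n")
    return panel
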