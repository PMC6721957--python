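# dimerstab

Thermodynamic–kinetic stability analysis for homodimeric enzymes whose
inactive monomer aggregates irreversibly.

Many oligomeric enzymes are *kinetically stabilized*: the functional
dimer D dissociates into a folded but inactive monomer M, which either
unfolds reversibly (U) or is lost irreversibly to an aggregate (Ag):

```
D  ⇌  M  ⇌  U
      │
      └─k_Ag─▶  Ag
```

The monomer–dimer leg is governed by the dissociation constant
K_D = [M]²/[D] (mass balance C_T = [M] + 2[D], subunit units), the
folding leg by the two-state free energy ΔG_MU, and the aggregation leg
by a first-order rate k_Ag whose temperature dependence follows the
Arrhenius law ln k = ln A − E_a/RT and is interpreted through
transition-state theory, ΔG‡ = RT[ln(k_BT/h) − ln k].  Disease-linked
point mutations of such enzymes destabilize the system through two
distinct routes: shifting the dimer equilibrium toward the monomer
(interface mutants, "Gr1") or accelerating monomer aggregation at
wild-type-like dimer content ("Gr2").  This package fits every
observable that constrains the scheme and assembles the per-variant
energy landscape needed to tell those mechanisms apart.  It was built
around the homodimeric metabolic enzyme fumarylacetoacetate hydrolase
(FAH), whose missense variants cause hereditary tyrosinemia type I, but
nothing in the code is specific to it.

## What it fits

| Observable | Model | Module |
|---|---|---|
| CD thermal melts (222 nm) | two-state linear extrapolation model (LEM), ΔG(T) = ΔH(1 − T/Tm) | `denaturation` |
| Concentration-dependent bimodal melts | shared-parameter global mixture χ_A·f₁(Tm1) + (1−χ_A)·f₂(Tm2) | `denaturation` |
| Chemical denaturation | LEM, ΔG(c) = ΔG0 − m·c | `denaturation` |
| Initial rates vs substrate | Michaelis–Menten with dimer-only active sites (2[D]) | `equilibrium` |
| Initial rates vs total enzyme | v(C_T) = kcat·2[D](C_T; K_D)·S/(Km+S) → K_D | `equilibrium` |
| Isothermal CD decays | single-exponential monomer loss → k_Ag | `kinetics` |
| k_Ag(T) | Arrhenius regression → E_a, ln A; Eyring barrier ΔG‡ | `kinetics` |
| DOSY gradient decays | Stejskal–Tanner → D; Stokes–Einstein diameter | `hydrodynamics` |

All fitters are scikit-learn-style estimators (`fit`/`predict`, fitted
attributes with trailing underscores) with thin functional wrappers;
`synthetic` generates every input class from the corresponding forward
model, and `landscape` assembles fits into per-variant summaries and
classifies the destabilization mechanism.

## Worked example

```python
import dimerstab as ds
from dimerstab import synthetic as syn

# a monomer-regime thermal melt with 2% noise
curve = syn.melt_curve_monomer(seed=11, noise=0.02)
melt = ds.fit_two_state_melt(curve)
print(f"Tm  = {melt.tm_ - 273.15:.2f} +/- {melt.tm_err_:.2f} C")
print(f"dH  = {melt.dh_:.1f} +/- {melt.dh_err_:.1f} kcal/mol")

# dimer dissociation constant from an activity-vs-concentration scan
ct, v = syn.ctotal_rates(seed=11, cv=0.10)
kd_fit = ds.fit_activity_vs_concentration(ct, v, s_fixed_uM=2000.0)
print(f"K_D = {kd_fit.kd_:.3f} +/- {kd_fit.kd_err_:.3f} uM")

state = ds.monomer_dimer_partition(ds.EquilibriumSpec(5.0, kd_fit.kd_, 310.15))
print(f"dimer fraction at 5 uM = {state.fraction_dimer:.3f}")

# aggregation rate and its transition-state barrier at 37 C
trace = syn.decay_trace(seed=11, noise=0.02)
dec = ds.fit_decay(trace)
print(f"k_Ag = {dec.k_ag_:.3e} /s  -> dG_barrier = "
      f"{ds.barrier_free_energy(dec.k_ag_, 310.15):.1f} kcal/mol")
```

prints

```
Tm  = 68.42 +/- 0.18 C
dH  = 72.3 +/- 2.5 kcal/mol
K_D = 0.453 +/- 0.041 uM
dimer fraction at 5 uM = 0.809
k_Ag = 3.536e-04 /s  -> dG_barrier = 23.1 kcal/mol
```

The melt recovers its generating parameters (Tm = 68.3 °C, ΔH = 75
kcal/mol) within the fitted errors; the titration recovers K_D = 0.5 μM,
at which 5 μM of enzyme is ~80% dimeric; the decay rate of ~3.5×10⁻⁴ s⁻¹
corresponds to a ~23 kcal/mol free-energy barrier between the folded
monomer and the aggregation transition state.

A command-line interface mirrors the library
(`dimerstab simulate|fit-melt|fit-chem|fit-decay|fit-arrhenius|
fit-activity|fit-dosy|landscape|classify`).

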