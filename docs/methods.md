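# Methods

## The model

The package analyses a homodimeric enzyme through a four-state scheme:
an active dimer D in rapid equilibrium with an inactive folded monomer
M, which can unfold reversibly to U or convert irreversibly to an
aggregate Ag with first-order rate k_Ag.

**Monomer–dimer equilibrium.** We adopt the convention
K_D = [M]²/[D] with the total concentration C_T counted in subunit
units, so the mass balance is C_T = [M] + 2[D] and the free monomer is
the unique non-negative root [M] = (K_D/4)(−1 + √(1 + 8C_T/K_D)).  The
dissociation free energy is ΔG_DM = −RT·ln(K_D/C°) with C° = 1 M, so a
sub-micromolar K_D gives a positive ΔG_DM of ~9 kcal/mol at 37 °C.
Units: concentrations μM, energies kcal/mol, R = 1.987×10⁻³
kcal·mol⁻¹·K⁻¹ throughout; temperatures are Kelvin internally with
Celsius accepted (and auto-detected below 150) at I/O boundaries.

**Folding.** The monomer's folded population follows the two-state
Boltzmann form f = 1/(1 + exp(−ΔG_MU/RT)).  At the wild-type stability
of 9.5 kcal/mol this exceeds 99.99% at 37 °C; a marginal variant at
1.2 kcal/mol retains ~12.5% unfolded population by direct evaluation.

**Enzymology.** Only subunits assembled in dimers carry competent
active sites: v = kcat·2[D]·S/(Km + S).  kcat is defined per subunit
within the dimer (active sites = 2[D]).  Because assays are often run
where the monomer is not negligible, the Michaelis–Menten estimator
exposes both the monomer-corrected normalization (Vmax/2[D], default)
and the naive one (Vmax/C_T).

**Denaturation.** Thermal melts use the linear extrapolation model with
ΔG(T) = ΔH(1 − T/Tm) and ΔCp = 0 (pure van't Hoff): the data are single
ΔH fits over ≤65 K windows where a heat-capacity term is not
identifiable.  Chemical denaturation uses ΔG(c) = ΔG0 − m·c.  In both
cases folded/unfolded signals are linear baselines and the observed
signal is the population-weighted average; fits are scale- and
sign-agnostic in the signal.

**Bimodal melts.** Concentration-dependent melts of the dimer regime are
modelled as a mixture: a molar fraction χ_A of the protein (the pool
that ends in the aggregate) melts through a first apparent transition
(Tm1, ΔH1) and the remainder through the monomer-unfolding transition
(Tm2, ΔH2), i.e. θ(T) = χ_A·θ₁ + (1−χ_A)·θ₂.  The normalized mixture is
chosen so that χ_A = 0 collapses exactly onto the plain two-state fit.
In the global fit Tm1, Tm2, ΔH1, ΔH2 and both baselines are shared
across the concentration series (sharing the enthalpies as well as the
temperatures keeps the two-parameter transitions identifiable at
moderate noise) and one bounded χ_A ∈ [0,1] is fitted per curve.

**Phase diagram.** 1 − χ_A is modelled as exp(−C_T/C*) — a
phenomenological single-scale decay; the monomer line
[M] = (1−χ_A)·C_T is reported against the diagonal [M] = C_T, whose
deviation (equal to χ_A) measures the aggregation propensity at each
concentration.  An all-zero χ_A input is flagged as effectively
monomeric (C* unbounded) rather than fitted.

**Aggregation kinetics.** Isothermal decays are single exponentials
θ(t) = θ_∞ + (θ_0−θ_∞)e^(−k_Ag t); no stretched exponential or
nucleation lag is modelled, as monomer loss is empirically first order
in this system.  A decay is rejected when the fitted signal change over
the trace is below 3× the noise floor (estimated from first
differences), and flagged when the trace spans less than 3/k_Ag.
Arrhenius analysis is a linear regression of ln k on 1/T (unweighted by
default; optional 1/σ² weights), Ea = −slope·R.  Transition-state
expressions use κ = 1: ΔG‡ = RT[ln(k_BT/h) − ln k].  Note that
ln(k_BT/h) ≈ 29.5 at ambient temperatures; literature values quoted
near 28 imply a different prefactor convention (κ < 1 or a
diffusion-limited prefactor) that cannot be reconstructed from a quoted
number alone, so the package always reports the physical ln(k_BT/h).

**Scheme integration.** `simulate_scheme1_timecourse` integrates
d[Ag]/dt = k_Ag[M](t) under a rapid pre-equilibrium assumption — the
D⇌M re-partitioning is instantaneous relative to aggregation — so the
soluble pool C_T − [Ag] is re-partitioned at every step.  In the
C_T ≪ K_D limit this reduces to the closed-form exponential
[M](t) = C_T·e^(−k_Ag t); at high C_T the dimer reservoir buffers the
monomer and decay is slower than exponential.

**Hydrodynamics.** DOSY attenuation follows the Stejskal–Tanner
relation I(g) = I₀·exp(−Dγ²g²δ²(Δ−δ/3)) with defaults δ = 3 ms and
Δ = 0.2 s; diameters come from Stokes–Einstein d = k_BT/(3πηD) with
water viscosities 1.002, 0.890 and 0.6913 mPa·s at 20/25/37 °C
(overridable for buffers).  Mixed monomer/dimer samples in fast
exchange show one averaged D; the two-species inversion requires
user-supplied reference coefficients for pure monomer and pure dimer,
which are rarely measurable directly and usually come from structure-
based estimates — the main caveat of that route.

## Classification

A variant's mechanism group is a pure function of its landscape and a
threshold set printed in every report: relative dimer fraction < 0.7 →
Gr1 (interface destabilization); relative k_Ag > 2 at wild-type-like
dimer content → Gr2 (monomer kinetic destabilization); ΔG_MU < 3
kcal/mol → unfolding-destabilized, overriding both; both Gr1 and Gr2
flags raised, or required quantities missing → indeterminate.  The
cutoffs are analysis choices — the qualitative separations they encode
(substantially reduced dimer content; severalfold-accelerated
aggregation; marginal stability) have no unique numeric boundary — and
are deliberately configurable.  Structural location is treated as
metadata only; classification always follows the measured quantities.

## Numerical choices

All nonlinear fits run multi-start least squares: 5 seeded jittered
starting points, bounded trust-region optimization (tolerances 1e−12),
best residual wins, followed by an unbounded Levenberg–Marquardt polish
at machine-precision tolerances.  The polish matters because the LEM
enthalpy lies along a nearly flat direction against the baselines:
independent optimizers otherwise park ~1e−6 apart in relative terms.
Parameter errors are 1σ from the fit covariance (no bootstrap by
default).  Rate fits (Michaelis–Menten, activity-vs-C_T) weight
residuals by 1/rate by default because initial-rate noise is
proportional to the rate; unweighted fits would let the saturated
points drown the informative low-rate region.  The DOSY fit is
performed in the nondimensional variable β = D·b_max to keep the
optimizer's scales O(1).  The Stejskal–Tanner and decay fits refuse
degenerate inputs (flat signal, non-decaying intensities) rather than
returning boundary estimates; the Michaelis–Menten fit flags a Km at
its lower bound, and the K_D fit flags scans that do not bracket the
fitted constant.

## Synthetic data

The generator emits every input class from the same forward models the
estimators invert, with defaults at the wild-type parameter set: melts
over 25–90 °C in 0.5 K steps (Tm = 68.3 °C, ΔH = 75 kcal/mol; bimodal
families at C_T = 2.5–25 μM with Tm1 = 48 °C, Tm2 = 70 °C,
χ_A = 1 − e^(−C_T/5 μM)), denaturant grids 0–7 M in 0.1 M steps
(ΔG0 = 9.5 kcal/mol, m = 3 kcal/mol/M at 37 °C), Arrhenius series at 5
temperatures over 302–318 K (Ea = 20.9 kcal/mol, ln A = 26), titrations
at 10 substrate points over 5–500 μM (Km = 25.2 μM, kcat = 0.10 s⁻¹ at
5 μM enzyme), concentration scans over 0.1–10 μM (K_D = 0.5 μM), and
32-step DOSY ramps (D = 4.55×10⁻¹¹ m²/s, a ~94 Å particle at 20 °C).
ΔH1 = 60 kcal/mol for the aggregation-coupled transition is a
representative choice (the apparent first transition is less
cooperative than monomer unfolding).  Noise is additive Gaussian scaled
to the signal span for ellipticities, proportional for rates, and
lognormal for rate constants, keeping positive quantities positive.
Generation is deterministic given (design, seed), and each dataset
carries a machine-readable truth record that the recovery tests treat
as the contract.

What the generator does **not** emulate: instrument drift and 1/f
noise, thermal-lag hysteresis in melts, incomplete baselines, buffer-
dependent viscosity, slow-exchange DOSY lineshapes, and any real
mutant's correlated parameter shifts (panel variants perturb K_D, k_Ag
and Tm independently).  Passing recovery tests therefore demonstrate
estimator correctness and precision under the assumed noise structure,
not robustness to every artifact of real CD or NMR data.

## Problem sizes

Recovery experiments use 200 seeded replicates per scalar parameter
(50 families for the global bimodal fit, whose four-curve problems are
~10× larger); medians over replicates are reported.  These sizes give
stable medians — repeat runs at different master seeds move them by
well under the experimental uncertainties they are compared against.

## Known limitations

* ΔCp = 0 means ΔG_MU(T) extrapolated far from Tm is biased; stability
  comparisons should use the Tm-shift formula ΔΔG = ΔH·ΔTm/Tm or
  chemical denaturation at the temperature of interest.
* The bimodal model treats χ_A as temperature-independent within one
  scan, i.e. the aggregate pool is set before the scan's first
  transition; kinetic coupling between scan rate and aggregation is not
  modelled.
* The activity-vs-C_T fit assumes Km and kcat are known (or fitted
  jointly at the cost of identifiability); it cannot separate a K_D
  shift from a kcat loss on its own.
* The classification thresholds are heuristics; borderline variants
  should be inspected, not trusted to the label.
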