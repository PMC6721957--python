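"""Per-variant energy-landscape assembly and mechanistic classification.

Each variant of the dimeric enzyme is summarized relative to the wild
type: relative catalytic activity, relative dimer fraction at the assay
concentration, relative aggregation rate, the unfolding free energy
ΔG_MU, the dimer dissociation free energy ΔG_DM, and the transition-state
barrier ΔG‡ implied by k_Ag.  Variants are then sorted into mechanism
groups:

* **Gr1** — dimer-interface destabilizers: the monomer-dimer equilibrium
  shifts toward the monomer (low relative dimer fraction).
* **Gr2** — monomer kinetic destabilizers: wild-type-like dimer content
  but an elevated aggregation rate.
* **unfolding-destabilized** — the folded state itself is marginal
  (ΔG_MU below the cut), overriding the other labels.
* **WT-like / indeterminate** — no flag raised, or conflicting flags.

The numeric cutoffs are not measured quantities; they are configurable
analysis choices printed in every report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from math import isnan

import numpy as np
import pandas as pd

from .constants import R_KCAL
from .equilibrium import EquilibriumSpec, monomer_dimer_partition
from .exceptions import InvalidInputError
from .kinetics import barrier_free_energy

GROUPS = ("WT-like", "Gr1", "Gr2", "unfolding-destabilized", "indeterminate")

NAN = float("nan")


@dataclass(frozen=True)
class Thresholds:
    """Classification cutoffs (all configurable, printed in reports)."""

    rel_dimer_cut: float = 0.7      # below → interface destabilization
    rel_kag_cut: float = 2.0        # above → kinetic destabilization
    dg_mu_cut: float = 3.0          # kcal/mol; below → marginal fold


@dataclass
class VariantLandscape:
    """One variant's energy landscape and relative phenotype."""

    label: str
    rel_activity: float = NAN
    rel_dimer_fraction: float = NAN
    rel_kag: float = NAN
    dg_mu: float = NAN
    dg_dm: float = NAN
    barrier_dg: float = NAN
    group: str = "indeterminate"
    flags: list = field(default_factory=list)

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


def classify_mechanism(landscape: VariantLandscape,
                       thresholds: Thresholds = Thresholds()) -> str:
    """Assign a mechanism group; pure function of (landscape, thresholds)."""
    dg = landscape.dg_mu
    if not isnan(dg) and dg < thresholds.dg_mu_cut:
        return "unfolding-destabilized"
    rd, rk = landscape.rel_dimer_fraction, landscape.rel_kag
    if isnan(rd) or isnan(rk):
        return "indeterminate"
    gr1 = rd < thresholds.rel_dimer_cut
    gr2 = rk > thresholds.rel_kag_cut
    if gr1 and gr2:
        return "indeterminate"
    if gr1:
        return "Gr1"
    if gr2:
        return "Gr2"
    return "WT-like"


def assemble_landscape(label, wt, *, dg_mu=NAN, k_d=NAN, k_ag=NAN,
                       activity=NAN, assay_c_total=5.0, temperature=310.15,
                       thresholds: Thresholds = Thresholds()
                       ) -> VariantLandscape:
    """Build a variant's landscape relative to a wild-type reference.

    ``wt`` is a dict with keys among {"k_d", "k_ag", "activity", "dg_mu"};
    the wild-type K_D is required (relative quantities are undefined
    without a reference).  Missing variant quantities are flagged, never
    imputed.  Dimer fractions are evaluated at ``assay_c_total`` μM.
    """
    if wt is None or "k_d" not in wt:
        raise InvalidInputError(
            "a wild-type reference (with at least k_d) is required")
    if isnan(dg_mu) and isnan(k_d) and isnan(k_ag):
        raise InvalidInputError(
            "need at least dg_mu and one of (k_d, k_ag) for a landscape")

    flags = []
    wt_frac = monomer_dimer_partition(
        EquilibriumSpec(assay_c_total, wt["k_d"], temperature)).fraction_dimer

    if not isnan(k_d):
        state = monomer_dimer_partition(
            EquilibriumSpec(assay_c_total, k_d, temperature))
        rel_dimer = state.fraction_dimer / wt_frac
        dg_dm = state.dg_dm
    else:
        rel_dimer, dg_dm = NAN, NAN
        flags.append("missing:k_d")

    if not isnan(k_ag):
        rel_kag = k_ag / wt["k_ag"] if "k_ag" in wt else NAN
        barrier = barrier_free_energy(k_ag, temperature)
        if "k_ag" not in wt:
            flags.append("missing:wt_k_ag")
    else:
        rel_kag, barrier = NAN, NAN
        flags.append("missing:k_ag")

    if not isnan(activity) and wt.get("activity"):
        rel_activity = activity / wt["activity"]
    else:
        rel_activity = NAN
        flags.append("missing:activity")

    if isnan(dg_mu):
        flags.append("missing:dg_mu")

    ls = VariantLandscape(label=label, rel_activity=rel_activity,
                          rel_dimer_fraction=rel_dimer, rel_kag=rel_kag,
                          dg_mu=dg_mu, dg_dm=dg_dm, barrier_dg=barrier,
                          flags=flags)
    ls.group = classify_mechanism(ls, thresholds)
    return ls


# ---------------------------------------------------------------------------
# end-to-end panel analysis
# ---------------------------------------------------------------------------

def analyze_panel(panel, dg_mu_wt=9.5, dh_vh=75.0, s_fixed_uM=2000.0,
                  temperature=310.15, thresholds: Thresholds = Thresholds()):
    """Fit every variant's datasets and classify its mechanism.

    ``panel`` is the structure produced by the synthetic ``mutant_panel``
    (or any mapping of label → {"ctotal": (C_T, v), "decay": KineticTrace,
    "melt": MeltCurve}).  K_D comes from the activity-vs-C_T scan, k_Ag
    from the decay trace, and ΔG_MU from the wild-type free energy minus
    the Tm-shift destabilization ΔH·ΔTm/Tm_wt.  Returns a list of
    :class:`VariantLandscape`, wild type first.
    """
    from .denaturation import ddg_from_tm_shift, fit_two_state_melt
    from .equilibrium import fit_activity_vs_concentration
    from .kinetics import fit_decay

    if "WT" not in panel:
        raise InvalidInputError("panel must contain a WT reference")

    def fit_one(data):
        ct, v = data["ctotal"]
        kd = fit_activity_vs_concentration(ct, v, s_fixed_uM).kd_
        kag = fit_decay(data["decay"]).k_ag_
        tm = fit_two_state_melt(data["melt"]).tm_
        return kd, kag, tm

    wt_kd, wt_kag, wt_tm = fit_one(panel["WT"])
    wt = {"k_d": wt_kd, "k_ag": wt_kag, "dg_mu": dg_mu_wt}
    results = []
    for label in ["WT"] + [k for k in panel if k != "WT"]:
        kd, kag, tm = (wt_kd, wt_kag, wt_tm) if label == "WT" \
            else fit_one(panel[label])
        dg_mu = dg_mu_wt - ddg_from_tm_shift(dh_vh, wt_tm, tm)
        results.append(assemble_landscape(
            label, wt, dg_mu=dg_mu, k_d=kd, k_ag=kag,
            temperature=temperature, thresholds=thresholds))
    return results


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def serialize_landscapes(landscapes, thresholds: Thresholds = Thresholds()):
    """JSON report: thresholds used plus one record per variant."""
    return json.dumps({
        "thresholds": asdict(thresholds),
        "variants": [ls.to_dict() for ls in landscapes],
    }, indent=2, sort_keys=True)


def parse_landscapes(text):
    """Inverse of :func:`serialize_landscapes`."""
    obj = json.loads(text)
    return ([VariantLandscape.from_dict(d) for d in obj["variants"]],
            Thresholds(**obj["thresholds"]))


def landscape_table(landscapes) -> pd.DataFrame:
    """One row per variant, columns matching the landscape fields."""
    rows = [ls.to_dict() for ls in landscapes]
    for r in rows:
        r["flags"] = ";".join(r["flags"])
    return pd.DataFrame(rows)
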