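"""CSV and manifest I/O.

All tabular inputs are plain CSV with a header row; lines starting with
``#`` are comments.  Concentrations are μM, rates μM/s, energies
kcal/mol; temperatures in files are Celsius (converted to Kelvin on
read).  Manifests are YAML key-value files listing datasets and their
metadata (path, C_T, temperature, label, calibration blocks).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .constants import celsius_to_kelvin
from .denaturation import MeltCurve
from .exceptions import InvalidInputError
from .hydrodynamics import GradientDecay
from .kinetics import KineticTrace


def _read_csv(path, required_cols):
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise InvalidInputError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}")
    return df


def read_melt_csv(path, c_total=float("nan"), label="") -> MeltCurve:
    """Read ``temperature_C, ellipticity`` into a :class:`MeltCurve`."""
    df = _read_csv(path, ["temperature_C", "ellipticity"])
    return MeltCurve(temperature=celsius_to_kelvin(df["temperature_C"].to_numpy()),
                     ellipticity=df["ellipticity"].to_numpy(),
                     c_total=c_total, label=label or Path(path).stem)


def read_chem_csv(path):
    """Read ``denaturant_M, ellipticity``; returns (denaturant, signal)."""
    df = _read_csv(path, ["denaturant_M", "ellipticity"])
    return df["denaturant_M"].to_numpy(), df["ellipticity"].to_numpy()


def read_trace_csv(path, temperature=float("nan"),
                   c_total=float("nan")) -> KineticTrace:
    """Read ``time_s, ellipticity`` into a :class:`KineticTrace`."""
    df = _read_csv(path, ["time_s", "ellipticity"])
    return KineticTrace(time=df["time_s"].to_numpy(),
                        ellipticity=df["ellipticity"].to_numpy(),
                        temperature=temperature, c_total=c_total)


def read_rate_table(path):
    """Read a rate table; returns (x, rate, kind).

    ``kind`` is "substrate", "ctotal" or "arrhenius" depending on whether
    the first column is ``substrate_uM``, ``ctotal_uM`` or
    ``temperature_C`` (the latter paired with ``k_ag_per_s``, converted
    to Kelvin).
    """
    df = pd.read_csv(path, comment="#")
    if "substrate_uM" in df.columns:
        return df["substrate_uM"].to_numpy(), df["rate_uM_per_s"].to_numpy(), "substrate"
    if "ctotal_uM" in df.columns:
        return df["ctotal_uM"].to_numpy(), df["rate_uM_per_s"].to_numpy(), "ctotal"
    if "temperature_C" in df.columns and "k_ag_per_s" in df.columns:
        return (celsius_to_kelvin(df["temperature_C"].to_numpy()),
                df["k_ag_per_s"].to_numpy(), "arrhenius")
    raise InvalidInputError(f"{path}: unrecognized rate-table columns "
                            f"{list(df.columns)}")


def read_dosy_csv(path, g_max, delta=3e-3, big_delta=0.2,
                  gamma=None) -> GradientDecay:
    """Read ``gradient_fraction, intensity`` plus calibration values."""
    df = _read_csv(path, ["gradient_fraction", "intensity"])
    kwargs = {} if gamma is None else {"gamma": gamma}
    return GradientDecay(gradient_fraction=df["gradient_fraction"].to_numpy(),
                         intensity=df["intensity"].to_numpy(),
                         g_max=g_max, delta=delta, big_delta=big_delta,
                         **kwargs)


def read_manifest(path) -> dict:
    """Load a YAML manifest of datasets and metadata."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InvalidInputError(f"{path}: manifest must be a mapping")
    return data


def write_manifest(path, data):
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
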