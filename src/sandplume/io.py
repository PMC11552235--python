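"""File formats and unit-suffixed configuration.

Internally everything is strict SI (m, s, mol/m^3); configuration files and
tables carry explicit unit suffixes (``c0_mM``, ``depth_mm``, ``c_star_uM``,
``dose_molar``) and are converted on ingest.  Traces travel as two-column
delimited text (time_s, volts) with a JSON sidecar for sampling rate and
stimulus windows.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .capsule import SCENARIOS, ConcentrationField, DetectabilityResult
from .nerve import DoseResponseSeries, NerveTrace
from .params import PhysicalParams

__all__ = [
    "ConfigError",
    "load_config",
    "params_from_config",
    "write_trace",
    "read_trace",
    "write_field_csv",
    "write_detectability_json",
    "read_detectability_json",
    "write_dose_response_csv",
    "read_dose_response_csv",
]


class ConfigError(ValueError):
    """A configuration entry failed validation; the message names the field."""


# config key -> (PhysicalParams field, factor to SI)
_CONFIG_KEYS = {
    "D_m2_per_s": ("D", 1.0),
    "T_K": ("T", 1.0),
    "eta_Pa_s": ("eta", 1.0),
    "r_mol_nm": ("r_mol", 1e-9),
    "c0_mM": ("c0", 1.0),          # 1 mM == 1 mol/m^3
    "V_mL": ("V", 1e-6),
    "a_major_mm": ("a_major", 1e-3),
    "a_minor_mm": ("a_minor", 1e-3),
    "depth_mm": ("depth_l", 1e-3),
    "c_star_uM": ("c_star", 1e-3),  # 1 uM == 1e-3 mol/m^3
    "t_max_s": ("t_max", 1.0),
    "layer_depth_mm": ("layer_depth", 1e-3),
}
_EXTRA_KEYS = {"scenario", "c0_list_mM", "depth_list_mm", "seed"}


def load_config(path) -> dict:
    """Load a YAML config file (plain key-value mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config file must contain a key-value mapping")
    return cfg


def params_from_config(cfg: dict) -> tuple[PhysicalParams, dict]:
    """Validate a unit-suffixed config mapping into (PhysicalParams, extras).

    Unknown keys, non-numeric values and bad scenarios raise ConfigError
    naming the offending field.  Extras carry ``scenario`` and optional
    sweep lists (converted to SI).
    """
    kwargs = {}
    extras = {}
    for key, value in cfg.items():
        if key in _CONFIG_KEYS:
            field_name, factor = _CONFIG_KEYS[key]
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigError(f"config field {key!r} must be a number, got {value!r}")
            kwargs[field_name] = float(value) * factor
        elif key == "scenario":
            if value not in SCENARIOS:
                raise ConfigError(f"config field 'scenario' must be one of {SCENARIOS}, got {value!r}")
            extras["scenario"] = value
        elif key == "c0_list_mM":
            extras["c0_list"] = _numeric_list(key, value)
        elif key == "depth_list_mm":
            extras["depth_list"] = [v * 1e-3 for v in _numeric_list(key, value)]
        elif key == "seed":
            if not isinstance(value, int) or isinstance(value, bool):
                raise ConfigError(f"config field 'seed' must be an integer, got {value!r}")
            extras["seed"] = value
        else:
            raise ConfigError(f"unknown config field {key!r} (check the unit suffix)")
    try:
        params = PhysicalParams(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    extras.setdefault("scenario", "free_interface")
    return params, extras


def _numeric_list(key: str, value) -> list[float]:
    if not isinstance(value, (list, tuple)) or not value:
        raise ConfigError(f"config field {key!r} must be a non-empty list of numbers")
    out = []
    for v in value:
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ConfigError(f"config field {key!r} must contain only numbers, got {v!r}")
        out.append(float(v))
    return out


# ---------------------------------------------------------------------------
# traces


def write_trace(path, trace: NerveTrace, sidecar=None) -> None:
    """Two-column text (time_s <TAB> volts) plus a JSON sidecar."""
    path = Path(path)
    data = np.column_stack([trace.times, trace.samples])
    np.savetxt(path, data, fmt="%.6f\t%.8e", header="time_s\tvolts")
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    meta = {k: v for k, v in trace.meta.items()
            if isinstance(v, (int, float, str, bool, type(None)))}
    sidecar.write_text(json.dumps({
        "fs": trace.fs,
        "species": trace.species,
        "stimuli": [
            {"label": lab, "onset_s": on, "offset_s": off}
            for lab, on, off in trace.stimuli
        ],
        "meta": meta,
    }, indent=2, sort_keys=True))


def read_trace(path, sidecar=None) -> NerveTrace:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing stimulus sidecar {sidecar} for trace {path}")
    side = json.loads(sidecar.read_text())
    data = np.loadtxt(path)
    samples = data[:, 1] if data.ndim == 2 else data
    return NerveTrace(
        fs=float(side["fs"]),
        samples=samples,
        stimuli=[(s["label"], float(s["onset_s"]), float(s["offset_s"]))
                 for s in side.get("stimuli", [])],
        species=side.get("species", ""),
        meta=side.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# fields, detectability, dose–response tables


def write_field_csv(path, field: ConcentrationField) -> None:
    """Long-format CSV: scenario,t,x,y,z,c."""
    field.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def write_detectability_json(path, results: list[DetectabilityResult]) -> None:
    """Deterministic JSON records of a detectability sweep."""
    Path(path).write_text(
        json.dumps([r.to_record() for r in results], indent=2, sort_keys=True) + "\n"
    )


def read_detectability_json(path) -> list[DetectabilityResult]:
    records = json.loads(Path(path).read_text())
    return [
        DetectabilityResult(
            c0=r["c0_mM"], depth_l=r["depth_mm"] * 1e-3, c_star=r["c_star_mM"],
            onset_time=r["onset_time_s"],
            peak_surface_conc=r["peak_surface_conc_mM"],
            detected_within_t_max=r["detected_within_t_max"],
            scenario=r["scenario"],
        )
        for r in records
    ]


def write_dose_response_csv(path, series_list) -> None:
    """CSV columns: compound,species,dose_molar,replicate,area (dose in M)."""
    pd.concat([s.to_dataframe() for s in series_list], ignore_index=True).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_dose_response_csv(path) -> list[DoseResponseSeries]:
    df = pd.read_csv(path)
    out = []
    for (compound, species), grp in df.groupby(["compound", "species"], sort=True):
        blanks = grp.loc[grp["dose_molar"] == 0.0, "area"].to_numpy()
        dosed = grp[grp["dose_molar"] > 0.0]
        doses = np.sort(dosed["dose_molar"].unique()) * 1e3  # M -> mol/m^3
        responses = [
            dosed.loc[np.isclose(dosed["dose_molar"] * 1e3, d), "area"].to_numpy()
            for d in doses
        ]
        out.append(DoseResponseSeries(compound=compound, species=species,
                                      doses=doses, responses=responses, blanks=blanks))
    return out
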