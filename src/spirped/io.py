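"""Readers and writers: NONMEM-dialect datasets, flat configs, tidy outputs.

Datasets are rectangular CSV tables in the NONMEM event/observation dialect
(ID, TIME, AMT, DV, CMT, EVID, MDV plus covariates), with "." as the missing
value token.  Every file written by the package carries provenance comment
headers (package version, seed, config hash) on lines starting with "#".
Concentrations are stored in mg/L; a display conversion to ng/mL (x1000) is
available at this layer only.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import PKParameterSet, ValidationError
from .population import VariabilitySpec

MISSING_TOKEN = "."
REQUIRED_NM_COLUMNS = ("ID", "TIME", "AMT", "DV", "CMT", "EVID", "MDV")

#: Config keys of the structural parameters, in file order.
PARAM_KEYS = {"CL": "cl", "CLM1": "clm1", "V2": "v2", "Q": "q", "V3": "v3",
              "KA": "ka", "ALAG1": "alag1", "FM": "fm", "CLM": "clm",
              "V4": "v4", "Q1": "q1", "V5": "v5"}
OMEGA_KEYS = {"OMEGA_KA": "ka", "OMEGA_CL": "cl", "OMEGA_V2": "v2",
              "OMEGA_Q": "q", "OMEGA_CLM1": "clm1", "OMEGA_CLM": "clm",
              "OMEGA_V4": "v4", "OMEGA_Q1": "q1", "OMEGA_V5": "v5"}


def validate_nm_dataset(df: pd.DataFrame) -> None:
    """Enforce the event/observation invariants of the dataset dialect."""
    missing = [c for c in REQUIRED_NM_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"dataset is missing columns {missing}")
    evid = df["EVID"].to_numpy()
    mdv = df["MDV"].to_numpy()
    dv_missing = df["DV"].isna().to_numpy()
    amt = df["AMT"].to_numpy(dtype=float)
    is_dose = evid == 1
    is_obs = evid == 0
    ok = np.where(
        is_dose, (mdv == 1) & dv_missing & (amt > 0),
        np.where(is_obs,
                 np.isnan(amt) & ((mdv == 1) | ((mdv == 0) & ~dv_missing)),
                 False))
    if not np.all(ok):
        bad = df.index[~ok].tolist()[:20]
        raise ValidationError(f"invalid event/observation rows at index {bad}")
    for sid, sub in df.groupby("ID"):
        if np.any(np.diff(sub.TIME.to_numpy()) < 0):
            raise ValidationError(f"TIME not non-decreasing within ID {sid}")


def provenance_header(seed: int | None = None, config: dict | None = None,
                      ) -> list[str]:
    lines = [f"# spirped {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
        lines.append(f"# config_sha256: {digest[:16]}")
    return lines


def write_nm_dataset(df: pd.DataFrame, path, seed: int | None = None,
                     config: dict | None = None,
                     units_ng_per_ml: bool = False) -> None:
    """Write a validated dataset as CSV with '.' for missing values."""
    validate_nm_dataset(df)
    out = df.copy()
    if units_ng_per_ml:
        out["DV"] = out["DV"] * 1000.0
    buffer = _io.StringIO()
    # full float precision so a write/read round trip is lossless
    out.to_csv(buffer, index=False, na_rep=MISSING_TOKEN,
               float_format="%.17g")
    Path(path).write_text(
        "\n".join(provenance_header(seed, config)) + "\n" + buffer.getvalue())


def read_nm_dataset(path) -> pd.DataFrame:
    """Read and validate a NONMEM-dialect CSV dataset."""
    df = pd.read_csv(path, comment="#", na_values=[MISSING_TOKEN])
    for col in ("ID", "CMT", "EVID", "MDV"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    validate_nm_dataset(df)
    return df


def write_tidy_csv(df: pd.DataFrame, path, seed: int | None = None,
                   config: dict | None = None) -> None:
    """Write a tidy result table with provenance headers."""
    buffer = _io.StringIO()
    df.to_csv(buffer, index=False)
    Path(path).write_text(
        "\n".join(provenance_header(seed, config)) + "\n" + buffer.getvalue())


def params_to_config(params: PKParameterSet) -> dict[str, float]:
    return {key: getattr(params, attr) for key, attr in PARAM_KEYS.items()}


def params_from_config(config: dict) -> PKParameterSet:
    try:
        kwargs = {attr: float(config[key]) for key, attr in PARAM_KEYS.items()}
    except KeyError as exc:
        raise ValidationError(f"config is missing parameter key {exc}") from None
    return PKParameterSet(**kwargs)


def variability_to_config(spec: VariabilitySpec) -> dict[str, float]:
    out = {key: spec.omega(attr) for key, attr in OMEGA_KEYS.items()}
    out["COV_CL_V2"] = spec.cov_cl_v2
    out["EPS1"] = spec.eps1
    out["EPS2"] = spec.eps2
    return out


def variability_from_config(config: dict) -> VariabilitySpec:
    omega2 = {attr: float(config[key]) for key, attr in OMEGA_KEYS.items()
              if key in config}
    return VariabilitySpec(
        omega2=omega2,
        cov_cl_v2=float(config.get("COV_CL_V2", 0.0)),
        eps1=float(config.get("EPS1", 0.0)),
        eps2=float(config.get("EPS2", 0.0)),
    )


def load_config(path) -> dict:
    """Load a flat YAML/JSON-style key-value config file."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValidationError("config file must contain a flat mapping")
    return config


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=False)
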