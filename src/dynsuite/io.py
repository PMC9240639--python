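"""Table readers/writers, run configuration and the results bundle.

All tables are UTF-8, tab-delimited, with `#` comment lines ignored and the
string "NA" for missing values. Residue numbering is the author-assigned
(PDB-style, 1-based) numbering and is never re-indexed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spin import (
    CSA_PPM,
    DEFAULT_FIELD_MHZ,
    GAMMA_H,
    GAMMA_N,
    R_NH_ANGSTROM,
    SpinConstants,
)

__all__ = ["SCHEMAS", "read_table", "write_table", "RunConfig", "run_report",
           "load_report"]


def _positive(col):
    return lambda s: (s.dropna() > 0).all(), f"{col} must be positive"


def _nonneg(col):
    return lambda s: (s.dropna() >= 0).all(), f"{col} must be non-negative"


#: schema name -> (required columns, optional columns, {col: (check, message)})
SCHEMAS = {
    "relaxation": (
        ["res_num", "res_name", "field_MHz", "R1", "R1_err", "R2", "R2_err",
         "NOE", "NOE_err"],
        [],
        {c: _positive(c) for c in ("R1", "R1_err", "R2", "R2_err", "NOE_err",
                                   "field_MHz")},
    ),
    "hdx": (
        ["res_num", "time_s", "intensity"],
        ["intensity_err"],
        {"time_s": _positive("time_s"), "intensity": _nonneg("intensity")},
    ),
    "shifts": (["res_num", "H_ppm", "N_ppm"], ["res_name"], {}),
    "rdc": (
        ["res_num", "D_Hz", "D_err"],
        ["medium"],
        {"D_err": _positive("D_err")},
    ),
    "modelfree_results": (
        ["res_num", "model", "s2", "tau_e_ps", "rex", "chi2"],
        ["res_name", "s2_err", "tau_e_err_ps", "rex_err", "exchange", "flags",
         "tau_c_ns", "sf2", "tau_s_ps"],
        {},
    ),
}

_STRING_COLS = {"res_name", "model", "flags", "medium", "exchange", "segment"}


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a tab-delimited table against a named schema.

    Missing values are written "NA". Failures name the offending column or
    1-based data row.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema '{schema_name}', expected one of {list(SCHEMAS)}")
    required, optional, checks = SCHEMAS[schema_name]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path.name}: missing column(s) {missing} required by schema "
            f"'{schema_name}'"
        )
    for col in df.columns:
        if col in _STRING_COLS:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(
                f"{path.name}: non-numeric value '{df[col][bad.idxmax()]}' in "
                f"column '{col}', data row {row}"
            )
        df[col] = converted
    for col, (check, message) in checks.items():
        if col not in df.columns:
            continue
        ok = check(df[col])
        if not ok:
            series = df[col].dropna()
            viol = series[~(series > 0)] if "positive" in message else series[~(series >= 0)]
            row = int(viol.index[0]) + 1 if len(viol) else "?"
            raise ValueError(f"{path.name}: {message} (first violation at data row {row})")
    if "res_num" in df.columns:
        df["res_num"] = df["res_num"].astype("Int64")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class RunConfig:
    """All tunable constants and thresholds of a pipeline run.

    Round-trips through YAML unchanged; every field has a default.
    """

    gamma_H: float = GAMMA_H
    gamma_N: float = GAMMA_N
    r_NH_angstrom: float = R_NH_ANGSTROM
    csa_ppm: float = CSA_PPM
    field_MHz: float = DEFAULT_FIELD_MHZ
    noe_cutoff: float = 0.65
    trim_sd: float = 1.5
    rex_threshold: float = 2.0
    mc_draws: int = 0
    alpha: float = 0.14
    k_sigma: float = 4.0
    min_hits: int = 3
    censor_decay: float = 0.05
    hdx_pH: float = 7.0
    hdx_temperature_K: float = 308.0
    seed: int = 0

    @property
    def constants(self) -> SpinConstants:
        return SpinConstants.at_field(
            self.field_MHz,
            gamma_N=self.gamma_N,
            r_NH=self.r_NH_angstrom * 1e-10,
            delta_sigma=self.csa_ppm,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the resolved configuration, for run logs."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return {"__dataframe__": obj.replace({np.nan: None}).to_dict(orient="list")}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_report(stages: dict, config: RunConfig | None = None, path=None):
    """Assemble stage outputs into a summary text and a re-loadable bundle.

    `stages` maps stage name -> dict of headline numbers / tables. Returns
    (text, bundle); when `path` is given the bundle is written as JSON next
    to a plain-text summary.
    """
    if not stages:
        raise ValueError("no completed stages to report")
    config = config or RunConfig()
    bundle = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "stages": _jsonable(stages),
    }
    lines = [
        "dynsuite run report",
        f"config digest: {config.digest()}",
        f"seed: {config.seed}",
        f"constants: field {config.field_MHz:.1f} MHz, r_NH {config.r_NH_angstrom} A, "
        f"CSA {config.csa_ppm} ppm",
        "",
    ]
    for name, content in stages.items():
        lines.append(f"[{name}]")
        for key, val in content.items():
            if isinstance(val, pd.DataFrame):
                lines.append(f"  {key}: table with {len(val)} rows")
            elif isinstance(val, float):
                lines.append(f"  {key}: {val:.6g}")
            else:
                lines.append(f"  {key}: {val}")
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.with_suffix(".json").write_text(json.dumps(bundle, indent=1))
        path.with_suffix(".txt").write_text(text)
    return text, bundle


def load_report(path) -> dict:
    """Re-load a bundle written by :func:`run_report`."""
    data = json.loads(Path(path).read_text())
    for stage in data.get("stages", {}).values():
        for key, val in list(stage.items()):
            if isinstance(val, dict) and "__dataframe__" in val:
                stage[key] = pd.DataFrame(val["__dataframe__"])
    return data
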