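"""Table readers/writers, run configuration and the end-to-end pipeline.

File dialects are deliberately rigid: column names are fixed, concentration
units are explicit in the column names (``l0_uM``, ``conc_mM``) and unknown
configuration keys are rejected rather than ignored.  A ``-`` intensity
cell marks an unintegrable proton; the whole proton is skipped with a
warning, mirroring how missing table entries are treated in reports.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nmrbind.std_affinity import AFTitration, fit_langmuir
from nmrbind.std_buildup import BuildupCurve, fit_buildup, relative_std0
from nmrbind.synthetic import (
    DEFAULT_T1_LADDER_UM,
    NoiseModel,
    gen_af_titration,
    gen_t1_titration,
)
from nmrbind.t1sel import (
    InversionRecoveryTrace,
    T1Titration,
    estimate_ic50_t1,
    fit_inversion_recovery,
)

__all__ = [
    "ConfigError",
    "ParseError",
    "read_buildup_table",
    "read_t1_traces",
    "read_t1_table",
    "read_af_table",
    "std0_report",
    "load_config",
    "run_pipeline",
    "validate_report",
]


class ParseError(ValueError):
    """A table failed validation; the message names the offending line."""


class ConfigError(ValueError):
    """A run configuration failed schema validation."""


MISSING_MARK = "-"


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, column: str, path: Path) -> pd.Series:
    def conv(row_val):
        idx, val = row_val
        try:
            return float(val)
        except ValueError:
            raise ParseError(
                f"{path}: line {idx + 2}: non-numeric value {val!r} in "
                f"column {column!r}"
            ) from None

    return pd.Series(
        [conv(item) for item in df[column].items()], index=df.index
    )


def read_buildup_table(path: str | Path) -> list[BuildupCurve]:
    """Read a long-format STD build-up table.

    Columns: ``ligand_id, proton_label, t_sat_s, std_fraction``.  Protons
    with any ``-`` intensity are skipped entirely (logged as a warning).
    Duplicate (ligand, proton, time) rows are an error.
    """
    path = Path(path)
    df = _read_table(path, ["ligand_id", "proton_label", "t_sat_s", "std_fraction"])

    skipped = df.loc[df["std_fraction"] == MISSING_MARK, ["ligand_id", "proton_label"]]
    skip_keys = set(map(tuple, skipped.values))
    for lig, prot in sorted(skip_keys):
        warnings.warn(
            f"{path}: proton {prot} of {lig} has unintegrable ('{MISSING_MARK}') "
            "entries; skipping",
            stacklevel=2,
        )
    df = df[~df.apply(lambda r: (r["ligand_id"], r["proton_label"]) in skip_keys, axis=1)]

    df = df.assign(
        t_sat_s=_numeric(df, "t_sat_s", path),
        std_fraction=_numeric(df, "std_fraction", path),
    )
    dup = df.duplicated(["ligand_id", "proton_label", "t_sat_s"])
    if dup.any():
        first = int(df.index[dup][0]) + 2
        raise ParseError(f"{path}: line {first}: duplicate (proton, time) row")

    curves = []
    for (lig, prot), grp in df.groupby(["ligand_id", "proton_label"], sort=True):
        grp = grp.sort_values("t_sat_s")
        curves.append(
            BuildupCurve(
                proton_label=prot,
                ligand_id=lig,
                saturation_times=grp["t_sat_s"].to_numpy(),
                std_fractions=grp["std_fraction"].to_numpy(),
            )
        )
    return curves


def read_t1_traces(path: str | Path, protein_conc_uM: float) -> list[InversionRecoveryTrace]:
    """Read inversion-recovery traces: ``ligand_id, l0_uM, delay_s, intensity``."""
    path = Path(path)
    df = _read_table(path, ["ligand_id", "l0_uM", "delay_s", "intensity"])
    df = df.assign(
        l0_uM=_numeric(df, "l0_uM", path),
        delay_s=_numeric(df, "delay_s", path),
        intensity=_numeric(df, "intensity", path),
    )
    traces = []
    for (lig, l0), grp in df.groupby(["ligand_id", "l0_uM"], sort=True):
        grp = grp.sort_values("delay_s")
        traces.append(
            InversionRecoveryTrace(
                recovery_delays=grp["delay_s"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                ligand_conc_uM=float(l0),
                protein_conc_uM=protein_conc_uM,
                ligand_id=str(lig),
            )
        )
    return traces


def read_t1_table(path: str | Path, protein_conc_uM: float) -> T1Titration:
    """Read a pre-fitted titration table: ``l0_uM, t1_obs_s``."""
    path = Path(path)
    df = _read_table(path, ["l0_uM", "t1_obs_s"])
    return T1Titration(
        ligand_concs_uM=_numeric(df, "l0_uM", path).to_numpy(),
        t1_obs_s=_numeric(df, "t1_obs_s", path).to_numpy(),
        protein_conc_uM=protein_conc_uM,
    )


def read_af_table(path: str | Path, protein_conc_mM: float) -> AFTitration:
    """Read an STD-AF0 isotherm table: ``conc_mM, af0_per_s``."""
    path = Path(path)
    df = _read_table(path, ["conc_mM", "af0_per_s"])
    return AFTitration(
        ligand_concs=_numeric(df, "conc_mM", path).to_numpy(),
        protein_conc=protein_conc_mM,
        af0_values=_numeric(df, "af0_per_s", path).to_numpy(),
    )


def std0_report(curves: list[BuildupCurve]) -> pd.DataFrame:
    """Per-proton STD0 and relative STD0 table (one row per ligand/proton).

    Absolute STD0 is rounded to 2 decimals and the relative value to the
    nearest integer in the table; unrounded values are carried in
    ``std0_raw``.  Relatives are computed per ligand from the unrounded
    fits, so they need not match ratios of the rounded column.
    """
    rows = []
    for lig in sorted({c.ligand_id for c in curves}):
        fits = [fit_buildup(c) for c in curves if c.ligand_id == lig]
        rel = relative_std0(fits)
        for f, r in zip(fits, rel):
            rows.append(
                {
                    "ligand_id": lig,
                    "proton_label": f.proton_label,
                    "std0_per_s": round(f.std0, 2),
                    "relative_std0": int(round(r)),
                    "std0_raw": f.std0,
                    "std_max": f.std_max,
                    "k_sat_per_s": f.k_sat,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------- run config

_SAMPLE_KEYS = {
    "p0_uM",
    "l0_uM",
    "kd_uM",
    "kon_per_M_s",
    "temperature_K",
    "spectrometer_MHz",
}
_TOP_KEYS = {"estimator", "seed", "sample", "synthetic", "inputs", "output_dir"}
_SYNTH_KEYS = {
    "af0_max",
    "ic50_mM",
    "ic50_uM",
    "ladder_mM",
    "ladder_uM",
    "p0_uM",
    "t1_bound_plus_tau_s",
    "noise_sigma",
    "mode",
}
_INPUT_KEYS = {"af_table", "t1_traces", "t1_table", "protein_uM", "protein_mM"}

#: Default sample conditions of the packaged STD workflow (19 µM protein,
#: 1.6 mM ligand at 600 MHz) and of the T1 workflow ladder (20 µM protein).
DEFAULT_STD_SAMPLE = {
    "p0_uM": 19.0,
    "l0_uM": 1600.0,
    "temperature_K": 298.0,
    "spectrometer_MHz": 600.0,
}


def _reject_unknown(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> dict:
    """Load and validate a JSON/YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    cfg = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    _reject_unknown(cfg, _TOP_KEYS, "config")
    estimator = cfg.get("estimator")
    if estimator not in ("std-af", "t1sel"):
        raise ConfigError("estimator must be 'std-af' or 't1sel'")
    if not isinstance(cfg.get("seed", 0), int):
        raise ConfigError("seed must be an integer")
    for block, keys in (
        ("sample", _SAMPLE_KEYS),
        ("synthetic", _SYNTH_KEYS),
        ("inputs", _INPUT_KEYS),
    ):
        if block in cfg:
            if not isinstance(cfg[block], dict):
                raise ConfigError(f"{block} must be a mapping")
            _reject_unknown(cfg[block], keys, block)
    if ("synthetic" in cfg) == ("inputs" in cfg):
        raise ConfigError("exactly one of 'synthetic' or 'inputs' is required")
    return cfg


REPORT_SCHEMA = {
    "estimator": str,
    "seed": int,
    "ic50": float,
    "ic50_units": str,
    "se": float,
    "n_points": int,
    "stages": list,
}


def validate_report(report: dict) -> None:
    """Check a pipeline report against the packaged schema (keys + types)."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(
                f"report key {key!r} has type {type(report[key]).__name__}, "
                f"expected {typ.__name__}"
            )
    extra = set(report) - set(REPORT_SCHEMA)
    if extra:
        raise ValueError(f"report has unknown key(s): {sorted(extra)}")


def run_pipeline(cfg: dict) -> dict:
    """Execute one IC50 workflow end-to-end and return a JSON-able report.

    Stage failures are re-raised with the stage name prepended so the caller
    can attribute the error.
    """
    cfg = validate_config(cfg)
    estimator = cfg["estimator"]
    seed = cfg.get("seed", 0)
    stages: list[dict] = []

    def run_stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        stages.append({"stage": name, "ok": True})
        return result

    if estimator == "std-af":
        if "synthetic" in cfg:
            syn = cfg["synthetic"]
            noise = NoiseModel(sigma=syn.get("noise_sigma", 0.0), seed=seed)
            titr = run_stage(
                "generate-af-titration",
                lambda: gen_af_titration(
                    af0_max=syn.get("af0_max", 10.0),
                    ic50=syn["ic50_mM"],
                    ladder=syn.get("ladder_mM"),
                    noise=noise,
                ),
            )
        else:
            inp = cfg["inputs"]
            titr = run_stage(
                "read-af-table",
                lambda: read_af_table(inp["af_table"], inp.get("protein_mM", 0.019)),
            )
        fit = run_stage("fit-langmuir", lambda: fit_langmuir(titr, seed=seed))
        ic50, se, units = fit.ic50, fit.ic50_err, "mM"
        n_points = int(titr.ligand_concs.size)
    else:
        if "synthetic" in cfg:
            syn = cfg["synthetic"]
            noise = NoiseModel(sigma=syn.get("noise_sigma", 0.0), seed=seed)
            titr = run_stage(
                "generate-t1-titration",
                lambda: gen_t1_titration(
                    ic50_uM=syn["ic50_uM"],
                    ladder_uM=syn.get("ladder_uM", DEFAULT_T1_LADDER_UM),
                    p0_uM=syn.get("p0_uM", 20.0),
                    t1_bound_plus_tau_s=syn.get("t1_bound_plus_tau_s", 0.1),
                    noise=noise,
                    mode=syn.get("mode", "linear"),
                ),
            )
        else:
            inp = cfg["inputs"]
            p0 = inp.get("protein_uM", 20.0)
            if "t1_traces" in inp:
                traces = run_stage(
                    "read-t1-traces", lambda: read_t1_traces(inp["t1_traces"], p0)
                )
                fits = run_stage(
                    "fit-inversion-recovery",
                    lambda: [fit_inversion_recovery(t) for t in traces],
                )
                titr = T1Titration(
                    ligand_concs_uM=np.array([t.ligand_conc_uM for t in traces]),
                    t1_obs_s=np.array([f.t1_sel for f in fits]),
                    protein_conc_uM=p0,
                )
            else:
                titr = run_stage(
                    "read-t1-table", lambda: read_t1_table(inp["t1_table"], p0)
                )
        ic50, se = run_stage("estimate-ic50", lambda: estimate_ic50_t1(titr))
        units = "uM"
        n_points = int(titr.ligand_concs_uM.size)

    report = {
        "estimator": estimator,
        "seed": seed,
        "ic50": float(ic50),
        "ic50_units": units,
        "se": float(se),
        "n_points": n_points,
        "stages": stages,
    }
    validate_report(report)
    out_dir = cfg.get("output_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
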