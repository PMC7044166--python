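"""Configuration loading and delimited-text I/O binding the pipeline together.

All tabular I/O is comma-separated UTF-8 with a mandatory header row.  The
config file is YAML; omitted fields fall back to the built-in study defaults
(three arms of five subjects, the 10-point sampling schedule, the published
calibration ranges/QC levels) and unknown keys are a hard error.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .nca import ConcentrationTimeProfile, NCAResult
from .simulate import DDIEffect, GroupArm, PKParams, StudyDesign
from .validation import AcceptancePolicy

MG_PER_KG_TO_NG_PER_KG = 1e6

PROFILE_COLUMNS = ["subject_id", "group", "analyte", "time_h", "conc_ng_per_mL", "blq"]


class ConfigError(ValueError):
    pass


class SchemaError(ValueError):
    pass


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "doses_mg_per_kg": {"DSV": 50.0, "TAM": 10.0},
    "sampling_times_h": [0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 5.0, 12.0, 24.0, 48.0],
    "groups": [
        {"label": "I", "analytes": ["DSV"]},
        {"label": "II", "analytes": ["TAM"]},
        {"label": "III", "analytes": ["DSV", "TAM"]},
    ],
    "n_per_group": 5,
    "lloq_ng_per_mL": {"DSV": 20.0, "TAM": 0.1, "TOH": 0.5},
    "llod_ng_per_mL": {"DSV": 10.0, "TAM": 0.04, "TOH": 0.30},
    "calibration_range_ng_per_mL": {
        "DSV": [20.0, 1000.0], "TAM": [0.1, 500.0], "TOH": [0.5, 500.0]},
    "qc_levels_ng_per_mL": {
        "DSV": [20.0, 60.0, 500.0, 800.0],
        "TAM": [0.1, 0.3, 100.0, 400.0],
        "TOH": [0.5, 1.5, 150.0, 400.0]},
    "calibration_truth": {
        "DSV": {"intercept": -0.0386, "slope": 0.0234},
        "TAM": {"intercept": 0.0147, "slope": 0.9565},
        "TOH": {"intercept": -0.0106, "slope": 0.2363}},
    # base kinetics chosen so noise-free profiles land at plausible rat-scale
    # Cmax/tmax/half-lives (see simulate.default_base_params)
    "pk_params": {
        "DSV": {"ka": 0.6, "ke": 0.0385, "V_F": 290000.0},
        "TAM": {"ka": 2.0, "ke": 0.0433, "V_F": 30000.0,
                "fm": 0.3, "kem": 0.5, "Vm_F": 640.0}},
    "noise": {"cv": 0.05, "sd_add": 0.0},
    "iiv_cv": 0.20,
    "ddi_effect": {},
    "acceptance": {
        "limit_lloq": 20.0, "limit_other": 15.0,
        "selectivity_ratio_analyte": 5.0, "selectivity_ratio_is": 20.0,
        "carryover_analyte": 20.0, "carryover_is": 5.0},
    "alpha": 0.05,
    "halflife_constant": 0.693,
    "t_test": "pooled",
    "calibration_weighting": "none",
}

_PKPARAM_KEYS = {"ka", "ke", "V_F", "fm", "kem", "Vm_F"}
_GROUP_KEYS = {"label", "analytes"}
_DDI_KEYS = {"dose_scale", "ke_scale"}


@dataclass(frozen=True)
class StudyConfig:
    """Fully-resolved study configuration (doses already in ng/kg)."""

    raw: Mapping[str, Any]
    seed: int
    doses_ng_per_kg: Mapping[str, float]
    sampling_times: tuple[float, ...]
    groups: tuple[GroupArm, ...]
    n_per_group: int
    lloq: Mapping[str, float]
    llod: Mapping[str, float]
    calibration_range: Mapping[str, tuple[float, float]]
    qc_levels: Mapping[str, tuple[float, ...]]
    calibration_truth: Mapping[str, Mapping[str, float]]
    pk_params: Mapping[str, Mapping[str, float]]
    noise_cv: float
    noise_sd_add: float
    iiv_cv: float
    ddi_effect: Mapping[str, DDIEffect]
    acceptance: AcceptancePolicy
    alpha: float
    halflife_constant: float
    t_test: str
    calibration_weighting: str

    def to_design(self) -> StudyDesign:
        return StudyDesign(
            groups=self.groups, n_per_group=self.n_per_group,
            sampling_times=self.sampling_times, lloq=dict(self.lloq),
            noise_cv=self.noise_cv, noise_sd_add=self.noise_sd_add,
            iiv_cv=self.iiv_cv, seed=self.seed)

    def base_params(self) -> dict[str, PKParams]:
        out = {}
        for analyte, p in self.pk_params.items():
            out[analyte] = PKParams(dose=0.0, **p)
        return out


def _check_keys(section: str, mapping: Mapping, allowed) -> None:
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {section}: {sorted(unknown)}")


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> StudyConfig:
    """Load YAML config, merging over the built-in defaults.

    Unknown keys anywhere in the file are a ConfigError (no silent ignoring).
    Doses are given in mg/kg and converted to ng/kg exactly once, here.
    """
    user: dict[str, Any] = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must hold a mapping")
        user.update(loaded)
    if overrides:
        user.update(overrides)

    _check_keys("config", user, DEFAULT_CONFIG)
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in user.items():
        if isinstance(cfg[key], dict) and isinstance(value, dict) \
                and key not in ("doses_mg_per_kg", "ddi_effect"):
            cfg[key].update(value)
        else:
            cfg[key] = value

    _check_keys("noise", cfg["noise"], {"cv", "sd_add"})
    _check_keys("acceptance", cfg["acceptance"], AcceptancePolicy().__dict__)
    for analyte, p in cfg["pk_params"].items():
        _check_keys(f"pk_params.{analyte}", p, _PKPARAM_KEYS)
    for grp in cfg["groups"]:
        _check_keys("groups[]", grp, _GROUP_KEYS)
    for analyte, eff in cfg["ddi_effect"].items():
        _check_keys(f"ddi_effect.{analyte}", eff, _DDI_KEYS)

    doses_ng = {a: float(d) * MG_PER_KG_TO_NG_PER_KG
                for a, d in cfg["doses_mg_per_kg"].items()}
    for a, d in doses_ng.items():
        if d <= 0:
            raise ConfigError(f"dose for {a} must be > 0")
    groups = []
    for grp in cfg["groups"]:
        missing = [a for a in grp["analytes"] if a not in doses_ng]
        if missing:
            raise ConfigError(f"group {grp['label']}: no dose for {missing}")
        groups.append(GroupArm(grp["label"], {a: doses_ng[a] for a in grp["analytes"]}))

    cal_range = {a: (float(lo), float(hi))
                 for a, (lo, hi) in cfg["calibration_range_ng_per_mL"].items()}
    qc = {a: tuple(float(v) for v in levels)
          for a, levels in cfg["qc_levels_ng_per_mL"].items()}
    for analyte, levels in qc.items():
        lo, hi = cal_range[analyte]
        for lv in levels:
            if not (lo <= lv <= hi):
                raise ConfigError(f"QC level {lv} for {analyte} outside range [{lo}, {hi}]")

    return StudyConfig(
        raw=cfg,
        seed=int(cfg["seed"]),
        doses_ng_per_kg=doses_ng,
        sampling_times=tuple(float(t) for t in cfg["sampling_times_h"]),
        groups=tuple(groups),
        n_per_group=int(cfg["n_per_group"]),
        lloq={a: float(v) for a, v in cfg["lloq_ng_per_mL"].items()},
        llod={a: float(v) for a, v in cfg["llod_ng_per_mL"].items()},
        calibration_range=cal_range,
        qc_levels=qc,
        calibration_truth=cfg["calibration_truth"],
        pk_params=cfg["pk_params"],
        noise_cv=float(cfg["noise"]["cv"]),
        noise_sd_add=float(cfg["noise"]["sd_add"]),
        iiv_cv=float(cfg["iiv_cv"]),
        ddi_effect={a: DDIEffect(**eff) for a, eff in cfg["ddi_effect"].items()},
        acceptance=AcceptancePolicy(**cfg["acceptance"]),
        alpha=float(cfg["alpha"]),
        halflife_constant=float(cfg["halflife_constant"]),
        t_test=str(cfg["t_test"]),
        calibration_weighting=str(cfg["calibration_weighting"]),
    )


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def write_profiles(profiles: Sequence[ConcentrationTimeProfile],
                   path: str | Path) -> None:
    rows = []
    for p in profiles:
        for t, c, b in zip(p.times, p.concs, p.blq):
            rows.append({"subject_id": p.subject_id, "group": p.group,
                         "analyte": p.analyte, "time_h": t,
                         "conc_ng_per_mL": repr(float(c)), "blq": int(b)})
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


def read_profiles(path: str | Path,
                  doses: Mapping[str, float] | None = None
                  ) -> list[ConcentrationTimeProfile]:
    """Parse a concentration-time CSV into validated profiles.

    ``doses`` (analyte -> ng/kg) attaches doses for clearance computation;
    a metabolite (TOH) inherits the TAM dose for bookkeeping.  Malformed
    content is reported with the offending subjects/rows.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    bad = df.index[df["conc_ng_per_mL"].astype(float) < 0].tolist()
    if bad:
        raise SchemaError(f"{path}: negative concentration on data row(s) {bad}")
    if not set(df["blq"].unique()) <= {0, 1}:
        raise SchemaError(f"{path}: blq must be 0/1")
    doses = doses or {}
    profiles = []
    for (sid, group, analyte), grp in df.groupby(
            ["subject_id", "group", "analyte"], sort=True):
        t = grp["time_h"].astype(float).to_numpy()
        order_bad = np.any(np.diff(t) <= 0)
        if order_bad:
            raise SchemaError(
                f"{path}: non-monotone times for subject {sid} analyte {analyte}")
        dose = doses.get(analyte)
        if analyte == "TOH" and dose is None:
            dose = doses.get("TAM")
        try:
            profiles.append(ConcentrationTimeProfile(
                subject_id=str(sid), group=str(group), analyte=str(analyte),
                times=t, concs=grp["conc_ng_per_mL"].astype(float).to_numpy(),
                blq=grp["blq"].astype(int).to_numpy().astype(bool), dose=dose))
        except ValueError as exc:
            raise SchemaError(f"{path}: subject {sid} analyte {analyte}: {exc}") from exc
    return profiles


# ---------------------------------------------------------------------------
# Results / report
# ---------------------------------------------------------------------------

def nca_results_to_frame(results: Sequence[NCAResult]) -> pd.DataFrame:
    cols = ["subject_id", "group", "analyte", "cmax", "tmax", "kel", "t_half",
            "auc_0_t", "auc_0_inf", "cl_f", "extrap_pct", "extrap_warning",
            "n_terminal", "r2_terminal"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results],
                        columns=cols)


def write_report(out_dir: str | Path, config: StudyConfig,
                 tables: Mapping[str, pd.DataFrame],
                 texts: Mapping[str, str] | None = None) -> list[Path]:
    """Write result tables (2-decimal rounding), free-text blocks and a
    reproducibility header (seed, version, full resolved config)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    info = {"package": "quantpk", "version": __version__,
            "seed": config.seed, "config": _jsonable(config.raw)}
    p = out / "run_info.json"
    p.write_text(json.dumps(info, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    written.append(p)
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.round(2).to_csv(p, index=False)
        written.append(p)
    for name, text in (texts or {}).items():
        p = out / f"{name}.txt"
        p.write_text(text + "\n", encoding="utf-8")
        written.append(p)
    return written


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
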