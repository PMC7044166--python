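"""Synthetic study generator.

One-compartment first-order-absorption kinetics for orally dosed parents,
with first-order formation/elimination of a single metabolite, log-normal
between-subject variability, proportional + additive assay noise, and BLQ
censoring.  The generator exists so the quantitation/validation/NCA pipeline
is fully testable against known truth; it is not a mechanistic model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nca import ConcentrationTimeProfile

#: Relative tolerance below which two rate constants are treated as equal and
#: the analytic confluent limit is used instead of the generic formula.
RATE_TOL = 1e-6

PAPER_SCHEDULE = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 5.0, 12.0, 24.0, 48.0)


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= RATE_TOL * max(abs(a), abs(b))


@dataclass(frozen=True)
class PKParams:
    """Kinetic parameters for one parent analyte (and optionally its metabolite).

    Rates in 1/h, volumes in mL/kg, dose in ng/kg.  ``fm`` is the fraction of
    eliminated parent converted to the metabolite; ``kem``/``Vm_F`` describe
    the metabolite.  Equal-rate pairs are legal: the confluent analytic limits
    are used automatically.
    """

    ka: float
    ke: float
    V_F: float
    dose: float
    fm: float = 0.0
    kem: float = 1.0
    Vm_F: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ka", "ke", "V_F", "kem", "Vm_F"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if not 0.0 <= self.fm <= 1.0:
            raise ValueError("fm must be in [0, 1]")


@dataclass(frozen=True)
class GroupArm:
    """One treatment arm: label plus administered parent doses (ng/kg)."""

    label: str
    doses: Mapping[str, float]

    @property
    def is_combo(self) -> bool:
        return len(self.doses) > 1


@dataclass(frozen=True)
class StudyDesign:
    groups: tuple[GroupArm, ...]
    n_per_group: int = 5
    sampling_times: tuple[float, ...] = PAPER_SCHEDULE
    lloq: Mapping[str, float] = None  # type: ignore[assignment]
    noise_cv: float = 0.05
    noise_sd_add: float = 0.0
    iiv_cv: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.sampling_times, dtype=float)
        if times[0] != 0 or np.any(np.diff(times) <= 0):
            raise ValueError("sampling_times must start at 0 and be strictly increasing")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.noise_cv < 0 or self.noise_sd_add < 0 or self.iiv_cv < 0:
            raise ValueError("CVs/SDs must be >= 0")
        if self.lloq is None:
            object.__setattr__(self, "lloq", {})


@dataclass(frozen=True)
class DDIEffect:
    """Multiplicative interaction applied to a victim analyte in combo arms."""

    dose_scale: float = 1.0  # bioavailability-equivalent exposure scaling
    ke_scale: float = 1.0


@dataclass
class SimulatedDataset:
    profiles: list[ConcentrationTimeProfile]
    true_params: dict[tuple[str, str], PKParams]
    true_curves: dict[tuple[str, str], np.ndarray]
    design: StudyDesign


# ---------------------------------------------------------------------------
# Kinetic solutions
# ---------------------------------------------------------------------------

def simulate_parent(params: PKParams, times) -> np.ndarray:
    """Noise-free parent concentration (ng/mL) at the given times (h).

    C(t) = dose*ka / (V_F*(ka-ke)) * (exp(-ke t) - exp(-ka t)); the confluent
    ka == ke limit C(t) = dose*k*t/V_F * exp(-k t) is used when the rates are
    within RATE_TOL.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    ka, ke, V, D = params.ka, params.ke, params.V_F, params.dose
    if _close(ka, ke):
        # limit of the generic expression as ka -> ke (L'Hopital)
        k = 0.5 * (ka + ke)
        out = D * k * t * np.exp(-k * t) / V
    else:
        out = D * ka / (V * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
    # guard against ~1e-16-scale negatives from exponential cancellation
    return np.maximum(out, 0.0)


def simulate_metabolite(params: PKParams, times) -> np.ndarray:
    """Noise-free metabolite concentration for the ka -> ke(-> fm) -> kem cascade.

    Standard sum-of-three-exponentials solution; every confluent rate pair
    falls back to its analytic limit.  AUC_0-inf equals fm*dose/(Vm_F*kem).
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if params.fm == 0.0:
        return np.zeros_like(t)
    ka, ke, km = params.ka, params.ke, params.kem
    pref = params.fm * params.dose / params.Vm_F
    c_ab, c_am, c_bm = _close(ka, ke), _close(ka, km), _close(ke, km)
    if sum((c_ab, c_am, c_bm)) >= 2:
        # all three rates effectively equal
        k = (ka + ke + km) / 3.0
        out = pref * k * k * t * t / 2.0 * np.exp(-k * t)
    elif c_ab:  # ka == ke != kem
        k = 0.5 * (ka + ke)
        a = k - km
        out = pref * k * k * np.exp(-km * t) * (1.0 - (1.0 + a * t) * np.exp(-a * t)) / (a * a)
    elif c_bm:  # ke == kem != ka
        k = 0.5 * (ke + km)
        out = pref * k * ka / (k - ka) * (
            (np.exp(-ka * t) - np.exp(-k * t)) / (k - ka) - t * np.exp(-k * t)
        )
    elif c_am:  # ka == kem != ke
        k = 0.5 * (ka + km)
        out = pref * ke * k / (ke - k) * (
            t * np.exp(-k * t) - (np.exp(-ke * t) - np.exp(-k * t)) / (k - ke)
        )
    else:
        out = pref * ke * ka * (
            np.exp(-ka * t) / ((ke - ka) * (km - ka))
            + np.exp(-ke * t) / ((ka - ke) * (km - ke))
            + np.exp(-km * t) / ((ka - km) * (ke - km))
        )
    # guard against ~1e-16-scale negatives from exponential cancellation
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# Measurement model
# ---------------------------------------------------------------------------

def add_assay_noise(
    true_conc,
    noise_cv: float,
    noise_sd_add: float,
    lloq: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Proportional+additive noise and BLQ flagging.

    measured = true*(1 + N(0, cv)) + N(0, sd), truncated at 0.  Returns the
    uncensored measured values together with the BLQ mask (measured < lloq);
    censoring (what gets reported) is the caller's decision.
    """
    c = np.asarray(true_conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("true concentrations must be >= 0")
    if noise_cv < 0 or noise_sd_add < 0:
        raise ValueError("noise_cv and noise_sd_add must be >= 0")
    eps_p = rng.standard_normal(c.shape)
    eps_a = rng.standard_normal(c.shape)
    measured = np.maximum(c * (1.0 + noise_cv * eps_p) + noise_sd_add * eps_a, 0.0)
    blq = measured < lloq
    return measured, blq


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------

def _draw_subject_params(base: PKParams, dose: float, iiv_cv: float,
                         rng: np.random.Generator) -> PKParams:
    # log-normal, median-preserving, on ka/ke/V_F only
    sigma = np.sqrt(np.log1p(iiv_cv * iiv_cv))
    m = rng.lognormal(mean=0.0, sigma=sigma, size=3)
    return replace(base, ka=base.ka * m[0], ke=base.ke * m[1],
                   V_F=base.V_F * m[2], dose=dose)


def simulate_study(
    design: StudyDesign,
    base_params: Mapping[str, PKParams],
    ddi_effect: Mapping[str, DDIEffect] | None = None,
) -> SimulatedDataset:
    """Simulate all arms of the study; fully reproducible from design.seed.

    ``ddi_effect`` is applied to the listed victim analytes only in combo
    arms (those administering more than one parent); the no-interaction case
    corresponds to omitting it (all factors 1).  A parent with ``fm > 0``
    additionally yields a TOH metabolite profile.
    """
    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.sampling_times, dtype=float)
    profiles: list[ConcentrationTimeProfile] = []
    true_params: dict[tuple[str, str], PKParams] = {}
    true_curves: dict[tuple[str, str], np.ndarray] = {}
    ddi_effect = dict(ddi_effect or {})

    for arm in design.groups:
        for analyte in arm.doses:
            if analyte not in base_params:
                raise ValueError(f"unknown analyte label {analyte!r} in arm {arm.label!r}")
        for i in range(design.n_per_group):
            sid = f"{arm.label}-{i + 1}"
            for analyte in sorted(arm.doses):
                p = _draw_subject_params(base_params[analyte], arm.doses[analyte],
                                         design.iiv_cv, rng)
                if arm.is_combo and analyte in ddi_effect:
                    eff = ddi_effect[analyte]
                    p = replace(p, dose=p.dose * eff.dose_scale, ke=p.ke * eff.ke_scale)
                true_params[(sid, analyte)] = p
                _emit(profiles, true_curves, sid, arm.label, analyte,
                      simulate_parent(p, times), p.dose, times, design, rng)
                if p.fm > 0:
                    _emit(profiles, true_curves, sid, arm.label, "TOH",
                          simulate_metabolite(p, times), p.dose, times, design, rng)
    return SimulatedDataset(profiles, true_params, true_curves, design)


def _emit(profiles, true_curves, sid, group, analyte, ctrue, dose, times, design, rng):
    lloq = float(design.lloq.get(analyte, 0.0))
    measured, blq = add_assay_noise(ctrue, design.noise_cv, design.noise_sd_add, lloq, rng)
    reported = np.where(blq, 0.0, measured)
    profiles.append(ConcentrationTimeProfile(
        subject_id=sid, group=group, analyte=analyte,
        times=times, concs=reported, blq=blq, dose=dose,
    ))
    true_curves[(sid, analyte)] = ctrue


# ---------------------------------------------------------------------------
# Calibration / QC batch simulation
# ---------------------------------------------------------------------------

DEFAULT_STAGE_FACTORS = {"neat": 1.0, "post": 1.0, "pre": 1.0}


def simulate_calibration_batch(
    slope: float,
    intercept: float,
    levels: Sequence[float],
    replicates: int,
    noise_cv: float,
    rng: np.random.Generator,
    analyte: str = "",
    stage_factors: Mapping[str, float] | None = None,
    is_response: float = 1.0,
    blank_response: float = 0.0,
    n_blanks: int = 0,
) -> pd.DataFrame:
    """Spiked-response table across spiking stages.

    response = (intercept + slope*conc) * stage_factor * (1 + N(0, cv)).
    Stage factors default to 1 everywhere; setting e.g. pre=0.95, post=1.0
    yields a 95% extraction recovery, post != neat a matrix effect.  Blank
    rows (stage 'blank') carry ``blank_response`` unperturbed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    factors = dict(DEFAULT_STAGE_FACTORS)
    factors.update(stage_factors or {})
    rows = []
    for level in levels:
        if level < 0:
            raise ValueError("levels must be >= 0")
        truth = intercept + slope * level
        for stage in ("pre", "post", "neat"):
            for rep in range(1, replicates + 1):
                resp = truth * factors[stage] * (1.0 + noise_cv * rng.standard_normal())
                rows.append({
                    "analyte": analyte, "level_ng_per_mL": float(level),
                    "replicate": rep, "stage": stage,
                    "response": resp, "is_response": is_response,
                })
    for rep in range(1, n_blanks + 1):
        rows.append({
            "analyte": analyte, "level_ng_per_mL": 0.0, "replicate": rep,
            "stage": "blank", "response": blank_response, "is_response": is_response,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tuned defaults (see io_config for the config-file view of these numbers)
# ---------------------------------------------------------------------------

def default_base_params() -> dict[str, PKParams]:
    """Base kinetics tuned to give plausible rat-scale profiles.

    TAM: Cmax near 300 ng/mL around t = 2 h, t1/2 about 16 h; DSV: Cmax near
    145 ng/mL around t = 5 h, t1/2 about 18 h.  TOH is formation-limited
    (kem > ke, so its terminal slope tracks the parent) with a
    metabolite/parent AUC ratio near 1.2 and an observed peak around 4-5 h;
    an elimination-limited metabolite would peak after 24 h and leave no
    usable terminal phase on the 10-point schedule.  Doses are filled in at
    simulation time.
    """
    return {
        "DSV": PKParams(ka=0.6, ke=0.0385, V_F=290_000.0, dose=0.0),
        "TAM": PKParams(ka=2.0, ke=0.0433, V_F=30_000.0, dose=0.0,
                        fm=0.3, kem=0.5, Vm_F=640.0),
    }


def default_design(seed: int = 0, **overrides) -> StudyDesign:
    """Three-arm design: DSV 50 mg/kg, TAM 10 mg/kg, and their combination."""
    kwargs = dict(
        groups=(
            GroupArm("I", {"DSV": 50e6}),
            GroupArm("II", {"TAM": 10e6}),
            GroupArm("III", {"DSV": 50e6, "TAM": 10e6}),
        ),
        n_per_group=5,
        sampling_times=PAPER_SCHEDULE,
        lloq={"DSV": 20.0, "TAM": 0.1, "TOH": 0.5},
        noise_cv=0.05,
        noise_sd_add=0.0,
        iiv_cv=0.20,
        seed=seed,
    )
    kwargs.update(overrides)
    return StudyDesign(**kwargs)
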