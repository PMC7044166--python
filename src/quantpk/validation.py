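"""Bioanalytical method-validation statistics and acceptance rules.

Covers accuracy/precision (recovery %, Er %, RSD %), extraction recovery,
matrix effect, selectivity and carryover signal checks, stability and
dilution integrity, plus a battery runner that evaluates a whole dataset
against the acceptance policy (20% at LLOQ, 15% elsewhere, signal-ratio
thresholds for selectivity/carryover).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METRICS = (
    "selectivity", "recovery", "matrix_effect", "precision_intraday",
    "precision_interday", "accuracy", "dilution_integrity", "stability",
    "carryover",
)


@dataclass(frozen=True)
class AcceptancePolicy:
    """Acceptance limits; defaults follow common regulatory practice."""

    limit_lloq: float = 20.0          # % Er/RSD limit at the LLOQ level
    limit_other: float = 15.0         # % Er/RSD limit at higher levels
    selectivity_ratio_analyte: float = 5.0   # LLOQ signal >= 5x blank
    selectivity_ratio_is: float = 20.0       # IS signal >= 20x blank
    carryover_analyte: float = 20.0   # blank peak < 20% of LLOQ response
    carryover_is: float = 5.0         # blank IS peak < 5% of IS response

    def __post_init__(self) -> None:
        for name in ("limit_lloq", "limit_other", "selectivity_ratio_analyte",
                     "selectivity_ratio_is", "carryover_analyte", "carryover_is"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def er_limit(self, is_lloq: bool) -> float:
        return self.limit_lloq if is_lloq else self.limit_other


@dataclass(frozen=True)
class ValidationRecord:
    """One evaluated validation metric.  ``passed`` is None when not evaluable."""

    metric: str
    analyte: str
    level: float | str | None
    value: float | None
    dispersion: float | None
    limit: float | None
    passed: bool | None
    note: str = ""


class AccuracyPrecision(NamedTuple):
    recovery_pct: float
    rsd_pct: float | None
    er_pct: float


def accuracy_precision(found, nominal: float) -> AccuracyPrecision:
    """Recovery % = 100*mean/nominal; Er % = 100*(mean-nominal)/nominal;
    RSD % = 100*sd/mean with sample (n-1) SD.  RSD is None when mean == 0."""
    f = np.asarray(found, dtype=float)
    if len(f) < 2:
        raise ValueError("need >= 2 replicates")
    if nominal <= 0:
        raise ValueError("nominal must be > 0")
    m = float(f.mean())
    recovery = 100.0 * m / nominal
    er = 100.0 * (m - nominal) / nominal
    rsd = 100.0 * float(f.std(ddof=1)) / m if m != 0 else None
    return AccuracyPrecision(recovery, rsd, er)


def _ratio_pct(num, den, mode: str) -> float:
    a = np.asarray(num, dtype=float)
    b = np.asarray(den, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("need >= 1 response in each set")
    if mode == "ratio_of_means":
        if b.mean() == 0:
            raise ValueError("reference responses have zero mean")
        return float(100.0 * a.mean() / b.mean())
    if mode == "mean_of_ratios":
        if a.shape != b.shape:
            raise ValueError("mean_of_ratios needs paired sets of equal length")
        if np.any(b == 0):
            raise ValueError("zero reference response")
        return float(100.0 * (a / b).mean())
    raise ValueError(f"unknown mode {mode!r}")


def extraction_recovery(pre_extraction_responses, post_extraction_responses,
                        mode: str = "ratio_of_means") -> float:
    """100 * mean(pre-extraction spiked) / mean(post-extraction spiked)."""
    return _ratio_pct(pre_extraction_responses, post_extraction_responses, mode)


def matrix_effect(post_extraction_responses, neat_solution_responses,
                  mode: str = "ratio_of_means") -> float:
    """100 * mean(post-extraction spiked) / mean(neat solvent solution)."""
    return _ratio_pct(post_extraction_responses, neat_solution_responses, mode)


def selectivity_check(
    blank_signal: float,
    lloq_signal: float,
    is_signal: float,
    is_blank_signal: float,
    policy: AcceptancePolicy = AcceptancePolicy(),
    analyte: str = "",
) -> ValidationRecord:
    """Pass iff LLOQ signal >= 5x blank and IS signal >= 20x its blank (inclusive)."""
    for name, v in (("blank_signal", blank_signal), ("lloq_signal", lloq_signal),
                    ("is_signal", is_signal), ("is_blank_signal", is_blank_signal)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    ok_analyte = lloq_signal >= policy.selectivity_ratio_analyte * blank_signal
    ok_is = is_signal >= policy.selectivity_ratio_is * is_blank_signal
    ratio = np.inf if blank_signal == 0 else lloq_signal / blank_signal
    return ValidationRecord(
        metric="selectivity", analyte=analyte, level="LLOQ",
        value=float(ratio) if np.isfinite(ratio) else None,
        dispersion=None, limit=policy.selectivity_ratio_analyte,
        passed=bool(ok_analyte and ok_is),
    )


def carryover_check(
    blank_after_high_analyte: float,
    blank_after_high_is: float,
    lloq_response: float,
    is_response: float,
    policy: AcceptancePolicy = AcceptancePolicy(),
    analyte: str = "",
) -> ValidationRecord:
    """Pass iff blank-after-high analyte peak < 20% of the LLOQ response and
    the IS peak < 5% of the working IS response (both strict)."""
    if min(blank_after_high_analyte, blank_after_high_is, lloq_response, is_response) < 0:
        raise ValueError("signals must be >= 0")
    if lloq_response <= 0 or is_response <= 0:
        raise ValueError("reference responses must be > 0")
    pct_analyte = 100.0 * blank_after_high_analyte / lloq_response
    pct_is = 100.0 * blank_after_high_is / is_response
    ok = pct_analyte < policy.carryover_analyte and pct_is < policy.carryover_is
    return ValidationRecord(
        metric="carryover", analyte=analyte, level=None,
        value=pct_analyte, dispersion=pct_is,
        limit=policy.carryover_analyte, passed=bool(ok),
    )


def stability_recovery(
    stored_found,
    fresh_nominal: float,
    condition: str,
    policy: AcceptancePolicy = AcceptancePolicy(),
    analyte: str = "",
) -> ValidationRecord:
    """Storage-condition recovery; pass iff within 100 +/- limit_other."""
    ap = accuracy_precision(stored_found, fresh_nominal)
    ok = abs(ap.recovery_pct - 100.0) <= policy.limit_other
    return ValidationRecord(
        metric="stability", analyte=analyte, level=condition,
        value=ap.recovery_pct, dispersion=ap.rsd_pct,
        limit=policy.limit_other, passed=bool(ok), note=condition,
    )


def dilution_integrity(
    found_after_dilution_correction,
    nominal: float,
    policy: AcceptancePolicy = AcceptancePolicy(),
    analyte: str = "",
    dilution_label: str = "",
) -> ValidationRecord:
    """Accuracy of dilution-corrected results; pass iff |Er%| <= limit_other."""
    ap = accuracy_precision(found_after_dilution_correction, nominal)
    ok = abs(ap.er_pct) <= policy.limit_other
    return ValidationRecord(
        metric="dilution_integrity", analyte=analyte, level=nominal,
        value=ap.recovery_pct, dispersion=ap.rsd_pct,
        limit=policy.limit_other, passed=bool(ok), note=dilution_label,
    )


# ---------------------------------------------------------------------------
# Battery
# ---------------------------------------------------------------------------

@dataclass
class ValidationDataset:
    """Inputs for the full battery; any table may be None (-> not evaluable).

    recovery_responses: columns analyte, level_ng_per_mL, stage{pre,post,neat}, response
    qc_found: columns analyte, level, day, replicate, found
    dilution: columns analyte, nominal, factor, replicate, found_corrected
    stability: columns analyte, condition, nominal, replicate, found
    signals: analyte -> dict(blank, lloq_signal, is_signal, is_blank)
    carryover_signals: analyte -> dict(blank_after_high, blank_after_high_is,
                                       lloq_response, is_response)
    lloq: analyte -> LLOQ level (to pick the 20% vs 15% limit)
    """

    recovery_responses: pd.DataFrame | None = None
    qc_found: pd.DataFrame | None = None
    dilution: pd.DataFrame | None = None
    stability: pd.DataFrame | None = None
    signals: Mapping[str, Mapping[str, float]] | None = None
    carryover_signals: Mapping[str, Mapping[str, float]] | None = None
    lloq: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class BatterySummary:
    records: tuple[ValidationRecord, ...]
    passed: bool          # conjunction over evaluable records
    n_not_evaluable: int


def _not_evaluable(metric: str, note: str) -> ValidationRecord:
    return ValidationRecord(metric=metric, analyte="*", level=None, value=None,
                            dispersion=None, limit=None, passed=None, note=note)


def run_validation_battery(
    data: ValidationDataset,
    policy: AcceptancePolicy = AcceptancePolicy(),
) -> BatterySummary:
    """Evaluate every available metric per analyte x level.

    Missing inputs yield a 'not evaluable' record; the battery always
    completes.  The summary verdict is the conjunction of evaluable records.
    """
    records: list[ValidationRecord] = []

    if data.recovery_responses is not None:
        df = data.recovery_responses
        for (analyte, level), grp in df.groupby(["analyte", "level_ng_per_mL"], sort=True):
            pre = grp.loc[grp.stage == "pre", "response"].to_numpy()
            post = grp.loc[grp.stage == "post", "response"].to_numpy()
            neat = grp.loc[grp.stage == "neat", "response"].to_numpy()
            is_lloq = level == data.lloq.get(analyte)
            limit = policy.er_limit(is_lloq)
            if len(pre) and len(post):
                rec = extraction_recovery(pre, post)
                records.append(ValidationRecord(
                    "recovery", analyte, level, rec, None, limit,
                    bool(abs(rec - 100.0) <= limit)))
            if len(post) and len(neat):
                me = matrix_effect(post, neat)
                records.append(ValidationRecord(
                    "matrix_effect", analyte, level, me, None, limit,
                    bool(abs(me - 100.0) <= limit)))
        if not len(df):
            records.append(_not_evaluable("recovery", "empty recovery table"))
    else:
        records.append(_not_evaluable("recovery", "no stage-tagged responses"))
        records.append(_not_evaluable("matrix_effect", "no stage-tagged responses"))

    if data.qc_found is not None:
        df = data.qc_found
        first_day = df["day"].min()
        for (analyte, level), grp in df.groupby(["analyte", "level"], sort=True):
            is_lloq = level == data.lloq.get(analyte)
            limit = policy.er_limit(is_lloq)
            intra = grp.loc[grp.day == first_day, "found"].to_numpy()
            inter = grp["found"].to_numpy()
            for metric, found in (("precision_intraday", intra), ("precision_interday", inter)):
                if len(found) < 2:
                    continue
                ap = accuracy_precision(found, level)
                ok = abs(ap.er_pct) <= limit and (ap.rsd_pct is None or ap.rsd_pct <= limit)
                records.append(ValidationRecord(
                    metric, analyte, level, ap.recovery_pct, ap.rsd_pct, limit, bool(ok)))
    else:
        records.append(_not_evaluable("precision_intraday", "no QC found-concentration table"))
        records.append(_not_evaluable("precision_interday", "no QC found-concentration table"))

    if data.dilution is not None:
        for (analyte, nominal, factor), grp in data.dilution.groupby(
                ["analyte", "nominal", "factor"], sort=True):
            records.append(dilution_integrity(
                grp["found_corrected"].to_numpy(), nominal, policy,
                analyte=analyte, dilution_label=f"1:{int(factor)}"))
    else:
        records.append(_not_evaluable("dilution_integrity", "no dilution table"))

    if data.stability is not None:
        for (analyte, condition, nominal), grp in data.stability.groupby(
                ["analyte", "condition", "nominal"], sort=True):
            records.append(stability_recovery(
                grp["found"].to_numpy(), nominal, condition, policy, analyte=analyte))
    else:
        records.append(_not_evaluable("stability", "no stability table"))

    if data.signals is not None:
        for analyte, sig in sorted(data.signals.items()):
            records.append(selectivity_check(
                sig["blank"], sig["lloq_signal"], sig["is_signal"],
                sig["is_blank"], policy, analyte=analyte))
    else:
        records.append(_not_evaluable("selectivity", "no selectivity signals"))

    if data.carryover_signals is not None:
        for analyte, sig in sorted(data.carryover_signals.items()):
            records.append(carryover_check(
                sig["blank_after_high"], sig["blank_after_high_is"],
                sig["lloq_response"], sig["is_response"], policy, analyte=analyte))
    else:
        records.append(_not_evaluable("carryover", "no carryover signals"))

    evaluable = [r for r in records if r.passed is not None]
    passed = all(r.passed for r in evaluable) if evaluable else False
    n_na = sum(1 for r in records if r.passed is None)
    logger.debug("validation battery: %d records, %d not evaluable, passed=%s",
                 len(records), n_na, passed)
    return BatterySummary(tuple(records), passed, n_na)


def records_to_frame(records: Sequence[ValidationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
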