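"""Non-compartmental analysis of concentration-time profiles and group statistics.

Implements the model-free PK quantities (Cmax/tmax by inspection, terminal
elimination rate from a log-linear fit, half-life, linear-trapezoidal AUC with
extrapolation to infinity, apparent oral clearance) plus the interaction
statistics used to compare co-administration against single administration:
relative bioavailability, metabolite/parent exposure ratio, and two-sample
t-tests on per-subject parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Constant used for the half-life formula t_1/2 = HALF_LIFE_CONSTANT / kel.
#: Deliberately 0.693 (not ln 2); pass ``constant=math.log(2)`` to override.
HALF_LIFE_CONSTANT = 0.693

PARENT_ANALYTES = ("DSV", "TAM")
METABOLITE_ANALYTES = ("TOH",)
ANALYTES = PARENT_ANALYTES + METABOLITE_ANALYTES


class NCAError(ValueError):
    """Raised when a profile cannot be analysed (all-BLQ, rising tail, ...)."""


@dataclass(frozen=True, eq=False)
class ConcentrationTimeProfile:
    """One subject x analyte concentration-time series.

    ``concs`` holds the reported (censored) concentrations: BLQ entries are
    stored as the censored value (conventionally 0) and flagged in ``blq``.
    ``dose`` is in ng/kg; for a metabolite it carries the parent dose for
    bookkeeping only.
    """

    subject_id: str
    group: str
    analyte: str
    times: np.ndarray
    concs: np.ndarray
    blq: np.ndarray
    dose: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "concs", np.asarray(self.concs, dtype=float))
        object.__setattr__(self, "blq", np.asarray(self.blq, dtype=bool))
        if not (len(self.times) == len(self.concs) == len(self.blq)):
            raise ValueError("times, concs and blq must have equal length")
        if len(self.times) == 0:
            raise ValueError("empty profile")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"times must be strictly increasing ({self.subject_id}/{self.analyte})")
        if self.times[0] != 0:
            raise ValueError(f"first sampling time must be 0 ({self.subject_id}/{self.analyte})")
        if np.any(self.concs[~self.blq] < 0):
            raise ValueError(f"negative non-BLQ concentration ({self.subject_id}/{self.analyte})")

    @property
    def n_quantifiable(self) -> int:
        return int((~self.blq).sum())


@dataclass(frozen=True)
class TerminalFit:
    """Terminal log-linear regression result; ``kel`` is -slope (1/h)."""

    kel: float
    n_points: int
    r_squared: float
    adj_r_squared: float
    t_start: float
    includes_cmax: bool = False


@dataclass(frozen=True)
class NCAResult:
    subject_id: str
    group: str
    analyte: str
    cmax: float
    tmax: float
    kel: float
    t_half: float
    auc_0_t: float
    auc_0_inf: float
    cl_f: float | None
    extrap_pct: float
    extrap_warning: bool
    n_terminal: int
    r2_terminal: float


@dataclass(frozen=True)
class GroupComparison:
    """Two-group summary for one PK parameter (a = reference, b = test)."""

    parameter: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_stat: float
    p_value: float
    significant: bool
    alpha: float = 0.05
    rb_pct: float | None = None
    mr_pct: float | None = None


# ---------------------------------------------------------------------------
# BLQ handling
# ---------------------------------------------------------------------------

def _prepare(profile: ConcentrationTimeProfile) -> tuple[np.ndarray, np.ndarray, int]:
    """Return (times, concs, tmax_index) after applying the BLQ policy.

    BLQ samples before tmax are substituted with 0; BLQ samples at or after
    tmax are dropped.  tmax is the time of the maximum quantifiable
    concentration (earliest on ties).
    """
    if profile.n_quantifiable == 0:
        raise NCAError(f"all samples BLQ ({profile.subject_id}/{profile.analyte})")
    obs_t = profile.times[~profile.blq]
    obs_c = profile.concs[~profile.blq]
    tmax = obs_t[int(np.argmax(obs_c))]  # argmax takes the first maximum
    keep = (~profile.blq) | (profile.times < tmax)
    t = profile.times[keep]
    c = np.where(profile.blq[keep], 0.0, profile.concs[keep])
    imax = int(np.searchsorted(t, tmax))
    return t, c, imax


# ---------------------------------------------------------------------------
# Per-profile quantities
# ---------------------------------------------------------------------------

def cmax_tmax(profile: ConcentrationTimeProfile) -> tuple[float, float]:
    """Maximum observed quantifiable concentration and its time (earliest tie)."""
    if profile.n_quantifiable == 0:
        raise NCAError(f"all samples BLQ ({profile.subject_id}/{profile.analyte})")
    obs_t = profile.times[~profile.blq]
    obs_c = profile.concs[~profile.blq]
    i = int(np.argmax(obs_c))
    return float(obs_c[i]), float(obs_t[i])


def _loglinear(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    """OLS of ln(c) on t -> (slope, r2, adj_r2)."""
    y = np.log(c)
    n = len(t)
    tbar = t.mean()
    ybar = y.mean()
    sxx = float(((t - tbar) ** 2).sum())
    sxy = float(((t - tbar) * (y - ybar)).sum())
    syy = float(((y - ybar) ** 2).sum())
    slope = sxy / sxx
    if syy <= 0:
        r2 = 1.0 if abs(slope) < 1e-300 else 0.0
    else:
        r2 = min(1.0, (sxy * sxy) / (sxx * syy))
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return slope, r2, adj


def terminal_kel(
    profile: ConcentrationTimeProfile,
    min_points: int = 3,
    window: tuple[float, float] | None = None,
) -> TerminalFit:
    """Terminal elimination rate constant from the log-linear tail.

    Default selection: among all candidate windows of >= ``min_points`` usable
    points ending at the last quantifiable sample and starting strictly after
    tmax (the Cmax sample excluded), pick the best adjusted R-squared; a
    shorter window must beat a longer one by more than 1e-4 to be preferred.
    If fewer than ``min_points`` samples exist strictly after tmax the Cmax
    sample itself is admitted (a profile already in monotone decline).
    An explicit ``window=(t_lo, t_hi)`` overrides the search.
    """
    t, c, imax = _prepare(profile)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1]) & (c > 0)
        if sel.sum() < min_points:
            raise NCAError(f"terminal window holds {int(sel.sum())} points, need {min_points}")
        slope, r2, adj = _loglinear(t[sel], c[sel])
        if slope >= 0:
            raise NCAError(f"non-negative terminal slope in fixed window ({profile.subject_id}/{profile.analyte})")
        return TerminalFit(-slope, int(sel.sum()), r2, adj, float(t[sel][0]), bool(t[sel][0] <= t[imax]))

    usable = np.flatnonzero((np.arange(len(t)) > imax) & (c > 0))
    includes_cmax = False
    if len(usable) < min_points:
        usable = np.flatnonzero((np.arange(len(t)) >= imax) & (c > 0))
        includes_cmax = True
    if len(usable) < min_points:
        raise NCAError(
            f"fewer than {min_points} usable points after tmax ({profile.subject_id}/{profile.analyte})"
        )
    best: TerminalFit | None = None
    # longest window first; a later (shorter) candidate must win by > 1e-4
    for k in range(len(usable) - min_points + 1):
        idx = usable[k:]
        slope, r2, adj = _loglinear(t[idx], c[idx])
        if slope >= 0:
            continue
        if best is None or adj > best.adj_r_squared + 1e-4:
            best = TerminalFit(-slope, len(idx), r2, adj, float(t[idx[0]]),
                               includes_cmax and idx[0] == imax)
    if best is None:
        raise NCAError(
            f"no terminal window with negative slope ({profile.subject_id}/{profile.analyte})"
        )
    logger.debug("terminal_kel %s/%s: kel=%.6g n=%d r2=%.6f", profile.subject_id,
                 profile.analyte, best.kel, best.n_points, best.r_squared)
    return best


def half_life(kel: float, constant: float = HALF_LIFE_CONSTANT) -> float:
    """t_1/2 = 0.693 / kel (the conventional rounded constant)."""
    if kel <= 0:
        raise NCAError(f"kel must be positive, got {kel}")
    return constant / kel


def auc_trapezoid(profile: ConcentrationTimeProfile) -> float:
    """Linear-trapezoidal AUC from 0 to the last quantifiable time."""
    t, c, _ = _prepare(profile)
    if len(t) < 2:
        raise NCAError(f"need >= 2 usable points for AUC ({profile.subject_id}/{profile.analyte})")
    dt = np.diff(t)
    return float(np.sum(dt * (c[:-1] + c[1:]) / 2.0))


def auc_extrapolate(auc_0_t: float, c_last: float, kel: float) -> tuple[float, float]:
    """AUC_0-inf = AUC_0-t + C_last/kel; returns (auc_0_inf, extrapolated %)."""
    if kel <= 0:
        raise NCAError(f"kel must be positive, got {kel}")
    if c_last < 0:
        raise NCAError(f"c_last must be >= 0, got {c_last}")
    tail = c_last / kel
    auc_inf = auc_0_t + tail
    extrap_pct = 100.0 * tail / auc_inf if auc_inf > 0 else 0.0
    return float(auc_inf), float(extrap_pct)


def clearance(dose: float, auc_0_inf: float) -> float:
    """Apparent oral clearance CL/F = dose / AUC_0-inf (mL/h/kg for ng/kg doses)."""
    if dose <= 0 or auc_0_inf <= 0:
        raise NCAError("dose and AUC_0-inf must both be positive")
    return dose / auc_0_inf


def run_nca(
    profile: ConcentrationTimeProfile,
    min_points: int = 3,
    window: tuple[float, float] | None = None,
    halflife_constant: float = HALF_LIFE_CONSTANT,
    extrap_warn_pct: float = 20.0,
) -> NCAResult:
    """Full per-profile NCA.  CL/F is computed only for administered parents."""
    try:
        cmax, tmax = cmax_tmax(profile)
        fit = terminal_kel(profile, min_points=min_points, window=window)
        auc_t = auc_trapezoid(profile)
        t, c, _ = _prepare(profile)
        c_last = float(c[-1])
        auc_inf, extrap_pct = auc_extrapolate(auc_t, c_last, fit.kel)
    except NCAError as exc:
        raise NCAError(f"{profile.subject_id}/{profile.analyte}: {exc}") from exc
    cl_f = None
    if profile.analyte in PARENT_ANALYTES and profile.dose is not None:
        cl_f = clearance(profile.dose, auc_inf)
    result = NCAResult(
        subject_id=profile.subject_id,
        group=profile.group,
        analyte=profile.analyte,
        cmax=cmax,
        tmax=tmax,
        kel=fit.kel,
        t_half=half_life(fit.kel, halflife_constant),
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        cl_f=cl_f,
        extrap_pct=extrap_pct,
        extrap_warning=extrap_pct > extrap_warn_pct,
        n_terminal=fit.n_points,
        r2_terminal=fit.r_squared,
    )
    logger.debug("run_nca %s/%s: %s", profile.subject_id, profile.analyte, result)
    return result


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def relative_bioavailability(
    auc_treated,
    auc_control,
    mode: str = "ratio_of_means",
    rng: np.random.Generator | None = None,
    n_boot: int = 2000,
):
    """Exposure ratio treated/control as a percentage.

    ``ratio_of_means`` (default) returns 100 * mean(treated)/mean(control) and
    accepts scalars or per-subject arrays.  ``bootstrap_pairs`` resamples
    random (treated, control) pairings across the two independent groups and
    returns (mean %, SD %) of the pairwise ratios.
    """
    at = np.atleast_1d(np.asarray(auc_treated, dtype=float))
    ac = np.atleast_1d(np.asarray(auc_control, dtype=float))
    if np.any(at <= 0) or np.any(ac <= 0):
        raise ValueError("AUC values must be positive")
    if mode == "ratio_of_means":
        return float(100.0 * at.mean() / ac.mean())
    if mode == "bootstrap_pairs":
        if rng is None:
            raise ValueError("bootstrap_pairs mode needs an rng")
        i = rng.integers(0, len(at), size=n_boot)
        j = rng.integers(0, len(ac), size=n_boot)
        ratios = 100.0 * at[i] / ac[j]
        return float(ratios.mean()), float(ratios.std(ddof=1))
    raise ValueError(f"unknown mode {mode!r}")


def metabolite_ratio(auc_metabolite, auc_parent):
    """Metabolite/parent AUC_0-inf ratio in percent (elementwise for arrays)."""
    am = np.asarray(auc_metabolite, dtype=float)
    ap = np.asarray(auc_parent, dtype=float)
    if np.any(am <= 0) or np.any(ap <= 0):
        raise ValueError("AUC values must be positive")
    out = 100.0 * am / ap
    return float(out) if out.ndim == 0 else out


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    parameter: str = "",
    equal_var: bool = True,
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sample t-test (pooled Student by default, Welch with equal_var=False)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 subjects per group")
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    if sd_a == 0.0 and sd_b == 0.0:
        if a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = np.inf if b.mean() > a.mean() else -np.inf, 0.0
    else:
        import warnings

        with warnings.catch_warnings():
            # near-identical samples (e.g. tied tmax) trip scipy's
            # catastrophic-cancellation warning; the test is still valid
            warnings.simplefilter("ignore", RuntimeWarning)
            t_stat, p = stats.ttest_ind(b, a, equal_var=equal_var)
        t_stat, p = float(t_stat), float(p)
    return GroupComparison(
        parameter=parameter,
        mean_a=float(a.mean()), sd_a=sd_a, n_a=len(a),
        mean_b=float(b.mean()), sd_b=sd_b, n_b=len(b),
        t_stat=t_stat, p_value=p, significant=bool(p < alpha), alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

_SUMMARY_PARAMS = [
    ("cmax", "Cmax (ng/mL)"),
    ("tmax", "tmax (h)"),
    ("t_half", "t1/2 (h)"),
    ("auc_0_inf", "AUC0-inf (ng.h/mL)"),
    ("cl_f", "CL/F (mL/h/kg)"),
]


def build_table5(
    single: Mapping[str, Sequence[NCAResult]],
    combo: Mapping[str, Sequence[NCAResult]],
    alpha: float = 0.05,
    equal_var: bool = True,
):
    """Summary of single vs co-administration per analyte and parameter.

    Returns a pandas DataFrame with per-parameter mean/SD for both arms, the
    t-test, and derived R.B.% (AUC ratio co/single, ratio of group means) and
    M.R.% (per-animal TOH/TAM AUC ratio within each arm) rows.
    """
    import pandas as pd

    rows = []
    analytes = [a for a in ANALYTES if a in single and a in combo]
    for analyte in analytes:
        res_s = list(single[analyte])
        res_c = list(combo[analyte])
        for attr, label in _SUMMARY_PARAMS:
            vs = [getattr(r, attr) for r in res_s if getattr(r, attr) is not None]
            vc = [getattr(r, attr) for r in res_c if getattr(r, attr) is not None]
            if len(vs) < 2 or len(vc) < 2:
                continue
            cmp_ = compare_groups(vs, vc, parameter=attr, equal_var=equal_var, alpha=alpha)
            rows.append({
                "analyte": analyte, "parameter": attr, "label": label,
                "single_mean": cmp_.mean_a, "single_sd": cmp_.sd_a,
                "combo_mean": cmp_.mean_b, "combo_sd": cmp_.sd_b,
                "t_stat": cmp_.t_stat, "p_value": cmp_.p_value,
                "significant": cmp_.significant,
            })
        rb = relative_bioavailability(
            [r.auc_0_inf for r in res_c], [r.auc_0_inf for r in res_s])
        rows.append({
            "analyte": analyte, "parameter": "rb_pct", "label": "R.B. (%)",
            "single_mean": np.nan, "single_sd": np.nan,
            "combo_mean": rb, "combo_sd": np.nan,
            "t_stat": np.nan, "p_value": np.nan, "significant": False,
        })
    if "TAM" in analytes and "TOH" in analytes:
        for arm_label, res in (("single", single), ("combo", combo)):
            mr = _per_animal_mr(res["TAM"], res["TOH"])
            rows.append({
                "analyte": "TOH", "parameter": f"mr_pct_{arm_label}",
                "label": f"M.R. (%) [{arm_label}]",
                "single_mean": float(np.mean(mr)) if arm_label == "single" else np.nan,
                "single_sd": float(np.std(mr, ddof=1)) if arm_label == "single" else np.nan,
                "combo_mean": float(np.mean(mr)) if arm_label == "combo" else np.nan,
                "combo_sd": float(np.std(mr, ddof=1)) if arm_label == "combo" else np.nan,
                "t_stat": np.nan, "p_value": np.nan, "significant": False,
            })
    return pd.DataFrame(rows)


def _per_animal_mr(parent: Sequence[NCAResult], metabolite: Sequence[NCAResult]) -> np.ndarray:
    """Per-subject metabolite/parent AUC_0-inf percent, matched by subject_id."""
    p = {r.subject_id: r.auc_0_inf for r in parent}
    m = {r.subject_id: r.auc_0_inf for r in metabolite}
    shared = sorted(set(p) & set(m))
    if not shared:
        raise ValueError("no shared subjects between parent and metabolite results")
    return np.array([metabolite_ratio(m[s], p[s]) for s in shared])


def format_table5(df) -> str:
    """Human-readable rendering of a build_table5 frame (mean +/- SD, * for p<alpha)."""
    lines = [f"{'analyte':8s} {'parameter':14s} {'single':>22s} {'co-admin':>22s} {'p':>8s}"]

    def ms(mean, sd):
        if np.isnan(mean):
            return "-"
        if np.isnan(sd):
            return f"{mean:.2f}"
        return f"{mean:.2f} +/- {sd:.2f}"

    for _, row in df.iterrows():
        p = "" if np.isnan(row["p_value"]) else f"{row['p_value']:.4f}"
        star = "*" if row["significant"] else ""
        lines.append(
            f"{row['analyte']:8s} {row['parameter']:14s} "
            f"{ms(row['single_mean'], row['single_sd']):>22s} "
            f"{ms(row['combo_mean'], row['combo_sd']):>22s} {p:>8s}{star}"
        )
    return "\n".join(lines)
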