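"""Calibration-line fitting, back-calculation and LLOD/LLOQ determination.

The fit is ordinary (optionally 1/x- or 1/x^2-weighted) least squares of the
analyte/IS response ratio on the spiked concentration, reporting the classic
regression statistics: Pearson r, SD of the intercept (S_a), SD of the slope
(S_b) and SD of residuals (S_y/x).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationCurve:
    analyte: str
    intercept_a: float
    slope_b: float
    r: float
    S_a: float
    S_b: float
    S_yx: float
    range_low: float
    range_high: float
    n_points: int
    weighting: str = "none"

    def __post_init__(self) -> None:
        if self.slope_b == 0:
            raise CalibrationError("slope must be nonzero")
        if not -1.0 <= self.r <= 1.0:
            raise CalibrationError("r outside [-1, 1]")
        if self.range_low >= self.range_high:
            raise CalibrationError("range_low must be < range_high")
        if min(self.S_a, self.S_b, self.S_yx) < 0:
            raise CalibrationError("regression SDs must be >= 0")


class BackCalcResult(NamedTuple):
    """Back-calculated concentration(s) with range flags (never clamped)."""

    conc: np.ndarray | float
    below_range: np.ndarray | bool
    above_range: np.ndarray | bool


@dataclass(frozen=True)
class LevelData:
    """Replicate measurements at one candidate limit level."""

    level: float
    signals: Sequence[float]
    found_concs: Sequence[float]


@dataclass(frozen=True)
class LimitDetermination:
    analyte: str
    llod: float | None
    lloq: float | None
    blank_signal: float
    diagnostics: tuple[dict, ...]


_WEIGHTS = ("none", "1/x", "1/x2")


def fit_calibration(
    conc,
    response_ratio,
    analyte: str = "",
    weighting: str = "none",
) -> CalibrationCurve:
    """Least-squares calibration line of response ratio vs concentration.

    Unweighted statistics: S_y/x = sqrt(SSres/(n-2)); S_b = S_y/x/sqrt(Sxx);
    S_a = S_y/x * sqrt(sum(x^2)/(n*Sxx)).  Weighted fits use the analogous
    weighted expressions.
    """
    x = np.asarray(conc, dtype=float)
    y = np.asarray(response_ratio, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CalibrationError("conc and response_ratio must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise CalibrationError(f"need >= 3 calibration points, got {n}")
    if len(np.unique(x)) < 3:
        raise CalibrationError("need >= 3 distinct concentration levels")
    if weighting not in _WEIGHTS:
        raise CalibrationError(f"weighting must be one of {_WEIGHTS}")
    if weighting == "none":
        w = np.ones_like(x)
    else:
        if np.any(x <= 0):
            raise CalibrationError("weighted fits need strictly positive concentrations")
        w = 1.0 / x if weighting == "1/x" else 1.0 / (x * x)

    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    syy = (w * (y - ybar) ** 2).sum()
    if sxx == 0:
        raise CalibrationError("all concentrations identical: no slope")
    b = sxy / sxx
    a = ybar - b * xbar
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else 1.0
    r = float(np.clip(r, -1.0, 1.0))
    resid = y - (a + b * x)
    ss_res = float((w * resid * resid).sum())
    s_yx = np.sqrt(max(ss_res, 0.0) / (n - 2))
    s_b = s_yx / np.sqrt(sxx)
    s_a = s_yx * np.sqrt((w * x * x).sum() / (sw * sxx))
    return CalibrationCurve(
        analyte=analyte, intercept_a=float(a), slope_b=float(b), r=r,
        S_a=float(s_a), S_b=float(s_b), S_yx=float(s_yx),
        range_low=float(x.min()), range_high=float(x.max()),
        n_points=n, weighting=weighting,
    )


def predict(curve: CalibrationCurve, conc):
    """Predicted response ratio at the given concentration(s)."""
    c = np.asarray(conc, dtype=float)
    out = curve.intercept_a + curve.slope_b * c
    return float(out) if out.ndim == 0 else out


def back_calculate(curve: CalibrationCurve, response_ratio) -> BackCalcResult:
    """Invert the calibration line: conc = (ratio - a)/b.

    Out-of-range results (below the low standard / above the high standard,
    the latter requiring dilution) are flagged, never clamped; negative
    concentrations are returned as-is so error statistics stay unbiased.
    """
    y = np.asarray(response_ratio, dtype=float)
    conc = (y - curve.intercept_a) / curve.slope_b
    below = conc < curve.range_low
    above = conc > curve.range_high
    if conc.ndim == 0:
        return BackCalcResult(float(conc), bool(below), bool(above))
    return BackCalcResult(conc, below, above)


def determine_limits(
    blank_signals,
    levels: Sequence[LevelData],
    analyte: str = "",
    llod_ratio: float = 3.0,
    lloq_ratio: float = 5.0,
    max_er_pct: float = 20.0,
    max_rsd_pct: float = 20.0,
) -> LimitDetermination:
    """LLOD/LLOQ by blank-signal ratios plus accuracy/precision at LLOQ.

    LLOD = lowest level whose mean signal is >= 3x the mean blank signal;
    LLOQ = lowest level whose mean signal is >= 5x the mean blank AND whose
    replicate found concentrations satisfy |Er%| <= 20 and RSD% <= 20.
    A blank signal of exactly 0 makes both ratio criteria vacuous.  When no
    level qualifies the corresponding limit is None (not an exception).
    """
    blanks = np.asarray(blank_signals, dtype=float)
    if blanks.size < 1:
        raise CalibrationError("need >= 1 blank signal")
    blank = float(blanks.mean())
    lvls = [float(lv.level) for lv in levels]
    if any(b >= a for a, b in zip(lvls[1:], lvls)):
        raise CalibrationError("candidate levels must be sorted ascending")
    llod = lloq = None
    diagnostics = []
    for lv in levels:
        found = np.asarray(lv.found_concs, dtype=float)
        sig = np.asarray(lv.signals, dtype=float)
        if len(found) < 3 or len(sig) < 3:
            raise CalibrationError(f"level {lv.level}: need >= 3 replicates")
        mean_sig = float(sig.mean())
        mean_found = float(found.mean())
        er = 100.0 * (mean_found - lv.level) / lv.level
        rsd = 100.0 * float(found.std(ddof=1)) / mean_found if mean_found != 0 else np.inf
        ratio = np.inf if blank == 0 else mean_sig / blank
        ok_llod = blank == 0 or mean_sig >= llod_ratio * blank
        ok_lloq = (blank == 0 or mean_sig >= lloq_ratio * blank) \
            and abs(er) <= max_er_pct and rsd <= max_rsd_pct
        if llod is None and ok_llod:
            llod = lv.level
        if lloq is None and ok_lloq:
            lloq = lv.level
        diagnostics.append({
            "level": lv.level, "mean_signal": mean_sig, "signal_ratio": ratio,
            "er_pct": er, "rsd_pct": rsd, "llod_ok": ok_llod, "lloq_ok": ok_lloq,
        })
    return LimitDetermination(analyte=analyte, llod=llod, lloq=lloq,
                              blank_signal=blank, diagnostics=tuple(diagnostics))


def apply_dilution(conc: float, dilution_factor: float) -> float:
    """Dilution-corrected concentration: measured * factor (factor >= 1)."""
    if dilution_factor < 1:
        raise CalibrationError(f"dilution factor must be >= 1, got {dilution_factor}")
    return conc * dilution_factor
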