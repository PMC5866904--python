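"""Noncompartmental analysis (NCA) of a single IV-bolus concentration profile.

Estimates areas (AUC, AUMC) by the linear-up / log-down trapezoidal rule with
an IV-bolus back-extrapolated C0 anchor, fits the terminal elimination rate
constant λz (and its first-moment analogue λz*) by log-linear regression over
an automatically selected terminal window, extrapolates both areas to
infinity, and derives clearance, distribution volumes, mean residence time
and half-lives.

Units: time min, concentration µmol/L, dose µmol; clearance is reported in
mL/min and volumes in mL (the single L→mL conversion lives in
:func:`derive_parameters`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from gdnca.simulate import ConcentrationTimeProfile, ValidationError

__all__ = [
    "LambdaZFit",
    "NCAResult",
    "NotEvaluableError",
    "find_cmax_tmax",
    "back_extrapolate_c0",
    "trapezoid_linear",
    "trapezoid_log",
    "integrate_auc_aumc",
    "fit_lambda_z",
    "extrapolate_to_infinity",
    "derive_parameters",
    "run_nca",
    "run_nca_cohort",
]

#: NCA parameter columns produced for the per-subject table, in report order.
PARAMETER_COLUMNS = (
    "auc_last",
    "auc_inf",
    "auc_extrapolated_pct",
    "auc_inf_per_dose",
    "cmax",
    "tmax",
    "cmax_per_dose",
    "cl",
    "v_ss",
    "v_z",
    "mrt",
    "t_half_beta",
    "t_half_eff",
    "aumc_last",
    "aumc_inf",
    "lambda_z",
    "lambda_z_r_squared",
    "lambda_z_n_points",
)


class NotEvaluableError(Exception):
    """A profile cannot yield a (complete) NCA result.

    Carries a short machine-readable ``reason``; ``run_nca`` never returns a
    partial parameter set.
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}{': ' + detail if detail else ''}")


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal-phase log-linear regression result.

    ``lambda_z`` is the negative slope of ln(y) vs t over the selected window
    (y = C for the ordinary fit, y = C·t for the first-moment variant);
    ``c_last_pred`` is the regression-predicted y at the last quantifiable
    time of the profile.
    """

    lambda_z: float  # 1/min
    intercept_log: float  # ln(µmol/L) (or ln(µmol·min/L) for the starred fit)
    r_squared: float
    adjusted_r_squared: float
    n_points: int
    time_range: tuple[float, float]  # min
    c_last_pred: float


@dataclass(frozen=True)
class NCAResult:
    """Per-subject noncompartmental parameter set."""

    subject_id: str
    group: str
    dose: float  # µmol
    auc_last: float  # µmol·min/L
    aumc_last: float  # µmol·min²/L
    auc_inf: float
    aumc_inf: float
    auc_extrapolated_pct: float
    cmax: float  # µmol/L
    tmax: float  # min
    cmax_per_dose: float
    auc_inf_per_dose: float
    lambda_z_fit: LambdaZFit
    lambda_z_star_fit: LambdaZFit | None
    cl: float  # mL/min
    v_z: float  # mL
    v_ss: float  # mL
    mrt: float  # min
    t_half_beta: float  # min
    t_half_eff: float  # min
    quality_flags: frozenset[str] = frozenset()

    def to_row(self) -> dict:
        """Flatten into one row of the per-subject parameter table."""
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "dose": self.dose,
            "auc_last": self.auc_last,
            "auc_inf": self.auc_inf,
            "auc_extrapolated_pct": self.auc_extrapolated_pct,
            "auc_inf_per_dose": self.auc_inf_per_dose,
            "cmax": self.cmax,
            "tmax": self.tmax,
            "cmax_per_dose": self.cmax_per_dose,
            "cl": self.cl,
            "v_ss": self.v_ss,
            "v_z": self.v_z,
            "mrt": self.mrt,
            "t_half_beta": self.t_half_beta,
            "t_half_eff": self.t_half_eff,
            "aumc_last": self.aumc_last,
            "aumc_inf": self.aumc_inf,
            "lambda_z": self.lambda_z_fit.lambda_z,
            "lambda_z_r_squared": self.lambda_z_fit.r_squared,
            "lambda_z_n_points": self.lambda_z_fit.n_points,
            "quality_flags": ";".join(sorted(self.quality_flags)),
        }


# -- elementary operations ---------------------------------------------------

def _quantifiable(profile: ConcentrationTimeProfile) -> tuple[np.ndarray, np.ndarray]:
    """Times and concentrations of the non-BLQ samples."""
    keep = ~profile.blq_flags
    return profile.times[keep], profile.concentrations[keep]


def find_cmax_tmax(profile: ConcentrationTimeProfile) -> tuple[float, float]:
    """Observed peak concentration and its time; ties broken toward earlier time."""
    t, c = _quantifiable(profile)
    if len(c) == 0:
        raise NotEvaluableError("all_blq", "no quantifiable samples")
    i = int(np.argmax(c))  # argmax returns the first index on ties
    return float(c[i]), float(t[i])


def back_extrapolate_c0(profile: ConcentrationTimeProfile) -> tuple[float, bool]:
    """IV-bolus C0 anchor by log-linear extrapolation through the first two points.

    Returns ``(c0, fallback)``; ``fallback`` is True when the first two
    quantifiable concentrations are non-decreasing (or non-positive) and the
    first observed concentration is used instead.
    """
    t, c = _quantifiable(profile)
    if len(c) < 2:
        raise NotEvaluableError("lt_2_points_for_c0", "need two quantifiable samples")
    t1, t2 = float(t[0]), float(t[1])
    c1, c2 = float(c[0]), float(c[1])
    if c1 > 0 and c2 > 0 and c2 < c1:
        slope = math.log(c2 / c1) / (t2 - t1)
        return c1 * math.exp(-slope * t1), False
    return c1, True


def trapezoid_linear(c1: float, c2: float, dt: float) -> float:
    """Linear trapezoid ``dt·(c1 + c2)/2``; used for ascending/flat segments."""
    if dt <= 0:
        raise ValidationError(f"dt must be positive, got {dt}")
    if c1 < 0 or c2 < 0:
        raise ValidationError("concentrations must be non-negative")
    return dt * (c1 + c2) / 2.0


def trapezoid_log(c1: float, c2: float, dt: float) -> float:
    """Log trapezoid ``dt·(c1 − c2)/ln(c1/c2)``.

    Exact for two points on one exponential.  Rejects equal or non-positive
    endpoints; the integrator is responsible for falling back to the linear
    rule (with a flag) in those degenerate cases.
    """
    if dt <= 0:
        raise ValidationError(f"dt must be positive, got {dt}")
    if c1 <= 0 or c2 <= 0 or c1 == c2:
        raise ValidationError("log trapezoid needs positive, unequal endpoints")
    return dt * (c1 - c2) / math.log(c1 / c2)


def integrate_auc_aumc(
    profile: ConcentrationTimeProfile, c0: float
) -> tuple[float, float, set[str]]:
    """Cumulative AUC and AUMC from t = 0 to the last quantifiable sample.

    Prepends the (0, c0) anchor.  Each segment uses the linear rule when the
    concentration is non-decreasing across it and the log rule when strictly
    decreasing.  AUMC applies the same assignment to the first-moment curve
    y = C·t (log rule on the product for descending-C segments, with a
    linear fallback whenever the product endpoints are equal or non-positive,
    as at t = 0).  Returns ``(auc_last, aumc_last, flags)``.
    """
    tq, cq = _quantifiable(profile)
    if len(cq) < 3:
        raise NotEvaluableError("lt_3_quantifiable", "need three quantifiable samples")
    if c0 < 0:
        raise ValidationError("c0 must be non-negative")
    t = np.concatenate([[0.0], tq])
    c = np.concatenate([[float(c0)], cq])
    flags: set[str] = set()
    auc = 0.0
    aumc = 0.0
    for i in range(len(t) - 1):
        t1, t2 = t[i], t[i + 1]
        c1, c2 = c[i], c[i + 1]
        dt = t2 - t1
        y1, y2 = c1 * t1, c2 * t2
        descending = c2 < c1
        if descending and c1 > 0 and c2 > 0:
            auc += trapezoid_log(c1, c2, dt)
            if y1 > 0 and y2 > 0 and y1 != y2:
                aumc += trapezoid_log(y1, y2, dt)
            else:
                aumc += trapezoid_linear(y1, y2, dt)
        else:
            if c1 == c2 and c1 > 0:
                flags.add("flat_segment_linear")
            auc += trapezoid_linear(c1, c2, dt)
            aumc += trapezoid_linear(y1, y2, dt)
    return auc, aumc, flags


def _best_terminal_window(
    t: np.ndarray, log_y: np.ndarray
) -> tuple[int, float, float, float, float] | None:
    """Scan all terminal (suffix) windows of ≥ 3 points for the best log-linear fit.

    Returns ``(start_index, slope, intercept, r2, adj_r2)`` of the window with
    the highest adjusted R² among windows with a negative slope, ties broken
    toward more points; ``None`` when no window declines.  Uses a reverse
    Welford accumulation so the scan is O(n) and numerically stable on dense
    grids.
    """
    m = len(t)
    best = None
    n = 0
    mean_t = mean_y = m2_t = m2_y = c_ty = 0.0
    # accumulate points from the end; after adding point i the statistics
    # describe the window [i, m)
    for i in range(m - 1, -1, -1):
        n += 1
        dt = t[i] - mean_t
        dy = log_y[i] - mean_y
        mean_t += dt / n
        mean_y += dy / n
        m2_t += dt * (t[i] - mean_t)
        m2_y += dy * (log_y[i] - mean_y)
        c_ty += dt * (log_y[i] - mean_y)
        if n < 3:
            continue
        slope = c_ty / m2_t
        if slope >= 0 or m2_y <= 0:
            continue
        r2 = min(max((c_ty * c_ty) / (m2_t * m2_y), 0.0), 1.0)
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        intercept = mean_y - slope * mean_t
        # iterate with n increasing, so ">=" prefers more points on exact ties
        if best is None or adj_r2 >= best[4]:
            best = (i, slope, intercept, r2, adj_r2)
    return best


def _ols_loglinear(t: np.ndarray, log_y: np.ndarray) -> tuple[float, float, float, float]:
    """Plain OLS of log_y on t: slope, intercept, R², adjusted R²."""
    n = len(t)
    tc = t - t.mean()
    yc = log_y - log_y.mean()
    sxx = float(tc @ tc)
    syy = float(yc @ yc)
    sxy = float(tc @ yc)
    slope = sxy / sxx
    intercept = float(log_y.mean() - slope * t.mean())
    r2 = 1.0 if syy == 0 else min(max(sxy * sxy / (sxx * syy), 0.0), 1.0)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return slope, intercept, r2, adj


def fit_lambda_z(
    profile: ConcentrationTimeProfile,
    transform: Literal["conc", "conc_times_time"] = "conc",
    window: tuple[float, float] | None = None,
) -> LambdaZFit:
    """Terminal rate constant by log-linear regression.

    ``transform="conc"`` regresses ln C vs t (λz); ``"conc_times_time"``
    regresses ln(C·t) vs t (λz*, the first-moment analogue).  Without an
    explicit ``window`` (inclusive time range), all suffix windows of at
    least three points lying strictly after the peak of the transformed
    series are scanned and the one with the highest adjusted R² wins, ties
    broken toward more points.
    """
    tq, cq = _quantifiable(profile)
    if len(cq) == 0:
        raise NotEvaluableError("all_blq", "no quantifiable samples")
    y = cq * tq if transform == "conc_times_time" else cq
    t_last = float(tq[-1])

    if window is not None:
        lo, hi = window
        keep = (tq >= lo) & (tq <= hi) & (y > 0)
        if np.count_nonzero(keep) < 3:
            raise NotEvaluableError("lt_3_terminal_points", "window holds < 3 points")
        tw, yw = tq[keep], np.log(y[keep])
        slope, intercept, r2, adj = _ols_loglinear(tw, yw)
        if slope >= 0:
            raise NotEvaluableError("no_terminal_decline", "non-negative slope in window")
        start_t, end_t = float(tw[0]), float(tw[-1])
        n_points = len(tw)
    else:
        i_peak = int(np.argmax(y))
        keep = np.arange(len(y)) > i_peak
        keep &= y > 0
        tw = tq[keep]
        yw = y[keep]
        if len(tw) < 3:
            raise NotEvaluableError("lt_3_terminal_points", "need 3 points after the peak")
        best = _best_terminal_window(tw, np.log(yw))
        if best is None:
            raise NotEvaluableError("no_terminal_decline", "no declining terminal window")
        i0, slope, intercept, r2, adj = best
        start_t, end_t = float(tw[i0]), float(tw[-1])
        n_points = len(tw) - i0

    return LambdaZFit(
        lambda_z=-slope,
        intercept_log=intercept,
        r_squared=r2,
        adjusted_r_squared=adj,
        n_points=n_points,
        time_range=(start_t, end_t),
        c_last_pred=math.exp(intercept + slope * t_last),
    )


def extrapolate_to_infinity(
    auc_last: float,
    aumc_last: float,
    fit: LambdaZFit,
    fit_star: LambdaZFit | None,
    t_last: float,
) -> tuple[float, float, float, set[str]]:
    """Extend both areas to infinite time.

    AUC gains the tail ``c_last_pred/λz``.  When ``fit_star`` is given (the
    first-moment regression), the AUMC tail is the predicted (C·t) at
    ``t_last`` divided by λz*; otherwise (default pipeline behaviour, and
    the fallback whenever the λz* regression is not estimable, flagged) it
    is the closed-form tail of an exponential decline from the predicted
    C_last, ``C_last·(t_last/λz + 1/λz²)``.  Returns
    ``(auc_inf, aumc_inf, auc_extrapolated_pct, flags)``.
    """
    if fit.lambda_z <= 0:
        raise NotEvaluableError("no_terminal_decline", "lambda_z must be positive")
    flags: set[str] = set()
    auc_inf = auc_last + fit.c_last_pred / fit.lambda_z
    if fit_star is not None and fit_star.lambda_z > 0:
        aumc_inf = aumc_last + fit_star.c_last_pred / fit_star.lambda_z
    else:
        aumc_inf = aumc_last + fit.c_last_pred * (
            t_last / fit.lambda_z + 1.0 / fit.lambda_z**2
        )
    pct = 100.0 * (auc_inf - auc_last) / auc_inf
    if pct > 20.0:
        flags.add("extrapolation_gt_20pct")
    return auc_inf, aumc_inf, pct, flags


def derive_parameters(
    auc_inf: float, aumc_inf: float, fit: LambdaZFit, dose: float
) -> dict[str, float]:
    """Clearance, volumes, residence time and half-lives from the areas.

    With dose in µmol and AUC in µmol·min/L, ``dose/AUC_inf`` is in L/min;
    the factor 1000 converts to mL/min here and nowhere else.
    """
    if dose <= 0:
        raise ValidationError("dose must be positive")
    if auc_inf <= 0 or aumc_inf <= 0 or fit.lambda_z <= 0:
        raise ValidationError("areas and lambda_z must be positive")
    cl = 1000.0 * dose / auc_inf  # mL/min
    mrt = aumc_inf / auc_inf  # min
    return {
        "cl": cl,
        "v_z": cl / fit.lambda_z,
        "mrt": mrt,
        "v_ss": cl * mrt,  # = 1000·dose·AUMC/AUC²
        "t_half_beta": math.log(2.0) / fit.lambda_z,
        "t_half_eff": 0.693 * mrt,
    }


# -- orchestration -----------------------------------------------------------

def run_nca(
    profile: ConcentrationTimeProfile,
    dose: float | None = None,
    lambda_z_window: tuple[float, float] | None = None,
    clast: Literal["pred", "obs"] = "pred",
    aumc_tail: Literal["lambda_z", "lambda_star"] = "lambda_z",
) -> NCAResult:
    """Full noncompartmental analysis of one profile.

    BLQ samples are excluded from integration and regression.  ``clast``
    selects the regression-predicted ("pred") or last observed ("obs")
    concentration for the extrapolated tails.  ``aumc_tail`` selects the
    AUMC extrapolation: ``"lambda_z"`` (default) uses the closed-form
    exponential tail ``C_last·(t_last/λz + 1/λz²)``; ``"lambda_star"`` uses
    the first-moment regression λz* where estimable, falling back (flagged)
    to the closed form — on sparse late-peaked first-moment curves the λz*
    slope is often non-estimable or so close to zero that its tail is
    unstable.  Raises :class:`NotEvaluableError` rather than returning a
    partial result.
    """
    dose = profile.dose if dose is None else float(dose)
    if dose <= 0:
        raise ValidationError("dose must be positive")
    flags: set[str] = set()

    tq, cq = _quantifiable(profile)
    if len(cq) == 0:
        raise NotEvaluableError("all_blq", "no quantifiable samples")
    if len(cq) < 3:
        raise NotEvaluableError("lt_3_quantifiable", "need three quantifiable samples")
    if profile.blq_flags.any():
        flags.add("blq_samples_excluded")

    cmax, tmax = find_cmax_tmax(profile)
    c0, c0_fallback = back_extrapolate_c0(profile)
    if c0_fallback:
        flags.add("c0_first_observation_fallback")

    auc_last, aumc_last, int_flags = integrate_auc_aumc(profile, c0)
    flags |= int_flags

    fit = fit_lambda_z(profile, "conc", window=lambda_z_window)
    if fit.r_squared < 0.8:
        flags.add("lambda_z_r2_lt_0.8")

    fit_star: LambdaZFit | None = None
    if aumc_tail == "lambda_star":
        try:
            fit_star = fit_lambda_z(profile, "conc_times_time", window=lambda_z_window)
        except NotEvaluableError:
            fit_star = None
        if fit_star is None or fit_star.lambda_z <= 0:
            flags.add("aumc_tail_lambda_z_fallback")
            fit_star = None

    t_last = float(tq[-1])
    if clast == "obs":
        fit = replace(fit, c_last_pred=float(cq[-1]))
        if fit_star is not None:
            fit_star = replace(fit_star, c_last_pred=float(cq[-1]) * t_last)

    auc_inf, aumc_inf, pct, tail_flags = extrapolate_to_infinity(
        auc_last, aumc_last, fit, fit_star, t_last
    )
    flags |= tail_flags

    derived = derive_parameters(auc_inf, aumc_inf, fit, dose)
    return NCAResult(
        subject_id=profile.subject_id,
        group=profile.group,
        dose=dose,
        auc_last=auc_last,
        aumc_last=aumc_last,
        auc_inf=auc_inf,
        aumc_inf=aumc_inf,
        auc_extrapolated_pct=pct,
        cmax=cmax,
        tmax=tmax,
        cmax_per_dose=cmax / dose,
        auc_inf_per_dose=auc_inf / dose,
        lambda_z_fit=fit,
        lambda_z_star_fit=fit_star,
        quality_flags=frozenset(flags),
        **derived,
    )


def run_nca_cohort(
    profiles: Iterable[ConcentrationTimeProfile], **options
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run NCA over a cohort.

    Returns ``(parameters, failures)``: one parameter row per evaluable
    subject and one failure record (subject, reason) per subject that could
    not be analysed.
    """
    rows, failures = [], []
    for profile in profiles:
        try:
            rows.append(run_nca(profile, **options).to_row())
        except NotEvaluableError as err:
            failures.append(
                {
                    "subject_id": profile.subject_id,
                    "group": profile.group,
                    "reason": err.reason,
                    "detail": str(err),
                }
            )
    parameters = pd.DataFrame(
        rows,
        columns=["subject_id", "group", "dose", *PARAMETER_COLUMNS, "quality_flags"],
    )
    failure_table = pd.DataFrame(
        failures, columns=["subject_id", "group", "reason", "detail"]
    )
    return parameters, failure_table
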