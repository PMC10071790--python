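"""Blood/plasma pharmacokinetics of the radiolabelled antibody.

Noncompartmental analysis (NCA) on decay-corrected plasma radioactivity:
AUC by the linear-up/log-down trapezoid, terminal slope from a log-linear fit
of the last points, extrapolation to infinity, and total clearance
CL = dose / AUC(0->inf). The activity unit cancels between dose and AUC, so
CL comes out in mL/h. Alongside: the blood-to-plasma radioactivity ratio,
a monoexponential model of the intact-antibody fraction measured by gel
electrophoresis of serial plasma samples, and the radiochemical-purity
quotient from the QC methods.

Percentages are carried on the 0-100 scale throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import SubjectInfo

__all__ = [
    "PlasmaSample",
    "PlasmaPKResult",
    "blood_plasma_ratio",
    "fit_intact_fraction",
    "auc_linupdown",
    "auc_and_clearance",
    "radiochemical_purity",
]


@dataclass(frozen=True)
class PlasmaSample:
    time_post_injection_h: float
    whole_blood_conc: float  # kBq/mL
    plasma_conc: float  # kBq/mL
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        if self.time_post_injection_h < 0:
            raise ValueError("sample time must be >= 0 h")
        if self.whole_blood_conc < 0 or self.plasma_conc < 0:
            raise ValueError("concentrations must be >= 0")


@dataclass(frozen=True)
class PlasmaPKResult:
    auc_0_last: float  # kBq*h/mL
    auc_0_inf: float
    terminal_lambda_per_h: float
    cl_total_mL_per_h: float
    blood_to_plasma_ratio: float
    extrapolated: bool  # False when the terminal phase refused extrapolation
    cl_intact_mL_per_h: float | None = None  # on intact-corrected activity, if requested

    def __post_init__(self) -> None:
        if not (self.auc_0_inf >= self.auc_0_last >= 0):
            raise ValueError("need auc_0_inf >= auc_0_last >= 0")


def _check_times(samples: Sequence[PlasmaSample]) -> None:
    t = [s.time_post_injection_h for s in samples]
    if any(b <= a for a, b in zip(t, t[1:])):
        raise ValueError("sample times must be strictly increasing")


def blood_plasma_ratio(samples: Sequence[PlasmaSample]) -> tuple[np.ndarray, float]:
    """Per-time blood/plasma radioactivity ratios and their mean.

    Samples with zero plasma concentration are excluded with a warning.
    """
    _check_times(samples)
    ratios = []
    for s in samples:
        if s.plasma_conc <= 0:
            warnings.warn(
                f"zero plasma concentration at t={s.time_post_injection_h} h excluded from ratio",
                stacklevel=2,
            )
            continue
        ratios.append(s.whole_blood_conc / s.plasma_conc)
    if not ratios:
        raise ValueError("no valid samples for blood-to-plasma ratio")
    arr = np.array(ratios)
    return arr, float(arr.mean())


def fit_intact_fraction(times_h: np.ndarray, intact_pct: np.ndarray) -> tuple[float, float]:
    """Least-squares monoexponential f(t) = f0 * exp(-rate * t_days).

    Returns (f0 in %, rate in 1/day). Fit is linear in log space, which makes
    it scale-free in the percentages: rescaling them rescales f0 only.
    """
    t = np.asarray(times_h, dtype=float) / 24.0  # days
    f = np.asarray(intact_pct, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 intact-fraction points")
    if np.any(f <= 0) or np.any(f > 100 + 1e-9):
        raise ValueError("intact percentages must be in (0, 100]")
    slope, intercept = np.polyfit(t, np.log(f), 1)
    return float(np.exp(intercept)), float(-slope)


def auc_linupdown(times_h: np.ndarray, conc: np.ndarray) -> float:
    """AUC by the linear-up/log-down trapezoid.

    Log trapezoid on strictly declining positive segments (exact for a
    monoexponential), linear trapezoid otherwise.
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c1 > c2 > 0:
            auc += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            auc += dt * (c1 + c2) / 2.0
    return auc


def _terminal_lambda(times_h: np.ndarray, conc: np.ndarray, n_points: int) -> float | None:
    """Log-linear slope of the last ``n_points``; None if not a declining phase."""
    t = times_h[-n_points:]
    c = conc[-n_points:]
    if np.any(c <= 0) or np.any(np.diff(c) >= 0):
        return None
    slope, _ = np.polyfit(t, np.log(c), 1)
    lam = -float(slope)
    return lam if lam > 0 else None


def auc_and_clearance(
    samples: Sequence[PlasmaSample],
    subject: SubjectInfo,
    *,
    terminal_points: int = 3,
    intact_pct: np.ndarray | None = None,
) -> PlasmaPKResult:
    """Noncompartmental AUC and total clearance from a decay-corrected series.

    AUC(0->last) by linear-up/log-down; terminal lambda from the last
    ``terminal_points`` (>= 3) samples; AUC(0->inf) = AUC(0->last) +
    C_last/lambda; CL = injected activity / AUC(0->inf), in mL/h. A
    non-monotone terminal phase refuses extrapolation: the result carries
    AUC(0->last) only and is flagged ``extrapolated=False``.

    With ``intact_pct`` (aligned with the samples), a clearance computed on
    intact-corrected plasma activity (total x intact fraction) is reported
    alongside the total-radioactivity value.
    """
    _check_times(samples)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for a terminal fit")
    if terminal_points < 3:
        raise ValueError("terminal fit needs >= 3 points")
    if not all(s.decay_corrected for s in samples):
        raise ValueError("plasma series must be decay-corrected to injection")
    t = np.array([s.time_post_injection_h for s in samples])
    c = np.array([s.plasma_conc for s in samples])
    a0_kBq = subject.injected_activity_MBq * 1000.0

    if t[0] > 0:
        # IV bolus: back-extrapolate C0 log-linearly from the first two samples
        if c[0] > c[1] > 0:
            c0 = c[0] * (c[0] / c[1]) ** (t[0] / (t[1] - t[0]))
        else:
            c0 = c[0]
        t = np.concatenate(([0.0], t))
        c = np.concatenate(([c0], c))

    auc_last = auc_linupdown(t, c)
    lam = _terminal_lambda(t, c, terminal_points)
    if lam is None:
        auc_inf = auc_last
        cl = a0_kBq / auc_inf if auc_inf > 0 else math.nan
        extrapolated = False
        lam_out = math.nan
    else:
        auc_inf = auc_last + c[-1] / lam
        cl = a0_kBq / auc_inf
        extrapolated = True
        lam_out = lam

    _, bp_mean = blood_plasma_ratio(samples) if any(s.whole_blood_conc > 0 for s in samples) else (None, math.nan)

    cl_intact = None
    if intact_pct is not None:
        frac = np.asarray(intact_pct, dtype=float) / 100.0
        if len(frac) == len(c) - 1:  # account for the back-extrapolated t=0 point
            frac = np.concatenate(([frac[0]], frac))
        ci = c * frac
        auc_i = auc_linupdown(t, ci)
        lam_i = _terminal_lambda(t, ci, terminal_points)
        if lam_i is not None:
            auc_i += ci[-1] / lam_i
        cl_intact = a0_kBq / auc_i if auc_i > 0 else math.nan

    return PlasmaPKResult(
        auc_0_last=auc_last,
        auc_0_inf=auc_inf,
        terminal_lambda_per_h=lam_out,
        cl_total_mL_per_h=cl,
        blood_to_plasma_ratio=bp_mean,
        extrapolated=extrapolated,
        cl_intact_mL_per_h=cl_intact,
    )


def radiochemical_purity(filter_counts: float, filtrate_counts: float) -> float:
    """Radioactivity on the filter over the total, as a percentage."""
    if filter_counts < 0 or filtrate_counts < 0:
        raise ValueError("counts must be >= 0")
    total = filter_counts + filtrate_counts
    if total <= 0:
        raise ValueError("total counts must be > 0")
    return 100.0 * filter_counts / total
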