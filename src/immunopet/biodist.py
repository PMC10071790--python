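"""Ex vivo tissue quantification and two-group statistics.

Dissected tissues are gamma-counted at a known time post-injection; counts
are decay-corrected back to injection, divided by wet weight, and normalized
by injected activity per body weight (SUV). Phosphor-plate autoradiographs
are background-subtracted, corrected for decay both to injection and across
the exposure window (time-averaged decay factor), and normalized to the
injected dose. Group comparisons use the independent-samples t test
(Student pooled by default, Welch behind the ``equal_var`` switch), two-sided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import ZR89, Radionuclide, SubjectInfo, decay_correction_factor, suv

__all__ = [
    "ExVivoSample",
    "AutoradiographROI",
    "exvivo_suv",
    "normalize_autoradiograph",
    "group_ttest",
    "ttest_from_summaries",
]


@dataclass(frozen=True)
class ExVivoSample:
    tissue: str
    wet_weight_g: float
    measured_activity_kBq: float
    measurement_time_h: float  # post-injection
    subject: SubjectInfo

    def __post_init__(self) -> None:
        if not self.wet_weight_g > 0:
            raise ValueError(f"{self.tissue}: wet weight must be > 0")
        if self.measured_activity_kBq < 0:
            raise ValueError(f"{self.tissue}: activity must be >= 0")
        if self.measurement_time_h < 0:
            raise ValueError(f"{self.tissue}: measurement time must be >= 0")


@dataclass(frozen=True)
class AutoradiographROI:
    region: str  # "cortex" | "medulla"
    psl_per_mm2: float
    background_psl_per_mm2: float
    exposure_start_h: float  # post-injection
    exposure_duration_h: float

    def __post_init__(self) -> None:
        if self.psl_per_mm2 < 0 or self.background_psl_per_mm2 < 0:
            raise ValueError("PSL values must be >= 0")
        if not self.exposure_duration_h > 0:
            raise ValueError("exposure duration must be > 0")


def exvivo_suv(sample: ExVivoSample, nuclide: Radionuclide = ZR89) -> float:
    """SUV of a dissected tissue: decay-correct to injection, per-gram, per A0/W."""
    corrected_kBq = sample.measured_activity_kBq * decay_correction_factor(
        nuclide, sample.measurement_time_h
    )
    conc_kBq_per_g = corrected_kBq / sample.wet_weight_g
    return suv(conc_kBq_per_g, sample.subject, decay_corrected=True)


def normalize_autoradiograph(
    roi: AutoradiographROI,
    subject: SubjectInfo,
    nuclide: Radionuclide = ZR89,
) -> float:
    """Background-subtracted PSL/mm2 per MBq injected, decay-corrected.

    The signal accumulated over an exposure [t0, t0+T] scales with the
    time-averaged surviving activity 2^(-t0/T_half) * (1 - e^(-lam T)) / (lam T);
    dividing the net PSL by this factor and by the injected activity refers
    the value to injection time per MBq.
    """
    net = roi.psl_per_mm2 - roi.background_psl_per_mm2
    if net < 0:
        warnings.warn(
            f"{roi.region}: background exceeds signal; clamping net PSL to 0", stacklevel=2
        )
        net = 0.0
    lam = nuclide.decay_constant_per_h
    t0, T = roi.exposure_start_h, roi.exposure_duration_h
    exposure_factor = 2.0 ** (-t0 / nuclide.half_life_h) * (1 - math.exp(-lam * T)) / (lam * T)
    return net / exposure_factor / subject.injected_activity_MBq


def group_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    *,
    equal_var: bool = True,
    alpha: float = 0.05,
) -> tuple[float, float, float, bool]:
    """Independent-samples t test, two-sided.

    Student pooled-variance by default; ``equal_var=False`` gives Welch.
    Returns (t, df, p, significant at ``alpha``).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue), bool(res.pvalue < alpha)


def ttest_from_summaries(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    *,
    equal_var: bool = True,
) -> tuple[float, float, float]:
    """Pooled (or Welch) t test from printed group summaries; returns (t, df, p)."""
    res = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=equal_var)
    if equal_var:
        df = float(n_a + n_b - 2)
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return float(res.statistic), df, float(res.pvalue)
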