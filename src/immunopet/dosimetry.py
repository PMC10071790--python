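"""MIRD-style internal dosimetry from organ biokinetics.

The chain is: organ time-activity fractions (physical decay included) ->
residence times tau (the normalized numbers of disintegrations, in hours) ->
rabbit-to-human extrapolation by relative organ mass -> organ absorbed doses
through a user-supplied S-value matrix, D(target) = sum_src tau_src *
S(target <- source) -> effective dose under ICRP-103 tissue weighting
factors.

The total-body residence time defaults to the physical-decay bound
T_half/ln2 (no excretion assumed), and the remainder of the body carries
whatever the named source organs do not. S-values are input data, not
computed: phantom Monte-Carlo libraries are out of scope, so the shipped
matrix is a clearly-labelled synthetic stand-in exercising the formalism.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import ZR89, Radionuclide

__all__ = [
    "OrganBiokinetics",
    "PhantomMasses",
    "ResidenceTimeTable",
    "SMatrix",
    "DoseReport",
    "ICRP103_WEIGHTS",
    "NAMED_ICRP_TISSUES",
    "residence_time",
    "scale_rabbit_to_human",
    "remainder_and_total",
    "organ_doses",
    "effective_dose",
    "administered_dose",
]

#: ICRP Publication 103 tissue weighting factors (sum to 1). "remainder" is
#: the arithmetic mean of the remainder-tissue equivalent doses.
ICRP103_WEIGHTS: dict[str, float] = {
    "red_marrow": 0.12,
    "colon": 0.12,
    "lung": 0.12,
    "stomach": 0.12,
    "breast": 0.12,
    "remainder": 0.12,
    "gonads": 0.08,
    "bladder": 0.04,
    "oesophagus": 0.04,
    "liver": 0.04,
    "thyroid": 0.04,
    "bone_surface": 0.01,
    "brain": 0.01,
    "salivary_glands": 0.01,
    "skin": 0.01,
}

NAMED_ICRP_TISSUES = tuple(k for k in ICRP103_WEIGHTS if k != "remainder")


@dataclass(frozen=True)
class OrganBiokinetics:
    """Fraction of injected activity in one organ over time, decay included."""

    organ: str
    times_h: np.ndarray
    fraction_of_injected: np.ndarray
    decay_corrected: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        f = np.asarray(self.fraction_of_injected, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "fraction_of_injected", f)
        if len(t) != len(f):
            raise ValueError(f"{self.organ}: times and fractions must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.organ}: times must be strictly increasing")
        if np.any(f < 0) or np.any(f > 1 + 1e-12):
            raise ValueError(f"{self.organ}: fractions must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomMasses:
    species: str
    organ_masses_kg: dict[str, float]
    total_body_kg: float

    def __post_init__(self) -> None:
        if not self.total_body_kg > 0:
            raise ValueError("total body mass must be > 0")
        for organ, m in self.organ_masses_kg.items():
            if not 0 < m < self.total_body_kg:
                raise ValueError(f"{organ}: organ mass must be in (0, total body mass)")


@dataclass(frozen=True)
class ResidenceTimeTable:
    """Per-organ residence times (h) plus remainder; organ sum + remainder = total."""

    organ_tau_h: dict[str, float]
    remainder_h: float
    total_h: float

    def __post_init__(self) -> None:
        if any(tau < 0 for tau in self.organ_tau_h.values()) or self.remainder_h < -1e-12:
            raise ValueError("residence times must be >= 0")
        s = sum(self.organ_tau_h.values()) + self.remainder_h
        if not math.isclose(s, self.total_h, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("organ sum + remainder must equal total")


@dataclass(frozen=True)
class SMatrix:
    """S values in mGy/(MBq*h), keyed (target, source); warn-only sanity check."""

    entries: dict[tuple[str, str], float]
    phantom: str = "unspecified"

    def __post_init__(self) -> None:
        for key, v in self.entries.items():
            if v < 0:
                raise ValueError(f"S{key} must be >= 0")
        for (target, source), v in self.entries.items():
            self_dose = self.entries.get((target, target))
            if target == source or self_dose is None:
                continue
            if v > self_dose:
                warnings.warn(
                    f"S({target}<-{source}) = {v} exceeds self-dose S({target}<-{target})",
                    stacklevel=2,
                )

    @property
    def sources(self) -> set[str]:
        return {s for _, s in self.entries}

    @property
    def targets(self) -> set[str]:
        return {t for t, _ in self.entries}


@dataclass(frozen=True)
class DoseReport:
    organ_dose_mGy_per_MBq: dict[str, float]
    effective_dose_mSv_per_MBq: float
    weights_version: str = "ICRP 103"

    def __post_init__(self) -> None:
        if self.effective_dose_mSv_per_MBq < 0:
            raise ValueError("effective dose must be >= 0")


def residence_time(bio: OrganBiokinetics, nuclide: Radionuclide = ZR89) -> float:
    """Residence time tau = integral of the activity fraction, in hours.

    Trapezoid over the observed range plus an analytic tail beyond the last
    sample assuming physical decay only (no further biological clearance — a
    conservative tail for a slowly-cleared tracer).
    """
    if bio.decay_corrected:
        raise ValueError(f"{bio.organ}: residence time needs a NOT-decay-corrected series")
    t, f = bio.times_h, bio.fraction_of_injected
    area = float(np.trapezoid(f, t))
    tail = float(f[-1]) / nuclide.decay_constant_per_h
    return area + tail


def scale_rabbit_to_human(
    bios: Mapping[str, OrganBiokinetics],
    masses_rabbit: PhantomMasses,
    masses_human: PhantomMasses,
) -> dict[str, OrganBiokinetics]:
    """Extrapolate rabbit organ fractions to the human phantom.

    f_human = f_rabbit * (m_organ,h / m_TB,h) / (m_organ,r / m_TB,r). Where
    the scaled per-time sum over organs exceeds 1, all organ fractions at
    that time are renormalized proportionally (ratios preserved) and the
    event is reported via a warning.
    """
    organs = list(bios)
    for organ in organs:
        if organ not in masses_rabbit.organ_masses_kg or organ not in masses_human.organ_masses_kg:
            raise KeyError(f"organ {organ!r} missing from a phantom mass table")
    t_ref = next(iter(bios.values())).times_h
    scaled = {}
    for organ, bio in bios.items():
        if not np.array_equal(bio.times_h, t_ref):
            raise ValueError("all organ series must share one time grid for scaling")
        rel_h = masses_human.organ_masses_kg[organ] / masses_human.total_body_kg
        rel_r = masses_rabbit.organ_masses_kg[organ] / masses_rabbit.total_body_kg
        scaled[organ] = bio.fraction_of_injected * (rel_h / rel_r)
    total = np.sum([scaled[o] for o in organs], axis=0)
    over = total > 1.0
    if np.any(over):
        warnings.warn(
            f"mass scaling pushed organ-fraction sums above 1 at {int(over.sum())} time point(s); renormalized",
            stacklevel=2,
        )
        norm = np.where(over, total, 1.0)
        for organ in organs:
            scaled[organ] = scaled[organ] / norm
    return {
        organ: OrganBiokinetics(organ, t_ref.copy(), np.clip(scaled[organ], 0.0, 1.0))
        for organ in organs
    }


def remainder_and_total(
    taus: Mapping[str, float],
    nuclide: Radionuclide = ZR89,
    total_h: float | None = None,
) -> ResidenceTimeTable:
    """Close the residence-time budget with a remainder-of-body term.

    ``total_h`` defaults to the no-excretion physical bound T_half/ln2;
    a measured whole-body total may be supplied instead.
    """
    bound = nuclide.half_life_h / math.log(2.0)
    total = bound if total_h is None else float(total_h)
    if total > bound + 1e-9:
        raise ValueError(f"total residence time {total} h exceeds the physical bound {bound:.4f} h")
    organ_sum = sum(taus.values())
    if organ_sum > total + 1e-9:
        raise ValueError(f"organ residence times sum to {organ_sum:.4f} h > total {total:.4f} h")
    remainder = max(total - organ_sum, 0.0)
    return ResidenceTimeTable(dict(taus), remainder, total)


def organ_doses(table: ResidenceTimeTable, s: SMatrix) -> dict[str, float]:
    """Absorbed dose per target: D = sum_source tau_source * S(target <- source).

    The remainder of the body is a source with its own S row. Any source
    lacking S entries is reported explicitly.
    """
    taus = dict(table.organ_tau_h)
    taus["remainder"] = table.remainder_h
    missing = [src for src in taus if src not in s.sources]
    if missing:
        raise KeyError(f"no S-value entries for source organ(s): {sorted(missing)}")
    doses: dict[str, float] = {}
    for target in sorted(s.targets):
        doses[target] = sum(
            tau * s.entries.get((target, src), 0.0) for src, tau in taus.items()
        )
    return doses


def effective_dose(
    organ_dose: Mapping[str, float],
    weights: Mapping[str, float] | None = None,
) -> float:
    """ICRP-103 effective dose, mSv/MBq.

    E = sum_T w_T H_T. The radiation weighting factor is 1 for the photons,
    electrons and positrons emitted here, so organ mGy map to mSv
    numerically. The remainder weight applies to the arithmetic mean of the
    doses of organs not matching a named ICRP tissue; a named tissue absent
    from ``organ_dose`` falls back to that remainder mean.
    """
    w = dict(ICRP103_WEIGHTS if weights is None else weights)
    if abs(sum(w.values()) - 1.0) > 1e-9:
        raise ValueError(f"tissue weights must sum to 1, got {sum(w.values())!r}")
    named = set(w) - {"remainder"}
    unassessed = [d for organ, d in organ_dose.items() if organ not in named]
    remainder_mean = float(np.mean(unassessed)) if unassessed else float(np.mean(list(organ_dose.values())))
    e = 0.0
    for tissue, weight in w.items():
        if tissue == "remainder":
            e += weight * remainder_mean
        else:
            e += weight * organ_dose.get(tissue, remainder_mean)
    return e


def administered_dose(
    effective_coeff_mSv_per_MBq: float,
    activity_MBq: float,
    *,
    sig_figs: int = 2,
) -> float:
    """Effective dose of an administration: coefficient x activity, mSv.

    Rounded to ``sig_figs`` significant figures for reporting.
    """
    if effective_coeff_mSv_per_MBq <= 0 or activity_MBq <= 0:
        raise ValueError("coefficient and activity must be > 0")
    dose = effective_coeff_mSv_per_MBq * activity_MBq
    if sig_figs is None:
        return dose
    exponent = math.floor(math.log10(abs(dose)))
    return round(dose, -exponent + sig_figs - 1)
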