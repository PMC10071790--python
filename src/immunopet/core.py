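"""Core domain types and arithmetic for framed PET data.

Everything downstream (perfusion fitting, plasma PK, biodistribution,
dosimetry) is built on four primitives defined here:

* :class:`Radionuclide` — physical half-life and decay constant.
* :class:`FrameSchedule` — the dynamic framing of a PET acquisition.
* :class:`TimeActivityCurve` — per-frame radioactivity concentration for one
  region, carrying an explicit decay-correction flag.
* :class:`SubjectInfo` — injected activity, body weight, species and group.

Plus the two operations every stage relies on: physical decay correction to
injection time and the standardized uptake value (SUV).

Units are carried in names throughout: seconds for frame timing, minutes for
kinetic fitting, hours for decay and PK, kBq/mL for concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Radionuclide",
    "FrameSchedule",
    "TimeActivityCurve",
    "SubjectInfo",
    "ZR89",
    "ZR89_PHYSICAL",
    "O15",
    "O15_FRAME_SCHEDULE",
    "ZR89_DYNAMIC_SCHEDULE",
    "decay_correction_factor",
    "decay_factor",
    "suv",
    "tac_resample_midpoints",
]


@dataclass(frozen=True)
class Radionuclide:
    """A radionuclide with physical half-life ``half_life_h`` in hours."""

    name: str
    half_life_h: float

    def __post_init__(self) -> None:
        if not (self.half_life_h > 0 and math.isfinite(self.half_life_h)):
            raise ValueError(f"half_life_h must be finite and > 0, got {self.half_life_h}")

    @property
    def decay_constant_per_h(self) -> float:
        """lambda = ln 2 / T_half, in 1/h."""
        return math.log(2.0) / self.half_life_h


#: Zr-89 with the half-life as commonly rounded in preclinical reports (3.3 d).
ZR89 = Radionuclide("Zr-89", 79.2)
#: Zr-89 with the physical half-life (78.41 h), selectable where precision matters.
ZR89_PHYSICAL = Radionuclide("Zr-89", 78.41)
#: O-15, T_half = 122.24 s.
O15 = Radionuclide("O-15", 122.24 / 3600.0)


@dataclass(frozen=True)
class FrameSchedule:
    """An ordered, non-overlapping set of PET time frames.

    ``frames`` is a tuple of ``(start_s, duration_s)`` pairs sorted by start.
    """

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("FrameSchedule needs at least one frame")
        prev_end = -math.inf
        prev_mid = -math.inf
        for i, (start, dur) in enumerate(self.frames):
            if start < 0:
                raise ValueError(f"frame {i}: start {start} s < 0")
            if dur <= 0:
                raise ValueError(f"frame {i}: duration {dur} s <= 0")
            if start < prev_end - 1e-9:
                raise ValueError(f"frame {i} overlaps the previous frame")
            mid = start + dur / 2.0
            if mid <= prev_mid:
                raise ValueError(f"frame {i}: mid-times must be strictly increasing")
            prev_end, prev_mid = start + dur, mid

    @classmethod
    def from_blocks(cls, blocks: Sequence[tuple[int, float]], start_s: float = 0.0) -> "FrameSchedule":
        """Build a contiguous schedule from ``(n_frames, duration_s)`` blocks."""
        frames = []
        t = float(start_s)
        for n, dur in blocks:
            for _ in range(int(n)):
                frames.append((t, float(dur)))
                t += dur
        return cls(tuple(frames))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def starts_s(self) -> np.ndarray:
        return np.array([f[0] for f in self.frames], dtype=float)

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([f[1] for f in self.frames], dtype=float)

    @property
    def mid_times_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s / 2.0

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.mid_times_s / 60.0

    @property
    def end_s(self) -> float:
        last = self.frames[-1]
        return last[0] + last[1]


#: Radiowater perfusion framing: 15 x 4 s, 4 x 10 s, 4 x 20 s, 3 x 60 s (6 min total).
O15_FRAME_SCHEDULE = FrameSchedule.from_blocks([(15, 4), (4, 10), (4, 20), (3, 60)])
#: Dynamic antibody framing: 4 x 30 s, 4 x 60 s, 2 x 120 s, 2 x 600 s (30 min total).
ZR89_DYNAMIC_SCHEDULE = FrameSchedule.from_blocks([(4, 30), (4, 60), (2, 120), (2, 600)])


@dataclass(frozen=True)
class TimeActivityCurve:
    """Framed radioactivity concentration series for one region.

    ``decay_corrected_to_injection`` records whether values have been referred
    back to injection time; mixing corrected and uncorrected curves in one
    computation raises, never passes silently.
    """

    region: str
    schedule: FrameSchedule
    concentration_kBq_per_mL: np.ndarray
    decay_corrected_to_injection: bool
    nuclide: Radionuclide

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentration_kBq_per_mL, dtype=float)
        object.__setattr__(self, "concentration_kBq_per_mL", conc)
        if conc.ndim != 1 or len(conc) != len(self.schedule):
            raise ValueError(
                f"{self.region}: need one concentration per frame "
                f"({len(conc)} values, {len(self.schedule)} frames)"
            )
        if not np.all(np.isfinite(conc)):
            raise ValueError(f"{self.region}: concentrations must be finite")
        if np.any(conc < 0):
            raise ValueError(f"{self.region}: concentrations must be >= 0")

    def with_concentrations(self, conc: np.ndarray, **changes) -> "TimeActivityCurve":
        return replace(self, concentration_kBq_per_mL=np.asarray(conc, dtype=float), **changes)


@dataclass(frozen=True)
class SubjectInfo:
    """Subject metadata: the normalization constants of every downstream stage."""

    subject_id: str
    species: str  # "rabbit" | "human"
    group: str  # "UUO" | "healthy"
    body_weight_kg: float
    injected_activity_MBq: float
    injection_time_h: float = 0.0  # origin of the post-injection clock

    def __post_init__(self) -> None:
        if self.species not in ("rabbit", "human"):
            raise ValueError(f"species must be 'rabbit' or 'human', got {self.species!r}")
        if not self.body_weight_kg > 0:
            raise ValueError("body_weight_kg must be > 0")
        if not self.injected_activity_MBq > 0:
            raise ValueError("injected_activity_MBq must be > 0")


def decay_correction_factor(nuclide: Radionuclide, elapsed_h: float | np.ndarray) -> float | np.ndarray:
    """Factor referring a measurement at ``elapsed_h`` back to injection time.

    Multiplying a measured concentration by ``2**(elapsed_h / T_half)`` undoes
    the physical decay accumulated since injection.
    """
    elapsed = np.asarray(elapsed_h, dtype=float)
    if np.any(elapsed < 0):
        raise ValueError("elapsed_h must be >= 0")
    factor = np.exp2(elapsed / nuclide.half_life_h)
    return float(factor) if np.isscalar(elapsed_h) or elapsed.ndim == 0 else factor


def decay_factor(nuclide: Radionuclide, elapsed_h: float | np.ndarray) -> float | np.ndarray:
    """Surviving fraction ``2**(-elapsed_h / T_half)`` — the inverse of decay correction."""
    elapsed = np.asarray(elapsed_h, dtype=float)
    if np.any(elapsed < 0):
        raise ValueError("elapsed_h must be >= 0")
    factor = np.exp2(-elapsed / nuclide.half_life_h)
    return float(factor) if np.isscalar(elapsed_h) or elapsed.ndim == 0 else factor


def suv(
    concentration_kBq_per_mL: float | np.ndarray,
    subject: SubjectInfo,
    *,
    decay_corrected: bool = True,
    tissue_density_g_per_mL: float = 1.0,
) -> float | np.ndarray:
    """Standardized uptake value: C / (A0 / W).

    ``C`` must already be decay-corrected to injection (``decay_corrected=True``
    is an assertion by the caller, not a unit conversion); A0 is the injected
    activity in kBq and W the body weight in g. At the default tissue density
    of 1 g/mL, kBq/mL and kBq/g coincide and SUV is dimensionless.
    """
    if not decay_corrected:
        raise ValueError("SUV requires decay-corrected concentrations; correct to injection first")
    if not tissue_density_g_per_mL > 0:
        raise ValueError("tissue_density_g_per_mL must be > 0")
    conc_kBq_per_g = np.asarray(concentration_kBq_per_mL, dtype=float) / tissue_density_g_per_mL
    a0_kBq = subject.injected_activity_MBq * 1000.0
    weight_g = subject.body_weight_kg * 1000.0
    out = conc_kBq_per_g / (a0_kBq / weight_g)
    return float(out) if out.ndim == 0 else out


def tac_resample_midpoints(tac: TimeActivityCurve) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a framed TAC to (mid-times in minutes, concentrations) for fitting."""
    return tac.schedule.mid_times_min, tac.concentration_kBq_per_mL.copy()
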