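"""CSV/YAML/JSON readers and writers with unit-bearing headers.

All tabular formats carry their units in the column names so a file is
self-describing; readers reject files whose headers do not match and report
malformed rows with line numbers. JSON reports embed software version, seed,
a config hash and the nuclide constants used, and round-trip losslessly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import FrameSchedule, Radionuclide, SubjectInfo, TimeActivityCurve
from .dosimetry import PhantomMasses, SMatrix

__all__ = [
    "read_tac_csv",
    "write_tac_csv",
    "read_plasma_csv",
    "write_plasma_csv",
    "read_organ_biokinetics_csv",
    "write_organ_biokinetics_csv",
    "read_masses_yaml",
    "read_smatrix_csv",
    "read_subject_yaml",
    "write_subject_yaml",
    "write_report_json",
    "read_report_json",
]

TAC_COLUMNS = [
    "region",
    "frame_start_s",
    "frame_duration_s",
    "conc_kBq_per_mL",
    "decay_corrected",
    "nuclide",
    "half_life_h",
]

PLASMA_COLUMNS = ["time_h", "blood_kBq_per_mL", "plasma_kBq_per_mL", "intact_pct"]
ORGAN_BIO_COLUMNS = ["organ", "time_h", "fraction_id"]
SMATRIX_COLUMNS = ["source", "target", "mGy_per_MBq_h"]


def _require_columns(df: pd.DataFrame, expected: list[str], path: Path, optional: set[str] = frozenset()) -> None:
    missing = [c for c in expected if c not in df.columns and c not in optional]
    if missing:
        raise ValueError(
            f"{path}: missing required unit-bearing column(s) {missing}; found {list(df.columns)}"
        )


def write_tac_csv(tacs: list[TimeActivityCurve], path: str | Path) -> None:
    rows = []
    for tac in tacs:
        for (start, dur), c in zip(tac.schedule.frames, tac.concentration_kBq_per_mL):
            rows.append(
                (tac.region, start, dur, c, int(tac.decay_corrected_to_injection),
                 tac.nuclide.name, tac.nuclide.half_life_h)
            )
    pd.DataFrame(rows, columns=TAC_COLUMNS).to_csv(path, index=False)


def read_tac_csv(path: str | Path) -> list[TimeActivityCurve]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, TAC_COLUMNS, path)
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after header
        if row["frame_duration_s"] <= 0:
            raise ValueError(f"{path}:{line}: frame_duration_s must be > 0")
        if not np.isfinite(row["conc_kBq_per_mL"]) or row["conc_kBq_per_mL"] < 0:
            raise ValueError(f"{path}:{line}: conc_kBq_per_mL must be finite and >= 0")
    tacs = []
    for region, g in df.groupby("region", sort=False):
        schedule = FrameSchedule(tuple(zip(g["frame_start_s"].astype(float), g["frame_duration_s"].astype(float))))
        nuclide = Radionuclide(str(g["nuclide"].iloc[0]), float(g["half_life_h"].iloc[0]))
        flags = set(g["decay_corrected"].astype(int))
        if len(flags) != 1:
            raise ValueError(f"{path}: mixed decay_corrected flags within region {region!r}")
        tacs.append(
            TimeActivityCurve(
                region=str(region), schedule=schedule,
                concentration_kBq_per_mL=g["conc_kBq_per_mL"].to_numpy(dtype=float),
                decay_corrected_to_injection=bool(flags.pop()), nuclide=nuclide,
            )
        )
    return tacs


def write_plasma_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[PLASMA_COLUMNS if "intact_pct" in df.columns else PLASMA_COLUMNS[:3]].to_csv(path, index=False)


def read_plasma_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, PLASMA_COLUMNS, path, optional={"intact_pct"})
    return df


def write_organ_biokinetics_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[ORGAN_BIO_COLUMNS].to_csv(path, index=False)


def read_organ_biokinetics_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ORGAN_BIO_COLUMNS, path)
    return df


def read_masses_yaml(path: str | Path) -> PhantomMasses:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PhantomMasses(
        species=data["species"],
        organ_masses_kg={k: float(v) for k, v in data["organ_masses_kg"].items()},
        total_body_kg=float(data["total_body_kg"]),
    )


def read_smatrix_csv(path: str | Path, phantom: str = "file") -> SMatrix:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, SMATRIX_COLUMNS, path)
    entries = {
        (str(r["target"]), str(r["source"])): float(r["mGy_per_MBq_h"]) for _, r in df.iterrows()
    }
    return SMatrix(entries=entries, phantom=phantom)


def read_subject_yaml(path: str | Path) -> SubjectInfo:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SubjectInfo(**data)


def write_subject_yaml(subject: SubjectInfo, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "subject_id": subject.subject_id,
                "species": subject.species,
                "group": subject.group,
                "body_weight_kg": subject.body_weight_kg,
                "injected_activity_MBq": subject.injected_activity_MBq,
                "injection_time_h": subject.injection_time_h,
            },
            fh,
        )


def _config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report_json(
    payload: Mapping[str, Any],
    path: str | Path,
    *,
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
    nuclide: Radionuclide | None = None,
) -> None:
    """Write a stage report with provenance (version, seed, config hash, nuclide)."""
    doc = {
        "meta": {
            "software": "immunopet",
            "version": __version__,
            "seed": seed,
            "config_hash": _config_hash(config or {}),
            "nuclide": None if nuclide is None else {
                "name": nuclide.name, "half_life_h": nuclide.half_life_h,
            },
        },
        "payload": dict(payload),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def read_report_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
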