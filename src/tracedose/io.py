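"""Readers and writers for the pipeline's delimited file schemas.

All tabular IO is UTF-8. Biodistribution, caliper and result tables are
comma-delimited with a header row; S-value and organ-mass tables are
tab-delimited. Floats use the decimal point with no thousands separators.

Schemas
-------
biodistribution CSV
    organ, t_h, animal, raw_counts, background, calibration_mbq_per_count,
    organ_mass_g, injected_activity_mbq
S-value TSV
    source_organ, target_organ, s_value_gy_per_mbq_h
mass TSV
    organ, mass_g  (must contain a ``total_body`` row)
caliper CSV
    animal, group, day, L_mm, S_mm
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .cumulated_activity import CumulatedActivity
from .dose_engine import TOTAL_BODY, SValueTable
from .errors import ValidationError
from .growth_metrics import GrowthFit, GrowthRecord
from .synthetic_data import OrganSample

__all__ = [
    "read_biodistribution_csv",
    "write_biodistribution_csv",
    "read_svalue_table",
    "read_organ_map",
    "read_caliper_csv",
    "write_tiac_table",
    "write_growth_table",
]

_BIODIST_COLUMNS = [
    "organ",
    "t_h",
    "animal",
    "raw_counts",
    "background",
    "calibration_mbq_per_count",
    "organ_mass_g",
    "injected_activity_mbq",
]


def write_biodistribution_csv(samples: Iterable[OrganSample], path) -> None:
    df = pd.DataFrame([{c: getattr(s, c) for c in _BIODIST_COLUMNS} for s in samples])
    df.to_csv(path, index=False, float_format="%.10g")


def read_biodistribution_csv(path) -> list[OrganSample]:
    df = pd.read_csv(path)
    missing = set(_BIODIST_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [
        OrganSample(
            organ=str(r.organ),
            t_h=float(r.t_h),
            animal=str(r.animal),
            raw_counts=float(r.raw_counts),
            background=float(r.background),
            calibration_mbq_per_count=float(r.calibration_mbq_per_count),
            organ_mass_g=float(r.organ_mass_g),
            injected_activity_mbq=float(r.injected_activity_mbq),
        )
        for r in df.itertuples()
    ]


def read_svalue_table(svalues_path, masses_path, species: str) -> SValueTable:
    """Assemble an :class:`SValueTable` from the S-value and mass TSVs."""
    sv = pd.read_csv(svalues_path, sep="\t", comment="#")
    need = {"source_organ", "target_organ", "s_value_gy_per_mbq_h"}
    if not need <= set(sv.columns):
        raise ValidationError(f"{svalues_path}: need columns {sorted(need)}")
    masses = pd.read_csv(masses_path, sep="\t", comment="#")
    if not {"organ", "mass_g"} <= set(masses.columns):
        raise ValidationError(f"{masses_path}: need columns organ, mass_g")
    mass_map = {str(r.organ): float(r.mass_g) for r in masses.itertuples()}
    if TOTAL_BODY not in mass_map:
        raise ValidationError(f"{masses_path}: missing a '{TOTAL_BODY}' row")
    total = mass_map.pop(TOTAL_BODY)
    entries = {
        (str(r.source_organ), str(r.target_organ)): float(r.s_value_gy_per_mbq_h)
        for r in sv.itertuples()
    }
    return SValueTable(
        species=species, entries=entries, organ_masses=mass_map, total_body_mass=total
    )


def read_organ_map(path) -> dict[str, str]:
    """Mouse→human organ-label mapping from YAML (a flat string mapping)."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping of organ labels")
    return {str(k): str(v) for k, v in data.items()}


def read_caliper_csv(path) -> list[GrowthRecord]:
    df = pd.read_csv(path)
    need = {"animal", "group", "day", "L_mm", "S_mm"}
    if not need <= set(df.columns):
        raise ValidationError(f"{path}: need columns {sorted(need)}")
    records = []
    for (animal, group), g in df.groupby(["animal", "group"], sort=True):
        g = g.sort_values("day")
        records.append(
            GrowthRecord(
                animal=str(animal),
                days=g["day"].to_numpy(float),
                largest_mm=g["L_mm"].to_numpy(float),
                smallest_mm=g["S_mm"].to_numpy(float),
                group=str(group),
            )
        )
    return records


def write_caliper_csv(records: Iterable[GrowthRecord], path) -> None:
    rows = []
    for r in records:
        for d, L, S in zip(r.days, r.largest_mm, r.smallest_mm):
            rows.append({"animal": r.animal, "group": r.group, "day": d, "L_mm": L, "S_mm": S})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def write_tiac_table(results: Sequence[CumulatedActivity], path) -> None:
    df = pd.DataFrame(
        [
            {
                "organ": r.organ,
                "tiac": r.tiac,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_resamples": r.n_resamples,
                "n_skipped": r.n_skipped,
                "scheme": r.scheme.value,
                "seed": r.seed,
                "reliable": r.reliable,
            }
            for r in results
        ]
    )
    df.to_csv(path, index=False, float_format="%.10g")


def write_growth_table(fits: Sequence[GrowthFit], path) -> None:
    df = pd.DataFrame(
        [
            {
                "animal": f.animal,
                "group": f.group,
                "N0_mm3": f.n0_mm3,
                "a_per_day": f.a_per_day,
                "DT_days": f.doubling_time_days,
                "r_squared": f.r_squared,
                "n_excluded": f.n_excluded,
                "shrinking": f.shrinking,
            }
            for f in fits
        ]
    )
    df.to_csv(path, index=False, float_format="%.10g")
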