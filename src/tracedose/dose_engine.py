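"""MIRD-formalism absorbed doses and mouse-to-human extrapolation.

The MIRD schema gives the absorbed dose to a target organ as

    D(target) = Σ_source Ã(source) · S(source → target)

where Ã is the cumulated activity (MBq·h, the total number of decays in the
source) and S is the species- and radionuclide-specific S-value in
Gy/(MBq·h). Cumulated activity comes from the per-gram TIAC as
Ã = tiac × organ mass × injected activity.

Two dose modes are supported: ``self`` (source = target only, the default)
and ``cross`` (full source→target sum, requiring an S entry for every source
with nonzero cumulated activity).

Human extrapolation rescales the murine per-gram TIAC by human organ mass and
the ratio of total-body masses (``relative_mass``, the default), or carries
the per-organ mouse TIAC over unchanged (``direct``). The extrapolated TIACs
then feed the same MIRD sum with human S-values, reported per GBq.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .errors import MissingSValueError, OrganMappingError, ValidationError

__all__ = [
    "SValueTable",
    "DoseReport",
    "cumulated_activity_absolute",
    "absorbed_dose",
    "scale_dose_to_activity",
    "extrapolate_human_tiac",
    "build_dose_table",
    "TOTAL_BODY",
]

#: Organ label used for the whole-body row of dose tables.
TOTAL_BODY = "total_body"


@dataclass(frozen=True)
class SValueTable:
    """S-values and organ masses for one species.

    ``entries`` maps (source organ, target organ) to S in Gy/(MBq·h);
    ``organ_masses`` is in grams.
    """

    species: str
    entries: Mapping[tuple[str, str], float]
    organ_masses: Mapping[str, float]
    total_body_mass: float

    def __post_init__(self):
        for (src, tgt), s in self.entries.items():
            if s < 0:
                raise ValidationError(f"S({src}->{tgt}) must be >= 0, got {s}")
        for organ, m in self.organ_masses.items():
            if not m > 0:
                raise ValidationError(f"mass of {organ!r} must be > 0, got {m}")
        if not self.total_body_mass > 0:
            raise ValidationError("total-body mass must be > 0")

    def s(self, source: str, target: str) -> float:
        try:
            return self.entries[(source, target)]
        except KeyError:
            raise MissingSValueError(source, target) from None

    def has(self, source: str, target: str) -> bool:
        return (source, target) in self.entries

    def mass(self, organ: str) -> float:
        if organ == TOTAL_BODY:
            return self.total_body_mass
        try:
            return self.organ_masses[organ]
        except KeyError:
            raise OrganMappingError(f"no mass for organ {organ!r} ({self.species})") from None


def cumulated_activity_absolute(
    tiac: float, organ_mass_g: float, injected_activity_mbq: float
) -> float:
    """Invert the per-gram normalization: Ã = tiac × mass × injected (MBq·h)."""
    if not organ_mass_g > 0:
        raise ValidationError(f"organ mass must be > 0, got {organ_mass_g}")
    if not injected_activity_mbq > 0:
        raise ValidationError(f"injected activity must be > 0, got {injected_activity_mbq}")
    return tiac * organ_mass_g * injected_activity_mbq


def absorbed_dose(
    cumulated: Mapping[str, float],
    s_table: SValueTable,
    target: str,
    mode: str = "self",
) -> float:
    """MIRD absorbed dose to ``target`` in Gy from cumulated activities in MBq·h."""
    if mode == "self":
        return cumulated.get(target, 0.0) * s_table.s(target, target)
    if mode != "cross":
        raise ValidationError(f"unknown dose mode {mode!r}")
    dose = 0.0
    for source, a_cum in cumulated.items():
        if a_cum == 0.0:
            continue
        dose += a_cum * s_table.s(source, target)
    return dose


def scale_dose_to_activity(dose_per_unit: float, activity: float) -> float:
    """Dose at a stated injected activity: dose_per_unit × activity.

    Units must agree (e.g. Gy/GBq × GBq). Negative activity is rejected.
    """
    if activity < 0:
        raise ValidationError(f"activity must be >= 0, got {activity}")
    return dose_per_unit * activity


def extrapolate_human_tiac(
    mouse_tiac_per_g: Mapping[str, float],
    mouse: SValueTable,
    human: SValueTable,
    strategy: str = "relative_mass",
    organ_map: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Extrapolate murine per-gram TIACs to human per-organ TIACs.

    ``relative_mass``: human tiac(organ) = mouse tiac/g × human organ mass ×
    (mouse total-body mass / human total-body mass). ``direct``: the mouse
    per-organ TIAC (tiac/g × mouse organ mass) carried over unchanged.
    ``organ_map`` translates mouse organ labels to human table labels.
    """
    if strategy not in ("relative_mass", "direct"):
        raise ValidationError(f"unknown extrapolation strategy {strategy!r}")
    organ_map = dict(organ_map or {})
    out: dict[str, float] = {}
    for organ, tiac_g in mouse_tiac_per_g.items():
        h_organ = organ_map.get(organ, organ)
        if h_organ not in human.organ_masses and h_organ != TOTAL_BODY:
            raise OrganMappingError(
                f"mouse organ {organ!r} maps to {h_organ!r}, absent from human mass table"
            )
        if strategy == "relative_mass":
            out[h_organ] = (
                tiac_g * human.mass(h_organ) * mouse.total_body_mass / human.total_body_mass
            )
        else:
            out[h_organ] = tiac_g * mouse.mass(organ)
    return out


@dataclass
class DoseReport:
    """Per-organ absorbed doses at a stated injected activity.

    ``table`` has one row per organ plus a total-body row, with columns
    tiac (fraction-IA·h), cumulated_activity_mbq_h, dose_per_unit
    (Gy/MBq for mouse, Gy/GBq for human) and dose_gy at the stated activity.
    """

    table: pd.DataFrame
    species: str
    injected_activity: float
    activity_unit: str  # "MBq" or "GBq"
    mode: str
    provenance: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# provenance: {json.dumps(self.provenance, sort_keys=True)}\n")
            self.table.to_csv(fh, index=False, float_format="%.10g")

    def to_json(self, path) -> None:
        payload = {
            "species": self.species,
            "injected_activity": self.injected_activity,
            "activity_unit": self.activity_unit,
            "mode": self.mode,
            "provenance": self.provenance,
            "rows": self.table.to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _provenance(seed: int | None, **config) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str)
    return {
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "seed": seed,
    }


def build_dose_table(
    cumulated: Mapping[str, float],
    s_table: SValueTable,
    injected_activity: float,
    species: str,
    mode: str = "self",
    activity_unit: str | None = None,
    seed: int | None = None,
) -> DoseReport:
    """Assemble the per-organ dose report (the human-table twin).

    ``cumulated`` maps organ → Ã in MBq·h at the stated injected activity
    (MBq for mouse, GBq expressed as 1000 MBq units handled via
    ``activity_unit``). A total-body row is appended when the table carries a
    total-body self S-value; its cumulated activity defaults to the sum over
    organs unless provided explicitly.
    """
    if not injected_activity >= 0:
        raise ValidationError("injected activity must be >= 0")
    unit = activity_unit or ("GBq" if species == "human" else "MBq")
    inj_mbq = injected_activity * (1000.0 if unit == "GBq" else 1.0)
    cumulated = dict(cumulated)
    if TOTAL_BODY not in cumulated and s_table.has(TOTAL_BODY, TOTAL_BODY):
        cumulated[TOTAL_BODY] = sum(
            v for k, v in cumulated.items() if k != TOTAL_BODY
        )
    organs = [k for k in cumulated if k != TOTAL_BODY] + (
        [TOTAL_BODY] if TOTAL_BODY in cumulated else []
    )
    rows = []
    per_unit_scale = 1000.0 if unit == "GBq" else 1.0  # Gy/MBq -> Gy/GBq
    for organ in organs:
        dose = absorbed_dose(cumulated, s_table, organ, mode=mode)
        per_unit = (dose / inj_mbq * per_unit_scale) if inj_mbq > 0 else 0.0
        rows.append(
            {
                "organ": organ,
                "tiac": cumulated[organ] / inj_mbq if inj_mbq > 0 else 0.0,
                "cumulated_activity_mbq_h": cumulated[organ],
                f"dose_gy_per_{unit.lower()}": per_unit,
                "dose_gy": scale_dose_to_activity(per_unit, injected_activity),
            }
        )
    table = pd.DataFrame(rows)
    return DoseReport(
        table=table,
        species=species,
        injected_activity=injected_activity,
        activity_unit=unit,
        mode=mode,
        provenance=_provenance(
            seed,
            species=species,
            mode=mode,
            injected_activity=injected_activity,
            activity_unit=unit,
            organs=sorted(cumulated),
        ),
    )
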