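"""Readers and writers for substance/study tables and result reports.

Input dialects
--------------
* Substances: CSV/TSV with header ``substance_id,name,cas,smiles,
  natural_toxin_flag`` (CAS and flag optional), or an SDF whose records
  carry properties of the same names.
* Studies: CSV/TSV with header ``substance_id,source,route,duration_days,
  effect_level_type,effect_level,dose_unit,reliability_rank``.

Every rejected row is reported with a reason; rows are never silently
dropped.  Dose units other than mg/kg bw/day are converted on read using
configurable per-route intake fractions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from rdkit import Chem

from .records import (
    ClassSummary,
    ClassThreshold,
    DatasetReport,
    DoseUnit,
    Route,
    StudyRecord,
    SubstanceRecord,
)

#: Default intake fractions for converting non-bodyweight dose units,
#: chosen for young rats in subacute studies: kg feed per kg bw per day
#: (dietary) and L water per kg bw per day (drinking water).
DEFAULT_INTAKE_FRACTIONS = {
    Route.dietary: 0.08,
    Route.drinking_water: 0.10,
}


@dataclass
class RejectedRow:
    """One input row that failed validation, with the reason."""

    index: int
    reason: str
    raw: dict = field(default_factory=dict)


@dataclass
class ReadResult:
    """Validated records plus the rejection report (conservation of rows)."""

    records: list
    rejected: list[RejectedRow]

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _truthy(value) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes", "y", "t"}


def read_substances(path: str | Path) -> ReadResult:
    """Read a substance table (CSV/TSV or SDF) into validated records.

    Unparsable structures and missing identifiers become row-level
    rejections with a reason.  An empty file yields an empty result and a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".sdf":
        rows = _sdf_rows(path)
    else:
        df = _read_table(path)
        rows = [row.to_dict() for _, row in df.iterrows()]

    records: list[SubstanceRecord] = []
    rejected: list[RejectedRow] = []
    seen: set[str] = set()
    for i, row in enumerate(rows):
        try:
            rec = SubstanceRecord(
                substance_id=str(row.get("substance_id", "")).strip(),
                name=str(row.get("name", "")).strip(),
                cas=(str(row["cas"]).strip() or None) if row.get("cas") else None,
                smiles=str(row.get("smiles", "")).strip(),
                natural_toxin_flag=_truthy(row.get("natural_toxin_flag", "")),
            )
            if not rec.substance_id:
                raise ValueError("missing substance_id")
            if rec.substance_id in seen:
                raise ValueError(f"duplicate substance_id {rec.substance_id!r}")
        except (ValueError, TypeError) as exc:
            rejected.append(RejectedRow(index=i, reason=_brief(exc), raw=dict(row)))
            continue
        seen.add(rec.substance_id)
        records.append(rec)
    if not rows:
        warnings.warn(f"{path}: empty substance table", stacklevel=2)
    return ReadResult(records=records, rejected=rejected)


def _sdf_rows(path: Path) -> list[dict]:
    rows = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for mol in supplier:
        if mol is None:
            rows.append({"smiles": ""})  # rejected downstream with a reason
            continue
        props = mol.GetPropsAsDict()
        rows.append(
            {
                "substance_id": props.get("substance_id", mol.GetProp("_Name") if mol.HasProp("_Name") else ""),
                "name": props.get("name", ""),
                "cas": props.get("cas", ""),
                "smiles": Chem.MolToSmiles(mol),
                "natural_toxin_flag": props.get("natural_toxin_flag", ""),
            }
        )
    return rows


def convert_dose(
    value: float,
    unit: DoseUnit | str,
    route: Route | str,
    intake_fraction: Optional[float] = None,
) -> float:
    """Convert an effect level to mg/kg bw/day.

    mg/kg bw/day passes through unchanged.  Dietary mg/kg-diet and
    drinking-water mg/L are multiplied by the intake fraction (kg feed or
    L water per kg bw per day); if none is given the per-route default
    from :data:`DEFAULT_INTAKE_FRACTIONS` applies.
    """
    unit = DoseUnit(unit)
    route = Route(route)
    if value <= 0:
        raise ValueError("dose value must be positive")
    if unit is DoseUnit.mg_kg_bw_day:
        return float(value)
    if intake_fraction is None:
        intake_fraction = DEFAULT_INTAKE_FRACTIONS.get(route)
    if intake_fraction is None or intake_fraction <= 0:
        raise ValueError(
            f"no intake fraction configured for unit {unit.value} via route "
            f"{route.value}; supply intake_fraction explicitly"
        )
    return float(value) * float(intake_fraction)


def read_studies(
    path: str | Path,
    intake_fractions: Optional[dict[Route, float]] = None,
) -> ReadResult:
    """Read a study table, converting all dose units to mg/kg bw/day."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path)
    fractions = dict(DEFAULT_INTAKE_FRACTIONS)
    if intake_fractions:
        fractions.update(intake_fractions)

    records: list[StudyRecord] = []
    rejected: list[RejectedRow] = []
    for i, row in df.iterrows():
        raw = row.to_dict()
        try:
            route = Route(str(raw["route"]).strip())
            unit = DoseUnit(str(raw.get("dose_unit", "mg_kg_bw_day")).strip())
            level = float(raw["effect_level"])
            level = convert_dose(level, unit, route, fractions.get(route))
            rec = StudyRecord(
                substance_id=str(raw["substance_id"]).strip(),
                source=str(raw["source"]).strip(),
                route=route,
                duration_days=int(float(raw["duration_days"])),
                effect_level_type=str(raw["effect_level_type"]).strip(),
                effect_level=level,
                dose_unit=DoseUnit.mg_kg_bw_day,
                reliability_rank=int(float(raw["reliability_rank"])),
            )
        except (ValueError, TypeError, KeyError) as exc:
            rejected.append(RejectedRow(index=int(i), reason=_brief(exc), raw=raw))
            continue
        records.append(rec)
    if df.empty:
        warnings.warn(f"{path}: empty study table", stacklevel=2)
    return ReadResult(records=records, rejected=rejected)


def _brief(exc: Exception) -> str:
    try:
        from pydantic import ValidationError

        if isinstance(exc, ValidationError):
            return "; ".join(
                f"{'.'.join(str(l) for l in e['loc'])}: {e['msg']}"
                for e in exc.errors()
            )
    except ImportError:  # pragma: no cover
        pass
    text = str(exc).strip().splitlines()
    return text[0] if text else exc.__class__.__name__


def write_substances(records: Iterable[SubstanceRecord], path: str | Path) -> None:
    """Write substances in the CSV dialect read by :func:`read_substances`."""
    rows = [
        {
            "substance_id": r.substance_id,
            "name": r.name,
            "cas": r.cas or "",
            "smiles": r.smiles,
            "natural_toxin_flag": str(r.natural_toxin_flag).lower(),
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["substance_id", "name", "cas", "smiles", "natural_toxin_flag"]
    ).to_csv(path, index=False)


def write_studies(records: Iterable[StudyRecord], path: str | Path) -> None:
    """Write studies in the CSV dialect read by :func:`read_studies`."""
    rows = [
        {
            "substance_id": r.substance_id,
            "source": r.source.value,
            "route": r.route.value,
            "duration_days": r.duration_days,
            "effect_level_type": r.effect_level_type.value,
            "effect_level": repr(r.effect_level),
            "dose_unit": r.dose_unit.value,
            "reliability_rank": r.reliability_rank,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "substance_id",
            "source",
            "route",
            "duration_days",
            "effect_level_type",
            "effect_level",
            "dose_unit",
            "reliability_rank",
        ],
    ).to_csv(path, index=False)


def write_report(report: DatasetReport, path: str | Path) -> Path:
    """Write a report as JSON plus a flat per-substance CSV alongside.

    The JSON retains full float precision; re-reading it with
    :func:`read_report` reproduces every value bit-exactly.  Returns the
    path of the JSON document.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report.model_dump(mode="json"), indent=2))
    csv_path = path.with_name(path.stem + "_substances.csv")
    pd.DataFrame(report.per_substance).to_csv(csv_path, index=False)
    return path


def read_report(path: str | Path) -> DatasetReport:
    """Re-read a JSON report written by :func:`write_report`."""
    data = json.loads(Path(path).read_text())
    data["thresholds"] = [ClassThreshold(**t) for t in data["thresholds"]]
    data["summaries"] = [ClassSummary(**s) for s in data["summaries"]]
    return DatasetReport(**data)
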