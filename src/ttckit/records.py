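"""Domain records for the TTC derivation pipeline.

The pipeline moves substances (structures with identifiers) and studies
(repeated-dose oral rat studies with an effect level) through curation,
structural classification, point-of-departure (POD) adjustment, and
per-class threshold derivation.  Every record type here is a validated
pydantic model; invalid rows never survive construction.
"""

from __future__ import annotations

import enum
import math
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from ._chem import mol_from_smiles


class ExclusionCategory(str, enum.Enum):
    """Substance groups conventionally exempted from the TTC approach."""

    inorganic = "inorganic"
    organometal = "organometal"
    organophosphorus = "organophosphorus"
    organosilicon = "organosilicon"
    steroid = "steroid"
    azoxy = "azoxy"
    natural_toxin = "natural_toxin"


class StudySource(str, enum.Enum):
    CSCL = "CSCL"
    NTP = "NTP"
    OECD_SIDS = "OECD_SIDS"
    journal = "journal"
    ISHA = "ISHA"
    synthetic = "synthetic"


class Route(str, enum.Enum):
    gavage = "gavage"
    dietary = "dietary"
    drinking_water = "drinking_water"


class EffectLevelType(str, enum.Enum):
    NOAEL = "NOAEL"
    LOAEL = "LOAEL"


class DoseUnit(str, enum.Enum):
    mg_kg_bw_day = "mg_kg_bw_day"
    mg_kg_diet = "mg_kg_diet"
    mg_L_water = "mg_L_water"


class CramerClass(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"


CRAMER_CLASSES = (CramerClass.I, CramerClass.II, CramerClass.III)


class SubstanceRecord(BaseModel):
    """A chemical with structure, identifiers, and curation flags."""

    model_config = ConfigDict(frozen=True)

    substance_id: str
    name: str = ""
    cas: Optional[str] = None
    smiles: str
    exclusion_flag: Optional[ExclusionCategory] = None
    natural_toxin_flag: bool = False

    @field_validator("smiles")
    @classmethod
    def _smiles_parses(cls, v: str) -> str:
        if mol_from_smiles(v) is None:
            raise ValueError(f"SMILES does not parse to a valid molecule: {v!r}")
        return v

    def mol(self):
        return mol_from_smiles(self.smiles)


class StudyRecord(BaseModel):
    """One repeated-dose oral study: effect level, duration, source, reliability.

    ``effect_level`` is stored in mg/kg bw/day after unit conversion;
    ``reliability_rank`` is an explicit integer where 1 is most reliable.
    """

    model_config = ConfigDict(frozen=True)

    substance_id: str
    source: StudySource
    route: Route
    duration_days: int = Field(ge=1)
    effect_level_type: EffectLevelType
    effect_level: float = Field(gt=0)
    dose_unit: DoseUnit = DoseUnit.mg_kg_bw_day
    reliability_rank: int = Field(ge=1)


class AdjustedPOD(BaseModel):
    """A chronic-equivalent POD with the audit trail of applied factors.

    adjusted_pod = raw_effect_level / (loael_factor × duration_factor),
    where the LOAEL-to-NOAEL factor is 3 (else 1) and the subacute /
    subchronic-to-chronic factor is 6 (28-83 d) or 3 (84-179 d).
    """

    model_config = ConfigDict(frozen=True)

    substance_id: str
    raw_effect_level: float = Field(gt=0)
    loael_factor_applied: Literal[1, 3]
    duration_factor_applied: Literal[3, 6]
    adjusted_pod: float = Field(gt=0)
    study: StudyRecord

    @model_validator(mode="after")
    def _factor_identity(self) -> "AdjustedPOD":
        expected = self.raw_effect_level / (
            self.loael_factor_applied * self.duration_factor_applied
        )
        if not math.isclose(self.adjusted_pod, expected, rel_tol=1e-12):
            raise ValueError(
                "adjusted_pod must equal raw_effect_level / "
                "(loael_factor × duration_factor)"
            )
        return self


class CramerAssignment(BaseModel):
    """Structural class assignment with the traversed decision path.

    ``decision_path`` is the ordered (question_id, answer) trace from the
    tree root to the terminal class; expert overrides may carry an empty
    path but must carry a reason, and retain the tree's own verdict in
    ``tree_class`` for audit.
    """

    model_config = ConfigDict(frozen=True)

    substance_id: str
    cramer_class: CramerClass
    decision_path: tuple[tuple[str, bool], ...] = ()
    source: Literal["tree", "expert_override"] = "tree"
    override_reason: Optional[str] = None
    tree_class: Optional[CramerClass] = None
    concordant: Optional[bool] = None

    @model_validator(mode="after")
    def _override_has_reason(self) -> "CramerAssignment":
        if self.source == "expert_override" and not self.override_reason:
            raise ValueError("expert_override assignments must carry a reason")
        if self.source == "tree" and not self.decision_path:
            raise ValueError("tree assignments must carry a decision path")
        return self


#: 5th-percentile z-score of the standard normal, fixed to full double
#: precision so threshold arithmetic is bit-reproducible across platforms.
Z_P05 = -1.6448536269514722


class ClassThreshold(BaseModel):
    """Per-class lognormal fit, 5th-percentile POD, and derived thresholds."""

    cramer_class: CramerClass
    n: int = Field(ge=0)
    log_mu: Optional[float] = None
    log_sigma: Optional[float] = Field(default=None, ge=0)
    pod_p5: Optional[float] = None  # mg/kg bw/day
    tdi_ug_kg_day: Optional[float] = None
    threshold_ug_person_day: Optional[float] = None
    reliable: bool = False


class ClassSummary(BaseModel):
    """Descriptive statistics of adjusted PODs within one Cramer class."""

    cramer_class: CramerClass
    n: int = Field(ge=1)
    median: float  # mg/kg bw/day
    geometric_mean: float  # mg/kg bw/day
    ecdf: tuple[tuple[float, float], ...]  # (log POD, cumulative fraction)


class DatasetReport(BaseModel):
    """Full pipeline output: thresholds, summaries, and accounting tables."""

    thresholds: list[ClassThreshold]
    summaries: list[ClassSummary]
    exclusion_counts: dict[str, int]
    duration_counts: dict[str, int]
    source_counts: dict[str, int]
    per_substance: list[dict]
    config: dict = {}
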