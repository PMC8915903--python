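"""Point-of-departure adjustment to chronic-equivalent doses.

Each critical study's NO(A)EL or LO(A)EL is divided by a LOAEL-to-NOAEL
conversion factor of 3 (when only a LOAEL is available) and by a
study-duration factor: 6 for subacute studies (28-83 days) and 3 for
subchronic studies (84-179 days).  Both factors are multiplicative and
simultaneous; the audit trail records each one.

Findings-level judgments (which observed effects are adverse, which are
species-specific and not human-relevant) are assumed to be already
encoded in the input effect level.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .records import (
    AdjustedPOD,
    CramerAssignment,
    CramerClass,
    EffectLevelType,
    StudyRecord,
    SubstanceRecord,
)

SUBACUTE_RANGE = (28, 83)
SUBCHRONIC_RANGE = (84, 179)
LOAEL_TO_NOAEL_FACTOR = 3
SUBACUTE_TO_CHRONIC_FACTOR = 6
SUBCHRONIC_TO_CHRONIC_FACTOR = 3


def duration_factor(duration_days: int) -> int:
    """Chronic-adjustment factor for an administration period in days."""
    if SUBACUTE_RANGE[0] <= duration_days <= SUBACUTE_RANGE[1]:
        return SUBACUTE_TO_CHRONIC_FACTOR
    if SUBCHRONIC_RANGE[0] <= duration_days <= SUBCHRONIC_RANGE[1]:
        return SUBCHRONIC_TO_CHRONIC_FACTOR
    raise ValueError(
        f"duration {duration_days} d outside the admissible 28-179 d window; "
        "curation should have filtered this study"
    )


def derive_adjusted_pod(study: StudyRecord) -> AdjustedPOD:
    """Convert one study into a chronic-equivalent adjusted POD."""
    loael_factor = (
        LOAEL_TO_NOAEL_FACTOR
        if study.effect_level_type is EffectLevelType.LOAEL
        else 1
    )
    dur_factor = duration_factor(study.duration_days)
    return AdjustedPOD(
        substance_id=study.substance_id,
        raw_effect_level=study.effect_level,
        loael_factor_applied=loael_factor,
        duration_factor_applied=dur_factor,
        adjusted_pod=study.effect_level / (loael_factor * dur_factor),
        study=study,
    )


def pod_table(
    retained: Sequence[tuple[SubstanceRecord, StudyRecord]],
    assignments: Mapping[str, CramerAssignment] | Sequence[CramerAssignment],
) -> dict[CramerClass, list[AdjustedPOD]]:
    """Adjusted PODs for all retained substances, grouped by Cramer class.

    Every retained substance must have exactly one assignment; duplicates
    and missing assignments raise with the offending substance named.
    """
    if not isinstance(assignments, Mapping):
        assignments = {a.substance_id: a for a in assignments}
    groups: dict[CramerClass, list[AdjustedPOD]] = {c: [] for c in CramerClass}
    seen: set[str] = set()
    for substance, study in retained:
        sid = substance.substance_id
        if sid in seen:
            raise ValueError(f"duplicate substance in retained set: {sid}")
        seen.add(sid)
        assignment = assignments.get(sid)
        if assignment is None:
            raise ValueError(f"no Cramer assignment for substance {sid}")
        groups[assignment.cramer_class].append(derive_adjusted_pod(study))
    return groups
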