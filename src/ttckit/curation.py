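"""Dataset curation: critical-study selection and structural exclusions.

A TTC dataset keeps one *critical study* per substance — the most
conservative admissible study, ranked by reliability, then duration, then
effect level — and removes substance groups conventionally exempted from
the TTC approach (inorganics, organometallics, organophosphorus and
organosilicon compounds, steroids, azoxy compounds, natural toxins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml
from rdkit import Chem

from ._chem import has_carbon, largest_carbon_fragment
from .records import (
    ExclusionCategory,
    StudyRecord,
    StudySource,
    SubstanceRecord,
)

#: Admissible administration-period window in days.  Subacute (28-83 d)
#: and subchronic (84-179 d) studies are both admitted; shorter or longer
#: studies have no defined chronic-adjustment factor here.
DURATION_WINDOW = (28, 179)

_SOURCE_ORDER = {s: i for i, s in enumerate(StudySource)}


@dataclass(frozen=True)
class ExclusionRule:
    """One exclusion category with its structural (or flag) predicate."""

    category: ExclusionCategory
    kind: str  # no_carbon | elements | smarts | flag
    elements: frozenset[int] = frozenset()
    patterns: tuple = ()

    def matches(self, substance: SubstanceRecord, mol: Chem.Mol) -> bool:
        if self.kind == "no_carbon":
            return not has_carbon(mol)
        if self.kind == "elements":
            return any(a.GetAtomicNum() in self.elements for a in mol.GetAtoms())
        if self.kind == "smarts":
            return any(mol.HasSubstructMatch(p) for p in self.patterns)
        if self.kind == "flag":
            return substance.natural_toxin_flag
        raise ValueError(f"unknown rule kind {self.kind!r}")


def _default_rules_path() -> Path:
    return Path(str(resources.files("ttckit") / "data" / "exclusion_rules.yaml"))


def load_exclusion_rules(path: str | Path | None = None) -> list[ExclusionRule]:
    """Load the ordered exclusion rules from a YAML rules file."""
    raw = yaml.safe_load(Path(path or _default_rules_path()).read_text())
    table = Chem.GetPeriodicTable()
    rules = []
    for category in raw["order"]:
        spec = raw["rules"][category]
        kind = spec["type"]
        elements: frozenset[int] = frozenset()
        patterns: tuple = ()
        if kind == "elements":
            elements = frozenset(table.GetAtomicNumber(s) for s in spec["symbols"])
        elif kind == "smarts":
            compiled = []
            for p in spec["patterns"]:
                patt = Chem.MolFromSmarts(p)
                if patt is None:
                    raise ValueError(f"bad SMARTS in rule {category}: {p!r}")
                compiled.append(patt)
            patterns = tuple(compiled)
        rules.append(
            ExclusionRule(
                category=ExclusionCategory(category),
                kind=kind,
                elements=elements,
                patterns=patterns,
            )
        )
    return rules


_DEFAULT_RULES: list[ExclusionRule] | None = None


def _rules(rules: Optional[Sequence[ExclusionRule]]) -> Sequence[ExclusionRule]:
    global _DEFAULT_RULES
    if rules is not None:
        return rules
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_exclusion_rules()
    return _DEFAULT_RULES


def check_exclusion(
    substance: SubstanceRecord,
    rules: Optional[Sequence[ExclusionRule]] = None,
) -> Optional[ExclusionCategory]:
    """Return the first matching exclusion category, or None.

    Categories are tested in the fixed order of the rules file
    (inorganic → organometal → organophosphorus → organosilicon →
    steroid → azoxy → natural_toxin); the predicate sees the full
    molecule, not the salt-stripped fragment, because counter-ions
    (e.g. metal salts) are themselves grounds for exclusion.
    """
    mol = substance.mol()
    if mol is None:
        raise ValueError(
            f"substance {substance.substance_id}: structure does not parse; "
            "should have been rejected at read time"
        )
    for rule in _rules(rules):
        if rule.matches(substance, mol):
            return rule.category
    return None


def select_critical_study(studies: Sequence[StudyRecord]) -> StudyRecord:
    """Pick the single critical study for one substance.

    Ordering: higher reliability (lower rank) first, then longer duration,
    then lower effect level — the most conservative admissible study.
    Remaining ties break deterministically by source enum order, then by
    input position.
    """
    if not studies:
        raise ValueError("no studies given")
    ids = {s.substance_id for s in studies}
    if len(ids) > 1:
        raise ValueError(f"studies span multiple substances: {sorted(ids)}")
    return min(
        enumerate(studies),
        key=lambda pair: (
            pair[1].reliability_rank,
            -pair[1].duration_days,
            pair[1].effect_level,
            _SOURCE_ORDER[pair[1].source],
            pair[0],
        ),
    )[1]


@dataclass
class CurationResult:
    """Outcome of dataset curation with full row accounting."""

    retained: list[tuple[SubstanceRecord, StudyRecord]]
    excluded: list[tuple[SubstanceRecord, ExclusionCategory]]
    no_admissible_study: list[SubstanceRecord] = field(default_factory=list)
    orphan_studies: list[StudyRecord] = field(default_factory=list)

    @property
    def exclusion_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, category in self.excluded:
            counts[category.value] = counts.get(category.value, 0) + 1
        return counts


def curate_dataset(
    substances: Iterable[SubstanceRecord],
    studies: Iterable[StudyRecord],
    rules: Optional[Sequence[ExclusionRule]] = None,
    duration_window: tuple[int, int] = DURATION_WINDOW,
) -> CurationResult:
    """Apply exclusion rules and pick one critical study per substance.

    Substances whose studies all fall outside the admissible duration
    window are reported under ``no_admissible_study``; studies that
    reference unknown substances are collected as ``orphan_studies``.
    The selected-study ordering is insensitive to input row order.
    """
    substances = list(substances)
    known = {s.substance_id for s in substances}
    lo, hi = duration_window

    by_substance: dict[str, list[StudyRecord]] = {}
    orphans: list[StudyRecord] = []
    for study in studies:
        if study.substance_id not in known:
            orphans.append(study)
            continue
        if lo <= study.duration_days <= hi:
            by_substance.setdefault(study.substance_id, []).append(study)

    # Deterministic iteration regardless of substance row order.
    retained: list[tuple[SubstanceRecord, StudyRecord]] = []
    excluded: list[tuple[SubstanceRecord, ExclusionCategory]] = []
    no_admissible: list[SubstanceRecord] = []
    for substance in sorted(substances, key=lambda s: s.substance_id):
        admissible = by_substance.get(substance.substance_id)
        if not admissible:
            no_admissible.append(substance)
            continue
        category = check_exclusion(substance, rules)
        if category is not None:
            excluded.append(
                (substance.model_copy(update={"exclusion_flag": category}), category)
            )
        else:
            retained.append((substance, select_critical_study(admissible)))
    return CurationResult(
        retained=retained,
        excluded=excluded,
        no_admissible_study=no_admissible,
        orphan_studies=orphans,
    )
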