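"""Structural-class (Cramer I/II/III) decision-tree classifier.

The classifier walks the yes/no decision tree defined in
``data/cramer_tree.yaml`` over the salt-stripped largest carbon fragment
of each substance, records the full (question, answer) path, and supports
reasoned expert overrides that retain the tree verdict for audit.

Built-in predicates referenced by the tree file
-----------------------------------------------
``lookup``
    Canonical-SMILES membership in a named lookup list; with
    ``scaffold: true`` a molecule whose Murcko ring scaffold equals the
    scaffold of a list entry also counts ("structurally closely related").
``smarts_any``
    Any match from a named SMARTS set defined in the tree file.
``hetero_elements``
    Any atom outside {C, H, O, N} that is not neutral divalent sulfur.
``acyclic`` / ``has_heterocycle`` / ``aromatic_carbocycle`` /
``multiple_aromatic_rings``
    Ring-topology tests.
``hydrocarbon_or_carbohydrate``
    Pure CH skeleton, or a C/H/O polyol with at least three hydroxyls.
``heteroatoms_only_oxygen``
    All heteroatoms are oxygen (reactive oxygen groups were already
    intercepted by the alert question upstream).
``fg_types_le``
    At most *n* distinct functional-group types from a small catalog
    (alcohol, aldehyde, ketone, acid, ester, ether, acetal).
``simple_heterocycle``
    Exactly one 5/6-membered ring whose ring heteroatoms are N/O/S and
    whose substituent heteroatoms are limited to oxygen.
``simple_alicyclic``
    At most ``max_rings`` rings, no aromatics, heteroatoms limited to
    oxygen.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml
from rdkit import Chem

from ._chem import (
    canonical_smiles,
    has_carbon,
    largest_carbon_fragment,
    mol_from_smiles,
    murcko_scaffold_smiles,
)
from .records import CramerAssignment, CramerClass, SubstanceRecord

_TERMINALS = {
    "class I": CramerClass.I,
    "class II": CramerClass.II,
    "class III": CramerClass.III,
}

# Functional-group catalog for the fg_types_le predicate.
_FG_CATALOG = {
    "alcohol": "[CX4][OX2H]",
    "aldehyde": "[CX3H1]=[OX1]",
    "ketone": "[#6][CX3](=[OX1])[#6]",
    "carboxylic_acid": "[CX3](=[OX1])[OX2H]",
    "ester": "[CX3](=[OX1])[OX2][#6]",
    "ether": "[#6][OX2;!$(OC=O)][#6]",
    "acetal": "[CX4]([OX2][#6])[OX2][#6]",
}


@dataclass(frozen=True)
class DecisionNode:
    """One yes/no question of the tree with its outgoing edges."""

    question_id: str
    question: str
    predicate: dict
    if_yes: str  # node id or terminal label
    if_no: str


class LookupLists:
    """Named lists of canonicalized structures consulted by the tree.

    Membership is tested on the canonical SMILES of the salt-stripped
    largest carbon fragment; scaffold membership additionally collects
    the Murcko scaffolds of all entries.
    """

    def __init__(self, lists: dict[str, list[dict]]):
        self._canonical: dict[str, dict[str, str]] = {}
        self._scaffolds: dict[str, dict[str, str]] = {}
        for name, entries in lists.items():
            canon: dict[str, str] = {}
            scaff: dict[str, str] = {}
            for entry in entries:
                smi = canonical_smiles(entry["smiles"])
                if smi is None:
                    raise ValueError(
                        f"lookup list {name!r}: bad SMILES {entry['smiles']!r}"
                    )
                canon[smi] = entry.get("name", smi)
                mol = mol_from_smiles(smi)
                sc = murcko_scaffold_smiles(mol)
                if sc:
                    scaff.setdefault(sc, entry.get("name", smi))
            self._canonical[name] = canon
            self._scaffolds[name] = scaff

    def names(self) -> list[str]:
        return sorted(self._canonical)

    def member(
        self, list_name: str, mol: Chem.Mol, scaffold: bool = False
    ) -> Optional[str]:
        """Matched entry name, or None."""
        smi = Chem.MolToSmiles(mol)
        hit = self._canonical[list_name].get(smi)
        if hit is not None or not scaffold:
            return hit
        sc = murcko_scaffold_smiles(mol)
        if sc:
            return self._scaffolds[list_name].get(sc)
        return None


class CramerTree:
    """The compiled decision tree: nodes, SMARTS sets, and traversal."""

    def __init__(self, spec: dict):
        self.root: str = spec["root"]
        self.smarts_sets: dict[str, dict[str, Chem.Mol]] = {}
        for set_name, patterns in (spec.get("smarts_sets") or {}).items():
            compiled = {}
            for pname, smarts in patterns.items():
                patt = Chem.MolFromSmarts(smarts)
                if patt is None:
                    raise ValueError(f"bad SMARTS {set_name}.{pname}: {smarts!r}")
                compiled[pname] = patt
            self.smarts_sets[set_name] = compiled
        self.nodes: dict[str, DecisionNode] = {}
        for node_id, node in spec["nodes"].items():
            self.nodes[node_id] = DecisionNode(
                question_id=node_id,
                question=str(node["question"]),
                predicate=dict(node["predicate"]),
                if_yes=str(node["if_yes"]),
                if_no=str(node["if_no"]),
            )
        self._validate()

    def _validate(self) -> None:
        if self.root not in self.nodes:
            raise ValueError(f"root {self.root!r} is not a node")
        for node in self.nodes.values():
            for target in (node.if_yes, node.if_no):
                if target not in self.nodes and target not in _TERMINALS:
                    raise ValueError(
                        f"node {node.question_id}: unknown target {target!r}"
                    )
        # Rooted DAG: no node may be reachable from itself.
        state: dict[str, int] = {}

        def visit(nid: str) -> None:
            if nid in _TERMINALS:
                return
            if state.get(nid) == 1:
                raise ValueError(f"cycle through node {nid}")
            if state.get(nid) == 2:
                return
            state[nid] = 1
            node = self.nodes[nid]
            visit(node.if_yes)
            visit(node.if_no)
            state[nid] = 2

        visit(self.root)

    # ---- predicate evaluation -------------------------------------------

    def answer(self, node: DecisionNode, mol: Chem.Mol, lists: LookupLists) -> bool:
        p = node.predicate
        kind = p["type"]
        if kind == "lookup":
            return lists.member(p["list"], mol, scaffold=bool(p.get("scaffold"))) is not None
        if kind == "smarts_any":
            patterns = self.smarts_sets[p["set"]]
            return any(mol.HasSubstructMatch(patt) for patt in patterns.values())
        if kind == "hetero_elements":
            return _has_hetero_elements(mol)
        if kind == "acyclic":
            return mol.GetRingInfo().NumRings() == 0
        if kind == "hydrocarbon_or_carbohydrate":
            return _hydrocarbon_or_carbohydrate(mol)
        if kind == "heteroatoms_only_oxygen":
            return all(
                a.GetAtomicNum() in (1, 6, 8) for a in mol.GetAtoms()
            )
        if kind == "fg_types_le":
            return _fg_type_count(mol) <= int(p["n"])
        if kind == "has_heterocycle":
            return any(
                a.IsInRing() and a.GetAtomicNum() != 6 for a in mol.GetAtoms()
            )
        if kind == "aromatic_carbocycle":
            return _has_aromatic_carbocycle(mol)
        if kind == "multiple_aromatic_rings":
            return _aromatic_ring_count(mol) > 1
        if kind == "simple_heterocycle":
            return _simple_heterocycle(mol)
        if kind == "simple_alicyclic":
            return _simple_alicyclic(mol, int(p.get("max_rings", 2)))
        raise ValueError(f"unknown predicate type {kind!r}")


def _has_hetero_elements(mol: Chem.Mol) -> bool:
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z in (1, 6, 7, 8):
            continue
        if z == 16 and atom.GetTotalValence() <= 2 and atom.GetFormalCharge() == 0:
            continue  # divalent sulfur is tolerated
        return True
    return False


_POLYOL = Chem.MolFromSmarts("[CX4][OX2H]")


def _hydrocarbon_or_carbohydrate(mol: Chem.Mol) -> bool:
    atoms = {a.GetAtomicNum() for a in mol.GetAtoms()}
    if atoms <= {1, 6}:
        return True
    if atoms <= {1, 6, 8} and len(mol.GetSubstructMatches(_POLYOL)) >= 3:
        return True
    return False


def _fg_type_count(mol: Chem.Mol) -> int:
    return sum(
        1
        for patt in _FG_PATTERNS.values()
        if mol.HasSubstructMatch(patt)
    )


_FG_PATTERNS = {name: Chem.MolFromSmarts(s) for name, s in _FG_CATALOG.items()}


def _aromatic_rings(mol: Chem.Mol) -> list[tuple[int, ...]]:
    return [
        ring
        for ring in mol.GetRingInfo().AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    ]


def _aromatic_ring_count(mol: Chem.Mol) -> int:
    return len(_aromatic_rings(mol))


def _has_aromatic_carbocycle(mol: Chem.Mol) -> bool:
    return any(
        all(mol.GetAtomWithIdx(i).GetAtomicNum() == 6 for i in ring)
        for ring in _aromatic_rings(mol)
    )


def _simple_heterocycle(mol: Chem.Mol) -> bool:
    info = mol.GetRingInfo()
    if info.NumRings() != 1:
        return False
    (ring,) = info.AtomRings()
    if len(ring) not in (5, 6):
        return False
    ring_set = set(ring)
    for i in ring:
        z = mol.GetAtomWithIdx(i).GetAtomicNum()
        if z not in (6, 7, 8, 16):
            return False
    # substituents limited to C/H/O chemistry
    for atom in mol.GetAtoms():
        if atom.GetIdx() in ring_set:
            continue
        if atom.GetAtomicNum() not in (1, 6, 8):
            return False
    return True


def _simple_alicyclic(mol: Chem.Mol, max_rings: int) -> bool:
    if mol.GetRingInfo().NumRings() > max_rings:
        return False
    if any(a.GetIsAromatic() for a in mol.GetAtoms()):
        return False
    return all(a.GetAtomicNum() in (1, 6, 8) for a in mol.GetAtoms())


# ---- loading ------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(str(resources.files("ttckit") / "data" / name))


def load_tree(path: str | Path | None = None) -> CramerTree:
    """Load and validate the decision tree from its YAML definition."""
    return CramerTree(yaml.safe_load(Path(path or _data_path("cramer_tree.yaml")).read_text()))


def load_lookup_lists(path: str | Path | None = None) -> LookupLists:
    """Load the body-constituent and food-component lookup lists."""
    return LookupLists(yaml.safe_load(Path(path or _data_path("lookup_lists.yaml")).read_text()))


_DEFAULT_TREE: CramerTree | None = None
_DEFAULT_LISTS: LookupLists | None = None


def default_tree() -> CramerTree:
    global _DEFAULT_TREE
    if _DEFAULT_TREE is None:
        _DEFAULT_TREE = load_tree()
    return _DEFAULT_TREE


def default_lists() -> LookupLists:
    global _DEFAULT_LISTS
    if _DEFAULT_LISTS is None:
        _DEFAULT_LISTS = load_lookup_lists()
    return _DEFAULT_LISTS


# ---- classification -----------------------------------------------------


def classify_cramer(
    substance: SubstanceRecord | str,
    tree: Optional[CramerTree] = None,
    lists: Optional[LookupLists] = None,
) -> CramerAssignment:
    """Classify one substance, returning class plus the full decision path.

    Salts and mixtures are stripped to the largest carbon-containing
    fragment, and the fragment is canonicalized first, so any SMILES of
    the same molecule yields an identical class and path.  Molecules with
    no carbon atom are not classifiable and raise (the exclusion filter
    removes them upstream).
    """
    tree = tree or default_tree()
    lists = lists or default_lists()
    if isinstance(substance, str):
        substance = SubstanceRecord(substance_id=substance, smiles=substance)
    mol = mol_from_smiles(substance.smiles)
    if mol is None:
        raise ValueError(f"unparsable structure for {substance.substance_id}")
    frag = largest_carbon_fragment(mol)
    if not has_carbon(frag):
        raise ValueError(
            f"{substance.substance_id}: no carbon atom; route through the "
            "exclusion filter instead of the structural classifier"
        )
    # Re-parse the canonical fragment so atom order never affects matching.
    frag = mol_from_smiles(Chem.MolToSmiles(frag))

    path: list[tuple[str, bool]] = []
    current = tree.root
    while current not in _TERMINALS:
        node = tree.nodes[current]
        ans = tree.answer(node, frag, lists)
        path.append((node.question_id, ans))
        current = node.if_yes if ans else node.if_no
    return CramerAssignment(
        substance_id=substance.substance_id,
        cramer_class=_TERMINALS[current],
        decision_path=tuple(path),
        source="tree",
    )


def replay_path(
    assignment: CramerAssignment,
    tree: Optional[CramerTree] = None,
) -> CramerClass:
    """Replay a recorded decision path from the root to its terminal class.

    Verifies the structural integrity of the path (starts at the root,
    each answer selects the edge actually taken) without re-evaluating
    predicates; raises if the path does not walk the tree.
    """
    tree = tree or default_tree()
    current = tree.root
    for question_id, ans in assignment.decision_path:
        if current != question_id:
            raise ValueError(
                f"path step {question_id} does not match tree position {current}"
            )
        node = tree.nodes[current]
        current = node.if_yes if ans else node.if_no
    if current not in _TERMINALS:
        raise ValueError(f"path ends at non-terminal {current}")
    return _TERMINALS[current]


@dataclass(frozen=True)
class Override:
    substance_id: str
    cramer_class: CramerClass
    reason: str


def apply_overrides(
    assignments: Sequence[CramerAssignment],
    overrides: Iterable[Override | tuple[str, str, str]],
) -> tuple[list[CramerAssignment], list[str]]:
    """Apply expert overrides to tree assignments.

    Returns the updated assignments and a list of warnings (overrides for
    unknown substances).  Overridden assignments carry
    ``source="expert_override"``, the reason, the original tree class,
    and a concordance flag.
    """
    parsed: dict[str, Override] = {}
    for ov in overrides:
        if not isinstance(ov, Override):
            ov = Override(ov[0], CramerClass(ov[1]), ov[2])
        parsed[ov.substance_id] = ov

    known = {a.substance_id for a in assignments}
    warnings = [
        f"override for unknown substance {sid!r} ignored"
        for sid in parsed
        if sid not in known
    ]
    out: list[CramerAssignment] = []
    for a in assignments:
        ov = parsed.get(a.substance_id)
        if ov is None:
            out.append(a)
            continue
        out.append(
            CramerAssignment(
                substance_id=a.substance_id,
                cramer_class=ov.cramer_class,
                decision_path=a.decision_path,
                source="expert_override",
                override_reason=ov.reason,
                tree_class=a.cramer_class,
                concordant=(ov.cramer_class == a.cramer_class),
            )
        )
    return out, warnings


def class_distribution(
    assignments: Sequence[CramerAssignment],
) -> dict[CramerClass, tuple[int, int]]:
    """Counts and nearest-integer percentages per class.

    Percentages are count / n × 100 rounded half away from zero to the
    nearest integer, the convention used in published TTC dataset tables.
    """
    if not assignments:
        raise ValueError("no assignments")
    n = len(assignments)
    out: dict[CramerClass, tuple[int, int]] = {}
    for cls in CramerClass:
        count = sum(1 for a in assignments if a.cramer_class is cls)
        pct = int(count / n * 100 + 0.5)
        out[cls] = (count, pct)
    return out
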