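"""Structural-class decision tree: exemplar verdicts, path validity,
canonicalization invariance, and expert overrides."""

import pytest
from rdkit import Chem

from ttckit.cramer import (
    Override,
    apply_overrides,
    class_distribution,
    classify_cramer,
    replay_path,
)
from ttckit.records import CramerClass, SubstanceRecord
from ttckit.synthetic import CLASS_EXEMPLARS

EXEMPLAR_CASES = [
    (name, smiles, cls)
    for cls, entries in CLASS_EXEMPLARS.items()
    for name, smiles in entries
]


@pytest.mark.parametrize("name,smiles,expected", EXEMPLAR_CASES, ids=[c[0] for c in EXEMPLAR_CASES])
def test_exemplar_library_classes(name, smiles, expected, tree, lists):
    """The curated exemplar library classifies to its annotated classes."""
    a = classify_cramer(SubstanceRecord(substance_id=name, smiles=smiles), tree, lists)
    assert a.cramer_class == expected


@pytest.mark.parametrize("name,smiles,expected", EXEMPLAR_CASES, ids=[c[0] for c in EXEMPLAR_CASES])
def test_decision_paths_replay_to_reported_class(name, smiles, expected, tree, lists):
    """Replaying each recorded path from the root reaches the reported class."""
    a = classify_cramer(SubstanceRecord(substance_id=name, smiles=smiles), tree, lists)
    assert a.decision_path[0][0] == tree.root
    assert replay_path(a, tree) == a.cramer_class


def test_canonicalization_invariance(tree, lists):
    """Any SMILES of the same molecule yields identical class and path."""
    cases = [
        ("OCC", "CCO"),
        ("c1ccccc1N", "Nc1ccccc1"),
        ("O=Cc1ccco1", "c1cc(C=O)oc1"),
        ("CC(=O)OCC", "C(C)OC(C)=O"),
    ]
    for alt, ref in cases:
        a = classify_cramer(SubstanceRecord(substance_id="a", smiles=alt), tree, lists)
        b = classify_cramer(SubstanceRecord(substance_id="b", smiles=ref), tree, lists)
        assert (a.cramer_class, a.decision_path) == (b.cramer_class, b.decision_path)


def test_atom_renumbering_invariance(tree, lists):
    """Randomized atom orderings never change the verdict."""
    import random

    rnd = random.Random(0)
    for _, smiles in CLASS_EXEMPLARS[CramerClass.III][:8]:
        mol = Chem.MolFromSmiles(smiles)
        ref = classify_cramer(SubstanceRecord(substance_id="r", smiles=smiles), tree, lists)
        order = list(range(mol.GetNumAtoms()))
        rnd.shuffle(order)
        scrambled = Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)
        got = classify_cramer(SubstanceRecord(substance_id="s", smiles=scrambled), tree, lists)
        assert (got.cramer_class, got.decision_path) == (ref.cramer_class, ref.decision_path)


def test_salt_stripped_to_largest_carbon_fragment(tree, lists):
    """Counter-ions do not change the class of the parent molecule."""
    salt = classify_cramer(SubstanceRecord(substance_id="s", smiles="CCO.[Na+].[Cl-]"), tree, lists)
    parent = classify_cramer(SubstanceRecord(substance_id="p", smiles="CCO"), tree, lists)
    assert salt.cramer_class == parent.cramer_class == CramerClass.I


def test_primary_aromatic_amines_all_class_iii(tree, lists):
    amines = ["Nc1ccccc1", "Cc1ccc(N)cc1", "COc1ccc(N)cc1", "Nc1ccc2ccccc2c1", "Nc1ccc(N)cc1"]
    for smi in amines:
        a = classify_cramer(SubstanceRecord(substance_id=smi, smiles=smi), tree, lists)
        assert a.cramer_class == CramerClass.III, smi


def test_simple_alcohols_and_acetates_all_class_i(tree, lists):
    """Unbranched C2-C6 alcohols and their acetate esters are Class I."""
    alcohols = ["CCO", "CCCO", "CCCCO", "CCCCCO", "CCCCCCO"]
    smiles = alcohols + [a[:-1] + "OC(C)=O" for a in alcohols]
    for smi in smiles:
        a = classify_cramer(SubstanceRecord(substance_id=smi, smiles=smi), tree, lists)
        assert a.cramer_class == CramerClass.I, smi


def test_ethanol_class_i(tree, lists):
    a = classify_cramer(SubstanceRecord(substance_id="ethanol", smiles="CCO"), tree, lists)
    assert a.cramer_class == CramerClass.I


def test_carbon_free_molecule_routes_to_exclusion_filter(tree, lists):
    with pytest.raises(ValueError, match="exclusion"):
        classify_cramer(SubstanceRecord(substance_id="x", smiles="OS(=O)(=O)O"), tree, lists)


class TestOverrides:
    def _assignments(self, tree, lists):
        return [
            classify_cramer(SubstanceRecord(substance_id=f"S{i}", smiles=s), tree, lists)
            for i, s in enumerate(["CCO", "Nc1ccccc1"])
        ]

    def test_override_applied_with_provenance(self, tree, lists):
        assignments = self._assignments(tree, lists)
        updated, warnings = apply_overrides(
            assignments, [Override("S0", CramerClass.II, "metabolism argument")]
        )
        assert warnings == []
        assert updated[0].cramer_class == CramerClass.II
        assert updated[0].source == "expert_override"
        assert updated[0].override_reason == "metabolism argument"
        assert updated[0].tree_class == CramerClass.I
        assert updated[0].concordant is False

    def test_empty_override_table_is_identity(self, tree, lists):
        assignments = self._assignments(tree, lists)
        updated, warnings = apply_overrides(assignments, [])
        assert updated == assignments and warnings == []

    def test_concordant_override_still_flagged_as_override(self, tree, lists):
        assignments = self._assignments(tree, lists)
        updated, _ = apply_overrides(
            assignments, [Override("S1", CramerClass.III, "confirmed by review")]
        )
        assert updated[1].source == "expert_override"
        assert updated[1].concordant is True

    def test_unknown_substance_warns(self, tree, lists):
        assignments = self._assignments(tree, lists)
        _, warnings = apply_overrides(assignments, [Override("GHOST", CramerClass.I, "x")])
        assert len(warnings) == 1 and "GHOST" in warnings[0]


class TestClassDistribution:
    def _assignments(self, counts):
        out = []
        by_class = {
            CramerClass.I: "CCO",
            CramerClass.II: "Cc1cnccn1",
            CramerClass.III: "Nc1ccccc1",
        }
        i = 0
        for cls, count in counts.items():
            for _ in range(count):
                out.append(
                    classify_cramer(
                        SubstanceRecord(substance_id=f"S{i}", smiles=by_class[cls])
                    )
                )
                i += 1
        return out

    def test_published_dataset_counts_round_to_29_3_68(self):
        dist = class_distribution(
            self._assignments({CramerClass.I: 19, CramerClass.II: 2, CramerClass.III: 44})
        )
        # same ratios as 190/22/444 at one tenth scale round to 29/3/68 too
        assert dist[CramerClass.I] == (19, 29)
        assert dist[CramerClass.II] == (2, 3)
        assert dist[CramerClass.III] == (44, 68)

    def test_single_substance(self):
        dist = class_distribution(self._assignments({CramerClass.I: 1}))
        assert dist[CramerClass.I] == (1, 100)
        assert dist[CramerClass.III] == (0, 0)

    def test_equal_thirds_round_down(self):
        dist = class_distribution(
            self._assignments({CramerClass.I: 1, CramerClass.II: 1, CramerClass.III: 1})
        )
        assert [pct for _, pct in dist.values()] == [33, 33, 33]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            class_distribution([])
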