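"""Shared RDKit helpers: parsing, canonicalization, fragment handling.

All structure handling in the package funnels through these functions so
that salt stripping and canonical-identity semantics are defined in exactly
one place.
"""

from __future__ import annotations

from functools import lru_cache

from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

# RDKit's per-molecule parse warnings are noise for bulk table reading;
# parse failures are surfaced as explicit row rejections instead.
RDLogger.DisableLog("rdApp.*")


def mol_from_smiles(smiles: str) -> Chem.Mol | None:
    """Parse a SMILES string, returning ``None`` on failure."""
    if not isinstance(smiles, str) or not smiles.strip():
        return None
    return Chem.MolFromSmiles(smiles.strip())


def largest_carbon_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Largest covalent fragment containing at least one carbon atom.

    Salts and mixtures are reduced to this fragment before classification.
    If no fragment contains carbon (fully inorganic input), the largest
    fragment by heavy-atom count is returned unchanged.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    carbon = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    pool = carbon or list(frags)
    return max(pool, key=lambda f: f.GetNumHeavyAtoms())


@lru_cache(maxsize=100_000)
def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES of the largest carbon fragment, or None if unparsable."""
    mol = mol_from_smiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(largest_carbon_fragment(mol))


def murcko_scaffold_smiles(mol: Chem.Mol) -> str:
    """Canonical Murcko (ring-system) scaffold SMILES; empty for acyclic."""
    try:
        scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    except Exception:
        return ""
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def has_carbon(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())
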