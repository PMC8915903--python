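"""Chemotype fingerprints and principal-component chemical-space profiling.

Substances are fingerprinted against a named set of substructure
(SMARTS) chemotype definitions as binary presence vectors; datasets are
compared by per-chemotype occupancy histograms and by PCA projections of
the pooled, column-centered fingerprint matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from sklearn.decomposition import PCA

from ._chem import mol_from_smiles
from .records import SubstanceRecord


@dataclass(frozen=True)
class ChemotypeDefinition:
    """One named structural fragment pattern."""

    chemotype_id: str
    label: str
    smarts: str
    pattern: Chem.Mol

    @staticmethod
    def compile(chemotype_id: str, label: str, smarts: str) -> "ChemotypeDefinition":
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"chemotype {chemotype_id}: bad SMARTS {smarts!r}")
        return ChemotypeDefinition(chemotype_id, label, smarts, patt)


def load_chemotypes(path: str | Path | None = None) -> list[ChemotypeDefinition]:
    """Load chemotype definitions from YAML (default: bundled set)."""
    if path is None:
        path = Path(str(resources.files("ttckit") / "data" / "chemotypes.yaml"))
    raw = yaml.safe_load(Path(path).read_text())
    return [
        ChemotypeDefinition.compile(e["id"], e.get("label", e["id"]), e["pattern"])
        for e in raw["chemotypes"]
    ]


def fingerprint(
    substance: SubstanceRecord | str,
    definitions: Sequence[ChemotypeDefinition],
) -> np.ndarray:
    """Binary presence vector: bit i is 1 iff pattern i matches at least once."""
    smiles = substance if isinstance(substance, str) else substance.smiles
    mol = mol_from_smiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable structure: {smiles!r}")
    return np.array(
        [1 if mol.HasSubstructMatch(d.pattern) else 0 for d in definitions],
        dtype=np.int8,
    )


def fingerprint_matrix(
    substances: Iterable[SubstanceRecord],
    definitions: Sequence[ChemotypeDefinition],
    dataset_label: str = "dataset",
) -> pd.DataFrame:
    """Fingerprint a whole dataset; rows indexed by substance id.

    The frame carries a ``dataset`` column so pooled matrices keep row
    provenance for plotting.
    """
    subs = list(substances)
    data = np.vstack([fingerprint(s, definitions) for s in subs]) if subs else (
        np.zeros((0, len(definitions)), dtype=np.int8)
    )
    df = pd.DataFrame(
        data,
        index=[s.substance_id for s in subs],
        columns=[d.chemotype_id for d in definitions],
    )
    df.insert(0, "dataset", dataset_label)
    return df


def chemotype_histogram(matrices: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-dataset occupancy fraction per chemotype.

    fraction = substances matching the chemotype / dataset size.
    """
    if not matrices:
        raise ValueError("at least one dataset required")
    rows = {}
    for m in matrices:
        if len(m) == 0:
            raise ValueError("empty dataset in histogram input")
        label = str(m["dataset"].iloc[0])
        rows[label] = m.drop(columns="dataset").mean(axis=0)
    return pd.DataFrame(rows).T


@dataclass
class PCProjection:
    """PCA of a pooled fingerprint matrix."""

    scores: pd.DataFrame  # columns PC1..PCk plus dataset label
    loadings: pd.DataFrame  # chemotypes × components
    explained_variance_ratio: np.ndarray


def pc_projection(pooled: pd.DataFrame, k: int = 4) -> PCProjection:
    """Principal components of the pooled, column-centered binary matrix.

    Components are ordered by decreasing explained variance, and each
    component's sign is canonicalized so its largest-magnitude loading is
    positive.  ``k`` larger than the matrix rank raises.
    """
    x = pooled.drop(columns="dataset").to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(centered)
    loadings = pca.components_.T  # chemotypes × components

    # Sign canonicalization: largest-|loading| entry positive per component.
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    cols = [f"PC{i + 1}" for i in range(k)]
    score_df = pd.DataFrame(scores, index=pooled.index, columns=cols)
    score_df.insert(0, "dataset", pooled["dataset"].to_numpy())
    loading_df = pd.DataFrame(
        loadings, index=pooled.columns.drop("dataset"), columns=cols
    )
    return PCProjection(
        scores=score_df,
        loadings=loading_df,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def plot_projection(
    projection: PCProjection,
    components: tuple[str, str] = ("PC1", "PC2"),
    path: Optional[str | Path] = None,
):
    """Scatter of dataset-labeled scores on a pair of components."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for label, sub in projection.scores.groupby("dataset"):
        ax.scatter(sub[components[0]], sub[components[1]], s=12, alpha=0.6, label=label)
    ax.set_xlabel(components[0])
    ax.set_ylabel(components[1])
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
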