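"""Circular fingerprints, Dice similarity and the similarity matrix.

Molecules are encoded as hashed Morgan (ECFP-style) fingerprints held as
explicit fixed-length bit vectors — 1024 bits, radius 2 by default — and
pairwise structural similarity is the Dice coefficient over set bits,

    dice(a, b) = 2 |a ∩ b| / (|a| + |b|),

which ranges from 0 (disjoint substructure features) to 1 (identical bit
sets).  The same binary vectors feed both the similarity matrix and the
2-D embedding downstream, so edge formation and node placement are two
views of one representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .io import MoleculeRecord

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 1024


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary substructure fingerprint of one molecule."""

    mol_id: str
    bits: np.ndarray  # uint8 vector of 0/1

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=np.uint8))

    @property
    def n_bits(self) -> int:
        return self.bits.shape[0]

    @property
    def n_on(self) -> int:
        return int(self.bits.sum())

    @property
    def on_bits(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.bits).tolist())


def compute_fingerprint(
    record: MoleculeRecord | str,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    mol_id: str | None = None,
) -> Fingerprint:
    """Hashed circular fingerprint of a molecule.

    Atom-centered environments of radius 0..``radius`` are hashed into a
    ``n_bits``-long binary vector.  Deterministic for a given canonical
    SMILES.

    Parameters
    ----------
    record:
        A :class:`~csnkit.io.MoleculeRecord` or a bare SMILES string.
    radius:
        Maximum environment radius (bond count), default 2.
    n_bits:
        Vector length, default 1024; must be ≥ 8.
    mol_id:
        Identifier to attach when ``record`` is a bare SMILES.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 8:
        raise ValueError("n_bits must be >= 8")
    if isinstance(record, MoleculeRecord):
        smiles, key = record.smiles, record.mol_id
    else:
        smiles, key = record, (mol_id if mol_id is not None else record)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() < 1:
        raise ValueError(f"unparseable structure for {key!r}: {smiles!r}")
    generator = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = generator.GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(mol_id=key, bits=bits)


def compute_fingerprints(
    records: Sequence[MoleculeRecord],
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> list[Fingerprint]:
    """Fingerprints for an ordered collection of records."""
    return [compute_fingerprint(r, radius=radius, n_bits=n_bits) for r in records]


def dice_similarity(a: Fingerprint | np.ndarray, b: Fingerprint | np.ndarray) -> float:
    """Dice coefficient 2|a∩b| / (|a| + |b|) between two bit vectors.

    Raises
    ------
    ValueError
        On a length mismatch, or when both vectors are empty (the
        coefficient is undefined there; silently returning 0 or 1 would
        hide upstream bugs).
    """
    va = a.bits if isinstance(a, Fingerprint) else np.asarray(a, dtype=np.uint8)
    vb = b.bits if isinstance(b, Fingerprint) else np.asarray(b, dtype=np.uint8)
    if va.shape != vb.shape:
        raise ValueError(f"fingerprint length mismatch: {va.shape[0]} vs {vb.shape[0]}")
    na = int(va.sum())
    nb = int(vb.sum())
    if na == 0 and nb == 0:
        raise ValueError("Dice similarity is undefined for two empty bit vectors")
    inter = int(np.sum((va != 0) & (vb != 0)))
    return 2.0 * inter / (na + nb)


@dataclass
class SimilarityMatrix:
    """Symmetric Dice similarity matrix over an ordered compound set."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, mol_id: str) -> int:
        return self.ids.index(mol_id)

    def similarity(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.index_of(id_a), self.index_of(id_b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), index_label="mol_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimilarityMatrix":
        frame = pd.read_csv(Path(path), index_col=0)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        return cls(ids=list(frame.index), values=frame.to_numpy())


def similarity_matrix(fps: Sequence[Fingerprint]) -> SimilarityMatrix:
    """Full pairwise Dice similarity matrix.

    Requires at least two fingerprints of a uniform length; the diagonal
    is exactly 1.0 and the matrix is symmetric by construction.
    """
    fps = list(fps)
    if len(fps) < 2:
        raise ValueError("similarity matrix requires at least 2 fingerprints")
    lengths = {f.n_bits for f in fps}
    if len(lengths) != 1:
        raise ValueError(f"fingerprints have mixed lengths: {sorted(lengths)}")
    bits = np.stack([f.bits for f in fps]).astype(np.float64)
    counts = bits.sum(axis=1)
    if np.any(counts == 0):
        empty = [f.mol_id for f in fps if f.n_on == 0]
        raise ValueError(f"empty fingerprints are not allowed: {empty}")
    inter = bits @ bits.T
    values = 2.0 * inter / (counts[:, None] + counts[None, :])
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=[f.mol_id for f in fps], values=values)


def hierarchical_order(
    m: SimilarityMatrix, method: str = "average"
) -> tuple[list[str], np.ndarray]:
    """Agglomerative clustering of the compound set on distance 1 − similarity.

    Returns the dendrogram leaf order (for heatmap rendering) and the
    SciPy linkage matrix.  Average linkage by default — the conventional
    choice for similarity heatmaps.
    """
    dist = 1.0 - m.values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method=method)
    order = [m.ids[i] for i in leaves_list(tree)]
    return order, tree


def plot_similarity_heatmap(
    m: SimilarityMatrix, path: str | Path, method: str = "average"
) -> None:
    """Render the similarity matrix as a clustered heatmap (red high, blue low)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order, _ = hierarchical_order(m, method=method)
    idx = [m.ids.index(i) for i in order]
    values = m.values[np.ix_(idx, idx)]
    fig, ax = plt.subplots(figsize=(max(4, m.n * 0.25), max(4, m.n * 0.25)))
    im = ax.imshow(values, cmap="coolwarm", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(m.n), order, rotation=90, fontsize=6)
    ax.set_yticks(range(m.n), order, fontsize=6)
    fig.colorbar(im, ax=ax, label="Dice similarity")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
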