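"""Chemical space network construction.

A chemical space network (CSN) is a graph whose nodes are molecules and
whose edges connect pairs with Dice similarity strictly greater than a
threshold (default 0.45).  Two layouts are supported:

* **t-SNE CSN** — node coordinates come from t-SNE dimensionality
  reduction of the same 1024-bit fingerprints that define the edges, so
  spatial proximity carries similarity information and edge lengths are
  meaningful.  This enables the proximity-constrained grouping step.
* **threshold CSN** — the classic coordinate-free variant with a
  force-directed layout; coordinates are cosmetic and flagged as such.

Molecules with no qualifying edge do not participate in the network: they
are listed in ``isolated_ids`` and excluded from the node set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.manifold import TSNE

from .fingerprints import Fingerprint, SimilarityMatrix
from .io import MoleculeRecord, sort_key

DEFAULT_SIMILARITY_THRESHOLD = 0.45
DEFAULT_SEED = 0


@dataclass
class CSNode:
    mol_id: str
    x: float
    y: float
    degree: int = 0


@dataclass
class CSNEdge:
    """Undirected edge; ``id_a`` precedes ``id_b`` under the canonical id order."""

    id_a: str
    id_b: str
    similarity: float
    embedded_length: float | None = None


@dataclass
class ChemSpaceNetwork:
    nodes: list[CSNode]
    edges: list[CSNEdge]
    isolated_ids: list[str]
    params: dict = field(default_factory=dict)

    @property
    def node_ids(self) -> list[str]:
        return [n.mol_id for n in self.nodes]

    def coordinates(self) -> dict[str, tuple[float, float]]:
        return {n.mol_id: (n.x, n.y) for n in self.nodes}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(**{k: v for k, v in self.params.items() if v is not None})
        for n in self.nodes:
            g.add_node(n.mol_id, x=n.x, y=n.y, degree=n.degree)
        for e in self.edges:
            g.add_edge(
                e.id_a,
                e.id_b,
                similarity=e.similarity,
                embedded_length=e.embedded_length if e.embedded_length is not None else float("nan"),
            )
        return g

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), Path(path))

    def to_node_link_json(self, path: str | Path) -> None:
        data = nx.node_link_data(self.to_networkx(), edges="links")
        data["isolated_ids"] = list(self.isolated_ids)
        Path(path).write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")


def build_edges(
    m: SimilarityMatrix, threshold: float = DEFAULT_SIMILARITY_THRESHOLD
) -> list[CSNEdge]:
    """All unordered pairs with similarity strictly greater than ``threshold``.

    A pair at exactly the threshold does not form an edge.  Edges are
    returned in canonical order (sorted endpoint pairs), independent of
    molecule input order.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    edges: list[CSNEdge] = []
    for i in range(m.n):
        for j in range(i + 1, m.n):
            s = float(m.values[i, j])
            if s > threshold:
                a, b = sorted((m.ids[i], m.ids[j]), key=sort_key)
                edges.append(CSNEdge(id_a=a, id_b=b, similarity=s))
    edges.sort(key=lambda e: (sort_key(e.id_a), sort_key(e.id_b)))
    return edges


def default_perplexity(n: int) -> float:
    """Small-sample default: min(10, (n − 1) / 3), floored at 2."""
    return max(2.0, min(10.0, (n - 1) / 3.0))


def _normalize_unit_square(coords: np.ndarray) -> np.ndarray:
    """Linearly rescale each axis to span [0, 1]; a degenerate axis maps to 0.5."""
    out = np.empty_like(coords, dtype=float)
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        span = col.max() - col.min()
        if span <= 0:
            out[:, axis] = 0.5
        else:
            out[:, axis] = (col - col.min()) / span
    return out


def embed_fingerprints(
    fps: Sequence[Fingerprint],
    seed: int = DEFAULT_SEED,
    perplexity: float | None = None,
    metric: str = "euclidean",
    n_iter: int = 1000,
) -> dict[str, tuple[float, float]]:
    """2-D t-SNE embedding of the fingerprint bit vectors.

    Coordinates are rescaled so each axis spans [0, 1]; the run is
    reproducible given ``seed``.

    Parameters
    ----------
    fps:
        At least 4 fingerprints of uniform length.
    seed:
        Random seed for t-SNE.
    perplexity:
        Neighborhood-size parameter; must be < number of fingerprints.
        Defaults to ``min(10, (n − 1)/3)`` for small-sample stability.
    metric:
        ``"euclidean"`` on the raw bit vectors (default, PCA-style
        deterministic initialization), or ``"dice"`` to embed precomputed
        1 − Dice distances (random but seeded initialization, which
        sklearn requires for precomputed distances).
    n_iter:
        Gradient-descent iterations (≥ 250).
    """
    fps = list(fps)
    n = len(fps)
    if n < 4:
        raise ValueError("embedding requires at least 4 fingerprints")
    if perplexity is None:
        perplexity = default_perplexity(n)
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} infeasible for n={n}")
    bits = np.stack([f.bits for f in fps]).astype(np.float64)
    if metric == "euclidean":
        tsne = TSNE(
            n_components=2,
            perplexity=perplexity,
            init="pca",
            random_state=seed,
            max_iter=max(250, n_iter),
        )
        coords = tsne.fit_transform(bits)
    elif metric == "dice":
        from .fingerprints import similarity_matrix

        dist = 1.0 - similarity_matrix(fps).values
        np.fill_diagonal(dist, 0.0)
        tsne = TSNE(
            n_components=2,
            perplexity=perplexity,
            metric="precomputed",
            init="random",
            random_state=seed,
            max_iter=max(250, n_iter),
        )
        coords = tsne.fit_transform(dist)
    else:
        raise ValueError(f"unknown embedding metric {metric!r}")
    coords = _normalize_unit_square(coords)
    return {f.mol_id: (float(x), float(y)) for f, (x, y) in zip(fps, coords)}


def _edge_lengths(
    edges: Sequence[CSNEdge], coords: Mapping[str, tuple[float, float]]
) -> None:
    for e in edges:
        xa, ya = coords[e.id_a]
        xb, yb = coords[e.id_b]
        e.embedded_length = float(np.hypot(xa - xb, ya - yb))


def _assemble(
    m: SimilarityMatrix,
    coords: Mapping[str, tuple[float, float]],
    edges: list[CSNEdge],
    params: dict,
) -> ChemSpaceNetwork:
    degree: dict[str, int] = {i: 0 for i in m.ids}
    for e in edges:
        degree[e.id_a] += 1
        degree[e.id_b] += 1
    participating = [i for i in m.ids if degree[i] > 0]
    isolated = [i for i in m.ids if degree[i] == 0]
    _edge_lengths(edges, coords)
    nodes = [
        CSNode(mol_id=i, x=coords[i][0], y=coords[i][1], degree=degree[i])
        for i in participating
    ]
    return ChemSpaceNetwork(nodes=nodes, edges=edges, isolated_ids=isolated, params=params)


def assemble_network(
    records: Sequence[MoleculeRecord] | None,
    fps: Sequence[Fingerprint],
    m: SimilarityMatrix,
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    seed: int = DEFAULT_SEED,
    perplexity: float | None = None,
    metric: str = "euclidean",
) -> ChemSpaceNetwork:
    """Build the t-SNE CSN from fingerprints and the similarity matrix.

    All molecules are embedded; molecules with zero qualifying edges are
    then moved to ``isolated_ids`` and excluded from the node set (they do
    not participate in network generation).  Edge lengths are Euclidean
    distances between the normalized endpoint coordinates.
    """
    fp_ids = [f.mol_id for f in fps]
    if fp_ids != list(m.ids):
        raise ValueError("fingerprint ids and similarity matrix ids do not match")
    if records is not None:
        rec_ids = [r.mol_id for r in records]
        if sorted(rec_ids) != sorted(fp_ids):
            raise ValueError("record ids and fingerprint ids do not match")
    if perplexity is None:
        perplexity = default_perplexity(len(fps))
    coords = embed_fingerprints(fps, seed=seed, perplexity=perplexity, metric=metric)
    edges = build_edges(m, threshold)
    params = {
        "layout": "tsne",
        "threshold": threshold,
        "seed": seed,
        "perplexity": perplexity,
        "metric": metric,
    }
    return _assemble(m, coords, edges, params)


def build_threshold_csn(
    m: SimilarityMatrix,
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    seed: int = DEFAULT_SEED,
) -> ChemSpaceNetwork:
    """Classic threshold CSN with a force-directed (spring) layout.

    The edge set is identical to :func:`assemble_network` at the same
    threshold; only the coordinates differ and they carry no similarity
    semantics (``params["layout"] == "force-directed"``).
    """
    edges = build_edges(m, threshold)
    g = nx.Graph()
    g.add_nodes_from(m.ids)
    g.add_edges_from((e.id_a, e.id_b) for e in edges)
    pos = nx.spring_layout(g, seed=seed)
    coords_arr = np.array([pos[i] for i in m.ids], dtype=float)
    coords_arr = _normalize_unit_square(coords_arr)
    coords = {i: (float(x), float(y)) for i, (x, y) in zip(m.ids, coords_arr)}
    params = {"layout": "force-directed", "threshold": threshold, "seed": seed}
    return _assemble(m, coords, edges, params)


def plot_network(
    net: ChemSpaceNetwork,
    path: str | Path,
    group_of: Mapping[str, int] | None = None,
    names: Mapping[str, str] | None = None,
) -> None:
    """Static rendering: grouped nodes colored, unassigned nodes gray."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import cm

    group_of = group_of or {}
    coords = net.coordinates()
    fig, ax = plt.subplots(figsize=(7, 7))
    for e in net.edges:
        xa, ya = coords[e.id_a]
        xb, yb = coords[e.id_b]
        ax.plot([xa, xb], [ya, yb], color="0.8", lw=0.8, zorder=1)
    group_ids = sorted({g for g in group_of.values()})
    cmap = cm.get_cmap("tab10") if hasattr(cm, "get_cmap") else plt.get_cmap("tab10")
    colors = {g: cmap(k % 10) for k, g in enumerate(group_ids)}
    for n in net.nodes:
        g = group_of.get(n.mol_id)
        color = colors.get(g, "0.6")
        ax.scatter([n.x], [n.y], s=60, color=color, edgecolor="k", lw=0.4, zorder=2)
        if names:
            ax.annotate(names.get(n.mol_id, n.mol_id), (n.x, n.y), fontsize=5)
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 1.05)
    ax.set_aspect("equal")
    ax.set_title(f"chemical space network ({net.params.get('layout', '?')} layout)")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
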