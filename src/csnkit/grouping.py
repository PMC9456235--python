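"""Proximity-constrained compound grouping and the MWGS statistic.

Compound families are cut out of the t-SNE CSN by combining the two
similarity signals the network carries: edge connectivity (structural
similarity above the threshold) and embedded proximity (edge length in the
normalized t-SNE plane).  Edges longer than an edge-length threshold are
dropped, and the connected components of what remains are the candidate
groups.  Components smaller than ``min_group_size`` (default 3) are moved
to the unassigned set.

Within each surviving group, every member's mean within-group similarity

    MWGS = (Σᵢ Sᵢ − 1) / (n − 1)

is its average Dice similarity to the *other* members (the sum runs over
all n members including the self-similarity of 1, which is subtracted).
The member with the largest MWGS is the group's representative compound;
groups are conventionally labelled after it ("<representative> group").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .fingerprints import SimilarityMatrix
from .io import sort_key
from .network import ChemSpaceNetwork

logger = logging.getLogger(__name__)

DEFAULT_MIN_GROUP_SIZE = 3
DEFAULT_LENGTH_QUANTILE = 0.8


@dataclass
class CompoundGroup:
    """One clustered compound family."""

    group_id: int
    member_ids: list[str]
    mwgs_by_member: dict[str, float] = field(default_factory=dict)
    representative_id: str | None = None
    label: str | None = None

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class GroupingResult:
    groups: list[CompoundGroup]
    unassigned_ids: list[str]
    params: dict = field(default_factory=dict)

    def membership(self) -> dict[str, int]:
        """``mol_id -> group_id`` for assigned members only."""
        return {m: g.group_id for g in self.groups for m in g.member_ids}


def edge_length_at_quantile(net: ChemSpaceNetwork, quantile: float) -> float:
    """Edge-length threshold at a quantile of the embedded edge lengths."""
    if not net.edges:
        return 0.0
    lengths = [e.embedded_length for e in net.edges]
    if any(l is None for l in lengths):
        raise ValueError("network edges have no embedded lengths")
    return float(np.quantile(lengths, quantile))


def spatial_group(
    net: ChemSpaceNetwork, edge_length_threshold: float
) -> list[list[str]]:
    """Partition the node set by connectivity through short edges.

    Only edges with ``embedded_length <= edge_length_threshold`` are
    retained; the partition is the connected components of the remaining
    subgraph (nodes with no short edge become singletons).  Deterministic:
    components are ordered by descending size, then smallest member id,
    and members within a component are sorted.
    """
    g = nx.Graph()
    g.add_nodes_from(net.node_ids)
    for e in net.edges:
        if e.embedded_length is None:
            raise ValueError("network edges have no embedded lengths")
        if e.embedded_length <= edge_length_threshold:
            g.add_edge(e.id_a, e.id_b)
    components = [sorted(c, key=sort_key) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), sort_key(c[0])))
    return components


def filter_groups(
    partition: Sequence[Sequence[str]],
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> GroupingResult:
    """Drop components smaller than ``min_group_size`` into the unassigned set.

    Surviving groups are renumbered 1..k by descending size, ties broken
    by smallest member id.
    """
    if min_group_size < 1:
        raise ValueError("min_group_size must be >= 1")
    survivors = [list(c) for c in partition if len(c) >= min_group_size]
    unassigned = sorted(
        (m for c in partition if len(c) < min_group_size for m in c), key=sort_key
    )
    survivors.sort(key=lambda c: (-len(c), sort_key(min(c, key=sort_key))))
    groups = [
        CompoundGroup(group_id=k, member_ids=sorted(c, key=sort_key))
        for k, c in enumerate(survivors, start=1)
    ]
    return GroupingResult(
        groups=groups,
        unassigned_ids=unassigned,
        params={"min_group_size": min_group_size},
    )


def mwgs(
    group_members: Sequence[str],
    m: SimilarityMatrix,
    denominator: str = "n-1",
) -> dict[str, float]:
    """Mean within-group similarity of every member of a group.

    For a member with similarities Sᵢ to the n group members (including
    its self-similarity of 1), MWGS = (Σ Sᵢ − 1)/(n − 1): the mean
    similarity to the *other* members, so a group of identical molecules
    scores exactly 1.  ``denominator="n"`` divides by n instead, keeping
    the self term in the average's weight.

    Raises
    ------
    ValueError
        For a singleton group (undefined) or a member missing from the
        similarity matrix.
    """
    members = list(group_members)
    if len(members) < 2:
        raise ValueError("MWGS is undefined for groups of fewer than 2 members")
    if denominator not in ("n-1", "n"):
        raise ValueError(f"unknown MWGS denominator mode {denominator!r}")
    idx = [m.index_of(mol) for mol in members]
    sub = m.values[np.ix_(idx, idx)]
    n = len(members)
    sums = sub.sum(axis=1)
    denom = (n - 1) if denominator == "n-1" else n
    values = (sums - 1.0) / denom
    return {mol: float(v) for mol, v in zip(members, values)}


def select_representative(
    group_members: Sequence[str] | CompoundGroup,
    mwgs_values: Mapping[str, float],
) -> str:
    """The member with the largest MWGS; ties go to the smallest mol_id."""
    members = (
        group_members.member_ids
        if isinstance(group_members, CompoundGroup)
        else list(group_members)
    )
    best = max(mwgs_values[m] for m in members)
    winners = sorted((m for m in members if mwgs_values[m] == best), key=sort_key)
    if len(winners) > 1:
        logger.info(
            "MWGS tie at %.6f among %s; choosing %s", best, winners, winners[0]
        )
    return winners[0]


def annotate_groups(
    result: GroupingResult,
    m: SimilarityMatrix,
    names: Mapping[str, str] | None = None,
    denominator: str = "n-1",
) -> GroupingResult:
    """Fill in MWGS values, representatives and labels for every group."""
    names = names or {}
    for group in result.groups:
        group.mwgs_by_member = mwgs(group.member_ids, m, denominator=denominator)
        group.representative_id = select_representative(group, group.mwgs_by_member)
        rep_name = names.get(group.representative_id, str(group.representative_id))
        group.label = f"{rep_name} group"
    return result


def group_network(
    net: ChemSpaceNetwork,
    m: SimilarityMatrix,
    edge_length_threshold: float | None = None,
    edge_length_quantile: float = DEFAULT_LENGTH_QUANTILE,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
    names: Mapping[str, str] | None = None,
    denominator: str = "n-1",
) -> GroupingResult:
    """Full grouping pass over a network.

    When no absolute ``edge_length_threshold`` is given, it is set at the
    ``edge_length_quantile`` (default 0.8) of the embedded edge lengths,
    which prunes the long inter-cluster bridges while keeping local
    structure.
    """
    if edge_length_threshold is None:
        edge_length_threshold = edge_length_at_quantile(net, edge_length_quantile)
    partition = spatial_group(net, edge_length_threshold)
    result = filter_groups(partition, min_group_size=min_group_size)
    result.params.update(
        edge_length_threshold=edge_length_threshold,
        edge_length_quantile=edge_length_quantile,
        mwgs_denominator=denominator,
    )
    return annotate_groups(result, m, names=names, denominator=denominator)
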