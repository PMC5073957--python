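"""Grouping of charge clusters conserved across proteins.

Two same-polarity clusters from different proteins are linked when
their global-alignment identity reaches a threshold (default 1.0,
i.e. exact sequence identity — repeats of one cluster sequence across
strain variants of a protein). Connected components spanning at least
two distinct proteins are reported as conserved groups.

Identity is defined as (aligned matches) / (length of the longer
sequence), under a global alignment scoring match +1, mismatch 0,
gap 0; the maximal match count is then the longest common subsequence.
Dividing by the longer length penalizes length mismatch, so identity
1.0 means string equality.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import networkx as nx
from Bio import Align

from .model import ChargeCluster, ConservedGroup, Polarity

__all__ = [
    "cluster_similarity",
    "group_conserved",
    "summarize_conservation",
    "ConservationSummary",
]

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = 0
_aligner.open_gap_score = 0
_aligner.extend_gap_score = 0


def cluster_similarity(a: ChargeCluster, b: ChargeCluster) -> float:
    """Alignment identity between two same-polarity cluster sequences.

    Returns matches / max(len_a, len_b) in [0, 1]; 1.0 iff the
    sequences are identical.
    """
    if a.polarity is not b.polarity:
        raise ValueError("cannot compare clusters of opposite polarity")
    if a.sequence == b.sequence:
        return 1.0
    matches = _aligner.score(a.sequence, b.sequence)
    return matches / max(len(a.sequence), len(b.sequence))


def group_conserved(
    clusters: Sequence[ChargeCluster], identity_threshold: float = 1.0
) -> List[ConservedGroup]:
    """Group clusters whose sequences recur across >= 2 distinct proteins.

    Per polarity, clusters from different proteins with pairwise
    identity >= ``identity_threshold`` are joined; each connected
    component spanning at least two proteins becomes one group.
    Group ids are assigned deterministically by (polarity, smallest
    member protein_id, start), independent of input order.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    groups: List[Tuple[Polarity, List[ChargeCluster]]] = []
    for polarity in Polarity:
        members = sorted(
            (c for c in clusters if c.polarity is polarity),
            key=lambda c: (c.protein_id, c.start, c.end),
        )
        graph = nx.Graph()
        graph.add_nodes_from(range(len(members)))
        if identity_threshold == 1.0:
            # identity 1.0 is string equality: bucket by sequence
            buckets: Dict[str, List[int]] = {}
            for i, c in enumerate(members):
                buckets.setdefault(c.sequence, []).append(i)
            for bucket in buckets.values():
                graph.add_edges_from(zip(bucket, bucket[1:]))
        else:
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    if members[i].protein_id == members[j].protein_id:
                        continue
                    if cluster_similarity(members[i], members[j]) >= identity_threshold:
                        graph.add_edge(i, j)
        for component in nx.connected_components(graph):
            comp = sorted(component)
            proteins = {members[i].protein_id for i in comp}
            if len(proteins) < 2:
                continue
            groups.append((polarity, [members[i] for i in comp]))

    polarity_order = {Polarity.POSITIVE: 0, Polarity.NEGATIVE: 1}
    groups.sort(
        key=lambda g: (
            polarity_order[g[0]],
            min((m.protein_id, m.start) for m in g[1]),
        )
    )
    out = []
    for group_id, (polarity, members) in enumerate(groups, start=1):
        counts = Counter(m.sequence for m in members)
        top = max(counts.values())
        representative = min(s for s, n in counts.items() if n == top)
        out.append(
            ConservedGroup(
                group_id=group_id,
                polarity=polarity,
                members=tuple(members),
                n_proteins=len({m.protein_id for m in members}),
                representative_sequence=representative,
            )
        )
    return out


@dataclass(frozen=True)
class ConservationSummary:
    polarity: Polarity
    n_groups: int
    n_conserved_clusters: int
    n_proteins: int
    group_protein_counts: Tuple[int, ...]  # n_proteins per group, sorted


def summarize_conservation(
    groups: Sequence[ConservedGroup],
) -> Dict[Polarity, ConservationSummary]:
    """Per-polarity totals: conserved clusters, distinct proteins, sizes."""
    out = {}
    for polarity in Polarity:
        mine = [g for g in groups if g.polarity is polarity]
        proteins = {m.protein_id for g in mine for m in g.members}
        out[polarity] = ConservationSummary(
            polarity=polarity,
            n_groups=len(mine),
            n_conserved_clusters=sum(len(g.members) for g in mine),
            n_proteins=len(proteins),
            group_protein_counts=tuple(sorted(g.n_proteins for g in mine)),
        )
    return out
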