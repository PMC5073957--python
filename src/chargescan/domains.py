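"""Mapping of charge clusters relative to functional domains.

Each cluster is assigned exactly one positional category: N-terminal
(wholly before the first domain), within a domain, interdomain (wholly
inside a gap between domains), C-terminal (wholly after the last
domain), or unannotated when the protein has no domain annotation.
A cluster straddling a domain boundary is assigned by largest overlap,
with ties resolved in favour of the domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .model import ChargeCluster, DomainAnnotation, LocationCategory, Polarity

__all__ = [
    "DomainLayout",
    "normalize_domains",
    "build_layouts",
    "locate_cluster",
    "assign_locations",
    "location_contingency",
]

logger = logging.getLogger(__name__)

#: Fixed column order of the location contingency table.
CONTINGENCY_COLUMNS = (
    LocationCategory.DOMAIN,
    LocationCategory.N_TERMINAL,
    LocationCategory.INTERDOMAIN,
    LocationCategory.C_TERMINAL,
)


@dataclass(frozen=True)
class DomainLayout:
    """Merged, ordered domain intervals of one protein (1-based inclusive)."""

    protein_id: str
    merged_domains: Tuple[Tuple[int, int], ...]
    protein_length: int


def normalize_domains(
    annotations: Sequence[DomainAnnotation], protein_length: int
) -> DomainLayout:
    """Merge overlapping/adjacent domain intervals into a layout.

    Intervals are clipped to [1, protein_length]; intervals touching
    (gap 0) or overlapping are merged into one.
    """
    if not annotations:
        return DomainLayout("", (), protein_length)
    ids = {a.protein_id for a in annotations}
    if len(ids) > 1:
        raise ValueError(f"annotations span multiple proteins: {sorted(ids)}")
    protein_id = annotations[0].protein_id
    clipped = []
    for a in annotations:
        start, end = max(1, a.start), min(protein_length, a.end)
        if start > end:
            logger.warning(
                "domain %s on %s (%d-%d) lies outside the protein; skipped",
                a.domain_name, protein_id, a.start, a.end,
            )
            continue
        if end != a.end or start != a.start:
            logger.warning(
                "domain %s on %s clipped to (%d, %d)", a.domain_name, protein_id, start, end
            )
        clipped.append((start, end))
    merged: List[Tuple[int, int]] = []
    for start, end in sorted(clipped):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return DomainLayout(protein_id, tuple(merged), protein_length)


def build_layouts(
    annotations: Sequence[DomainAnnotation], protein_lengths: Dict[str, int]
) -> Dict[str, DomainLayout]:
    """Group annotations by protein and normalize each into a layout."""
    by_protein: Dict[str, List[DomainAnnotation]] = {}
    for a in annotations:
        by_protein.setdefault(a.protein_id, []).append(a)
    layouts = {}
    for protein_id, annots in by_protein.items():
        if protein_id not in protein_lengths:
            logger.warning("domain annotation for unknown protein %s ignored", protein_id)
            continue
        layouts[protein_id] = normalize_domains(annots, protein_lengths[protein_id])
    return layouts


def locate_cluster(cluster: ChargeCluster, layout: DomainLayout) -> LocationCategory:
    """Assign one positional category to a cluster given a domain layout.

    Majority-overlap rule for boundary-straddling clusters: the category
    (domain vs. the flanking region(s) the cluster touches) holding the
    most cluster residues wins; ties go to the domain.
    """
    domains = layout.merged_domains
    if not domains:
        return LocationCategory.UNANNOTATED
    start, end = cluster.start, cluster.end
    first_start = domains[0][0]
    last_end = domains[-1][1]
    if end < first_start:
        return LocationCategory.N_TERMINAL
    if start > last_end:
        return LocationCategory.C_TERMINAL

    in_domain = sum(
        max(0, min(end, d_end) - max(start, d_start) + 1) for d_start, d_end in domains
    )
    if in_domain == 0:
        # wholly inside one gap between two consecutive domains
        return LocationCategory.INTERDOMAIN

    length = cluster.length
    if in_domain == length:
        return LocationCategory.DOMAIN
    # straddles at least one boundary: count residues per flanking category
    overlaps = {
        LocationCategory.DOMAIN: in_domain,
        LocationCategory.N_TERMINAL: max(0, first_start - start),
        LocationCategory.C_TERMINAL: max(0, end - last_end),
    }
    interdomain = 0
    for (_, prev_end), (next_start, _) in zip(domains, domains[1:]):
        interdomain += max(0, min(end, next_start - 1) - max(start, prev_end + 1) + 1)
    overlaps[LocationCategory.INTERDOMAIN] = interdomain
    # ties resolve to DOMAIN because it is listed first
    order = (
        LocationCategory.DOMAIN,
        LocationCategory.N_TERMINAL,
        LocationCategory.INTERDOMAIN,
        LocationCategory.C_TERMINAL,
    )
    return max(order, key=lambda cat: (overlaps[cat], -order.index(cat)))


def assign_locations(
    clusters: Sequence[ChargeCluster], layouts: Dict[str, DomainLayout]
) -> List[ChargeCluster]:
    """Return clusters with their location category filled in.

    Clusters on proteins absent from ``layouts`` are ``unannotated``.
    """
    out = []
    for c in clusters:
        layout = layouts.get(c.protein_id)
        category = (
            locate_cluster(c, layout) if layout is not None else LocationCategory.UNANNOTATED
        )
        out.append(c.with_location(category))
    return out


def location_contingency(
    clusters: Sequence[ChargeCluster],
) -> Tuple[np.ndarray, int]:
    """2x4 location-by-polarity count table.

    Rows: positive, negative. Columns: domain, N-terminal, interdomain,
    C-terminal. Unannotated clusters are excluded from the table and
    returned as a separate count.
    """
    table = np.zeros((2, 4), dtype=np.int64)
    excluded = 0
    col_index = {cat: j for j, cat in enumerate(CONTINGENCY_COLUMNS)}
    for c in clusters:
        if c.location is None:
            raise ValueError(f"cluster on {c.protein_id!r} has no location assigned")
        if c.location is LocationCategory.UNANNOTATED:
            excluded += 1
            continue
        row = 0 if c.polarity is Polarity.POSITIVE else 1
        table[row, col_index[c.location]] += 1
    return table, excluded
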