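"""Readers and writers: FASTA proteomes, domain/metadata tables, cluster tables.

All tables are plain TSV with a header row (UTF-8, no quoting). Cluster
coordinates are written 1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Union

import pandas as pd
from Bio import SeqIO

from .model import (
    VALID_RESIDUES,
    ChargeCluster,
    DomainAnnotation,
    LocationCategory,
    Polarity,
    ProteinRecord,
)

__all__ = [
    "MetadataRow",
    "read_fasta",
    "write_fasta",
    "read_table",
    "read_domains",
    "read_metadata",
    "read_clusters",
    "write_clusters",
    "write_classifications",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class MetadataRow:
    """One proteome-metadata entry (virus name, family, genome group)."""

    protein_id: str
    virus: Optional[str] = None
    family: Optional[str] = None
    group: Optional[str] = None


def _parse_fasta_id(header_id: str) -> str:
    """Extract the accession from a UniProt-style ``db|ACC|NAME`` id."""
    parts = header_id.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return header_id


def _find_bad_sequence_line(path: PathLike, bad_char: str) -> int:
    """Locate the first sequence line containing ``bad_char`` (1-based)."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">"):
                continue
            if bad_char in line.upper():
                return lineno
    return -1


def read_fasta(path: PathLike) -> List[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    UniProt-style headers ``>db|ACC|NAME description`` yield ``id == ACC``;
    otherwise the first whitespace-delimited token is the id. Sequences
    are upper-cased; input order is preserved.

    Raises
    ------
    ValueError
        If the file contains no sequences, a duplicate id, or a
        non-letter character in a sequence.
    """
    records: List[ProteinRecord] = []
    seen = set()
    for seq_record in SeqIO.parse(str(path), "fasta"):
        rec_id = _parse_fasta_id(seq_record.id)
        if rec_id in seen:
            raise ValueError(f"duplicate protein id {rec_id!r} in {path}")
        seen.add(rec_id)
        sequence = str(seq_record.seq).upper()
        bad = set(sequence) - VALID_RESIDUES
        if bad:
            char = sorted(bad)[0]
            lineno = _find_bad_sequence_line(path, char)
            raise ValueError(
                f"invalid sequence character {char!r} in {path} "
                f"(line {lineno}, record {rec_id!r})"
            )
        description = seq_record.description
        # drop the id token from the description remainder
        if description.startswith(seq_record.id):
            description = description[len(seq_record.id) :].strip()
        records.append(ProteinRecord(id=rec_id, description=description, sequence=sequence))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(records: List[ProteinRecord], path: PathLike, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    with open(path, "w") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


_REQUIRED_COLUMNS = {
    "domains": ["protein_id", "domain_name", "start", "end"],
    "metadata": ["protein_id", "virus", "family", "group"],
    "clusters": [
        "protein_id",
        "polarity",
        "start",
        "end",
        "length",
        "charged_count",
        "net_charge",
        "min_window_p",
        "location",
        "cpp_candidate",
        "sequence",
    ],
}


def read_table(path: PathLike, kind: str) -> list:
    """Read a TSV table of the given ``kind``.

    ``kind`` is one of ``"domains"`` (-> :class:`DomainAnnotation`),
    ``"metadata"`` (-> :class:`MetadataRow`) or ``"clusters"``
    (-> :class:`ChargeCluster`). Unknown extra columns are ignored.
    """
    if kind not in _REQUIRED_COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    if kind == "domains":
        return _parse_domain_rows(df, path)
    if kind == "metadata":
        return [
            MetadataRow(
                protein_id=row.protein_id,
                virus=row.virus or None,
                family=row.family or None,
                group=row.group or None,
            )
            for row in df.itertuples()
        ]
    return _parse_cluster_rows(df, path)


def _parse_domain_rows(df: pd.DataFrame, path: PathLike) -> List[DomainAnnotation]:
    out = []
    for i, row in enumerate(df.itertuples(), start=2):  # line 1 is the header
        start, end = int(row.start), int(row.end)
        if start > end:
            raise ValueError(f"{path} row {i}: start {start} > end {end}")
        out.append(DomainAnnotation(row.protein_id, row.domain_name, start, end))
    return out


def _parse_cluster_rows(df: pd.DataFrame, path: PathLike) -> List[ChargeCluster]:
    out = []
    for i, row in enumerate(df.itertuples(), start=2):
        start, end = int(row.start), int(row.end)
        if start > end:
            raise ValueError(f"{path} row {i}: start {start} > end {end}")
        location = LocationCategory(row.location) if row.location else None
        out.append(
            ChargeCluster(
                protein_id=row.protein_id,
                polarity=Polarity(row.polarity),
                start=start,
                end=end,
                charged_count=int(row.charged_count),
                net_charge=int(row.net_charge),
                min_window_p=float(row.min_window_p),
                sequence=row.sequence,
                location=location,
                cpp_candidate=row.cpp_candidate == "true",
            )
        )
    return out


def read_domains(path: PathLike) -> List[DomainAnnotation]:
    return read_table(path, "domains")


def read_metadata(path: PathLike) -> List[MetadataRow]:
    return read_table(path, "metadata")


def read_clusters(path: PathLike) -> List[ChargeCluster]:
    return read_table(path, "clusters")


def write_clusters(clusters: List[ChargeCluster], path: PathLike) -> None:
    """Write a cluster table as TSV.

    Rows are sorted by (protein_id, start, polarity) so repeated runs
    produce byte-identical files. ``min_window_p`` is written in
    scientific notation with enough digits to round-trip exactly.
    """
    header = _REQUIRED_COLUMNS["clusters"]
    ordered = sorted(clusters, key=lambda c: (c.protein_id, c.start, c.polarity.value))
    with open(path, "w") as handle:
        handle.write("\t".join(header) + "\n")
        for c in ordered:
            if not math.isfinite(c.min_window_p):
                raise ValueError(f"cluster on {c.protein_id!r}: non-finite p-value")
            handle.write(
                "\t".join(
                    [
                        c.protein_id,
                        c.polarity.value,
                        str(c.start),
                        str(c.end),
                        str(c.length),
                        str(c.charged_count),
                        str(c.net_charge),
                        f"{c.min_window_p:.16e}",
                        c.location.value if c.location is not None else "",
                        "true" if c.cpp_candidate else "false",
                        c.sequence,
                    ]
                )
                + "\n"
            )


def write_classifications(classifications, path: PathLike) -> None:
    """Write protein-level labels (cc_free/pcc_only/ncc_only/mixed) as TSV."""
    ordered = sorted(classifications, key=lambda c: c.protein_id)
    with open(path, "w") as handle:
        handle.write("protein_id\tlabel\n")
        for c in ordered:
            handle.write(f"{c.protein_id}\t{c.label.value}\n")
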