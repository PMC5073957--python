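"""Core domain types for charge-cluster screening.

A charge cluster (CC) is a run of a protein sequence significantly
enriched in charged residues of one sign: positive (Lys, Arg; PCC) or
negative (Asp, Glu; NCC). Types here carry the detection parameters,
the detected clusters, the domain annotations used to map them, and
the protein-level classification labels.

All coordinates on these types are 1-based and inclusive, matching the
convention of protein feature tables.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "Polarity",
    "LocationCategory",
    "ProteinRecord",
    "DomainAnnotation",
    "ChargeCluster",
    "ScanConfig",
    "WindowStat",
    "ProteinLabel",
    "ProteinClassification",
    "ConservedGroup",
    "POSITIVE_RESIDUES",
    "NEGATIVE_RESIDUES",
]

#: Residues carrying a positive side-chain charge at physiological pH.
POSITIVE_RESIDUES = frozenset("KR")
#: Residues carrying a negative side-chain charge.
NEGATIVE_RESIDUES = frozenset("DE")

# 20 standard residues plus the ambiguity/rare letters B, Z, X, U, O, J.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" "BZXUOJ")


class Polarity(str, enum.Enum):
    """Charge sign of a cluster."""

    POSITIVE = "positive"
    NEGATIVE = "negative"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class LocationCategory(str, enum.Enum):
    """Position of a cluster relative to a protein's annotated domains."""

    N_TERMINAL = "n_terminal"
    DOMAIN = "domain"
    INTERDOMAIN = "interdomain"
    C_TERMINAL = "c_terminal"
    UNANNOTATED = "unannotated"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with optional virus metadata.

    Parameters
    ----------
    id
        Accession, unique within one loaded proteome set.
    description
        Free-text header remainder.
    sequence
        Upper-case amino-acid string; ambiguity letters are retained.
    virus, family, group
        Optional taxonomy labels (e.g. family ``Herpesviridae``, genome
        group ``dsDNA``).
    """

    id: str
    description: str = ""
    sequence: str = ""
    virus: Optional[str] = None
    family: Optional[str] = None
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainAnnotation:
    """A functional-domain interval on a protein (simplified Pfam hit)."""

    protein_id: str
    domain_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"domain {self.domain_name!r} on {self.protein_id!r}: "
                f"invalid interval ({self.start}, {self.end})"
            )


@dataclass(frozen=True)
class ScanConfig:
    """Detection parameters for the windowed binomial scan.

    Attributes
    ----------
    window_w
        Sliding-window width *w* (residues).
    alpha
        Per-window significance level for the binomial upper tail.
    background_mode
        How the null charge frequency p0 is obtained: ``"proteome"``
        (pooled over all records), ``"per_protein"`` (one p0 per
        record), or ``"fixed"`` (user-supplied).
    fixed_p0_pos, fixed_p0_neg
        Null frequencies used in ``fixed`` mode.
    positive_alphabet, negative_alphabet
        The residue sets defining each charge class.
    """

    window_w: int = 20
    alpha: float = 1e-5
    background_mode: str = "proteome"
    fixed_p0_pos: Optional[float] = None
    fixed_p0_neg: Optional[float] = None
    positive_alphabet: frozenset = POSITIVE_RESIDUES
    negative_alphabet: frozenset = NEGATIVE_RESIDUES

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.window_w < 2:
            raise ValueError(f"window_w must be >= 2, got {self.window_w}")
        if self.background_mode not in ("proteome", "per_protein", "fixed"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")
        object.__setattr__(self, "positive_alphabet", frozenset(self.positive_alphabet))
        object.__setattr__(self, "negative_alphabet", frozenset(self.negative_alphabet))
        if self.positive_alphabet & self.negative_alphabet:
            raise ValueError("polarity alphabets must be disjoint")

    def alphabet(self, polarity: Polarity) -> frozenset:
        return (
            self.positive_alphabet
            if polarity is Polarity.POSITIVE
            else self.negative_alphabet
        )

    def fixed_p0(self, polarity: Polarity) -> Optional[float]:
        return (
            self.fixed_p0_pos if polarity is Polarity.POSITIVE else self.fixed_p0_neg
        )


@dataclass(frozen=True)
class WindowStat:
    """Charged-residue count and binomial tail probability of one window."""

    start: int  # 1-based
    width: int
    k: int
    tail_p: float

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.width:
            raise ValueError(f"window count k={self.k} outside [0, {self.width}]")


@dataclass(frozen=True)
class ChargeCluster:
    """A detected charge cluster.

    ``start``/``end`` are 1-based inclusive; the cluster sequence begins
    and ends with a residue of its polarity class (trimming contract).
    ``min_window_p`` is the smallest binomial upper-tail probability among
    the significant windows that triggered the cluster.
    """

    protein_id: str
    polarity: Polarity
    start: int
    end: int
    charged_count: int
    net_charge: int
    min_window_p: float
    sequence: str
    location: Optional[LocationCategory] = None
    cpp_candidate: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"cluster on {self.protein_id!r}: invalid interval "
                f"({self.start}, {self.end})"
            )
        if len(self.sequence) != self.length:
            raise ValueError(
                f"cluster on {self.protein_id!r}: sequence length "
                f"{len(self.sequence)} != span {self.length}"
            )
        if self.charged_count < 1:
            raise ValueError("cluster must contain at least one charged residue")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def with_location(self, location: LocationCategory) -> "ChargeCluster":
        return replace(self, location=location)

    def with_cpp_flag(self, flag: bool) -> "ChargeCluster":
        return replace(self, cpp_candidate=flag)


class ProteinLabel(str, enum.Enum):
    """Protein-level classification by the cluster types it carries."""

    CC_FREE = "cc_free"
    PCC_ONLY = "pcc_only"
    NCC_ONLY = "ncc_only"
    MIXED = "mixed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ProteinClassification:
    protein_id: str
    label: ProteinLabel


@dataclass(frozen=True)
class ConservedGroup:
    """A set of same-polarity clusters shared across >= 2 proteins."""

    group_id: int
    polarity: Polarity
    members: tuple = field(default_factory=tuple)
    n_proteins: int = 0
    representative_sequence: str = ""

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise ValueError("a conserved group spans at least two proteins")
        if any(m.polarity is not self.polarity for m in self.members):
            raise ValueError("all group members must share the group polarity")
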