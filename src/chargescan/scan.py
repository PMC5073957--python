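"""Windowed binomial detection of charge clusters.

The detector slides a window of width ``w`` (default 20) along each
protein and counts residues of one charge class (positive: K/R;
negative: D/E). Under the null model the count in a window is
Binomial(w, p0), with p0 the background frequency of that class. A
window whose upper-tail probability P(X >= k) falls at or below the
significance level ``alpha`` (default 1e-5) is significant; maximal
runs of residues covered by significant windows, trimmed inward so
they start and end on a charged residue, are reported as charge
clusters. Because of the trimming, clusters may be shorter than ``w``.

Proteins shorter than ``w`` are evaluated as a single whole-sequence
window. Positive and negative scans are fully independent; a protein
carrying clusters of both signs is labelled ``mixed``.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .model import (
    ChargeCluster,
    Polarity,
    ProteinClassification,
    ProteinLabel,
    ProteinRecord,
    ScanConfig,
    WindowStat,
)

__all__ = [
    "encode_charge",
    "estimate_background",
    "binomial_tail",
    "critical_count",
    "window_stats",
    "scan_protein",
    "scan_proteome",
    "flag_cpp_candidates",
]

logger = logging.getLogger(__name__)


def encode_charge(
    sequence: str, polarity: Polarity, config: ScanConfig = ScanConfig()
) -> np.ndarray:
    """Binary indicator of the polarity class along ``sequence``.

    Position ``i`` is 1 iff residue ``i`` belongs to the polarity's
    alphabet; every other letter — including His and the ambiguity
    codes B/Z/X/U/O/J — is neutral (0).
    """
    alphabet = config.alphabet(polarity)
    return np.frombuffer(
        bytes(1 if ch in alphabet else 0 for ch in sequence), dtype=np.uint8
    ).copy()


def estimate_background(
    records: Sequence[ProteinRecord],
    polarity: Polarity,
    config: ScanConfig = ScanConfig(),
) -> Union[float, Dict[str, float]]:
    """Null per-residue frequency p0 of the polarity class.

    ``proteome`` mode pools all records (total class residues / total
    residues); ``per_protein`` returns a mapping id -> p0; ``fixed``
    returns the configured value.
    """
    if config.background_mode == "fixed":
        p0 = config.fixed_p0(polarity)
        if p0 is None:
            raise ValueError(
                f"background_mode='fixed' but no fixed p0 configured for {polarity}"
            )
        return p0
    if not records or sum(len(r) for r in records) == 0:
        raise ValueError("cannot estimate background from an empty proteome")
    alphabet = config.alphabet(polarity)
    if config.background_mode == "per_protein":
        return {
            r.id: sum(ch in alphabet for ch in r.sequence) / len(r) for r in records
        }
    total = sum(len(r) for r in records)
    charged = sum(sum(ch in alphabet for ch in r.sequence) for r in records)
    return charged / total


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Upper-tail probability P(X >= k) for X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0={p0} outside [0, 1]")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def critical_count(w: int, p0: float, alpha: float) -> Union[int, None]:
    """Smallest count k* in [0, w] with P(X >= k*) <= alpha.

    Returns ``None`` when even a fully charged window (k = w) is not
    significant at ``alpha``.
    """
    if w < 1:
        raise ValueError(f"window width must be >= 1, got {w}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    # tail is non-increasing in k, so bisect over k = 0..w
    tails = stats.binom.sf(np.arange(-1, w), w, p0)  # tails[k] = P(X >= k)
    hits = np.nonzero(tails <= alpha)[0]
    if hits.size == 0:
        return None
    return int(hits[0])


def window_stats(
    sequence: str, polarity: Polarity, p0: float, config: ScanConfig = ScanConfig()
) -> List[WindowStat]:
    """Per-window class counts and tail probabilities (diagnostic view)."""
    indicator = encode_charge(sequence, polarity, config)
    width = min(config.window_w, len(sequence))
    counts = _window_counts(indicator, width)
    return [
        WindowStat(start=i + 1, width=width, k=int(k), tail_p=binomial_tail(int(k), width, p0))
        for i, k in enumerate(counts)
    ]


def _window_counts(indicator: np.ndarray, width: int) -> np.ndarray:
    """Class-residue count of every window of ``width`` (vectorised)."""
    cumsum = np.concatenate([[0], np.cumsum(indicator, dtype=np.int64)])
    return cumsum[width:] - cumsum[: len(indicator) - width + 1]


def scan_protein(
    record: ProteinRecord,
    polarity: Polarity,
    p0: float,
    config: ScanConfig = ScanConfig(),
) -> List[ChargeCluster]:
    """Detect charge clusters of one polarity in one protein.

    Every window of width ``min(w, L)`` is tested; residues covered by
    at least one significant window are unioned; each maximal
    contiguous covered run, trimmed to charged boundaries, becomes one
    cluster. Reported clusters are disjoint and sorted by start.
    """
    sequence = record.sequence
    length = len(sequence)
    width = min(config.window_w, length)
    indicator = encode_charge(sequence, polarity, config)
    kstar = critical_count(width, p0, config.alpha)
    if kstar is None:
        return []
    counts = _window_counts(indicator, width)
    significant = np.nonzero(counts >= kstar)[0]  # 0-based window starts
    if significant.size == 0:
        return []

    covered = np.zeros(length, dtype=bool)
    for i in significant:
        covered[i : i + width] = True

    pos_alphabet = config.positive_alphabet
    neg_alphabet = config.negative_alphabet
    clusters: List[ChargeCluster] = []
    for run_start, run_end in _contiguous_runs(covered):
        # trim inward to the first/last residue of the polarity class
        charged_idx = np.nonzero(indicator[run_start : run_end + 1])[0]
        if charged_idx.size == 0:  # guarded; cannot occur when kstar >= 1
            logger.warning(
                "dropping candidate region %d-%d on %s: no %s residues",
                run_start + 1,
                run_end + 1,
                record.id,
                polarity.value,
            )
            continue
        start = run_start + int(charged_idx[0])
        end = run_start + int(charged_idx[-1])
        in_run = significant[(significant >= run_start) & (significant + width - 1 <= run_end)]
        max_k = int(counts[in_run].max())
        segment = sequence[start : end + 1]
        n_pos = sum(ch in pos_alphabet for ch in segment)
        n_neg = sum(ch in neg_alphabet for ch in segment)
        clusters.append(
            ChargeCluster(
                protein_id=record.id,
                polarity=polarity,
                start=start + 1,
                end=end + 1,
                charged_count=n_pos if polarity is Polarity.POSITIVE else n_neg,
                net_charge=n_pos - n_neg,
                min_window_p=binomial_tail(max_k, width, p0),
                sequence=segment,
            )
        )
    return clusters


def _contiguous_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True in ``mask`` as 0-based inclusive (start, end)."""
    padded = np.concatenate([[0], mask.view(np.int8), [0]])
    diff = np.diff(padded)
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def scan_proteome(
    records: Sequence[ProteinRecord], config: ScanConfig = ScanConfig()
) -> Tuple[List[ChargeCluster], List[ProteinClassification]]:
    """Scan every record for both polarities and classify each protein.

    Background p0 is estimated once per polarity according to
    ``config.background_mode``. Opposite-polarity clusters may overlap;
    there is no cross-polarity suppression.
    """
    backgrounds = {
        pol: estimate_background(records, pol, config) for pol in Polarity
    }
    clusters: List[ChargeCluster] = []
    classifications: List[ProteinClassification] = []
    for record in records:
        per_polarity = {}
        for pol in Polarity:
            p0 = backgrounds[pol]
            if isinstance(p0, dict):
                p0 = p0[record.id]
            per_polarity[pol] = scan_protein(record, pol, p0, config)
            clusters.extend(per_polarity[pol])
        has_pos = bool(per_polarity[Polarity.POSITIVE])
        has_neg = bool(per_polarity[Polarity.NEGATIVE])
        label = (
            ProteinLabel.MIXED
            if has_pos and has_neg
            else ProteinLabel.PCC_ONLY
            if has_pos
            else ProteinLabel.NCC_ONLY
            if has_neg
            else ProteinLabel.CC_FREE
        )
        classifications.append(ProteinClassification(record.id, label))
    return flag_cpp_candidates(clusters), classifications


#: Length window (aa) for cell-penetrating-peptide candidates.
CPP_MIN_LENGTH = 7
CPP_MAX_LENGTH = 30


def flag_cpp_candidates(clusters: List[ChargeCluster]) -> List[ChargeCluster]:
    """Flag positive clusters of 7-30 aa as cell-penetrating-peptide
    candidates; all other clusters get ``cpp_candidate = False``.

    Short cationic peptides in this length range are the classical CPP
    profile; negative clusters are never flagged.
    """
    return [
        c.with_cpp_flag(
            c.polarity is Polarity.POSITIVE
            and CPP_MIN_LENGTH <= c.length <= CPP_MAX_LENGTH
        )
        for c in clusters
    ]
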