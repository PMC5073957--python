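"""Comparative statistics over detected charge clusters.

Covers the contingency analysis of cluster locations by polarity
(Pearson chi-square, with an optional Monte Carlo permutation p-value
under fixed margins), two-group length comparisons (Welch t-test with
a Mann-Whitney companion), one-way ANOVA of lengths across virus
groups/families, and per-family / per-group summary tables including
the NCC:PCC ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .io import MetadataRow
from .model import ChargeCluster, Polarity, ProteinClassification, ProteinLabel

__all__ = [
    "ContingencyResult",
    "TwoGroupResult",
    "AnovaResult",
    "GroupSummary",
    "OverallSummary",
    "chi_square_independence",
    "compare_two_groups",
    "anova_lengths",
    "summarize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyResult:
    statistic: float
    df: int
    p_value: float
    method: str  # "pearson_chi2" or "monte_carlo"


def chi_square_independence(
    table,
    method: str = "pearson_chi2",
    mc_reps: int = 100_000,
    seed: Optional[int] = None,
) -> ContingencyResult:
    """Chi-square test of independence on an r x c count table.

    ``pearson_chi2`` gives the classical asymptotic p-value with
    df = (r-1)(c-1). ``monte_carlo`` estimates the p-value by sampling
    ``mc_reps`` tables with the observed margins (Patefield's
    algorithm) and counting statistics at least as large; the estimate
    uses the (b+1)/(m+1) permutation convention.
    """
    observed = np.asarray(table, dtype=np.int64)
    if observed.ndim != 2 or observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (observed < 0).any():
        raise ValueError("contingency table must be non-negative")
    row_margins = observed.sum(axis=1)
    col_margins = observed.sum(axis=0)
    if (row_margins == 0).any() or (col_margins == 0).any():
        raise ValueError("degenerate table: a row or column marginal is zero")
    expected = np.outer(row_margins, col_margins) / observed.sum()
    statistic = float(((observed - expected) ** 2 / expected).sum())
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    if method == "pearson_chi2":
        p_value = float(sps.chi2.sf(statistic, df))
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        sampler = sps.random_table(row_margins, col_margins, seed=rng)
        samples = sampler.rvs(mc_reps)  # (reps, r, c)
        sim = ((samples - expected) ** 2 / expected).sum(axis=(1, 2))
        exceed = int((sim >= statistic - 1e-12).sum())
        p_value = (exceed + 1) / (mc_reps + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ContingencyResult(statistic=statistic, df=df, p_value=p_value, method=method)


@dataclass(frozen=True)
class TwoGroupResult:
    t_statistic: float
    t_p_value: float
    u_statistic: float
    u_p_value: float


def compare_two_groups(
    lengths_a: Sequence[float], lengths_b: Sequence[float]
) -> TwoGroupResult:
    """Welch two-sample t-test plus Mann-Whitney U on two length samples.

    Both p-values are two-sided. The nonparametric companion guards the
    t-test against the heavy right tail typical of protein lengths.
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    for name, x in (("a", a), ("b", b)):
        if x.size < 2:
            raise ValueError(f"group {name}: need at least 2 values, got {x.size}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        # identical constant samples: define t = 0, p = 1
        u = sps.mannwhitneyu(a, b, alternative="two-sided")
        return TwoGroupResult(0.0, 1.0, float(u.statistic), float(u.pvalue))
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance; t-test undefined")
    t = sps.ttest_ind(a, b, equal_var=False)
    u = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TwoGroupResult(
        float(t.statistic), float(t.pvalue), float(u.statistic), float(u.pvalue)
    )


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


def anova_lengths(groups: Dict[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA of lengths across named groups."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    samples = []
    for key, values in groups.items():
        x = np.asarray(values, dtype=float)
        if x.size < 2:
            raise ValueError(f"group {key!r}: need at least 2 values, got {x.size}")
        samples.append(x)
    pooled = np.concatenate(samples)
    within = sum(((x - x.mean()) ** 2).sum() for x in samples)
    if within == 0:
        if all(math.isclose(x.mean(), pooled.mean()) for x in samples):
            return AnovaResult(0.0, len(samples) - 1, pooled.size - len(samples), 1.0)
        raise ValueError("zero within-group variance; F undefined")
    res = sps.f_oneway(*samples)
    return AnovaResult(
        f_statistic=float(res.statistic),
        df_between=len(samples) - 1,
        df_within=pooled.size - len(samples),
        p_value=float(res.pvalue),
    )


@dataclass(frozen=True)
class GroupSummary:
    """Cluster and protein summaries for one virus family or genome group."""

    key: str
    level: str  # "family", "group" or "all"
    n_proteins: int
    n_pcc: int
    n_ncc: int
    mean_protein_length: float
    sd_protein_length: float
    mean_cluster_length: float
    sd_cluster_length: float
    ncc_pcc_ratio: Optional[float]  # None when n_pcc == 0


@dataclass(frozen=True)
class OverallSummary:
    n_proteins: int
    n_pcc: int
    n_ncc: int
    n_clusters: int
    cc_free_count: int
    cc_free_fraction: float
    mixed_count: int
    pcc_only_count: int
    ncc_only_count: int
    min_cluster_length: Optional[int]
    max_cluster_length: Optional[int]
    mean_pcc_length: float
    sd_pcc_length: float
    mean_ncc_length: float
    sd_ncc_length: float


def _mean_sd(values: Sequence[float]) -> Tuple[float, float]:
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return float("nan"), float("nan")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return float(x.mean()), sd


def summarize(
    clusters: Sequence[ChargeCluster],
    classifications: Sequence[ProteinClassification],
    metadata: Sequence[MetadataRow],
    protein_lengths: Dict[str, int],
) -> Tuple[List[GroupSummary], OverallSummary]:
    """Per-family and per-genome-group summaries plus proteome totals.

    One row per family and per genome group present in the metadata,
    plus an ``all`` row. Proteins missing from the metadata are grouped
    under ``unknown``. Rows are deterministically ordered by
    (level, key); per-level counts are additive to the ``all`` row.
    """
    meta_by_id = {m.protein_id: m for m in metadata}
    known_ids = {c.protein_id for c in classifications}
    unknown = {c.protein_id for c in clusters} - set(meta_by_id) | (
        known_ids - set(meta_by_id) if metadata else set()
    )
    if metadata and unknown:
        logger.warning(
            "%d protein id(s) missing from metadata; grouped under 'unknown'",
            len(unknown),
        )

    def keys_for(protein_id: str, level: str) -> str:
        m = meta_by_id.get(protein_id)
        value = getattr(m, "family" if level == "family" else "group", None) if m else None
        return value if value else "unknown"

    rows: List[GroupSummary] = []
    for level in ("family", "group"):
        buckets: Dict[str, Dict[str, list]] = {}
        for c in classifications:
            key = keys_for(c.protein_id, level)
            bucket = buckets.setdefault(key, {"proteins": [], "clusters": []})
            bucket["proteins"].append(c.protein_id)
        for cl in clusters:
            key = keys_for(cl.protein_id, level)
            buckets.setdefault(key, {"proteins": [], "clusters": []})["clusters"].append(cl)
        for key in sorted(buckets):
            bucket = buckets[key]
            n_pcc = sum(c.polarity is Polarity.POSITIVE for c in bucket["clusters"])
            n_ncc = sum(c.polarity is Polarity.NEGATIVE for c in bucket["clusters"])
            plen_mean, plen_sd = _mean_sd(
                [protein_lengths[p] for p in bucket["proteins"] if p in protein_lengths]
            )
            clen_mean, clen_sd = _mean_sd([c.length for c in bucket["clusters"]])
            rows.append(
                GroupSummary(
                    key=key,
                    level=level,
                    n_proteins=len(bucket["proteins"]),
                    n_pcc=n_pcc,
                    n_ncc=n_ncc,
                    mean_protein_length=plen_mean,
                    sd_protein_length=plen_sd,
                    mean_cluster_length=clen_mean,
                    sd_cluster_length=clen_sd,
                    ncc_pcc_ratio=n_ncc / n_pcc if n_pcc > 0 else None,
                )
            )

    n_pcc_all = sum(c.polarity is Polarity.POSITIVE for c in clusters)
    n_ncc_all = len(clusters) - n_pcc_all
    plen_mean, plen_sd = _mean_sd(
        [protein_lengths[c.protein_id] for c in classifications if c.protein_id in protein_lengths]
    )
    clen_mean, clen_sd = _mean_sd([c.length for c in clusters])
    rows.append(
        GroupSummary(
            key="all",
            level="all",
            n_proteins=len(classifications),
            n_pcc=n_pcc_all,
            n_ncc=n_ncc_all,
            mean_protein_length=plen_mean,
            sd_protein_length=plen_sd,
            mean_cluster_length=clen_mean,
            sd_cluster_length=clen_sd,
            ncc_pcc_ratio=n_ncc_all / n_pcc_all if n_pcc_all > 0 else None,
        )
    )

    label_counts = {label: 0 for label in ProteinLabel}
    for c in classifications:
        label_counts[c.label] += 1
    pcc_lengths = [c.length for c in clusters if c.polarity is Polarity.POSITIVE]
    ncc_lengths = [c.length for c in clusters if c.polarity is Polarity.NEGATIVE]
    pcc_mean, pcc_sd = _mean_sd(pcc_lengths)
    ncc_mean, ncc_sd = _mean_sd(ncc_lengths)
    all_lengths = [c.length for c in clusters]
    overall = OverallSummary(
        n_proteins=len(classifications),
        n_pcc=n_pcc_all,
        n_ncc=n_ncc_all,
        n_clusters=len(clusters),
        cc_free_count=label_counts[ProteinLabel.CC_FREE],
        cc_free_fraction=(
            label_counts[ProteinLabel.CC_FREE] / len(classifications)
            if classifications
            else float("nan")
        ),
        mixed_count=label_counts[ProteinLabel.MIXED],
        pcc_only_count=label_counts[ProteinLabel.PCC_ONLY],
        ncc_only_count=label_counts[ProteinLabel.NCC_ONLY],
        min_cluster_length=min(all_lengths) if all_lengths else None,
        max_cluster_length=max(all_lengths) if all_lengths else None,
        mean_pcc_length=pcc_mean,
        sd_pcc_length=pcc_sd,
        mean_ncc_length=ncc_mean,
        sd_ncc_length=ncc_sd,
    )
    rows.sort(key=lambda r: ({"family": 0, "group": 1, "all": 2}[r.level], r.key))
    return rows, overall
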