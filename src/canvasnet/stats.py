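"""Statistical tests used across the analyses.

Mann-Whitney U for group expression comparisons, Fisher / chi-squared for
2x2 contingency tables (with odds ratios), a width- and chromosome-preserving
permutation test for region-set overlap (community vs TAD style questions),
and Benjamini-Hochberg correction for lists of results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    alternative: str


def mann_whitney_u(
    group1, group2, alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U test (U reported for group1).

    Uses the exact null distribution when min(n1, n2) <= 8 and there are no
    ties across the pooled sample; otherwise the normal approximation with tie
    and continuity corrections. Two identical constant groups give p = 1.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return TestResult(x.size * y.size / 2, 1.0, "degenerate", x.size, y.size, alternative)
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return TestResult(
        float(res.statistic), float(res.pvalue), method, x.size, y.size, alternative
    )


@dataclass
class ContingencyResult:
    """2x2 table with odds ratio and a Fisher or chi-squared p-value."""

    table: np.ndarray
    odds_ratio: float
    log2_odds_ratio: float
    method: str
    p_value: float
    alternative: str
    continuity_corrected: bool  # 0.5 added to every cell for the OR

    def as_dict(self) -> dict:
        a, b = self.table[0]
        c, d = self.table[1]
        return {
            "n11": int(a), "n12": int(b), "n21": int(c), "n22": int(d),
            "odds_ratio": self.odds_ratio,
            "log2_odds_ratio": self.log2_odds_ratio,
            "method": self.method,
            "p_value": self.p_value,
            "alternative": self.alternative,
            "or_continuity_corrected": self.continuity_corrected,
        }


def odds_ratio(table) -> tuple[float, float, bool]:
    """Sample odds ratio ad/bc with a 0.5 continuity correction (flagged)
    when any cell is zero."""
    t = np.asarray(table, dtype=float)
    corrected = bool((t == 0).any())
    if corrected:
        t = t + 0.5
    orr = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(orr), float(np.log2(orr)), corrected


def fisher_or_chisq(
    table, prefer: str = "auto", alternative: str = "two-sided"
) -> ContingencyResult:
    """Contingency test on a 2x2 table of non-negative integer counts.

    ``prefer="auto"`` uses the chi-squared test (without continuity
    correction) when every expected cell is at least 5, and Fisher's exact
    test otherwise. A table with a zero margin has no evidence either way:
    p = 1, odds ratio undefined (NaN).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return ContingencyResult(t, float("nan"), float("nan"), "degenerate", 1.0, alternative, False)
    orr, log2_orr, corrected = odds_ratio(t)
    if prefer == "auto":
        n = t.sum()
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
        prefer = "chi_squared" if (expected >= 5).all() else "fisher"
    if prefer == "chi_squared":
        if alternative != "two-sided":
            raise ValueError("chi-squared test is two-sided; use prefer='fisher'")
        stat, p, _, _ = sps.chi2_contingency(t, correction=False)
        return ContingencyResult(t, orr, log2_orr, "chi_squared", float(p), alternative, corrected)
    if prefer == "fisher":
        alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
        _, p = sps.fisher_exact(t, alternative=alt)
        return ContingencyResult(t, orr, log2_orr, "fisher", float(p), alternative, corrected)
    raise ValueError(f"unknown test preference {prefer!r}")


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")


def shortest_distance_per_cell(distances: pd.DataFrame) -> pd.Series:
    """Per-cell shortest spot-pair distance for DNA-FISH quantitation.

    ``distances`` has columns ``cell`` and ``distance`` with one row per
    measured signal pair; cells contribute their minimum distance to the
    final analysis. Cells with no measured pair are simply absent.
    """
    if (distances["distance"] < 0).any():
        raise ValueError("negative distance")
    return distances.groupby("cell")["distance"].min()


# ---------------------------------------------------------------------------
# permutation overlap test


def _merge_intervals(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = {}
    for chrom, sub in df.groupby("chrom"):
        sub = sub.sort_values("start")
        starts, ends = [], []
        for s, e in zip(sub["start"].values, sub["end"].values):
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.array(starts), np.array(ends))
    return merged


def count_overlapping(query: pd.DataFrame, reference: pd.DataFrame) -> int:
    """Number of query regions overlapping at least one reference region."""
    merged = _merge_intervals(reference)
    n = 0
    for chrom, sub in query.groupby("chrom"):
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        qs = sub["start"].values
        qe = sub["end"].values
        idx = np.searchsorted(starts, qe, side="left") - 1
        ok = (idx >= 0) & (np.where(idx >= 0, ends[np.clip(idx, 0, None)], 0) > qs)
        n += int(ok.sum())
    return n


@dataclass
class PermutationOverlapResult:
    observed: int
    null_mean: float
    null_sd: float
    z_score: float
    p_value: float  # empirical, (1 + #{null >= observed}) / (N + 1)
    n_permutations: int
    seed: int
    strategy: str


def permutation_overlap_test(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    genome: dict[str, int],
    n_permutations: int = 1000,
    seed: int = 0,
    strategy: str = "uniform",
) -> PermutationOverlapResult:
    """Permutation test for overlap between two region sets.

    The observed statistic is the number of query regions overlapping at
    least one reference region. The null redraws each query region's position
    ``n_permutations`` times, preserving its width and chromosome: uniformly
    within the chromosome (``strategy="uniform"``) or by a circular shift of
    all regions on a chromosome by one shared random offset
    (``strategy="circular"``). The empirical p-value uses the +1 pseudocount
    convention and is therefore never zero.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if strategy not in {"uniform", "circular"}:
        raise ValueError(f"unknown randomisation strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    observed = count_overlapping(query, reference)
    merged_ref = _merge_intervals(reference)
    null = np.zeros(n_permutations, dtype=int)
    by_chrom = {
        chrom: (sub["start"].values.copy(), (sub["end"] - sub["start"]).values)
        for chrom, sub in query.groupby("chrom")
    }
    for i in range(n_permutations):
        total = 0
        for chrom, (starts, widths) in by_chrom.items():
            size = genome[chrom]
            if strategy == "uniform":
                max_start = size - widths
                if (max_start < 0).any():
                    raise ValueError(f"query region wider than chromosome {chrom}")
                new_starts = (rng.random(len(widths)) * (max_start + 1)).astype(np.int64)
            else:
                shift = int(rng.integers(0, size))
                new_starts = (starts + shift) % np.maximum(size - widths, 1)
            if chrom not in merged_ref:
                continue
            ms, me = merged_ref[chrom]
            idx = np.searchsorted(ms, new_starts + widths, side="left") - 1
            ok = (idx >= 0) & (np.where(idx >= 0, me[np.clip(idx, 0, None)], 0) > new_starts)
            total += int(ok.sum())
        null[i] = total
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if n_permutations > 1 else 0.0
    diff = observed - mean
    if sd > 0:
        z = diff / sd
    elif diff == 0:
        z = 0.0
    else:
        z = math.copysign(math.inf, diff)
    p = (1 + int((null >= observed).sum())) / (n_permutations + 1)
    return PermutationOverlapResult(
        observed, mean, sd, float(z), float(p), n_permutations, seed, strategy
    )
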