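"""Composite OCT4/SOX2/NANOG (OSN) occupancy and interaction-change coupling.

OSN peaks are built by merging the three factors' peak sets (gap strictly
below the merge distance, 100 bp by default) and keeping only merged regions
supported by a peak of every factor. Their condition specificity, chromatin
state context and association with interaction rewiring (2x2 odds ratios,
chi-squared / Fisher) are computed here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chromatin import BACKGROUND, FRAGMENT_LABELS
from .genome_io import SegmentationTrack
from .stats import ContingencyResult, fisher_or_chisq

logger = logging.getLogger(__name__)

OSN_CHANGES = ("lost", "gained", "retained", "never")
INTERACTION_CHANGES = ("lost", "gained", "retained")


@dataclass
class OSNPeak:
    """A merged region occupied by all three of OCT4, SOX2 and NANOG."""

    chrom: str
    start: int
    end: int
    factors: tuple[str, ...]
    condition: str

    @property
    def centre(self) -> int:
        return (self.start + self.end) // 2


def _merge_with_gap(df: pd.DataFrame, merge_distance: int) -> list[dict]:
    """Merge intervals transitively when the gap is strictly below
    ``merge_distance`` (touching or overlapping intervals always merge)."""
    out: list[dict] = []
    cur = None
    for row in df.sort_values(["chrom", "start", "end"]).itertuples(index=False):
        if cur is not None and row.chrom == cur["chrom"] and row.start - cur["end"] < merge_distance:
            cur["end"] = max(cur["end"], row.end)
            cur["factors"].add(row.factor)
        else:
            if cur is not None:
                out.append(cur)
            cur = {"chrom": row.chrom, "start": row.start, "end": row.end,
                   "factors": {row.factor}}
    if cur is not None:
        out.append(cur)
    return out


def build_osn_peaks(
    peaks_oct4: pd.DataFrame,
    peaks_sox2: pd.DataFrame,
    peaks_nanog: pd.DataFrame,
    merge_distance: int = 100,
    condition: str = "",
) -> list[OSNPeak]:
    """Composite OSN peaks: union-merge of the three factors' peaks, keeping
    merged regions that contain at least one original peak of each factor.

    Each peak DataFrame needs columns chrom, start, end. An empty factor set
    empties the result (with a warning).
    """
    named = []
    for df, factor in ((peaks_oct4, "OCT4"), (peaks_sox2, "SOX2"), (peaks_nanog, "NANOG")):
        if df.empty:
            warnings.warn(f"no {factor} peaks: OSN peak set is empty", stacklevel=2)
            return []
        d = df[["chrom", "start", "end"]].copy()
        d["factor"] = factor
        named.append(d)
    merged = _merge_with_gap(pd.concat(named, ignore_index=True), merge_distance)
    peaks = [
        OSNPeak(m["chrom"], int(m["start"]), int(m["end"]),
                tuple(sorted(m["factors"])), condition)
        for m in merged
        if m["factors"] == {"OCT4", "SOX2", "NANOG"}
    ]
    return peaks


def filter_peaks_by_signal(
    peaks: pd.DataFrame,
    signal_windows: pd.DataFrame,
    window: int = 500,
    min_log2_rpm: float = 0.0,
) -> pd.DataFrame:
    """Keep peaks overlapping at least one fixed-width signal window above
    threshold.

    ``signal_windows`` has columns chrom, start, value with windows tiled at
    ``window`` bp (non-sliding, aligned to position 0 by default upstream);
    windows missing from the table count as below threshold.
    """
    above = signal_windows[signal_windows["value"] > min_log2_rpm]
    keys = {
        (c, s) for c, s in zip(above["chrom"].values, above["start"].values)
    }
    keep = []
    for row in peaks.itertuples(index=False):
        first = (row.start // window) * window
        hit = any(
            (row.chrom, w) in keys for w in range(first, row.end, window)
        )
        keep.append(hit)
    return peaks[np.array(keep, dtype=bool)].reset_index(drop=True)


def classify_osn_specificity(
    osn_a: list[OSNPeak], osn_b: list[OSNPeak], min_overlap: int = 1
) -> tuple[dict[int, str], dict[int, str]]:
    """Per-peak shared/specific labels by cross-condition overlap (>= 1 bp).

    Returns two dicts (index -> label) for the A and B peak lists.
    """
    def label(peaks, others, own, other_name):
        by_chrom: dict[str, list[OSNPeak]] = {}
        for p in others:
            by_chrom.setdefault(p.chrom, []).append(p)
        out = {}
        for i, p in enumerate(peaks):
            hit = any(
                min(p.end, q.end) - max(p.start, q.start) >= min_overlap
                for q in by_chrom.get(p.chrom, [])
            )
            out[i] = "shared" if hit else own
        return out

    return (
        label(osn_a, osn_b, "A_specific", "B"),
        label(osn_b, osn_a, "B_specific", "A"),
    )


def state_overlap_matrix(
    peak_sets: dict[str, list[OSNPeak] | pd.DataFrame],
    segmentations: dict[str, SegmentationTrack],
) -> pd.DataFrame:
    """Percentage of peaks per chromatin state, one column per peak set.

    Each peak is assigned the state at its centre base in the segmentation
    named by the column's condition suffix (``peak_sets`` keys are
    ``"<label>:<condition>"``); uncovered centres are background. Columns sum
    to 100 where populated.
    """
    cols = {}
    for key, peaks in peak_sets.items():
        label, _, condition = key.partition(":")
        seg = segmentations[condition]
        counts = {s: 0 for s in FRAGMENT_LABELS}
        if isinstance(peaks, pd.DataFrame):
            centres = [
                (r.chrom, (int(r.start) + int(r.end)) // 2)
                for r in peaks.itertuples(index=False)
            ]
        else:
            centres = [(p.chrom, p.centre) for p in peaks]
        for chrom, centre in centres:
            state = seg.state_at(chrom, centre) or BACKGROUND
            counts[state] += 1
        total = sum(counts.values())
        cols[key] = {
            s: (100 * c / total if total else np.nan) for s, c in counts.items()
        }
    return pd.DataFrame(cols).reindex(list(FRAGMENT_LABELS))


def sample_control_regions(
    genome: dict[str, int],
    n: int = 10_000,
    width: int = 1200,
    seed: int = 0,
    exclude: pd.DataFrame | None = None,
    max_attempts: int = 100,
) -> pd.DataFrame:
    """Randomly placed fixed-width control regions, seed-reproducible.

    Regions are sampled uniformly over the covered genome (chromosome chosen
    proportionally to its length), entirely within chromosome bounds. When an
    exclusion list is given, overlapping draws are rejected and redrawn.
    """
    total = sum(genome.values())
    if total < n * width:
        raise ValueError("genome too short for the requested control regions")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    probs = np.array([genome[c] - width + 1 for c in chroms], dtype=float)
    if (probs <= 0).any():
        raise ValueError("control width exceeds a chromosome length")
    probs /= probs.sum()
    excl = None
    if exclude is not None and not exclude.empty:
        from .stats import _merge_intervals

        excl = _merge_intervals(exclude)
    rows = []
    for _ in range(n):
        for _attempt in range(max_attempts):
            c = chroms[int(rng.choice(len(chroms), p=probs))]
            start = int(rng.integers(0, genome[c] - width + 1))
            if excl and c in excl:
                ms, me = excl[c]
                i = int(np.searchsorted(ms, start + width, side="left")) - 1
                if i >= 0 and me[i] > start:
                    continue
            rows.append((c, start, start + width))
            break
        else:
            raise RuntimeError("could not place control region outside exclusions")
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def osn_interaction_contingency(
    changes: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[tuple[str, str], ContingencyResult]]:
    """Association between OSN occupancy change and interaction change.

    ``changes`` has one row per enhancer fragment with columns ``osn_change``
    (lost / gained / retained / never) and ``interaction_change`` (lost /
    gained / retained). Returns the full 4x3 count matrix, its row-wise
    percentages, and for every (OSN class, interaction class) pair the 2x2
    collapse (this cell vs the rest) with odds ratio, log2 OR and a
    chi-squared p-value (Fisher substituted automatically when any expected
    cell is below 5). Pairs with an empty margin are reported with NaN odds
    ratios.
    """
    counts = pd.DataFrame(0, index=list(OSN_CHANGES), columns=list(INTERACTION_CHANGES))
    for row in changes.itertuples(index=False):
        counts.loc[row.osn_change, row.interaction_change] += 1
    row_sums = counts.sum(axis=1)
    pct = counts.divide(row_sums.where(row_sums > 0), axis=0) * 100
    results: dict[tuple[str, str], ContingencyResult] = {}
    total = counts.values.sum()
    for osn in OSN_CHANGES:
        for inter in INTERACTION_CHANGES:
            a = int(counts.loc[osn, inter])
            b = int(counts.loc[osn].sum() - a)
            c = int(counts[inter].sum() - a)
            d = int(total - a - b - c)
            results[(osn, inter)] = fisher_or_chisq(
                np.array([[a, b], [c, d]]), prefer="auto"
            )
    return counts, pct, results


def contingency_table(
    results: dict[tuple[str, str], ContingencyResult]
) -> pd.DataFrame:
    rows = []
    for (osn, inter), res in results.items():
        rows.append({"osn_change": osn, "interaction_change": inter, **res.as_dict()})
    return pd.DataFrame(rows)
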