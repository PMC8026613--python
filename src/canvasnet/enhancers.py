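"""Enhancer stitching, super-enhancer calling and target-gene assignment.

Enhancer peaks (H3K27ac) are stitched into regulatory elements when their gap
is at most the stitching distance (1.5 kb by default). Super-enhancers are
called with the rank-signal tangent geometry: constituents are ranked by
total signal, rank and signal are both scaled to [0, 1], and the cutoff sits
where a slope-1 line is tangent to the convex rank curve, i.e. at
argmax(x - y); every element with signal above the cutoff signal is a
super-enhancer. Elements are then mapped to target genes through the
interaction network: an element targets every gene whose baited promoter
fragment is connected, by an edge supported in the element's condition, to a
fragment the element overlaps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import BaitAnnotation, FragmentMap
from .network_core import MergedNetwork

logger = logging.getLogger(__name__)


@dataclass
class RegulatoryElement:
    """A stitched enhancer element for one condition."""

    element_id: str
    chrom: str
    start: int
    end: int
    n_constituents: int
    signal: float  # summed constituent peak signal
    condition: str
    rank: int = -1  # ascending by signal, unique within a call set
    is_super: bool = False

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def stitch_peaks(
    peaks: pd.DataFrame, stitch_distance: int = 1500, condition: str = ""
) -> list[RegulatoryElement]:
    """Merge peaks whose gap is at most ``stitch_distance`` bp, transitively.

    ``peaks`` needs columns chrom, start, end, signal. The stitched element
    signal is the sum of its constituent peak signals. Idempotent: stitching
    the stitched output changes nothing.
    """
    elements: list[RegulatoryElement] = []
    if peaks.empty:
        return elements
    df = peaks.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    cur = None
    for row in df.itertuples(index=False):
        if cur is not None and row.chrom == cur["chrom"] and row.start - cur["end"] <= stitch_distance:
            cur["end"] = max(cur["end"], row.end)
            cur["signal"] += row.signal
            cur["n"] += 1
        else:
            if cur is not None:
                elements.append(cur)
            cur = {
                "chrom": row.chrom, "start": row.start, "end": row.end,
                "signal": float(row.signal), "n": 1,
            }
    if cur is not None:
        elements.append(cur)
    return [
        RegulatoryElement(
            f"{condition or 'E'}_{i:05d}", e["chrom"], e["start"], e["end"],
            e["n"], e["signal"], condition,
        )
        for i, e in enumerate(elements)
    ]


def call_super_enhancers(
    elements: list[RegulatoryElement],
) -> tuple[list[RegulatoryElement], float]:
    """Assign ranks and super-enhancer flags; returns (elements, cutoff signal).

    The cutoff is scale-invariant because both axes are normalised to [0, 1]
    before taking argmax(x - y). Ties in signal are broken by genomic order so
    the rank (and hence the cutoff) is deterministic. If all signals are equal
    the rank curve is flat, the cutoff sits at the top and no element is
    called super (with a warning).
    """
    if len(elements) < 2:
        raise ValueError("super-enhancer calling needs at least 2 elements")
    order = sorted(
        range(len(elements)),
        key=lambda i: (elements[i].signal, elements[i].chrom, elements[i].start),
    )
    signals = np.array([elements[i].signal for i in order], dtype=float)
    for rank, i in enumerate(order):
        elements[i].rank = rank
    n = len(signals)
    x = np.arange(n) / (n - 1)
    span = signals[-1] - signals[0]
    if span == 0:
        warnings.warn("all element signals equal; no super-enhancers called", stacklevel=2)
        cutoff_signal = signals[-1]
        for el in elements:
            el.is_super = False
        return elements, float(cutoff_signal)
    y = (signals - signals[0]) / span
    cutoff_idx = int(np.argmax(x - y))
    cutoff_signal = float(signals[cutoff_idx])
    for el in elements:
        el.is_super = el.signal > cutoff_signal
    return elements, cutoff_signal


def elements_to_dataframe(elements: list[RegulatoryElement]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in elements])


def match_elements_across_conditions(
    elements_a: list[RegulatoryElement],
    elements_b: list[RegulatoryElement],
    min_overlap: int = 1,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Label each element shared or condition-specific by cross-condition overlap.

    An element is shared iff it overlaps (by at least ``min_overlap`` bp) any
    element of the other condition. One-to-many overlaps are preserved as
    pairs, so the shared counts may legitimately differ between the two
    conditions. Returns (element_id -> label, overlap-pair table).
    """
    labels: dict[str, str] = {}
    pairs = []
    by_chrom_b: dict[str, list[RegulatoryElement]] = {}
    for el in elements_b:
        by_chrom_b.setdefault(el.chrom, []).append(el)
    shared_b: set[str] = set()
    for ea in elements_a:
        hit = False
        for eb in by_chrom_b.get(ea.chrom, []):
            ov = min(ea.end, eb.end) - max(ea.start, eb.start)
            if ov >= min_overlap:
                hit = True
                shared_b.add(eb.element_id)
                pairs.append({"element_A": ea.element_id, "element_B": eb.element_id, "overlap_bp": ov})
        labels[ea.element_id] = "shared" if hit else "A_specific"
    for eb in elements_b:
        labels[eb.element_id] = "shared" if eb.element_id in shared_b else "B_specific"
    return labels, pd.DataFrame(pairs, columns=["element_A", "element_B", "overlap_bp"])


@dataclass
class TargetAssignment:
    """Per-gene record of the elements contacting its promoter fragments."""

    gene: str
    elements_A: set[str] = field(default_factory=set)
    elements_B: set[str] = field(default_factory=set)

    @property
    def gene_class(self) -> str:
        if self.elements_A and self.elements_B:
            return "shared"
        return "A_only" if self.elements_A else "B_only"


def map_elements_to_targets(
    elements: list[RegulatoryElement],
    network: MergedNetwork,
    bait_annotation: BaitAnnotation,
    condition: str,
) -> dict[str, set[str]]:
    """Genes targeted by each element through condition-supported interactions.

    An element reaches a gene when it overlaps a fragment that is connected
    by a condition-supported edge to a fragment carrying the gene's promoter.
    Elements sitting on a bait fragment are still mapped through edges only
    (no self-target); such cases are logged.
    """
    fm = network.fragment_map
    targets: dict[str, set[str]] = {}
    for el in elements:
        genes: set[str] = set()
        frags = fm.overlapping(el.chrom, el.start, el.end)
        for frag in frags:
            if frag not in network.graph:
                continue
            for nb in network.graph.neighbors(frag):
                if not network.edge_supported_in(frag, nb, condition):
                    continue
                genes |= bait_annotation.genes_by_fragment.get(nb, set())
        overlapped_bait_genes = set()
        for frag in frags:
            overlapped_bait_genes |= bait_annotation.genes_by_fragment.get(frag, set())
        if overlapped_bait_genes:
            logger.debug(
                "element %s overlaps bait fragment(s); genes %s reachable only via edges",
                el.element_id, sorted(overlapped_bait_genes),
            )
        targets[el.element_id] = genes
    return targets


def classify_target_genes(
    targets_a: dict[str, set[str]], targets_b: dict[str, set[str]]
) -> dict[str, TargetAssignment]:
    """Combine per-condition element->gene maps into per-gene classes."""
    by_gene: dict[str, TargetAssignment] = {}
    for el, genes in targets_a.items():
        for g in genes:
            by_gene.setdefault(g, TargetAssignment(g)).elements_A.add(el)
    for el, genes in targets_b.items():
        for g in genes:
            by_gene.setdefault(g, TargetAssignment(g)).elements_B.add(el)
    return by_gene


def se_and_enhancer_gene_lists(
    se_targets: dict[str, TargetAssignment],
    enhancer_targets: dict[str, TargetAssignment],
) -> tuple[dict[str, str], dict[str, str]]:
    """Gene classes for SE targets and for plain-enhancer targets.

    Genes contacted by a super-enhancer in either condition are removed from
    the plain-enhancer gene list, so the two lists are disjoint.
    """
    se_classes = {g: t.gene_class for g, t in se_targets.items()}
    enh_classes = {
        g: t.gene_class
        for g, t in enhancer_targets.items()
        if g not in se_classes
    }
    return se_classes, enh_classes


def contacts_per_element(targets: dict[str, set[str]]) -> pd.Series:
    """Number of contacted promoters (genes) per element."""
    return pd.Series({el: len(genes) for el, genes in targets.items()}, dtype=int)


def elements_per_gene(targets: dict[str, set[str]]) -> pd.Series:
    """Number of contacting elements per gene."""
    counts: dict[str, int] = {}
    for genes in targets.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, dtype=int)


# ---------------------------------------------------------------------------
# decommissioning quantitation


def quantify_methylation(
    regions: pd.DataFrame, cpg_calls: pd.DataFrame
) -> pd.Series:
    """Percent methylation per region: 100 * sum(meth) / sum(total) over the
    CpG calls inside each region. Regions with no covered CpG get NaN and are
    excluded from summaries downstream."""
    if (cpg_calls["meth_count"] > cpg_calls["total_count"]).any():
        raise ValueError("meth_count exceeds total_count")
    out = {}
    by_chrom = {c: sub.sort_values("pos") for c, sub in cpg_calls.groupby("chrom")}
    for row in regions.itertuples(index=True):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            out[row.Index] = np.nan
            continue
        pos = sub["pos"].values
        lo = np.searchsorted(pos, row.start, side="left")
        hi = np.searchsorted(pos, row.end, side="left")
        total = sub["total_count"].values[lo:hi].sum()
        meth = sub["meth_count"].values[lo:hi].sum()
        out[row.Index] = 100 * meth / total if total > 0 else np.nan
    return pd.Series(out, dtype=float)


def histone_gain_classifier(
    signal_a, signal_b, log2fc_threshold: float = 1.0
) -> tuple[np.ndarray, float]:
    """Per-region gain calls and the set-level log2 fold change of medians.

    Signals are log2-scale per region; a region gains the mark when
    signal_B - signal_A exceeds the threshold. Non-finite pairs are excluded
    (logged). The set-level statistic is log2(median(2^B) / median(2^A)),
    i.e. the fold change of the linear-scale medians, reported separately
    from the per-region calls.
    """
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.all():
        logger.warning("%d regions with non-finite signal excluded", int((~ok).sum()))
    gain = np.zeros(a.shape, dtype=bool)
    gain[ok] = (b[ok] - a[ok]) > log2fc_threshold
    med_fc = float(np.log2(np.median(2.0 ** b[ok]) / np.median(2.0 ** a[ok])))
    return gain, med_fc
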