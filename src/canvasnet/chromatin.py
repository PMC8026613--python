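"""Fragment-level chromatin state reduction and expression categories.

A genome segmentation assigns one of seven reduced chromatin states to each
segment: active, H3K4me1-only, bivalent, Polycomb-associated (H3K27me3
without H3K4 marks), heterochromatin, unclassified and background. A
restriction fragment typically overlaps several segments; the fragment is
reduced to a single state with supersession rules: any single state
supersedes background, bivalent supersedes Polycomb, and any other mixture of
two or more states is labelled mixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import BaitAnnotation, FragmentMap, SegmentationTrack

logger = logging.getLogger(__name__)

ACTIVE = "active"
H3K4ME1_ONLY = "h3k4me1_only"
BIVALENT = "bivalent"
POLYCOMB = "polycomb"
HETEROCHROMATIN = "heterochromatin"
UNCLASSIFIED = "unclassified"
BACKGROUND = "background"
MIXED = "mixed"

STATES = (
    ACTIVE,
    H3K4ME1_ONLY,
    BIVALENT,
    POLYCOMB,
    HETEROCHROMATIN,
    UNCLASSIFIED,
    BACKGROUND,
)
#: all labels a fragment can carry (the seven states plus the derived mixed)
FRAGMENT_LABELS = STATES + (MIXED,)


def reduce_states(overlapping_states: set[str]) -> str:
    """Reduce the set of states overlapping a fragment to one label.

    Deterministic and order-free: the input is a set. Unknown labels are
    rejected by name.
    """
    unknown = overlapping_states - set(STATES)
    if unknown:
        raise ValueError(f"unknown chromatin state label(s): {sorted(unknown)}")
    s = overlapping_states - {BACKGROUND}
    if not s:
        return BACKGROUND
    if len(s) == 1:
        return next(iter(s))
    if s == {BIVALENT, POLYCOMB}:
        return BIVALENT
    return MIXED


@dataclass
class FragmentStateAssignment:
    """One chromatin state per fragment for one condition.

    ``overlap_bp`` keeps the provenance: per fragment, the number of bases
    each state overlapped, from which the final label is reproducible via
    :func:`reduce_states`.
    """

    condition: str
    states: dict[str, str]
    overlap_bp: dict[str, dict[str, int]] = field(default_factory=dict)

    def state_of(self, frag_id: str) -> str:
        # uncovered fragments are background: segmentations are genome-wide
        # and gaps only arise from upstream filtering
        return self.states.get(frag_id, BACKGROUND)


def assign_fragment_states(
    segmentation: SegmentationTrack,
    fragment_map: FragmentMap,
    min_state_bp: int = 1,
) -> FragmentStateAssignment:
    """Assign one reduced chromatin state to every fragment.

    A state counts toward a fragment when it overlaps it by at least
    ``min_state_bp`` bases (default 1 bp: any overlap counts). Uncovered bases
    count as background.
    """
    overlap: dict[str, dict[str, int]] = {}
    for row in segmentation.segments.itertuples(index=False):
        for frag in fragment_map.overlapping(row.chrom, row.start, row.end):
            iv = fragment_map.get_interval(frag)
            bp = min(row.end, iv.end) - max(row.start, iv.start)
            if bp > 0:
                d = overlap.setdefault(frag, {})
                d[row.state] = d.get(row.state, 0) + bp
    states = {}
    for frag, d in overlap.items():
        eligible = {s for s, bp in d.items() if bp >= min_state_bp}
        states[frag] = reduce_states(eligible) if eligible else BACKGROUND
    return FragmentStateAssignment(segmentation.condition, states, overlap)


def state_transition_matrix(
    assignment_a: FragmentStateAssignment,
    assignment_b: FragmentStateAssignment,
    fragment_ids: list[str],
    destination_percentages: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-condition state transition counts over a fragment set.

    Returns ``(counts, percentages)`` with source states (condition A) as rows
    and destination states (condition B) as columns; percentages are
    normalised within each destination state (columns sum to 100 where the
    destination is populated).
    """
    labels = list(FRAGMENT_LABELS)
    counts = pd.DataFrame(0, index=labels, columns=labels)
    for frag in fragment_ids:
        counts.loc[assignment_a.state_of(frag), assignment_b.state_of(frag)] += 1
    if destination_percentages:
        col_sums = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = counts.divide(col_sums.where(col_sums > 0), axis=1) * 100
    else:
        row_sums = counts.sum(axis=1)
        pct = counts.divide(row_sums.where(row_sums > 0), axis=0) * 100
    return counts, pct


def longest_interaction_state_profile(
    top_edges: list[tuple[str, str, float]],
    assignment: FragmentStateAssignment,
    bait_annotation: BaitAnnotation,
) -> tuple[pd.DataFrame, float]:
    """Chromatin states at both ends of the longest interactions.

    For each edge, the bait side is the end carrying a gene annotation; edges
    with two baited ends are counted once per direction. Returns the per-edge
    table (bait_state, other_state) and the fraction of edges whose bait
    fragment is bivalent.
    """
    rows = []
    n_bivalent_bait = 0
    n_edges = 0
    for u, v, dist in top_edges:
        u_bait = bait_annotation.is_bait(u)
        v_bait = bait_annotation.is_bait(v)
        if u_bait and v_bait:
            directions = [(u, v), (v, u)]
        elif v_bait:
            directions = [(v, u)]
        else:
            # neither end baited: fall back to the first fragment id
            directions = [(u, v)]
        n_edges += 1
        edge_has_bivalent_bait = False
        for bait, other in directions:
            bs = assignment.state_of(bait)
            rows.append(
                {
                    "bait": bait,
                    "other_end": other,
                    "distance": dist,
                    "bait_state": bs,
                    "other_state": assignment.state_of(other),
                }
            )
            if bs == BIVALENT:
                edge_has_bivalent_bait = True
        if edge_has_bivalent_bait:
            n_bivalent_bait += 1
    table = pd.DataFrame(
        rows, columns=["bait", "other_end", "distance", "bait_state", "other_state"]
    )
    fraction = n_bivalent_bait / n_edges if n_edges else float("nan")
    return table, fraction


@dataclass
class ExpressionCategory:
    """Fragment-level differential-expression category (up/down/unchanged/mixed)."""

    categories: dict[str, str]

    def of(self, frag_id: str) -> str:
        return self.categories.get(frag_id, "unchanged")


def assign_expression_category(
    bait_annotation: BaitAnnotation,
    de_table: pd.DataFrame,
    padj_threshold: float = 0.05,
) -> ExpressionCategory:
    """Aggregate per-gene differential expression calls to bait fragments.

    A fragment is up/down when all its significant genes agree in direction,
    unchanged when none is significant, and mixed when significant genes
    disagree. ``de_table`` needs columns gene, log2fc, padj; genes absent from
    it are treated as unchanged (logged).
    """
    de = de_table.set_index("gene")
    categories = {}
    missing: set[str] = set()
    for frag, genes in bait_annotation.genes_by_fragment.items():
        directions = set()
        for gene in genes:
            if gene not in de.index:
                missing.add(gene)
                continue
            row = de.loc[gene]
            if row["padj"] < padj_threshold and row["log2fc"] != 0:
                directions.add("up" if row["log2fc"] > 0 else "down")
        if not directions:
            categories[frag] = "unchanged"
        elif len(directions) == 1:
            categories[frag] = next(iter(directions))
        else:
            categories[frag] = "mixed"
    if missing:
        logger.warning(
            "%d annotated genes missing from DE table; treated as unchanged",
            len(missing),
        )
    return ExpressionCategory(categories)
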