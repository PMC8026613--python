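"""Genomic file formats and the fragment-resolution data model.

All coordinates are 0-based half-open internally. BED is native; washU
``chr:start-end`` pair strings are treated as 0-based half-open as well. This
module is the single place where coordinate conventions are converted.

The node universe of every network in this package is a :class:`FragmentMap`:
the partition of the genome into restriction fragments (HindIII in the study
this package was built around, ~4 kb average). Interaction calls, chromatin
segmentations, peaks and promoters are all resolved against it.
"""

from __future__ import annotations

import gzip
import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = {"+", "-", "."}


class FileFormatError(ValueError):
    """A file violated the invariants of its declared format."""


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class FragmentMap:
    """Ordered, validated partition of chromosomes into restriction fragments.

    Per chromosome, fragments are sorted, non-overlapping and tile the covered
    range without gaps, so every covered base maps to exactly one fragment
    (``lookup`` is total over covered bases and is implemented with a binary
    search on the start positions).
    """

    def __init__(self, records: Iterable[tuple[str, GenomicInterval]]):
        self._ids: list[str] = []
        self._intervals: list[GenomicInterval] = []
        by_chrom: dict[str, list[int]] = {}
        seen = set()
        for frag_id, iv in records:
            if frag_id in seen:
                raise FileFormatError(f"duplicate fragment id {frag_id!r}")
            seen.add(frag_id)
            by_chrom.setdefault(iv.chrom, []).append(len(self._ids))
            self._ids.append(frag_id)
            self._intervals.append(iv)
        self._chrom_starts: dict[str, np.ndarray] = {}
        self._chrom_ends: dict[str, np.ndarray] = {}
        self._chrom_idx: dict[str, np.ndarray] = {}
        for chrom, idx in by_chrom.items():
            idx = sorted(idx, key=lambda i: self._intervals[i].start)
            starts = np.array([self._intervals[i].start for i in idx])
            ends = np.array([self._intervals[i].end for i in idx])
            bad = np.nonzero(starts[1:] < ends[:-1])[0]
            if bad.size:
                i = int(bad[0])
                raise FileFormatError(
                    f"overlap at {chrom}:{starts[i + 1]} "
                    f"(fragments {self._ids[idx[i]]} and {self._ids[idx[i + 1]]})"
                )
            gaps = np.nonzero(starts[1:] > ends[:-1])[0]
            if gaps.size:
                i = int(gaps[0])
                raise FileFormatError(
                    f"gap in fragment tiling at {chrom}:{ends[i]}-{starts[i + 1]}"
                )
            self._chrom_starts[chrom] = starts
            self._chrom_ends[chrom] = ends
            self._chrom_idx[chrom] = np.array(idx)
        self._by_coords = {
            (iv.chrom, iv.start, iv.end): fid
            for fid, iv in zip(self._ids, self._intervals)
        }

    def __len__(self) -> int:
        return len(self._ids)

    def __contains__(self, frag_id: str) -> bool:
        return frag_id in self._id_index()

    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._chrom_starts)

    def chrom_bounds(self, chrom: str) -> tuple[int, int]:
        """Covered range ``(start, end)`` of a chromosome."""
        return int(self._chrom_starts[chrom][0]), int(self._chrom_ends[chrom][-1])

    # fast id -> interval map, built lazily
    def _id_index(self) -> dict[str, int]:
        if not hasattr(self, "_idmap"):
            self._idmap = {fid: i for i, fid in enumerate(self._ids)}
        return self._idmap

    def get_interval(self, frag_id: str) -> GenomicInterval:
        return self._intervals[self._id_index()[frag_id]]

    def midpoint(self, frag_id: str) -> float:
        return self.get_interval(frag_id).midpoint

    def chrom_of(self, frag_id: str) -> str:
        return self.get_interval(frag_id).chrom

    def lookup(self, chrom: str, pos: int) -> str | None:
        """Fragment covering base ``pos`` (0-based), or None if uncovered."""
        if chrom not in self._chrom_starts:
            return None
        starts = self._chrom_starts[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= self._chrom_ends[chrom][i]:
            return None
        return self._ids[self._chrom_idx[chrom][i]]

    def match_exact(
        self, chrom: str, start: int, end: int, tolerance: int = 0
    ) -> str | None:
        """Fragment with exactly these coordinates (optionally +/- tolerance bp)."""
        hit = self._by_coords.get((chrom, start, end))
        if hit is not None or tolerance == 0:
            return hit
        for ds in range(-tolerance, tolerance + 1):
            for de in range(-tolerance, tolerance + 1):
                hit = self._by_coords.get((chrom, start + ds, end + de))
                if hit is not None:
                    return hit
        return None

    def overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        """All fragments overlapping ``[start, end)``."""
        if chrom not in self._chrom_starts or start >= end:
            return []
        starts = self._chrom_starts[chrom]
        ends = self._chrom_ends[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        return [self._ids[j] for j in self._chrom_idx[chrom][lo:hi]]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self._intervals],
                "start": [iv.start for iv in self._intervals],
                "end": [iv.end for iv in self._intervals],
                "fragment_id": self._ids,
            }
        )

    def write(self, path) -> None:
        with _open_text(path, "wt") as fh:
            for fid, iv in zip(self._ids, self._intervals):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{fid}\n")


def read_fragment_map(path) -> FragmentMap:
    """Read a restriction-fragment map from BED3/BED4.

    When the BED name column is absent, ids are assigned as
    ``chrom:start-end``. Overlapping fragments and malformed coordinates are
    rejected with the offending line number.
    """
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FileFormatError(f"line {lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FileFormatError(
                    f"line {lineno}: malformed coordinates {fields[1:3]}"
                ) from exc
            name = fields[3] if len(fields) >= 4 and fields[3] else None
            if name is None:
                name = f"{chrom}:{start}-{end}"
            try:
                iv = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise FileFormatError(f"line {lineno}: {exc}") from exc
            records.append((name, iv))
    return FragmentMap(records)


@dataclass
class BaitAnnotation:
    """Map of baited fragment id -> set of gene identifiers."""

    genes_by_fragment: dict[str, set[str]] = field(default_factory=dict)

    def fragments_of(self, gene: str) -> list[str]:
        return sorted(
            f for f, gs in self.genes_by_fragment.items() if gene in gs
        )

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.genes_by_fragment.values():
            out |= gs
        return out

    def is_bait(self, frag_id: str) -> bool:
        return frag_id in self.genes_by_fragment


def read_promoters(path, fragment_map: FragmentMap, window: int = 1000) -> BaitAnnotation:
    """Read a TSS table (gene, chrom, tss, strand) into a bait annotation.

    The promoter is the ``window`` bp immediately upstream of the TSS,
    strand-relative: ``[tss - window, tss)`` on + and ``[tss + 1,
    tss + 1 + window)`` on -. Promoters running past the chromosome start are
    clipped to 0. A gene is annotated to every fragment its promoter overlaps.
    Unstranded rows default to + with a warning.
    """
    table = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    required = {"gene", "chrom", "tss", "strand"}
    missing = required - set(table.columns)
    if missing:
        raise FileFormatError(f"TSS table missing columns: {sorted(missing)}")
    ann = BaitAnnotation()
    for row in table.itertuples(index=False):
        strand = row.strand if row.strand in {"+", "-"} else None
        if strand is None:
            warnings.warn(
                f"gene {row.gene}: unstranded TSS, assuming + strand",
                stacklevel=2,
            )
            strand = "+"
        tss = int(row.tss)
        if strand == "+":
            start, end = max(0, tss - window), tss
        else:
            start, end = tss + 1, tss + 1 + window
        if start >= end:
            continue
        for frag in fragment_map.overlapping(row.chrom, start, end):
            ann.genes_by_fragment.setdefault(frag, set()).add(row.gene)
    return ann


@dataclass(frozen=True)
class InteractionCall:
    """A significant promoter interaction between two fragments."""

    bait_fragment_id: str
    other_fragment_id: str
    score: float
    read_count: int
    condition: str

    def __post_init__(self):
        if self.bait_fragment_id == self.other_fragment_id:
            raise ValueError("self-interaction call")
        if self.score < 0:
            raise ValueError(f"negative interaction score {self.score}")
        if self.read_count < 0:
            raise ValueError("negative read count")


IBED_COLUMNS = [
    "bait_chr", "bait_start", "bait_end", "bait_name",
    "otherEnd_chr", "otherEnd_start", "otherEnd_end", "otherEnd_name",
    "N_reads", "score",
]


def _dedup_calls(calls: list[InteractionCall]) -> list[InteractionCall]:
    """Collapse duplicate rows (same unordered pair, same condition):
    keep the maximum score, sum read counts."""
    merged: dict[tuple, InteractionCall] = {}
    n_dup = 0
    for c in calls:
        key = (frozenset((c.bait_fragment_id, c.other_fragment_id)), c.condition)
        if key in merged:
            n_dup += 1
            prev = merged[key]
            merged[key] = InteractionCall(
                prev.bait_fragment_id,
                prev.other_fragment_id,
                max(prev.score, c.score),
                prev.read_count + c.read_count,
                c.condition,
            )
        else:
            merged[key] = c
    if n_dup:
        logger.warning("collapsed %d duplicate interaction rows", n_dup)
    return list(merged.values())


def read_interactions(
    path,
    fragment_map: FragmentMap,
    condition: str,
    dialect: str = "auto",
    on_unmapped: str = "skip",
    tolerance: int = 0,
) -> list[InteractionCall]:
    """Read significant-interaction calls (ibed or washU pairwise text).

    Rows are matched to fragments by exact start/end equality (optionally with
    a +/- ``tolerance`` bp window for off-by-one dialects); nearest-fragment
    snapping is deliberately not performed. ``on_unmapped`` is ``"skip"``
    (log a warning per unmappable row) or ``"error"``.
    """
    if on_unmapped not in {"skip", "error"}:
        raise ValueError(f"on_unmapped must be skip|error, got {on_unmapped!r}")
    with _open_text(path) as fh:
        first = fh.readline()
        rest = fh.read()
    if dialect == "auto":
        dialect = "ibed" if "bait_chr" in first else "washu"

    calls: list[InteractionCall] = []
    n_skipped = 0

    def resolve(chrom, start, end, lineno):
        frag = fragment_map.match_exact(chrom, int(start), int(end), tolerance)
        if frag is None:
            nonlocal n_skipped
            if on_unmapped == "error":
                raise FileFormatError(
                    f"line {lineno}: {chrom}:{start}-{end} matches no fragment"
                )
            logger.warning(
                "line %d: %s:%s-%s matches no fragment; row skipped",
                lineno, chrom, start, end,
            )
            n_skipped += 1
        return frag

    if dialect == "ibed":
        table = pd.read_csv(io.StringIO(first + rest), sep="\t")
        missing = set(IBED_COLUMNS) - set(table.columns)
        if missing:
            raise FileFormatError(f"ibed missing columns: {sorted(missing)}")
        for lineno, row in enumerate(table.itertuples(index=False), 2):
            if row.score < 0:
                raise FileFormatError(f"line {lineno}: negative score {row.score}")
            bait = resolve(row.bait_chr, row.bait_start, row.bait_end, lineno)
            other = resolve(
                row.otherEnd_chr, row.otherEnd_start, row.otherEnd_end, lineno
            )
            if bait is None or other is None:
                continue
            calls.append(
                InteractionCall(bait, other, float(row.score), int(row.N_reads), condition)
            )
    elif dialect == "washu":
        for lineno, line in enumerate((first + rest).splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FileFormatError(
                    f"line {lineno}: expected 3 washU columns, got {len(fields)}"
                )
            score = float(fields[2])
            if score < 0:
                raise FileFormatError(f"line {lineno}: negative score {score}")

            def parse_locus(tok):
                chrom, span = tok.split(":")
                start, end = span.split("-")
                return chrom, int(start), int(end)

            c1, s1, e1 = parse_locus(fields[0])
            c2, s2, e2 = parse_locus(fields[1])
            bait = resolve(c1, s1, e1, lineno)
            other = resolve(c2, s2, e2, lineno)
            if bait is None or other is None:
                continue
            calls.append(InteractionCall(bait, other, score, 0, condition))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if n_skipped:
        logger.warning("%d unmappable rows skipped in %s", n_skipped, path)
    return _dedup_calls(calls)


@dataclass
class SegmentationTrack:
    """A chromatin-state segmentation (intervals with state labels)."""

    condition: str
    segments: pd.DataFrame  # columns: chrom, start, end, state

    def __post_init__(self):
        df = self.segments.sort_values(["chrom", "start"]).reset_index(drop=True)
        same = df["chrom"].values[1:] == df["chrom"].values[:-1]
        if np.any(same & (df["start"].values[1:] < df["end"].values[:-1])):
            i = int(np.nonzero(same & (df["start"].values[1:] < df["end"].values[:-1]))[0][0])
            raise FileFormatError(
                f"overlapping segments at {df['chrom'][i + 1]}:{df['start'][i + 1]}"
            )
        self.segments = df

    def state_at(self, chrom: str, pos: int) -> str | None:
        """State label covering base ``pos``, or None if uncovered."""
        df = self.segments
        sub = df[df["chrom"] == chrom]
        if sub.empty:
            return None
        starts = sub["start"].values
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= sub["end"].values[i]:
            return None
        return sub["state"].values[i]


def read_segmentation(path, condition: str) -> SegmentationTrack:
    """Read a segmentation from BED4 (name column = state label)."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FileFormatError(f"line {lineno}: segmentation BED needs 4 columns")
            rows.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
    return SegmentationTrack(
        condition, pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    )


def read_peaks(path) -> pd.DataFrame:
    """Read peaks from BED5+ or narrowPeak into (chrom, start, end, signal).

    narrowPeak (10 columns) uses signalValue (column 7); BED5 uses the score
    column. Signals must be finite.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) >= 10:
                signal = float(fields[6])
            elif len(fields) >= 5:
                signal = float(fields[4])
            else:
                raise FileFormatError(
                    f"line {lineno}: peak file needs >=5 (BED) or 10 (narrowPeak) columns"
                )
            if not np.isfinite(signal):
                raise FileFormatError(f"line {lineno}: non-finite signal")
            rows.append((fields[0], int(fields[1]), int(fields[2]), signal))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "signal"])


def read_methylation(path) -> pd.DataFrame:
    """Read per-CpG methylation calls (chrom, pos, meth_count, total_count)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "meth_count", "total_count"}
    missing = required - set(df.columns)
    if missing:
        raise FileFormatError(f"methylation table missing columns: {sorted(missing)}")
    bad = df["meth_count"] > df["total_count"]
    if bad.any():
        raise FileFormatError(
            f"meth_count exceeds total_count at row {int(np.nonzero(bad.values)[0][0]) + 2}"
        )
    return df


def read_bed_regions(path) -> pd.DataFrame:
    """Read plain BED3/4 regions into a DataFrame (chrom, start, end[, name])."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------------
# network export

EXPORT_FORMATS = {"gexf", "graphml", "tsv"}


def write_network_export(graph: nx.Graph, path, fmt: str = "gexf", layout=None) -> list[str]:
    """Export a network to GEXF 1.2, GraphML or a node/edge TSV pair.

    Node and edge attributes already on the graph (fragment coordinates,
    specificity, chromatin state, per-condition scores, ...) are carried
    through; ``layout`` (node -> (x, y)) is embedded when given. Returns the
    list of files written.
    """
    fmt = fmt.lower()
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown export format {fmt!r}")
    g = graph.copy()
    if layout is not None:
        for node, (x, y) in layout.items():
            g.nodes[node]["x"] = float(x)
            g.nodes[node]["y"] = float(y)
    # GEXF/GraphML writers cannot serialise None or numpy scalars
    def clean(data):
        for k in list(data):
            if data[k] is None:
                del data[k]
            elif isinstance(data[k], np.generic):
                data[k] = data[k].item()

    clean(g.graph)
    for _, data in g.nodes(data=True):
        clean(data)
    for _, _, data in g.edges(data=True):
        clean(data)
    path = str(path)
    if fmt == "gexf":
        nx.write_gexf(g, path, version="1.2draft")
        return [path]
    if fmt == "graphml":
        nx.write_graphml(g, path)
        return [path]
    nodes_path, edges_path = path + ".nodes.tsv", path + ".edges.tsv"
    ndf = pd.DataFrame(
        [{"node": n, **d} for n, d in g.nodes(data=True)]
    )
    edf = pd.DataFrame(
        [{"source": u, "target": v, **d} for u, v, d in g.edges(data=True)]
    )
    ndf.to_csv(nodes_path, sep="\t", index=False)
    edf.to_csv(edges_path, sep="\t", index=False)
    return [nodes_path, edges_path]


def read_network_export(path, fmt: str = "gexf") -> nx.Graph:
    """Read a network previously written by :func:`write_network_export`."""
    fmt = fmt.lower()
    if fmt == "gexf":
        g = nx.read_gexf(str(path))
        # round-trip hygiene: gexf writer adds a label attribute
        for _, d in g.nodes(data=True):
            d.pop("label", None)
        return g
    if fmt == "graphml":
        return nx.read_graphml(str(path))
    if fmt == "tsv":
        path = str(path)
        ndf = pd.read_csv(path + ".nodes.tsv", sep="\t")
        edf = pd.read_csv(path + ".edges.tsv", sep="\t")
        g = nx.Graph()
        for row in ndf.itertuples(index=False):
            d = row._asdict()
            g.add_node(str(d.pop("node")), **{k: v for k, v in d.items() if pd.notna(v)})
        for row in edf.itertuples(index=False):
            d = row._asdict()
            u, v = str(d.pop("source")), str(d.pop("target"))
            g.add_edge(u, v, **{k: val for k, val in d.items() if pd.notna(val)})
        return g
    raise ValueError(f"unknown export format {fmt!r}")
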