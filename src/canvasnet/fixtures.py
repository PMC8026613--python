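"""Seeded generator of a miniature two-condition promoter-interaction study.

The generator plants, on a small two-chromosome genome, every structure the
analysis stages are meant to detect, and records the ground truth in a
manifest so each stage's output can be checked exactly:

* eight interaction communities (dense blocks of shared interactions) chained
  into one sub-network by sparse links between genomically adjacent blocks;
* condition-B-specific long-range (>1 Mb) bridge interactions, most of them
  joining bivalent-chromatin anchors;
* super-enhancer and plain-enhancer loci with per-condition H3K27ac peaks and
  interaction-wired target genes (A-only / B-only / shared);
* enhancer fragments whose OSN (OCT4/SOX2/NANOG) occupancy change is coupled
  to their interaction change at a configurable rate;
* matching segmentations, TADs, expression, DE calls and CpG methylation.

Every file in the written bundle is readable by the package's own readers,
and the same seed always produces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    BaitAnnotation,
    FragmentMap,
    GenomicInterval,
    InteractionCall,
    SegmentationTrack,
)


@dataclass
class FixtureParams:
    """Generator parameters; defaults define the standard study conditions."""

    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000}
    )
    fragment_size: int = 4000
    n_communities: int = 8
    community_size_range: tuple = (10, 25)
    intra_edge_prob: float = 0.5
    inter_edge_prob: float = 0.02  # between genomically adjacent communities
    community_gap_fragments: int = 50
    n_bridges: int = 15
    bivalent_bridge_fraction: float = 0.8
    n_super_enhancer_loci: int = 12
    n_enhancer_loci: int = 18
    n_osn_fragments: int = 500
    osn_coupling: float = 0.9  # P(OSN change mirrors interaction change)
    expression_shift: float = 2.0  # log2 FPKM boost for SE-target genes
    null: bool = False  # exchangeable conditions, no planted structure


@dataclass
class Fixture:
    """In-memory bundle plus ground-truth manifest."""

    params: FixtureParams
    seed: int
    fragment_map: FragmentMap
    baits: BaitAnnotation
    bait_table: pd.DataFrame  # gene, chrom, tss, strand
    calls_a: list
    calls_b: list
    interactions: pd.DataFrame  # full edge table with both scores
    segmentation_a: SegmentationTrack
    segmentation_b: SegmentationTrack
    h3k27ac: dict  # condition -> peak DataFrame
    factor_peaks: dict  # (factor, condition) -> peak DataFrame
    tads: pd.DataFrame
    expression: pd.DataFrame
    methylation: dict  # condition -> CpG call DataFrame
    manifest: dict

    def write(self, outdir) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.fragment_map.write(out / "fragments.bed")
        self.bait_table.to_csv(out / "baits.tsv", sep="\t", index=False)
        for cond in ("A", "B"):
            self._write_ibed(out / f"interactions_{cond}.ibed", cond)
            seg = self.segmentation_a if cond == "A" else self.segmentation_b
            with open(out / f"segmentation_{cond}.bed", "w") as fh:
                for r in seg.segments.itertuples(index=False):
                    fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.state}\n")
            self._write_peaks(out / f"h3k27ac_{cond}.bed", self.h3k27ac[cond])
            for factor in ("oct4", "sox2", "nanog"):
                self._write_peaks(
                    out / f"{factor}_{cond}.bed",
                    self.factor_peaks[(factor.upper(), cond)],
                )
            self.methylation[cond].to_csv(
                out / f"methylation_{cond}.tsv", sep="\t", index=False
            )
        with open(out / "tads.bed", "w") as fh:
            for r in self.tads.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tTAD\n")
        self.expression.to_csv(
            out / "expression.tsv", sep="\t", index=False, float_format="%.4f"
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
        return out

    @staticmethod
    def _write_peaks(path, df: pd.DataFrame) -> None:
        has_signal = "signal" in df.columns
        with open(path, "w") as fh:
            for i, r in enumerate(df.itertuples(index=False)):
                line = f"{r.chrom}\t{r.start}\t{r.end}\tpeak_{i:05d}"
                if has_signal:
                    line += f"\t{r.signal:.4f}"
                fh.write(line + "\n")

    def _write_ibed(self, path, condition: str) -> None:
        fm = self.fragment_map
        col = f"score_{condition}"
        with open(path, "w") as fh:
            fh.write(
                "bait_chr\tbait_start\tbait_end\tbait_name\totherEnd_chr\t"
                "otherEnd_start\totherEnd_end\totherEnd_name\tN_reads\tscore\n"
            )
            for r in self.interactions.itertuples(index=False):
                score = getattr(r, col)
                if not np.isfinite(score):
                    continue
                bi = fm.get_interval(r.bait)
                oi = fm.get_interval(r.other)
                bait_genes = self.baits.genes_by_fragment.get(r.bait)
                name = ";".join(sorted(bait_genes)) if bait_genes else "."
                fh.write(
                    f"{bi.chrom}\t{bi.start}\t{bi.end}\t{name}\t"
                    f"{oi.chrom}\t{oi.start}\t{oi.end}\t.\t"
                    f"{getattr(r, f'reads_{condition}')}\t{score:.3f}\n"
                )


def _frag_id(chrom: str, idx: int, size: int) -> str:
    return f"{chrom}:{idx * size}-{(idx + 1) * size}"


def _sig_score(rng) -> float:
    """Significant CHiCAGO-like score: 5 + Exponential(mean 4)."""
    return float(5.0 + rng.exponential(4.0))


def _support_score(rng) -> float:
    """Sub-threshold support score for shared edges: Uniform(3, 5)."""
    return float(rng.uniform(3.0, 5.0))


def _edge_scores(pattern: str, rng) -> tuple[float, float]:
    """(score_A, score_B) for a condition pattern; NaN marks absence."""
    if pattern == "A":
        return _sig_score(rng), float("nan")
    if pattern == "B":
        return float("nan"), _sig_score(rng)
    if pattern == "shared":
        hi, lo = _sig_score(rng), (
            _sig_score(rng) if rng.random() < 0.5 else _support_score(rng)
        )
        return (hi, lo) if rng.random() < 0.5 else (lo, hi)
    raise ValueError(pattern)


def generate_fixture(
    params: FixtureParams | None = None, seed: int = 7
) -> Fixture:
    """Generate the default two-condition study with planted structure."""
    p = params or FixtureParams()
    rng = np.random.default_rng(seed)
    fsize = p.fragment_size
    n_frags = {c: s // fsize for c, s in p.chrom_sizes.items()}

    # -- fragment universe -------------------------------------------------
    records = []
    for chrom in sorted(p.chrom_sizes):
        for i in range(n_frags[chrom]):
            records.append(
                (
                    _frag_id(chrom, i, fsize),
                    GenomicInterval(chrom, i * fsize, (i + 1) * fsize),
                )
            )
    fm = FragmentMap(records)

    def fid(chrom, idx):
        return _frag_id(chrom, idx, fsize)

    edges: list[dict] = []
    bait_rows: list[dict] = []
    seg_rows = {"A": [], "B": []}
    genes_meta: list[dict] = []  # gene, kind, shift_a, shift_b, de

    def add_edge(chrom, bait_idx, other_idx, pattern):
        sa, sb = _edge_scores(pattern, rng)
        edges.append(
            {
                "bait": fid(chrom, bait_idx),
                "other": fid(chrom, other_idx),
                "score_A": sa,
                "score_B": sb,
                "reads_A": int(rng.integers(5, 100)) if np.isfinite(sa) else 0,
                "reads_B": int(rng.integers(5, 100)) if np.isfinite(sb) else 0,
                "pattern": pattern,
            }
        )

    def add_bait(chrom, idx, gene):
        start = fm.get_interval(fid(chrom, idx)).start
        bait_rows.append(
            {"gene": gene, "chrom": chrom, "tss": start + 2000, "strand": "+"}
        )

    # -- planted communities (chr1, one chained sub-network) ---------------
    sizes = rng.integers(
        p.community_size_range[0], p.community_size_range[1] + 1, p.n_communities
    )
    base = 100
    comm_members: list[list[int]] = []
    start_idx = base
    for size in sizes:
        comm_members.append(list(range(start_idx, start_idx + int(size))))
        start_idx += int(size) + p.community_gap_fragments
    region_end = start_idx * fsize
    if region_end > p.chrom_sizes["chr1"] * 0.2:
        raise ValueError("community blocks do not fit the reserved region")

    def intra_pattern():
        if not p.null:
            return "shared"
        r = rng.random()
        return "shared" if r < 0.8 else ("A" if r < 0.9 else "B")

    for k, members in enumerate(comm_members):
        # guaranteed spanning path keeps each planted community connected
        for a, b in zip(members, members[1:]):
            add_edge("chr1", a, b, intra_pattern())
        for i, a in enumerate(members):
            for b in members[i + 2 :]:
                if rng.random() < p.intra_edge_prob:
                    add_edge("chr1", a, b, intra_pattern())
        for j, g in enumerate(members[:3]):
            add_bait("chr1", g, f"CG{k}_{j}")
            shift = 0.0 if p.null else p.expression_shift
            de = "none"
            if not p.null:
                de = "up_A" if k < 2 else ("up_B" if k < 4 else "none")
            genes_meta.append({"gene": f"CG{k}_{j}", "kind": "community", "de": de})
        lo, hi = members[0] * fsize, (members[-1] + 1) * fsize
        seg_rows["A"].append(("chr1", lo, hi, "active"))
        seg_rows["B"].append(("chr1", lo, hi, "active"))
    # sparse links between genomically adjacent communities
    for ka in range(p.n_communities - 1):
        linked = False
        for a in comm_members[ka]:
            for b in comm_members[ka + 1]:
                if rng.random() < p.inter_edge_prob:
                    add_edge("chr1", a, b, intra_pattern())
                    linked = True
        if not linked:
            add_edge("chr1", comm_members[ka][0], comm_members[ka + 1][0], intra_pattern())

    # -- long-range condition-B bridges (chr1, 10 Mb onwards) --------------
    bridges = []
    n_bivalent = int(round(p.n_bridges * p.bivalent_bridge_fraction))
    for b in range(p.n_bridges):
        a1 = 2500 + b * 10
        a2 = a1 + 260 + b * 40
        add_edge("chr1", a1, a2, "B")
        add_bait("chr1", a1, f"BG{b:02d}")
        genes_meta.append(
            {"gene": f"BG{b:02d}", "kind": "bridge", "de": "down_B" if not p.null else "none"}
        )
        bivalent = b < n_bivalent
        for idx in (a1, a2):
            s, e = idx * fsize, (idx + 1) * fsize
            if bivalent:
                seg_rows["B"].append(("chr1", s, e, "bivalent"))
                mode = b % 3
                if mode == 0:  # stays Polycomb-marked in A
                    seg_rows["A"].append(("chr1", s, e, "polycomb"))
                elif mode == 1:  # active patch inside a Polycomb block -> mixed
                    seg_rows["A"].append(("chr1", s, s + 1500, "polycomb"))
                    seg_rows["A"].append(("chr1", s + 1500, s + 2500, "active"))
                    seg_rows["A"].append(("chr1", s + 2500, e, "polycomb"))
                else:
                    seg_rows["A"].append(("chr1", s, e, "active"))
            else:
                seg_rows["B"].append(("chr1", s, e, "active"))
                seg_rows["A"].append(("chr1", s, e, "active"))
        bridges.append(
            {
                "frag1": fid("chr1", a1),
                "frag2": fid("chr1", a2),
                "distance": (a2 - a1) * fsize,
                "bivalent": bool(bivalent),
                "gene": f"BG{b:02d}",
            }
        )

    # -- super-enhancer and enhancer loci (chr1, 4 Mb region) --------------
    h3k27ac = {"A": [], "B": []}
    se_gene_classes: dict[str, str] = {}
    enhancer_gene_classes: dict[str, str] = {}
    se_loci = []

    def presence(j):
        if p.null:
            return "shared"
        return ("A", "B", "shared")[j % 3]

    def class_of(pres):
        return {"A": "A_only", "B": "B_only", "shared": "shared"}[pres]

    for j in range(p.n_super_enhancer_loci):
        e_idx = 1000 + j * 12
        g_idx = e_idx + 2
        pres = presence(j)
        gene = f"SEG{j:02d}"
        add_bait("chr1", g_idx, gene)
        add_edge("chr1", g_idx, e_idx, pres)
        s = e_idx * fsize
        for cond in ("A", "B"):
            if pres in (cond, "shared"):
                for off in (200, 1400, 2600):
                    h3k27ac[cond].append(
                        ("chr1", s + off, s + off + 800, float(rng.uniform(25, 40)))
                    )
                seg_rows[cond].append(("chr1", s, s + fsize, "active"))
        se_gene_classes[gene] = class_of(pres)
        se_loci.append({"fragment": fid("chr1", e_idx), "presence": pres, "gene": gene})
        genes_meta.append({"gene": gene, "kind": f"se_{pres}", "de": "none"})

    enhancer_regions = []  # for methylation quantitation
    for q in range(p.n_enhancer_loci):
        e_idx = 1200 + q * 4
        g_idx = e_idx + 2
        pres = presence(q)
        gene = f"ENG{q:02d}"
        add_bait("chr1", g_idx, gene)
        add_edge("chr1", g_idx, e_idx, pres)
        s = e_idx * fsize
        for cond in ("A", "B"):
            if pres in (cond, "shared"):
                h3k27ac[cond].append(
                    ("chr1", s + 500, s + 1100, float(rng.uniform(1, 4)))
                )
                seg_rows[cond].append(("chr1", s, s + fsize, "active"))
        enhancer_gene_classes[gene] = class_of(pres)
        enhancer_regions.append(
            {"chrom": "chr1", "start": s + 500, "end": s + 1100, "presence": pres}
        )
        genes_meta.append({"gene": gene, "kind": f"enh_{pres}", "de": "none"})
    # two extra plain enhancers contacting SE-target genes: those genes must
    # drop out of the plain-enhancer gene list
    if not p.null:
        for e_idx, se_j in ((1006, 0), (1018, 2)):
            g_idx = 1000 + se_j * 12 + 2
            add_edge("chr1", g_idx, e_idx, "shared")
            s = e_idx * fsize
            for cond in ("A", "B"):
                h3k27ac[cond].append(
                    ("chr1", s + 500, s + 1100, float(rng.uniform(1, 4)))
                )
            overlapped = f"SEG{se_j:02d}"
            enhancer_gene_classes.pop(overlapped, None)

    # -- OSN / interaction coupling block (chr2) ---------------------------
    factor_peaks = {
        (f, c): [] for f in ("OCT4", "SOX2", "NANOG") for c in ("A", "B")
    }
    n_hubs = 20
    hub_spacing = n_frags["chr2"] // (n_hubs + 1)
    hub_idx = [h * hub_spacing + 4 for h in range(n_hubs)]
    for h, idx in enumerate(hub_idx):
        add_bait("chr2", idx, f"HG{h:02d}")
        genes_meta.append({"gene": f"HG{h:02d}", "kind": "hub", "de": "none"})
    osn_truth = []
    inter_classes = ("lost", "gained", "retained")
    for i in range(p.n_osn_fragments):
        e_idx = i * 8
        if e_idx in hub_idx:
            e_idx += 1
        inter = inter_classes[int(rng.integers(0, 3))]
        if p.null or rng.random() >= p.osn_coupling:
            osn = ("lost", "gained", "retained", "never")[int(rng.integers(0, 4))]
        else:
            osn = inter
        hub = min(hub_idx, key=lambda h: abs(h - e_idx))
        pattern = {"lost": "A", "gained": "B", "retained": "shared"}[inter]
        add_edge("chr2", hub, e_idx, pattern)
        s = e_idx * fsize
        for cond, present in (
            ("A", osn in ("lost", "retained")),
            ("B", osn in ("gained", "retained")),
        ):
            if present:
                factor_peaks[("OCT4", cond)].append(("chr2", s + 500, s + 1700))
                factor_peaks[("SOX2", cond)].append(("chr2", s + 600, s + 1800))
                factor_peaks[("NANOG", cond)].append(("chr2", s + 700, s + 1900))
        seg_rows["A"].append(("chr2", s, s + fsize, "active"))
        seg_rows["B"].append(("chr2", s, s + fsize, "active"))
        osn_truth.append(
            {"fragment": fid("chr2", e_idx), "osn_change": osn, "interaction_change": inter}
        )

    # -- TADs --------------------------------------------------------------
    tad_rows = [
        ("chr1", members[0] * fsize, (members[-1] + 1) * fsize)
        for members in comm_members
    ]
    for t in range(4):
        s = 17_000_000 + t * 600_000
        tad_rows.append(("chr2", s, s + 500_000))
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end"])

    # -- expression and DE -------------------------------------------------
    expr_rows = []
    for g in genes_meta:
        base_expr = float(rng.normal(3.0, 1.0))
        ea, eb = base_expr, base_expr
        kind = g["kind"]
        if not p.null:
            if kind == "se_A":
                ea += p.expression_shift
            elif kind == "se_B":
                eb += p.expression_shift
            elif kind == "se_shared":
                ea += p.expression_shift
                eb += p.expression_shift
            elif kind.startswith("enh_"):
                boost = p.expression_shift / 2
                if kind != "enh_B":
                    ea += boost
                if kind != "enh_A":
                    eb += boost
        if g["de"] == "up_A":
            ea += 2.0
        elif g["de"] == "up_B":
            eb += 2.0
        elif g["de"] == "down_B":
            eb -= 1.5
        lfc = eb - ea
        expr_rows.append(
            {
                "gene": g["gene"],
                "expr_A": ea,
                "expr_B": eb,
                "log2fc": lfc,
                "padj": 0.001 if abs(lfc) > 0.5 else 0.9,
            }
        )
    n_filler = max(0, 200 - len(expr_rows))
    for i in range(n_filler):
        base_expr = float(rng.normal(3.0, 1.0))
        expr_rows.append(
            {"gene": f"XG{i:03d}", "expr_A": base_expr, "expr_B": base_expr,
             "log2fc": 0.0, "padj": 0.9}
        )
    expression = pd.DataFrame(expr_rows)

    # -- CpG methylation (per condition) -----------------------------------
    meth = {"A": [], "B": []}
    for r in enhancer_regions:
        # A-active enhancers gain methylation in B; shared/B-specific stay low
        pa = 0.25
        pb = 0.90 if r["presence"] == "A" else 0.30
        for k in range(5):
            pos = r["start"] + 50 + k * 100
            for cond, prob in (("A", pa), ("B", pb)):
                meth[cond].append(
                    (r["chrom"], pos, int(rng.binomial(20, prob)), 20)
                )
    # genome-background CpGs (chr1 3.0-3.5 Mb)
    for k in range(200):
        pos = 3_000_000 + k * 2500
        for cond, prob in (("A", 0.20), ("B", 0.70)):
            meth[cond].append(("chr1", pos, int(rng.binomial(20, prob)), 20))
    methylation = {
        c: pd.DataFrame(rows, columns=["chrom", "pos", "meth_count", "total_count"])
        for c, rows in meth.items()
    }

    # -- assemble ----------------------------------------------------------
    interactions = pd.DataFrame(edges)
    bait_table = pd.DataFrame(bait_rows).sort_values("gene").reset_index(drop=True)
    baits = BaitAnnotation()
    for r in bait_table.itertuples(index=False):
        frag = fm.lookup(r.chrom, r.tss - 1)  # promoter upstream of TSS
        baits.genes_by_fragment.setdefault(frag, set()).add(r.gene)
    calls = {"A": [], "B": []}
    for r in interactions.itertuples(index=False):
        for cond in ("A", "B"):
            score = getattr(r, f"score_{cond}")
            if np.isfinite(score):
                calls[cond].append(
                    InteractionCall(
                        r.bait, r.other, float(score),
                        int(getattr(r, f"reads_{cond}")), cond,
                    )
                )
    seg = {
        c: SegmentationTrack(
            c, pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
        )
        for c, rows in seg_rows.items()
    }
    h3k27ac_df = {
        c: pd.DataFrame(rows, columns=["chrom", "start", "end", "signal"])
        for c, rows in h3k27ac.items()
    }
    factor_df = {
        key: pd.DataFrame(rows, columns=["chrom", "start", "end"])
        for key, rows in factor_peaks.items()
    }

    manifest = {
        "seed": seed,
        "null": p.null,
        "genome": p.chrom_sizes,
        "params": {k: v for k, v in asdict(p).items() if k != "chrom_sizes"},
        "communities": [
            [fid("chr1", i) for i in members] for members in comm_members
        ],
        "community_regions": [
            {"chrom": "chr1", "start": m[0] * fsize, "end": (m[-1] + 1) * fsize}
            for m in comm_members
        ],
        "bridges": bridges,
        "bivalent_bridge_fraction": (n_bivalent / p.n_bridges) if not p.null else 0.0,
        "se_loci": se_loci,
        "se_gene_classes": se_gene_classes,
        "enhancer_gene_classes": enhancer_gene_classes,
        "osn_truth": osn_truth,
        "n_hub_baits": n_hubs,
    }
    return Fixture(
        p, seed, fm, baits, bait_table, calls["A"], calls["B"], interactions,
        seg["A"], seg["B"], h3k27ac_df, factor_df, tads, expression,
        methylation, manifest,
    )


def generate_null_fixture(
    params: FixtureParams | None = None, seed: int = 7
) -> Fixture:
    """Fixture with statistically exchangeable conditions and no planted
    structure (no bridges, uncoupled OSN/interaction changes, no expression
    shifts); used for type-I error and odds-ratio calibration checks."""
    p = params or FixtureParams()
    p = FixtureParams(**{**asdict(p), "null": True, "n_bridges": 0,
                         "osn_coupling": 0.0, "expression_shift": 0.0})
    return generate_fixture(p, seed)
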