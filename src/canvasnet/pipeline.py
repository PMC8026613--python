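"""End-to-end orchestration of the analysis stages on a file bundle.

Stage order: build -> annotate -> census/communities -> long-range state
profiles -> super-enhancer calling -> target assignment -> OSN -> statistics
-> layouts. Each stage is skippable; a stage whose inputs were skipped fails
with a stage-labelled error. Every output file embeds the tool version, a
hash of the configuration and the seeds used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import chromatin, enhancers, genome_io, layout, network_core, occupancy, stats

STAGES = (
    "build", "annotate", "census", "communities", "longrange",
    "se", "targets", "osn", "stats", "layout",
)


@dataclass
class RunConfig:
    """Declarative configuration for a full pipeline run."""

    fragments: str = "fragments.bed"
    baits: str = "baits.tsv"
    interactions_a: str = "interactions_A.ibed"
    interactions_b: str = "interactions_B.ibed"
    segmentation_a: str = "segmentation_A.bed"
    segmentation_b: str = "segmentation_B.bed"
    h3k27ac_a: str = "h3k27ac_A.bed"
    h3k27ac_b: str = "h3k27ac_B.bed"
    factor_peaks: dict = field(
        default_factory=lambda: {
            (f, c): f"{f.lower()}_{c}.bed"
            for f in ("OCT4", "SOX2", "NANOG")
            for c in ("A", "B")
        }
    )
    tads: str = "tads.bed"
    expression: str = "expression.tsv"
    input_dir: str = "."
    output_dir: str = "canvasnet_out"
    sig_threshold: float = 5.0
    support_threshold: float = 3.0
    modularity_threshold: float = 0.7
    stitch_distance: int = 1500
    osn_merge_distance: int = 100
    promoter_window: int = 1000
    top_n_longest: int = 1000
    min_state_bp: int = 1
    distance_bands: dict = field(default_factory=lambda: dict(network_core.DEFAULT_BANDS))
    n_permutations: int = 500
    seed: int = 0
    skip: list = field(default_factory=list)

    def config_hash(self) -> str:
        # directory locations do not affect the analysis; keep them out so
        # identical runs in different places produce identical outputs
        payload = {
            k: (sorted(v.items()) if isinstance(v, dict) else v)
            for k, v in dataclasses.asdict(self).items()
            if k not in ("input_dir", "output_dir")
        }
        blob = json.dumps(
            {k: str(v) for k, v in payload.items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["factor_peaks"] = {f"{f}_{c}": v for (f, c), v in d["factor_peaks"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "factor_peaks" in d:
            d["factor_peaks"] = {
                (k.rsplit("_", 1)[0], k.rsplit("_", 1)[1]): v
                for k, v in d["factor_peaks"].items()
            }
        d.update(overrides)
        return cls(**d)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


def _metadata_line(config: RunConfig) -> str:
    return (
        f"# canvasnet v{__version__} config={config.config_hash()} "
        f"seed={config.seed}"
    )


def _write_tsv(df: pd.DataFrame, path, config: RunConfig, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(_metadata_line(config) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def fragment_change_classes(
    network: network_core.MergedNetwork,
    states_a: chromatin.FragmentStateAssignment,
    states_b: chromatin.FragmentStateAssignment,
    osn_a: list[occupancy.OSNPeak],
    osn_b: list[occupancy.OSNPeak],
) -> pd.DataFrame:
    """OSN-change and interaction-change classes for enhancer-bearing fragments.

    The universe is every network fragment in the active chromatin state in
    either condition. Interaction change per fragment: lost when it carries
    A-specific but no B-specific edges, gained symmetrically, retained
    otherwise. OSN change from overlap with condition-labelled OSN peaks;
    fragments without OSN occupancy in either condition are "never".
    """
    fm = network.fragment_map

    def osn_frags(peaks):
        out: set[str] = set()
        for p in peaks:
            out.update(fm.overlapping(p.chrom, p.start, p.end))
        return out

    in_a, in_b = osn_frags(osn_a), osn_frags(osn_b)
    rows = []
    for frag in network.graph.nodes:
        if chromatin.ACTIVE not in (states_a.state_of(frag), states_b.state_of(frag)):
            continue
        specs = {
            network.graph.edges[frag, nb]["specificity"]
            for nb in network.graph.neighbors(frag)
        }
        has_a = bool(specs & {network_core.A_SPECIFIC})
        has_b = bool(specs & {network_core.B_SPECIFIC})
        if has_a and not has_b:
            inter = "lost"
        elif has_b and not has_a:
            inter = "gained"
        else:
            inter = "retained"
        a, b = frag in in_a, frag in in_b
        if a and b:
            osn = "retained"
        elif a:
            osn = "lost"
        elif b:
            osn = "gained"
        else:
            osn = "never"
        rows.append({"fragment": frag, "osn_change": osn, "interaction_change": inter})
    return pd.DataFrame(rows, columns=["fragment", "osn_change", "interaction_change"])


def run_pipeline(config: RunConfig) -> dict:
    """Run all requested stages; returns the in-memory results keyed by stage."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    skip = set(config.skip)
    unknown = skip - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) in skip list: {sorted(unknown)}")
    results: dict = {"config": config}

    def need(path, stage):
        p = indir / path
        if not p.exists():
            raise StageError(stage, f"missing input {p}")
        return p

    # ---- build -----------------------------------------------------------
    if "build" in skip:
        raise StageError("build", "the build stage cannot be skipped")
    fm = genome_io.read_fragment_map(need(config.fragments, "build"))
    baits = genome_io.read_promoters(
        need(config.baits, "build"), fm, window=config.promoter_window
    )
    calls_a = genome_io.read_interactions(
        need(config.interactions_a, "build"), fm, "A"
    )
    calls_b = genome_io.read_interactions(
        need(config.interactions_b, "build"), fm, "B"
    )
    network = network_core.build_merged_network(
        calls_a, calls_b, fm,
        sig_threshold=config.sig_threshold,
        support_threshold=config.support_threshold,
    )
    network.graph.graph.update(
        tool_version=__version__, config_hash=config.config_hash(), seed=config.seed
    )
    results["network"] = network
    results["baits"] = baits
    genome_io.write_network_export(network.graph, outdir / "network.gexf", "gexf")

    # ---- annotate --------------------------------------------------------
    states = {}
    if "annotate" not in skip:
        for cond, path in (("A", config.segmentation_a), ("B", config.segmentation_b)):
            seg = genome_io.read_segmentation(need(path, "annotate"), cond)
            states[cond] = chromatin.assign_fragment_states(
                seg, fm, min_state_bp=config.min_state_bp
            )
        results["states"] = states
        if (indir / config.expression).exists():
            de = pd.read_csv(indir / config.expression, sep="\t")
            results["expression_categories"] = chromatin.assign_expression_category(
                baits, de
            )
        for node in network.graph.nodes:
            network.graph.nodes[node]["state"] = states["B"].state_of(node)

    # ---- census + communities -------------------------------------------
    components = network_core.connected_components(network)
    results["components"] = components
    if "census" not in skip:
        census = network_core.subnetwork_census(network, components)
        results["census"] = census
        _write_tsv(network_core.census_table(census), outdir / "census.tsv", config)
    if "communities" not in skip:
        partitions = [
            network_core.detect_communities(
                network, comp,
                modularity_threshold=config.modularity_threshold,
                seed=config.seed,
            )
            for comp in components
        ]
        results["communities"] = partitions
        rows = []
        for part in partitions:
            for ci, members in enumerate(part.communities):
                for frag in members:
                    rows.append(
                        {
                            "fragment": frag,
                            "component": part.component_id,
                            "community": f"{part.component_id}.{ci}",
                            "modularity": part.modularity,
                            "split_applied": part.split_applied,
                        }
                    )
        _write_tsv(pd.DataFrame(rows), outdir / "communities.tsv", config)

    # ---- long-range ------------------------------------------------------
    if "longrange" not in skip:
        if "annotate" in skip:
            raise StageError("longrange", "requires the annotate stage")
        longrange = {}
        for cond in ("A", "B"):
            top = network_core.select_top_longest(
                network, cond, n=config.top_n_longest
            )
            profile, bivalent_fraction = chromatin.longest_interaction_state_profile(
                top, states[cond], baits
            )
            longrange[cond] = {
                "top": top, "profile": profile,
                "bivalent_bait_fraction": bivalent_fraction,
            }
            _write_tsv(profile, outdir / f"longest_state_profile_{cond}.tsv", config)
        anchors = sorted(
            {f for t in longrange["B"]["top"] for f in t[:2]}
        )
        counts, pct = chromatin.state_transition_matrix(
            states["A"], states["B"], anchors
        )
        _write_tsv(counts, outdir / "state_transitions_counts.tsv", config, index=True)
        _write_tsv(pct, outdir / "state_transitions_pct.tsv", config, index=True)
        longrange["transition_counts"] = counts
        longrange["transition_pct"] = pct
        results["longrange"] = longrange

    # ---- super-enhancers -------------------------------------------------
    if "se" not in skip:
        se_results = {}
        for cond, path in (("A", config.h3k27ac_a), ("B", config.h3k27ac_b)):
            peaks = genome_io.read_peaks(need(path, "se"))
            elements = enhancers.stitch_peaks(
                peaks, stitch_distance=config.stitch_distance, condition=cond
            )
            elements, cutoff = enhancers.call_super_enhancers(elements)
            se_results[cond] = {"elements": elements, "cutoff": cutoff}
            _write_tsv(
                enhancers.elements_to_dataframe(elements),
                outdir / f"elements_{cond}.tsv", config,
            )
        labels, pairs = enhancers.match_elements_across_conditions(
            [e for e in se_results["A"]["elements"] if e.is_super],
            [e for e in se_results["B"]["elements"] if e.is_super],
        )
        se_results["se_match_labels"] = labels
        se_results["se_match_pairs"] = pairs
        results["se"] = se_results

    # ---- targets ---------------------------------------------------------
    if "targets" not in skip:
        if "se" in skip:
            raise StageError("targets", "requires the se stage outputs")
        se_targets = {}
        enh_targets = {}
        for cond in ("A", "B"):
            elements = results["se"][cond]["elements"]
            supers = [e for e in elements if e.is_super]
            plains = [e for e in elements if not e.is_super]
            se_targets[cond] = enhancers.map_elements_to_targets(
                supers, network, baits, cond
            )
            enh_targets[cond] = enhancers.map_elements_to_targets(
                plains, network, baits, cond
            )
        se_by_gene = enhancers.classify_target_genes(se_targets["A"], se_targets["B"])
        enh_by_gene = enhancers.classify_target_genes(enh_targets["A"], enh_targets["B"])
        se_classes, enh_classes = enhancers.se_and_enhancer_gene_lists(
            se_by_gene, enh_by_gene
        )
        results["targets"] = {
            "se_gene_classes": se_classes,
            "enhancer_gene_classes": enh_classes,
        }
        df = pd.DataFrame(
            [{"gene": g, "element_type": "SE", "gene_class": c} for g, c in sorted(se_classes.items())]
            + [{"gene": g, "element_type": "enhancer", "gene_class": c} for g, c in sorted(enh_classes.items())]
        )
        _write_tsv(df, outdir / "target_genes.tsv", config)

    # ---- OSN -------------------------------------------------------------
    if "osn" not in skip:
        if "annotate" in skip:
            raise StageError("osn", "requires the annotate stage")
        osn_peaks = {}
        for cond in ("A", "B"):
            factor = {}
            for f in ("OCT4", "SOX2", "NANOG"):
                factor[f] = genome_io.read_bed_regions(
                    need(config.factor_peaks[(f, cond)], "osn")
                )
            osn_peaks[cond] = occupancy.build_osn_peaks(
                factor["OCT4"], factor["SOX2"], factor["NANOG"],
                merge_distance=config.osn_merge_distance, condition=cond,
            )
        changes = fragment_change_classes(
            network, states["A"], states["B"], osn_peaks["A"], osn_peaks["B"]
        )
        counts, pct, tests = occupancy.osn_interaction_contingency(changes)
        results["osn"] = {
            "peaks": osn_peaks,
            "changes": changes,
            "contingency_counts": counts,
            "contingency_pct": pct,
            "contingency_tests": tests,
        }
        _write_tsv(counts, outdir / "osn_contingency_counts.tsv", config, index=True)
        _write_tsv(
            occupancy.contingency_table(tests), outdir / "osn_contingency_tests.tsv",
            config,
        )

    # ---- stats (community vs TAD overlap) --------------------------------
    if "stats" not in skip:
        if "communities" in skip:
            raise StageError("stats", "requires the communities stage")
        tads = genome_io.read_bed_regions(need(config.tads, "stats"))
        genome = {
            chrom: fm.chrom_bounds(chrom)[1] for chrom in fm.chromosomes
        }
        rows = []
        # only modularity-split communities are structural units comparable
        # to TADs; unsplit components would swamp the query with trivial pairs
        for part in results["communities"]:
            if not part.split_applied:
                continue
            for members in part.communities:
                ivs = [fm.get_interval(f) for f in members]
                rows.append(
                    {
                        "chrom": ivs[0].chrom,
                        "start": min(iv.start for iv in ivs),
                        "end": max(iv.end for iv in ivs),
                    }
                )
        community_regions = pd.DataFrame(rows)
        overlap = stats.permutation_overlap_test(
            community_regions, tads[["chrom", "start", "end"]], genome,
            n_permutations=config.n_permutations, seed=config.seed,
        )
        results["tad_overlap"] = overlap
        _write_tsv(
            pd.DataFrame([overlap.__dict__]), outdir / "tad_overlap.tsv", config
        )

    # ---- layout ----------------------------------------------------------
    if "layout" not in skip:
        fa2 = layout.force_directed_layout(
            network.graph, iterations=100, seed=config.seed
        )
        results["layout"] = fa2
        coords = pd.DataFrame(
            [(n, x, y) for n, (x, y) in sorted(fa2.coordinates.items())],
            columns=["fragment", "x", "y"],
        )
        _write_tsv(coords, outdir / "layout.tsv", config)
        genome_io.write_network_export(
            network.graph, outdir / "network_layout.gexf", "gexf",
            layout=fa2.coordinates,
        )
        if "census" not in skip:
            census = results["census"]
            changing = max(census, key=lambda d: abs(d.edges_B - d.edges_A))
            members = components[changing.component_id].members
            if 3 <= len(members) <= 400:
                mds = layout.genomic_mds_layout(network, members)
                results["mds"] = mds
                _write_tsv(
                    pd.DataFrame(
                        [(n, x, y) for n, (x, y) in sorted(mds.coordinates.items())],
                        columns=["fragment", "x", "y"],
                    ),
                    outdir / "mds_most_changing.tsv", config,
                )

    # ---- provenance ------------------------------------------------------
    meta = {
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "thresholds": {
            "sig": config.sig_threshold,
            "support": config.support_threshold,
            "modularity": config.modularity_threshold,
            "stitch": config.stitch_distance,
            "osn_merge": config.osn_merge_distance,
            "distance_bands": config.distance_bands,
        },
        "stages_skipped": sorted(skip),
    }
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    results["metadata"] = meta
    return results
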