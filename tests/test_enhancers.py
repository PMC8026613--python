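"""Enhancer stitching, super-enhancer calling and target assignment."""

import numpy as np
import pandas as pd
import pytest

from canvasnet import enhancers as en
from canvasnet import network_core as nc
from canvasnet import stats as st
from canvasnet.genome_io import BaitAnnotation, FragmentMap, GenomicInterval, InteractionCall


def peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "signal"])


def merge_oracle(rows, gap):
    """Independent interval-merge-with-gap oracle."""
    out = []
    for chrom, start, end, signal in sorted(rows):
        if out and out[-1][0] == chrom and start - out[-1][2] <= gap:
            out[-1][2] = max(out[-1][2], end)
            out[-1][3] += signal
            out[-1][4] += 1
        else:
            out.append([chrom, start, end, signal, 1])
    return out


class TestStitchPeaks:
    def test_gap_boundaries(self):
        merged = en.stitch_peaks(peaks([("chr1", 0, 1000, 1.0), ("chr1", 2000, 3000, 2.0)]))
        assert len(merged) == 1 and merged[0].signal == 3.0  # gap 1000 <= 1500
        apart = en.stitch_peaks(peaks([("chr1", 0, 1000, 1.0), ("chr1", 3000, 4000, 2.0)]))
        assert len(apart) == 2  # gap 2000 > 1500

    def test_random_sets_match_merge_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            rows = [
                ("chr1" if rng.random() < 0.7 else "chr2",
                 int(s), int(s) + int(rng.integers(100, 2000)),
                 float(rng.uniform(1, 10)))
                for s in rng.integers(0, 100_000, size=rng.integers(1, 30))
            ]
            got = en.stitch_peaks(peaks(rows), stitch_distance=1500)
            expected = merge_oracle(rows, 1500)
            assert [(e.chrom, e.start, e.end, e.n_constituents) for e in got] == [
                (r[0], r[1], r[2], r[4]) for r in expected
            ]
            assert [e.signal for e in got] == pytest.approx([r[3] for r in expected])

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        rows = [
            ("chr1", int(s), int(s) + 500, 1.0)
            for s in rng.integers(0, 50_000, size=25)
        ]
        once = en.stitch_peaks(peaks(rows))
        twice = en.stitch_peaks(
            peaks([(e.chrom, e.start, e.end, e.signal) for e in once])
        )
        assert [(e.chrom, e.start, e.end) for e in once] == [
            (e.chrom, e.start, e.end) for e in twice
        ]
        assert [e.signal for e in once] == pytest.approx([e.signal for e in twice])


def elements_with_signals(signals):
    return [
        en.RegulatoryElement(f"e{i}", "chr1", i * 10_000, i * 10_000 + 1000, 1, s, "A")
        for i, s in enumerate(signals)
    ]


class TestSuperEnhancerCall:
    def test_single_outlier(self):
        els, cutoff = en.call_super_enhancers(elements_with_signals([1, 2, 3, 4, 100]))
        assert cutoff == 4
        assert sorted(e.signal for e in els if e.is_super) == [100]

    def test_two_tier_signals(self):
        els, _ = en.call_super_enhancers(elements_with_signals([1, 1, 1, 10, 10]))
        assert sorted(e.signal for e in els if e.is_super) == [10, 10]

    def test_all_equal_no_supers(self):
        with pytest.warns(UserWarning, match="no super-enhancers"):
            els, _ = en.call_super_enhancers(elements_with_signals([5, 5, 5]))
        assert not any(e.is_super for e in els)

    def test_cutoff_matches_scaled_argmax_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(30):
            signals = sorted(rng.lognormal(1, 1, size=rng.integers(3, 40)))
            els, cutoff = en.call_super_enhancers(elements_with_signals(list(signals)))
            x = np.linspace(0, 1, len(signals))
            y = (np.array(signals) - signals[0]) / (signals[-1] - signals[0])
            assert cutoff == pytest.approx(signals[int(np.argmax(x - y))])

    def test_affine_invariance(self):
        """Rescaling all signals affinely cannot change which elements are
        super (both axes are normalised to [0, 1] first)."""
        rng = np.random.default_rng(16)
        signals = list(rng.lognormal(1, 1, size=25))
        base, _ = en.call_super_enhancers(elements_with_signals(signals))
        flags = [e.is_super for e in base]
        for a, b in [(3.0, 0.0), (0.5, 10.0), (100.0, -1.0)]:
            scaled, _ = en.call_super_enhancers(
                elements_with_signals([a * s + b for s in signals])
            )
            assert [e.is_super for e in scaled] == flags

    def test_ranks_unique(self):
        els, _ = en.call_super_enhancers(elements_with_signals([2, 2, 2, 9]))
        assert sorted(e.rank for e in els) == [0, 1, 2, 3]

    def test_too_few_elements_rejected(self):
        with pytest.raises(ValueError):
            en.call_super_enhancers(elements_with_signals([1]))


class TestMatchAcrossConditions:
    def el(self, eid, start, end, cond):
        return en.RegulatoryElement(eid, "chr1", start, end, 1, 1.0, cond)

    def test_one_to_two_overlap(self):
        a = [self.el("a1", 0, 10_000, "A")]
        b = [self.el("b1", 0, 2000, "B"), self.el("b2", 5000, 8000, "B")]
        labels, pairs = en.match_elements_across_conditions(a, b)
        assert labels == {"a1": "shared", "b1": "shared", "b2": "shared"}
        assert len(pairs) == 2  # one A element, two B elements

    def test_disjoint_all_specific(self):
        a = [self.el("a1", 0, 1000, "A")]
        b = [self.el("b1", 5000, 6000, "B")]
        labels, pairs = en.match_elements_across_conditions(a, b)
        assert labels == {"a1": "A_specific", "b1": "B_specific"}
        assert pairs.empty

    def test_random_sets_match_pairwise_oracle(self):
        rng = np.random.default_rng(27)
        for _ in range(20):
            a = [
                self.el(f"a{i}", int(s), int(s) + 1000, "A")
                for i, s in enumerate(rng.integers(0, 50_000, 15))
            ]
            b = [
                self.el(f"b{i}", int(s), int(s) + 1000, "B")
                for i, s in enumerate(rng.integers(0, 50_000, 15))
            ]
            labels, _ = en.match_elements_across_conditions(a, b)
            for ea in a:
                hit = any(min(ea.end, eb.end) - max(ea.start, eb.start) >= 1 for eb in b)
                assert labels[ea.element_id] == ("shared" if hit else "A_specific")


def star_network():
    """Bait gene G at fragment 0; enhancer fragments 2 (A-only edge) and 4
    (shared edge)."""
    fm = FragmentMap(
        [(f"f{i}", GenomicInterval("chr1", i * 4000, (i + 1) * 4000)) for i in range(6)]
    )
    calls_a = [
        InteractionCall("f0", "f2", 6.0, 1, "A"),
        InteractionCall("f0", "f4", 6.0, 1, "A"),
    ]
    calls_b = [InteractionCall("f0", "f4", 6.0, 1, "B")]
    net = nc.build_merged_network(calls_a, calls_b, fm)
    baits = BaitAnnotation({"f0": {"G"}})
    return net, baits


class TestTargets:
    def test_condition_specific_wiring(self):
        net, baits = star_network()
        se_a = [en.RegulatoryElement("se1", "chr1", 8500, 9500, 1, 50.0, "A", is_super=True)]
        targets = en.map_elements_to_targets(se_a, net, baits, "A")
        assert targets == {"se1": {"G"}}
        # the same element mapped through condition B finds nothing (A-only edge)
        assert en.map_elements_to_targets(se_a, net, baits, "B") == {"se1": set()}

    def test_shared_edge_gives_shared_class(self):
        net, baits = star_network()
        se = [en.RegulatoryElement("se1", "chr1", 16_500, 17_500, 1, 50.0, "", is_super=True)]
        by_gene = en.classify_target_genes(
            en.map_elements_to_targets(se, net, baits, "A"),
            en.map_elements_to_targets(se, net, baits, "B"),
        )
        assert by_gene["G"].gene_class == "shared"

    def test_element_on_bait_fragment_maps_through_edges_only(self):
        net, baits = star_network()
        on_bait = [en.RegulatoryElement("x", "chr1", 100, 900, 1, 5.0, "A")]
        targets = en.map_elements_to_targets(on_bait, net, baits, "A")
        assert targets == {"x": set()}  # f0 has no baited neighbours

    def test_se_contacted_genes_removed_from_enhancer_list(self):
        se = {"G1": en.TargetAssignment("G1", {"se"}, set())}
        enh = {
            "G1": en.TargetAssignment("G1", {"e1"}, set()),
            "G2": en.TargetAssignment("G2", set(), {"e2"}),
        }
        se_classes, enh_classes = en.se_and_enhancer_gene_lists(se, enh)
        assert se_classes == {"G1": "A_only"}
        assert enh_classes == {"G2": "B_only"}

    def test_gene_classes_partition(self, study, network):
        """A_only + B_only + shared partitions the SE-target gene set."""
        els = {}
        for cond in ("A", "B"):
            e = en.stitch_peaks(study.h3k27ac[cond], 1500, cond)
            e, _ = en.call_super_enhancers(e)
            els[cond] = [x for x in e if x.is_super]
        by_gene = en.classify_target_genes(
            en.map_elements_to_targets(els["A"], network, study.baits, "A"),
            en.map_elements_to_targets(els["B"], network, study.baits, "B"),
        )
        classes = [t.gene_class for t in by_gene.values()]
        assert set(classes) <= {"A_only", "B_only", "shared"}
        assert len(by_gene) == len(set(by_gene))

    def test_contact_count_distributions(self):
        targets = {"e1": {"G1", "G2", "G3"}, "e2": set()}
        per_el = en.contacts_per_element(targets)
        assert per_el["e1"] == 3 and per_el["e2"] == 0
        per_gene = en.elements_per_gene(targets)
        assert per_gene["G1"] == 1
        assert en.elements_per_gene({}).empty


class TestQuantitation:
    def test_pooled_methylation(self):
        regions = pd.DataFrame([("chr1", 0, 1000)], columns=["chrom", "start", "end"])
        calls = pd.DataFrame(
            [("chr1", 10, 2, 4), ("chr1", 20, 2, 4)],
            columns=["chrom", "pos", "meth_count", "total_count"],
        )
        assert en.quantify_methylation(regions, calls)[0] == 50.0

    def test_no_cpg_is_missing(self):
        regions = pd.DataFrame([("chr1", 0, 1000)], columns=["chrom", "start", "end"])
        calls = pd.DataFrame(
            [("chr2", 10, 2, 4)], columns=["chrom", "pos", "meth_count", "total_count"]
        )
        assert np.isnan(en.quantify_methylation(regions, calls)[0])

    def test_random_calls_match_pooled_ratio(self):
        rng = np.random.default_rng(33)
        regions = pd.DataFrame(
            [("chr1", i * 1000, i * 1000 + 800) for i in range(20)],
            columns=["chrom", "start", "end"],
        )
        calls = pd.DataFrame(
            [
                ("chr1", int(p), int(m), 10)
                for p, m in zip(rng.integers(0, 20_000, 300), rng.integers(0, 11, 300))
            ],
            columns=["chrom", "pos", "meth_count", "total_count"],
        )
        got = en.quantify_methylation(regions, calls)
        for i, row in regions.iterrows():
            inside = calls[
                (calls["pos"] >= row["start"]) & (calls["pos"] < row["end"])
            ]
            if inside["total_count"].sum() == 0:
                assert np.isnan(got[i])
            else:
                assert got[i] == pytest.approx(
                    100 * inside["meth_count"].sum() / inside["total_count"].sum()
                )

    def test_invalid_counts_rejected(self):
        regions = pd.DataFrame([("chr1", 0, 100)], columns=["chrom", "start", "end"])
        calls = pd.DataFrame(
            [("chr1", 10, 5, 4)], columns=["chrom", "pos", "meth_count", "total_count"]
        )
        with pytest.raises(ValueError):
            en.quantify_methylation(regions, calls)


class TestHistoneGain:
    def test_threshold_cases(self):
        gain, _ = en.histone_gain_classifier([0.0, 0.0], [1.5, 0.9])
        assert list(gain) == [True, False]

    def test_median_fold_change(self):
        # linear medians 1.0 vs 4.0 -> log2 fold change 2
        a = np.log2([1.0, 1.0, 1.0])
        b = np.log2([4.0, 4.0, 4.0])
        _, fc = en.histone_gain_classifier(a, b)
        assert fc == pytest.approx(2.0)

    def test_nonfinite_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            gain, _ = en.histone_gain_classifier([0.0, np.nan], [2.0, 5.0])
        assert list(gain) == [True, False]


class TestExpressionPower:
    def test_planted_shift_detected_with_high_power(self):
        """With 50 genes per group and a one-standard-deviation shift, the
        two-sided rank test rejects at alpha = 0.05 in at least 90% of
        replicates."""
        rng = np.random.default_rng(55)
        reps = 200
        hits = 0
        for _ in range(reps):
            base = rng.normal(3, 1, size=50)
            shifted = rng.normal(4, 1, size=50)
            if st.mann_whitney_u(list(shifted), list(base)).p_value < 0.05:
                hits += 1
        assert hits / reps >= 0.9
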