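"""Super-enhancer calling and interaction-mediated target genes.

Stitches H3K27ac peaks (1.5 kb gap), calls super-enhancers with the
rank-curve tangent cutoff, maps elements to target genes through
condition-supported network edges, and compares the expression of
condition-specific versus shared SE-target genes with a rank test.
"""

import canvasnet as cn
from canvasnet import enhancers as en
from canvasnet import stats as st

study = cn.generate_fixture(seed=7)
network = cn.build_merged_network(study.calls_a, study.calls_b, study.fragment_map)

elements = {}
for cond in ("A", "B"):
    els = en.stitch_peaks(study.h3k27ac[cond], stitch_distance=1500, condition=cond)
    els, cutoff = en.call_super_enhancers(els)
    elements[cond] = els
    n_super = sum(e.is_super for e in els)
    print(f"condition {cond}: {len(els)} elements, {n_super} super-enhancers "
          f"(signal cutoff {cutoff:.1f})")

se_targets = {
    c: en.map_elements_to_targets(
        [e for e in elements[c] if e.is_super], network, study.baits, c
    )
    for c in ("A", "B")
}
enh_targets = {
    c: en.map_elements_to_targets(
        [e for e in elements[c] if not e.is_super], network, study.baits, c
    )
    for c in ("A", "B")
}
se_classes, enh_classes = en.se_and_enhancer_gene_lists(
    en.classify_target_genes(se_targets["A"], se_targets["B"]),
    en.classify_target_genes(enh_targets["A"], enh_targets["B"]),
)
by_class = {}
for c in se_classes.values():
    by_class[c] = by_class.get(c, 0) + 1
print("SE-target gene classes:", dict(sorted(by_class.items())))
print(f"plain-enhancer target genes (SE-contacted genes removed): {len(enh_classes)}")

# expression of A-specific SE targets vs all other genes, in condition A
expr = study.expression.set_index("gene")
a_targets = [g for g, c in se_classes.items() if c == "A_only"]
rest = [g for g in expr.index if g not in se_classes]
res = st.mann_whitney_u(
    list(expr.loc[a_targets, "expr_A"]), list(expr.loc[rest, "expr_A"])
)
print(
    f"A-specific SE targets vs non-SE genes (expr in A): "
    f"U = {res.statistic:.0f}, p = {res.p_value:.3g} ({res.method})"
)
# SE-contacted genes carry the planted expression boost, so the rank test
# rejects: SE wiring tracks transcriptional output.
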