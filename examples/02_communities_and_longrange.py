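"""Community structure and long-range interaction chromatin states.

Splits the largest sub-network into communities by modularity optimisation
(components with best-partition Q >= 0.7 are split), tests community/TAD
overlap by permutation, and profiles the chromatin states joined by the
longest condition-B interactions (the analog of Polycomb-network formation).
"""

import pandas as pd

import canvasnet as cn
from canvasnet import chromatin as ch
from canvasnet import network_core as nc
from canvasnet import stats as st

study = cn.generate_fixture(seed=7)
network = cn.build_merged_network(study.calls_a, study.calls_b, study.fragment_map)
components = nc.connected_components(network)
part = nc.detect_communities(network, components[0], seed=0)
print(
    f"largest sub-network: Q = {part.modularity:.3f}, "
    f"{len(part.communities)} communities (split applied: {part.split_applied})"
)

# community genomic spans vs TADs
fm = study.fragment_map
regions = pd.DataFrame(
    [
        {
            "chrom": fm.get_interval(m[0]).chrom,
            "start": min(fm.get_interval(f).start for f in m),
            "end": max(fm.get_interval(f).end for f in m),
        }
        for m in part.communities
    ]
)
genome = {c: fm.chrom_bounds(c)[1] for c in fm.chromosomes}
overlap = st.permutation_overlap_test(regions, study.tads, genome, 1000, seed=0)
print(
    f"community/TAD overlap: {overlap.observed}/{len(regions)} observed, "
    f"null mean {overlap.null_mean:.2f}, empirical p = {overlap.p_value:.4f}"
)

# chromatin states at the longest condition-B interactions
states_b = ch.assign_fragment_states(study.segmentation_b, fm)
top = nc.select_top_longest(network, "B", n=15)
profile, frac = ch.longest_interaction_state_profile(top, states_b, study.baits)
print(f"fraction of longest B interactions with a bivalent promoter: {frac:.2f}")
# A high bivalent fraction marks de-novo long-range Polycomb-associated
# interaction networks in condition B.
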