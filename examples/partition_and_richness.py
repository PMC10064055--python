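"""Partition paired OTU tables into compartment-specific and shared OTUs.

Simulates paired epiphyte (leaf-surface) and endophyte (leaf-interior)
communities over 11 hosts, applies the <10-read error filter, and reports
the OTU partition plus the paired t-test on log richness.
"""

import phyllonet as pn

tree = pn.simulate_tree(n_tips=11, seed=1)
params = pn.CommunitySimParams(n_hosts=11, n_otus=400, depth=20000, seed=2)
epi, endo = pn.simulate_paired_communities(tree, params)

epi = pn.filter_low_count(epi, min_reads=10)
endo = pn.filter_low_count(endo, min_reads=10)

part = pn.partition_otus(epi, endo)
print(
    f"{part.n_total} OTUs total: {part.n_epiphyte_specific} "
    f"({part.pct_epiphyte_specific}%) epiphyte-specific, "
    f"{part.n_endophyte_specific} ({part.pct_endophyte_specific}%) "
    f"endophyte-specific, {part.n_shared} ({part.pct_shared}%) shared"
)

rich_epi, rich_endo = pn.richness(epi), pn.richness(endo)
res = pn.paired_t_log(
    {k: float(v) for k, v in rich_epi.items()},
    {k: float(v) for k, v in rich_endo.items()},
    tail="greater",
)
print(
    f"paired t on log richness (epiphyte > endophyte): "
    f"t = {res.statistic:.2f}, df = {res.extra['df']}, p = {res.p_value:.3f}"
)
print(
    "A small p would mean leaf surfaces host reliably more OTUs than leaf "
    "interiors across the same hosts."
)
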