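"""Run the complete analysis pipeline on a synthetic paired-community world.

One config drives every stage: preprocessing, partition and richness tests,
community ordination and permutation tests, phylogenetic signal, network
metrics with null-model z-scores, and robustness.  Outputs land in
scratch/pipeline_demo/ as report.json + summary.md.
"""

import phyllonet as pn

cfg = pn.PipelineConfig(
    synthetic=pn.CommunitySimParams(n_hosts=11, n_otus=300, depth=20000),
    n_null=100,
    n_perm_anosim=999,
    n_perm_mantel=499,
    n_perm_k=499,
    n_rep_extinction=50,
    nmds_starts=8,
    seed=42,
    output_dir="scratch/pipeline_demo",
)
report = pn.run_pipeline(cfg)

print(open("scratch/pipeline_demo/summary.md").read())
print(
    "The Mantel contrast (significant for epiphytes, not endophytes) and the "
    "network z-score signs mirror the field pattern this package is built "
    "to analyse."
)
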