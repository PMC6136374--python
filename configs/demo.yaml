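# Demo pipeline configuration: simulated study at reduced scale.
# 2000 genes, AraPPINet-like mean degree 50, planted x5 cross-set
# enrichment with 10+10 core genes, R=200 randomized networks.
replicates: 200
sim_n_nodes: 2000
sim_mean_degree: 50.0
sim_size_a: 50
sim_size_b: 200
sim_enrichment_factor: 5.0
sim_n_core_a: 10
sim_n_core_b: 10
sim_core_excess: 10.0
sim_n_samples: 50
n_resamples: 100
seed: 11
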