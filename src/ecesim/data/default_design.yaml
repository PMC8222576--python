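mu_levels:
- 0.0
- 0.0005
- 0.001
- 0.0015
- 0.002
- 0.0025
- 0.003
- 0.0035
- 0.004
- 0.0045
- 0.005
tau_levels:
- 0.0
- 0.0005
- 0.001
- 0.0015
- 0.002
- 0.0025
- 0.003
- 0.0035
- 0.004
- 0.0045
- 0.005
n_replicates: 10
generations: 100
population_size: 60
n_codons: 6000
steps: 501
master_seed: 0
evaluator: surrogate
out_dir: runs
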