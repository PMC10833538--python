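# RNA-folding model, N = 100, contrasting recombination probabilities.
model: rna
L: 100
sigma: 0.025
alpha: 12
U: 0.1
N_values: [100]
regimes: ["limited:0.01", "limited:1", free]
replicates: 5
target_D: 0.1
max_generations: 3000
master_seed: 2
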