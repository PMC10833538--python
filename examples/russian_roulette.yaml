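# Divergence experiment on the random (Russian roulette) holey landscape:
# three population sizes under free recombination, 10 replicate pairs each.
model: russian_roulette
L: 30
p: 0.5
U: 0.1
N_values: [10, 50, 100]
regimes: [free]
replicates: 10
target_D: 0.15
max_generations: 4000
master_seed: 1
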