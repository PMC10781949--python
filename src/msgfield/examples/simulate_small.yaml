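# Small synchronization run: 200 oscillators, Cauchy frequencies well below
# the critical coupling 2*gamma, so the steady order parameter approaches
# sqrt(1 - 2*gamma/coupling) ~ 0.95.
omega0: 0.0
gamma: 0.05
coupling: 1.0
n: 200
dt: 0.01
horizon: 50.0
burn_in_fraction: 0.5
seed: 1
out_prefix: sync_small
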