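# msgfield

Message-force-field simulation of coupled biological oscillators:
synchronization and its breaking by proliferation, entropy accounting for
message flows, a six-stage early-embryo demonstration of inner/outer
symmetry breaking, and finite transition-system models (causal, surrogate,
message-field) with category-theoretic consistency checks.

## The problem and the model

Living systems are open systems that exchange *messages* — secreted
chemicals, light, mechanical stimuli, cell-cell contacts.  A message exerts
a force that changes the state of the receiver, decaying exponentially with
the sender-receiver distance *d*:

    G(d) = exp(-beta d)          (diffusive messages)
    G(d) = 1 if d = 0 else 0     (contact messages, e.g. cadherin adhesion)

gated by receptor expression and an activation threshold.  Message flow
*J = (1/A) dn/dt* through a unit area generates entropy at density
*sigma = Σᵢ Gᵢ Jᵢ*, the package's measure of how strongly a configuration
drives irreversible change.

Each cell (or subsystem) is a limit-cycle oscillator reduced to a phase
θⱼ with natural frequency ωⱼ, coupled through the message force field in
Kuramoto form:

    dθⱼ/dt = ωⱼ + (1/N) Σₖ G_jk h(θⱼ − θₖ),      h(x) = −sin(x) by default.

Coherence is measured by the order parameter R e^{iΘ} = (1/N) Σⱼ e^{iθⱼ}
(R = 1: full synchrony; R ≈ 0: incoherence).  For natural frequencies drawn
from a Cauchy (Lorentzian) distribution with scale γ and a global binding
strength G_E, the stationary order parameter obeys

    R∞ = sqrt(1 − 2γ/G_E)  for G_E > 2γ,   R∞ = 0  otherwise,

so synchronization requires coupling above the critical value G_c = 2γ.
The package simulates the finite-N dynamics, verifies this law, and
recovers G_c from steady states by regressing R̄² on 1/G.

On top of the dynamics sit populations (spatial cells, contact graphs,
synchronous division, compaction, inner/outer classification by received
force, coherence clustering) and a discrete layer: any run summarizes into
finite transition systems whose maps can be checked for functoriality,
monoid-action laws, and adjunction witnesses between small freely generated
categories.

## Worked example

The six-stage embryo demonstration — fertilized egg to 16-cell stage, with
seven autocrine growth factors (EGF, IGF-I, GM-CSF, BDNF, CSF-1, artemin,
GDNF) on six receptors, E-cadherin compaction at the 8-cell stage, and
differentiation into trophectoderm and inner cell mass:

```
$ msgfield embryo --seed 1 --out demo_out
S1 fertilized egg: cells= 1 R=1.000 sigma=0.000 clusters=1
S2         2-cell: cells= 2 R=1.000 sigma=5.150 clusters=1
S3         4-cell: cells= 4 R=1.000 sigma=20.601 clusters=1
S4         8-cell: cells= 8 R=1.000 sigma=41.202 clusters=1
S5     compaction: cells= 8 R=1.000 sigma=108.706 clusters=1
S6        16-cell: cells=16 R=0.783 sigma=82.405 clusters=2
final populations: 2 (inner 4, outer 12); cdx2 proxy on 12 outer cells
wrote report and transition systems under demo_out
```

Reading the output: division stages S1–S4 stay fully synchronized (R = 1.0,
one coherence cluster) because the uniform autocrine field couples every
cell equally; entropy generation sigma grows with the number of message
flows as the population doubles.  At S5 compaction makes the received force
asymmetric (the two centre cells gain contacts), which labels 2 cells
"inner" and 6 "outer"; the cdx2 transcript proxy localizes to the outer
cells.  After the final division the cross-lineage coupling is attenuated
and the 4 inner and 12 outer cells synchronize separately: the global R
drops to ~0.78 while the coherence detector reports exactly 2 clusters —
the inner cell mass and the trophectoderm.

The same machinery at the population scale, recovering the critical
coupling for γ = 0.5 (theory: G_c = 2γ = 1):

```
$ msgfield sweep --gamma 0.5 --n 400 --grid 1.25,1.5,2,2.5,3,4 --seed 5 --out sweep.tsv
G_c estimate = 0.8987 (intercept 0.9296); wrote sweep.tsv
```

Other subcommands: `msgfield simulate --config FILE` (packaged example in
`src/msgfield/examples/simulate_small.yaml`), `msgfield fixtures --name
eight_cell --out PREFIX` (canonical cluster geometries), and
`msgfield check-models --system FILE` (transition-system law checks).

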