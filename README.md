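# diracsp

Joint denoising of **node and edge signals on networks** with the
topological Dirac operator.

Topological signals attach a value to every simplex of a network: a scalar
per node (a 0-cochain χ) and a flow per edge (a 1-cochain ϕ) — think ocean
currents projected on a mesh, synaptic flows, or any node feature paired
with an edge flux. Classical Laplacian smoothing (graph/simplicial signal
processing) denoises each dimension separately and assumes the true signal
is smooth or harmonic. Both assumptions often fail on real data. This
package denoises the stacked *topological spinor* ψ = (χ, ϕ) jointly,
without assuming smoothness.

## The model

For a graph with boundary (signed incidence) matrix **B**, the Dirac
operator and gamma matrix are

    D = [[0, B], [Bᵀ, 0]],     γ = diag(+1 on nodes, −1 on edges),

so that D² = diag(L₀, L₁) stacks the graph Laplacian and the edge (Hodge)
Laplacian. The eigenstates of the *topological Dirac equation*
(D + mγ)ψ = Eψ obey the relativistic dispersion relation E² = m² + λ²
(λ a singular value of B); the mass m opens a spectral gap |E| ≥ |m| and
tunes the relative scale of the node and edge blocks of each eigenstate —
exactly the freedom real data needs.

**Dirac-equation signal processing (DESP)** reconstructs a noisy
measurement ψ̃ = ψ + ε by minimizing

    L(ψ̂) = ‖ψ̂ − ψ̃‖² + τ ψ̂ᵀ (D + mγ − E I)² ψ̂,

whose closed-form solution attenuates the component at energy Eₖ by
1/(1 + τ(Eₖ − E)²). The energy E is learned by a damped Rayleigh-quotient
fixed point (Armijo backtracking guarantees monotone loss decrease); the
mass m by a grid sweep, selected either by the per-mass loss Lₘ or by the
relativistic dispersion-relation error Sₘ = |Eₘ² − λₘ² − m²|, which
vanishes exactly on Dirac-equation eigenstates. Setting m = 0 recovers
Dirac signal processing (DSP); m = E = 0 recovers blockwise Laplacian
smoothing (LSP). **IDESP** iterates DESP on the residual to peel off one
eigenstate per round, stopping when the coefficient of variation
cV(J) = ‖Σψ̂ⱼ − ψ̃‖/‖Σψ̂ⱼ‖ best matches the known noise-to-signal ratio.

Everything needed to exercise the pipeline ships with the package: the
Network Geometry with Flavor (NGF, d=2, s=−1) benchmark generator,
Dirac-equation eigenstate/mixture signals, the projected-Gaussian noise
model, and loaders for edge-list/signal CSV files (including drifter-style
edge flows lifted to spinors via ψ = C(σ + Dσ)).

## Worked example

```python
import numpy as np
import diracsp as dsp

network = dsp.ngf_network(20, seed=1)          # NGF skeleton: 20 nodes, 37 edges
system = dsp.dirac_system(network)

# true signal: lowest-energy eigenstate of the Dirac equation at mass 1.5
psi, meta = dsp.sample_signal(system, dsp.SignalSpec(mass=1.5, selector=0))
noisy = dsp.add_noise(psi, dsp.NoiseSpec(alpha=0.3, seed=7), system)

model = dsp.DiracEquationDenoiser(noisy, system, tau=10.0)
res = model.fit()                               # mass sweep + energy learning
print(res.summary())
```

prints

```
Dirac-equation signal processing results
==============================================
Network:            N0=20  N1=37
tau:                10
mass grid:          51 points in [0, 2.958]
criterion:          loss
selected mass:      1.41981
learned energy:     -3.27915
loss L_m:           0.0612545
RDRE S_m:           0.000662409
inner iterations:   10 (converged: True)
m_hat (loss):       1.41981
m_S (RDRE):         0
==============================================
```

The sweep recovers the mass (1.42 vs the true 1.5, about one grid step) and
the energy (−3.28 vs the true −3.32). `res.error(psi)` reports the
reconstruction errors — here Δψ = 0.085 against a noise level of 0.27,
while plain Laplacian smoothing (`model.fit(method="lsp")`) leaves an error
of 0.99: this strongly nonharmonic signal is invisible to a low-pass
filter but recovered almost exactly by DESP. `res.plot_sweep()` shows Lₘ
and Sₘ over the grid; `dsp.IteratedDenoiser(...).fit(cv_true=...)` runs
the iterated peeling.

The same operations are available from the shell:

```bash
diracsp generate-ngf --n0 20 --seed 1 --out net.csv
diracsp simulate-signal --edges net.csv --mass 1.5 --state 0 --out sig.csv
diracsp add-noise --edges net.csv --signal sig.csv --alpha 0.3 --seed 7 --out noisy.csv
diracsp denoise --edges net.csv --signal noisy.csv --method desp --tau 10 --out rec.csv
diracsp run-experiment --preset fig4-comparison --seed 1 --out-dir results/
```

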