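# neurogsp

Directed graph signal processing of parcellated brain activity on cellular
connectomes.

Tracer-derived inter-areal connectomes are directed and weighted: the
fraction of labeled neurons projecting from one cortical area to another is
not symmetric, and the weights span several orders of magnitude. Standard
connectome-eigenmode ("connectome harmonics") analyses assume an undirected
graph and discard that directionality. `neurogsp` implements the directed
alternative for researchers in network neuroscience: it builds the
normalized directed graph Laplacian of the connectome's ergodic random
walk,

    𝓛 = I − (Π^{1/2} P Π^{−1/2} + Π^{−1/2} Pᵀ Π^{1/2}) / 2,
    P = D⁻¹A,  Π = diag(π),  πP = π,

eigendecomposes it into connectome eigenmodes ψ₁…ψ_N with graph
frequencies 0 = λ₁ ≤ … ≤ λ_N ≤ 2, expands regional time series on that
basis (graph Fourier transform, `w = Ψᵀf`), splits the spectrum into
equal-energy low- and high-frequency bands, and quantifies each region's
**cellular-functional decoupling**

    CFD_i = log₂( ‖f_i^high‖₂ / ‖f_i^low‖₂ ),

the log-ratio of a region's graph-irregular (decoupled) to graph-smooth
(anatomy-coupled) signal content. Inference against degree-preserving
rewired graphs, graph spectral randomization, Moran spectral
randomization, and variogram-matched spatial-autocorrelation-preserving
surrogates is included, along with cross-basis (homolog-area)
reconstruction, a two-stage binomial localization test, and a synthetic
study generator so the whole pipeline is testable without any data
downloads.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
import neurogsp as ng

spec = ng.SyntheticSpec(seed=1)                      # 55 regions, 2x5 scans
graph = ng.make_connectome(spec)
tm = ng.transition_model(graph)
basis = ng.eigenmodes(ng.directed_laplacian(tm), graph.labels)
print(f"lambda_1 = {basis.eigenvalues[0]:.2e}, lambda_N = {basis.eigenvalues[-1]:.3f}")

scans, planted = ng.make_cohort(spec, basis=basis)
pooled = ng.RegionalTimeSeries(labels=graph.labels,
                               values=np.hstack([t.values for t in scans]))
cutoff = ng.dichotomize(ng.mean_esd(ng.gft(basis, pooled)))
print(f"dichotomization cutoff C = {cutoff.c} of {basis.n_modes}")

acc20 = ng.reconstruction_accuracy(basis, pooled, 20)
print(f"20-mode activity reconstruction accuracy = {acc20:.3f}")

group = ng.group_mean_cfd([ng.cfd(t, basis, cutoff) for t in scans])
rho = spearmanr(planted, group.values).statistic
print(f"planted-gradient recovery: Spearman rho = {rho:.3f}")
```

prints

```
lambda_1 = 1.55e-15, lambda_N = 1.624
dichotomization cutoff C = 28 of 55
20-mode activity reconstruction accuracy = 0.613
planted-gradient recovery: Spearman rho = 0.947
```

λ₁ ≈ 0 is the ergodicity check (the random walk's stationary direction is
the zero-frequency mode); C = 28 is where the cumulative mean energy
spectral density crosses half the total, defining the low/high bands; the
20-mode accuracy is the fraction of total signal norm captured by the 20
smoothest eigenmodes (the synthetic signal spreads energy across both
bands by design, so it sits well below 1); and ρ = 0.947 shows the
decoupling index recovering the generator's planted per-region log₂
band-energy gradient.

A scikit-learn-style surface is available too (`ConnectomeEigenmodes`,
`GraphBandFilter`, `DecouplingIndex` compose with sklearn pipelines), and
a CLI covers the same steps file-to-file:

```bash
neurogsp simulate --n-regions 55 --seed 1 out/sim
neurogsp eigenmodes out/sim/connectome.tsv out/eig
neurogsp cfd --eigenmodes-path out/eig/eigenmodes.tsv \
             --eigenvalues-path out/eig/eigenvalues.tsv \
             out/sim/scan_*.tsv out/cfd.tsv
```

See `docs/methods.md` for the model, the surrogate constructions and the
numerical conventions.

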