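# Methods

## Model

`neurogsp` treats parcellated brain activity as a graph signal living on a
weighted, directed, inter-areal connectome. The analysis proceeds in five
steps.

**1. Random-walk operator.** Given a nonnegative adjacency `A` (rows =
source areas, weights are connection fractions), the random walk has
transition matrix `P = D⁻¹A` with `D` the diagonal out-degree matrix. The
walk must be ergodic, which requires strong connectivity; when a graph
fails that test, a uniform teleportation blend
`P' = (1 − α)P + α/N` (PageRank construction, default α = 0.01 when
requested) restores ergodicity. The α actually applied is recorded in all
outputs. The stationary distribution π (πP = π, Σπ = 1) is obtained by a
direct dense solve of the left-eigenvector system rather than power
iteration, because periodic chains — a 2-cycle is the smallest example —
have a unique stationary distribution but no power-iteration limit.

**2. Directed Laplacian and eigenmodes.** The normalized directed graph
Laplacian is

    𝓛 = I − (Π^{1/2} P Π^{−1/2} + Π^{−1/2} Pᵀ Π^{1/2}) / 2,   Π = diag(π).

It is symmetric by construction, annihilates √π, has spectrum in [0, 2],
and reduces exactly to the normalized undirected Laplacian
`I − D^{−1/2} A D^{−1/2}` when `A` is symmetric (both identities are
regression-tested). Its eigenvectors ψ₁…ψ_N (ascending eigenvalues) are the
connectome eigenmodes; eigenvalues act as graph frequencies. Eigenvector
sign is fixed deterministically by making each mode's largest-magnitude
entry nonnegative (ties broken by lowest region index); bases of repeated
eigenvalues are arbitrary up to rotation, and downstream comparisons are
written to be subspace-safe.

**3. Graph Fourier analysis.** Regional signals `f` (N × T, z-scored per
region with population divisor T, so each region's L2 concentration is
exactly √T) transform as `w = Ψᵀf`; `ESD(k, t) = w_k(t)²`. The spectrum is
dichotomized at the smallest C whose cumulative time-averaged ESD reaches
half the total; modes 1..C form the low-frequency (graph-smooth, coupled)
band and C+1..N the high-frequency (decoupled) band. Band filtering is the
orthogonal projection `Ψ^{(keep)}Ψᵀf` — idempotent, and complementary bands
sum to the input. A low/medium/high tripartition (keep the lowest K_L and
highest K_H modes, discard the middle) is supported for sensitivity
analyses.

**4. Decoupling index.** Per region,
`CFD_i = log₂(‖f_i^high‖₂ / ‖f_i^low‖₂)`: 0 is perfect balance, −1 means
the coupled component carries twice the norm of the decoupled one, +1 the
reverse. The index is scale-invariant and exactly antisymmetric under band
swap. Group maps are the arithmetic mean of per-scan maps (computing CFD
on concatenated data is available but not the default, since the
scan-level surrogate test is defined per scan).

**5. Inference.** Four nulls:

- *rewired graphs*: directed double-edge swaps preserving binary in-/out-
  degrees with weights riding on their source slots (target swaps = 10 per
  edge within a bounded attempt budget; draws that break strong
  connectivity are redrawn);
- *graph spectral randomization (SR)*: i.i.d. sign flips of GFT
  coefficient rows — per-mode ESD preserved exactly; coefficient
  permutation across modes is available as an alternative scheme;
- *Moran spectral randomization*: sign-flip re-mixing of a map's loadings
  on the Moran eigenvector basis of a row-standardized, symmetrized,
  doubly-centered spatial weight matrix; because Moran's I of a centered
  map is a sign-invariant quadratic form in these loadings, surrogates
  preserve I exactly;
- *variogram-matched surrogates*: permute the map, smooth with an
  exponential distance kernel (length scale over distance quantiles
  0.05–0.5, blend weight over 0.4–1.0), pick the candidate whose 25-bin
  empirical variogram best matches the original's, and rank-remap onto the
  original values so the surrogate's value distribution is exact.

All surrogate p-values use the +1 convention (observed counted into the
null), so p ≥ 1/(n_draws + 1). Class-level concentration uses the mean
concentration per cortical class against SR nulls, one-sided, BH-corrected
across classes at q = 0.05. Regional CFD localization is two-stage: a scan
flags a region (de)coupled when its CFD is outside all n_s = 19 per-scan SR
surrogates (exact per-scan level 1/(19+1) = 0.05 per tail), and the count
of flagging scans is compared with the critical count of
Bin(n_tests, 0.05), two-sided, Bonferroni-corrected across regions
(BH optional).

## Synthetic data

The generator emulates the statistical shape of tracer-plus-fMRI studies,
not their biology: a 55-region, 70 %-dense directed graph whose log₁₀
weights are Gaussian (mean −2, sd 1, hence spanning several orders of
magnitude), made strongly connected by planting a random Hamiltonian cycle
before filling to density; spherical 3-D coordinates for spatial
surrogates; and cohorts of 2 subjects × 5 scans × 512 time points sharing
one planted per-region log₂ band-energy ratio drawn U(−1, 1), with
observation noise sd 0.1 and the low band set to N/2 = 27 modes (an
equal-split default that keeps the two bands comparable in size).

Signals follow the same projector algebra the pipeline estimates:
`f_t = diag(g_low)·P_low ε_t + diag(g_high)·P_high η_t + noise`. Because
region-wise gains do not commute with mode-wise projectors, each band's
filtered component picks up leakage from the other band, and the naive
gain ratio `g_high/g_low` is not the quantity the decoupling index
measures. The gain law is therefore defined implicitly: gains are
calibrated by a damped multiplicative fixed point on the analytic
stationary covariance — z-scoring included, since the per-region
rescaling also fails to commute with the projectors — so that the
*expected* band-energy ratio equals the planted value exactly. Planted
ratios are then recovered up to estimation noise only (Spearman
0.93–0.99 across seeds at T = 1024; regions whose bands are carried by
localized modes have fewer effective degrees of freedom and show the
largest per-region fluctuation, up to ≈0.15 in |CFD| at T = 1024).

What passing tests do *not* show about real data: the generator has no
hemodynamics, no temporal autocorrelation, no inter-subject anatomical
variability, and its planted gradient is exactly realizable in the
estimator's own model family — real decoupling estimates face model
mismatch these simulations cannot reveal.

## Numerical choices

- Stationary solve: replace one redundant row of `(Pᵀ − I)x = 0` with the
  normalization Σx = 1; negative round-off mass below 1e-12 is clipped.
- Symmetry is enforced on every constructed Laplacian by averaging with
  its transpose (removes ~1e-17 float asymmetry before `eigh`).
- Dichotomization ties: smallest C with cumulative energy ≥ half (a 1e-12
  slack absorbs exact-tie round-off); C is capped at N − 1 so the high
  band is never empty.
- Density thresholding keeps all edges tied at the cut weight and reports
  the achieved density rather than tie-breaking arbitrarily.
- Zero-norm filtered components raise an error naming the region instead
  of returning ±Inf decoupling values.
- `threshold_to_density`, rewiring and all surrogate ensembles are
  deterministic given their seed.

## Problem sizes

Tests run the full pipeline at study scale (N = 55) with scans of 64–1024
time points, 500-repetition calibration of the class test with 99
surrogates per repetition, and 10-seed recovery sweeps; the complete suite
finishes in well under a minute. The reference script rebuilds the
55-region basis and band-limited constructions from scratch at each run.

## Known limitations

- The directed Laplacian requires strictly positive π; graphs with
  transient regions must use teleportation, which perturbs the spectrum
  slightly (the applied α is always recorded).
- Variogram surrogates optimize over a small grid of kernel scales and
  blends rather than a continuous fit; they match smooth maps well but are
  not a full generalized-variogram fit.
- The binomial localization test treats scans as exchangeable independent
  tests; within-subject correlation across scans is not modeled.
- Degenerate (repeated) Laplacian eigenvalues make individual modes
  non-identifiable; only band projections are stable there.
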