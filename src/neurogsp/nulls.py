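"""Surrogate null models and the nonparametric tests built on them.

Four families of nulls are used to benchmark eigenmode analyses:

* **Rewired graphs** — degree-preserving directed double-edge swaps that
  keep every node's in- and out-degree and the multiset of edge weights
  while destroying the graph's specific wiring.
* **Graph spectral randomization (SR)** — random sign flips of the GFT
  coefficients of a signal; the energy spectrum (per-mode ESD) is preserved
  exactly while regional localization is scrambled.
* **Moran spectral randomization (MSR)** — re-mixing of a map's loadings on
  the Moran eigenvector basis of a spatial weight matrix, preserving the
  map's spatial autocorrelation (Moran's I) exactly for sign flips.
* **Variogram-matched surrogates** — rank-remapped, distance-kernel
  smoothed permutations of a map whose empirical variogram is fitted to the
  original's; the surrogate's value distribution equals the original's
  exactly.

All rank-based surrogate p-values use the +1 convention (the observed value
is counted into the null), so p >= 1/(n_draws + 1) always.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .connectome import ConnectomeGraph, EigenmodeBasis, check_strongly_connected
from .gsp import RegionalTimeSeries, cross_basis_reconstruction, gft

__all__ = [
    "SurrogateSpec",
    "TestResult",
    "rewire_graph",
    "spectral_randomization",
    "morans_i",
    "moran_surrogates",
    "variogram",
    "variogram_surrogates",
    "class_concentration_test",
    "cfd_localization",
    "binomial_critical_count",
    "spearman_surrogate_test",
    "dice",
    "nonhomolog_null",
]


@dataclass(frozen=True)
class SurrogateSpec:
    """What null to draw, how many times, and from which seed."""

    kind: str
    n_draws: int = 1000
    seed: int = 0
    params: dict = field(default_factory=dict)

    _KINDS = ("rewired_graph", "spectral_randomization", "moran",
              "variogram", "nonhomolog_subset")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown surrogate kind {self.kind!r}")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one surrogate-based test."""

    statistic: float
    p_value: float
    n_surrogates: int
    tail: str = "one_sided"
    corrected: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must be in (0, 1]")


# ---------------------------------------------------------------------------
# Rewired-graph null
# ---------------------------------------------------------------------------

def rewire_graph(graph: ConnectomeGraph, swaps_per_edge: int = 10,
                 seed: int = 0, max_draw_retries: int = 50) -> ConnectomeGraph:
    """Degree-preserving randomization of a directed weighted graph.

    Attempts up to ``swaps_per_edge * n_edges`` successful directed
    double-edge swaps (within a bounded attempt budget): two edges
    (a->b, c->d) become (a->d, c->b) provided no self-loop or duplicate
    edge results.  Each weight travels with its source slot, so the weight
    multiset and every node's binary in-/out-degree are preserved exactly.
    Graphs admitting few or no valid swaps (e.g. a directed 3-cycle) simply
    return a sparsely randomized or identical configuration — every output
    is still an admissible member of the degree-preserving ensemble.
    Draws that lose strong connectivity are rejected and redrawn (bounded
    retries).
    """
    rng = np.random.default_rng(seed)
    src0, dst0 = np.nonzero(graph.weights)
    n_edges = src0.size
    if n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    target_swaps = swaps_per_edge * n_edges

    for _ in range(max_draw_retries):
        src = src0.copy()
        dst = dst0.copy()
        wts = graph.weights[src0, dst0].copy()
        edge_set = set(zip(src.tolist(), dst.tolist()))
        done = 0
        attempts = 0
        max_attempts = 20 * target_swaps
        while done < target_swaps and attempts < max_attempts:
            attempts += 1
            i, j = rng.integers(0, n_edges, size=2)
            if i == j:
                continue
            a, b = src[i], dst[i]
            c, d = src[j], dst[j]
            if a == d or c == b:  # would create self-loop
                continue
            if (a, d) in edge_set or (c, b) in edge_set:
                continue
            edge_set.discard((a, b))
            edge_set.discard((c, d))
            edge_set.add((a, d))
            edge_set.add((c, b))
            dst[i], dst[j] = d, b
            done += 1
        w = np.zeros_like(graph.weights)
        w[src, dst] = wts
        try:
            out = ConnectomeGraph(labels=graph.labels, weights=w,
                                  class_map=graph.class_map)
        except ValueError:
            continue
        if check_strongly_connected(out)[0]:
            return out
    raise RuntimeError(
        f"could not produce a strongly connected rewiring in "
        f"{max_draw_retries} draws ({n_edges} edges, "
        f"{target_swaps} swaps requested)"
    )


# ---------------------------------------------------------------------------
# Graph spectral randomization
# ---------------------------------------------------------------------------

def spectral_randomization(basis: EigenmodeBasis, ts: RegionalTimeSeries,
                           seed: int = 0,
                           scheme: str = "sign_flip") -> RegionalTimeSeries:
    """One SR surrogate signal: randomize GFT coefficients, keep the spectrum.

    ``scheme='sign_flip'`` (default) multiplies each mode's coefficient row
    by an i.i.d. random sign, preserving per-mode ESD and total energy
    exactly.  ``scheme='permute'`` instead permutes the coefficient rows
    across modes (preserves total energy and the multiset of mode energies,
    not their frequency assignment).
    """
    rng = np.random.default_rng(seed)
    w = gft(basis, ts).w
    n = basis.n_modes
    if scheme == "sign_flip":
        s = rng.choice([-1.0, 1.0], size=n)
        w_surr = s[:, None] * w
    elif scheme == "permute":
        w_surr = w[rng.permutation(n), :]
    else:
        raise ValueError(f"unknown SR scheme {scheme!r}")
    return RegionalTimeSeries(labels=ts.labels, values=basis.modes @ w_surr)


# ---------------------------------------------------------------------------
# Moran spectral randomization
# ---------------------------------------------------------------------------

def morans_i(x: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I spatial autocorrelation of a map under a weight matrix.

    Definitional form ``I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2``
    with ``z`` the centered map and ``S0`` the total weight.
    """
    x = np.asarray(x, dtype=float)
    W = np.asarray(weights, dtype=float)
    z = x - x.mean()
    s0 = W.sum()
    denom = (z ** 2).sum()
    if s0 == 0 or denom == 0:
        raise ValueError("degenerate weights or constant map in Moran's I")
    return float(len(x) / s0 * (z @ W @ z) / denom)


def _moran_basis(weights: np.ndarray):
    """Moran eigenvector maps of a symmetric spatial weight matrix.

    Rows are standardized to sum 1, the result symmetrized, then doubly
    centered; the eigenvectors orthogonal to the constant vector form the
    basis.
    """
    W = np.asarray(weights, dtype=float)
    if np.max(np.abs(W - W.T)) > 1e-10:
        raise ValueError("Moran surrogates require a symmetric weight matrix")
    if np.any(W < 0):
        raise ValueError("spatial weights must be nonnegative")
    n = W.shape[0]
    rs = W.sum(axis=1)
    if np.any(rs <= 0):
        raise ValueError("every region needs at least one positive weight")
    Wrs = W / rs[:, None]
    Wsym = (Wrs + Wrs.T) / 2.0
    H = np.eye(n) - np.ones((n, n)) / n
    M = H @ Wsym @ H
    evals, evecs = scipy.linalg.eigh((M + M.T) / 2.0)
    # drop the eigenvector spanning the constant direction (eigenvalue ~ 0
    # with maximal overlap with 1)
    overlap = np.abs(evecs.sum(axis=0))
    const_idx = int(np.argmax(overlap))
    keep = np.ones(n, dtype=bool)
    keep[const_idx] = False
    return evecs[:, keep]


def moran_surrogates(weights: np.ndarray, data, n_draws: int = 1000,
                     seed: int = 0) -> np.ndarray:
    """MSR surrogate ensemble for a map (length N) or time series (N x T).

    The data is projected on the Moran eigenvector maps of ``weights`` and
    the loadings are re-mixed with i.i.d. random signs (singleton
    procedure).  Because Moran's I of any centered map is a sign-invariant
    quadratic form in those loadings, every surrogate preserves the
    original's Moran's I exactly, along with its mean and variance.

    Returns an array of shape ``(n_draws, *data.shape)``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    x = np.asarray(data, dtype=float)
    squeeze = x.ndim == 1
    X = x[:, None] if squeeze else x
    U = _moran_basis(weights)  # N x (N-1), orthonormal, centered columns
    mean = X.mean(axis=0, keepdims=True)
    coeffs = U.T @ (X - mean)  # (N-1) x T
    rng = np.random.default_rng(seed)
    out = np.empty((n_draws,) + X.shape)
    for d in range(n_draws):
        s = rng.choice([-1.0, 1.0], size=U.shape[1])
        out[d] = mean + U @ (s[:, None] * coeffs)
    return out[:, :, 0] if squeeze else out


# ---------------------------------------------------------------------------
# Variogram-matched surrogates
# ---------------------------------------------------------------------------

def variogram(values: np.ndarray, distances: np.ndarray,
              n_bins: int = 25):
    """Binned empirical variogram ``gamma(h) = mean of (x_i - x_j)^2 / 2``.

    Bins are equal-width over the observed distance range.  Returns
    ``(bin_centers, gamma)`` with NaN for empty bins.
    """
    x = np.asarray(values, dtype=float)
    D = np.asarray(distances, dtype=float)
    iu = np.triu_indices(len(x), k=1)
    d = D[iu]
    if d.max() <= d.min():
        raise ValueError("degenerate distance matrix (all distances equal)")
    sq = 0.5 * (x[iu[0]] - x[iu[1]]) ** 2
    edges = np.linspace(d.min(), d.max(), n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    gamma = np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = which == b
        if m.any():
            gamma[b] = sq[m].mean()
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, gamma


def _variogram_objective(x, ref_gamma, distances, n_bins):
    _, g = variogram(x, distances, n_bins)
    m = np.isfinite(ref_gamma) & np.isfinite(g)
    return float(((g[m] - ref_gamma[m]) ** 2).sum())


def variogram_surrogates(values: np.ndarray, distances: np.ndarray,
                         n_draws: int = 1000, seed: int = 0,
                         n_bins: int = 25) -> np.ndarray:
    """Spatial-autocorrelation-preserving surrogate maps by variogram matching.

    Each draw permutes the map, smooths it with an exponential distance
    kernel ``exp(-d / delta)`` over a grid of length scales, blends the
    smoothed field with the raw permutation over a grid of mixing weights,
    and rank-remaps the best-fitting candidate (smallest squared deviation
    between its binned variogram and the original's) back onto the original
    values.  The rank remap makes every surrogate's value distribution equal
    the original's exactly.

    Returns an ``(n_draws, N)`` array.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    x = np.asarray(values, dtype=float)
    D = np.asarray(distances, dtype=float)
    if np.max(np.abs(D - D.T)) > 1e-10:
        raise ValueError("distance matrix must be symmetric")
    iu = np.triu_indices(len(x), k=1)
    if D[iu].max() <= D[iu].min():
        raise ValueError("degenerate distance matrix (all distances equal)")
    _, ref_gamma = variogram(x, D, n_bins)
    x_sorted = np.sort(x)
    # candidate length scales: quantiles of the pairwise distances
    deltas = np.quantile(D[iu], [0.05, 0.1, 0.2, 0.3, 0.5])
    kernels = []
    for delta in deltas:
        K = np.exp(-D / max(delta, 1e-12))
        kernels.append(K / K.sum(axis=1, keepdims=True))
    blends = np.array([0.4, 0.6, 0.8, 1.0])

    rng = np.random.default_rng(seed)
    out = np.empty((n_draws, len(x)))
    for d_i in range(n_draws):
        perm = x[rng.permutation(len(x))]
        best, best_obj = None, np.inf
        for K in kernels:
            sm = K @ perm
            for b in blends:
                cand = (1.0 - b) * perm + b * sm
                surr = _rank_remap(cand, x_sorted)
                obj = _variogram_objective(surr, ref_gamma, D, n_bins)
                if obj < best_obj:
                    best, best_obj = surr, obj
        out[d_i] = best
    return out


def _rank_remap(candidate: np.ndarray, sorted_target: np.ndarray) -> np.ndarray:
    """Replace values by the target values of equal rank."""
    out = np.empty_like(candidate)
    out[np.argsort(candidate, kind="stable")] = sorted_target
    return out


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def _exceedance_p(observed: float, null: np.ndarray, tail: str) -> float:
    null = np.asarray(null, dtype=float)
    n = null.size
    if tail == "greater":
        k = int(np.sum(null >= observed))
    elif tail == "less":
        k = int(np.sum(null <= observed))
    elif tail == "two_sided":
        k = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + k) / (1 + n)


def class_concentration_test(concentration, labels, class_map: dict[str, str],
                             surrogate_maps: np.ndarray,
                             q: float = 0.05):
    """Permutation test of class-level mean activity concentration.

    For every cortical class the statistic is the mean concentration over
    its regions; the one-sided p-value is the exceedance rank of the
    observed mean in the surrogate ensemble's class means (+1 convention).
    Benjamini-Hochberg correction is applied across classes at level ``q``.

    Returns a DataFrame with class, n, statistic, p, p_corrected,
    significant.
    """
    import pandas as pd

    labels = list(labels)
    x = np.asarray(concentration, dtype=float)
    S = np.asarray(surrogate_maps, dtype=float)
    if S.ndim != 2 or S.shape[1] != len(labels):
        raise ValueError("surrogate_maps must be (n_draws, N)")
    missing = [l for l in labels if l not in class_map]
    if missing:
        raise ValueError(f"region(s) without class assignment: {missing}")
    classes = sorted(set(class_map[l] for l in labels))
    rows = []
    for cls in classes:
        idx = [i for i, l in enumerate(labels) if class_map[l] == cls]
        if not idx:
            raise ValueError(f"empty class {cls!r}")
        obs = x[idx].mean()
        null = S[:, idx].mean(axis=1)
        rows.append({"class": cls, "n": len(idx), "statistic": obs,
                     "p": _exceedance_p(obs, null, "greater")})
    df = pd.DataFrame(rows)
    rej, p_corr, _, _ = multipletests(df["p"], alpha=q, method="fdr_bh")
    df["p_corrected"] = p_corr
    df["significant"] = rej
    df.attrs["n_surrogates"] = S.shape[0]
    return df


def binomial_critical_count(n_tests: int, alpha: float, level: float) -> int:
    """Smallest count k with ``P(Bin(n_tests, alpha) >= k) <= level``."""
    for k in range(n_tests + 1):
        if scipy.stats.binom.sf(k - 1, n_tests, alpha) <= level:
            return k
    return n_tests + 1  # unreachable at any sane level


def cfd_localization(per_scan_cfd: np.ndarray,
                     per_scan_surrogates: np.ndarray,
                     labels,
                     alpha: float | None = None,
                     n_tests: int | None = None,
                     family_alpha: float = 0.05,
                     correction: str = "bonferroni"):
    """Two-stage binomial localization of significantly (de)coupled regions.

    Stage 1 (per scan): a scan flags a region *decoupled* when its observed
    CFD exceeds all ``n_s`` surrogate CFDs for that scan, and *coupled* when
    it falls below all of them — each tail an exact level ``1/(n_s + 1)``
    test (0.05 with the standard 19 surrogates).

    Stage 2 (group): under the null every scan flags each tail independently
    with probability ``alpha``, so the number of flagging scans follows
    ``Bin(n_tests, alpha)``.  A region is labeled when a tail's count
    reaches the critical count at a two-sided level ``family_alpha``
    corrected across regions (Bonferroni by default, ``correction='fdr_bh'``
    switches to Benjamini-Hochberg on the exact binomial tail p-values).

    Parameters
    ----------
    per_scan_cfd : (n_scans, N)
    per_scan_surrogates : (n_scans, n_s, N)
    labels : region identifiers
    alpha : per-scan flag level; default ``1/(n_s + 1)``
    n_tests : binomial size; defaults to n_scans

    Returns a DataFrame (region, n_decoupled, n_coupled, label, ...) and
    records the attained per-scan level in ``df.attrs``.
    """
    import warnings

    import pandas as pd

    C = np.asarray(per_scan_cfd, dtype=float)
    S = np.asarray(per_scan_surrogates, dtype=float)
    n_scans, n_regions = C.shape
    if S.shape[0] != n_scans or S.shape[2] != n_regions:
        raise ValueError("surrogates must be (n_scans, n_s, N)")
    n_s = S.shape[1]
    attained = 1.0 / (n_s + 1)
    if n_s < 19:
        warnings.warn(
            f"only {n_s} surrogates per scan: attained per-scan level "
            f"{attained:.3f} exceeds 0.05", stacklevel=2)
    if alpha is None:
        alpha = attained
    if n_tests is None:
        n_tests = n_scans

    dec_flags = (C[:, None, :] > S).all(axis=1)  # scan x region
    cpl_flags = (C[:, None, :] < S).all(axis=1)
    n_dec = dec_flags.sum(axis=0)
    n_cpl = cpl_flags.sum(axis=0)

    per_tail_level = family_alpha / 2.0
    if correction == "bonferroni":
        crit = binomial_critical_count(n_tests, alpha,
                                       per_tail_level / n_regions)
        sig_dec = n_dec >= crit
        sig_cpl = n_cpl >= crit
    elif correction == "fdr_bh":
        p_dec = scipy.stats.binom.sf(n_dec - 1, n_tests, alpha)
        p_cpl = scipy.stats.binom.sf(n_cpl - 1, n_tests, alpha)
        sig_dec, _, _, _ = multipletests(p_dec, alpha=per_tail_level,
                                         method="fdr_bh")
        sig_cpl, _, _, _ = multipletests(p_cpl, alpha=per_tail_level,
                                         method="fdr_bh")
        crit = None
    else:
        raise ValueError(f"unknown correction {correction!r}")

    label_out = []
    for i in range(n_regions):
        if sig_dec[i] and sig_cpl[i]:
            label_out.append("decoupled" if n_dec[i] >= n_cpl[i] else "coupled")
        elif sig_dec[i]:
            label_out.append("decoupled")
        elif sig_cpl[i]:
            label_out.append("coupled")
        else:
            label_out.append("ns")
    df = pd.DataFrame({
        "region": list(labels),
        "n_decoupled": n_dec,
        "n_coupled": n_cpl,
        "label": label_out,
    })
    df.attrs["attained_per_scan_level"] = attained
    df.attrs["n_tests"] = n_tests
    df.attrs["critical_count"] = crit
    return df


def spearman_surrogate_test(x, y, surrogates_of_x: np.ndarray) -> TestResult:
    """Spearman correlation of two maps, tested against SA-preserving nulls.

    Two-sided p: exceedance of |rho| in the surrogate distribution of
    Spearman correlations between each surrogate of ``x`` and ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("rank correlation needs at least 5 regions")
    if len(x) != len(y):
        raise ValueError("maps have different lengths")
    S = np.asarray(surrogates_of_x, dtype=float)
    rho = float(scipy.stats.spearmanr(x, y).statistic)
    null = np.array([scipy.stats.spearmanr(s, y).statistic for s in S])
    return TestResult(statistic=rho,
                      p_value=_exceedance_p(rho, null, "two_sided"),
                      n_surrogates=S.shape[0], tail="two_sided")


def dice(a, b) -> float:
    """Dice overlap ``2|a & b| / (|a| + |b|)`` of two region sets."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("Dice coefficient undefined for two empty sets")
    return 2.0 * len(a & b) / (len(a) + len(b))


def nonhomolog_null(ts_full: RegionalTimeSeries, homolog_labels,
                    basis_a: EigenmodeBasis, k: int,
                    n_draws: int = 1000, seed: int = 0) -> np.ndarray:
    """Cross-basis reconstruction accuracy over random non-homolog subsets.

    Each draw samples ``len(homolog_labels)`` regions uniformly without
    replacement from the regions *not* in the homolog list, maps them
    positionally onto the basis labels, and evaluates both reconstruction
    accuracies.  Returns an ``(n_draws, 2)`` array of
    (activity_accuracy, fc_accuracy).
    """
    homolog = [str(l) for l in homolog_labels]
    pool = [l for l in ts_full.labels if l not in homolog]
    m = len(homolog)
    if len(pool) < m:
        raise ValueError(
            f"only {len(pool)} non-homolog regions available, need {m}")
    if len(basis_a.labels) != m:
        raise ValueError("basis size must match the homolog list length")
    rng = np.random.default_rng(seed)
    out = np.empty((n_draws, 2))
    for d in range(n_draws):
        picked = list(rng.choice(pool, size=m, replace=False))
        mapping = dict(zip(basis_a.labels, picked))
        out[d] = cross_basis_reconstruction(basis_a, ts_full, k, mapping)
    return out
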