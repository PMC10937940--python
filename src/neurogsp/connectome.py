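"""Directed weighted connectome graphs and their Laplacian eigenmode bases.

A cellular connectome is a dense, weighted, directed graph between cortical
areas whose edge weights are connection fractions (FLNe-like, spanning several
orders of magnitude).  Spectral analysis of signals on such a graph requires a
symmetric reference operator; for directed graphs this is the normalized
directed graph Laplacian built from the random walk on the graph,

    L = I - (Pi^{1/2} P Pi^{-1/2} + Pi^{-1/2} P^T Pi^{1/2}) / 2,

where ``P = D^{-1} A`` is the row-stochastic transition matrix of the random
walk (``D`` the diagonal out-degree matrix) and ``Pi = diag(pi)`` holds the
stationary distribution ``pi P = pi``.  The operator is symmetric, so it has a
real spectrum ``0 = lambda_1 <= ... <= lambda_N <= 2`` and an orthonormal
eigenvector basis; eigenvalues act as graph frequencies and eigenvectors as
connectome eigenmodes.  For symmetric adjacency the operator reduces exactly
to the familiar normalized undirected Laplacian ``I - D^{-1/2} A D^{-1/2}``.

The random walk must be ergodic, i.e. the graph strongly connected; when it
is not, a uniform teleportation (PageRank-style) blend restores ergodicity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectomeGraph",
    "TransitionModel",
    "EigenmodeBasis",
    "build_graph",
    "check_strongly_connected",
    "transition_model",
    "directed_laplacian",
    "undirected_laplacian",
    "threshold_to_density",
    "eigenmodes",
    "subgraph",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConnectomeGraph:
    """A labeled, nonnegative, directed weight matrix (rows = source areas).

    Attributes
    ----------
    labels : tuple of str
        Ordered, unique region identifiers.
    weights : ndarray, shape (N, N)
        Nonnegative weights; ``weights[i, j]`` is the edge i -> j.  The
        diagonal is exactly zero.
    class_map : dict or None
        Optional region -> cortical-class assignment.
    """

    labels: tuple[str, ...]
    weights: np.ndarray
    class_map: dict[str, str] | None = None

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {w.shape}")
        if len(self.labels) != w.shape[0]:
            raise ValueError("number of labels does not match matrix size")
        if len(set(self.labels)) != len(self.labels):
            dup = sorted({l for l in self.labels if list(self.labels).count(l) > 1})
            raise ValueError(f"duplicate region labels: {dup}")
        if len(self.labels) < 2:
            raise ValueError("a connectome needs at least 2 regions")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain NaN or Inf")
        if np.any(w < 0):
            i, j = np.argwhere(w < 0)[0]
            raise ValueError(
                f"negative weight {w[i, j]!r} at cell "
                f"({self.labels[i]!r}, {self.labels[j]!r})"
            )
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero (use build_graph to construct)")
        row_ok = (w > 0).any(axis=1)
        col_ok = (w > 0).any(axis=0)
        isolated = ~(row_ok | col_ok)
        if isolated.any():
            bad = [self.labels[i] for i in np.flatnonzero(isolated)]
            raise ValueError(f"isolated regions (no edges at all): {bad}")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", tuple(self.labels))


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic random-walk model with its stationary distribution."""

    P: np.ndarray
    pi: np.ndarray
    teleport_alpha: float = 0.0

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-10:
            raise ValueError("stationary distribution must be a probability vector")
        if np.max(np.abs(pi @ P - pi)) > 1e-8:
            raise ValueError("pi is not stationary for P")
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "pi", pi)


@dataclass(frozen=True)
class EigenmodeBasis:
    """Ascending-eigenvalue orthonormal eigenmode basis of a graph Laplacian.

    ``modes[:, k]`` is the k-th eigenmode; eigenvalues are graph frequencies.
    Sign convention: in each mode, the entry of largest absolute value is
    non-negative (ties broken by lowest region index).
    """

    eigenvalues: np.ndarray
    modes: np.ndarray
    labels: tuple[str, ...]
    source_kind: str = "directed"

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        m = np.asarray(self.modes, dtype=float)
        if np.any(np.diff(ev) < -1e-12):
            raise ValueError("eigenvalues must be sorted ascending")
        g = m.T @ m
        if np.max(np.abs(g - np.eye(g.shape[0]))) > 1e-8:
            raise ValueError("modes are not orthonormal")
        object.__setattr__(self, "eigenvalues", ev)
        object.__setattr__(self, "modes", m)
        object.__setattr__(self, "labels", tuple(self.labels))


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_graph(weights, labels=None, orientation: str = "source_rows",
                class_map: dict[str, str] | None = None) -> ConnectomeGraph:
    """Build a :class:`ConnectomeGraph` from a labeled square weight matrix.

    Parameters
    ----------
    weights : DataFrame or ndarray
        Square matrix of nonnegative connection weights.  If a DataFrame,
        labels are taken from its index (which must equal its columns).
    labels : sequence of str, optional
        Required when ``weights`` is a bare array.
    orientation : {'source_rows', 'target_rows'}
        Convention of the *input* matrix.  Internally rows are always
        sources; ``target_rows`` input is transposed.
    class_map : dict, optional
        Region -> cortical class.

    Self-loops (diagonal entries) are zeroed with a log message; they carry
    no meaning for inter-areal connectivity.
    """
    import pandas as pd

    if isinstance(weights, pd.DataFrame):
        if labels is not None:
            raise ValueError("labels given both in DataFrame and explicitly")
        if list(weights.index) != list(weights.columns):
            raise ValueError("DataFrame index and columns must agree")
        labels = [str(x) for x in weights.index]
        w = weights.to_numpy(dtype=float)
    else:
        if labels is None:
            raise ValueError("labels required for array input")
        labels = [str(x) for x in labels]
        w = np.array(weights, dtype=float)

    if orientation not in ("source_rows", "target_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        i, j = np.argwhere(~np.isfinite(w))[0]
        raise ValueError(f"non-finite weight at cell ({labels[i]!r}, {labels[j]!r})")
    if np.any(w < 0):
        i, j = np.argwhere(w < 0)[0]
        raise ValueError(
            f"negative weight {w[i, j]!r} at cell ({labels[i]!r}, {labels[j]!r})"
        )
    if orientation == "target_rows":
        w = w.T.copy()
    if np.any(np.diag(w) != 0):
        n_loops = int(np.count_nonzero(np.diag(w)))
        logger.info("zeroing %d self-loop(s) on the diagonal", n_loops)
        np.fill_diagonal(w, 0.0)
    return ConnectomeGraph(labels=tuple(labels), weights=w, class_map=class_map)


def check_strongly_connected(graph: ConnectomeGraph):
    """Return ``(flag, components)`` for strong connectivity of the graph.

    ``components`` is a list of label lists, one per strongly connected
    component (a single list covering all labels when the flag is True).
    """
    n, comp = connected_components(
        csr_matrix(graph.weights > 0), directed=True, connection="strong"
    )
    groups: list[list[str]] = [[] for _ in range(n)]
    for idx, c in enumerate(comp):
        groups[c].append(graph.labels[idx])
    return n == 1, groups


def transition_model(graph: ConnectomeGraph,
                     teleport_alpha: float = 0.0) -> TransitionModel:
    """Random-walk transition matrix ``P = D^{-1} A`` and stationary ``pi``.

    With ``teleport_alpha = 0`` the graph must be strongly connected (the
    stationary distribution of the pure walk is then unique); otherwise the
    walk is blended with uniform teleportation at the given rate,
    ``P' = (1 - a) P + a / N``, which makes any graph ergodic.  The alpha
    actually applied is recorded on the returned model.

    The stationary distribution is obtained as the left eigenvector of P at
    eigenvalue 1 by a direct dense linear solve, which is exact for periodic
    chains where power iteration would not converge.
    """
    if not 0.0 <= teleport_alpha < 1.0:
        raise ValueError("teleport_alpha must be in [0, 1)")
    A = graph.weights
    n = graph.n_regions
    out_deg = A.sum(axis=1)
    if teleport_alpha == 0.0:
        if np.any(out_deg <= 0):
            bad = [graph.labels[i] for i in np.flatnonzero(out_deg <= 0)]
            raise ValueError(
                f"regions with zero out-degree {bad}; "
                "use teleport_alpha > 0 to regularize"
            )
        flag, comps = check_strongly_connected(graph)
        if not flag:
            raise ValueError(
                f"graph is not strongly connected ({len(comps)} components); "
                "pass teleport_alpha > 0 (PageRank-style teleportation) to "
                "obtain an ergodic walk"
            )
        P = A / out_deg[:, None]
    else:
        # rows with zero out-degree become pure teleportation rows
        P0 = np.zeros_like(A)
        pos = out_deg > 0
        P0[pos] = A[pos] / out_deg[pos, None]
        P0[~pos] = 1.0 / n
        P = (1.0 - teleport_alpha) * P0 + teleport_alpha / n

    pi = _stationary_distribution(P)
    return TransitionModel(P=P, pi=pi, teleport_alpha=float(teleport_alpha))


def _stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Solve pi P = pi, sum(pi) = 1 by a dense linear solve."""
    n = P.shape[0]
    M = P.T - np.eye(n)
    M[-1, :] = 1.0  # replace one redundant equation with the normalization
    b = np.zeros(n)
    b[-1] = 1.0
    pi = scipy.linalg.solve(M, b)
    pi = np.where(np.abs(pi) < 1e-15, 0.0, pi)
    if np.any(pi < -1e-12):
        raise ValueError("stationary solve produced negative mass")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Laplacians
# ---------------------------------------------------------------------------

def directed_laplacian(tm: TransitionModel) -> np.ndarray:
    """Normalized directed graph Laplacian of an ergodic random walk.

    ``L = I - (Pi^{1/2} P Pi^{-1/2} + Pi^{-1/2} P^T Pi^{1/2}) / 2`` with
    ``Pi = diag(pi)``.  Symmetric by construction; ``L @ sqrt(pi) = 0``.
    """
    pi = tm.pi
    if np.any(pi <= 0):
        raise ValueError(
            "stationary distribution has zero mass at some region; the "
            "directed Laplacian requires strictly positive pi (use "
            "teleportation)"
        )
    s = np.sqrt(pi)
    M = (s[:, None] * tm.P / s[None, :])
    L = np.eye(len(pi)) - (M + M.T) / 2.0
    return (L + L.T) / 2.0  # remove floating-point asymmetry


def undirected_laplacian(weights: np.ndarray, symmetrize: bool = False) -> np.ndarray:
    """Normalized undirected Laplacian ``I - D^{-1/2} A D^{-1/2}``.

    ``weights`` must be symmetric unless ``symmetrize=True``, in which case
    the matrix is symmetrized by averaging with its transpose.
    """
    A = np.asarray(weights, dtype=float)
    if symmetrize:
        A = (A + A.T) / 2.0
    elif np.max(np.abs(A - A.T)) > 1e-10:
        raise ValueError("input is asymmetric; pass symmetrize=True to average")
    deg = A.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError(
            f"zero-degree node(s) at indices {np.flatnonzero(deg <= 0).tolist()}"
        )
    d = 1.0 / np.sqrt(deg)
    L = np.eye(A.shape[0]) - d[:, None] * A * d[None, :]
    return (L + L.T) / 2.0


def threshold_to_density(weights: np.ndarray, target_density: float):
    """Keep the strongest off-diagonal edges to match a target edge density.

    Returns ``(thresholded, achieved_density)``.  Edges tied at the cut
    weight are all retained, so the achieved density may weakly exceed the
    target; it is reported rather than silently tie-broken.
    """
    if target_density <= 0:
        raise ValueError("target_density must be in (0, 1]")
    if target_density > 1:
        raise ValueError("target_density must be in (0, 1]")
    A = np.asarray(weights, dtype=float).copy()
    n = A.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = A[off]
    n_off = vals.size
    pos = vals[vals > 0]
    m = int(np.ceil(target_density * n_off - 1e-12))
    if m >= pos.size:
        achieved = pos.size / n_off
        return A, achieved
    cut = np.sort(pos)[::-1][m - 1]
    keep = (A >= cut) & off
    out = np.where(keep, A, 0.0)
    achieved = int(keep.sum()) / n_off
    return out, achieved


def eigenmodes(L: np.ndarray, labels, source_kind: str = "directed") -> EigenmodeBasis:
    """Full eigendecomposition of a symmetric graph Laplacian.

    Eigenvalues ascending; each eigenvector's largest-magnitude entry is made
    non-negative (deterministic up to degenerate eigenspaces, whose basis is
    inherently arbitrary).
    """
    L = np.asarray(L, dtype=float)
    if np.max(np.abs(L - L.T)) > 1e-8:
        raise ValueError("Laplacian is asymmetric beyond tolerance 1e-8")
    evals, evecs = scipy.linalg.eigh((L + L.T) / 2.0)
    evecs = _fix_signs(evecs)
    return EigenmodeBasis(eigenvalues=evals, modes=evecs,
                          labels=tuple(labels), source_kind=source_kind)


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make each column's largest-|entry| non-negative (first index on ties)."""
    V = V.copy()
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs[None, :]


def subgraph(graph: ConnectomeGraph, keep_labels) -> ConnectomeGraph:
    """Restrict and reorder the graph to ``keep_labels`` (order preserved)."""
    keep_labels = [str(x) for x in keep_labels]
    pos = {l: i for i, l in enumerate(graph.labels)}
    unknown = [l for l in keep_labels if l not in pos]
    if unknown:
        raise ValueError(f"unknown region labels: {unknown}")
    idx = np.array([pos[l] for l in keep_labels])
    w = graph.weights[np.ix_(idx, idx)].copy()
    np.fill_diagonal(w, 0.0)
    cmap = None
    if graph.class_map is not None:
        cmap = {l: graph.class_map[l] for l in keep_labels if l in graph.class_map}
    return ConnectomeGraph(labels=tuple(keep_labels), weights=w, class_map=cmap)


def log10_weights(graph: ConnectomeGraph) -> np.ndarray:
    """log10 of the positive weights (NaN where absent) — for display only.

    The analysis itself always runs on linear weights; fraction-of-labeled-
    neuron weights are < 1, so their log10 is negative and unsuitable as an
    adjacency.
    """
    w = graph.weights
    out = np.full_like(w, np.nan)
    mask = w > 0
    out[mask] = np.log10(w[mask])
    return out
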