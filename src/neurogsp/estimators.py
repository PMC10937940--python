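"""scikit-learn style estimators wrapping the eigenmode pipeline.

These adapters expose the decomposition with the ``fit`` / ``transform``
protocol so it composes with sklearn pipelines and model selection.  The
sample convention follows sklearn: ``X`` has shape ``(n_samples,
n_features) = (T, N)``, i.e. one time point per row — the transpose of the
region x time layout the functional API uses.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import connectome as cn
from . import decoupling as dc
from . import gsp

__all__ = ["ConnectomeEigenmodes", "GraphBandFilter", "DecouplingIndex"]


def _as_timeseries(X, labels):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(labels):
        raise ValueError(
            f"X must be (n_timepoints, {len(labels)}), got {X.shape}")
    return gsp.RegionalTimeSeries(labels=labels, values=X.T)


class ConnectomeEigenmodes(BaseEstimator, TransformerMixin):
    """Graph Fourier basis of a connectome, as a transformer.

    ``fit`` consumes the weighted adjacency matrix (via its ``weights``
    parameter or fit argument) and builds the Laplacian eigenmode basis;
    ``transform`` maps regional signals to spectral coefficients (GFT) and
    ``inverse_transform`` reconstructs them (IGFT).

    Parameters
    ----------
    orientation : {'source_rows', 'target_rows'}
        Convention of the input adjacency.
    teleport_alpha : float
        Uniform teleportation rate for graphs that are not strongly
        connected (0 requires strong connectivity).
    kind : {'directed', 'undirected'}
        Directed random-walk Laplacian, or the normalized undirected
        Laplacian of an (assumed symmetric) adjacency.

    Attributes
    ----------
    graph_ : ConnectomeGraph
    eigenvalues_ : ndarray of graph frequencies, ascending
    modes_ : (N, N) orthonormal eigenmodes (columns)
    basis_ : EigenmodeBasis
    teleport_alpha_ : float, the teleportation actually applied
    """

    def __init__(self, orientation: str = "source_rows",
                 teleport_alpha: float = 0.0, kind: str = "directed"):
        self.orientation = orientation
        self.teleport_alpha = teleport_alpha
        self.kind = kind

    def fit(self, X, y=None, labels=None):
        """Fit the eigenmode basis from a square weight matrix ``X``."""
        import pandas as pd

        if labels is None and not isinstance(X, pd.DataFrame):
            labels = [f"R{i+1:02d}" for i in range(np.asarray(X).shape[0])]
        graph = cn.build_graph(X, labels=labels, orientation=self.orientation)
        if self.kind == "directed":
            tm = cn.transition_model(graph, self.teleport_alpha)
            L = cn.directed_laplacian(tm)
            self.transition_ = tm
            self.teleport_alpha_ = tm.teleport_alpha
        elif self.kind == "undirected":
            L = cn.undirected_laplacian(graph.weights)
            self.transition_ = None
            self.teleport_alpha_ = 0.0
        else:
            raise ValueError(f"unknown kind {self.kind!r}")
        basis = cn.eigenmodes(L, graph.labels, source_kind=self.kind)
        self.graph_ = graph
        self.basis_ = basis
        self.labels_ = basis.labels
        self.eigenvalues_ = basis.eigenvalues
        self.modes_ = basis.modes
        self.n_features_in_ = graph.n_regions
        return self

    def transform(self, X):
        """GFT: (T, N) signals -> (T, N) spectral coefficients."""
        check_is_fitted(self, "basis_")
        ts = _as_timeseries(X, self.labels_)
        return gsp.gft(self.basis_, ts).w.T

    def inverse_transform(self, W):
        """IGFT: (T, N) coefficients -> (T, N) signals."""
        check_is_fitted(self, "basis_")
        W = np.asarray(W, dtype=float)
        coeffs = gsp.SpectralCoefficients(eigenvalues=self.eigenvalues_,
                                          w=W.T)
        return gsp.igft(self.basis_, coeffs).values.T


class GraphBandFilter(BaseEstimator, TransformerMixin):
    """Band-limit signals to the low or high graph-frequency band.

    With ``cutoff='auto'`` the dichotomization cutoff (equal-energy split
    of the mean ESD) is estimated from the data seen at fit time; a fixed
    :class:`~neurogsp.gsp.CutoffSpec` can be given instead.

    Attributes
    ----------
    cutoff_ : CutoffSpec actually used.
    """

    def __init__(self, basis=None, band: str = "low", cutoff="auto"):
        self.basis = basis
        self.band = band
        self.cutoff = cutoff

    def fit(self, X, y=None):
        if self.basis is None:
            raise ValueError("GraphBandFilter requires a fitted basis")
        if self.band not in ("low", "high"):
            raise ValueError(f"band must be 'low' or 'high', got {self.band!r}")
        if self.cutoff == "auto":
            ts = _as_timeseries(X, self.basis.labels)
            self.cutoff_ = gsp.dichotomize(gsp.mean_esd(gsp.gft(self.basis, ts)))
        else:
            self.cutoff_ = self.cutoff
        self.n_features_in_ = self.basis.n_modes
        return self

    def transform(self, X):
        check_is_fitted(self, "cutoff_")
        ts = _as_timeseries(X, self.basis.labels)
        fn = gsp.low_pass if self.band == "low" else gsp.high_pass
        return fn(self.basis, ts, self.cutoff_).values.T


class DecouplingIndex(BaseEstimator):
    """Per-region decoupling index estimator.

    ``fit`` takes one scan (or a list of scans) of shape (T, N), z-scores
    each region, splits the signal at the cutoff and computes the log2
    high/low norm ratio per region; with several scans the per-scan maps
    are averaged.

    Attributes
    ----------
    cfd_ : (N,) group decoupling values
    per_scan_ : (n_scans, N) per-scan values
    cutoff_ : CutoffSpec used
    result_ : CFDResult
    """

    def __init__(self, basis=None, cutoff="auto", zscore: bool = True):
        self.basis = basis
        self.cutoff = cutoff
        self.zscore = zscore

    def fit(self, X, y=None):
        if self.basis is None:
            raise ValueError("DecouplingIndex requires a fitted basis")
        scans = X if isinstance(X, (list, tuple)) else [X]
        series = []
        for scan in scans:
            ts = _as_timeseries(scan, self.basis.labels)
            series.append(gsp.zscore(ts) if self.zscore else ts)
        if self.cutoff == "auto":
            pooled = np.hstack([t.values for t in series])
            ts_all = gsp.RegionalTimeSeries(labels=self.basis.labels,
                                            values=pooled)
            self.cutoff_ = gsp.dichotomize(
                gsp.mean_esd(gsp.gft(self.basis, ts_all)))
        else:
            self.cutoff_ = self.cutoff
        results = [dc.cfd(t, self.basis, self.cutoff_) for t in series]
        group = dc.group_mean_cfd(results)
        self.result_ = group
        self.cfd_ = group.values
        self.per_scan_ = group.per_scan
        self.n_features_in_ = self.basis.n_modes
        return self

    def fit_predict(self, X, y=None):
        """Convenience: fit and return the group decoupling map."""
        return self.fit(X).cfd_
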