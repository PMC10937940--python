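"""Graph Fourier analysis of parcellated regional time series.

A regional signal ``f`` (regions x time) living on a connectome graph is
expanded on the Laplacian eigenmode basis ``Psi`` by the graph Fourier
transform ``w = Psi^T f``; the inverse transform ``f = Psi w`` reconstructs
it.  Squared coefficients ``|w_k(t)|^2`` form the graph energy spectral
density (ESD); a region's activity concentration is the L2-norm of its time
course.  Dichotomizing the ordered spectrum where cumulative mean ESD
reaches half the total splits the basis into low-frequency (graph-smooth)
and high-frequency (graph-irregular) mode sets, and the corresponding
band-limited projections of the signal are its coupled and decoupled
components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import EigenmodeBasis

__all__ = [
    "RegionalTimeSeries",
    "SpectralCoefficients",
    "CutoffSpec",
    "ConcentrationMap",
    "zscore",
    "gft",
    "igft",
    "esd",
    "mean_esd",
    "activity_concentration",
    "dichotomize",
    "graph_filter",
    "low_pass",
    "high_pass",
    "reconstruction_accuracy",
    "fc",
    "fc_reconstruction_accuracy",
    "cross_basis_reconstruction",
]


@dataclass(frozen=True)
class RegionalTimeSeries:
    """N x T signal, one row per region."""

    labels: tuple[str, ...]
    values: np.ndarray
    zscored: bool = False

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D region x time matrix")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match number of rows")
        if v.shape[1] < 2:
            raise ValueError("need at least 2 time points")
        if not np.all(np.isfinite(v)):
            raise ValueError("time series contains NaN or Inf")
        if self.zscored:
            if np.max(np.abs(v.mean(axis=1))) > 1e-8:
                raise ValueError("zscored flag set but means are not 0")
            if np.max(np.abs(v.std(axis=1) - 1.0)) > 1e-6:
                raise ValueError("zscored flag set but sds are not 1")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))


@dataclass(frozen=True)
class SpectralCoefficients:
    """GFT coefficients ``w`` (mode x time) with the basis eigenvalues."""

    eigenvalues: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        ev = np.asarray(self.eigenvalues, dtype=float)
        if w.shape[0] != ev.shape[0]:
            raise ValueError("coefficient rows must match number of eigenvalues")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "eigenvalues", ev)


@dataclass(frozen=True)
class CutoffSpec:
    """Partition of the ordered spectrum into frequency bands.

    ``mode='dichotomy'``: modes 1..C are low-frequency, C+1..N high.
    ``mode='tripartition'``: the lowest ``k_low`` and highest ``k_high``
    modes form the bands; the middle band is discarded from the index.
    Mode indices are 1-based in all user-facing I/O.
    """

    mode: str = "dichotomy"
    c: int | None = None
    k_low: int | None = None
    k_high: int | None = None

    def __post_init__(self) -> None:
        if self.mode == "dichotomy":
            if self.c is None or self.c < 1:
                raise ValueError("dichotomy cutoff requires C >= 1")
        elif self.mode == "tripartition":
            if self.k_low is None or self.k_high is None:
                raise ValueError("tripartition requires k_low and k_high")
            if self.k_low < 1 or self.k_high < 1:
                raise ValueError("k_low and k_high must be >= 1")
        else:
            raise ValueError(f"unknown cutoff mode {self.mode!r}")

    def validate(self, n_modes: int) -> None:
        if self.mode == "dichotomy":
            if not 1 <= self.c <= n_modes - 1:
                raise ValueError(f"C={self.c} out of range for {n_modes} modes")
        else:
            if self.k_low + self.k_high > n_modes:
                raise ValueError("k_low + k_high exceeds number of modes")

    def low_indices(self, n_modes: int) -> np.ndarray:
        """0-based indices of the low-frequency band."""
        self.validate(n_modes)
        k = self.c if self.mode == "dichotomy" else self.k_low
        return np.arange(k)

    def high_indices(self, n_modes: int) -> np.ndarray:
        """0-based indices of the high-frequency band."""
        self.validate(n_modes)
        if self.mode == "dichotomy":
            return np.arange(self.c, n_modes)
        return np.arange(n_modes - self.k_high, n_modes)


@dataclass(frozen=True)
class ConcentrationMap:
    """Per-region activity concentration (L2-norm over time)."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("concentrations must be nonnegative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def zscore(ts: RegionalTimeSeries) -> RegionalTimeSeries:
    """Z-score each region's time course (population divisor T).

    After z-scoring every region has mean 0, sd 1 and therefore activity
    concentration exactly sqrt(T).  Idempotent within floating point.
    """
    v = ts.values
    sd = v.std(axis=1)
    if np.any(sd <= 0):
        bad = [ts.labels[i] for i in np.flatnonzero(sd <= 0)]
        raise ValueError(f"constant time course at region(s) {bad}")
    z = (v - v.mean(axis=1, keepdims=True)) / sd[:, None]
    return RegionalTimeSeries(labels=ts.labels, values=z, zscored=True)


def _check_aligned(basis: EigenmodeBasis, ts: RegionalTimeSeries) -> None:
    if basis.labels != ts.labels:
        raise ValueError(
            "basis and time-series labels differ "
            f"(basis {basis.labels[:3]}..., signal {ts.labels[:3]}...)"
        )


def gft(basis: EigenmodeBasis, ts: RegionalTimeSeries) -> SpectralCoefficients:
    """Graph Fourier transform ``w = Psi^T f`` (column by column)."""
    _check_aligned(basis, ts)
    return SpectralCoefficients(eigenvalues=basis.eigenvalues,
                                w=basis.modes.T @ ts.values)


def igft(basis: EigenmodeBasis, coeffs: SpectralCoefficients) -> RegionalTimeSeries:
    """Inverse graph Fourier transform ``f = Psi w``."""
    if coeffs.w.shape[0] != basis.n_modes:
        raise ValueError(
            f"coefficient rows ({coeffs.w.shape[0]}) do not match basis size "
            f"({basis.n_modes})"
        )
    return RegionalTimeSeries(labels=basis.labels, values=basis.modes @ coeffs.w)


def esd(coeffs: SpectralCoefficients) -> np.ndarray:
    """Energy spectral density ``|w_k(t)|^2`` (mode x time)."""
    return coeffs.w ** 2


def mean_esd(coeffs: SpectralCoefficients) -> np.ndarray:
    """Time-averaged ESD per mode (length-N vector)."""
    return (coeffs.w ** 2).mean(axis=1)


def activity_concentration(ts: RegionalTimeSeries) -> ConcentrationMap:
    """L2-norm of each region's time course."""
    return ConcentrationMap(labels=ts.labels,
                            values=np.linalg.norm(ts.values, axis=1))


def dichotomize(mean_esd_vector: np.ndarray) -> CutoffSpec:
    """Split the ordered spectrum into two equal-energy halves.

    C is the smallest mode count whose cumulative mean ESD reaches half the
    total (modes in ascending-eigenvalue order); modes 1..C are the
    low-frequency band.
    """
    v = np.asarray(mean_esd_vector, dtype=float)
    if np.any(v < 0):
        raise ValueError("mean ESD must be nonnegative")
    total = v.sum()
    if total <= 0:
        raise ValueError("mean ESD is all zero; cannot dichotomize")
    c = int(np.searchsorted(np.cumsum(v), total / 2.0 - 1e-12) + 1)
    c = min(c, len(v) - 1)  # keep at least one high-frequency mode
    return CutoffSpec(mode="dichotomy", c=c)


def graph_filter(basis: EigenmodeBasis, ts: RegionalTimeSeries,
                 keep_modes) -> RegionalTimeSeries:
    """Band-limit a signal to the given mode set (0-based indices).

    Implements ``f_filtered = Psi^{(keep)} Psi^T f`` where ``Psi^{(keep)}``
    zeroes all dropped columns; this is an orthogonal projection, hence
    idempotent, and complementary mode sets sum to the identity.
    """
    keep = np.asarray(list(keep_modes), dtype=int)
    if keep.size == 0:
        raise ValueError("keep_modes must not be empty")
    if keep.min() < 0 or keep.max() >= basis.n_modes:
        raise ValueError("keep_modes out of range")
    w = gft(basis, ts).w
    mask = np.zeros(basis.n_modes, dtype=bool)
    mask[keep] = True
    wk = np.where(mask[:, None], w, 0.0)
    return RegionalTimeSeries(labels=ts.labels, values=basis.modes @ wk)


def low_pass(basis: EigenmodeBasis, ts: RegionalTimeSeries,
             cutoff: CutoffSpec) -> RegionalTimeSeries:
    """Low-frequency (graph-smooth, coupled) component of the signal."""
    return graph_filter(basis, ts, cutoff.low_indices(basis.n_modes))


def high_pass(basis: EigenmodeBasis, ts: RegionalTimeSeries,
              cutoff: CutoffSpec) -> RegionalTimeSeries:
    """High-frequency (graph-irregular, decoupled) component of the signal."""
    return graph_filter(basis, ts, cutoff.high_indices(basis.n_modes))


# ---------------------------------------------------------------------------
# Reconstruction accuracy
# ---------------------------------------------------------------------------

def reconstruct(basis: EigenmodeBasis, ts: RegionalTimeSeries,
                k: int) -> RegionalTimeSeries:
    """Reconstruction from the first k (lowest-frequency) modes."""
    if not 1 <= k <= basis.n_modes:
        raise ValueError(f"k={k} out of range [1, {basis.n_modes}]")
    return graph_filter(basis, ts, np.arange(k))


def reconstruction_accuracy(basis: EigenmodeBasis, ts: RegionalTimeSeries,
                            k: int, per_region: bool = False):
    """Activity-concentration reconstruction accuracy of the first k modes.

    Default is the global ratio ``||f_rec||_F / ||f||_F`` — monotone
    non-decreasing in k, equal to 1 at k = N.  With ``per_region=True``
    the per-region concentration ratios are returned instead.
    """
    total = np.linalg.norm(ts.values)
    if total == 0:
        raise ValueError("zero signal has no reconstruction accuracy")
    rec = reconstruct(basis, ts, k)
    if per_region:
        emp = np.linalg.norm(ts.values, axis=1)
        if np.any(emp == 0):
            raise ValueError("zero-norm region in per-region accuracy")
        return np.linalg.norm(rec.values, axis=1) / emp
    return float(np.linalg.norm(rec.values) / total)


def fc(ts: RegionalTimeSeries) -> np.ndarray:
    """Pearson functional-connectivity matrix (unit diagonal)."""
    if ts.n_timepoints < 3:
        raise ValueError("need T >= 3 for functional connectivity")
    sd = ts.values.std(axis=1)
    if np.any(sd <= 0):
        bad = [ts.labels[i] for i in np.flatnonzero(sd <= 0)]
        raise ValueError(f"constant region(s) {bad} have undefined correlation")
    return np.corrcoef(ts.values)


def fc_reconstruction_accuracy(basis: EigenmodeBasis, ts: RegionalTimeSeries,
                               k: int) -> float:
    """Pearson correlation of empirical vs reconstructed FC.

    Compared over the strict upper triangle only — C(N,2) unique edges,
    excluding the uninformative unit diagonal.
    """
    emp = fc(ts)
    rec = fc(reconstruct(basis, ts, k))
    iu = np.triu_indices(ts.n_regions, k=1)
    return float(np.corrcoef(emp[iu], rec[iu])[0, 1])


def cross_basis_reconstruction(basis_a: EigenmodeBasis, ts_b: RegionalTimeSeries,
                               k: int, mapping: dict[str, str] | None = None):
    """Reconstruct one system's activity with another system's eigenmodes.

    ``mapping`` sends each basis label to the homologous label in ``ts_b``
    (identity when None).  The signal rows are reordered to the basis order
    through the mapping, then expanded / truncated on ``basis_a``.

    Returns ``(activity_accuracy, fc_accuracy)``.
    """
    if mapping is None:
        mapping = {l: l for l in basis_a.labels}
    if set(mapping.keys()) != set(basis_a.labels):
        raise ValueError("mapping keys must be exactly the basis labels")
    targets = list(mapping.values())
    if len(set(targets)) != len(targets):
        raise ValueError("homolog mapping is not a bijection")
    pos = {l: i for i, l in enumerate(ts_b.labels)}
    missing = [t for t in targets if t not in pos]
    if missing:
        raise ValueError(f"mapped labels missing from the signal: {missing}")
    idx = [pos[mapping[l]] for l in basis_a.labels]
    aligned = RegionalTimeSeries(labels=basis_a.labels,
                                 values=ts_b.values[idx, :])
    return (reconstruction_accuracy(basis_a, aligned, k),
            fc_reconstruction_accuracy(basis_a, aligned, k))
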