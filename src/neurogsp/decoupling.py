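"""Regional cellular-functional decoupling (CFD).

The decoupling index of a region is the binary-log ratio of the L2-norms of
its high-frequency (decoupled) and low-frequency (coupled) graph-filtered
components over time,

    CFD_i = log2( ||f_i^high||_2 / ||f_i^low||_2 ).

CFD = 0 marks a perfect balance between coupling and decoupling; CFD near
-1 marks activity strongly coupled to the underlying connections (the low
band carries twice the norm of the high band), CFD near +1 the reverse.
The index is invariant to rescaling the whole signal and exactly negates
when the two bands are swapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import EigenmodeBasis
from .gsp import CutoffSpec, RegionalTimeSeries, high_pass, low_pass

__all__ = ["CFDResult", "cfd", "group_mean_cfd", "class_summary"]


@dataclass(frozen=True)
class CFDResult:
    """Per-region decoupling values under a fixed band cutoff."""

    labels: tuple[str, ...]
    values: np.ndarray
    cutoff: CutoffSpec
    per_scan: np.ndarray | None = None  # scan x region
    significance: tuple[str, ...] | None = None  # coupled / decoupled / ns

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels),):
            raise ValueError("values must be one number per region")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"region": self.labels, "cfd": self.values})
        if self.significance is not None:
            df["significance"] = list(self.significance)
        return df


def cfd(ts: RegionalTimeSeries, basis: EigenmodeBasis,
        cutoff: CutoffSpec) -> CFDResult:
    """Compute the decoupling index at every region of one scan.

    Raises when a region's filtered component has zero norm (the log ratio
    would be infinite); that indicates a degenerate signal, not decoupling.
    """
    lo = low_pass(basis, ts, cutoff)
    hi = high_pass(basis, ts, cutoff)
    lo_n = np.linalg.norm(lo.values, axis=1)
    hi_n = np.linalg.norm(hi.values, axis=1)
    bad = np.flatnonzero((lo_n == 0) | (hi_n == 0))
    if bad.size:
        names = [ts.labels[i] for i in bad]
        raise ValueError(
            f"zero-norm filtered component at region(s) {names}; "
            "the log ratio is undefined there"
        )
    return CFDResult(labels=ts.labels, values=np.log2(hi_n / lo_n),
                     cutoff=cutoff)


def group_mean_cfd(results: list[CFDResult]) -> CFDResult:
    """Arithmetic mean of per-scan CFD maps; stacks the scans for later tests."""
    if not results:
        raise ValueError("need at least one CFD result")
    ref = results[0]
    for r in results[1:]:
        if r.labels != ref.labels:
            raise ValueError("CFD results have mismatched region labels")
        if r.cutoff != ref.cutoff:
            raise ValueError("CFD results have mismatched cutoffs")
    stack = np.vstack([r.values for r in results])
    return CFDResult(labels=ref.labels, values=stack.mean(axis=0),
                     cutoff=ref.cutoff, per_scan=stack)


def class_summary(values, labels, class_map: dict[str, str]) -> pd.DataFrame:
    """Box-plot statistics of a regional map grouped by cortical class.

    Per class: n, median, quartiles (linear interpolation), whisker
    endpoints (most extreme non-outlier values) and outliers under the
    1.5 x IQR rule.  Classes are ordered by their median value.
    """
    labels = list(labels)
    values = np.asarray(values, dtype=float)
    missing = [l for l in labels if l not in class_map]
    if missing:
        raise ValueError(f"region(s) without class assignment: {missing}")
    rows = []
    for cls in sorted(set(class_map[l] for l in labels)):
        v = np.sort(values[[i for i, l in enumerate(labels)
                            if class_map[l] == cls]])
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inliers = v[(v >= lo_fence) & (v <= hi_fence)]
        outliers = v[(v < lo_fence) | (v > hi_fence)]
        rows.append({
            "class": cls, "n": int(v.size), "median": med,
            "q1": q1, "q3": q3,
            "whisker_low": inliers.min(), "whisker_high": inliers.max(),
            "outliers": outliers.tolist(),
        })
    return (pd.DataFrame(rows)
            .sort_values("median", kind="stable")
            .reset_index(drop=True))
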