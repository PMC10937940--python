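"""Delimited-text I/O, run configuration and pipeline orchestration.

All matrices travel as labeled TSV/CSV (first row and first column are
region labels); results are tidy delimited tables.  Every table written by
a pipeline run carries a header comment with the configuration hash and
seed, and a provenance file records the configuration together with the
achieved parameters (teleportation actually applied, chosen cutoff,
attained surrogate significance level).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectome as cn
from . import decoupling as dc
from . import gsp
from . import nulls
from .synthetic import SyntheticSpec, make_cohort, make_connectome, \
    make_coordinates

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_matrix", "write_matrix", "read_timeseries",
           "run_pipeline", "simulate_to_dir"]


def read_matrix(path, orientation: str = "source_rows") -> pd.DataFrame:
    """Read a labeled square matrix from delimited text.

    The delimiter is sniffed from the extension (.csv -> comma, otherwise
    tab).  ``orientation='target_rows'`` transposes on read, so
    ``read(A, target_rows) == read(A^T, source_rows)``.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if df.index.duplicated().any():
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate row labels {dup}")
    if df.columns.duplicated().any():
        dup = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"{path}: duplicate column labels {dup}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    if orientation == "target_rows":
        df = df.T
    elif orientation != "source_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return df


def write_matrix(df: pd.DataFrame, path, header_comment: str | None = None):
    """Write a labeled matrix as delimited text (delimiter from extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep=sep)


def read_timeseries(path) -> gsp.RegionalTimeSeries:
    """Read a region x time table (label column first)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    df.index = df.index.map(str)
    if df.index.duplicated().any():
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate region labels {dup}")
    return gsp.RegionalTimeSeries(labels=tuple(df.index),
                                  values=df.to_numpy(dtype=float))


def _read_two_column_map(path) -> dict[str, str]:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    return {str(a): str(b) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (loadable from YAML/JSON)."""

    connectome: str
    timeseries: list[str]
    output_dir: str
    class_map: str | None = None
    coordinates: str | None = None
    orientation: str = "source_rows"
    zscore: bool = True
    teleport_alpha: float = 0.0
    cutoff_mode: str = "auto"       # 'auto' | 'dichotomy' | 'tripartition'
    c: int | None = None
    k_low: int | None = None
    k_high: int | None = None
    n_class_surrogates: int = 1000
    n_scan_surrogates: int = 19
    run_tests: bool = True
    correction: str = "bonferroni"
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yml", ".yaml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        cfg = cls(**data)
        for key in ("connectome", "class_map", "coordinates"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} path does not exist: {p}")
        for p in cfg.timeseries:
            if not Path(p).exists():
                raise FileNotFoundError(f"time-series path does not exist: {p}")
        return cfg

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration.

        The output directory is excluded so results written to different
        locations from the same analysis carry the same stamp.
        """
        d = asdict(self)
        d.pop("output_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _resolve_cutoff(cfg: RunConfig, mean_esd_vec) -> gsp.CutoffSpec:
    if cfg.cutoff_mode == "auto":
        return gsp.dichotomize(mean_esd_vec)
    if cfg.cutoff_mode == "dichotomy":
        return gsp.CutoffSpec(mode="dichotomy", c=cfg.c)
    if cfg.cutoff_mode == "tripartition":
        return gsp.CutoffSpec(mode="tripartition", k_low=cfg.k_low,
                              k_high=cfg.k_high)
    raise ValueError(f"unknown cutoff_mode {cfg.cutoff_mode!r}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run graph construction -> eigenmodes -> decomposition -> CFD -> tests.

    Writes all result tables into ``cfg.output_dir`` and returns a summary
    dict (also written as ``provenance.json``).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config_hash={cfg.digest()} seed={cfg.seed}"

    def _stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    stage = _stage("connectome")
    try:
        class_map = (_read_two_column_map(cfg.class_map)
                     if cfg.class_map else None)
        if cfg.run_tests and class_map is None:
            raise ValueError(
                "run_tests requested but no class map configured")
        wdf = read_matrix(cfg.connectome, orientation=cfg.orientation)
        graph = cn.build_graph(wdf, class_map=class_map)

        stage = _stage("laplacian")
        tm = cn.transition_model(graph, cfg.teleport_alpha)
        L = cn.directed_laplacian(tm)
        basis = cn.eigenmodes(L, graph.labels)

        stage = _stage("timeseries")
        scans = [read_timeseries(p) for p in cfg.timeseries]
        if cfg.zscore:
            scans = [gsp.zscore(ts) for ts in scans]
        for ts in scans:
            if ts.labels != graph.labels:
                raise ValueError("time-series labels do not match connectome")

        stage = _stage("decomposition")
        pooled = gsp.RegionalTimeSeries(
            labels=graph.labels,
            values=np.hstack([t.values for t in scans]))
        coeffs = gsp.gft(basis, pooled)
        mesd = gsp.mean_esd(coeffs)
        cutoff = _resolve_cutoff(cfg, mesd)
        n = basis.n_modes
        acc = [gsp.reconstruction_accuracy(basis, pooled, k)
               for k in range(1, n + 1)]

        stage = _stage("cfd")
        per_scan = [dc.cfd(ts, basis, cutoff) for ts in scans]
        group = dc.group_mean_cfd(per_scan)

        stage = _stage("tests")
        tests_out = {}
        if cfg.run_tests:
            rng = np.random.default_rng(cfg.seed)
            conc = gsp.activity_concentration(pooled)
            surr_maps = np.empty((cfg.n_class_surrogates, n))
            for d in range(cfg.n_class_surrogates):
                s = nulls.spectral_randomization(
                    basis, pooled, seed=int(rng.integers(2**31)))
                surr_maps[d] = np.linalg.norm(s.values, axis=1)
            class_df = nulls.class_concentration_test(
                conc.values, graph.labels, class_map, surr_maps)
            class_df.to_csv(out / "class_concentration_test.tsv",
                            sep="\t", index=False)
            surr_cfd = np.empty((len(scans), cfg.n_scan_surrogates, n))
            for i, ts in enumerate(scans):
                for j in range(cfg.n_scan_surrogates):
                    s = nulls.spectral_randomization(
                        basis, ts, seed=int(rng.integers(2**31)))
                    surr_cfd[i, j] = dc.cfd(s, basis, cutoff).values
            loc_df = nulls.cfd_localization(
                group.per_scan, surr_cfd, graph.labels,
                correction=cfg.correction)
            loc_df.to_csv(out / "cfd_localization.tsv", sep="\t", index=False)
            tests_out = {
                "attained_per_scan_level":
                    loc_df.attrs["attained_per_scan_level"],
                "n_significant_classes": int(class_df["significant"].sum()),
            }
            summ = dc.class_summary(group.values, graph.labels, class_map)
            summ.to_csv(out / "cfd_class_summary.tsv", sep="\t", index=False)

        stage = _stage("write")
        write_matrix(pd.DataFrame(basis.modes, index=graph.labels,
                                  columns=[f"mode_{k+1}" for k in range(n)]),
                     out / "eigenmodes.tsv", stamp)
        write_matrix(pd.DataFrame([basis.eigenvalues],
                                  index=["eigenvalue"],
                                  columns=[f"mode_{k+1}" for k in range(n)]),
                     out / "eigenvalues.tsv", stamp)
        pd.DataFrame({"mode": np.arange(1, n + 1), "mean_esd": mesd}) \
            .to_csv(out / "mean_esd.tsv", sep="\t", index=False)
        pd.DataFrame({"k": np.arange(1, n + 1), "accuracy": acc}) \
            .to_csv(out / "accuracy_curve.tsv", sep="\t", index=False)
        conc_all = gsp.activity_concentration(pooled)
        pd.DataFrame({"region": graph.labels, "concentration": conc_all.values}) \
            .to_csv(out / "concentration.tsv", sep="\t", index=False)
        group.to_frame().to_csv(out / "cfd.tsv", sep="\t", index=False)
        write_matrix(pd.DataFrame(group.per_scan,
                                  index=[f"scan_{i+1}"
                                         for i in range(len(scans))],
                                  columns=graph.labels),
                     out / "cfd_per_scan.tsv", stamp)

        provenance = {
            "config": asdict(cfg),
            "config_hash": cfg.digest(),
            "n_regions": n,
            "n_scans": len(scans),
            "teleport_alpha_applied": tm.teleport_alpha,
            "cutoff": {"mode": cutoff.mode, "c": cutoff.c,
                       "k_low": cutoff.k_low, "k_high": cutoff.k_high},
            **tests_out,
        }
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=2, default=float))
        return provenance
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def simulate_to_dir(spec: SyntheticSpec, out_dir) -> dict:
    """Write a full synthetic dataset (connectome, coordinates, cohort,
    ground truth) to a directory as delimited text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph = make_connectome(spec)
    from .connectome import directed_laplacian, eigenmodes, transition_model
    basis = eigenmodes(directed_laplacian(transition_model(graph)),
                       graph.labels)
    scans, truth = make_cohort(spec, basis=basis)
    xyz, dist = make_coordinates(spec.n_regions, seed=spec.seed)

    write_matrix(pd.DataFrame(graph.weights, index=graph.labels,
                              columns=graph.labels),
                 out / "connectome.tsv", f"seed={spec.seed}")
    pd.DataFrame(xyz, index=graph.labels, columns=["x", "y", "z"]) \
        .to_csv(out / "coordinates.tsv", sep="\t")
    write_matrix(pd.DataFrame(dist, index=graph.labels, columns=graph.labels),
                 out / "distances.tsv", f"seed={spec.seed}")
    pd.DataFrame({"region": graph.labels, "planted_log2_ratio": truth}) \
        .to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    paths = []
    for i, ts in enumerate(scans):
        p = out / f"scan_{i+1:03d}.tsv"
        pd.DataFrame(ts.values, index=ts.labels).to_csv(p, sep="\t")
        paths.append(str(p))
    manifest = {"n_regions": spec.n_regions, "n_scans": len(scans),
                "seed": spec.seed, "scans": paths}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
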