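"""End-to-end pipeline driver.

Runs connectivity -> template -> cycle basis -> projection -> inference ->
profiling from a declarative configuration, writing results tables, plots
and a reproducibility manifest.  Subgroup contrasts are expressed as
phenotype filters (a pandas query over the patient rows) rerunning the same
pipeline against the full control pool.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .connectivity import RoiTimeSeries, fisher_z_fc, gaussian_highpass, group_average
from .graph import WeightedGraph, vectorize_upper
from .inference import (
    build_design,
    edgewise_lme,
    freedman_lane_maxT,
    paired_t_mst_extra,
)
from .profiling import (
    cluster_profiles,
    distance_heatmap,
    profile_distances,
    profiles_for_cycles,
    radial_plot,
    summarize_clusters,
)
from .projection import project, subject_splits
from .topology import build_cycle_basis

logger = logging.getLogger("hodgecycles")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative pipeline configuration.

    ``mode`` selects the input stage: ``"fc"`` reads precomputed FC matrices
    (one delimited file per subject under ``data_dir/fc`` or an
    ``fc_stack.npz``), ``"timeseries"`` reads T x n series under
    ``data_dir/timeseries`` and applies the Gaussian high-pass (width
    ``highpass_width_s`` seconds, default 125) before correlation.
    ``subgroup_query`` filters the patient rows (controls are always kept).
    ``basis_dir`` reuses a previously saved cycle basis instead of deriving
    one from this run's group average — required when subgroup contrasts
    must share the main analysis' basis, or when the basis of a designated
    template graph is to be used.
    """

    data_dir: str
    out_dir: str
    mode: str = "fc"
    basis_dir: str | None = None
    phenotype: str | None = None  # default: <data_dir>/phenotype.csv
    labels: str | None = None  # default: <data_dir>/labels.tsv
    n_perm: int = 1000
    seed: int = 0
    alpha: float = 0.05
    n_contrasts: int = 1
    subgroup_query: str | None = None
    cluster_threshold: float = 0.5
    highpass_width_s: float = 125.0
    tr_s: float = 1.0
    run_edgewise: bool = True
    run_mst_extra: bool = True
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _load_edge_matrix(cfg: RunConfig, phenotype: pd.DataFrame) -> tuple[np.ndarray, int]:
    data = Path(cfg.data_dir)
    subjects = phenotype["subject"].tolist()
    mats = {}
    if cfg.mode == "fc":
        stack = data / "fc_stack.npz"
        if stack.exists():
            arr, subs = hio.read_array_stack(stack)
            mats = dict(zip(subs, arr))
        else:
            for sub in subjects:
                f = data / "fc" / f"{sub}.tsv"
                if not f.exists():
                    raise FileNotFoundError(f"no FC matrix for subject {sub!r}: {f}")
                mats[sub] = hio.read_matrix(f)
    elif cfg.mode == "timeseries":
        for sub in subjects:
            f = data / "timeseries" / f"{sub}.tsv"
            if not f.exists():
                raise FileNotFoundError(f"no time series for subject {sub!r}: {f}")
            ts = RoiTimeSeries(values=hio.read_matrix(f), tr_s=cfg.tr_s)
            ts = gaussian_highpass(ts, cfg.highpass_width_s)
            mats[sub] = fisher_z_fc(ts)
    else:
        raise ValueError(f"unknown mode {cfg.mode!r}")
    missing = [s for s in subjects if s not in mats]
    if missing:
        raise ValueError(f"data missing for subject(s): {missing[:5]}")
    W = np.stack([vectorize_upper(mats[s]) for s in subjects])
    n = mats[subjects[0]].shape[0]
    return W, n


def _apply_subgroup(phenotype: pd.DataFrame, query: str | None) -> pd.DataFrame:
    if not query:
        return phenotype
    patients = phenotype[phenotype["group"] == 1]
    selected = patients.query(query)
    if len(selected) == 0:
        raise ValueError(f"subgroup filter {query!r} selects no patients")
    controls = phenotype[phenotype["group"] == 0]
    return pd.concat([controls, selected]).reset_index(drop=True)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns a summary dict (also written as
    ``manifest.json`` in the output directory)."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "phenotype"
    try:
        phenotype = hio.read_phenotype(cfg.phenotype or Path(cfg.data_dir) / "phenotype.csv")
        phenotype = _apply_subgroup(phenotype, cfg.subgroup_query)
        logger.info("phenotype: %d subjects (%d patients)", len(phenotype), int(phenotype["group"].sum()))

        stage = "connectivity"
        W, n = _load_edge_matrix(cfg, phenotype)
        logger.info("connectivity: %d subjects x %d edges", *W.shape)

        stage = "basis"
        if cfg.basis_dir:
            bdir = Path(cfg.basis_dir)
            basis = hio.read_basis(bdir / "basis_triplets.tsv", bdir / "basis_header.json")
            if basis.n != n:
                raise ValueError(f"saved basis has n={basis.n}, data has n={n}")
        else:
            template = group_average([WeightedGraph(n=n, w=w) for w in W])
            basis = build_cycle_basis(template)
        hio.write_basis(basis, out / "basis_triplets.tsv", out / "basis_header.json")
        logger.info("basis: Q=%d cycles in m=%d edge space", basis.q, basis.m)

        stage = "projection"
        A = project(W, basis)

        stage = "inference"
        design = build_design(phenotype)
        result = freedman_lane_maxT(A, design, n_perm=cfg.n_perm, seed=cfg.seed, alpha=cfg.alpha)
        result.to_frame().to_csv(out / "cycle_stats.tsv", sep="\t", index=False)
        sig = result.significant(cfg.alpha)
        logger.info("inference: global p=%.4g, %d significant cycles", result.global_p, sig.size)

        stage = "edgewise"
        edge_sig = None
        if cfg.run_edgewise:
            ew = edgewise_lme(W, phenotype, alpha=cfg.alpha, n_contrasts=cfg.n_contrasts)
            edge_sig = ew.significant
            pd.DataFrame(
                {
                    "edge": np.arange(basis.m),
                    "beta_group": ew.beta_group,
                    "p": ew.p,
                    "q": ew.q,
                    "tested": ew.tested,
                    "significant": ew.significant,
                }
            ).to_csv(out / "edge_stats.tsv", sep="\t", index=False)

        stage = "mst_extra"
        if cfg.run_mst_extra and sig.size:
            splits = subject_splits(W, n, basis)
            paired = paired_t_mst_extra(splits.alpha_mst, splits.alpha_extra, sig, design)
            paired.to_csv(out / "mst_extra_stats.tsv", sep="\t", index=False)

        stage = "profiling"
        n_clusters = 0
        if sig.size:
            labels = hio.read_labels(cfg.labels or Path(cfg.data_dir) / "labels.tsv")
            profiles = profiles_for_cycles(basis, sig, labels, edge_sig)
            if sig.size >= 2:
                D = profile_distances(profiles)
                assignment = cluster_profiles(D, threshold=cfg.cluster_threshold)
            else:
                D = np.zeros((1, 1))
                assignment = np.zeros(1, dtype=int)
            summary = summarize_clusters(assignment, profiles)
            summary.to_csv(out / "cluster_summary.tsv", sep="\t", index=False)
            pd.DataFrame(
                {"cycle": sig, "cluster": assignment}
            ).to_csv(out / "cycle_clusters.tsv", sep="\t", index=False)
            n_clusters = int(assignment.max()) + 1
            if cfg.make_plots:
                radial_plot(summary, str(out / "cluster_radial.svg"))
                distance_heatmap(D, assignment, str(out / "cluster_distances.svg"))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    cfg_json = json.dumps(asdict(cfg), sort_keys=True, default=str)
    manifest = {
        "config": asdict(cfg),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_subjects": len(phenotype),
        "n_nodes": n,
        "m_edges": basis.m,
        "q_cycles": basis.q,
        "global_p": result.global_p,
        "n_significant_cycles": int(sig.size),
        "n_clusters": n_clusters,
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "elapsed_s": round(time.time() - t0, 2),
    }
    hio.write_manifest(manifest, out / "manifest.json")
    return manifest
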