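"""End-to-end bundle pipeline: sample, cluster, classify, summarise.

Artifacts written to the output directory:

* ``resolved_config.json`` — fully resolved configuration, seed, version
* ``ensemble.pdb`` — recorded conformations (CA-only multi-model PDB)
* ``ensemble_scores.csv`` — per-conformation scores
* ``centroids.pdb`` — cluster representatives
* ``arrangement_table.csv`` — counts per arrangement type (all / top-K)
* ``distance_stats.csv`` — per-arrangement residue-pair distance stats
* ``report.json`` — run report (counts, shares, per-stage timings)

A stage failure leaves earlier artifacts on disk and re-raises.
"""

from __future__ import annotations

import json
import time
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import (
    arrangement_table,
    classify_ensemble,
    cluster,
    crossing_angle_filter,
    distance_stats,
)
from .config import PipelineConfig, dump_metadata
from .pdbio import write_pdb
from .sampling import initial_bundle, run_mc


def _version() -> str:
    try:
        return version("tmbundle")
    except PackageNotFoundError:
        return "unknown"


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run sample -> cluster -> classify -> tables; returns the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    report: dict = {"version": _version(), "seed": config.seed}

    meta = config.to_metadata()
    meta["version"] = _version()
    (outdir / "resolved_config.json").write_text(json.dumps(meta, indent=2))

    t0 = time.perf_counter()
    rng = np.random.default_rng(config.seed)
    initial = initial_bundle(config.specs, rng, side=config.initial_side)
    scorer = config.restraints.scorer(config.specs)
    ensemble = run_mc(initial, scorer, config.mc)
    timings["sample"] = time.perf_counter() - t0
    write_pdb(outdir / "ensemble.pdb", ensemble)
    pd.DataFrame({"score": ensemble.scores}).to_csv(
        outdir / "ensemble_scores.csv", index_label="conformation"
    )
    report["n_sampled"] = len(ensemble)

    t0 = time.perf_counter()
    keep = crossing_angle_filter(ensemble, config.crossing_angle_max)
    filtered = ensemble.subset(np.flatnonzero(keep))
    report["n_after_crossing_filter"] = len(filtered)
    if len(filtered) == 0:
        raise RuntimeError("crossing-angle filter removed every conformation")
    clustered = cluster(filtered, cutoff=config.clustering_cutoff)
    timings["cluster"] = time.perf_counter() - t0
    centroids = filtered.subset(clustered.centroid_indices)
    write_pdb(outdir / "centroids.pdb", centroids)
    report["n_clusters"] = clustered.n_clusters

    t0 = time.perf_counter()
    labels = classify_ensemble(centroids)
    table = arrangement_table(labels, centroids.scores, top_k=config.top_k)
    table.to_frame().to_csv(outdir / "arrangement_table.csv", index=False)
    stats = distance_stats(centroids, labels)
    stats.to_csv(outdir / "distance_stats.csv")
    timings["classify"] = time.perf_counter() - t0

    report["arrangement_counts"] = table.counts_all
    report["arrangement_counts_top_k"] = table.counts_top
    report["top3_share_all_percent"] = table.top3_share_all()
    report["top3_count_top_k"] = table.top3_count_top()
    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
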