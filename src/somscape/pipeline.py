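"""The five chained stages as one callable pipeline.

Given a :class:`~somscape.config.RunConfig`, the pipeline builds the
lattice and trains the map (stage 1), overlays the additional data
(stage 2), partitions the map into contiguous clusters and labels the
genes (stage 3), summarises the overlay per cluster (stage 4), and runs
Fisher-exact enrichment against the annotation collection (stage 5).
All artefacts — trained map, hit table, overlaid codebook, cluster
labels, summaries, enrichment results, provenance — are written to an
output directory; identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .cluster import ClusterAssignment, assign_genes, merge_to_max_clusters, partition_map
from .config import RunConfig
from .enrich import GeneSetCollection, results_to_frame, run_enrichment
from .io import read_gmt, read_matrix, save_map, write_gmt, write_hits, write_matrix
from .lattice import build_lattice
from .overlay import OverlaidMap, OverlayMatrix, cluster_summary, overlay_map
from .plot import render_landscape
from .som import HitAssignment, TrainedMap, map_assignments, train_som
from .synthetic import SyntheticSpec, simulate_genesets, simulate_matrix, simulate_status


@dataclass
class PipelineResult:
    trained_map: TrainedMap
    hits: HitAssignment
    overlaid: OverlaidMap
    clusters: ClusterAssignment
    summary: "object"
    enrichment: "object"
    outdir: Path | None


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


def _load_inputs(config: RunConfig):
    if config.matrix_path is not None:
        data = read_matrix(config.matrix_path, kind="training")
        extra = (
            read_matrix(config.overlay_path, kind="overlay")
            if config.overlay_path
            else None
        )
        coll = read_gmt(config.gmt_path) if config.gmt_path else None
        truth = None
    else:
        syn = dict(config.synthetic)
        n_decoys = int(syn.pop("n_decoys", 9))
        planted = [tuple(p) for p in syn.pop("planted_sets", [])]
        spec = SyntheticSpec(
            **syn, planted_sets=planted, seed=config.stage_seed(0)
        )
        data, truth = simulate_matrix(spec)
        extra = simulate_status(truth, spec.status_probs, config.stage_seed(1))
        coll = simulate_genesets(truth, planted, n_decoys, config.stage_seed(2))
    return data, extra, coll, truth


def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    """Execute stages 1-5 and (optionally) write all artefacts.

    Any stage failure aborts with the stage name in the message; no
    partial output directory is left without its provenance record
    marking the run unfinished.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    data, extra, coll, truth = _stage("inputs")(_load_inputs)(config)

    @_stage("train")
    def s1():
        lat = build_lattice(config.shape, config.scale)
        tm = train_som(
            data,
            lat,
            rough_iters=config.rough_iters,
            finetune_iters=config.finetune_iters,
            seed=config.stage_seed(3),
            init=config.init,
            standardize=config.standardize,
        )
        return tm, map_assignments(tm, data)

    tm, hits = s1()

    @_stage("overlay")
    def s2():
        if extra is None:
            return None
        return overlay_map(tm, hits, extra, smoothing_sigma=config.smoothing_sigma)

    om = s2()

    @_stage("cluster")
    def s3():
        ca = partition_map(tm, plateau_tol=config.plateau_tol)
        ca = assign_genes(ca, hits)
        if config.k_max is not None:
            ca = merge_to_max_clusters(ca, tm, config.k_max)
        return ca

    ca = s3()

    @_stage("summary")
    def s4():
        if om is None:
            return None
        return cluster_summary(om, ca, statistic=config.summary_statistic)

    summary = s4()

    @_stage("enrich")
    def s5():
        if coll is None:
            return None
        return run_enrichment(ca, coll, tails=config.tails, alpha=config.alpha)

    results = s5()

    if out is not None:
        _write_artifacts(config, out, data, extra, coll, truth, tm, hits, om, ca, summary, results)

    return PipelineResult(tm, hits, om, ca, summary, results, out)


@_stage("write")
def _write_artifacts(config, out, data, extra, coll, truth, tm, hits, om, ca, summary, results):
    import pandas as pd

    config.to_json(out / "config.json")
    write_matrix(data, out / "matrix.tsv")
    if truth is not None:
        pd.DataFrame({"row_id": data.row_ids, "group": truth}).to_csv(
            out / "truth.tsv", sep="\t", index=False, lineterminator="\n"
        )
    if extra is not None:
        write_matrix(extra, out / "overlay_input.tsv")
    if coll is not None:
        write_gmt(coll, out / "sets.gmt")
    save_map(tm, out / "map.json")
    write_matrix(tm.codebook, out / "codebook.tsv")
    write_hits(hits, out / "hits.tsv")
    if om is not None:
        write_matrix(om, out / "overlaid_codebook.tsv")
    ca.node_frame().to_csv(out / "node_clusters.tsv", sep="\t", index=False, lineterminator="\n")
    ca.gene_frame().to_csv(out / "gene_clusters.tsv", sep="\t", index=False, lineterminator="\n")
    if summary is not None:
        summary.to_csv(out / "cluster_summary.tsv", sep="\t", lineterminator="\n")
    if results is not None:
        results_to_frame(results).to_csv(
            out / "enrichment.tsv", sep="\t", index=False, lineterminator="\n"
        )
    if config.render:
        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        for col in tm.codebook.feature_ids:
            render_landscape(tm, col, figdir / f"train_{col}.png")
        if om is not None:
            for col in om.col_ids:
                render_landscape(om, col, figdir / f"overlay_{col}.png")
    provenance = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "somscape_version": __version__,
        "n_rows": data.shape[0],
        "n_cols": data.shape[1],
        "n_nodes": tm.lattice.n_nodes,
        "n_clusters": ca.n_clusters,
        "qe_initial": tm.qe_trace[0],
        "qe_final": tm.qe_trace[-1],
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
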