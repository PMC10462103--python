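"""End-to-end analysis runs: validate → base → log maps → embed → flag → plot.

A run consumes a directory (or file) of gene trees, optionally one or
two phylogenomic summary trees and a gene-metadata CSV, and writes CSVs,
plots, a JSON report, and a run manifest into an output directory.
Re-running with identical inputs and seeds reproduces byte-identical
CSVs; timestamps live only in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .estimators import TreeEmbedding
from .geodesic import bhv_distance, rf_distance
from .reduce import flag_outlier_features, flag_outliers, tree_contrast_stats
from .tree import PhyloTree, parse_newick, read_metadata, read_trees, \
    validate_collection


@dataclass
class PipelineConfig:
    trees: str  # directory or multi-tree Newick file of gene trees
    outdir: str
    phylo: str | None = None  # phylogenomic tree file
    phylo_reduced: str | None = None  # user-supplied reduced-set summary tree
    metadata: str | None = None  # CSV with gene[,category]
    base: str = "auto"  # auto (= min_sq_bhv) | phylo | path to a tree file
    method: str = "pca"  # pca | mds_bhv | mds_rf
    nonmetric: bool = False
    rescale: bool = False
    q: int = 2
    threshold: float = 3.5
    drop: list = field(default_factory=list)  # gene names to exclude
    plot: str = "embedding.png"  # also .html / .svg; "" disables
    seed: int = 0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _input_hashes(cfg: PipelineConfig) -> dict:
    hashes = {}
    for attr in ("trees", "phylo", "phylo_reduced", "metadata"):
        val = getattr(cfg, attr)
        if val is None:
            continue
        p = Path(val)
        if p.is_dir():
            for f in sorted(p.glob("*.nwk")):
                hashes[str(f)] = _sha256(f)
        elif p.exists():
            hashes[str(p)] = _sha256(p)
    return hashes


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute a full analysis; returns the output directory."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _StageLogger()

    genes = read_trees(cfg.trees)
    if cfg.drop:
        missing = set(cfg.drop) - {t.name for t in genes}
        if missing:
            raise ValueError(f"--drop names not in collection: {sorted(missing)}")
        genes = [t for t in genes if t.name not in cfg.drop]
    phylos = []
    if cfg.phylo:
        phylos.append(read_trees(cfg.phylo)[0].copy(name="phylogenomic"))
    if cfg.phylo_reduced:
        phylos.append(read_trees(cfg.phylo_reduced)[0].copy(name="phylogenomic_reduced"))
    collection = validate_collection(genes + phylos)
    log("validate", n_trees=len(collection), n_leaves=collection[0].n_leaves)

    categories = {}
    if cfg.metadata:
        categories = read_metadata(cfg.metadata)

    if cfg.base == "auto":
        base_arg = "min_sq_bhv"
        phylo_arg = phylos[0] if phylos else None
    elif cfg.base == "phylo":
        base_arg = "phylogenomic"
        if not phylos:
            raise ValueError("base='phylo' requires a phylogenomic tree")
        phylo_arg = phylos[0]
    else:
        base_arg = read_trees(cfg.base)[0].copy(name="user_base")
        phylo_arg = phylos[0] if phylos else None

    emb_est = TreeEmbedding(method=cfg.method, q=cfg.q, base=base_arg,
                            phylogenomic=phylo_arg, rescale=cfg.rescale,
                            nonmetric=cfg.nonmetric, random_state=cfg.seed)
    coords = emb_est.fit_transform(collection)
    emb = emb_est.embedding_
    emb.tree_categories = [
        "phylogenomic" if t.name in {p.name for p in phylos}
        else categories.get(t.name, "") for t in collection]
    log("embed", method=cfg.method, q=cfg.q, shape=list(coords.shape))

    # two-level outlier diagnosis: the *flag* comes from the conservative
    # component screen on the visualized embedding; the *ranking* score
    # comes from the scale-aware per-feature screen on the log-map matrix
    # (threshold-free triage list; sensitive to anomalies on short
    # branches that absolute-variance components bury)
    flags = flag_outliers(emb, threshold=cfg.threshold)
    flagged = [name for name, _, f in flags if f]
    if cfg.method == "pca":
        M = emb_est.vectorizer_.transform(collection)
        ranking = flag_outlier_features(M, names=[t.name for t in collection],
                                        threshold=cfg.threshold)
    else:
        ranking = flags
    log("flag", n_flagged=len(flagged), top=[r[0] for r in ranking[:3]])

    # coords.csv: tree, category, components, ranking score + flag
    comp_cols = [f"PC{i+1}" if cfg.method == "pca" else f"MDS{i+1}"
                 for i in range(cfg.q)]
    flag_by_name = {name: f for name, _, f in flags}
    score_by_name = {name: score for name, score, _ in ranking}
    rows = []
    for i, t in enumerate(collection):
        rows.append({"tree": t.name, "category": emb.tree_categories[i],
                     **{c: coords[i, j] for j, c in enumerate(comp_cols)},
                     "outlier_score": score_by_name[t.name],
                     "flagged": flag_by_name[t.name]})
    pd.DataFrame(rows).to_csv(outdir / "coords.csv", index=False,
                              float_format="%.12g")

    report: dict = {
        "n_gene_trees": len(genes),
        "n_phylogenomic_trees": len(phylos),
        "n_leaves": collection[0].n_leaves,
        "method": cfg.method,
        "flagged": flagged,
        "outlier_ranking": [{"tree": n, "score": round(s, 4)}
                            for n, s, _ in ranking[:10]],
    }
    if cfg.method == "pca":
        report["base_tree"] = emb_est.base_tree_.name
        report["variance_explained"] = [
            float(v) for v in emb_est.explained_variance_ratio_[:cfg.q]]
        if getattr(emb_est, "vectorizer_", None) is not None and \
                emb_est.vectorizer_.selection_ is not None:
            sel = emb_est.vectorizer_.selection_
            report["base_criterion_sum_sq_bhv"] = sel.criterion_value
            pd.DataFrame(sorted(sel.candidate_scores.items()),
                         columns=["tree", "sum_sq_bhv"]).to_csv(
                outdir / "base_scores.csv", index=False, float_format="%.12g")
    if emb.stress is not None:
        report["stress"] = emb.stress
    if len(phylos) == 2:
        report["phylo_vs_reduced"] = tree_contrast_stats(phylos[0], phylos[1])
        log("contrast", bhv=report["phylo_vs_reduced"]["bhv"],
            rf=report["phylo_vs_reduced"]["rf"])
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, default=float) + "\n")

    if cfg.plot:
        from .viz import plot_embedding
        plot_embedding(emb, outdir / cfg.plot, highlight=flagged,
                       phylo_names=[p.name for p in phylos],
                       trees=collection if cfg.plot.endswith(".html") else None)
        log("plot", file=cfg.plot)

    manifest = {
        "command": " ".join(sys.argv),
        "config": asdict(cfg),
        "inputs": _input_hashes(cfg),
        "version": __version__,
        "seed": cfg.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime(t0)),
        "elapsed_s": round(time.time() - t0, 3),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir


class _StageLogger:
    """One structured log line per pipeline stage."""

    def __init__(self, stream=None):
        self.t0 = time.time()
        self.stream = stream if stream is not None else sys.stderr

    def __call__(self, stage: str, **info):
        fields = " ".join(f"{k}={v}" for k, v in info.items())
        print(f"[treelens +{time.time() - self.t0:6.2f}s] {stage}: {fields}",
              file=self.stream)
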