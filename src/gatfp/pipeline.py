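"""End-to-end orchestration: simulate -> build-dataset -> train -> query.

These functions back the command-line interface; each stage reads and
writes plain-text artifacts (tree JSON, TSV libraries, JSON manifests) so
synthetic and real-data corpora are interchangeable.  All randomness
derives from one top-level seed expanded into per-stage seeds that are
recorded in the manifests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import msio
from .gat_model import (EncoderConfig, FingerprintGAT, TrainConfig,
                        kfold_split, train_model)
from .graph_builder import (GraphSample, NodeFeatureSpec, accumulate_corpus_stats,
                            build_graph, build_vocabulary)
from .library_query import (PPM_WINDOWS, query_by_formula,
                            query_by_precursor_mass, rank_candidates, topk_rates)
from .synthetic_data import PlantedModel, generate_corpus

logger = logging.getLogger(__name__)

ABLATIONS = ("none", "FFe", "FFv", "FL")


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Stage configuration; the ablation mode toggles exactly one flag set.

    * ``FFe`` - edge features replaced by all-ones at graph building,
    * ``FFv`` - node features reduced to relative abundance,
    * ``FL``  - prediction head reduced to a single linear layer.
    """

    seed: int = 0
    ablation: str = "none"
    node_spec: NodeFeatureSpec = NodeFeatureSpec()
    encoder: EncoderConfig = EncoderConfig()
    train: TrainConfig = TrainConfig()

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise PipelineError(f"unknown ablation {self.ablation!r}")

    @property
    def effective_node_spec(self) -> NodeFeatureSpec:
        return NodeFeatureSpec.ffv() if self.ablation == "FFv" else self.node_spec

    @property
    def edge_mode(self) -> str:
        return "ones" if self.ablation == "FFe" else "full"

    @property
    def effective_encoder(self) -> EncoderConfig:
        enc = self.encoder
        if self.ablation == "FL":
            enc = replace(enc, head_layers=1)
        return enc


def run_simulate(out_dir: str | Path, seed: int, n_samples: int = 400,
                 n_bits: int = 32, **model_kw) -> dict:
    """Generate a planted corpus and write it in msio formats."""
    out = Path(out_dir)
    (out / "trees").mkdir(parents=True, exist_ok=True)
    model = PlantedModel(n_bits=n_bits, seed=seed, **model_kw)
    corpus = generate_corpus(model, n_samples)
    for tree in corpus.trees:
        msio.write_tree(tree, out / "trees" / f"{tree.sample_id}.json")
    msio.write_candidate_library(corpus.library, out / "library.tsv")
    (out / "targets.json").write_text(json.dumps(
        {sid: "".join(map(str, bits.tolist())) for sid, bits in corpus.targets.items()},
        indent=0, sort_keys=True))
    (out / "candidate_fps.json").write_text(json.dumps(
        {cid: "".join(map(str, bits.tolist()))
         for cid, bits in corpus.candidate_fps.items()}, indent=0, sort_keys=True))
    (out / "truth.json").write_text(json.dumps(corpus.truth, indent=0, sort_keys=True))
    manifest = {
        "kind": "synthetic-corpus", "seed": seed, "n_samples": n_samples,
        "n_bits": n_bits,
        "sample_ids": sorted(corpus.targets),
        "tree_dir": "trees", "library": "library.tsv",
        "layout_hash": f"synthetic:{n_bits}",
    }
    msio.write_manifest(manifest, out / "manifest.json")
    return manifest


def _load_corpus(corpus_dir: str | Path):
    corpus_dir = Path(corpus_dir)
    manifest = msio.read_manifest(corpus_dir / "manifest.json")
    trees = [msio.read_sirius_tree(corpus_dir / manifest["tree_dir"] / f"{sid}.json")
             for sid in manifest["sample_ids"]]
    targets = {
        sid: np.array([int(c) for c in s], dtype=np.int8)
        for sid, s in json.loads((corpus_dir / "targets.json").read_text()).items()
    }
    return manifest, trees, targets


def run_build_dataset(corpus_dir: str | Path, out_dir: str | Path,
                      config: RunConfig) -> dict:
    """Build GraphSamples (vocabulary/stats fitted on the given corpus)."""
    manifest, trees, targets = _load_corpus(corpus_dir)
    out = Path(out_dir)
    (out / "graphs").mkdir(parents=True, exist_ok=True)
    vocab = build_vocabulary(trees, reserve_unk=True)
    stats = accumulate_corpus_stats(trees, vocab)
    spec = config.effective_node_spec
    excluded = []
    n_ok = 0
    for tree in trees:
        if tree.sample_id not in targets:
            excluded.append({"sample_id": tree.sample_id, "reason": "missing target"})
            continue
        g = build_graph(tree, vocab, stats, spec, targets[tree.sample_id],
                        edge_mode=config.edge_mode)
        doc = {
            "sample_id": g.sample_id,
            "node_features": g.node_features.tolist(),
            "edge_index": g.edge_index.tolist(),
            "edge_features": g.edge_features.tolist(),
            "target": g.target.astype(int).tolist(),
        }
        (out / "graphs" / f"{g.sample_id}.json").write_text(json.dumps(doc))
        n_ok += 1
    if n_ok == 0:
        raise PipelineError("no samples were successfully processed")
    ds_manifest = {
        "kind": "graph-dataset", "source": str(corpus_dir),
        "ablation": config.ablation, "seed": config.seed,
        "n_samples": n_ok, "excluded": excluded,
        "feature_width": spec.width,
        "n_bits": manifest["n_bits"],
        "layout_hash": manifest.get("layout_hash", ""),
        "sample_ids": [t.sample_id for t in trees
                       if t.sample_id in targets],
    }
    msio.write_manifest(ds_manifest, out / "manifest.json")
    return ds_manifest


def load_dataset(dataset_dir: str | Path) -> tuple[dict, list[GraphSample]]:
    dataset_dir = Path(dataset_dir)
    manifest = msio.read_manifest(dataset_dir / "manifest.json")
    samples = []
    for sid in manifest["sample_ids"]:
        doc = json.loads((dataset_dir / "graphs" / f"{sid}.json").read_text())
        samples.append(GraphSample(
            sample_id=doc["sample_id"],
            node_features=np.array(doc["node_features"], dtype=np.float64),
            edge_index=np.array(doc["edge_index"], dtype=np.int64).reshape(-1, 2),
            edge_features=np.array(doc["edge_features"], dtype=np.float64).reshape(-1, 2),
            target=np.array(doc["target"], dtype=np.float64),
        ))
    return manifest, samples


def run_train_eval(dataset_dir: str | Path, out_dir: str | Path,
                   config: RunConfig):
    """K-fold train/eval; writes per-fold metrics CSV and the checkpoints."""
    manifest, samples = load_dataset(dataset_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enc = replace(config.effective_encoder,
                  in_dim=samples[0].node_features.shape[1],
                  output_dim=int(manifest["n_bits"]))
    split = kfold_split([s.sample_id for s in samples], config.train.n_folds,
                        config.seed)
    models, metrics = train_model(samples, enc, config.train, split)
    metrics.insert(0, "model", "FF" if config.ablation == "none" else config.ablation)
    metrics.to_csv(out / "metrics.csv", index=False)
    for k, model in enumerate(models):
        model.save(out / f"fold{k}.npz", layout_hash=manifest.get("layout_hash", ""))
    return metrics


def run_query(checkpoint: str | Path, dataset_dir: str | Path,
              corpus_dir: str | Path, out_dir: str | Path, mode: str,
              ppm_windows: tuple[float, ...] = PPM_WINDOWS,
              threshold: float = 0.5, ks: tuple[int, ...] = (1, 5, 10)) -> dict:
    """Predict fingerprints, retrieve candidates, rank, report top-k rates."""
    corpus_dir = Path(corpus_dir)
    model, ckpt_hash = FingerprintGAT.load(checkpoint)
    manifest, samples = load_dataset(dataset_dir)
    if ckpt_hash != manifest.get("layout_hash", ""):
        raise PipelineError(
            f"checkpoint layout hash {ckpt_hash!r} does not match dataset "
            f"{manifest.get('layout_hash', '')!r}")
    library = msio.read_candidate_library(corpus_dir / "library.tsv")
    truth = json.loads((corpus_dir / "truth.json").read_text())
    candidate_fps = {
        cid: np.array([int(c) for c in s], dtype=np.int8)
        for cid, s in json.loads((corpus_dir / "candidate_fps.json").read_text()).items()
    }
    trees = {t.sample_id: t
             for t in (msio.read_sirius_tree(corpus_dir / "trees" / f"{sid}.json")
                       for sid in manifest["sample_ids"])}

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"mode": mode, "top_k": {}}
    rows = []
    preds = {s.sample_id: model.predict(s) for s in samples}

    def run_block(label: str, retrieve):
        rankings = []
        for s in samples:
            cands = retrieve(s)
            ranked = rank_candidates(preds[s.sample_id], cands,
                                     threshold=threshold,
                                     truth_id=truth.get(s.sample_id),
                                     candidate_fps=candidate_fps)
            rankings.append(ranked)
            rows.append({
                "block": label, "sample_id": s.sample_id,
                "rank_of_truth": ranked.rank_of_truth,
                "retrieved": len(cands),
                "top_score": ranked.ranking[0][1] if ranked.ranking else None,
            })
        return {f"top{k}": rate for k, rate in topk_rates(rankings, list(ks)).items()}

    if mode == "precursor_mass":
        for ppm in ppm_windows:
            summary["top_k"][f"{ppm:g}ppm"] = run_block(
                f"{ppm:g}ppm",
                lambda s, ppm=ppm: query_by_precursor_mass(
                    trees[s.sample_id].precursor_mass - 1.0078250319, ppm, library))
    elif mode == "formula":
        summary["top_k"]["formula"] = run_block(
            "formula",
            lambda s: query_by_formula(trees[s.sample_id].precursor_formula, library))
    else:
        raise PipelineError(f"unknown query mode {mode!r}")

    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "query_results.tsv", sep="\t", index=False)
    (out / "query_summary.json").write_text(json.dumps(summary, indent=1))
    return summary
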