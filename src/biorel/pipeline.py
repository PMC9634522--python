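"""End-to-end experiment pipeline: synth -> preprocess -> train ->
predict -> evaluate, driven by one YAML config with a single root seed.

Config schema (all sections optional; defaults shown)::

    seed: 0
    stages: [synth, preprocess, train, predict, evaluate]
    split: [0.6, 0.2, 0.2]          # train/val/test document fractions
    synth:                           # SynthConfig fields
      n_documents: 200
    preprocess:
      keep_negatives: 1.0            # training-split subsampling only
    train:                           # ModelConfig + TrainConfig fields
      seeds: 3
      encoder: mha
      sdp_encoder: cnn
      max_epochs: 10

A run manifest (config hash, stage durations, output paths, metrics)
is written to ``<out_dir>/run_manifest.json`` even when a stage fails.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .candidates import (
    CandidateInstance,
    attach_paths,
    corpus_statistics,
    enumerate_candidates,
    filter_no_path,
    subsample_negatives,
)
from .encoding import EncodedInstance, build_feature_space, encode_instance
from .evaluation import make_key, score
from .model import ModelConfig
from .standoff import Document, RelationAnnotation
from .synth import CorpusBundle, SynthConfig, generate_corpus, write_corpus
from .task import ConstraintRule, load_task
from .train import TrainConfig, multi_seed_select


def preprocess_documents(
    docs: Sequence[Document],
    task: ConstraintRule,
    keep_negatives: Optional[float] = None,
    seed: int = 0,
) -> list[CandidateInstance]:
    """Documents -> labelled candidate instances with oriented paths.

    ``keep_negatives`` subsamples the negative instances (training
    split only — pass ``None`` for validation/test).
    """
    instances: list[CandidateInstance] = []
    for doc in docs:
        instances.extend(enumerate_candidates(doc, task))
    instances = filter_no_path(instances)
    instances = attach_paths(instances, task)
    if keep_negatives is not None and keep_negatives < 1.0:
        instances = subsample_negatives(instances, keep_negatives, seed)
    return instances


def encode_all(instances, space, task) -> list[EncodedInstance]:
    return [encode_instance(i, space, task.categories) for i in instances]


def gold_keys(docs: Sequence[Document]) -> set:
    return {
        make_key(d.doc_id, r.arg1_id, r.arg2_id, r.rtype)
        for d in docs
        for r in d.relations
    }


def intrasentence_gold_keys(docs: Sequence[Document]) -> set:
    out = set()
    for d in docs:
        ents = {e.id: e for e in d.entities}
        for r in d.relations:
            e1, e2 = ents[r.arg1_id], ents[r.arg2_id]
            if (
                e1.token_span is not None
                and e2.token_span is not None
                and e1.token_span[0] == e2.token_span[0]
            ):
                out.add(make_key(d.doc_id, r.arg1_id, r.arg2_id, r.rtype))
    return out


def predictions_to_keys(instances, labels) -> set:
    return {
        make_key(inst.doc_id, inst.e1.id, inst.e2.id, lab)
        for inst, lab in zip(instances, labels)
        if lab != "none"
    }


def predictions_to_annotations(instances, labels) -> dict[str, list[RelationAnnotation]]:
    """Group non-none predictions per document, ids renumbered from R1."""
    per_doc: dict[str, list[RelationAnnotation]] = {}
    for inst, lab in zip(instances, labels):
        if lab == "none":
            continue
        rels = per_doc.setdefault(inst.doc_id, [])
        rels.append(RelationAnnotation(f"R{len(rels) + 1}", lab, inst.e1.id, inst.e2.id))
    return per_doc


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _split_documents(docs, fractions):
    n = len(docs)
    n_train = int(fractions[0] * n)
    n_val = int(fractions[1] * n)
    return docs[:n_train], docs[n_train : n_train + n_val], docs[n_train + n_val :]


DEFAULT_STAGES = ("synth", "preprocess", "train", "predict", "evaluate")


def run_experiment(config, out_dir) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    config = dict(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", DEFAULT_STAGES))
    manifest: dict = {
        "config_hash": _config_hash(config),
        "package_version": __version__,
        "seed": seed,
        "stages": stages,
        "durations": {},
        "outputs": {},
        "status": "failed",
    }
    try:
        bundle: Optional[CorpusBundle] = None
        state: dict = {}
        for stage in stages:
            t0 = time.perf_counter()
            if stage == "synth":
                scfg = SynthConfig(seed=seed, **config.get("synth", {}))
                bundle = generate_corpus(scfg)
                write_corpus(bundle, out / "corpus")
                manifest["outputs"]["corpus"] = str(out / "corpus")
            elif stage == "preprocess":
                if bundle is None:
                    raise ValueError("preprocess requires the synth stage")
                task = bundle.task
                pcfg = config.get("preprocess", {})
                tr_docs, va_docs, te_docs = _split_documents(
                    bundle.documents, config.get("split", (0.6, 0.2, 0.2))
                )
                tr = preprocess_documents(
                    tr_docs, task,
                    keep_negatives=pcfg.get("keep_negatives"), seed=seed,
                )
                va = preprocess_documents(va_docs, task)
                te = preprocess_documents(te_docs, task)
                space = build_feature_space(tr, task.entity_types, seed=seed)
                state.update(
                    task=task, space=space,
                    tr=tr, va=va, te=te, te_docs=te_docs,
                    tr_enc=encode_all(tr, space, task),
                    va_enc=encode_all(va, space, task),
                    te_enc=encode_all(te, space, task),
                )
                stats = {
                    "train": corpus_statistics(tr),
                    "val": corpus_statistics(va),
                    "test": corpus_statistics(te),
                }
                (out / "instance_stats.json").write_text(json.dumps(stats, indent=2))
                manifest["outputs"]["instance_stats"] = str(out / "instance_stats.json")
            elif stage == "train":
                tcfg = dict(config.get("train", {}))
                n_seeds = int(tcfg.pop("seeds", 3))
                mc_keys = ModelConfig.__dataclass_fields__.keys()
                mcfg = ModelConfig(**{k: v for k, v in tcfg.items() if k in mc_keys})
                tc_keys = TrainConfig.__dataclass_fields__.keys()
                trc = TrainConfig(**{k: v for k, v in tcfg.items() if k in tc_keys})
                best, summary = multi_seed_select(
                    state["tr_enc"], state["va_enc"], state["space"],
                    state["task"].categories, mcfg, trc,
                    seeds=[seed + i for i in range(n_seeds)],
                )
                state["model"] = best
                manifest["outputs"]["seed_summary"] = asdict(summary)
                manifest["outputs"]["selected_seed"] = best.seed
            elif stage == "predict":
                labels = state["model"].model.predict_labels(state["te_enc"])
                state["pred_keys"] = predictions_to_keys(state["te"], labels)
                per_doc = predictions_to_annotations(state["te"], labels)
                pred_dir = out / "predictions"
                pred_dir.mkdir(exist_ok=True)
                from .standoff import write_predictions

                docs_by_id = {d.doc_id: d for d in state["te_docs"]}
                for doc_id, rels in per_doc.items():
                    (pred_dir / f"{doc_id}.a2").write_text(
                        write_predictions(docs_by_id[doc_id], rels, state["task"])
                    )
                manifest["outputs"]["predictions"] = str(pred_dir)
            elif stage == "evaluate":
                report = score(
                    state["pred_keys"],
                    gold_keys(state["te_docs"]),
                    intrasentence_gold=intrasentence_gold_keys(state["te_docs"]),
                )
                (out / "evaluation.json").write_text(
                    json.dumps(report.as_dict(), indent=2)
                )
                manifest["outputs"]["evaluation"] = report.as_dict()
            else:
                raise ValueError(f"unknown stage {stage!r}")
            manifest["durations"][stage] = round(time.perf_counter() - t0, 3)
        manifest["status"] = "ok"
    finally:
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
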