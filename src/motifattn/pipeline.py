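"""Config-driven pipeline: simulate -> train -> interpret -> evaluate.

Each stage writes its artifacts under the output directory and is skipped
on rerun when its outputs already exist, so an evaluate-only rerun reuses
cached training and interpretation.  A manifest records every artifact with
its SHA-256 hash and the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .evaluate import attention_sparsity_report, score_interactions
from .interpret import infer_interactions
from .model import ModelSpec, SequenceModel
from .motifs import MotifLibrary, random_library, read_motifs, write_motifs
from .train import TrainConfig, train_model

logger = logging.getLogger(__name__)

STAGES = ("simulate", "train", "interpret", "evaluate")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def _simulation_config(cfg: dict, seed: int) -> sim.SimulationConfig:
    sim_cfg = dict(cfg.get("simulate", {}))
    sim_cfg.pop("library", None)
    preset_name = sim_cfg.pop("preset", None)
    sim_cfg.setdefault("seed", seed)
    if preset_name:
        return sim.preset(preset_name, **sim_cfg)
    for key in ("pairs_per_positive", "pair_gap", "neg_motifs_per_sequence",
                "background_freqs"):
        if key in sim_cfg:
            sim_cfg[key] = tuple(sim_cfg[key])
    return sim.SimulationConfig(**sim_cfg)


def _library(cfg: dict, scfg: sim.SimulationConfig, seed: int,
             outdir: Path) -> MotifLibrary:
    lib_cfg = dict(cfg.get("simulate", {}).get("library", {}))
    path = lib_cfg.get("path")
    if path:
        return read_motifs(path)
    pool = int(lib_cfg.get("pool_size", scfg.n_motifs))
    rng = np.random.default_rng(seed + 7919)  # independent of dataset draws
    return random_library(pool, rng)


def stage_simulate(cfg: dict, outdir: Path, seed: int) -> None:
    marker = outdir / "dataset.fasta"
    if marker.exists():
        logger.info("simulate: cached")
        return
    scfg = _simulation_config(cfg, seed)
    lib = _library(cfg, scfg, seed, outdir)
    ds, truth = sim.generate_dataset(scfg, lib)
    train, val, test = sim.split_dataset(
        ds, rng=np.random.default_rng(scfg.seed + 1))
    sim.write_dataset(ds, outdir, truth)
    write_motifs(lib, outdir / "library.meme")
    scfg.to_yaml(outdir / "simulation_config.yaml")
    splits = {name: part.ids
              for name, part in zip(("train", "val", "test"),
                                    (train, val, test))}
    (outdir / "splits.json").write_text(json.dumps(splits))


def _load_splits(outdir: Path):
    ds, truth = sim.read_dataset(outdir)
    splits = json.loads((outdir / "splits.json").read_text())
    pos = {sid: i for i, sid in enumerate(ds.ids)}
    parts = tuple(ds.subset([pos[sid] for sid in splits[name]])
                  for name in ("train", "val", "test"))
    return ds, truth, parts


def _model_spec(cfg: dict, outdir: Path) -> ModelSpec:
    mcfg = dict(cfg.get("model", {}))
    preloaded_path = mcfg.pop("preloaded", None)
    if preloaded_path:
        mcfg["preloaded"] = read_motifs(preloaded_path)
    if "dilations" in mcfg:
        mcfg["dilations"] = tuple(mcfg["dilations"])
    return ModelSpec(**mcfg)


def stage_train(cfg: dict, outdir: Path, seed: int) -> None:
    ckpt = outdir / "model.ckpt"
    if ckpt.exists():
        logger.info("train: cached")
        return
    _, _, (train, val, test) = _load_splits(outdir)
    spec = _model_spec(cfg, outdir)
    tcfg_kwargs = dict(cfg.get("train", {}))
    if "seeds" in tcfg_kwargs:
        tcfg_kwargs["seeds"] = tuple(tcfg_kwargs["seeds"])
    else:
        tcfg_kwargs["seeds"] = (seed, seed + 1, seed + 2)
    tcfg = TrainConfig(**tcfg_kwargs)
    result = train_model(spec, tcfg, (train, val, test))
    result.model.save(ckpt)
    pd.DataFrame(result.history).to_csv(outdir / "training_history.tsv",
                                        sep="\t", index=False)
    summary = dict(best_seed=result.best_seed,
                   best_val_auc=result.best_val_auc,
                   test_auc=result.test_auc, test_aupr=result.test_aupr)
    (outdir / "training_summary.json").write_text(json.dumps(summary))


def stage_interpret(cfg: dict, outdir: Path, seed: int) -> None:
    out_path = outdir / "interactions.tsv"
    if out_path.exists():
        logger.info("interpret: cached")
        return
    if not (outdir / "model.ckpt").exists():
        raise FileNotFoundError(
            f"{outdir/'model.ckpt'} missing - run the train stage first")
    model = SequenceModel.load(outdir / "model.ckpt")
    _, _, (_, _, test) = _load_splits(outdir)
    lib = read_motifs(outdir / "library.meme")
    icfg = dict(cfg.get("interpret", {}))
    result = infer_interactions(
        model, test, library=lib,
        mode=icfg.get("mode", "raw"),
        background_policy=icfg.get("background", "negatives"),
        alpha=float(icfg.get("alpha", 0.05)),
        min_support=int(icfg.get("min_support", 5)),
        rng=np.random.default_rng(seed + 13))
    result.motif_table.to_csv(out_path, sep="\t", index=False)
    result.filter_table.to_csv(outdir / "filter_interactions.tsv",
                               sep="\t", index=False)
    ann = pd.DataFrame([vars(a) for a in result.annotations])
    ann.to_csv(outdir / "filter_annotations.tsv", sep="\t", index=False)


def stage_evaluate(cfg: dict, outdir: Path, seed: int) -> None:
    out_path = outdir / "interpretation_metrics.json"
    if out_path.exists():
        logger.info("evaluate: cached")
        return
    for req in ("interactions.tsv", "model.ckpt"):
        if not (outdir / req).exists():
            raise FileNotFoundError(
                f"{outdir/req} missing - run earlier stages first")
    _, truth, (_, _, test) = _load_splits(outdir)
    table = pd.read_csv(outdir / "interactions.tsv", sep="\t")
    predicted = {tuple(sorted((a, b)))
                 for a, b in zip(table.get("motif_a", []),
                                 table.get("motif_b", []))}
    metrics = score_interactions(predicted, truth)
    summary = json.loads((outdir / "training_summary.json").read_text())
    payload = dict(vars(metrics), **summary)
    out_path.write_text(json.dumps(payload, indent=2))

    model = SequenceModel.load(outdir / "model.ckpt")
    report = attention_sparsity_report(model, test.sequences[:500])
    report["histogram"].to_csv(outdir / "attention_histogram.tsv",
                               sep="\t", index=False)
    pd.DataFrame([{k: v for k, v in report.items() if k != "histogram"}]
                 ).to_csv(outdir / "attention_summary.tsv", sep="\t",
                          index=False)


def run_pipeline(config, outdir=None, seed: int | None = None,
                 stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the requested stages in order; returns the output directory.

    ``config`` is a path to a YAML file or a dict.  Stages are resumable:
    existing outputs are reused.  A ``manifest.json`` lists every artifact
    with its hash and the master seed.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    outdir = Path(outdir or cfg.get("outdir", "motifattn_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    runners = dict(simulate=stage_simulate, train=stage_train,
                   interpret=stage_interpret, evaluate=stage_evaluate)
    for stage in stages:
        runners[stage](cfg, outdir, seed)
    artifacts = sorted(p for p in outdir.iterdir()
                       if p.is_file() and p.name != "manifest.json")
    manifest = dict(seed=seed,
                    artifacts={p.name: _sha256(p) for p in artifacts})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
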