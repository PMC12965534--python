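"""Configuration-driven orchestration: simulate -> encode -> train ->
classify -> perturb -> rank -> fluctuation report.

One global seed deterministically derives a seed per stage (by hashing the
stage name), so re-running a config reproduces every artifact: integer
outputs exactly, floating-point outputs to numerical tolerance. The
evaluation split is held out, stratified by condition, before any training;
perturbations run on the held-out split's start-condition cells, mirroring
the practice of perturbing only test cells.

The training-set composition axis (``extra_control_cells``) appends extra
simulated control cells to the training split only — the analogue of
enlarging a fine-tuning corpus with external healthy reference cells while
keeping the evaluation set fixed — with class-imbalance handled by
inverse-frequency loss weights.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from . import __version__
from .encoding import RankEncoder
from .fluctuation import FluctuationThreshold, log2fc
from .io import read_corpus, write_corpus
from .model import StateTransformerClassifier
from .perturb import (
    CandidateTable,
    compute_goal_state,
    expressed_in_both_conditions,
    perturb_corpus,
    rank_candidates,
)
from .simulate import CONTROL, DISEASE, ExpressionCorpus, SimulationSpec, simulate_corpus

logger = logging.getLogger("rankshift")

SCENARIOS = {
    ("delete", "control->disease"),
    ("delete", "disease->control"),
    ("overexpress", "control->disease"),
    ("overexpress", "disease->control"),
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs. YAML-serializable."""

    simulation: SimulationSpec = field(default_factory=SimulationSpec)
    corpus_dir: str | None = None  # read instead of simulating when set
    model: dict = field(default_factory=dict)  # StateTransformerClassifier kwargs
    context_length: int = 128
    pretrain: bool = False
    scenarios: list[tuple[str, str]] = field(
        default_factory=lambda: [("delete", "control->disease")]
    )
    alpha: float = 0.05
    min_cells: int = 5
    extra_control_cells: int = 0
    fluctuation_iterations: int = 100
    fluctuation_percentile: float = 95.0
    fluctuation_pseudocount: float = 1.0
    run_fluctuation: bool = True
    test_fraction: float = 0.2
    outdir: str = "rankshift_run"
    seed: int = 0

    def validate(self) -> None:
        if self.corpus_dir is None:
            self.simulation.validate()
        for sc in self.scenarios:
            if tuple(sc) not in SCENARIOS:
                raise ValueError(f"unknown scenario {sc!r}")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenarios"] = [list(s) for s in self.scenarios]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            sim = dict(d["simulation"])
            for key in ("baseline_mean_log_params", "library_size_log_params"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            d["simulation"] = SimulationSpec(**sim)
        if "scenarios" in d:
            d["scenarios"] = [tuple(s) for s in d["scenarios"]]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    outdir: Path
    corpus: ExpressionCorpus
    report: "object"  # ClassificationReport
    candidates: dict[tuple[str, str], CandidateTable]
    fluctuation: "object | None"
    model: StateTransformerClassifier
    encoder: RankEncoder
    test_indices: np.ndarray


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    if logger.level == logging.NOTSET:
        logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and persist all artifacts under ``config.outdir``.

    On a stage failure the partial artifacts and the log are left in place
    and the error is re-raised with the stage name.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    stage = "init"
    t_start = time.time()
    try:
        # ---- corpus -------------------------------------------------------
        stage = "corpus"
        if config.corpus_dir is not None:
            corpus = read_corpus(config.corpus_dir)
            logger.info("read corpus from %s: %d cells x %d genes",
                        config.corpus_dir, corpus.n_cells, corpus.n_genes)
        else:
            spec = config.simulation.with_seed(stage_seed(config.seed, "simulate"))
            corpus = simulate_corpus(spec)
            write_corpus(corpus, outdir / "corpus")
            logger.info("simulated corpus: %d cells x %d genes, %d drivers (seed %d)",
                        corpus.n_cells, corpus.n_genes, len(corpus.ground_truth), spec.seed)

        # ---- split --------------------------------------------------------
        stage = "split"
        idx = np.arange(corpus.n_cells)
        train_idx, test_idx = train_test_split(
            idx,
            test_size=config.test_fraction,
            random_state=stage_seed(config.seed, "split") % (2**32),
            stratify=corpus.condition,
        )
        train = corpus.subset_cells(np.sort(train_idx))
        test = corpus.subset_cells(np.sort(test_idx))
        logger.info("split: %d train / %d test cells (stratified, fraction %.2f)",
                    train.n_cells, test.n_cells, config.test_fraction)

        # ---- composition (extra control cells in training only) -----------
        if config.extra_control_cells > 0:
            stage = "composition"
            extra_spec = dataclasses.replace(
                config.simulation,
                n_cells_control=config.extra_control_cells,
                n_cells_disease=1,
                seed=stage_seed(config.seed, "extra-control"),
            )
            extra = simulate_corpus(extra_spec)
            keep = extra.mask(CONTROL)
            extra = extra.subset_cells(np.flatnonzero(keep))
            extra.cell_ids = np.array(
                [f"extra_{c}" for c in extra.cell_ids], dtype=object
            )
            train = ExpressionCorpus(
                gene_ids=train.gene_ids,
                cell_ids=np.concatenate([train.cell_ids, extra.cell_ids]),
                counts=np.vstack([train.counts, extra.counts]),
                condition=np.concatenate([train.condition, extra.condition]),
                ground_truth=train.ground_truth,
            )
            logger.info("composition: appended %d extra control cells to training",
                        extra.n_cells)

        # ---- encode -------------------------------------------------------
        stage = "encode"
        encoder = RankEncoder(context_length=config.context_length).fit(train)
        encoder.vocabulary_.to_tsv(outdir / "vocabulary.tsv")
        enc_train = encoder.transform(train)
        train_kept = ~np.isin(train.cell_ids, encoder.dropped_cells_)
        y_train = train.condition[train_kept]
        n_dropped_train = len(encoder.dropped_cells_)
        enc_test = encoder.transform(test)
        test_kept = ~np.isin(test.cell_ids, encoder.dropped_cells_)
        y_test = test.condition[test_kept]
        n_dropped_test = len(encoder.dropped_cells_)
        logger.info("encoded: vocab %d genes, dropped %d train / %d test cells",
                    len(encoder.vocabulary_), n_dropped_train, n_dropped_test)

        # ---- train --------------------------------------------------------
        stage = "train"
        model_kwargs = dict(config.model)
        model_kwargs.setdefault("context_length", config.context_length)
        model_kwargs.setdefault("vocab_size", encoder.vocabulary_.size)
        model_kwargs.setdefault("seed", stage_seed(config.seed, "train"))
        model = StateTransformerClassifier(**model_kwargs)
        if config.pretrain:
            model.pretrain(enc_train)
            logger.info("pretrained %d epochs, loss %s",
                        model.pretrain_epochs, model.pretrain_loss_history_)
        model.fit(enc_train, y_train)
        model.save(outdir / "model.npz")
        logger.info(
            "finetuned from phase %s: loss %s, val acc %.3f, class_weight=%s",
            model.started_from_phase_, model.loss_history_,
            model.validation_accuracy_, model.class_weight,
        )

        # ---- classify -----------------------------------------------------
        stage = "classify"
        report = model.evaluate(enc_test, y_test, n_excluded=n_dropped_test)
        report.metadata["config_hash"] = config.config_hash()
        report.to_json(outdir / "classification_report.json")
        report.probabilities.to_csv(
            outdir / "probabilities.tsv", sep="\t", index=False
        )
        logger.info("test accuracy %.3f, macro-F1 %.3f",
                    report.accuracy, report.macro_f1)

        # ---- perturb ------------------------------------------------------
        candidates: dict[tuple[str, str], CandidateTable] = {}
        genes = [
            g for g in expressed_in_both_conditions(corpus)
            if g in encoder.vocabulary_
        ]
        enc_by_cond = {
            CONTROL: [e for e, c in zip(enc_test, y_test) if c == CONTROL],
            DISEASE: [e for e, c in zip(enc_test, y_test) if c == DISEASE],
        }
        emb_by_cond = {c: model.embed(enc_by_cond[c]) for c in (CONTROL, DISEASE)}
        for mode, direction in config.scenarios:
            stage = f"perturb:{mode}:{direction}"
            start_cond, goal_cond = direction.split("->")
            goal = compute_goal_state(emb_by_cond[goal_cond], goal_cond)
            records = perturb_corpus(
                model, enc_by_cond[start_cond], genes, mode, goal,
                encoder.vocabulary_, direction=direction,
            )
            table = rank_candidates(
                records,
                alpha=config.alpha,
                min_cells=config.min_cells,
                ground_truth=corpus.ground_truth or None,
            )
            table.metadata.update(
                mode=mode,
                direction=direction,
                goal_state=f"centroid of {goal.n_cells} held-out "
                           f"{goal_cond} cell embeddings",
                n_genes_tested=len(table.all_records),
                config_hash=config.config_hash(),
            )
            name = f"candidates_{mode}_{start_cond}_to_{goal_cond}.tsv"
            table.write(outdir / name)
            candidates[(mode, direction)] = table
            logger.info("%s %s: %d candidates of %d tested genes",
                        mode, direction, len(table.table), len(table.all_records))

        # ---- fluctuation --------------------------------------------------
        fluct = None
        if config.run_fluctuation:
            stage = "fluctuation"
            control_counts = corpus.counts[corpus.mask(CONTROL)]
            disease_counts = corpus.counts[corpus.mask(DISEASE)]
            est = FluctuationThreshold(
                n_iterations=config.fluctuation_iterations,
                percentile=config.fluctuation_percentile,
                pseudocount=config.fluctuation_pseudocount,
                seed=stage_seed(config.seed, "fluctuation"),
            ).fit(control_counts)
            observed = log2fc(
                disease_counts, control_counts, config.fluctuation_pseudocount
            )
            fluct = est.assess(observed, gene_ids=[str(g) for g in corpus.gene_ids])
            fluct.write(outdir)
            logger.info("fluctuation threshold +-%.3f (p%g, %d iterations)",
                        est.threshold_, config.fluctuation_percentile,
                        config.fluctuation_iterations)

        # ---- provenance ---------------------------------------------------
        stage = "provenance"
        provenance = {
            "package_version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "global_seed": config.seed,
            "stage_seeds": {
                s: stage_seed(config.seed, s)
                for s in ("simulate", "split", "extra-control", "train", "fluctuation")
            },
            "elapsed_seconds": round(time.time() - t_start, 2),
        }
        (outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=2), encoding="utf-8"
        )
        config.to_yaml(outdir / "config.yaml")
        logger.info("pipeline complete in %.1fs", time.time() - t_start)
        return PipelineResult(
            outdir=outdir,
            corpus=corpus,
            report=report,
            candidates=candidates,
            fluctuation=fluct,
            model=model,
            encoder=encoder,
            test_indices=np.sort(test_idx),
        )
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from None
    finally:
        handler.close()
        logger.removeHandler(handler)


def compare_compositions(configs: list[PipelineConfig]) -> pd.DataFrame:
    """Accuracy / macro-F1 per training composition on a common held-out set.

    All configs must define the same evaluation split (same corpus source,
    test fraction and global seed); they may differ in training composition
    (``extra_control_cells``, model settings). Descriptive only.
    """
    if len(configs) < 2:
        raise ValueError("need at least two configs to compare")
    ref = configs[0]
    for c in configs[1:]:
        same_corpus = (
            c.corpus_dir == ref.corpus_dir
            and c.simulation == ref.simulation
            and c.test_fraction == ref.test_fraction
            and c.seed == ref.seed
        )
        if not same_corpus:
            raise ValueError(
                "configs define different evaluation splits; corpus source, "
                "test_fraction and seed must match"
            )
    rows = []
    for i, c in enumerate(configs):
        result = run_pipeline(c)
        rows.append(
            {
                "composition": f"composition_{i}",
                "extra_control_cells": c.extra_control_cells,
                "n_train_cells": result.corpus.n_cells
                - len(result.test_indices)
                + c.extra_control_cells,
                "accuracy": result.report.accuracy,
                "macro_f1": result.report.macro_f1,
            }
        )
    return pd.DataFrame(rows)
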