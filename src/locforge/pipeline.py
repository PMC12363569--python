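"""End-to-end orchestration of the localization workflow.

One configuration object drives the five-stage workflow — sequence
input, descriptor/embedding representation, template layout, network
training, and multi-label prediction — with every stage writing its
artifact into a working directory and logging a content hash, so a run
is fully auditable and a rerun with the same configuration and seed
reproduces the prediction table byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataset as ds
from . import descriptors as desc
from . import evaluation as ev
from . import pfimg
from .embedding import MockEmbedder, embed_long_sequence
from .network import ArrayDataset, FocalLossConfig, ModelSpec, TrainConfig, save_model, train
from .synthetic import SyntheticSpec, make_benchmark_bundle

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, stage toggles and hyperparameters of one pipeline run."""

    workdir: Path
    fasta: Path | None = None
    annotations: Path | None = None
    ontology: Path | None = None
    synth_spec: SyntheticSpec | None = None
    task: str = "main"
    min_count: int = 50
    min_length: int = 40
    families: tuple[str, ...] = desc.FAMILIES
    reducer: str = "umap"
    build_template: bool = True
    template_path: Path | None = None
    embed_dim: int = 64
    max_segment_length: int = 1000
    test_fraction: float = 0.15
    identity_threshold: float = 0.30
    folds: int = 5
    model_overrides: dict = field(default_factory=dict)
    train_config: TrainConfig = field(default_factory=TrainConfig)
    thresholds: float = 0.5
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.workdir = Path(self.workdir)

    def validate(self) -> None:
        """Fail fast, before any stage executes."""
        if self.task not in ("main", "all"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.synth_spec is None:
            for name in ("fasta", "annotations", "ontology"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ValueError(f"config error: {name} path missing or absent: {path}")
        if not self.build_template:
            if self.template_path is None or not Path(self.template_path).exists():
                raise ValueError(
                    "config error: template stage disabled but no existing "
                    "template_path supplied"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "synth_spec" in payload and payload["synth_spec"] is not None:
            spec = payload["synth_spec"]
            if "length_range" in spec:
                spec["length_range"] = tuple(spec["length_range"])
            payload["synth_spec"] = SyntheticSpec(**spec)
        if "train_config" in payload:
            tc = payload["train_config"]
            if "focal" in tc:
                tc["focal"] = FocalLossConfig(**tc["focal"])
            payload["train_config"] = TrainConfig(**tc)
        if "families" in payload:
            payload["families"] = tuple(payload["families"])
        for key in ("workdir", "fasta", "annotations", "ontology", "template_path"):
            if payload.get(key) is not None:
                payload[key] = Path(payload[key])
        return cls(**payload)


@dataclass
class PipelineResult:
    predictions: pd.DataFrame
    report: ev.EvalReport
    artifacts: dict[str, Path]
    manifest: dict[str, str]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log_artifact(manifest: dict[str, str], name: str, path: Path) -> None:
    digest = _sha256(path)
    manifest[name] = digest
    logger.info("stage artifact %s -> %s (sha256 %s)", name, path, digest[:12])


def _label_matrix(records, labels: list[str]) -> np.ndarray:
    idx = {lab: j for j, lab in enumerate(labels)}
    y = np.zeros((len(records), len(labels)), dtype=int)
    for i, rec in enumerate(records):
        for lab in rec.labels:
            if lab in idx:
                y[i, idx[lab]] = 1
    return y


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and return predictions plus evaluation.

    Stages: (synth) -> parse/filter -> split -> featurize -> template ->
    embed -> train -> predict -> evaluate.  Any stage failure raises with
    the stage name; artifacts and their content hashes are written under
    ``config.workdir``.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    work = config.workdir
    work.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    artifacts: dict[str, Path] = {}

    def stage(name: str):
        logger.info("stage %s", name)
        return name

    try:
        current = stage("input")
        if config.synth_spec is not None:
            fasta, ann, ont = make_benchmark_bundle(config.synth_spec, work / "bundle")
        else:
            fasta, ann, ont = Path(config.fasta), Path(config.annotations), Path(config.ontology)
        for nm, p in (("fasta", fasta), ("annotations", ann), ("ontology", ont)):
            artifacts[nm] = p
            _log_artifact(manifest, nm, p)

        current = stage("parse")
        ontology = ds.LabelOntology.from_tsv(ont)
        records = ds.parse_records(fasta, ann, ontology)
        records = [
            dataclasses.replace(r, sequence=desc.sanitize_sequence(r.sequence))
            for r in records
        ]
        records = ds.filter_records(records, min_length=config.min_length)
        records = ds.close_records(records, ontology)
        labels = ds.build_label_space(records, ontology, task=config.task, min_count=config.min_count)

        current = stage("split")
        plan = ds.build_split_plan(
            records,
            test_fraction=config.test_fraction,
            identity_threshold=config.identity_threshold,
            folds=config.folds,
        )
        split_path = work / "split.json"
        plan.to_json(split_path)
        artifacts["split"] = split_path
        _log_artifact(manifest, "split", split_path)

        current = stage("featurize")
        dconfig = desc.DescriptorConfig(families=config.families)
        table = desc.feature_table({r.id: r.sequence for r in records}, dconfig)
        features_path = work / "features.tsv"
        table.to_csv(features_path, sep="\t", index_label="protein_id")
        artifacts["features"] = features_path
        _log_artifact(manifest, "features", features_path)

        current = stage("template")
        if config.build_template:
            cv_ids = sorted(plan.fold_of)
            template = pfimg.build_template(
                table.loc[cv_ids],
                method=config.reducer,
                seed=config.seed,
                fitted_on=f"{len(cv_ids)} CV proteins",
            )
            template_path = work / "template.json"
            template.to_json(template_path)
        else:
            template_path = Path(config.template_path)
            template = pfimg.PFImgTemplate.from_json(template_path)
        artifacts["template"] = template_path
        _log_artifact(manifest, "template", template_path)
        images = pfimg.render_images(table, template)

        current = stage("embed")
        backend = MockEmbedder(dim=config.embed_dim, seed=config.seed)
        embeddings = {
            r.id: embed_long_sequence(
                r.sequence, backend, config.max_segment_length, protein_id=r.id
            ).vector
            for r in records
        }
        emb_frame = pd.DataFrame.from_dict(embeddings, orient="index")
        emb_path = work / "embeddings.tsv"
        emb_frame.to_csv(emb_path, sep="\t", index_label="protein_id")
        artifacts["embeddings"] = emb_path
        _log_artifact(manifest, "embeddings", emb_path)

        current = stage("train")
        by_id = {r.id: r for r in records}

        def arrays(ids: list[str]) -> ArrayDataset:
            recs = [by_id[i] for i in ids]
            return ArrayDataset(
                images=np.stack([images[i].pixels for i in ids]),
                embeddings=np.stack([embeddings[i] for i in ids]),
                labels=_label_matrix(recs, labels),
            )

        val_ids = plan.fold_ids(1)
        train_ids = sorted(set(plan.fold_of) - set(val_ids))
        spec = ModelSpec(
            image_dims=(template.grid_height, template.grid_width),
            embedding_dim=config.embed_dim,
            n_labels=len(labels),
            **config.model_overrides,
        )
        model, history = train(spec, arrays(train_ids), arrays(val_ids), config.train_config)
        model_dir = work / "model"
        save_model(model, model_dir)
        hist_path = work / "history.csv"
        pd.DataFrame(history).to_csv(hist_path, index=False)
        artifacts["history"] = hist_path
        _log_artifact(manifest, "history", hist_path)

        current = stage("predict")
        test_ids = sorted(plan.test_ids)
        test = arrays(test_ids)
        scores = model.predict(test.images, test.embeddings)
        decided = ev.decide_matrix(scores, config.thresholds)
        main_terms = set(ontology.main_terms)
        rows = []
        for i, pid in enumerate(test_ids):
            decided_all = [labels[j] for j in np.nonzero(decided[i])[0]]
            closed = ds.close_labels(decided_all, ontology)
            row = {"protein_id": pid}
            row.update({f"score:{lab}": scores[i, j] for j, lab in enumerate(labels)})
            row["decided_all"] = ";".join(sorted(decided_all))
            row["decided_main"] = ";".join(sorted(closed & main_terms))
            rows.append(row)
        predictions = pd.DataFrame(rows)
        pred_path = work / "predictions.tsv"
        predictions.to_csv(pred_path, sep="\t", index=False, float_format="%.6g")
        artifacts["predictions"] = pred_path
        _log_artifact(manifest, "predictions", pred_path)

        current = stage("evaluate")
        report = ev.evaluate_multilabel(scores, test.labels, config.thresholds, labels)
        report_path = work / "report.json"
        report_path.write_text(json.dumps(report.to_dict(), indent=1))
        artifacts["report"] = report_path
        _log_artifact(manifest, "report", report_path)

        manifest_path = work / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1))
        artifacts["manifest"] = manifest_path
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    return PipelineResult(
        predictions=predictions, report=report, artifacts=artifacts, manifest=manifest
    )
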