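"""Desk-scale benchmark runs exercising the full stack.

These helpers pin the package's small-scale study conditions — a
250-protein planted-motif corpus, an AAC+DPC descriptor image on a 21x21
grid, the 64-dimensional mock embedder, and a narrow instance of the
hybrid network — so the same end-to-end computation backs both the test
suite and the reproduction script.  Training uses full-visibility
patience (no early stop) with learning rate 1e-3 for the 30-epoch
learnability run and 3e-3 for the 200-epoch memorization run; the
published-scale defaults (batch 32, learning rate 2e-4) remain the
``TrainConfig`` defaults.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .descriptors import DescriptorConfig, feature_table
from .embedding import MockEmbedder, embed_long_sequence
from .evaluation import evaluate_multilabel
from .network import ArrayDataset, LocalizationNet, ModelSpec, TrainConfig, focal_loss, train
from .pfimg import build_template, render_images
from .synthetic import SyntheticSpec, generate_dataset

__all__ = [
    "learnability_arrays",
    "run_learnability",
    "run_overfit",
    "drug_target_count_rows",
    "TINY_MODEL",
]


def drug_target_count_rows() -> list:
    """The packaged drug-target location count table as metric input rows."""
    from .evaluation import LocationCountRow

    with resources.files("locforge.data").joinpath(
        "drug_target_location_counts.tsv"
    ).open() as fh:
        frame = pd.read_csv(fh, sep="\t", comment="#")
    return [
        LocationCountRow(r["location"], int(r["true"]), int(r["predicted"]), int(r["hit"]))
        for _, r in frame.iterrows()
    ]

TINY_MODEL = dict(
    cnn_channels=(8, 16),
    cnn_fc=(64, 32),
    emb_fc=(64, 32),
    bilstm_hidden=32,
    bilstm_layers=2,
    n_tokens=8,
)


def learnability_arrays(seed: int) -> tuple[ArrayDataset, ArrayDataset, list[str]]:
    """Build the 200-train / 50-validation arrays of the planted-motif corpus."""
    spec = SyntheticSpec(n_proteins=250, length_range=(40, 150), seed=seed)
    records = generate_dataset(spec)
    labels = spec.ontology.main_terms
    table = feature_table(
        {r.id: r.sequence for r in records}, DescriptorConfig(families=("AAC", "DPC"))
    )
    template = build_template(table.iloc[:200], method="pca", seed=seed)
    images = render_images(table, template)
    backend = MockEmbedder(dim=64, seed=seed)
    embeddings = {
        r.id: embed_long_sequence(r.sequence, backend).vector for r in records
    }
    idx = {lab: j for j, lab in enumerate(labels)}
    y = np.zeros((len(records), len(labels)))
    for i, rec in enumerate(records):
        for lab in rec.labels:
            if lab in idx:
                y[i, idx[lab]] = 1

    def arrays(rows: slice) -> ArrayDataset:
        ids = [records[i].id for i in range(*rows.indices(len(records)))]
        return ArrayDataset(
            images=np.stack([images[i].pixels for i in ids]),
            embeddings=np.stack([embeddings[i] for i in ids]),
            labels=y[rows],
        )

    return arrays(slice(0, 200)), arrays(slice(200, 250)), labels


def _tiny_spec(train_set: ArrayDataset, labels: list[str]) -> ModelSpec:
    return ModelSpec(
        image_dims=train_set.images.shape[1:],
        embedding_dim=train_set.embeddings.shape[1],
        n_labels=len(labels),
        **TINY_MODEL,
    )


def run_learnability(seed: int = 0) -> dict:
    """Train 30 epochs on the planted-motif corpus; report held-out metrics."""
    train_set, val_set, labels = learnability_arrays(seed)
    spec = _tiny_spec(train_set, labels)
    config = TrainConfig(
        batch_size=32, learning_rate=1e-3, max_epochs=30, patience=30, seed=seed
    )
    model, history = train(spec, train_set, val_set, config)
    report = evaluate_multilabel(
        model.predict(val_set.images, val_set.embeddings), val_set.labels, 0.5, labels
    )
    return {
        "macro_f1": report.macro_f1,
        "macro_mcc": report.macro_mcc,
        "macro_auprc": report.macro_auprc,
        "epochs": len(history),
        "n_train": len(train_set),
        "n_val": len(val_set),
    }


def run_overfit(seed: int = 0, n_examples: int = 16, max_epochs: int = 200) -> dict:
    """Memorize a handful of examples; report the final training focal loss."""
    train_set, _, labels = learnability_arrays(seed)
    subset = ArrayDataset(
        images=train_set.images[:n_examples],
        embeddings=train_set.embeddings[:n_examples],
        labels=train_set.labels[:n_examples],
    )
    spec = _tiny_spec(subset, labels)
    config = TrainConfig(
        batch_size=n_examples,
        learning_rate=3e-3,
        max_epochs=max_epochs,
        patience=max_epochs,
        monitor_metric="val_loss",
        seed=seed,
    )
    model, history = train(spec, subset, subset, config)
    loss = focal_loss(model.predict(subset.images, subset.embeddings), subset.labels)
    return {"final_loss": loss, "epochs": len(history), "n": n_examples}
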