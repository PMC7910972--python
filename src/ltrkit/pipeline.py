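"""End-to-end workflows tying the modules together.

The lineage benchmark generates the standard 13-lineage synthetic library
(200 elements per lineage, strong hexamer signal, substitution rate 0.03),
featurizes it (k-mer counts 1..6 -> scaling -> PCA), makes the stratified
80/10/10 split, trains the requested network(s) for 25 epochs and reports
held-out test metrics.  The null benchmark does the same with labels
decoupled from sequences, giving the chance-level floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dnn import (
    EvaluationReport,
    HyperParams,
    Split,
    TrainedModel,
    build_cnn,
    build_fnn,
    evaluate,
    split_dataset,
    train,
)
from .kmer_features import FeatureMatrix, FeaturePipeline, KmerSpec
from .seqmodel import CANONICAL_LINEAGES
from .synthetic_data import generate_library, generate_null_library, make_profiles

logger = logging.getLogger(__name__)

#: PCA width used by the desk-scale benchmark (variance target 0.95, capped).
BENCHMARK_MAX_COMPONENTS = 128


@dataclass
class BenchmarkResult:
    models: dict[str, TrainedModel]
    reports: dict[str, EvaluationReport]
    split: Split
    labels: np.ndarray
    pipeline: FeaturePipeline


def featurize_split(
    elements,
    labels,
    seed: int,
    max_components: int | None = BENCHMARK_MAX_COMPONENTS,
    normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, Split, FeaturePipeline, np.ndarray]:
    """Counts -> split -> fit pipeline on train only -> transformed splits."""
    fm = FeatureMatrix.from_elements(elements, KmerSpec(1, 6), normalize=normalize)
    labels = np.asarray(labels)
    split = split_dataset(labels, seed=seed)
    pipeline = FeaturePipeline(n_components=0.95, max_components=max_components,
                               whiten=True)
    X_train = pipeline.fit_transform(fm.raw[split.train])
    X_val = pipeline.transform(fm.raw[split.val])
    X_test = pipeline.transform(fm.raw[split.test])
    return X_train, X_val, X_test, split, pipeline, labels


def run_lineage_benchmark(
    seed: int = 0,
    n_per_lineage: int = 200,
    mutation_rate: float = 0.03,
    epochs: int = 25,
    architectures: tuple[str, ...] = ("FNN", "CNN"),
    bias_weight: float = 8.0,
    max_components: int | None = BENCHMARK_MAX_COMPONENTS,
) -> BenchmarkResult:
    """The 13-lineage synthetic classification benchmark."""
    profiles, refs = make_profiles(
        CANONICAL_LINEAGES, seed=seed, bias_weight=bias_weight
    )
    lib = generate_library(
        profiles, refs, n_per_lineage=n_per_lineage,
        mutation_rate=mutation_rate, seed=seed + 1,
    )
    X_train, X_val, X_test, split, pipeline, labels = featurize_split(
        lib.elements, lib.labels(), seed=seed + 2, max_components=max_components
    )
    logger.info("benchmark features: %d PCA components", X_train.shape[1])
    models: dict[str, TrainedModel] = {}
    reports: dict[str, EvaluationReport] = {}
    for arch in architectures:
        hp = HyperParams(epochs=epochs, seed=seed + 3)
        if arch.upper() == "FNN":
            net = build_fnn(X_train.shape[1], len(set(labels)), hp)
        elif arch.upper() == "CNN":
            net = build_cnn(X_train.shape[1], len(set(labels)), hp)
        else:
            raise ValueError(f"unknown architecture {arch!r}")
        model = train(net, X_train, labels[split.train], X_val, labels[split.val], hp)
        model.pipeline = pipeline
        models[arch.upper()] = model
        reports[arch.upper()] = evaluate(model, X_test, labels[split.test])
    return BenchmarkResult(
        models=models, reports=reports, split=split, labels=labels, pipeline=pipeline
    )


def run_null_benchmark(
    seed: int = 0,
    n_total: int = 650,
    epochs: int = 25,
    architecture: str = "FNN",
) -> EvaluationReport:
    """Chance-level control: one sequence profile, round-robin labels."""
    elements, labels = generate_null_library(CANONICAL_LINEAGES, n_total, seed=seed)
    X_train, X_val, X_test, split, _, labels = featurize_split(
        elements, labels, seed=seed + 2
    )
    hp = HyperParams(epochs=epochs, seed=seed + 3)
    builder = build_fnn if architecture.upper() == "FNN" else build_cnn
    net = builder(X_train.shape[1], len(set(labels)), hp)
    model = train(net, X_train, labels[split.train], X_val, labels[split.val], hp)
    return evaluate(model, X_test, labels[split.test])
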