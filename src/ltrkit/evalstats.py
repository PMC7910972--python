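"""Dataset-comparison harness.

Balanced subsampling across libraries, stratified 10-fold cross-validation
of eight classical classifiers on k-mer features, and nonparametric
inference: a Kruskal-Wallis test across groups of per-fold F1 scores,
followed by pairwise two-sample rank tests with Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLASSIFIER_TAGS = ("LR", "LDA", "KNN", "MLP", "RF", "DT", "NB", "SVM")


def make_classifier(tag: str, seed: int = 0):
    """Interchangeable fit/predict adapters with fixed seeds, library defaults."""
    tag = tag.upper()
    if tag == "LR":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if tag == "LDA":
        return LinearDiscriminantAnalysis()
    if tag == "KNN":
        return KNeighborsClassifier()
    if tag == "MLP":
        return MLPClassifier(hidden_layer_sizes=(100,), max_iter=500, random_state=seed)
    if tag == "RF":
        return RandomForestClassifier(random_state=seed)
    if tag == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if tag == "NB":
        return GaussianNB()
    if tag in ("SVM", "SVC"):
        return SVC(random_state=seed)
    raise ValueError(f"unknown classifier tag {tag!r}; known: {CLASSIFIER_TAGS}")


def balanced_subsample(
    libraries: Mapping[str, Mapping[str, Sequence]], seed: int = 0
) -> dict[str, dict[str, list]]:
    """Downsample every (library, lineage) cell to the global per-lineage minimum.

    ``libraries`` maps library tag -> lineage -> items.  Only lineages present
    in every library are kept; the per-lineage minimum count across libraries
    sets each cell's size.  Deterministic under seed.
    """
    if not libraries:
        raise ValueError("no libraries given")
    shared = set.intersection(*(set(lib) for lib in libraries.values()))
    if not shared:
        raise ValueError("libraries share no lineage; nothing to balance")
    minima = {
        lineage: min(len(lib[lineage]) for lib in libraries.values())
        for lineage in shared
    }
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, list]] = {}
    for tag in sorted(libraries):
        out[tag] = {}
        for lineage in sorted(shared):
            items = list(libraries[tag][lineage])
            take = minima[lineage]
            if take == len(items):
                out[tag][lineage] = items
            else:
                idx = rng.choice(len(items), size=take, replace=False)
                out[tag][lineage] = [items[i] for i in np.sort(idx)]
    return out


@dataclass(frozen=True)
class CvResult:
    dataset: str
    classifier: str
    fold_f1: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not (0.0 <= s <= 1.0) for s in self.fold_f1):
            raise ValueError("per-fold F1 scores must lie in [0, 1]")

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1))


def kfold_cv(
    X: np.ndarray,
    y: Sequence[str],
    classifier_tag: str,
    k: int = 10,
    seed: int = 0,
    dataset: str = "dataset",
) -> CvResult:
    """Stratified k-fold cross-validation; macro F1 per fold."""
    X = np.asarray(X)
    y = np.asarray(y)
    if len(X) < k:
        raise ValueError(f"n={len(X)} rows cannot be split into k={k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in skf.split(X, y):
        clf = make_classifier(classifier_tag, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X[train_idx], y[train_idx])
            pred = clf.predict(X[test_idx])
        scores.append(float(f1_score(y[test_idx], pred, average="macro")))
    return CvResult(dataset=dataset, classifier=classifier_tag.upper(),
                    fold_f1=tuple(scores))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-squared p-value.

    Convention: if every pooled observation is identical the test is
    degenerate and (H=0, p=1) is returned.
    """
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def pairwise_bonferroni(
    groups: Sequence[Sequence[float]],
) -> np.ndarray:
    """Bonferroni-adjusted two-sample rank-test p-values for all group pairs.

    Mann-Whitney U (two-sided, tie-corrected) per pair; raw p multiplied by
    the number of comparisons m = g*(g-1)/2, capped at 1.  The returned
    matrix is symmetric with a unit diagonal.
    """
    g = len(groups)
    if g < 2:
        raise ValueError("need at least two groups")
    if any(len(x) == 0 for x in groups):
        raise ValueError("all groups must be non-empty")
    m = g * (g - 1) // 2
    out = np.ones((g, g), dtype=float)
    for i in range(g):
        for j in range(i + 1, g):
            a = np.asarray(groups[i], dtype=float)
            b = np.asarray(groups[j], dtype=float)
            pooled = np.concatenate([a, b])
            if np.all(pooled == pooled[0]):
                raw = 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, raw = stats.mannwhitneyu(a, b, alternative="two-sided")
            out[i, j] = out[j, i] = min(1.0, float(raw) * m)
    return out


def raw_pairwise_p(groups: Sequence[Sequence[float]]) -> np.ndarray:
    """Unadjusted pairwise rank-test p-values (same layout as pairwise_bonferroni)."""
    g = len(groups)
    out = np.ones((g, g), dtype=float)
    for i in range(g):
        for j in range(i + 1, g):
            a = np.asarray(groups[i], dtype=float)
            b = np.asarray(groups[j], dtype=float)
            pooled = np.concatenate([a, b])
            if np.all(pooled == pooled[0]):
                raw = 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, raw = stats.mannwhitneyu(a, b, alternative="two-sided")
            out[i, j] = out[j, i] = float(raw)
    return out


def cv_results_to_tsv(results: Sequence[CvResult], path, provenance: str | None = None) -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write("dataset\tclassifier\tfold\tf1\n")
        for res in results:
            for fold, score in enumerate(res.fold_f1):
                fh.write(f"{res.dataset}\t{res.classifier}\t{fold}\t{score:.6f}\n")


def comparison_matrix_to_tsv(
    matrix: np.ndarray, names: Sequence[str], path, provenance: str | None = None
) -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write("\t" + "\t".join(names) + "\n")
        for i, name in enumerate(names):
            row = "\t".join(f"{matrix[i, j]:.4g}" for j in range(len(names)))
            fh.write(f"{name}\t{row}\n")
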