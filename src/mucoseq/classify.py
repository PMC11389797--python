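"""Four-way classification harness: repeated stratified train/test splits,
a 200-tree random forest per iteration, a percentage confusion matrix
aggregated over iterations, averaged feature importances, top-k predictive
genes, and hierarchical heatmap ordering.

The protocol mirrors the transcriptome classification task: four groups
(cohort × treatment), each iteration drawing a fresh stratified split of
5 training and 2 test mice per group, a fresh forest, and accumulating the
test predictions.  At the protocol scale this is 10,000 iterations; the
iteration RNG is derived from the master seed by counter, so a reduced
iteration count reproduces a prefix of the full run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestClassifier

from ._random import iteration_seeds
from .design import validate_design
from .exceptions import InsufficientDataError, SplitInfeasibleError
from .preprocess import normalize_library_size, zscore_rows


@dataclass(frozen=True)
class ConfusionSummary:
    """Percentage confusion matrix aggregated over split iterations.

    ``matrix`` rows are true classes, columns predicted classes; each row
    sums to 100 (up to floating rounding).  Diagonal entries are the
    per-class accuracies.
    """

    classes: tuple
    matrix: pd.DataFrame
    iterations: int

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.classes), len(self.classes)):
            raise ValueError("confusion matrix shape mismatch")
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("negative confusion entries")

    @property
    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.matrix), index=self.matrix.index)

    @property
    def overall_accuracy(self) -> float:
        return float(self.diagonal.mean())

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": list(self.classes),
                "matrix_percent": self.matrix.round(6).to_dict(orient="index"),
                "iterations": int(self.iterations),
            },
            sort_keys=True,
        )


def repeated_split_classify(
    norm: pd.DataFrame,
    design: pd.DataFrame,
    n_train_per_group: int = 5,
    n_test_per_group: int = 2,
    n_trees: int = 200,
    iterations: int = 10_000,
    seed: int = 0,
    n_jobs: int = 1,
) -> tuple[ConfusionSummary, pd.Series]:
    """Run the repeated-split random-forest protocol.

    Features are the normalized, filtered genes; at the classifier boundary
    samples are rows, and each row is re-normalized to a fixed 10^6 total
    (a no-op if the matrix is already library-size normalized).  Per
    iteration a fresh stratified split is drawn and a fresh
    ``n_trees``-tree forest trained; test predictions accumulate into
    per-true-class counts and impurity importances are averaged over
    iterations.

    Returns the percentage confusion summary and the aggregated importance
    ranking (descending score, ties broken by gene ID).
    """
    need = n_train_per_group + n_test_per_group
    groups = validate_design(design, min_per_group=2)
    sizes = groups.value_counts()
    small = sizes[sizes < need]
    if not small.empty:
        raise SplitInfeasibleError(
            "groups too small for a "
            f"{n_train_per_group}+{n_test_per_group} split: "
            + ", ".join(f"{g} (n={n})" for g, n in small.items())
        )

    classes = tuple(sorted(sizes.index))
    # samples as rows; per-sample totals pinned to 1e6
    X = normalize_library_size(norm, scale=1e6).T
    X = X.loc[design.index]
    y = groups.loc[X.index].to_numpy()
    Xv = np.ascontiguousarray(X.to_numpy(dtype=float))

    class_members = {
        c: np.flatnonzero(y == c) for c in classes
    }
    class_pos = {c: i for i, c in enumerate(classes)}

    conf_counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    importance_sum = np.zeros(Xv.shape[1])

    seeds = iteration_seeds(seed, iterations)
    for it in range(iterations):
        rng = np.random.default_rng(seeds[it])
        train_idx, test_idx = [], []
        for c in classes:
            perm = rng.permutation(class_members[c])
            train_idx.extend(perm[:n_train_per_group])
            test_idx.extend(perm[n_train_per_group : n_train_per_group + n_test_per_group])
        train_idx = np.array(train_idx)
        test_idx = np.array(test_idx)

        forest = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(seeds[it]),
            n_jobs=n_jobs,
        )
        forest.fit(Xv[train_idx], y[train_idx])
        pred = forest.predict(Xv[test_idx])
        for true, hat in zip(y[test_idx], pred):
            conf_counts[class_pos[true], class_pos[hat]] += 1
        importance_sum += forest.feature_importances_

    denom = iterations * n_test_per_group
    matrix = pd.DataFrame(
        conf_counts / denom * 100.0, index=list(classes), columns=list(classes)
    )
    summary = ConfusionSummary(classes=classes, matrix=matrix, iterations=iterations)

    scores = pd.Series(importance_sum / iterations, index=X.columns, name="importance")
    ranking = scores.iloc[
        np.lexsort((scores.index.to_numpy(), -scores.to_numpy()))
    ]
    return summary, ranking


def top_features(ranking: pd.Series, k: int = 200) -> list[str]:
    """First ``k`` genes by descending importance, ties broken by gene ID."""
    if k > ranking.size:
        raise ValueError(f"k={k} exceeds the {ranking.size} ranked genes")
    ordered = ranking.iloc[
        np.lexsort((ranking.index.to_numpy(), -ranking.to_numpy()))
    ]
    return list(ordered.index[:k])


def cluster_heatmap_order(z: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Hierarchical leaf orders for a row-standardized expression matrix.

    Average-linkage agglomerative clustering under correlation distance,
    applied to rows (genes) and columns (samples) independently.
    Deterministic for a fixed input.
    """
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise InsufficientDataError(
            "heatmap ordering needs at least 2 rows and 2 columns"
        )
    values = z.to_numpy(dtype=float)
    if np.any(values.std(axis=1) == 0) or np.any(values.std(axis=0) == 0):
        raise InsufficientDataError(
            "constant rows/columns have no correlation distance; drop them first"
        )
    row_order = leaves_list(linkage(pdist(values, metric="correlation"), method="average"))
    col_order = leaves_list(linkage(pdist(values.T, metric="correlation"), method="average"))
    return row_order, col_order


class FourWayClassification:
    """Model object for the four-way classification protocol."""

    def __init__(
        self,
        norm: pd.DataFrame,
        design: pd.DataFrame,
        n_train_per_group: int = 5,
        n_test_per_group: int = 2,
        n_trees: int = 200,
    ) -> None:
        self.norm = norm
        self.design = design
        self.n_train_per_group = n_train_per_group
        self.n_test_per_group = n_test_per_group
        self.n_trees = n_trees

    def fit(self, iterations: int = 10_000, seed: int = 0, n_jobs: int = 1):
        confusion, ranking = repeated_split_classify(
            self.norm,
            self.design,
            n_train_per_group=self.n_train_per_group,
            n_test_per_group=self.n_test_per_group,
            n_trees=self.n_trees,
            iterations=iterations,
            seed=seed,
            n_jobs=n_jobs,
        )
        return FourWayClassificationResults(self, confusion, ranking, seed)


class FourWayClassificationResults:
    """Aggregated confusion matrix, importance ranking, and heatmap views."""

    def __init__(
        self,
        model: FourWayClassification,
        confusion: ConfusionSummary,
        importances: pd.Series,
        seed: int,
    ) -> None:
        self.model = model
        self.confusion = confusion
        self.importances = importances
        self.seed = seed

    def top_features(self, k: int = 200) -> list[str]:
        return top_features(self.importances, k=k)

    def ordered_heatmap(self, k: int = 200) -> pd.DataFrame:
        """Row-standardized expression of the top-k genes, rows and columns
        reordered by hierarchical clustering."""
        genes = self.top_features(k=k)
        z = zscore_rows(self.model.norm.loc[genes])
        row_order, col_order = cluster_heatmap_order(z)
        return z.iloc[row_order, col_order]

    def summary(self) -> str:
        c = self.confusion
        lines = [
            "Repeated-split random-forest classification",
            "=" * 48,
            f"classes: {', '.join(c.classes)}",
            f"iterations: {c.iterations}  trees/forest: {self.model.n_trees}",
            f"split: {self.model.n_train_per_group} train / "
            f"{self.model.n_test_per_group} test per group",
            f"overall accuracy: {c.overall_accuracy:.1f}%",
            "",
            "confusion matrix (% of predictions per true class):",
            c.matrix.round(1).to_string(),
        ]
        return "\n".join(lines)

    def plot_confusion(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.confusion.matrix
        im = ax.imshow(m.to_numpy(), cmap="Blues", vmin=0, vmax=100)
        ax.set_xticks(range(len(m.columns)), m.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(m.index)), m.index)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(m.shape[0]):
            for j in range(m.shape[1]):
                ax.text(j, i, f"{m.iat[i, j]:.0f}", ha="center", va="center")
        plt.colorbar(im, ax=ax, label="% of predictions")
        return ax
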