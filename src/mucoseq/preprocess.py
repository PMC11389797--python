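"""Count-matrix preprocessing: sparse-gene filtering, library-size (CPM-style)
normalization, PCA summaries and per-gene z-scoring.

A count matrix is a :class:`pandas.DataFrame` with genes as rows and samples
as columns, nonnegative values, and no duplicated identifiers on either axis.
The canonical order of operations is filter → normalize: sparse genes (more
than half of the samples at zero) are dropped first, then each sample is
rescaled so its total equals a fixed scaling factor (10^6 by default), which
makes samples with different library sizes comparable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .exceptions import DegenerateSampleError, EmptyInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for one sparse-gene filter pass."""

    n_input_genes: int
    n_removed: int
    n_retained: int
    zero_fraction_threshold: float

    def __post_init__(self) -> None:
        if self.n_input_genes != self.n_removed + self.n_retained:
            raise ValueError("inconsistent filter report")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def _check_matrix(counts: pd.DataFrame) -> None:
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise EmptyInputError("count matrix is empty")
    if counts.index.duplicated().any():
        raise ValueError("duplicated gene IDs in count matrix")
    if counts.columns.duplicated().any():
        raise ValueError("duplicated sample IDs in count matrix")


def filter_sparse_genes(
    counts: pd.DataFrame, max_zero_fraction: float = 0.5
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop genes whose zero fraction strictly exceeds ``max_zero_fraction``.

    A gene observed at zero in *more than* half of the samples carries little
    usable expression signal; it is removed.  A gene at exactly the threshold
    (e.g. 2 zeros out of 4 samples) is kept.  Sample set and gene order are
    preserved.
    """
    _check_matrix(counts)
    zero_frac = (counts == 0).sum(axis=1) / counts.shape[1]
    keep = zero_frac <= max_zero_fraction
    filtered = counts.loc[keep]
    report = FilterReport(
        n_input_genes=int(counts.shape[0]),
        n_removed=int((~keep).sum()),
        n_retained=int(keep.sum()),
        zero_fraction_threshold=float(max_zero_fraction),
    )
    logger.info(
        "sparse filter: %d/%d genes removed (>%g zero fraction), %d retained",
        report.n_removed,
        report.n_input_genes,
        max_zero_fraction,
        report.n_retained,
    )
    return filtered, report


def normalize_library_size(counts: pd.DataFrame, scale: float = 1e6) -> pd.DataFrame:
    """Rescale every sample (column) to a fixed total of ``scale``.

    With the default scale of 10^6 this is counts-per-million: value v in
    sample j becomes v * scale / total_j, so each output column sums to
    ``scale`` and within-sample gene ratios are unchanged.

    Raises
    ------
    DegenerateSampleError
        If any sample has a zero total, naming the offending sample(s).
    """
    _check_matrix(counts)
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if not zero.empty:
        raise DegenerateSampleError(
            f"samples with zero total counts cannot be normalized: "
            f"{list(zero.index)}"
        )
    return counts * (scale / totals)


def zscore_rows(norm: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene (row) to mean 0, variance 1 (population ddof=0).

    Constant rows have no scale and are mapped to all-zeros with a warning;
    this is the display normalization used before heatmap ordering.
    """
    _check_matrix(norm)
    values = norm.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant rows z-scored to zeros", stacklevel=2
        )
        sd[flat] = 1.0
    z = (values - mean) / sd
    z[flat, :] = 0.0
    return pd.DataFrame(z, index=norm.index, columns=norm.columns)


def pca_summary(
    norm: pd.DataFrame,
    n_components: int = 2,
    log1p: bool = False,
    scale_genes: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of samples in gene space.

    Samples are the observations; genes are mean-centered (and optionally
    unit-variance scaled).  Returns the sample coordinates (samples ×
    components) and the fraction of variance captured by each component,
    nonincreasing and summing to at most 1.

    ``n_components`` beyond the data rank is reduced with a logged warning
    rather than raised; zero-variance genes are dropped beforehand (their
    count is logged) because they carry no variance and break unit scaling.
    """
    _check_matrix(norm)
    X = norm.to_numpy(dtype=float).T  # samples × genes
    if log1p:
        X = np.log1p(X)
    var = X.var(axis=0, ddof=0)
    dead = var == 0
    if dead.any():
        logger.info("pca: dropping %d zero-variance genes", int(dead.sum()))
        X = X[:, ~dead]
        var = var[~dead]
    if X.shape[1] == 0:
        raise EmptyInputError("no genes with nonzero variance for PCA")
    if scale_genes:
        X = (X - X.mean(axis=0)) / np.sqrt(var)
    rank = min(X.shape[0] - 1, X.shape[1])
    k = int(n_components)
    if k > rank:
        logger.warning("pca: n_components=%d exceeds rank %d; reduced", k, rank)
        k = rank
    pca = PCA(n_components=k)
    coords = pca.fit_transform(X)
    frame = pd.DataFrame(
        coords, index=norm.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return frame, pca.explained_variance_ratio_.copy()
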