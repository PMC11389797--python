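"""Synthetic data with the statistical structure the analysis assumes.

Three generators emulate the study's raw inputs so that every downstream
stage can be exercised and validated without external downloads:

* :func:`generate_counts` — bulk RNA-seq gene-by-sample counts for a
  two-cohort × two-treatment design (negative-binomial counts over
  log-normal baseline means), with a configurable set of genes carrying a
  treatment effect shared in direction across both cohorts, cohort-specific
  effect genes, and an optional engineered sparse-gene fraction.  Ground
  truth (gene class and true effect direction) is returned alongside.
* :func:`generate_distance_measurements` — gamma-distributed
  bacteria-to-epithelium distances (μm) per mouse per FISH probe, with a
  treatment-dependent shift toward the epithelium.
* :func:`generate_mucus_timeseries` — paired control/treated ex vivo mucus
  thickness-versus-time series with linear growth plus Gaussian noise.

All generators are deterministic given their seed: the seed expands into
named substreams so each table can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._random import substream
from .design import validate_design
from .exceptions import InvalidDesignError

LONG_COLUMNS = ["mouse_id", "group", "variable", "probe", "time", "value"]

#: truth classes; cohort-specific classes are named after the actual cohorts
CLASS_NULL = "null"
CLASS_SHARED = "shared"


@dataclass(frozen=True)
class EffectSpec:
    """Parameters of one simulated RNA-seq experiment.

    Parameters
    ----------
    n_genes
        Total number of genes.
    n_shared_effect
        Genes perturbed in the SAME direction in both cohorts.
    n_cohort_specific
        Genes perturbed in one cohort only (this many per cohort).
    log2_effect_size
        Mean shift applied to treated groups: treated means are multiplied
        by ``2 ** (direction * log2_effect_size)``.
    dispersion
        Negative-binomial overdispersion alpha (> 0); variance is
        ``mu + alpha * mu**2``.
    sparse_fraction
        If given, exactly ``round(sparse_fraction * n_genes)`` genes are
        engineered to exceed 50% zero entries (and all other genes are kept
        at or below 50% zeros), making the sparse-gene filter outcome
        deterministic.  ``None`` leaves sparsity to the count distribution.
    seed
        Master seed for this dataset.
    """

    n_genes: int
    n_shared_effect: int = 0
    n_cohort_specific: int = 0
    log2_effect_size: float = 0.0
    dispersion: float = 0.3
    sparse_fraction: float | None = None
    seed: int = 0
    # log10-scale baseline-mean distribution across genes
    mean_log10_loc: float = 1.5
    mean_log10_scale: float = 0.8

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_shared_effect < 0 or self.n_cohort_specific < 0:
            raise ValueError("effect gene counts must be nonnegative")
        if self.n_shared_effect + 2 * self.n_cohort_specific > self.n_genes:
            raise ValueError(
                "n_shared_effect + 2*n_cohort_specific exceeds n_genes"
            )
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.sparse_fraction is not None and not (
            0.0 <= self.sparse_fraction <= 1.0
        ):
            raise ValueError("sparse_fraction must be in [0, 1]")


def generate_counts(
    design: pd.DataFrame,
    spec: EffectSpec,
    control_treatment: str = "PBS",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a count matrix and its ground-truth gene labels.

    Counts are negative-binomial with gene-specific baseline means drawn
    log-normally across genes (log10 mean ~ Normal(1.5, 0.8) by default, a
    standard emulation of the heavy-tailed expression distribution of bulk
    RNA-seq in which no single gene dominates the library).  In treated samples the mean of each affected gene is
    multiplied by ``2 ** (direction * log2_effect_size)``; the per-gene
    direction is a seeded coin flip, identical in both cohorts for shared
    genes.

    Returns
    -------
    counts
        Integer DataFrame, genes × samples.
    truth
        DataFrame indexed by gene_id with columns ``class`` (shared /
        <cohortA>_only / <cohortB>_only / null) and ``true_direction``
        (+1 / −1 / 0); every gene appears exactly once.
    """
    validate_design(design, min_per_group=2)
    cohorts = list(dict.fromkeys(design["cohort"]))
    if len(cohorts) != 2:
        raise InvalidDesignError(
            f"count simulation needs exactly 2 cohorts, got {cohorts}"
        )
    treatments = set(design["treatment"])
    if control_treatment not in treatments or len(treatments) != 2:
        raise InvalidDesignError(
            "design must contain the control treatment and exactly one other"
        )

    rng = substream(spec.seed, "counts")
    n_genes, n_samples = spec.n_genes, design.shape[0]
    genes = pd.Index(
        [f"gene_{i:05d}" for i in range(n_genes)], name="gene_id"
    )

    # truth classes on a shuffled gene order so class is not positional
    order = rng.permutation(n_genes)
    classes = np.full(n_genes, CLASS_NULL, dtype=object)
    k = 0
    classes[order[k : k + spec.n_shared_effect]] = CLASS_SHARED
    k += spec.n_shared_effect
    classes[order[k : k + spec.n_cohort_specific]] = f"{cohorts[0]}_only"
    k += spec.n_cohort_specific
    classes[order[k : k + spec.n_cohort_specific]] = f"{cohorts[1]}_only"

    directions = np.where(rng.random(n_genes) < 0.5, 1, -1).astype(np.int8)
    directions[classes == CLASS_NULL] = 0

    base_mean = 10.0 ** rng.normal(
        spec.mean_log10_loc, spec.mean_log10_scale, n_genes
    )

    sparse_idx = np.array([], dtype=int)
    if spec.sparse_fraction is not None:
        n_sparse = int(round(spec.sparse_fraction * n_genes))
        null_idx = np.flatnonzero(classes == CLASS_NULL)
        if n_sparse > null_idx.size:
            raise ValueError(
                "sparse_fraction requires more null genes than available"
            )
        sparse_idx = rng.choice(null_idx, size=n_sparse, replace=False)
        base_mean[sparse_idx] = 0.3  # near-zero expression for the sparse set

    # per-sample mean matrix with treatment effects per cohort
    mu = np.tile(base_mean[:, None], (1, n_samples))
    fold = 2.0 ** (spec.log2_effect_size * directions.astype(float))
    for j, (sample, row) in enumerate(design.iterrows()):
        if row["treatment"] == control_treatment:
            continue
        affected = (classes == CLASS_SHARED) | (
            classes == f"{row['cohort']}_only"
        )
        mu[affected, j] = mu[affected, j] * fold[affected]

    n_param = 1.0 / spec.dispersion
    counts = rng.negative_binomial(n_param, n_param / (n_param + mu))

    if spec.sparse_fraction is not None:
        _enforce_sparsity(counts, sparse_idx, rng)

    counts_df = pd.DataFrame(counts, index=genes, columns=design.index)
    truth = pd.DataFrame(
        {"class": classes, "true_direction": directions}, index=genes
    )
    return counts_df, truth


def _enforce_sparsity(
    counts: np.ndarray, sparse_idx: np.ndarray, rng: np.random.Generator
) -> None:
    """Make the >50%-zeros property exact, in place.

    Designated sparse genes get extra zeroed entries until strictly more
    than half of their samples are zero; every other gene that stochastically
    exceeded the threshold is topped up with ones until it is back at or
    below 50% zeros.  This pins the sparse-gene filter outcome to exactly
    the requested fraction.
    """
    n_samples = counts.shape[1]
    need_zeros = n_samples // 2 + 1  # strictly > 50%
    sparse_mask = np.zeros(counts.shape[0], dtype=bool)
    sparse_mask[sparse_idx] = True

    for g in sparse_idx:
        row = counts[g]
        deficit = need_zeros - int((row == 0).sum())
        if deficit > 0:
            nonzero = np.flatnonzero(row != 0)
            row[rng.choice(nonzero, size=deficit, replace=False)] = 0

    max_zeros = n_samples // 2 if n_samples % 2 == 0 else (n_samples - 1) // 2
    zero_counts = (counts == 0).sum(axis=1)
    for g in np.flatnonzero(~sparse_mask & (zero_counts > max_zeros)):
        row = counts[g]
        surplus = int((row == 0).sum()) - max_zeros
        zeros = np.flatnonzero(row == 0)
        row[rng.choice(zeros, size=surplus, replace=False)] = 1


def generate_distance_measurements(
    n_mice: int,
    per_mouse: int = 25,
    taxa_params: Mapping[str, tuple[float, float]] | None = None,
    treatment_scale: float = 1.0,
    groups: Sequence[str] = ("control", "treated"),
    seed: int = 0,
) -> pd.DataFrame:
    """Gamma-distributed bacteria-to-epithelium distances, long format.

    For each of ``n_mice`` mice per group and each FISH probe, draws
    ``per_mouse`` distances (μm) from Gamma(shape, scale).  In treated
    groups the scale is multiplied by ``treatment_scale``; values below 1
    shift bacteria toward the epithelium, emulating barrier breakdown.
    At least 25 measurements per mouse are required, matching the imaging
    protocol's validity rule downstream.
    """
    if per_mouse < 25:
        raise ValueError("per_mouse must be at least 25")
    if taxa_params is None:
        taxa_params = {"EUB338": (4.0, 15.0)}
    for probe, (shape, scale) in taxa_params.items():
        if shape <= 0 or scale <= 0:
            raise ValueError(f"nonpositive gamma parameters for probe {probe!r}")
    if treatment_scale <= 0:
        raise ValueError("treatment_scale must be positive")

    rng = substream(seed, "distances")
    rows = []
    for group in groups:
        factor = 1.0 if group == groups[0] else treatment_scale
        for m in range(1, n_mice + 1):
            mouse = f"{group}_m{m}"
            for probe, (shape, scale) in taxa_params.items():
                values = rng.gamma(shape, scale * factor, size=per_mouse)
                rows.append(
                    pd.DataFrame(
                        {
                            "mouse_id": mouse,
                            "group": group,
                            "variable": "distance",
                            "probe": probe,
                            "time": np.nan,
                            "value": values,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)[LONG_COLUMNS]


def generate_mucus_timeseries(
    n_pairs: int,
    control_rate: float = 2.0,
    treated_rate: float = 1.0,
    noise_sd: float = 2.0,
    duration_min: float = 45.0,
    dt_min: float = 5.0,
    baseline_um: float = 50.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired ex vivo mucus thickness-versus-time series.

    Each animal contributes two tissue series — one infused with plain
    medium (control) and one with the drug (treated) — measured every
    ``dt_min`` minutes over ``duration_min`` minutes (default 45-minute
    recording, i.e. 10 time points at 5-minute sampling).  Thickness grows
    linearly, ``baseline + rate * t``, plus Gaussian noise.
    """
    if duration_min <= 0:
        raise ValueError("duration_min must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if n_pairs < 1:
        raise ValueError("need at least one animal")

    rng = substream(seed, "timeseries")
    times = np.arange(0.0, duration_min + dt_min / 2, dt_min)
    rows = []
    for m in range(1, n_pairs + 1):
        for condition, rate in (("control", control_rate), ("treated", treated_rate)):
            noise = rng.normal(0.0, noise_sd, size=times.size) if noise_sd else 0.0
            rows.append(
                pd.DataFrame(
                    {
                        "mouse_id": f"m{m}",
                        "group": condition,
                        "variable": "thickness",
                        "probe": "",
                        "time": times,
                        "value": baseline_um + rate * times + noise,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)[LONG_COLUMNS]


def expected_sparse_removals(n_genes: int, sparse_fraction: float) -> int:
    """Number of genes the >50%-zeros filter will remove under engineering."""
    return int(round(sparse_fraction * n_genes))


def nb_mean_variance(mu: float, dispersion: float) -> tuple[float, float]:
    """Theoretical NB mean/variance for the generator's parameterisation."""
    return mu, mu + dispersion * mu * mu


def time_points(duration_min: float = 45.0, dt_min: float = 5.0) -> int:
    """Number of samples in one recording window (endpoints inclusive)."""
    return int(math.floor(duration_min / dt_min)) + 1
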