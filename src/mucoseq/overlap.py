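"""Direction-consistent overlap of two signed DEG sets with a bootstrap null.

The statistic: the number of genes significant in BOTH of two independent
comparisons (e.g. germ-free and conventionally raised cohorts, each treated
vs control) with the SAME fold-change sign — up in both or down in both.
Its significance is assessed against an empirical null built by drawing,
many times, random gene sets of the same sizes as the two significant sets
from the tested gene universe (without replacement); each sampled gene keeps
its observed fold-change sign from its cohort's full DEG table, and the
replicate value is the direction-consistent overlap of the two random sets.
The empirical p-value is the proportion of replicates with an overlap
greater than or equal to the observed value.

By linearity of expectation the null mean is
``size_a * size_b / G * a`` where ``a`` is the universe-wide sign-agreement
rate between the two cohorts' sign maps — a useful closed-form check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._random import substream
from .deg import SignedGeneSet
from .exceptions import SamplingError, UniverseMismatchError


def directional_overlap(a: SignedGeneSet, b: SignedGeneSet) -> int:
    """Number of shared member genes whose directions agree."""
    if a.universe != b.universe:
        raise UniverseMismatchError(
            f"gene universes differ (|A|={len(a.universe)}, |B|={len(b.universe)})"
        )
    return sum(
        1
        for g, d in a.members.items()
        if b.members.get(g, 0) == d
    )


def bootstrap_null(
    universe: Sequence[str],
    size_a: int,
    size_b: int,
    signs_a: Mapping[str, int],
    signs_b: Mapping[str, int],
    n_boot: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the direction-consistent overlap.

    Each replicate draws a uniform random subset of ``size_a`` and,
    independently, of ``size_b`` genes from ``universe`` without
    replacement; sampled genes keep their observed signs (direction 0
    counts as never agreeing).  Returns the ``n_boot`` replicate overlap
    counts.
    """
    genes = list(universe)
    G = len(genes)
    if size_a > G or size_b > G:
        raise SamplingError(
            f"set sizes ({size_a}, {size_b}) exceed universe of {G} genes"
        )
    missing = [g for g in genes if g not in signs_a or g not in signs_b]
    if missing:
        raise ValueError(
            f"sign maps do not cover the universe (e.g. {missing[:5]})"
        )
    sa = np.fromiter((signs_a[g] for g in genes), dtype=np.int8, count=G)
    sb = np.fromiter((signs_b[g] for g in genes), dtype=np.int8, count=G)
    agree = (sa == sb) & (sa != 0)

    rng = substream(seed, "overlap")
    null = np.empty(n_boot, dtype=np.int64)
    mark = np.zeros(G, dtype=bool)
    for r in range(n_boot):
        idx_a = rng.choice(G, size=size_a, replace=False)
        idx_b = rng.choice(G, size=size_b, replace=False)
        mark[idx_a] = True
        null[r] = np.count_nonzero(mark[idx_b] & agree[idx_b])
        mark[idx_a] = False
    return null


def empirical_p(observed: int, null: Sequence[int]) -> float:
    """Proportion of null replicates greater than or equal to ``observed``.

    A raw proportion (no +1 smoothing); when no replicate reaches the
    observed value this is 0 and the result should be reported as
    p < 1/B (see :attr:`OverlapResult.p_floor`).
    """
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    return float(np.count_nonzero(null >= observed) / null.size)


def expected_null_mean(
    universe_size: int, size_a: int, size_b: int, agreement_rate: float
) -> float:
    """Closed-form null mean: (size_a * size_b / G) * sign-agreement rate."""
    return size_a * size_b / universe_size * agreement_rate


def hypergeom_overlap_p(a: SignedGeneSet, b: SignedGeneSet) -> float:
    """Analytic upper-tail hypergeometric p for the UNSIGNED intersection.

    A cross-check utility only: it ignores fold-change signs, so it is not
    the headline statistic and is expected to be less conservative.
    """
    if a.universe != b.universe:
        raise UniverseMismatchError("gene universes differ")
    G = len(a.universe)
    k = len(set(a.members) & set(b.members))
    return float(stats.hypergeom.sf(k - 1, G, len(a), len(b)))


@dataclass(frozen=True)
class OverlapResult:
    """Observed overlap, bootstrap null, and empirical p-value."""

    observed_overlap: int
    null_distribution: np.ndarray
    empirical_p: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.null_distribution) != self.n_boot:
            raise ValueError("null length does not match n_boot")
        if not 0.0 <= self.empirical_p <= 1.0:
            raise ValueError("empirical p outside [0, 1]")

    @property
    def p_floor(self) -> float:
        """Resolution limit of the empirical p (1/B)."""
        return 1.0 / self.n_boot

    @property
    def p_display(self) -> str:
        if self.empirical_p == 0.0:
            return f"p < {self.p_floor:g}"
        return f"p = {self.empirical_p:g}"

    def to_dict(self, include_null: bool = False) -> dict:
        out = {
            "observed_overlap": int(self.observed_overlap),
            "empirical_p": self.empirical_p,
            "p_floor": self.p_floor,
            "p_display": self.p_display,
            "n_boot": int(self.n_boot),
            "seed": int(self.seed),
            "null_mean": float(np.mean(self.null_distribution)),
            "null_sd": float(np.std(self.null_distribution)),
            "null_max": int(np.max(self.null_distribution)),
        }
        if include_null:
            out["null_distribution"] = [int(v) for v in self.null_distribution]
        return out

    def to_json(self, include_null: bool = False) -> str:
        return json.dumps(self.to_dict(include_null=include_null), sort_keys=True)


class OverlapBootstrap:
    """Model object for the direction-consistent overlap statistic.

    Built from two signed gene sets sharing one universe; ``fit`` runs the
    bootstrap and returns results carrying the observed overlap, the null
    distribution, and the empirical p-value.
    """

    def __init__(self, set_a: SignedGeneSet, set_b: SignedGeneSet) -> None:
        if set_a.universe != set_b.universe:
            raise UniverseMismatchError("gene universes differ")
        self.set_a = set_a
        self.set_b = set_b
        self.universe = sorted(set_a.universe)

    def observed(self) -> int:
        return directional_overlap(self.set_a, self.set_b)

    def fit(
        self,
        n_boot: int = 10_000,
        seed: int = 0,
        signs_a: Mapping[str, int] | None = None,
        signs_b: Mapping[str, int] | None = None,
    ) -> "OverlapBootstrapResults":
        """Run the bootstrap.

        ``signs_a`` / ``signs_b`` are the full per-cohort sign maps over the
        universe (from each cohort's complete DEG table).  If omitted, the
        member signs are used and non-member genes count as direction 0,
        i.e. never agreeing — supply the full maps for the faithful null.
        """
        sa = dict(signs_a) if signs_a is not None else {
            g: self.set_a.members.get(g, 0) for g in self.universe
        }
        sb = dict(signs_b) if signs_b is not None else {
            g: self.set_b.members.get(g, 0) for g in self.universe
        }
        obs = self.observed()
        null = bootstrap_null(
            self.universe,
            len(self.set_a),
            len(self.set_b),
            sa,
            sb,
            n_boot=n_boot,
            seed=seed,
        )
        result = OverlapResult(
            observed_overlap=obs,
            null_distribution=null,
            empirical_p=empirical_p(obs, null),
            n_boot=n_boot,
            seed=seed,
        )
        return OverlapBootstrapResults(self, result)


class OverlapBootstrapResults:
    """Results wrapper with summary and plotting."""

    def __init__(self, model: OverlapBootstrap, result: OverlapResult) -> None:
        self.model = model
        self.result = result

    @property
    def observed(self) -> int:
        return self.result.observed_overlap

    @property
    def null(self) -> np.ndarray:
        return self.result.null_distribution

    @property
    def pvalue(self) -> float:
        return self.result.empirical_p

    def summary(self) -> str:
        r = self.result
        lines = [
            "Direction-consistent DEG overlap, bootstrap null",
            "=" * 48,
            f"universe:           {len(self.model.universe)} genes",
            f"set A members:      {len(self.model.set_a)}",
            f"set B members:      {len(self.model.set_b)}",
            f"observed overlap:   {r.observed_overlap}",
            f"null mean (B={r.n_boot}): {np.mean(r.null_distribution):.2f}",
            f"empirical p:        {r.p_display}",
            f"seed:               {r.seed}",
        ]
        return "\n".join(lines)

    def plot_null(self, ax=None):
        """Histogram of the null with the observed overlap marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.null, bins="auto", color="0.7", edgecolor="0.4")
        ax.axvline(self.observed, color="crimson", lw=2, label="observed")
        ax.set_xlabel("direction-consistent overlap")
        ax.set_ylabel("replicates")
        ax.legend()
        return ax
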