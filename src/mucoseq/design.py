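"""Sample-design tables.

A design is a :class:`pandas.DataFrame` indexed by sample ID with the factor
columns ``cohort`` (e.g. SPF donor mice vs germ-free FMT recipients),
``treatment`` (PBS vs vancomycin), and optionally ``route`` (oral/IP) and
``role`` (donor/recipient).  The derived ``group`` column — the cohort ×
treatment combination — defines the four classes of the classification task
and the two-group contrasts of the differential-expression stage.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .exceptions import InvalidDesignError

REQUIRED_COLUMNS = ("cohort", "treatment")


def make_fmt_design(
    n_per_group: int = 7,
    cohorts: Sequence[str] = ("SPF", "GF"),
    treatments: Sequence[str] = ("PBS", "Van"),
    route: str = "oral",
) -> pd.DataFrame:
    """Build the fecal-microbiota-transplant study design.

    Donor mice (first cohort) are treated directly; recipient germ-free mice
    (second cohort) receive the corresponding donor microbiota.  Groups are
    named ``<cohort>_<treatment>`` and hold ``n_per_group`` samples each.
    """
    if n_per_group < 2:
        raise InvalidDesignError("need at least 2 samples per group")
    rows = []
    for cohort in cohorts:
        role = "donor" if cohort == cohorts[0] else "recipient"
        for treatment in treatments:
            for i in range(1, n_per_group + 1):
                rows.append(
                    {
                        "sample_id": f"{cohort}_{treatment}_{i}",
                        "cohort": cohort,
                        "treatment": treatment,
                        "route": route,
                        "role": role,
                    }
                )
    design = pd.DataFrame(rows).set_index("sample_id")
    design["group"] = group_labels(design)
    return design


def group_labels(design: pd.DataFrame) -> pd.Series:
    """Cohort × treatment group label per sample."""
    _check_columns(design)
    return design["cohort"].astype(str) + "_" + design["treatment"].astype(str)


def validate_design(design: pd.DataFrame, min_per_group: int = 2) -> pd.Series:
    """Validate factor columns and group sizes; return group labels.

    Raises
    ------
    InvalidDesignError
        If factor columns are missing, sample IDs are duplicated, or any
        group holds fewer than ``min_per_group`` samples.
    """
    _check_columns(design)
    if design.index.duplicated().any():
        dupes = design.index[design.index.duplicated()].unique().tolist()
        raise InvalidDesignError(f"duplicated sample IDs: {dupes}")
    groups = group_labels(design)
    sizes = groups.value_counts()
    small = sizes[sizes < min_per_group]
    if not small.empty:
        raise InvalidDesignError(
            f"groups below the minimum of {min_per_group} samples: "
            + ", ".join(f"{g} (n={n})" for g, n in small.items())
        )
    return groups


def _check_columns(design: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in design.columns]
    if missing:
        raise InvalidDesignError(f"design table lacks required columns: {missing}")
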