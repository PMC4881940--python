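"""Long-format twin cohort container and conversions.

A cohort is a pandas DataFrame with one row per individual x stage x
outcome and columns::

    family_id, zygosity, twin_index, sex, age, stage, outcome, value

(item-level frames add ``scale`` and ``item``).  ``validate_cohort`` checks
the structural invariants of the twin design; ``pair_matrix`` reshapes one
outcome into per-pair stacked stage vectors for likelihood work.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["COHORT_COLUMNS", "validate_cohort", "pair_matrix", "read_cohort_csv", "write_cohort_csv"]

COHORT_COLUMNS = ["family_id", "zygosity", "twin_index", "sex", "age", "stage", "outcome", "value"]


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check twin-design invariants; returns the frame for chaining.

    Enforced: required columns; zygosity in {MZ, DZ}; twin_index in {1, 2}
    with exactly two members per family; sex and age constant within a pair
    (same-sex design); stages in {1..4}; unique
    (family_id, twin_index, stage, outcome) keys.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort frame missing columns {missing}")
    if not df["zygosity"].isin(["MZ", "DZ"]).all():
        raise ValueError("zygosity must be 'MZ' or 'DZ'")
    if not df["twin_index"].isin([1, 2]).all():
        raise ValueError("twin_index must be 1 or 2")
    if not df["stage"].isin([1, 2, 3, 4]).all():
        raise ValueError("stage must be in 1..4")
    per_fam = df.groupby("family_id")["twin_index"].nunique()
    if not (per_fam == 2).all():
        bad = per_fam.index[per_fam != 2].tolist()[:5]
        raise ValueError(f"families without exactly two twins: {bad}")
    for col in ("sex", "age", "zygosity"):
        if (df.groupby("family_id")[col].nunique() > 1).any():
            raise ValueError(f"{col} must be identical within a twin pair")
    if df.duplicated(["family_id", "twin_index", "stage", "outcome"]).any():
        raise ValueError("duplicated (family_id, twin_index, stage, outcome) keys")
    return df


def pair_matrix(df: pd.DataFrame, outcome: str, zygosity: str, n_stages: int = 4) -> np.ndarray:
    """Per-pair stacked stage vectors for one outcome and zygosity group.

    Returns an ``(n_pairs, 2 * n_stages)`` array ordered twin 1 stages
    1..T then twin 2 stages 1..T, with NaN where a score is missing.
    """
    sub = df[(df["outcome"] == outcome) & (df["zygosity"] == zygosity)]
    if sub.empty:
        return np.empty((0, 2 * n_stages))
    wide = sub.pivot_table(
        index="family_id", columns=["twin_index", "stage"], values="value", aggfunc="first", dropna=False
    )
    full_cols = pd.MultiIndex.from_product([[1, 2], range(1, n_stages + 1)], names=["twin_index", "stage"])
    wide = wide.reindex(columns=full_cols)
    return wide.to_numpy(dtype=float)


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"family_id": str, "zygosity": str, "sex": str, "outcome": str},
    )
    return validate_cohort(df)
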