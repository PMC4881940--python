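"""Scale scoring, compositing, and pre-model transformations.

The processing order is fixed: (1) score each scale as the mean of its
items after reverse-keying, requiring at least half the items present;
(2) standardize each scale on its baseline moments and average pairs of
scales into the two composites (well-being = happiness + life satisfaction;
mental health = reversed depression + reversed anxiety symptoms); (3) apply
the van der Waerden rank-normal transform per stage to correct skew;
(4) residualize on age and sex and re-standardize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScaleSpec",
    "SCALES",
    "score_scale",
    "score_items_frame",
    "standardize_on_baseline",
    "build_composites",
    "van_der_waerden",
    "residualize_age_sex",
    "preprocess_cohort",
    "cronbach_alpha",
]


@dataclass(frozen=True)
class ScaleSpec:
    """Definition of a self-report scale: item count, response points, keying."""

    name: str
    n_items: int
    point_scale: int
    reverse_items: frozenset = frozenset()
    min_nonmissing_fraction: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "reverse_items", frozenset(self.reverse_items))
        if not self.reverse_items <= set(range(1, self.n_items + 1)):
            raise ValueError("reverse_items must be item indices in 1..n_items")
        if not 0 < self.min_nonmissing_fraction <= 1:
            raise ValueError("min_nonmissing_fraction must be in (0, 1]")


#: The four instruments: subjective happiness (SHS), brief multidimensional
#: student life satisfaction (BMSLSS), mood-and-feelings depression symptoms
#: (MFQ), and short state anxiety (STAI6).
SCALES = {
    "SHS": ScaleSpec("SHS", n_items=4, point_scale=7, reverse_items=frozenset({4})),
    "BMSLSS": ScaleSpec("BMSLSS", n_items=6, point_scale=7),
    "MFQ": ScaleSpec("MFQ", n_items=13, point_scale=3),
    "STAI6": ScaleSpec("STAI6", n_items=6, point_scale=4),
}

#: Symptom scales entering the mental-health composite with flipped sign so
#: higher composite values mean fewer symptoms.
REVERSED_COMPOSITE_SCALES = {"MFQ", "STAI6"}

COMPOSITES = {"wellbeing": ("SHS", "BMSLSS"), "mentalhealth": ("MFQ", "STAI6")}


def score_scale(item_responses, spec: ScaleSpec) -> float:
    """Mean-of-items score with reverse-keying and a 50% presence rule.

    ``item_responses`` is a length-``n_items`` vector in 1..point_scale with
    NaN for missing.  Returns NaN when fewer than
    ``min_nonmissing_fraction`` of the items are present.
    """
    v = np.asarray(item_responses, dtype=float)
    if v.shape != (spec.n_items,):
        raise ValueError(f"expected {spec.n_items} responses for {spec.name}, got shape {v.shape}")
    present = ~np.isnan(v)
    vals = v[present]
    if np.any((vals < 1) | (vals > spec.point_scale)) or np.any(vals != np.round(vals)):
        raise ValueError(f"responses must be integers in 1..{spec.point_scale}")
    if present.sum() < spec.min_nonmissing_fraction * spec.n_items:
        return float("nan")
    keyed = v.copy()
    for i in spec.reverse_items:
        keyed[i - 1] = spec.point_scale + 1 - keyed[i - 1]
    return float(np.nanmean(keyed))


def score_items_frame(items: pd.DataFrame) -> pd.DataFrame:
    """Score an item-level cohort frame into a score-level cohort frame.

    Expects the cohort columns plus ``scale`` and ``item`` with ``value``
    holding item responses; emits one row per individual-stage-scale with
    ``outcome`` = scale name and ``value`` = scale score.
    """
    id_cols = ["family_id", "zygosity", "twin_index", "sex", "age", "stage", "scale"]
    out = []
    for keys, grp in items.groupby(id_cols, sort=False):
        spec = SCALES[keys[-1]]
        resp = np.full(spec.n_items, np.nan)
        resp[grp["item"].to_numpy(dtype=int) - 1] = grp["value"].to_numpy(dtype=float)
        out.append((*keys[:-1], keys[-1], score_scale(resp, spec)))
    return pd.DataFrame(out, columns=id_cols[:-1] + ["outcome", "value"])


def standardize_on_baseline(df: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Standardize every stage of each outcome by its baseline moments.

    All four stages are transformed as ``(x - m1) / s1`` where ``m1, s1``
    are the stage-1 mean and SD of that outcome, so the baseline column has
    mean 0 and SD 1 and later-stage shifts are expressed in baseline SD
    units.
    """
    df = df.copy()
    for outcome, grp in df.groupby("outcome"):
        base = grp.loc[grp["stage"] == 1, value_col]
        m, s = base.mean(), base.std(ddof=1)
        if not np.isfinite(s) or s == 0:
            raise ValueError(f"degenerate baseline SD for outcome {outcome!r}")
        df.loc[grp.index, value_col] = (grp[value_col] - m) / s
    return df


def build_composites(scores: pd.DataFrame) -> pd.DataFrame:
    """Average baseline-standardized scale pairs into the two composites.

    Symptom scales are negated after standardization (sign flip commutes
    with standardization), so higher composite values always denote greater
    well-being or fewer symptoms.  A composite is emitted only where both
    constituent scales are present at that stage.
    """
    std = standardize_on_baseline(scores)
    std.loc[std["outcome"].isin(REVERSED_COMPOSITE_SCALES), "value"] *= -1.0
    frames = []
    for comp, (s1, s2) in COMPOSITES.items():
        wide = std[std["outcome"].isin([s1, s2])].pivot_table(
            index=["family_id", "zygosity", "twin_index", "sex", "age", "stage"],
            columns="outcome",
            values="value",
            aggfunc="first",
            dropna=False,
        )
        if s1 not in wide.columns or s2 not in wide.columns:
            continue
        val = (wide[s1] + wide[s2]) / 2.0
        out = val.reset_index().rename(columns={0: "value"})
        out["outcome"] = comp
        frames.append(out[["family_id", "zygosity", "twin_index", "sex", "age", "stage", "outcome", "value"]])
    return pd.concat(frames, ignore_index=True)


def van_der_waerden(values) -> np.ndarray:
    """Rank-based inverse normal (van der Waerden) transform.

    Value with average rank ``r`` among ``n`` non-missing observations maps
    to ``Φ⁻¹(r / (n + 1))``; ties share their average rank and missing
    values propagate.  All-equal input returns zeros (degenerate ranks).
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    mask = ~np.isnan(v)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("van der Waerden transform needs at least 3 non-missing values")
    vals = v[mask]
    if np.all(vals == vals[0]):
        import warnings

        warnings.warn("all values identical; van der Waerden scores are all zero", RuntimeWarning)
        out[mask] = 0.0
        return out
    ranks = stats.rankdata(vals, method="average")
    out[mask] = stats.norm.ppf(ranks / (n + 1))
    return out


def residualize_age_sex(values, age, sex) -> np.ndarray:
    """OLS residuals of score on age and sex, re-standardized to mean 0, SD 1.

    ``sex`` may be 'M'/'F' or numeric binary.  Missing scores propagate;
    covariates must be complete where the score is present.
    """
    v = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if sex.dtype.kind in "OUS":
        sex = (sex == "F").astype(float)
    sex = sex.astype(float)
    mask = ~np.isnan(v)
    if mask.sum() < 3:
        raise ValueError("need at least 3 complete cases")
    X = np.column_stack([np.ones(mask.sum()), age[mask], sex[mask]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear or constant age/sex covariates")
    beta, *_ = np.linalg.lstsq(X, v[mask], rcond=None)
    resid = v[mask] - X @ beta
    sd = resid.std(ddof=1)
    if sd < 1e-12:
        raise ValueError("degenerate residual variance after age/sex correction")
    out = np.full(v.shape, np.nan)
    out[mask] = (resid - resid.mean()) / sd
    return out


def preprocess_cohort(
    cohort: pd.DataFrame,
    rank_normalize: bool = True,
    correct_age_sex: bool = True,
    per_stage_transform: bool = True,
) -> pd.DataFrame:
    """Full pre-model pipeline on a score-level cohort frame.

    When the frame holds raw scale scores (outcomes named as in ``SCALES``)
    the two composites are built first; a frame already holding composite
    scores passes straight to the transforms.  The van der Waerden
    transform is applied per outcome (per stage by default) and the age/sex
    residualization pools all individuals per outcome-stage.
    """
    if set(cohort["outcome"]).issuperset(SCALES):
        df = build_composites(cohort)
    else:
        df = cohort.copy()
    group_cols = ["outcome", "stage"] if per_stage_transform else ["outcome"]
    if rank_normalize:
        for _, idx in df.groupby(group_cols).groups.items():
            df.loc[idx, "value"] = van_der_waerden(df.loc[idx, "value"])
    if correct_age_sex:
        for _, idx in df.groupby(["outcome", "stage"]).groups.items():
            sub = df.loc[idx]
            df.loc[idx, "value"] = residualize_age_sex(sub["value"], sub["age"], sub["sex"])
    return df


def cronbach_alpha(items: np.ndarray) -> float:
    """Internal-consistency utility: alpha for an (n, k) item-response matrix."""
    items = np.asarray(items, dtype=float)
    items = items[~np.isnan(items).any(axis=1)]
    k = items.shape[1]
    item_vars = items.var(axis=0, ddof=1).sum()
    total_var = items.sum(axis=1).var(ddof=1)
    return k / (k - 1) * (1 - item_vars / total_var)
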