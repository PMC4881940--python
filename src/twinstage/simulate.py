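"""Seeded simulation of twin intervention cohorts.

Pairs are drawn jointly: each pair's eight stage scores (two twins x four
stages) come from one multivariate-normal draw with the exact covariance
implied by the Cholesky ACE loadings, which makes the simulated moments
converge to the closed-form pair covariance with no approximation error
beyond sampling noise.  Means follow the intervention trajectory plus age
and sex effects; ages are shared within a pair and truncated to a
plausible adolescent range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS, validate_cohort
from .params import CholeskyACEParams, MeanTrajectory, theoretical_pair_covariance
from .preprocess import SCALES, ScaleSpec

__all__ = ["simulate_cohort", "simulate_pair_scores", "simulate_items", "apply_missingness"]

AGE_RANGE = (14.0, 19.0)


def simulate_pair_scores(
    n_pairs: int, params: CholeskyACEParams, zygosity: str, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean (n_pairs, 2T) latent deviations for one zygosity group."""
    cov = theoretical_pair_covariance(params, zygosity)
    # Cholesky with a tiny jitter fallback for PSD-but-singular structures.
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    z = rng.standard_normal((n_pairs, cov.shape[0]))
    return z @ L.T


def _truncated_normal(rng, n, mean, sd, lo, hi):
    out = np.empty(n)
    remaining = np.arange(n)
    while remaining.size:
        draw = rng.normal(mean, sd, remaining.size)
        ok = (draw >= lo) & (draw <= hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def simulate_cohort(
    n_mz: int,
    n_dz: int,
    params: CholeskyACEParams,
    trajectory: MeanTrajectory,
    age_mean: float = 16.55,
    age_sd: float = 0.51,
    female_fraction: float = 0.58,
    seed: int = 0,
    outcome: str = "wellbeing",
) -> pd.DataFrame:
    """Simulate a long-format cohort of same-sex twin pairs.

    Emits ``2 * (n_mz + n_dz)`` individuals x 4 stages for one outcome.
    The age effect is centred at ``age_mean`` so ``trajectory.baseline_mean``
    stays the expected baseline score of an average-aged male.  Identical
    inputs and seed reproduce the frame exactly.
    """
    if n_mz < 1 or n_dz < 1:
        raise ValueError("need at least one pair per zygosity group")
    if not 0 <= female_fraction <= 1:
        raise ValueError("female_fraction must be in [0, 1]")
    params.validate_nondegenerate()
    if params.n_stages != 4:
        raise ValueError("cohort simulation requires four-stage parameters")
    rng = np.random.default_rng(seed)

    rows = []
    stage_means = trajectory.stage_means()
    pair_counter = 0
    for zyg, n_pairs in (("MZ", n_mz), ("DZ", n_dz)):
        dev = simulate_pair_scores(n_pairs, params, zyg, rng)
        ages = _truncated_normal(rng, n_pairs, age_mean, age_sd, *AGE_RANGE)
        female = rng.random(n_pairs) < female_fraction
        for i in range(n_pairs):
            fam = f"{zyg}{pair_counter + i + 1:05d}"
            sex = "F" if female[i] else "M"
            mu = (
                stage_means
                + trajectory.age_effect * (ages[i] - age_mean)
                + (trajectory.sex_effect if female[i] else 0.0)
            )
            for twin in (1, 2):
                scores = mu + dev[i, (twin - 1) * 4 : twin * 4]
                for s in range(4):
                    rows.append((fam, zyg, twin, sex, ages[i], s + 1, outcome, scores[s]))
        pair_counter += n_pairs
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return validate_cohort(df)


def simulate_items(
    cohort: pd.DataFrame, scale: str | ScaleSpec, loading: float = 0.85, seed: int = 0
) -> pd.DataFrame:
    """Ordinal item responses from latent scores by graded thresholding.

    Each item's latent value is ``loading * z + sqrt(1 - loading²) * noise``
    where ``z`` is the individual's (standardized) latent score; responses
    are the count of equally spaced thresholds (spanning ±2.5 latent SD)
    that the item latent exceeds, plus one.  Reverse-keyed items are
    emitted flipped, so scoring with reverse-keying recovers a monotone
    transform of the latent score.  Missing latents propagate.
    """
    spec = SCALES[scale] if isinstance(scale, str) else scale
    if not 0 <= loading <= 1:
        raise ValueError("loading must be in [0, 1]")
    rng = np.random.default_rng(seed)
    # latent scores are taken as-is on the (approximately standardized)
    # latent scale; thresholds span ±2.5 latent SD
    z = cohort["value"].to_numpy(dtype=float)
    n = z.size
    thresholds = np.linspace(-2.5, 2.5, spec.point_scale - 1)
    noise_sd = np.sqrt(max(0.0, 1.0 - loading**2))
    frames = []
    for item in range(1, spec.n_items + 1):
        latent = loading * z + noise_sd * rng.standard_normal(n)
        resp = 1.0 + (latent[:, None] > thresholds[None, :]).sum(axis=1)
        if item in spec.reverse_items:
            resp = spec.point_scale + 1 - resp
        resp[np.isnan(z)] = np.nan
        f = cohort.drop(columns=["outcome", "value"]).copy()
        f["scale"] = spec.name
        f["item"] = item
        f["value"] = resp
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def apply_missingness(cohort: pd.DataFrame, rate_per_stage, seed: int = 0) -> pd.DataFrame:
    """MCAR missingness: drop each individual-stage score with a per-stage rate.

    An individual's scores at a stage are set missing together across
    outcomes, mimicking a skipped assessment occasion.
    """
    rates = np.asarray(rate_per_stage, dtype=float)
    if rates.shape != (4,) or np.any(rates < 0) or np.any(rates >= 1):
        raise ValueError("rate_per_stage must be four proportions in [0, 1)")
    rng = np.random.default_rng(seed)
    df = cohort.copy()
    keys = df[["family_id", "twin_index", "stage"]].drop_duplicates().sort_values(
        ["family_id", "twin_index", "stage"], kind="stable"
    )
    u = rng.random(len(keys))
    keys = keys.assign(_drop=u < rates[keys["stage"].to_numpy() - 1])
    df = df.merge(keys, on=["family_id", "twin_index", "stage"], how="left")
    df.loc[df["_drop"], "value"] = np.nan
    return df.drop(columns="_drop")
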