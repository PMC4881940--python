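"""Cholesky ACE parameterization and implied twin-pair covariance.

The classical twin design decomposes phenotypic variance into additive
genetic (A), shared environmental (C), and non-shared environmental (E)
components.  For repeated measures across ``T`` stages, each component is
modeled with a triangular factor structure: factor ``j`` loads only on
stages ``j..T``, so its diagonal loading captures variance newly arising
("innovation") at stage ``j`` and its sub-diagonal loadings capture
transmission of that variance to later stages.

Pairs are stacked as 2T-vectors (twin 1 stages, then twin 2 stages).  The
within-twin covariance is ``Λa Λaᵀ + Λc Λcᵀ + Λe Λeᵀ``; the cross-twin
covariance is ``r·Λa Λaᵀ + Λc Λcᵀ`` with the kinship coefficient ``r = 1``
for monozygotic (MZ) and ``r = 0.5`` for dizygotic (DZ) pairs, and no
cross-twin E covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CholeskyACEParams",
    "MeanTrajectory",
    "proportions_to_loadings",
    "theoretical_pair_covariance",
]

#: Genetic correlation between members of a pair, by zygosity.
KINSHIP = {"MZ": 1.0, "DZ": 0.5}


def _as_lower_triangular(m, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {m.shape}")
    if not np.allclose(m, np.tril(m)):
        raise ValueError(f"{name} must be lower-triangular (factor j loads only on stages >= j)")
    return np.tril(m)


@dataclass(frozen=True)
class CholeskyACEParams:
    """Lower-triangular factor loadings for the A, C and E components.

    Each matrix is ``T x T`` with columns indexing factors (A1..AT etc.) and
    rows indexing stages.  ``T`` is 4 for the four-stage design
    (baseline / control / intervention / follow-up) and 1 for univariate
    models.
    """

    lambda_a: np.ndarray
    lambda_c: np.ndarray
    lambda_e: np.ndarray

    def __post_init__(self):
        la = _as_lower_triangular(self.lambda_a, "lambda_a")
        lc = _as_lower_triangular(self.lambda_c, "lambda_c")
        le = _as_lower_triangular(self.lambda_e, "lambda_e")
        if not (la.shape == lc.shape == le.shape):
            raise ValueError("lambda_a, lambda_c, lambda_e must share one shape")
        object.__setattr__(self, "lambda_a", la)
        object.__setattr__(self, "lambda_c", lc)
        object.__setattr__(self, "lambda_e", le)

    @property
    def n_stages(self) -> int:
        return self.lambda_a.shape[0]

    def component_covariances(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Implied A, C and E covariance matrices (ΛΛᵀ for each block)."""
        return (
            self.lambda_a @ self.lambda_a.T,
            self.lambda_c @ self.lambda_c.T,
            self.lambda_e @ self.lambda_e.T,
        )

    def total_variances(self) -> np.ndarray:
        """Phenotypic variance per stage: row sums of squared loadings."""
        return (self.lambda_a**2 + self.lambda_c**2 + self.lambda_e**2).sum(axis=1)

    def validate_nondegenerate(self) -> None:
        tv = self.total_variances()
        if np.any(tv <= 0):
            bad = np.flatnonzero(tv <= 0) + 1
            raise ValueError(f"zero total variance at stage(s) {bad.tolist()}")


def proportions_to_loadings(
    a_props, c_props, e_props
) -> CholeskyACEParams:
    """Convert a standardized-contribution table to loadings.

    Reported twin tables give squared standardized contributions (proportions
    of phenotypic variance); the generator is parameterized by loadings, so
    each entry is mapped by element-wise square root with all signs positive.

    Parameters are lower-triangular ``T x T`` arrays of proportions (entry
    ``(i, j)`` = contribution of factor ``j`` to stage ``i``).
    """
    mats = []
    for name, p in (("a", a_props), ("c", c_props), ("e", e_props)):
        p = np.asarray(p, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError(f"{name} proportions must lie in [0, 1]")
        mats.append(np.sqrt(np.tril(p)))
    return CholeskyACEParams(*mats)


def theoretical_pair_covariance(params: CholeskyACEParams, zygosity: str) -> np.ndarray:
    """Exact 2T x 2T covariance of a twin pair's stacked stage scores.

    Ordering: twin 1 stages 1..T, then twin 2 stages 1..T.  The matrix is
    symmetric positive semi-definite by construction.
    """
    if zygosity not in KINSHIP:
        raise ValueError(f"zygosity must be 'MZ' or 'DZ', got {zygosity!r}")
    r = KINSHIP[zygosity]
    cov_a, cov_c, cov_e = params.component_covariances()
    within = cov_a + cov_c + cov_e
    cross = r * cov_a + cov_c
    return np.block([[within, cross], [cross, within]])


@dataclass(frozen=True)
class MeanTrajectory:
    """Mean structure of the four-occasion design.

    The expected score at stage ``s`` (occasion coding ``time = 0..3``,
    ``time2 = 0, 0, 1, 2``) is::

        baseline_mean + control_increment * time + intervention_increment * time2
        + age_effect * (age - age centre) + sex_effect * [sex == F]

    so the trajectory is flat through the control period when
    ``control_increment`` is 0 and rises once the positive-activity
    intervention starts.  ``stage_times`` records the assessment weeks for
    provenance; model time is in occasion units.
    """

    baseline_mean: float = 0.0
    control_increment: float = 0.0
    intervention_increment: float = 0.0
    age_effect: float = 0.0
    sex_effect: float = 0.0
    stage_times: tuple = (1.0, 4.0, 7.0, 10.0)

    def __post_init__(self):
        st = tuple(float(t) for t in self.stage_times)
        if len(st) != 4 or any(b <= a for a, b in zip(st, st[1:])):
            raise ValueError("stage_times must be four strictly increasing values")
        object.__setattr__(self, "stage_times", st)

    def stage_means(self) -> np.ndarray:
        """Expected score per stage for an average-aged male individual."""
        time = np.arange(4.0)
        time2 = np.array([0.0, 0.0, 1.0, 2.0])
        return self.baseline_mean + self.control_increment * time + self.intervention_increment * time2
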