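"""Twin variance-component estimation.

Implements the classical twin-design estimators in increasing order of
machinery:

* one-way random-effects intraclass correlations (ICCs) per zygosity group,
* Falconer moment estimates ``a² = 2(rMZ − rDZ)``, ``c² = 2rDZ − rMZ``,
  ``e² = 1 − rMZ``,
* maximum-likelihood univariate ACE fits on pair scores,
* the four-stage triangular (Cholesky) ACE decomposition separating
  variance transmitted from earlier stages from innovations arising at each
  stage, with profile-likelihood confidence intervals.

All ML fits maximize the two-group Gaussian pair likelihood.  Pairs are
grouped by missingness pattern and summarized by per-pattern sufficient
statistics (count, mean, scatter), so each likelihood evaluation costs
O(patterns), independent of cohort size; stage means (common to both twins
and zygosity groups) are profiled out in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .cohort import pair_matrix
from .params import KINSHIP, CholeskyACEParams, theoretical_pair_covariance

__all__ = [
    "ICCEstimate",
    "FalconerEstimate",
    "ACEFit",
    "VarianceComponentsTable",
    "icc_anova",
    "intraclass_correlation",
    "falconer_estimates",
    "fit_univariate_ace",
    "fit_cholesky_ace",
    "fit_ace_pairs",
    "standardize_components",
    "stage_specific_proportion",
    "likelihood_ci",
]

_LOG_2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Descriptive estimators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCEstimate:
    """Twin intraclass correlations per zygosity group with pair counts."""

    r_mz: float
    r_dz: float
    n_mz_pairs: int
    n_dz_pairs: int
    p_mz: float
    p_dz: float


def icc_anova(pairs: np.ndarray) -> tuple[float, int, float]:
    """One-way random-effects ICC for an (n_pairs, 2) array of pair scores.

    Returns ``(icc, n_complete_pairs, p_value)`` where the p-value is the
    one-sided F test of between-pair variance (df ``n-1``, ``n``).  Pairs
    with either member missing are excluded.  A negative ICC (within-pair
    mean square exceeding between) is returned as computed.
    """
    y = np.asarray(pairs, dtype=float)
    y = y[~np.isnan(y).any(axis=1)]
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    pair_means = y.mean(axis=1)
    grand = y.mean()
    msb = 2.0 * np.sum((pair_means - grand) ** 2) / (n - 1)
    msw = np.sum((y - pair_means[:, None]) ** 2) / n
    icc = (msb - msw) / (msb + msw)
    p = float(stats.f.sf(msb / msw, n - 1, n)) if msw > 0 else 0.0
    return float(icc), n, p


def intraclass_correlation(cohort: pd.DataFrame, outcome: str, stage: int) -> ICCEstimate:
    """ICCs for both zygosity groups at one stage of one outcome."""
    res = {}
    for zyg in ("MZ", "DZ"):
        wide = pair_matrix(cohort, outcome, zyg)
        cols = [stage - 1, 4 + stage - 1]
        res[zyg] = icc_anova(wide[:, cols])
    return ICCEstimate(
        r_mz=res["MZ"][0],
        r_dz=res["DZ"][0],
        n_mz_pairs=res["MZ"][1],
        n_dz_pairs=res["DZ"][1],
        p_mz=res["MZ"][2],
        p_dz=res["DZ"][2],
    )


@dataclass(frozen=True)
class FalconerEstimate:
    """Moment estimates of the standardized A, C, E components.

    The identity ``a2 + c2 + e2 = 1`` holds exactly; estimates outside
    [0, 1] are returned as computed and flagged via ``out_of_bounds``.
    """

    a2: float
    c2: float
    e2: float

    @property
    def out_of_bounds(self) -> bool:
        return not all(0.0 <= x <= 1.0 for x in (self.a2, self.c2, self.e2))

    def truncated(self) -> "FalconerEstimate":
        """Clamp each component to [0, 1] and renormalize to sum 1."""
        vals = np.clip([self.a2, self.c2, self.e2], 0.0, 1.0)
        vals = vals / vals.sum()
        return FalconerEstimate(*vals)


def falconer_estimates(r_mz: float, r_dz: float) -> FalconerEstimate:
    """Classical twin moment estimators from the two intraclass correlations.

    Heritability is twice the MZ-DZ correlation difference; the shared
    environment is the MZ correlation minus heritability; the non-shared
    environment (including measurement error) is one minus the MZ
    correlation.
    """
    for r in (r_mz, r_dz):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    a2 = 2.0 * (r_mz - r_dz)
    c2 = r_mz - a2
    e2 = 1.0 - r_mz
    return FalconerEstimate(a2=a2, c2=c2, e2=e2)


# ---------------------------------------------------------------------------
# Two-group Gaussian pair likelihood with pattern-wise sufficient statistics
# ---------------------------------------------------------------------------


@dataclass
class _PatternStats:
    obs: np.ndarray  # observed indices into the 2T pair vector
    n: int
    ybar: np.ndarray
    scatter: np.ndarray  # MLE scatter (denominator n)


def _pattern_stats(y: np.ndarray, mode: str) -> list[_PatternStats]:
    y = np.asarray(y, dtype=float)
    if mode == "complete":
        y = y[~np.isnan(y).any(axis=1)]
        if y.shape[0] == 0:
            return []
        ybar = y.mean(axis=0)
        d = y - ybar
        return [_PatternStats(np.arange(y.shape[1]), y.shape[0], ybar, d.T @ d / y.shape[0])]
    if mode != "fiml":
        raise ValueError("mode must be 'complete' or 'fiml'")
    mask = ~np.isnan(y)
    out = []
    codes = mask @ (1 << np.arange(y.shape[1]))
    for code in np.unique(codes):
        if code == 0:
            continue
        rows = y[codes == code]
        obs = np.flatnonzero(mask[codes == code][0])
        sub = rows[:, obs]
        ybar = sub.mean(axis=0)
        d = sub - ybar
        out.append(_PatternStats(obs, sub.shape[0], ybar, d.T @ d / sub.shape[0]))
    return out


class _TwoGroupObjective:
    """−2·loglik of the two-group pair model as a function of loadings.

    The parameter vector stacks the lower-triangular entries (row-major) of
    Λa, Λc, Λe.  Stage means, repeated across twins and shared between
    groups, are profiled out exactly at every evaluation.
    """

    def __init__(self, y_mz: np.ndarray, y_dz: np.ndarray, n_stages: int, mode: str = "complete"):
        self.n_stages = n_stages
        self.tril = np.tril_indices(n_stages)
        self.n_load = len(self.tril[0])
        self.stats = {"MZ": _pattern_stats(y_mz, mode), "DZ": _pattern_stats(y_dz, mode)}
        for zyg, st in self.stats.items():
            if not st:
                raise ValueError(f"no usable {zyg} pairs")
        # Stage-mean design: pair index -> stage index (twin-stacked).
        self.stage_of = np.tile(np.arange(n_stages), 2)

    def params_from_theta(self, theta: np.ndarray) -> CholeskyACEParams:
        t = self.n_stages
        mats = []
        for k in range(3):
            m = np.zeros((t, t))
            m[self.tril] = theta[k * self.n_load : (k + 1) * self.n_load]
            mats.append(m)
        return CholeskyACEParams(*mats)

    def theta_from_params(self, params: CholeskyACEParams) -> np.ndarray:
        return np.concatenate(
            [params.lambda_a[self.tril], params.lambda_c[self.tril], params.lambda_e[self.tril]]
        )

    def neg2ll_and_means(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        params = self.params_from_theta(theta)
        cov_a, cov_c, cov_e = params.component_covariances()
        within = cov_a + cov_c + cov_e
        pieces = []
        A = np.zeros((self.n_stages, self.n_stages))
        b = np.zeros(self.n_stages)
        val = 0.0
        for zyg, st_list in self.stats.items():
            cross = KINSHIP[zyg] * cov_a + cov_c
            sigma = np.block([[within, cross], [cross, within]])
            for st in st_list:
                sig = sigma[np.ix_(st.obs, st.obs)]
                try:
                    L = np.linalg.cholesky(sig)
                    if np.any(np.diag(L) <= 0):
                        raise np.linalg.LinAlgError
                    l_inv = solve_triangular(L, np.eye(L.shape[0]), lower=True, check_finite=False)
                except np.linalg.LinAlgError:
                    return np.inf, np.zeros(self.n_stages)
                logdet = 2.0 * np.log(np.diag(L)).sum()
                inv = l_inv.T @ l_inv
                d = st.obs.size
                val += st.n * (d * _LOG_2PI + logdet + float(np.sum(inv * st.scatter)))
                # design rows mapping stage means onto this pattern
                R = np.zeros((d, self.n_stages))
                R[np.arange(d), self.stage_of[st.obs]] = 1.0
                RtI = R.T @ inv
                A += st.n * (RtI @ R)
                b += st.n * (RtI @ st.ybar)
                pieces.append((st, inv, R))
        try:
            means = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            means = np.zeros(self.n_stages)
        for st, inv, R in pieces:
            resid = st.ybar - R @ means
            val += st.n * float(resid @ inv @ resid)
        return val, means

    def __call__(self, theta: np.ndarray) -> float:
        return self.neg2ll_and_means(theta)[0]

    # -- starting values ----------------------------------------------------

    def _empirical_blocks(self):
        """Pairwise-complete empirical within/cross covariance blocks per group."""
        t = self.n_stages
        blocks = {}
        for zyg, st_list in self.stats.items():
            # reconstruct a pooled covariance estimate from pattern stats
            num = np.zeros((2 * t, 2 * t))
            den = np.zeros((2 * t, 2 * t))
            for st in st_list:
                ix = np.ix_(st.obs, st.obs)
                num[ix] += st.n * (st.scatter + np.outer(st.ybar, st.ybar))
                den[ix] += st.n
            mean_num = np.zeros(2 * t)
            mean_den = np.zeros(2 * t)
            for st in st_list:
                mean_num[st.obs] += st.n * st.ybar
                mean_den[st.obs] += st.n
            mu = mean_num / np.maximum(mean_den, 1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = num / np.maximum(den, 1) - np.outer(mu, mu)
            cov[den == 0] = 0.0
            w = 0.5 * (cov[:t, :t] + cov[t:, t:])
            c = 0.5 * (cov[:t, t:] + cov[:t, t:].T)
            blocks[zyg] = (0.5 * (w + w.T), c)
        return blocks

    def start_theta(self) -> np.ndarray:
        """Method-of-moments loadings from empirical covariance blocks."""
        blocks = self._empirical_blocks()
        w = 0.5 * (blocks["MZ"][0] + blocks["DZ"][0])
        b_mz, b_dz = blocks["MZ"][1], blocks["DZ"][1]
        cov_a = 2.0 * (b_mz - b_dz)
        cov_c = 2.0 * b_dz - b_mz
        cov_e = w - b_mz
        thetas = []
        for cov, floor in ((cov_a, 1e-4), (cov_c, 1e-4), (cov_e, 1e-3)):
            cov = 0.5 * (cov + cov.T)
            vals, vecs = np.linalg.eigh(cov)
            scale = max(np.max(np.abs(vals)), 1.0)
            cov = vecs @ np.diag(np.clip(vals, floor * scale, None)) @ vecs.T
            L = np.linalg.cholesky(cov)
            thetas.append(L[self.tril])
        return np.concatenate(thetas)

    def bounds(self):
        """Λe diagonal bounded away from zero keeps the pair covariance PD."""
        lb = np.full(3 * self.n_load, -np.inf)
        ub = np.full(3 * self.n_load, np.inf)
        diag_pos = np.flatnonzero(self.tril[0] == self.tril[1])
        lb[2 * self.n_load + diag_pos] = 1e-6
        return optimize.Bounds(lb, ub)


def _canonical_signs(params: CholeskyACEParams) -> CholeskyACEParams:
    """Resolve per-column sign indeterminacy: nonnegative diagonals."""
    mats = []
    for m in (params.lambda_a, params.lambda_c, params.lambda_e):
        m = m.copy()
        for j in range(m.shape[1]):
            if m[j, j] < 0:
                m[:, j] *= -1.0
        mats.append(m)
    return CholeskyACEParams(*mats)


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponentsTable:
    """Standardized per-stage contributions of each triangular factor.

    ``point`` is a tidy frame with columns ``component`` (A/C/E), ``factor``
    (1..T), ``stage`` (1..T), ``value``; entries exist only for
    ``factor <= stage`` (the triangular zero pattern).  ``totals`` sums
    factors per component and stage.  ``ci`` optionally maps
    ``(component, factor_or_'total', stage)`` to ``(lo, hi)``.
    """

    point: pd.DataFrame
    totals: pd.DataFrame
    ci: dict = field(default_factory=dict)

    def contribution(self, component: str, factor: int, stage: int) -> float:
        sel = self.point.query("component == @component and factor == @factor and stage == @stage")
        if sel.empty:
            return 0.0
        return float(sel["value"].iloc[0])

    def total(self, component: str, stage: int) -> float:
        sel = self.totals.query("component == @component and stage == @stage")
        return float(sel["value"].iloc[0])

    def to_wide(self, decimals: int | None = None) -> pd.DataFrame:
        """Report-shaped frame: rows A1..E_total, columns stages, CI strings."""
        t = int(self.point["stage"].max())
        rows = []
        index = []
        for comp in ("A", "C", "E"):
            for f in range(1, t + 1):
                index.append(f"{comp}{f}")
                rows.append(
                    [self._cell(comp, f, s, decimals) if f <= s else "" for s in range(1, t + 1)]
                )
            index.append(f"{comp}_total")
            rows.append([self._cell(comp, "total", s, decimals) for s in range(1, t + 1)])
        return pd.DataFrame(rows, index=index, columns=[f"stage{s}" for s in range(1, t + 1)])

    def _cell(self, comp, factor, stage, decimals):
        v = self.total(comp, stage) if factor == "total" else self.contribution(comp, factor, stage)
        if decimals is not None:
            v = round(v, decimals)
        key = (comp, factor, stage)
        if key in self.ci:
            lo, hi = self.ci[key]
            # conventional table style drops the leading zero in CI bounds
            return f"{v:.2f} ({f'{lo:.2f}'.lstrip('0')}-{f'{hi:.2f}'.lstrip('0')})"
        return f"{v:.2f}" if decimals is not None else v


def standardize_components(params: CholeskyACEParams) -> VarianceComponentsTable:
    """Squared loadings as proportions of each stage's phenotypic variance."""
    params.validate_nondegenerate()
    tv = params.total_variances()
    t = params.n_stages
    rows = []
    for comp, lam in (("A", params.lambda_a), ("C", params.lambda_c), ("E", params.lambda_e)):
        for stage in range(1, t + 1):
            for factor in range(1, stage + 1):
                rows.append((comp, factor, stage, lam[stage - 1, factor - 1] ** 2 / tv[stage - 1]))
    point = pd.DataFrame(rows, columns=["component", "factor", "stage", "value"])
    totals = point.groupby(["component", "stage"], as_index=False)["value"].sum()
    return VarianceComponentsTable(point=point, totals=totals)


def stage_specific_proportion(table, component: str, stage: int) -> float:
    """Share of a component's variance at a stage arising at that stage.

    The stage's own (diagonal) factor contribution divided by the summed
    contributions of factors 1..stage — e.g. E contributions (.22, .06, .20)
    at stage 3 give .20/.48 ≈ 0.42, the fraction of non-shared environmental
    influence specific to the intervention stage.  ``table`` may be a
    :class:`VarianceComponentsTable` or a sequence of the contributions of
    factors 1..stage.
    """
    if isinstance(table, VarianceComponentsTable):
        contribs = [table.contribution(component, f, stage) for f in range(1, stage + 1)]
    else:
        contribs = list(np.asarray(table, dtype=float))
        if len(contribs) != stage:
            raise ValueError(f"expected {stage} contributions for stage {stage}")
    denom = float(np.sum(contribs))
    if denom <= 0:
        raise ValueError("component total at this stage is zero")
    return float(contribs[stage - 1] / denom)


@dataclass
class ACEFit:
    """A converged two-group ACE maximum-likelihood fit."""

    params: CholeskyACEParams
    loglik: float
    n_free_parameters: int
    converged: bool
    components: VarianceComponentsTable
    stage_means: np.ndarray
    n_pairs: dict
    objective: _TwoGroupObjective = field(repr=False)
    theta: np.ndarray = field(repr=False)


def fit_ace_pairs(
    y_mz: np.ndarray,
    y_dz: np.ndarray,
    n_stages: int,
    mode: str = "complete",
    restarts: int = 5,
    seed: int = 0,
    drop_a: bool = False,
    tol: float = 1e-8,
) -> ACEFit:
    """Fit the ACE model to per-pair stacked stage vectors.

    ``y_mz`` / ``y_dz`` are ``(n_pairs, 2 * n_stages)`` arrays (twin 1
    stages then twin 2 stages).  ``drop_a`` fixes all genetic loadings at
    zero (the CE submodel used by likelihood-ratio tests).  Multiple
    seeded restarts jitter the method-of-moments start to guard against
    local optima; convergence is assessed on the best restart.
    """
    obj = _TwoGroupObjective(y_mz, y_dz, n_stages, mode=mode)
    bounds = obj.bounds()
    n_load = obj.n_load
    fixed_a = np.zeros(0, dtype=int)
    if drop_a:
        fixed_a = np.arange(n_load)

    free = np.setdiff1d(np.arange(3 * n_load), fixed_a)

    def restricted(theta_free):
        theta = np.zeros(3 * n_load)
        theta[free] = theta_free
        return obj(theta)

    start = obj.start_theta()
    rng = np.random.default_rng(seed)
    scale = max(np.abs(start).mean(), 0.1)
    best = None
    for k in range(max(1, restarts)):
        x0 = start[free] if k == 0 else start[free] + rng.normal(0, 0.3 * scale, free.size)
        res = optimize.minimize(
            restricted,
            x0,
            method="L-BFGS-B",
            bounds=optimize.Bounds(bounds.lb[free], bounds.ub[free]),
            options={"maxiter": 2000, "ftol": tol, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = np.zeros(3 * n_load)
    theta[free] = best.x
    neg2ll, means = obj.neg2ll_and_means(theta)
    params = _canonical_signs(obj.params_from_theta(theta))
    theta = obj.theta_from_params(params)
    n_free = free.size + n_stages  # loadings plus profiled stage means
    return ACEFit(
        params=params,
        loglik=-0.5 * neg2ll,
        n_free_parameters=n_free,
        converged=bool(best.success),
        components=standardize_components(params),
        stage_means=means,
        n_pairs={z: sum(st.n for st in obj.stats[z]) for z in ("MZ", "DZ")},
        objective=obj,
        theta=theta,
    )


def _stage_pairs(cohort: pd.DataFrame, outcome: str, stage: int):
    out = []
    for zyg in ("MZ", "DZ"):
        wide = pair_matrix(cohort, outcome, zyg)
        out.append(wide[:, [stage - 1, 4 + stage - 1]])
    return out


def fit_univariate_ace(
    cohort: pd.DataFrame,
    stage: int,
    outcome: str = "wellbeing",
    restarts: int = 5,
    seed: int = 0,
    min_pairs: int = 20,
) -> ACEFit:
    """Single-stage ACE fit on complete pairs at one assessment occasion."""
    y_mz, y_dz = _stage_pairs(cohort, outcome, stage)
    for name, y in (("MZ", y_mz), ("DZ", y_dz)):
        if (~np.isnan(y).any(axis=1)).sum() < min_pairs:
            raise ValueError(f"fewer than {min_pairs} complete {name} pairs at stage {stage}")
    return fit_ace_pairs(y_mz, y_dz, n_stages=1, mode="complete", restarts=restarts, seed=seed)


def fit_cholesky_ace(
    cohort: pd.DataFrame,
    outcome: str = "wellbeing",
    mode: str = "fiml",
    restarts: int = 5,
    seed: int = 0,
    min_pairs: int = 20,
) -> ACEFit:
    """Four-stage triangular ACE decomposition of one outcome.

    ``mode='fiml'`` (default) uses each pair's observed sub-vector of the
    eight stage scores; ``mode='complete'`` restricts to fully observed
    pairs as a cross-check.
    """
    y_mz = pair_matrix(cohort, outcome, "MZ")
    y_dz = pair_matrix(cohort, outcome, "DZ")
    for name, y in (("MZ", y_mz), ("DZ", y_dz)):
        if (~np.isnan(y).all(axis=1)).sum() < min_pairs:
            raise ValueError(f"fewer than {min_pairs} usable {name} pairs")
    return fit_ace_pairs(y_mz, y_dz, n_stages=4, mode=mode, restarts=restarts, seed=seed)


# ---------------------------------------------------------------------------
# Profile-likelihood confidence intervals
# ---------------------------------------------------------------------------


def _quantity_value(fit: ACEFit, component: str, factor, stage: int, theta: np.ndarray) -> float:
    params = fit.objective.params_from_theta(theta)
    table = standardize_components(params)
    if factor == "total":
        return table.total(component, stage)
    return table.contribution(component, int(factor), stage)


def likelihood_ci(
    fit: ACEFit,
    component: str,
    factor,
    stage: int,
    level: float = 0.95,
    tol: float = 5e-3,
) -> tuple[float, float]:
    """Profile-likelihood interval for a standardized contribution or total.

    Finds the values of the quantity where the profiled deviance
    ``2(loglik_max − loglik_profile)`` crosses the χ²₁ critical value,
    using a quadratic-penalty profile refit; bounds are clamped to [0, 1],
    the admissible range of a standardized quantity, so boundary estimates
    report .00 (or 1.00) endpoints.
    """
    crit = stats.chi2.ppf(level, 1)
    obj = fit.objective
    theta_hat = fit.theta.copy()
    f_min = obj(theta_hat)
    q_hat = _quantity_value(fit, component, factor, stage, theta_hat)

    def zero_constrained_deviance() -> float:
        """Exact profile at the quantity's zero boundary: fix the loadings
        that feed it at zero and reoptimize the rest."""
        comp_offset = {"A": 0, "C": obj.n_load, "E": 2 * obj.n_load}[component]
        row, col = obj.tril
        if factor == "total":
            fixed = comp_offset + np.flatnonzero(row == stage - 1)
        else:
            fixed = comp_offset + np.flatnonzero((row == stage - 1) & (col == factor - 1))
        free = np.setdiff1d(np.arange(3 * obj.n_load), fixed)
        bounds = obj.bounds()

        def restricted(tf):
            th = np.zeros(3 * obj.n_load)
            th[free] = tf
            return obj(th)

        res = optimize.minimize(
            restricted,
            theta_hat[free],
            method="L-BFGS-B",
            bounds=optimize.Bounds(bounds.lb[free], bounds.ub[free]),
            options={"maxiter": 2000, "ftol": 1e-10},
        )
        return res.fun - f_min

    bounds = obj.bounds()

    def quantity(th):
        return _quantity_value(fit, component, factor, stage, th)

    def deviance_at(v: float, theta_start: np.ndarray) -> tuple[float, np.ndarray]:
        """Constrained profile fit at quantity = v (SLSQP; penalty fallback)."""
        best = None
        try:
            res = optimize.minimize(
                obj,
                theta_start,
                method="SLSQP",
                bounds=list(zip(bounds.lb, bounds.ub)),
                constraints=[{"type": "eq", "fun": lambda th: quantity(th) - v}],
                options={"maxiter": 500, "ftol": 1e-10},
            )
            if np.isfinite(res.fun) and abs(quantity(res.x) - v) < 1e-5:
                best = res
        except (ValueError, np.linalg.LinAlgError):
            pass
        if best is None:
            theta = theta_hat.copy()
            for w in (1e4, 1e6, 1e8):
                pen = optimize.minimize(
                    lambda th: obj(th) + w * (quantity(th) - v) ** 2,
                    theta,
                    method="Nelder-Mead",
                    options={"maxiter": 6000, "fatol": 1e-10, "xatol": 1e-8},
                )
                theta = pen.x
            return obj(theta) - f_min, theta
        return best.fun - f_min, best.x

    def solve_bound(direction: int) -> float:
        limit = 1.0 if direction > 0 else 0.0
        # check whether the deviance at the admissible limit stays below crit
        if limit == 0.0:
            dev_limit = zero_constrained_deviance()
        else:
            dev_limit, _ = deviance_at(limit, theta_hat)
        if dev_limit <= crit:
            return limit
        # bisect between the estimate (deviance 0) and the limit
        a, b = q_hat, limit
        theta = theta_hat
        for _ in range(40):
            mid = 0.5 * (a + b)
            dev, theta = deviance_at(mid, theta)
            if dev > crit:
                b = mid
            else:
                a = mid
            if abs(b - a) < tol:
                break
        return 0.5 * (a + b)

    lo = solve_bound(-1)
    hi = solve_bound(+1)
    lo = min(lo, q_hat)
    hi = max(hi, q_hat)
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))
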