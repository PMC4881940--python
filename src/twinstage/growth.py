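"""Multilevel growth models for mean intervention response.

Repeated measures are nested within individuals, and individuals within
twin pairs.  The piecewise model codes occasions 0..3 with a second time
variable (0, 0, 1, 2) that activates at the start of the positive-activity
intervention, so its slope captures the additional per-occasion change from
the intervention onward::

    y = γ00 + γ10·time + γ20·time2
        + u_pair + b0 + b1·time + b2·time2 + ε

with a pair-level random intercept ``u_pair``, correlated individual-level
random intercept and slope(s) ``b``, and iid residuals.  The unconditional
model fixes γ20 = 0 and drops the time2 random slope.  Estimation is full
maximum likelihood: the marginal Gaussian likelihood of each pair's stacked
observation vector (up to 8 values) is maximized over the variance
parameters with the fixed effects profiled out by generalized least
squares, and pairs sharing an observation pattern are collapsed to
sufficient statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TIME_CODES",
    "build_time_codes",
    "GrowthFit",
    "fit_growth",
    "compare_growth_models",
    "predicted_trajectory",
]

_LOG_2PI = np.log(2.0 * np.pi)


def _solve_triangular(L: np.ndarray) -> np.ndarray:
    """Inverse of a lower-triangular Cholesky factor (raises if singular)."""
    from scipy.linalg import solve_triangular

    if np.any(np.diag(L) <= 0) or not np.all(np.isfinite(L)):
        raise np.linalg.LinAlgError("singular covariance")
    return solve_triangular(L, np.eye(L.shape[0]), lower=True, check_finite=False)

#: Occasion coding per stage: time counts occasions from baseline, time2
#: counts occasions since the intervention began.
TIME_CODES = {1: (0.0, 0.0), 2: (1.0, 0.0), 3: (2.0, 1.0), 4: (3.0, 2.0)}


def build_time_codes(stages) -> pd.DataFrame:
    """Deterministic (time, time2) codes for the given stages."""
    stages = list(stages)
    bad = [s for s in stages if s not in TIME_CODES]
    if bad:
        raise ValueError(f"unknown stage(s) {bad}; stages are 1..4")
    return pd.DataFrame(
        [(s, *TIME_CODES[s]) for s in stages], columns=["stage", "time", "time2"]
    )


@dataclass
class GrowthFit:
    model: str  # 'unconditional' | 'piecewise'
    gamma: np.ndarray  # fixed effects (γ00, γ10[, γ20])
    se: np.ndarray
    cov_gamma: np.ndarray
    tau_pair: float  # pair-level intercept variance
    G: np.ndarray  # individual-level random-effect covariance
    sigma2: float  # residual variance
    loglik: float
    n_free_parameters: int
    n_observations: int
    n_pairs: int
    converged: bool
    objective: object = field(repr=False, default=None)

    @property
    def gamma_00(self) -> float:
        return float(self.gamma[0])

    @property
    def gamma_10(self) -> float:
        return float(self.gamma[1])

    @property
    def gamma_20(self) -> float:
        return float(self.gamma[2]) if self.gamma.size > 2 else 0.0

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_free_parameters

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_free_parameters * np.log(self.n_observations)

    def t_table(self) -> pd.DataFrame:
        """Fixed-effect t statistics with residual df = n_obs − n_fixed."""
        df = self.n_observations - self.gamma.size
        t = self.gamma / self.se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        names = ["gamma_00", "gamma_10", "gamma_20"][: self.gamma.size]
        return pd.DataFrame({"estimate": self.gamma, "se": self.se, "t": t, "df": df, "p": p}, index=names)


class _GrowthObjective:
    """Profiled −2·loglik over variance parameters, pattern-collapsed."""

    def __init__(self, data: pd.DataFrame, model: str, value_col: str = "value"):
        if model not in ("unconditional", "piecewise"):
            raise ValueError("model must be 'unconditional' or 'piecewise'")
        self.model = model
        self.q = 3 if model == "piecewise" else 2  # fixed effects
        self.r = 3 if model == "piecewise" else 2  # individual RE dimension

        d = data.dropna(subset=[value_col]).copy()
        codes = d["stage"].map(TIME_CODES)
        d["time"] = codes.str[0]
        d["time2"] = codes.str[1]
        self.n_observations = len(d)
        # pattern = ordered tuple of (twin_index, stage) observed in the pair
        patterns: dict[tuple, list] = {}
        for fam, grp in d.groupby("family_id", sort=True):
            grp = grp.sort_values(["twin_index", "stage"], kind="stable")
            key = tuple(zip(grp["twin_index"], grp["stage"]))
            patterns.setdefault(key, []).append(grp[value_col].to_numpy(dtype=float))
        self.n_pairs = sum(len(v) for v in patterns.values())
        self.patterns = []
        for key, ys in patterns.items():
            Y = np.array(ys)
            n, dsize = Y.shape
            ybar = Y.mean(axis=0)
            resid = Y - ybar
            scatter = resid.T @ resid / n
            twins = np.array([k[0] for k in key])
            t = np.array([TIME_CODES[k[1]][0] for k in key])
            t2 = np.array([TIME_CODES[k[1]][1] for k in key])
            X = np.column_stack([np.ones(dsize), t, t2])[:, : self.q]
            Z = np.column_stack([np.ones(dsize), t, t2])[:, : self.r]
            same_twin = (twins[:, None] == twins[None, :]).astype(float)
            self.patterns.append(
                {"n": n, "ybar": ybar, "S": scatter, "X": X, "Z": Z, "same": same_twin, "d": dsize}
            )

    # variance parameter vector: [tau_sd, vech(chol G) (diag first per column,
    # row-major lower triangle), sigma]
    @property
    def n_varparams(self) -> int:
        return 1 + self.r * (self.r + 1) // 2 + 1

    def unpack(self, v: np.ndarray):
        tau = v[0] ** 2
        L = np.zeros((self.r, self.r))
        L[np.tril_indices(self.r)] = v[1 : 1 + self.r * (self.r + 1) // 2]
        G = L @ L.T
        sigma2 = v[-1] ** 2
        return tau, G, sigma2

    def pair_cov(self, pat, tau: float, G: np.ndarray, sigma2: float) -> np.ndarray:
        Z = pat["Z"]
        V = tau + (Z @ G @ Z.T) * pat["same"]
        return V + sigma2 * np.eye(pat["d"])

    def neg2ll_and_gls(self, v: np.ndarray):
        tau, G, sigma2 = self.unpack(v)
        A = np.zeros((self.q, self.q))
        b = np.zeros(self.q)
        pieces = []
        val = 0.0
        for pat in self.patterns:
            V = self.pair_cov(pat, tau, G, sigma2)
            try:
                L = np.linalg.cholesky(V)
                l_inv = _solve_triangular(L)
            except np.linalg.LinAlgError:
                return np.inf, np.zeros(self.q), None
            logdet = 2.0 * np.log(np.diag(L)).sum()
            inv = l_inv.T @ l_inv
            n, X = pat["n"], pat["X"]
            val += n * (pat["d"] * _LOG_2PI + logdet + float(np.sum(inv * pat["S"])))
            XtI = X.T @ inv
            A += n * (XtI @ X)
            b += n * (XtI @ pat["ybar"])
            pieces.append((pat, inv, X))
        try:
            gamma = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(self.q), None
        for pat, inv, X in pieces:
            r = pat["ybar"] - X @ gamma
            val += pat["n"] * float(r @ inv @ r)
        return val, gamma, np.linalg.inv(A)

    def __call__(self, v: np.ndarray) -> float:
        return self.neg2ll_and_gls(v)[0]

    def neg2ll_at(self, gamma: np.ndarray, v: np.ndarray) -> float:
        """−2·loglik at explicit fixed effects (for oracle cross-checks)."""
        tau, G, sigma2 = self.unpack(v)
        val = 0.0
        for pat in self.patterns:
            V = self.pair_cov(pat, tau, G, sigma2)
            sign, logdet = np.linalg.slogdet(V)
            inv = np.linalg.inv(V)
            r = pat["ybar"] - pat["X"] @ gamma
            val += pat["n"] * (
                pat["d"] * _LOG_2PI + logdet + float(np.sum(inv * pat["S"])) + float(r @ inv @ r)
            )
        return val


def fit_growth(
    data: pd.DataFrame,
    model: str = "piecewise",
    outcome: str | None = None,
    value_col: str = "value",
    min_individuals: int = 50,
) -> GrowthFit:
    """Fit the multilevel growth model by full maximum likelihood.

    ``data`` is a long composite table with columns ``family_id``,
    ``twin_index``, ``stage`` and ``value`` (optionally filtered to one
    ``outcome``).  Boundary solutions (a variance pinned at zero) are
    returned with ``converged`` still reporting optimizer success; the
    random-effects covariance is PSD by its Cholesky parameterization.
    """
    if outcome is not None:
        data = data[data["outcome"] == outcome]
    counts = data.dropna(subset=[value_col]).groupby(["family_id", "twin_index"])["stage"].nunique()
    if (counts >= 2).sum() < min_individuals:
        raise ValueError(f"need >= 2 occasions for >= {min_individuals} individuals")
    obj = _GrowthObjective(data, model, value_col=value_col)

    y_sd = float(np.nanstd(data[value_col]))
    nv = obj.n_varparams
    # row-major lower-triangle layout puts diagonal (j, j) at offset j(j+3)/2
    diag_idx = [0] + [1 + j * (j + 3) // 2 for j in range(obj.r)] + [nv - 1]
    # start: split variance evenly across pair, individual intercept, residual
    v0 = np.zeros(nv)
    v0[0] = 0.4 * y_sd
    tril = np.tril_indices(obj.r)
    start_L = np.zeros((obj.r, obj.r))
    start_L[0, 0] = 0.5 * y_sd
    for j in range(1, obj.r):
        start_L[j, j] = 0.1 * y_sd
    v0[1 : 1 + tril[0].size] = start_L[tril]
    v0[-1] = max(0.6 * y_sd, 1e-3)

    lb = np.full(nv, -np.inf)
    for i in diag_idx:
        lb[i] = 0.0
    lb[-1] = 1e-8
    res = optimize.minimize(
        obj, v0, method="L-BFGS-B", bounds=optimize.Bounds(lb, np.full(nv, np.inf)),
        options={"maxiter": 2000, "ftol": 1e-12},
    )
    # polish with Nelder-Mead in case L-BFGS-B stalls on a boundary
    res2 = optimize.minimize(obj, res.x, method="Nelder-Mead", options={"maxiter": 4000, "fatol": 1e-10})
    best = res2 if res2.fun < res.fun else res
    neg2ll, gamma, cov_gamma = obj.neg2ll_and_gls(best.x)
    tau, G, sigma2 = obj.unpack(best.x)
    k = obj.q + 1 + obj.r * (obj.r + 1) // 2 + 1
    return GrowthFit(
        model=model,
        gamma=gamma,
        se=np.sqrt(np.diag(cov_gamma)),
        cov_gamma=cov_gamma,
        tau_pair=tau,
        G=G,
        sigma2=sigma2,
        loglik=-0.5 * neg2ll,
        n_free_parameters=k,
        n_observations=obj.n_observations,
        n_pairs=obj.n_pairs,
        converged=bool(res.success or res2.success),
        objective=obj,
    )


def compare_growth_models(fit_a: GrowthFit, fit_b: GrowthFit) -> dict:
    """Fit comparison: Δloglik, LRT (nested fits), ΔAIC, ΔBIC, verdicts.

    ``fit_a`` is the simpler model.  The models are treated as nested when
    fitted to identical data with ``fit_a`` having fewer parameters (the
    unconditional model is the piecewise model with γ20 and its random
    slope removed); LRT df is the difference in free parameters.
    """
    if fit_a.n_observations != fit_b.n_observations:
        raise ValueError("fits must be on identical data (n_observations differ)")
    d_ll = fit_b.loglik - fit_a.loglik
    df = fit_b.n_free_parameters - fit_a.n_free_parameters
    nested = df > 0
    lrt = 2.0 * d_ll if nested else np.nan
    p = float(stats.chi2.sf(lrt, df)) if nested and df > 0 else np.nan
    d_aic = fit_b.aic - fit_a.aic
    d_bic = fit_b.bic - fit_a.bic
    verdict = {
        "lrt": ("b" if nested and p < 0.05 else "a" if nested else "n/a"),
        "aic": "b" if d_aic < 0 else ("a" if d_aic > 0 else "tie"),
        "bic": "b" if d_bic < 0 else ("a" if d_bic > 0 else "tie"),
    }
    if abs(d_ll) < 1e-12 and df == 0:
        verdict = {"lrt": "tie", "aic": "tie", "bic": "tie"}
    return {
        "delta_loglik": d_ll,
        "lrt": lrt,
        "lrt_df": df,
        "lrt_p": p,
        "nested": nested,
        "delta_aic": d_aic,
        "delta_bic": d_bic,
        "preferred": verdict,
    }


def predicted_trajectory(fit: GrowthFit) -> pd.DataFrame:
    """Model-predicted mean at each stage from the fixed effects."""
    rows = []
    for stage, (t, t2) in TIME_CODES.items():
        rows.append((stage, t, t2, fit.gamma_00 + fit.gamma_10 * t + fit.gamma_20 * t2))
    return pd.DataFrame(rows, columns=["stage", "time", "time2", "predicted_mean"])
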