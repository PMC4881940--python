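#!/usr/bin/env python
"""Twin variance-component analyses of the processed cohort.

For each outcome composite: intraclass correlations per zygosity group and
stage (with pair counts), Falconer moment estimates, per-stage univariate
ACE maximum-likelihood fits, the four-stage Cholesky ACE decomposition
(full-information likelihood over partially observed pairs), and the
derived stage-specific innovation proportions.  Writes the report tables
under results/."""

from pathlib import Path

import pandas as pd

from twinstage import (
    falconer_estimates,
    fit_cholesky_ace,
    fit_univariate_ace,
    intraclass_correlation,
    stage_specific_proportion,
)
from twinstage.cohort import read_cohort_csv

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260920


def main():
    processed = read_cohort_csv(OUT / "processed.csv")
    outcomes = sorted(processed["outcome"].unique())

    icc_rows, fal_rows, uni_rows, ssp_rows = [], [], [], []
    for outcome in outcomes:
        for stage in (1, 2, 3, 4):
            est = intraclass_correlation(processed, outcome, stage)
            icc_rows.append({"outcome": outcome, "stage": stage,
                             "r_mz": round(est.r_mz, 2), "n_mz": est.n_mz_pairs,
                             "r_dz": round(est.r_dz, 2), "n_dz": est.n_dz_pairs,
                             "p_mz": est.p_mz, "p_dz": est.p_dz})
            f = falconer_estimates(est.r_mz, est.r_dz)
            fal_rows.append({"outcome": outcome, "stage": stage,
                             "a2": round(f.a2, 2), "c2": round(f.c2, 2), "e2": round(f.e2, 2)})
            fit = fit_univariate_ace(processed, stage, outcome, seed=SEED)
            uni_rows.append({"outcome": outcome, "stage": stage,
                             "a2": round(fit.components.total("A", 1), 2),
                             "c2": round(fit.components.total("C", 1), 2),
                             "e2": round(fit.components.total("E", 1), 2),
                             "loglik": round(fit.loglik, 2)})

        chol = fit_cholesky_ace(processed, outcome, mode="fiml", seed=SEED)
        chol.components.to_wide(decimals=2).to_csv(OUT / f"components_{outcome}.csv")
        for comp in ("A", "C", "E"):
            for stage in (2, 3, 4):
                ssp_rows.append({"outcome": outcome, "component": comp, "stage": stage,
                                 "stage_specific": round(
                                     stage_specific_proportion(chol.components, comp, stage), 3)})
        print(f"\n=== {outcome}: standardized Cholesky ACE components ===")
        print(chol.components.to_wide(decimals=2))
        e3 = stage_specific_proportion(chol.components, "E", 3)
        print(f"E innovation share at the intervention stage: {100 * e3:.0f}%")

    for name, rows in (("icc_table", icc_rows), ("falconer", fal_rows),
                       ("univariate_ace", uni_rows), ("stage_specific", ssp_rows)):
        pd.DataFrame(rows).to_csv(OUT / f"{name}.csv", index=False)
    print("\nICC summary:")
    print(pd.DataFrame(icc_rows).drop(columns=["p_mz", "p_dz"]).to_string(index=False))
    print(f"\nwrote icc_table / falconer / univariate_ace / components_* / stage_specific under {OUT}")


if __name__ == "__main__":
    main()
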