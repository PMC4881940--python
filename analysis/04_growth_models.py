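#!/usr/bin/env python
"""Mean intervention response: unconditional vs piecewise multilevel
growth models per outcome composite, their comparison, and the
model-predicted stage trajectories.  Writes growth_fits.csv,
growth_comparison.csv and predicted_trajectory.csv under results/."""

from pathlib import Path

import pandas as pd

from twinstage import compare_growth_models, fit_growth, predicted_trajectory
from twinstage.cohort import read_cohort_csv

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    composites = read_cohort_csv(OUT / "composites.csv")
    fit_rows, cmp_rows, traj = [], [], []
    for outcome in sorted(composites["outcome"].unique()):
        sub = composites[composites["outcome"] == outcome]
        uncond = fit_growth(sub, "unconditional")
        piece = fit_growth(sub, "piecewise")
        for fit in (uncond, piece):
            fit_rows.append({"outcome": outcome, "model": fit.model,
                             "gamma_00": round(fit.gamma_00, 4), "gamma_10": round(fit.gamma_10, 4),
                             "gamma_20": round(fit.gamma_20, 4),
                             "loglik": round(fit.loglik, 2), "aic": round(fit.aic, 2),
                             "bic": round(fit.bic, 2), "n_parameters": fit.n_free_parameters,
                             "n_observations": fit.n_observations})
        comp = compare_growth_models(uncond, piece)
        cmp_rows.append({"outcome": outcome, "lrt": round(comp["lrt"], 2), "df": comp["lrt_df"],
                         "p": comp["lrt_p"], "delta_aic": round(comp["delta_aic"], 2),
                         "preferred_by_lrt": comp["preferred"]["lrt"]})
        t = predicted_trajectory(piece)
        t.insert(0, "outcome", outcome)
        traj.append(t)
        tt = piece.t_table()
        print(f"\n=== {outcome} (piecewise) ===")
        print(tt.round(4).to_string())
        print(f"piecewise preferred over unconditional: LRT={comp['lrt']:.1f} "
              f"(df={comp['lrt_df']}, p={comp['lrt_p']:.2g})")

    pd.DataFrame(fit_rows).to_csv(OUT / "growth_fits.csv", index=False)
    pd.DataFrame(cmp_rows).to_csv(OUT / "growth_comparison.csv", index=False)
    pd.concat(traj, ignore_index=True).to_csv(OUT / "predicted_trajectory.csv", index=False)
    print(f"\nwrote growth_fits / growth_comparison / predicted_trajectory under {OUT}")


if __name__ == "__main__":
    main()
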