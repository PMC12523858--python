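#!/usr/bin/env python
"""Survival-curve pipeline: simulate trial-scale arms, digitize, reconstruct,
fit the seven parametric families, and rank them by AIC/BIC.

Patient-level trial data are not public, so this driver demonstrates the
reconstruction/fitting pipeline on synthetic arms drawn from the published
base-case log-logistic models (CPS >= 5), at trial scale (~250 per arm) with
administrative censoring at 30 months and 10% dropout.  It verifies that

* the Guyot-style reconstruction reproduces the digitized curve, and
* the generating family ranks at/near the top of the information-criteria
  table, mirroring the published choice of log-logistic base-case models.

Outputs: results/fit_ranking_<arm>_<endpoint>.csv, results/reconstructed_ipd.csv
"""

import numpy as np
import pandas as pd

import psmcea as P

OUT = "results"
SEED = 20240901

arms = {
    ("intervention", "os"): ("loglogistic", (1.904, 16.860)),
    ("intervention", "pfs"): ("loglogistic", (2.212, 9.015)),
    ("comparator", "os"): ("loglogistic", (2.004, 13.331)),
    ("comparator", "pfs"): ("loglogistic", (2.445, 7.305)),
}

all_ipd = []
for i, ((arm, endpoint), (family, params)) in enumerate(arms.items()):
    truth = P.ParametricSurvival(family, params)
    ipd = P.simulate_ipd(
        P.SimulationRecipe(
            model=truth, n=250, cutoff_months=30.0, dropout_fraction=0.10,
            arm=f"{arm}_{endpoint}", seed=SEED + i,
        )
    )
    fixture = P.make_km_fixture(ipd, np.arange(0.0, 31.0, 3.0))
    rebuilt = P.reconstruct_ipd(fixture)
    all_ipd.append(rebuilt)

    km_in, km_out = P.km_estimate(ipd), P.km_estimate(rebuilt)

    def at(km, x):
        idx = np.searchsorted(km[:, 0], x, side="right") - 1
        return km[max(idx, 0), 1]

    max_err = max(abs(at(km_in, g) - at(km_out, g)) for g in fixture.risk_table[:, 0])

    fits = [P.fit_parametric(rebuilt, f) for f in P.FAMILIES]
    table = P.information_criteria(fits)
    table.to_csv(f"{OUT}/fit_ranking_{arm}_{endpoint}.csv", index=False)

    best = table.iloc[0]["family"]
    rank_true = int(np.flatnonzero(table["family"] == family)[0]) + 1
    print(
        f"{arm} {endpoint}: KM round-trip max error {max_err:.4f}; "
        f"best-AIC family {best}; generating family ({family}) ranks #{rank_true}"
    )

pd.concat(all_ipd).to_csv(f"{OUT}/reconstructed_ipd.csv", index=False)
print(f"wrote fit rankings and reconstructed pseudo-IPD under {OUT}/")
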