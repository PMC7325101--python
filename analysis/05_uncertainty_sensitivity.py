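#!/usr/bin/env python
"""Monte Carlo uncertainty and the accelerometer-adjustment sensitivity run.

Propagates uncertainty in the relative risks (log scale) and survey
prevalences (logit scale) through 1000 paired 7-year runs, then repeats the
2006-vs-2012 comparison with a synthetic stand-in for accelerometer-adjusted
prevalences (self-report scaled up 1.5x, the adjustment magnitude reported
for comparable instruments; the published Mexican adjustment equation is an
external input this analysis does not have).  Writes both tables under
results/.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np

from piburden import (
    apply_accelerometer_adjustment,
    compare_scenarios,
    flat_scenario,
    generate_inputs,
    run_monte_carlo,
)
from piburden.config import RunConfig, write_results
from piburden.synthetic_data import PIPrevalenceTable

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 12345
HORIZON = 7
N_DRAWS = 1000


def synthetic_adjusted(table: PIPrevalenceTable) -> PIPrevalenceTable:
    """Synthetic accelerometer-adjusted prevalences: self-report scaled 1.5x."""
    d = table.data.copy()
    for col in ("prevalence", "ci_low", "ci_high"):
        d[col] = np.clip(d[col] * 1.5, 0.0, 1.0)
    return PIPrevalenceTable(d)


def main() -> None:
    bundle = generate_inputs(seed=SEED, scale=1.0)
    base = flat_scenario(bundle.pi_prevalence, 2006, "ensanut2006", bundle.base_year, HORIZON)
    alt = flat_scenario(bundle.pi_prevalence, 2012, "ensanut2012", bundle.base_year, HORIZON)

    summary = run_monte_carlo(
        bundle, base, alt, n_draws=N_DRAWS, seed=SEED, horizon=HORIZON
    )
    write_results(summary, OUT, RunConfig(seed=SEED, n_draws=N_DRAWS))
    print(f"Monte Carlo ({N_DRAWS} draws), mean increase ± SE per outcome:")
    print(summary.to_frame().to_string())

    adjusted = apply_accelerometer_adjustment(
        bundle.pi_prevalence, synthetic_adjusted(bundle.pi_prevalence)
    )
    bundle_adj = replace(bundle, pi_prevalence=adjusted)
    base_a = flat_scenario(adjusted, 2006, "adj2006", bundle.base_year, HORIZON)
    alt_a = flat_scenario(adjusted, 2012, "adj2012", bundle.base_year, HORIZON)
    d_adj = compare_scenarios(bundle_adj, base_a, alt_a, HORIZON)
    d_unadj = compare_scenarios(bundle, base, alt, HORIZON)

    print("\nSensitivity: synthetic accelerometer-adjusted prevalences "
          "(increases vs the unadjusted run):")
    tab = d_adj.summary_table().rename(columns={"increase": "adjusted_increase"})
    tab["unadjusted_increase"] = d_unadj.summary_table()["increase"]
    print(tab.to_string())
    tab.to_csv(OUT / "sensitivity_accelerometer_adjusted.csv", index_label="outcome")


if __name__ == "__main__":
    main()
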