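#!/usr/bin/env python
"""Build the model inputs: packaged survey fixtures plus a synthetic bundle.

Writes the physical-inactivity prevalence table (with its recomputed
percent-change column), the published seven-year projection table, and a
summary of the synthetic input bundle (population and base rates by sex and
age band) under results/.
"""

from pathlib import Path

import pandas as pd

from piburden import generate_inputs, load_pi_prevalence_fixture, load_projection_fixture
from piburden.ontology import AGE_BANDS, SEXES
from piburden.scenario_engine import relative_prevalence_change

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 12345

def main() -> None:
    OUT.mkdir(exist_ok=True)

    prev = load_pi_prevalence_fixture()
    rows = []
    for band in ("35-44", "45-54", "55-64", "total"):
        p06 = prev.get("both", band, 2006)
        p12 = prev.get("both", band, 2012)
        change = relative_prevalence_change(p06.prevalence, p12.prevalence)
        rows.append((band, p06.prevalence, p12.prevalence, change, int(p12.printed_pct_change)))
    table = pd.DataFrame(
        rows, columns=["age_band", "prev_2006", "prev_2012", "pct_change", "printed"]
    )
    table.to_csv(OUT / "pi_prevalence_change.csv", index=False)
    print("Physical-inactivity prevalence, 2006 -> 2012 (recomputed % change):")
    print(table.to_string(index=False))
    assert (table["pct_change"] == table["printed"]).all(), "fixture arithmetic broken"

    load_projection_fixture().to_csv(OUT / "published_projection_fixture.csv")

    bundle = generate_inputs(seed=SEED, scale=1.0)
    rows = []
    for s, sex in enumerate(SEXES):
        for a, band in enumerate(AGE_BANDS):
            rows.append(
                (sex, band, round(bundle.population[s, a]),
                 bundle.base_rates.t2d[s, a], bundle.base_rates.chd[s, a],
                 bundle.base_rates.stroke[s, a], bundle.base_rates.non_cvd_death[s, a])
            )
    summary = pd.DataFrame(
        rows,
        columns=["sex", "age_band", "population", "t2d_rate", "chd_rate",
                 "stroke_rate", "non_cvd_death_rate"],
    )
    summary.to_csv(OUT / "synthetic_bundle_summary.csv", index=False)
    print(f"\nSynthetic bundle (seed {SEED}): "
          f"{bundle.population.sum():,.0f} persons aged 35-94; "
          f"baseline inactive share 35-64 matches the 2006 survey fixture.")


if __name__ == "__main__":
    main()
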