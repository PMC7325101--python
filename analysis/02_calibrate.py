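#!/usr/bin/env python
"""Calibrate model rates to base-year event/death targets.

With no national registry counts available, targets are synthesized from
the model itself under known multipliers (drawn in [0.7, 1.4]) — so the
loop's ability to recover them is directly checkable.  Writes the fitted
factors, the convergence trace and a recovery summary under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from piburden import generate_calibration_targets, generate_inputs
from piburden.calibration import calibrate

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 12345


def main() -> None:
    OUT.mkdir(exist_ok=True)
    bundle = generate_inputs(seed=SEED, scale=1.0)
    rng = np.random.default_rng(SEED + 1)
    true = rng.uniform(0.7, 1.4, size=(2, 6, 4))
    targets = generate_calibration_targets(bundle, true)
    result = calibrate(bundle, targets, tol=0.01)

    df = result.to_frame()
    df["true_factor"] = true.reshape(-1)
    df["recovery_error"] = np.abs(df.factor - df.true_factor) / df.true_factor
    df.to_csv(OUT / "calibration_factors.csv", index=False)
    pd.DataFrame(
        {"iteration": range(len(result.trace)), "max_relative_residual": result.trace}
    ).to_csv(OUT / "calibration_trace.csv", index=False)

    print(f"Calibration converged in {result.n_iter} iterations; "
          f"max residual {result.residual:.2%} (tolerance 1%).")
    print(f"Worst factor-recovery error: {df.recovery_error.max():.2%} "
          f"across {len(df)} sex x age-band x stream factors.")


if __name__ == "__main__":
    main()
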