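"""Monte Carlo propagation of input uncertainty through paired runs.

Each draw perturbs the log relative risks and the logit inactivity
prevalences by standard-normal multiples of their standard errors (the two
input families with published confidence intervals), re-runs the paired
scenario comparison, and records every outcome delta.  Transformed-scale
sampling keeps relative risks positive and prevalences inside (0, 1).
Draws use counter-based substreams of a single seed, so results are
bit-identical across repeats and independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ArgumentError, ConfigError
from .ontology import OUTCOMES
from .risk_engine import RelativeRisk
from .scenario_engine import ScenarioSpec, compare_scenarios
from .synthetic_data import InputBundle

__all__ = ["MonteCarloSummary", "ci_to_se", "run_monte_carlo"]

_Z95 = 1.959964


def ci_to_se(ci_low: float, ci_high: float, scale: str = "natural") -> float:
    """Standard error implied by a 95% CI on the chosen scale.

    ``se = (g(ci_high) − g(ci_low)) / (2 × 1.96)`` with ``g`` identity,
    ``log`` or ``logit``.
    """
    if not ci_low < ci_high:
        raise ArgumentError("ci_low must be strictly below ci_high")
    if scale == "natural":
        g = lambda x: x  # noqa: E731
    elif scale == "log":
        if ci_low <= 0:
            raise ArgumentError("log scale requires positive bounds")
        g = np.log
    elif scale == "logit":
        if not (0 < ci_low and ci_high < 1):
            raise ArgumentError("logit scale requires bounds inside (0, 1)")
        g = lambda x: np.log(x / (1.0 - x))  # noqa: E731
    else:
        raise ArgumentError(f"unknown scale {scale!r}")
    lo, hi = float(g(ci_low)), float(g(ci_high))
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ArgumentError("transformed bounds must be finite")
    return (hi - lo) / (2.0 * _Z95)


@dataclass
class MonteCarloSummary:
    """Mean ± SE of the outcome deltas over Monte Carlo draws."""

    mean: pd.Series  # indexed by outcome
    se: pd.Series
    n_draws: int
    seed: int
    se_kind: str = "sem"  # "sem" (SD/√n) or "sd"
    draws: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"mean_increase": self.mean, "se": self.se})
        df["n_draws"] = self.n_draws
        df["seed"] = self.seed
        return df


def _perturb_rr(rr: RelativeRisk, z: float) -> RelativeRisk:
    se = rr.ln_rr_se
    new = float(np.exp(np.log(rr.rr) + z * se))
    return replace(rr, rr=new)


def run_monte_carlo(
    bundle: InputBundle,
    base: ScenarioSpec,
    alt: ScenarioSpec,
    n_draws: int = 1000,
    seed: int = 0,
    horizon: int = 7,
    factors=None,
    se_kind: str = "sem",
    keep_draws: bool = False,
) -> MonteCarloSummary:
    """Propagate RR and prevalence uncertainty through paired runs.

    Per draw ``d`` a substream ``default_rng([seed, d])`` yields one z-score
    per relative-risk entry (applied on the log scale) and one per scenario
    band (applied as a constant logit shift of that scenario's trajectory);
    the paired comparison re-runs and the per-outcome increase is recorded.
    ``se`` is the SD of the draws divided by √n (``se_kind='sem'``, the
    presentation convention for simulation means) or the raw draw SD
    (``se_kind='sd'``).
    """
    if n_draws < 2:
        raise ArgumentError("n_draws must be at least 2")
    if se_kind not in ("sem", "sd"):
        raise ArgumentError("se_kind must be 'sem' or 'sd'")
    missing = [
        f"relative_risks[{r.outcome}/{r.sex}]"
        for r in bundle.relative_risks
        if r.ln_rr_se is None
    ]
    for scen in (base, alt):
        if scen.logit_se is None:
            missing.append(f"scenario[{scen.name}].logit_se")
    if missing:
        raise ConfigError(
            "Monte Carlo requires standard errors for all perturbed inputs; "
            "missing: " + ", ".join(missing)
        )

    rrs = bundle.relative_risks
    rows = np.empty((n_draws, len(OUTCOMES)))
    for d in range(n_draws):
        rng = np.random.default_rng([seed, d])
        z_rr = rng.standard_normal(len(rrs))
        z_base = rng.standard_normal(base.logit_se.shape)
        z_alt = rng.standard_normal(alt.logit_se.shape)
        bundle_d = replace(
            bundle, relative_risks=[_perturb_rr(r, z) for r, z in zip(rrs, z_rr)]
        )
        delta = compare_scenarios(
            bundle_d,
            base.perturbed(z_base),
            alt.perturbed(z_alt),
            horizon,
            factors=factors,
        )
        rows[d] = delta.increase.reindex(list(OUTCOMES)).to_numpy()

    draws = pd.DataFrame(rows, columns=list(OUTCOMES))
    sd = draws.std(ddof=1)
    se = sd / np.sqrt(n_draws) if se_kind == "sem" else sd
    return MonteCarloSummary(
        mean=draws.mean().rename("mean_increase"),
        se=se.rename("se"),
        n_draws=n_draws,
        seed=seed,
        se_kind=se_kind,
        draws=draws if keep_draws else None,
    )
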