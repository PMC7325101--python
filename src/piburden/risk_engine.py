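"""Rate and risk mathematics.

Three primitives drive the simulation:

* inverse-variance pooling of log relative risks, used to collapse
  multi-level activity contrasts into a single active-vs-inactive ratio;
* decomposition of an overall (population-average) event rate into
  stratum-specific rates for the active and inactive sub-populations that
  are mutually consistent with a relative risk and the inactivity
  prevalence — the standard attributable-fraction identity
  ``p·λ_inactive + (1−p)·λ_active = λ`` with ``λ_active = RR·λ_inactive``;
* a logistic annual-risk function over categorical risk-factor levels,
  standing in for cohort-estimated parametric risk equations whose
  coefficients are configuration inputs.

Annual probabilities are treated as rates directly (no exponential
conversion) because all rates involved are far below 0.2/year; an explicit
conversion helper is provided for callers that want it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ArgumentError, ConfigError

__all__ = [
    "RelativeRisk",
    "pool_log_rr",
    "decompose_rate",
    "annual_risk",
    "prob_to_rate",
    "rate_to_prob",
    "resolve_rr",
]


@dataclass(frozen=True)
class RelativeRisk:
    """Active-vs-inactive risk ratio for one outcome (values < 1 protect)."""

    outcome: str  # "t2d" | "chd" | "stroke"
    sex: str  # "male" | "female" | "both"
    rr: float
    ci_low: float | None = None
    ci_high: float | None = None
    source: str = ""

    def __post_init__(self):
        if self.rr <= 0:
            raise ArgumentError(f"relative risk must be positive, got {self.rr}")

    @property
    def ln_rr_se(self) -> float | None:
        """Standard error of log RR implied by the 95% CI, if one is present."""
        if self.ci_low is None or self.ci_high is None:
            return None
        # a degenerate (point) interval is allowed and yields SE 0
        if not (0 < self.ci_low <= self.ci_high):
            raise ArgumentError("invalid RR confidence interval")
        return float((np.log(self.ci_high) - np.log(self.ci_low)) / (2 * 1.959964))


def pool_log_rr(strata: Sequence[tuple[float, float]]) -> float:
    """Inverse-variance weighted pooling of relative risks on the log scale.

    Parameters
    ----------
    strata
        Pairs ``(rr, var)`` where ``var`` is the variance of ``ln rr``.

    Returns
    -------
    float
        ``exp( Σ w_i ln(rr_i) / Σ w_i )`` with ``w_i = 1/var_i``.
    """
    if len(strata) == 0:
        raise ArgumentError("pool_log_rr requires at least one stratum")
    rrs = np.array([s[0] for s in strata], dtype=float)
    var = np.array([s[1] for s in strata], dtype=float)
    if np.any(rrs <= 0):
        raise ArgumentError("all relative risks must be positive")
    if np.any(var <= 0):
        raise ArgumentError("all log-RR variances must be positive")
    w = 1.0 / var
    return float(np.exp(np.sum(w * np.log(rrs)) / np.sum(w)))


def decompose_rate(overall_rate, p_inactive, rr_active_vs_inactive):
    """Split a population-average rate into (active, inactive) stratum rates.

    Solves ``p·λ_i + (1−p)·λ_a = λ`` with ``λ_a = RR·λ_i``, i.e.
    ``λ_i = λ / (p + (1−p)·RR)``.  Accepts scalars or broadcastable arrays.

    Returns
    -------
    (rate_active, rate_inactive)
    """
    lam = np.asarray(overall_rate, dtype=float)
    p = np.asarray(p_inactive, dtype=float)
    rr = np.asarray(rr_active_vs_inactive, dtype=float)
    if np.any(lam < 0):
        raise ArgumentError("overall rate must be non-negative")
    if np.any((p < 0) | (p > 1)):
        raise ArgumentError("inactive prevalence must lie in [0, 1]")
    if np.any(rr <= 0):
        raise ArgumentError("relative risk must be positive")
    rate_inactive = lam / (p + (1.0 - p) * rr)
    rate_active = rr * rate_inactive
    if lam.ndim == 0 and p.ndim == 0 and rr.ndim == 0:
        return float(rate_active), float(rate_inactive)
    return rate_active, rate_inactive


def annual_risk(
    stratum: Mapping[str, str],
    sex: str,
    age_band: str,
    coeffs: Mapping[str, Mapping[str, float]],
    outcome: str,
) -> float:
    """Annual event probability from a logistic model on categorical levels.

    ``coeffs[outcome]`` maps term names to log-odds contributions:
    ``"intercept"``, optionally ``"sex:<sex>"`` and ``"age_band:<band>"``,
    and ``"<factor>:<level>"`` for every non-reference level a presented
    stratum can take.  Reference levels simply have no entry with nonzero
    value, but every presented ``factor:level`` key must exist so that a
    stratum outside the configured ontology fails loudly.
    """
    if outcome not in coeffs:
        raise ConfigError(f"no coefficients configured for outcome {outcome!r}")
    table = coeffs[outcome]
    eta = float(table.get("intercept", 0.0))
    eta += float(table.get(f"sex:{sex}", 0.0))
    eta += float(table.get(f"age_band:{age_band}", 0.0))
    for factor, level in stratum.items():
        key = f"{factor}:{level}"
        if key not in table:
            raise ConfigError(
                f"missing coefficient {key!r} for outcome {outcome!r}; "
                "reference levels must be present with coefficient 0"
            )
        eta += float(table[key])
    return float(1.0 / (1.0 + np.exp(-eta)))


def prob_to_rate(p):
    """Annual probability → instantaneous rate, ``−ln(1−p)``."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ArgumentError("probability must lie in [0, 1)")
    out = -np.log1p(-p)
    return float(out) if out.ndim == 0 else out


def rate_to_prob(r):
    """Instantaneous rate → annual probability, ``1−exp(−r)``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ArgumentError("rate must be non-negative")
    out = -np.expm1(-r)
    return float(out) if out.ndim == 0 else out


def resolve_rr(relative_risks: Iterable[RelativeRisk], outcome: str) -> np.ndarray:
    """Per-sex RR array ``(male, female)`` for one outcome.

    An entry with ``sex='both'`` covers both sexes; sex-specific entries must
    cover both sexes or a configuration error is raised.
    """
    entries = [r for r in relative_risks if r.outcome == outcome]
    if not entries:
        raise ConfigError(f"no relative risk configured for outcome {outcome!r}")
    both = [r for r in entries if r.sex == "both"]
    if both:
        return np.array([both[0].rr, both[0].rr], dtype=float)
    by_sex = {r.sex: r.rr for r in entries}
    if "male" not in by_sex or "female" not in by_sex:
        raise ConfigError(
            f"sex-specific relative risks for {outcome!r} must cover both sexes"
        )
    return np.array([by_sex["male"], by_sex["female"]], dtype=float)
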