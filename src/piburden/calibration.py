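"""Iterative proportional calibration of model rates to base-year targets.

Four streams are calibrated per sex × age band: total acute CHD events,
total acute stroke events, CHD deaths, and stroke deaths.  Event factors
scale the first-event incidence rates and the matching history event rates;
death factors scale the 30-day case fatalities and the matching chronic
CVD-death rates.  The update is multiplicative proportional fitting,
``factor ← factor × (target / simulated)^damping``, re-simulating the base
year (and hence the population at risk) after each update, and stops when
every stream's simulated count lies within a relative tolerance of its
target — 1% by default.  Because each stream's base-year count is linear in
its own factor given the others, the fixed point is reached in a handful of
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .cohort_model import (
    STREAMS,
    BridgeParams,
    HistoryParams,
    RateTable,
    advance_year,
    build_cycle_rates,
)
from .errors import ArgumentError, CalibrationError, StructuralInfeasibilityError
from .ontology import AGE_BANDS, N_AGE, N_SEX, SEXES

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import CalibrationTargetSet, InputBundle

__all__ = ["CalibrationFactors", "apply_factors", "simulate_base_year", "calibrate"]

_CHD_EV, _STROKE_EV, _CHD_D, _STROKE_D = range(4)


@dataclass
class CalibrationFactors:
    """Multiplicative stream factors plus convergence diagnostics."""

    values: np.ndarray  # (N_SEX, N_AGE, 4) in STREAMS order
    converged: bool = False
    n_iter: int = 0
    residual: float = np.inf
    trace: list[float] = field(default_factory=list)

    @classmethod
    def identity(cls) -> "CalibrationFactors":
        return cls(np.ones((N_SEX, N_AGE, len(STREAMS))))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, sex in enumerate(SEXES):
            for a, band in enumerate(AGE_BANDS):
                for k, stream in enumerate(STREAMS):
                    rows.append((sex, band, stream, self.values[s, a, k]))
        return pd.DataFrame(rows, columns=["sex", "age_band", "stream", "factor"])


def _as_factor_array(factors) -> np.ndarray | None:
    if factors is None:
        return None
    if isinstance(factors, CalibrationFactors):
        arr = factors.values
    else:
        arr = np.broadcast_to(
            np.asarray(factors, float), (N_SEX, N_AGE, len(STREAMS))
        )
    if np.any(arr <= 0):
        raise ArgumentError("calibration factors must be positive")
    return arr


def apply_factors(
    bundle: "InputBundle", factors=None
) -> tuple[RateTable, BridgeParams, HistoryParams]:
    """Return (base rates, bridge, history) with stream factors applied.

    Event factors multiply first-event incidence and history event rates;
    death factors multiply case fatalities (clipped at 1) and chronic
    CVD-death rates.  The bundle itself is never mutated.
    """
    f = _as_factor_array(factors)
    base = bundle.base_rates.copy()
    bridge = bundle.bridge_params.copy()
    history = bundle.history_params.copy()
    if f is None:
        return base, bridge, history

    base.chd = base.chd * f[..., _CHD_EV]
    base.stroke = base.stroke * f[..., _STROKE_EV]
    history.chd_event_rate = history.chd_event_rate * f[..., _CHD_EV][..., None]
    history.stroke_event_rate = history.stroke_event_rate * f[..., _STROKE_EV][..., None]

    bridge.chd_case_fatality = np.clip(
        bridge.chd_case_fatality * f[..., _CHD_D][..., None], 0.0, 1.0
    )
    bridge.stroke_case_fatality = np.clip(
        bridge.stroke_case_fatality * f[..., _STROKE_D], 0.0, 1.0
    )
    # chronic CVD death: post-CHD from the CHD stream, post-stroke from the
    # stroke stream, post-both by the configured attribution share
    cvd = history.cvd_death_rate.copy()
    cvd[..., 0] *= f[..., _CHD_D]
    cvd[..., 1] *= f[..., _STROKE_D]
    share = history.chd_share_both
    cvd[..., 2] *= share * f[..., _CHD_D] + (1.0 - share) * f[..., _STROKE_D]
    history.cvd_death_rate = cvd
    return base, bridge, history


def simulate_base_year(bundle: "InputBundle", factors=None) -> np.ndarray:
    """One base-year model cycle; returns stream counts (N_SEX, N_AGE, 4).

    The cohort starts from the bundle's base-year population at its baseline
    inactivity prevalence; rates are decomposed at that realised prevalence,
    exactly as in a full simulation year.
    """
    base, bridge, history = apply_factors(bundle, factors)
    cohort = bundle.initial_cohort()
    p = cohort.inactive_share()
    rates = build_cycle_rates(base, bundle.relative_risks, p, bundle.ontology)
    _, tallies = advance_year(cohort, rates, bridge, history)
    return np.stack([tallies[s] for s in STREAMS], axis=-1)


def calibrate(
    bundle: "InputBundle",
    targets: "CalibrationTargetSet",
    tol: float = 0.01,
    max_iter: int = 100,
    damping: float = 1.0,
) -> CalibrationFactors:
    """Fit stream factors so base-year counts match targets within ``tol``.

    The residual is the maximum over strata and streams of
    ``|simulated − target| / target`` (streams with zero target and zero
    structural capacity are ignored).  Raises
    :class:`StructuralInfeasibilityError` if a positive target sits on a
    stream the model cannot produce, and :class:`CalibrationError` carrying
    the worst residual if ``max_iter`` is exhausted.
    """
    if tol <= 0:
        raise ArgumentError("tol must be positive")
    if not 0 < damping <= 1:
        raise ArgumentError("damping must lie in (0, 1]")
    targets.validate()
    if targets.reference_year != bundle.base_year:
        raise ArgumentError(
            f"targets reference year {targets.reference_year} does not match "
            f"model base year {bundle.base_year}"
        )
    t = targets.values
    result = CalibrationFactors.identity()
    active = t > 0

    for it in range(max_iter + 1):
        sim = simulate_base_year(bundle, result.values)
        if np.any(active & (sim <= 0)):
            raise StructuralInfeasibilityError(
                "positive target on a stream the model produces no events for"
            )
        resid = 0.0
        if active.any():
            resid = float(np.max(np.abs(sim[active] - t[active]) / t[active]))
        result.trace.append(resid)
        result.residual = resid
        result.n_iter = it
        if resid <= tol:
            result.converged = True
            return result
        upd = np.ones_like(result.values)
        upd[active] = (t[active] / sim[active]) ** damping
        result.values = result.values * upd

    raise CalibrationError(
        f"calibration did not converge in {max_iter} iterations "
        f"(worst residual {result.residual:.4g})",
        worst_residual=result.residual,
    )
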