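"""Markov cohort engine: demographic-epidemiological, bridge and
disease-history submodels advanced in annual cycles.

The engine propagates *expected* person counts (a deterministic compartment
model, not a microsimulation).  Each annual cycle applies, in order:

1. rebalance of the physical-inactivity split to the scenario trajectory,
2. decomposition of calibrated overall incidence rates into active/inactive
   stratum rates at the current prevalence,
3. the annual transition step ``advance_year`` — first events among the
   CVD-free population, 30-day bridge fates (cardiac arrest / MI / angina /
   stroke with type-specific case fatality), and recurrence/death flows in
   the disease-history states,
4. demographic aging (1/10 of each 10-year band moves up per year; outflow
   from the top band exits the model).

Events are computed on start-of-year populations and attributed to the age
band occupied at event time.  The cohort is closed by default: no new
35-year-old entrants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .ontology import (
    AGE_BANDS,
    HEALTH_STATES,
    N_AGE,
    N_SEX,
    N_STATE,
    OUTCOMES,
    REPORT_BANDS,
    SEXES,
    Cohort,
    StratumOntology,
)
from .risk_engine import decompose_rate, resolve_rr

if TYPE_CHECKING:  # pragma: no cover
    from .scenario_engine import ScenarioSpec
    from .synthetic_data import InputBundle

__all__ = [
    "RateTable",
    "BridgeParams",
    "HistoryParams",
    "CycleRates",
    "SimulationResult",
    "advance_year",
    "age_cohort",
    "rebalance_pi",
    "build_cycle_rates",
    "run_simulation",
]

CHD_EVENT_TYPES: tuple[str, ...] = ("cardiac_arrest", "mi", "angina")
#: disease-history states, in cohort state order 1..3
POST_STATES: tuple[str, ...] = HEALTH_STATES[1:]
#: calibration target streams
STREAMS: tuple[str, ...] = ("chd_events", "stroke_events", "chd_deaths", "stroke_deaths")

_CONSERVATION_RTOL = 1e-9


@dataclass
class RateTable:
    """Overall annual first-event/death rates per (sex, age band).

    ``t2d`` applies to non-diabetic CVD-free persons, ``chd``/``stroke`` to
    all CVD-free persons, ``non_cvd_death`` to the CVD-free population (the
    disease-history states carry their own non-CVD death rates).
    """

    t2d: np.ndarray  # (N_SEX, N_AGE)
    chd: np.ndarray
    stroke: np.ndarray
    non_cvd_death: np.ndarray

    def validate(self) -> None:
        for name in ("t2d", "chd", "stroke", "non_cvd_death"):
            arr = getattr(self, name)
            if arr.shape != (N_SEX, N_AGE):
                raise ArgumentError(f"rate table {name} must have shape {(N_SEX, N_AGE)}")
            if np.any(arr < 0):
                raise ArgumentError(f"negative rate in {name}")

    def copy(self) -> "RateTable":
        return RateTable(
            self.t2d.copy(), self.chd.copy(), self.stroke.copy(), self.non_cvd_death.copy()
        )


@dataclass
class BridgeParams:
    """30-day fate of incident coronary and stroke events.

    Incident CHD resolves into cardiac arrest / MI / angina with proportions
    ``chd_type_split`` (summing to 1) and type-specific 30-day case fatality;
    the arrest case fatality is the complement of arrest survival.  Stroke
    events carry a single 30-day case fatality.
    """

    chd_type_split: np.ndarray  # (N_SEX, N_AGE, 3)
    chd_case_fatality: np.ndarray  # (N_SEX, N_AGE, 3)
    stroke_case_fatality: np.ndarray  # (N_SEX, N_AGE)

    def validate(self) -> None:
        if self.chd_type_split.shape != (N_SEX, N_AGE, len(CHD_EVENT_TYPES)):
            raise ArgumentError("chd_type_split has wrong shape")
        if np.any(self.chd_type_split < 0) or np.any(self.chd_type_split > 1):
            raise ArgumentError("chd_type_split entries must lie in [0, 1]")
        if not np.allclose(self.chd_type_split.sum(axis=-1), 1.0, atol=1e-9):
            raise ArgumentError("chd_type_split must sum to 1 per sex and age band")
        for arr in (self.chd_case_fatality, self.stroke_case_fatality):
            if np.any((arr < 0) | (arr > 1)):
                raise ArgumentError("case fatality must lie in [0, 1]")

    @property
    def arrest_survival(self) -> np.ndarray:
        return 1.0 - self.chd_case_fatality[..., 0]

    def chd_fatal_fraction(self) -> np.ndarray:
        """(N_SEX, N_AGE) 30-day death probability per incident CHD event."""
        return (self.chd_type_split * self.chd_case_fatality).sum(axis=-1)

    def mi_fraction(self) -> np.ndarray:
        return self.chd_type_split[..., CHD_EVENT_TYPES.index("mi")]

    def mi_case_fatality(self) -> np.ndarray:
        return self.chd_case_fatality[..., CHD_EVENT_TYPES.index("mi")]

    def copy(self) -> "BridgeParams":
        return BridgeParams(
            self.chd_type_split.copy(),
            self.chd_case_fatality.copy(),
            self.stroke_case_fatality.copy(),
        )


@dataclass
class HistoryParams:
    """Annual flows in the disease-history states (post-CHD, post-stroke,
    post-both), per (sex, age band, state).

    ``chd_event_rate`` is a recurrent coronary event (counted as MI) in the
    post-CHD and post-both states and a *first* coronary event in the
    post-stroke state (which then moves survivors to post-both);
    ``stroke_event_rate`` symmetrically.  ``cvd_death_rate`` is chronic
    cardiovascular death attributed to the CHD stream in post-CHD, the stroke
    stream in post-stroke, and split ``chd_share_both`` / ``1−chd_share_both``
    in post-both.  ``revascularization_rate`` is tallied only.
    """

    chd_event_rate: np.ndarray  # (N_SEX, N_AGE, 3)
    stroke_event_rate: np.ndarray
    revascularization_rate: np.ndarray
    cvd_death_rate: np.ndarray
    non_cvd_death_rate: np.ndarray
    chd_share_both: float = 0.5

    def validate(self) -> None:
        shape = (N_SEX, N_AGE, len(POST_STATES))
        for name in (
            "chd_event_rate",
            "stroke_event_rate",
            "revascularization_rate",
            "cvd_death_rate",
            "non_cvd_death_rate",
        ):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ArgumentError(f"history {name} must have shape {shape}")
            if np.any(arr < 0):
                raise ArgumentError(f"negative rate in history {name}")
        if not 0.0 <= self.chd_share_both <= 1.0:
            raise ArgumentError("chd_share_both must lie in [0, 1]")
        exit_prob = (
            self.chd_event_rate
            + self.stroke_event_rate
            + self.cvd_death_rate
            + self.non_cvd_death_rate
        )
        if np.any(exit_prob > 1.0 + 1e-12):
            raise ArgumentError("implied annual exit probability exceeds 1")

    def copy(self) -> "HistoryParams":
        return HistoryParams(
            self.chd_event_rate.copy(),
            self.stroke_event_rate.copy(),
            self.revascularization_rate.copy(),
            self.cvd_death_rate.copy(),
            self.non_cvd_death_rate.copy(),
            self.chd_share_both,
        )


@dataclass
class CycleRates:
    """Per-stratum annual rates for one cycle, after PI decomposition."""

    t2d: np.ndarray  # (N_SEX, N_AGE, n_strata)
    chd: np.ndarray
    stroke: np.ndarray
    non_cvd_death: np.ndarray  # (N_SEX, N_AGE)

    def validate(self) -> None:
        exit_prob = self.t2d + self.chd + self.stroke + self.non_cvd_death[..., None]
        if np.any(exit_prob > 1.0 + 1e-12):
            raise ArgumentError("implied annual exit probability exceeds 1")
        for name in ("t2d", "chd", "stroke", "non_cvd_death"):
            if np.any(getattr(self, name) < 0):
                raise ArgumentError(f"negative cycle rate in {name}")


def build_cycle_rates(
    base: RateTable,
    relative_risks,
    p_inactive: np.ndarray,
    ontology: StratumOntology,
) -> CycleRates:
    """Decompose overall incidence rates into per-stratum cycle rates.

    ``p_inactive`` is the *reference* inactive share per (sex, age band) —
    the baseline prevalence the overall rates were calibrated at.  The
    decomposition guarantees the population-average rate equals the
    calibrated overall rate at that reference prevalence; a scenario that
    moves the population between activity strata then shifts the average
    across the fixed stratum rates, which is what makes counterfactual
    trajectories bite.  T2D incidence is zeroed on diabetic strata.
    Physical inactivity modifies incident T2D, CHD and stroke only — not
    non-CVD death.
    """
    inact = ontology.inactive_mask
    diab = ontology.diabetic_mask
    n_strata = ontology.n_strata

    def split(lam: np.ndarray, rr_by_sex: np.ndarray) -> np.ndarray:
        rr = rr_by_sex[:, None]  # (N_SEX, 1) broadcast over age
        active, inactive = decompose_rate(lam, p_inactive, rr)
        out = np.empty((N_SEX, N_AGE, n_strata))
        out[..., :] = active[..., None]
        out[..., inact] = inactive[..., None]
        return out

    t2d = split(base.t2d, resolve_rr(relative_risks, "t2d"))
    t2d[..., diab] = 0.0
    chd = split(base.chd, resolve_rr(relative_risks, "chd"))
    stroke = split(base.stroke, resolve_rr(relative_risks, "stroke"))
    rates = CycleRates(t2d, chd, stroke, base.non_cvd_death)
    rates.validate()
    return rates


def advance_year(
    cells: Cohort,
    rates: CycleRates,
    bridge: BridgeParams,
    history: HistoryParams,
    check: bool = True,
) -> tuple[Cohort, dict[str, np.ndarray]]:
    """One annual transition step (no aging).

    Returns the advanced cohort and per-(sex, age band) tallies for the six
    reported outcomes plus the calibration streams (``chd_events``,
    ``stroke_events``, ``chd_deaths``, ``stroke_deaths`` — deaths aliases of
    the mortality outcomes), ``revascularizations`` and ``deaths_total``.
    Expected-count conservation (in = out + deaths) is asserted to 1e-9
    relative unless ``check`` is False.
    """
    if check:
        cells.validate()
        rates.validate()
        bridge.validate()
        history.validate()

    c = cells.counts
    new = c.copy()
    ont = cells.ontology

    ffrac = bridge.chd_fatal_fraction()[..., None]  # (S broadcast)
    mi_frac = bridge.mi_fraction()[..., None]
    cf_mi = bridge.mi_case_fatality()[..., None]
    cf_stroke = bridge.stroke_case_fatality[..., None]

    # --- demographic-epidemiological submodel: CVD-free population -------
    N = c[..., 0]
    ev_t2d = N * rates.t2d
    ev_chd = N * rates.chd
    ev_stroke = N * rates.stroke
    d_ncd = N * rates.non_cvd_death[..., None]

    chd_fatal = ev_chd * ffrac
    stroke_fatal = ev_stroke * cf_stroke

    new[..., 0] = N - ev_chd - ev_stroke - d_ncd - ev_t2d
    # incident T2D: move to the diabetes-flipped twin stratum (same state);
    # the changed risk profile takes effect from the next cycle
    mover = np.zeros_like(N)
    nd = ~ont.diabetic_mask
    mover[:, :, ont.diabetes_partner[nd]] = ev_t2d[:, :, nd]
    new[..., 0] += mover
    new[..., 1] += ev_chd - chd_fatal
    new[..., 2] += ev_stroke - stroke_fatal

    deaths = d_ncd.sum(-1) + chd_fatal.sum(-1) + stroke_fatal.sum(-1)
    tallies: dict[str, np.ndarray] = {
        "t2d_incidence": ev_t2d.sum(-1),
        "chd_incidence": ev_chd.sum(-1),
        "stroke_incidence": ev_stroke.sum(-1),
        "total_mi": (ev_chd * mi_frac).sum(-1),
        "chd_mortality": chd_fatal.sum(-1),
        "stroke_mortality": stroke_fatal.sum(-1),
        "chd_events": ev_chd.sum(-1),
        "stroke_events": ev_stroke.sum(-1),
        "revascularizations": np.zeros((N_SEX, N_AGE)),
    }

    # --- disease-history submodel ----------------------------------------
    for j, state in enumerate(POST_STATES):
        k = j + 1
        M = c[..., k]
        chd_ev = M * history.chd_event_rate[..., j][..., None]
        st_ev = M * history.stroke_event_rate[..., j][..., None]
        cvd_d = M * history.cvd_death_rate[..., j][..., None]
        ncd_d = M * history.non_cvd_death_rate[..., j][..., None]
        revasc = M * history.revascularization_rate[..., j][..., None]

        if state == "post_chd":
            # recurrent coronary events are MIs; a first stroke moves
            # survivors to post-both
            chd_fatal_h = chd_ev * cf_mi
            st_fatal_h = st_ev * cf_stroke
            new[..., k] -= chd_fatal_h + st_ev + cvd_d + ncd_d
            new[..., 3] += st_ev - st_fatal_h
            tallies["stroke_incidence"] += st_ev.sum(-1)
            tallies["total_mi"] += chd_ev.sum(-1)
            tallies["chd_mortality"] += chd_fatal_h.sum(-1) + cvd_d.sum(-1)
            tallies["stroke_mortality"] += st_fatal_h.sum(-1)
        elif state == "post_stroke":
            # a first coronary event passes through the full bridge;
            # recurrent strokes stay unless fatal
            chd_fatal_h = chd_ev * ffrac
            st_fatal_h = st_ev * cf_stroke
            new[..., k] -= chd_ev + st_fatal_h + cvd_d + ncd_d
            new[..., 3] += chd_ev - chd_fatal_h
            tallies["chd_incidence"] += chd_ev.sum(-1)
            tallies["total_mi"] += (chd_ev * mi_frac).sum(-1)
            tallies["chd_mortality"] += chd_fatal_h.sum(-1)
            tallies["stroke_mortality"] += st_fatal_h.sum(-1) + cvd_d.sum(-1)
        else:  # post_both
            chd_fatal_h = chd_ev * cf_mi
            st_fatal_h = st_ev * cf_stroke
            new[..., k] -= chd_fatal_h + st_fatal_h + cvd_d + ncd_d
            tallies["total_mi"] += chd_ev.sum(-1)
            tallies["chd_mortality"] += (
                chd_fatal_h.sum(-1) + history.chd_share_both * cvd_d.sum(-1)
            )
            tallies["stroke_mortality"] += (
                st_fatal_h.sum(-1) + (1.0 - history.chd_share_both) * cvd_d.sum(-1)
            )

        tallies["chd_events"] += chd_ev.sum(-1)
        tallies["stroke_events"] += st_ev.sum(-1)
        tallies["revascularizations"] += revasc.sum(-1)
        deaths += (chd_fatal_h + st_fatal_h + cvd_d + ncd_d).sum(-1)

    tallies["chd_deaths"] = tallies["chd_mortality"].copy()
    tallies["stroke_deaths"] = tallies["stroke_mortality"].copy()
    tallies["deaths_total"] = deaths

    if check:
        before = c.sum()
        after = new.sum() + deaths.sum()
        scale = max(before, 1.0)
        if abs(before - after) > _CONSERVATION_RTOL * scale:
            raise ArgumentError(
                f"person conservation violated: {before!r} -> {after!r}"
            )
        if np.any(new < -_CONSERVATION_RTOL * scale):
            raise ArgumentError("advance_year produced a negative compartment")
        np.clip(new, 0.0, None, out=new)

    return Cohort(ont, new), tallies


def age_cohort(cells: Cohort) -> tuple[Cohort, np.ndarray]:
    """Annual aging: 1/10 of each band moves to the next; the top band's
    outflow exits the model.  Returns (aged cohort, top-band exits per sex
    summed over strata and states)."""
    c = cells.counts
    new = 0.9 * c
    new[:, 1:] += 0.1 * c[:, :-1]
    exits = 0.1 * c[:, -1].sum(axis=(1, 2))
    return Cohort(cells.ontology, new), exits


def rebalance_pi(cells: Cohort, target_prevalence: np.ndarray) -> Cohort:
    """Move counts between pi-status twin strata so the inactive share per
    (sex, age band) equals the target, preserving every other marginal.

    ``target_prevalence`` has shape (N_SEX, N_AGE); NaN entries leave the
    band untouched.  The rebalance acts within every (other-factor
    combination, health state) pair, so all non-PI marginals are exactly
    preserved.
    """
    t = np.asarray(target_prevalence, dtype=float)
    if t.shape != (N_SEX, N_AGE):
        raise ArgumentError(f"target prevalence must have shape {(N_SEX, N_AGE)}")
    finite = np.isfinite(t)
    if np.any((t[finite] < 0) | (t[finite] > 1)):
        raise ArgumentError("target prevalence must lie in [0, 1]")

    ont = cells.ontology
    inact = np.flatnonzero(ont.inactive_mask)
    act = ont.pi_partner[inact]
    c = cells.counts.copy()
    pair_tot = c[:, :, inact, :] + c[:, :, act, :]
    tt = np.where(finite, t, 0.0)[:, :, None, None]
    new_inact = tt * pair_tot
    new_act = (1.0 - tt) * pair_tot
    mask4 = finite[:, :, None, None]
    c[:, :, inact, :] = np.where(mask4, new_inact, c[:, :, inact, :])
    c[:, :, act, :] = np.where(mask4, new_act, c[:, :, act, :])
    return Cohort(ont, c)


@dataclass
class SimulationResult:
    """Event/death counts per outcome × year × sex × age band."""

    counts: np.ndarray  # (len(OUTCOMES), horizon, N_SEX, N_AGE)
    start_year: int
    scenario_name: str = ""
    top_band_exits: np.ndarray | None = None

    @property
    def horizon(self) -> int:
        return self.counts.shape[1]

    def cumulative(self, bands: tuple[str, ...] = REPORT_BANDS) -> pd.Series:
        """Accumulated counts over the horizon, both sexes, selected bands."""
        idx = [AGE_BANDS.index(b) for b in bands]
        tot = self.counts[:, :, :, idx].sum(axis=(1, 2, 3))
        return pd.Series(tot, index=list(OUTCOMES), name="count")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (outcome, year, sex, age_band, count)."""
        rows = []
        for i, outcome in enumerate(OUTCOMES):
            for y in range(self.horizon):
                for s, sex in enumerate(SEXES):
                    for a, band in enumerate(AGE_BANDS):
                        rows.append(
                            (outcome, self.start_year + y, sex, band, self.counts[i, y, s, a])
                        )
        return pd.DataFrame(rows, columns=["outcome", "year", "sex", "age_band", "count"])


def run_simulation(
    bundle: "InputBundle",
    scenario: "ScenarioSpec",
    horizon: int,
    factors=None,
) -> SimulationResult:
    """Run the annual-cycle Markov model under one PI-prevalence scenario.

    Deterministic given its inputs.  Per year: PI rebalance to the scenario
    trajectory → annual transition step at the stratum rates decomposed at
    the bundle's baseline prevalence → aging.  ``factors`` (optional
    :class:`~piburden.calibration.CalibrationFactors` or array) scales the
    calibrated streams.
    """
    if horizon < 1:
        raise ArgumentError("horizon must be at least 1")
    if scenario.horizon < horizon:
        raise ArgumentError(
            f"scenario {scenario.name!r} covers {scenario.horizon} years, "
            f"needed {horizon}"
        )
    from .calibration import apply_factors  # local import to avoid a cycle

    base, bridge, history = apply_factors(bundle, factors)
    cohort = bundle.initial_cohort()
    # stratum rates are anchored once at the baseline inactive share; the
    # scenario acts purely through the population mix
    p_ref = cohort.inactive_share()
    rates = build_cycle_rates(base, bundle.relative_risks, p_ref, bundle.ontology)
    counts = np.zeros((len(OUTCOMES), horizon, N_SEX, N_AGE))
    exits = np.zeros((horizon, N_SEX))
    for y in range(horizon):
        year = scenario.start_year + y
        cohort = rebalance_pi(cohort, scenario.prevalence_for_year(year))
        cohort, tallies = advance_year(cohort, rates, bridge, history)
        for i, outcome in enumerate(OUTCOMES):
            counts[i, y] = tallies[outcome]
        cohort, exits[y] = age_cohort(cohort)
    return SimulationResult(counts, scenario.start_year, scenario.name, exits)
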