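"""Prevalence trajectories, counterfactual comparisons and reporting
arithmetic.

A scenario is a named physical-inactivity prevalence trajectory over the
simulation horizon.  The burden attributable to an exposure change is the
difference in accumulated events/deaths between two simulations that are
identical except for that trajectory: a status-quo run versus a
counterfactual run.  The WHO global-target scenario lowers prevalence
linearly to a 10% relative reduction by 2025 and 15% by 2030 (the 2030
reduction read as inclusive of the 2025 one).

Reporting conventions: accumulated counts rounded to the nearest 100 in
human-readable summaries only; percent changes computed from unrounded
counts, half-up to one decimal (count deltas) or to the nearest integer
(prevalence changes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .cohort_model import SimulationResult, run_simulation
from .errors import ArgumentError
from .ontology import AGE_BANDS, N_AGE, N_SEX, OUTCOMES, REPORT_BANDS
from .synthetic_data import InputBundle, PIPrevalenceTable

__all__ = [
    "ScenarioSpec",
    "OutcomeDelta",
    "flat_scenario",
    "who_trajectory",
    "compare_scenarios",
    "percent_difference_change",
    "relative_prevalence_change",
    "apply_accelerometer_adjustment",
    "round_to_hundred",
]


@dataclass
class ScenarioSpec:
    """A named PI-prevalence trajectory.

    ``trajectory`` maps calendar year → (N_SEX, N_AGE) inactive proportions;
    NaN entries leave a band unsteered (bands above 64 by default).
    ``logit_se`` optionally carries the logit-scale standard error of the
    trajectory's anchor prevalence for Monte Carlo perturbation.
    """

    name: str
    start_year: int
    horizon: int
    trajectory: dict[int, np.ndarray]
    entrants: bool = False
    logit_se: np.ndarray | None = None

    def __post_init__(self):
        for year in range(self.start_year, self.start_year + self.horizon):
            if year not in self.trajectory:
                raise ArgumentError(
                    f"scenario {self.name!r} trajectory missing year {year}"
                )
        for year, arr in self.trajectory.items():
            arr = np.asarray(arr, float)
            finite = np.isfinite(arr)
            if np.any((arr[finite] < 0) | (arr[finite] > 1)):
                raise ArgumentError(f"prevalence outside [0, 1] in year {year}")
            self.trajectory[year] = arr

    def prevalence_for_year(self, year: int) -> np.ndarray:
        if year < self.start_year:
            return self.trajectory[self.start_year]
        if year not in self.trajectory:
            raise ArgumentError(f"scenario {self.name!r} does not cover year {year}")
        return self.trajectory[year]

    def perturbed(self, z: np.ndarray, name_suffix: str = "~") -> "ScenarioSpec":
        """Shift the whole trajectory on the logit scale by ``z × logit_se``.

        The shift is constant over years, preserving the trajectory's shape;
        logit-scale sampling keeps every prevalence inside (0, 1).
        """
        if self.logit_se is None:
            raise ArgumentError(f"scenario {self.name!r} has no logit_se configured")
        shift = np.asarray(z, float) * self.logit_se
        new_traj = {}
        for year, arr in self.trajectory.items():
            with np.errstate(divide="ignore", invalid="ignore"):
                logit = np.log(arr / (1.0 - arr))
                out = 1.0 / (1.0 + np.exp(-(logit + shift)))
            new_traj[year] = np.where(np.isfinite(arr), out, arr)
        return ScenarioSpec(
            self.name + name_suffix,
            self.start_year,
            self.horizon,
            new_traj,
            self.entrants,
            self.logit_se,
        )


def flat_scenario(
    prevalence: PIPrevalenceTable | np.ndarray,
    year: int,
    name: str,
    start_year: int,
    horizon: int,
) -> ScenarioSpec:
    """Constant-prevalence scenario from a survey year (or explicit array)."""
    if isinstance(prevalence, PIPrevalenceTable):
        arr = prevalence.band_array(year)
        se = prevalence.logit_se_array(year)
    else:
        arr = np.asarray(prevalence, float)
        se = None
    traj = {y: arr for y in range(start_year, start_year + horizon)}
    return ScenarioSpec(name, start_year, horizon, traj, logit_se=se)


def who_trajectory(
    p_start: np.ndarray,
    start_year: int = 2016,
    mid_year: int = 2025,
    end_year: int = 2030,
    mid_reduction: float = 0.10,
    end_reduction: float = 0.15,
    name: str = "who_targets",
    logit_se: np.ndarray | None = None,
) -> ScenarioSpec:
    """Gradual linear decrease in PI prevalence to the WHO global targets.

    Prevalence reaches ``p_start×(1−mid_reduction)`` at ``mid_year`` and
    ``p_start×(1−end_reduction)`` at ``end_year`` (total reduction, i.e. the
    end anchor includes the mid-course one), interpolating linearly in
    prevalence between anchors and constant before ``start_year``.
    """
    if not (0 <= mid_reduction < 1 and 0 <= end_reduction < 1):
        raise ArgumentError("reductions must lie in [0, 1)")
    if not start_year < mid_year < end_year:
        raise ArgumentError("anchor years must be strictly increasing")
    p0 = np.asarray(p_start, float)
    traj: dict[int, np.ndarray] = {}
    for year in range(start_year, end_year + 1):
        if year <= mid_year:
            frac = (year - start_year) / (mid_year - start_year)
            mult = 1.0 - mid_reduction * frac
        else:
            frac = (year - mid_year) / (end_year - mid_year)
            mult = (1.0 - mid_reduction) - (end_reduction - mid_reduction) * frac
        traj[year] = p0 * mult
    return ScenarioSpec(
        name, start_year, end_year - start_year + 1, traj, logit_se=logit_se
    )


def _round_half_up(x: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent_difference_change(increase: float, base: float) -> float:
    """``100 × increase / base``, half-up to one decimal."""
    if base <= 0:
        raise ArgumentError("base count must be positive")
    return _round_half_up(100.0 * increase / base, 1)


def relative_prevalence_change(p_old: float, p_new: float) -> int:
    """``100 × (p_new − p_old) / p_old``, half-up to the nearest integer."""
    if p_old <= 0:
        raise ArgumentError("old prevalence must be positive")
    return int(_round_half_up(100.0 * (p_new - p_old) / p_old, 0))


def round_to_hundred(x) -> np.ndarray:
    """Round counts to the nearest 100 (half-up), the summary-table convention."""
    arr = np.asarray(x, dtype=float)
    out = np.floor(arr / 100.0 + 0.5) * 100.0
    return float(out) if out.ndim == 0 else out


@dataclass
class OutcomeDelta:
    """Accumulated counterfactual-minus-base counts per outcome."""

    base_count: pd.Series  # indexed by outcome
    alt_count: pd.Series
    base_name: str = "base"
    alt_name: str = "alt"
    base_result: SimulationResult | None = None
    alt_result: SimulationResult | None = None

    @property
    def increase(self) -> pd.Series:
        return (self.alt_count - self.base_count).rename("increase")

    @property
    def percent_change(self) -> pd.Series:
        return pd.Series(
            {
                o: percent_difference_change(self.increase[o], self.base_count[o])
                for o in self.base_count.index
            },
            name="percent_difference_change",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "base_count": self.base_count,
                "alt_count": self.alt_count,
                "increase": self.increase,
                "percent_difference_change": self.percent_change,
            }
        )

    def summary_table(self) -> pd.DataFrame:
        """Human-readable table: counts rounded to the nearest 100."""
        df = self.to_frame()
        out = pd.DataFrame(
            {
                "base_count": round_to_hundred(df.base_count.to_numpy()),
                "increase": round_to_hundred(df.increase.to_numpy()),
                "percent_difference_change": df.percent_difference_change,
            },
            index=df.index,
        )
        return out


def compare_scenarios(
    bundle: InputBundle,
    base: ScenarioSpec,
    alt: ScenarioSpec,
    horizon: int,
    factors=None,
    bands: tuple[str, ...] = REPORT_BANDS,
) -> OutcomeDelta:
    """Paired simulation under two PI trajectories on identical inputs.

    Both scenarios must cover ``horizon`` years from the same start year.
    Accumulated counts are summed over both sexes and the reporting bands
    (35–64 by default); the delta is counterfactual minus base.
    """
    if base.horizon < horizon or alt.horizon < horizon:
        raise ArgumentError("both scenarios must cover the requested horizon")
    if base.start_year != alt.start_year:
        raise ArgumentError("scenarios must share a start year")
    res_base = run_simulation(bundle, base, horizon, factors=factors)
    res_alt = run_simulation(bundle, alt, horizon, factors=factors)
    return OutcomeDelta(
        base_count=res_base.cumulative(bands).rename("base_count"),
        alt_count=res_alt.cumulative(bands).rename("alt_count"),
        base_name=base.name,
        alt_name=alt.name,
        base_result=res_base,
        alt_result=res_alt,
    )


def apply_accelerometer_adjustment(
    table: PIPrevalenceTable, adjusted: PIPrevalenceTable
) -> PIPrevalenceTable:
    """Swap self-reported prevalences for accelerometer-adjusted ones.

    The adjusted table must cover every (sex, age band, year) of the
    original; the substitution changes nothing downstream except the
    prevalence inputs, so the same comparisons re-run unchanged constitute
    the one-way sensitivity analysis.
    """
    orig_keys = set(zip(table.data.sex, table.data.age_band, table.data.year))
    adj_keys = set(zip(adjusted.data.sex, adjusted.data.age_band, adjusted.data.year))
    missing = orig_keys - adj_keys
    if missing:
        raise ArgumentError(
            f"adjusted table does not cover strata: {sorted(missing)}"
        )
    adjusted.validate()
    keep = adjusted.data[
        [k in orig_keys for k in zip(adjusted.data.sex, adjusted.data.age_band, adjusted.data.year)]
    ].reset_index(drop=True)
    return PIPrevalenceTable(keep)
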