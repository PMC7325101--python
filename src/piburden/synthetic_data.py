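"""Model inputs: packaged survey fixtures and synthetic input bundles.

Two kinds of inputs exist side by side.  The packaged fixtures transcribe
published national survey summaries — the ENSANUT 2006/2012 physical-
inactivity prevalences by 10-year age band and the seven-year accumulated
case-count projections — as plain CSV, so every percentage and ratio the
reporting layer produces can be checked against printed values.  Everything
else a national implementation would read from registries (population counts,
risk-factor stratum distributions, event and death rates, bridge and
disease-history parameters) is generated synthetically with the statistical
structure the model assumes: deterministic for a given seed, magnitudes
plausible for the 2010 Mexican 35+ population, rates increasing with age.

Synthetic stratum distributions combine independent marginals per risk
factor multiplicatively; no joint (copula) structure is imposed.
Prevalences are stored as proportions everywhere inside the package;
percentages appear only at I/O boundaries.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_model import STREAMS, BridgeParams, HistoryParams, RateTable
from .errors import ArgumentError, FixtureError
from .ontology import (
    AGE_BANDS,
    N_AGE,
    N_SEX,
    N_STATE,
    REPORT_BANDS,
    SEXES,
    Cohort,
    StratumOntology,
)
from .risk_engine import RelativeRisk

__all__ = [
    "PIPrevalenceTable",
    "InputBundle",
    "CalibrationTargetSet",
    "load_pi_prevalence_fixture",
    "load_projection_fixture",
    "load_default_relative_risks",
    "generate_inputs",
    "generate_calibration_targets",
]

BASE_YEAR = 2010
_PREVALENCE_FIXTURE = "pi_prevalence_ensanut.csv"
_PROJECTION_FIXTURE = "seven_year_projection.csv"
_RR_FIXTURE = "relative_risks_synthetic_ci.csv"


def _fixture_path(name: str) -> Path:
    path = importlib.resources.files("piburden.data") / name
    if not path.is_file():
        raise FixtureError(f"packaged fixture {name!r} is missing")
    return Path(str(path))


@dataclass
class PIPrevalenceTable:
    """Physical-inactivity prevalence by sex × age band × survey year.

    ``data`` columns: sex, age_band, year, prevalence, ci_low, ci_high and
    optionally survey_n, population_n (prevalences as proportions).  The
    ``total`` age band, when present, is the all-band summary row.
    """

    data: pd.DataFrame

    def validate(self) -> None:
        required = {"sex", "age_band", "year", "prevalence", "ci_low", "ci_high"}
        missing = required - set(self.data.columns)
        if missing:
            raise FixtureError(f"prevalence table missing columns {sorted(missing)}")
        d = self.data
        ok = (
            (d.ci_low >= 0)
            & (d.ci_low <= d.prevalence)
            & (d.prevalence <= d.ci_high)
            & (d.ci_high <= 1)
        )
        if not ok.all():
            bad = d.loc[~ok, ["sex", "age_band", "year"]].to_records(index=False)
            raise FixtureError(f"CI ordering violated for rows {list(bad)}")
        # every (sex, age_band) present for every year
        keys = d.groupby("year", sort=True).apply(
            lambda g: frozenset(zip(g.sex, g.age_band)), include_groups=False
        )
        if len(set(keys)) > 1:
            raise FixtureError("strata coverage differs between years")

    def get(self, sex: str, age_band: str, year: int):
        d = self.data
        row = d[(d.sex == sex) & (d.age_band == age_band) & (d.year == year)]
        if len(row) != 1:
            raise ArgumentError(f"no unique entry for ({sex}, {age_band}, {year})")
        return row.iloc[0]

    def years(self) -> list[int]:
        return sorted(int(y) for y in self.data.year.unique())

    def band_array(self, year: int) -> np.ndarray:
        """(N_SEX, N_AGE) prevalence for the given year; NaN outside the
        bands the table covers.  ``sex='both'`` rows broadcast to both sexes."""
        out = np.full((N_SEX, N_AGE), np.nan)
        d = self.data[(self.data.year == year) & (self.data.age_band != "total")]
        for row in d.itertuples(index=False):
            a = AGE_BANDS.index(row.age_band)
            if row.sex == "both":
                out[:, a] = row.prevalence
            else:
                out[SEXES.index(row.sex), a] = row.prevalence
        return out

    def logit_se_array(self, year: int) -> np.ndarray:
        """(N_SEX, N_AGE) standard error of logit prevalence implied by the
        95% CI; NaN outside covered bands."""
        from .uncertainty import ci_to_se

        out = np.full((N_SEX, N_AGE), np.nan)
        d = self.data[(self.data.year == year) & (self.data.age_band != "total")]
        for row in d.itertuples(index=False):
            a = AGE_BANDS.index(row.age_band)
            se = ci_to_se(row.ci_low, row.ci_high, scale="logit")
            if row.sex == "both":
                out[:, a] = se
            else:
                out[SEXES.index(row.sex), a] = se
        return out

    def write_csv(self, path) -> None:
        out = self.data.copy()
        for col in ("prevalence", "ci_low", "ci_high"):
            out[col + "_pct"] = out[col] * 100.0
            del out[col]
        out.to_csv(path, index=False)


def load_pi_prevalence_fixture() -> PIPrevalenceTable:
    """Packaged ENSANUT 2006/2012 physical-inactivity prevalence table.

    Eight rows — three 10-year age bands plus the all-band total, for each
    survey year — exactly as published, stored as proportions.
    """
    path = _fixture_path(_PREVALENCE_FIXTURE)
    try:
        raw = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - corrupt install
        raise FixtureError(f"cannot parse fixture {path}: {exc}") from exc
    expected = {
        "age_band",
        "year",
        "survey_n",
        "population_n",
        "prevalence_pct",
        "ci_low_pct",
        "ci_high_pct",
        "printed_pct_change",
    }
    if set(raw.columns) != expected or len(raw) != 8:
        raise FixtureError(f"fixture {path} is corrupt")
    table = pd.DataFrame(
        {
            "sex": "both",
            "age_band": raw.age_band,
            "year": raw.year.astype(int),
            "prevalence": raw.prevalence_pct / 100.0,
            "ci_low": raw.ci_low_pct / 100.0,
            "ci_high": raw.ci_high_pct / 100.0,
            "survey_n": raw.survey_n.astype(int),
            "population_n": raw.population_n.astype(int),
            "printed_pct_change": raw.printed_pct_change,
        }
    )
    out = PIPrevalenceTable(table)
    out.validate()
    return out


def load_projection_fixture() -> pd.DataFrame:
    """Packaged seven-year accumulated case-count projections.

    One row per outcome (CHD, stroke and T2D incidence, total MI, CHD and
    stroke mortality) with the base-case accumulated count and the increases
    under the unadjusted and accelerometer-adjusted inactivity prevalences,
    each with its Monte Carlo SE and printed percent change.
    """
    path = _fixture_path(_PROJECTION_FIXTURE)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise FixtureError(f"cannot parse fixture {path}: {exc}") from exc
    required = {
        "outcome",
        "base_count",
        "base_se",
        "unadjusted_increase",
        "unadjusted_se",
        "unadjusted_pct",
        "adjusted_increase",
        "adjusted_se",
        "adjusted_pct",
    }
    if set(df.columns) != required or len(df) != 6:
        raise FixtureError(f"fixture {path} is corrupt")
    return df.set_index("outcome")


def load_default_relative_risks() -> list[RelativeRisk]:
    """Default active-vs-inactive relative risks.

    Point values are the published meta-analytic estimates (T2D 0.78,
    stroke 0.80, CHD 0.86 men / 0.76 women); the confidence intervals are
    synthetic defaults used only to exercise uncertainty propagation.
    """
    df = pd.read_csv(_fixture_path(_RR_FIXTURE))
    return [
        RelativeRisk(r.outcome, r.sex, r.rr, r.ci_low, r.ci_high, r.source)
        for r in df.itertuples(index=False)
    ]


@dataclass
class InputBundle:
    """Everything one model run needs, on the package's internal grid."""

    ontology: StratumOntology
    population: np.ndarray  # (N_SEX, N_AGE) persons
    stratum_distribution: np.ndarray  # (N_SEX, N_AGE, n_strata), rows sum to 1
    cvd_history: np.ndarray  # (N_SEX, N_AGE, N_STATE), rows sum to 1
    base_rates: RateTable
    relative_risks: list[RelativeRisk]
    pi_prevalence: PIPrevalenceTable
    bridge_params: BridgeParams
    history_params: HistoryParams
    base_year: int = BASE_YEAR

    def validate(self) -> None:
        if self.population.shape != (N_SEX, N_AGE):
            raise ArgumentError("population must have shape (N_SEX, N_AGE)")
        if np.any(self.population < 0):
            raise ArgumentError("population counts must be non-negative")
        n = self.ontology.n_strata
        if self.stratum_distribution.shape != (N_SEX, N_AGE, n):
            raise ArgumentError("stratum_distribution has wrong shape")
        if np.any(self.stratum_distribution < 0):
            raise ArgumentError("stratum proportions must be non-negative")
        sums = self.stratum_distribution.sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ArgumentError("stratum proportions must sum to 1 per sex × age band")
        if self.cvd_history.shape != (N_SEX, N_AGE, N_STATE):
            raise ArgumentError("cvd_history has wrong shape")
        if np.any(self.cvd_history < 0) or np.any(
            np.abs(self.cvd_history.sum(axis=-1) - 1.0) > 1e-9
        ):
            raise ArgumentError("cvd_history rows must be distributions")
        self.base_rates.validate()
        self.bridge_params.validate()
        self.history_params.validate()
        self.pi_prevalence.validate()

    def initial_cohort(self) -> Cohort:
        counts = (
            self.population[:, :, None, None]
            * self.stratum_distribution[:, :, :, None]
            * self.cvd_history[:, :, None, :]
        )
        return Cohort(self.ontology, counts)


@dataclass
class CalibrationTargetSet:
    """Base-year target event/death counts per (sex, age band, stream)."""

    values: np.ndarray  # (N_SEX, N_AGE, len(STREAMS))
    reference_year: int = BASE_YEAR
    streams: tuple[str, ...] = STREAMS

    def validate(self) -> None:
        if self.values.shape != (N_SEX, N_AGE, len(STREAMS)):
            raise ArgumentError("target values have wrong shape")
        if np.any(self.values < 0):
            raise ArgumentError("targets must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, sex in enumerate(SEXES):
            for a, band in enumerate(AGE_BANDS):
                for k, stream in enumerate(STREAMS):
                    rows.append((sex, band, stream, self.values[s, a, k]))
        return pd.DataFrame(rows, columns=["sex", "age_band", "stream", "target"])


# --------------------------------------------------------------------------
# synthetic generation
# --------------------------------------------------------------------------

# plausible 2010 per-sex population (persons) by 10-year band, 35-44 .. 85-94
_POP_BASE = np.array([6.9e6, 4.9e6, 3.3e6, 2.0e6, 0.9e6, 0.2e6])
# annual overall first-event/death rates per person at the youngest band,
# with a per-decade growth factor
_RATE_ANCHORS = {
    # (male anchor, female anchor, growth per band)
    "t2d": (0.011, 0.010, 1.25),
    "chd": (0.0022, 0.0013, 1.75),
    "stroke": (0.0009, 0.0008, 1.85),
    "non_cvd_death": (0.004, 0.003, 2.0),
}
_FACTOR_MARGINALS = {
    "smoking": (0.72, 0.28),
    "sbp_band": (0.45, 0.35, 0.20),
    "hdl_band": (0.40, 0.60),
    "ldl_band": (0.65, 0.35),
    "bmi_band": (0.30, 0.40, 0.30),
    "diabetes": (0.86, 0.14),
}


def _age_curve(anchor: float, growth: float, jitter: np.ndarray) -> np.ndarray:
    return anchor * growth ** np.arange(N_AGE) * jitter


def generate_inputs(
    seed: int,
    scale: float = 1.0,
    ontology: StratumOntology | None = None,
    prevalence_year: int = 2006,
) -> InputBundle:
    """Deterministic synthetic input bundle.

    ``scale`` multiplies population counts only (rates are unchanged), so a
    down-scaled bundle runs the identical epidemiology on a smaller cohort.
    The baseline inactive share per band is taken from the packaged survey
    fixture for ``prevalence_year`` (the oldest three bands reuse the 55-64
    value, the closest published band).
    """
    if scale <= 0:
        raise ArgumentError("scale must be positive")
    rng = np.random.default_rng(seed)
    ont = ontology or StratumOntology()
    tab = ont.table()

    population = _POP_BASE[None, :] * rng.lognormal(0.0, 0.05, (N_SEX, N_AGE)) * scale

    prev_fix = load_pi_prevalence_fixture()
    band_prev = prev_fix.band_array(prevalence_year)
    # extend to 65+ bands with the oldest published value
    for a in range(len(REPORT_BANDS), N_AGE):
        band_prev[:, a] = band_prev[:, len(REPORT_BANDS) - 1]

    # independent marginals per factor, Dirichlet-jittered per sex × band,
    # combined multiplicatively; the PI marginal is pinned to the fixture
    dist = np.ones((N_SEX, N_AGE, ont.n_strata))
    for factor, levels in ont.factors.items():
        if factor == "pi_status":
            marg = np.stack([1.0 - band_prev, band_prev], axis=-1)
        else:
            base = np.array(_FACTOR_MARGINALS[factor])
            marg = rng.dirichlet(base * 60.0, size=(N_SEX, N_AGE))
        onehot = np.stack(
            [(tab[factor] == lev).to_numpy(float) for lev in levels], axis=0
        )  # (n_levels, n_strata)
        dist *= np.einsum("sal,lk->sak", marg, onehot)
    dist /= dist.sum(axis=-1, keepdims=True)

    jit = lambda: rng.lognormal(0.0, 0.05, (N_SEX, N_AGE))  # noqa: E731
    rates = {}
    for name, (m_anchor, f_anchor, growth) in _RATE_ANCHORS.items():
        anchors = np.array([m_anchor, f_anchor])[:, None]
        rates[name] = anchors * growth ** np.arange(N_AGE)[None, :] * jit()
    base_rates = RateTable(
        rates["t2d"], rates["chd"], rates["stroke"], rates["non_cvd_death"]
    )

    # bridge: CHD split over arrest/MI/angina, 30-day case fatality by type
    split = rng.dirichlet(np.array([7.0, 45.0, 48.0]) * 40.0, size=(N_SEX, N_AGE))
    cf_age = 1.0 + 0.12 * np.arange(N_AGE)
    cf_arrest = np.clip(0.65 * rng.lognormal(0.0, 0.03, (N_SEX, N_AGE)), 0, 0.95)
    cf_mi = np.clip(0.09 * cf_age[None, :] * rng.lognormal(0.0, 0.03, (N_SEX, N_AGE)), 0, 0.6)
    cf_angina = np.full((N_SEX, N_AGE), 0.01)
    bridge = BridgeParams(
        chd_type_split=split,
        chd_case_fatality=np.stack([cf_arrest, cf_mi, cf_angina], axis=-1),
        stroke_case_fatality=np.clip(
            0.16 * cf_age[None, :] * rng.lognormal(0.0, 0.03, (N_SEX, N_AGE)), 0, 0.7
        ),
    )

    # disease history: recurrence / revascularization / death rates by state
    hshape = (N_SEX, N_AGE, 3)
    hist_age = (1.0 + 0.15 * np.arange(N_AGE))[None, :, None]
    history = HistoryParams(
        chd_event_rate=np.broadcast_to(
            np.array([0.035, 0.012, 0.04])[None, None, :], hshape
        ).copy()
        * hist_age,
        stroke_event_rate=np.broadcast_to(
            np.array([0.008, 0.030, 0.035])[None, None, :], hshape
        ).copy()
        * hist_age,
        revascularization_rate=np.broadcast_to(
            np.array([0.02, 0.005, 0.02])[None, None, :], hshape
        ).copy(),
        cvd_death_rate=np.broadcast_to(
            np.array([0.012, 0.012, 0.022])[None, None, :], hshape
        ).copy()
        * hist_age,
        non_cvd_death_rate=np.broadcast_to(
            rates["non_cvd_death"][:, :, None] * 1.3, hshape
        ).copy(),
    )

    # prior-CVD fractions rising with age
    prior = 0.004 * 2.0 ** np.arange(N_AGE)
    prior = np.clip(prior, 0, 0.25)[None, :] * rng.lognormal(0.0, 0.05, (N_SEX, N_AGE))
    cvd_history = np.zeros((N_SEX, N_AGE, N_STATE))
    cvd_history[..., 1] = prior * 0.55
    cvd_history[..., 2] = prior * 0.35
    cvd_history[..., 3] = prior * 0.10
    cvd_history[..., 0] = 1.0 - prior

    bundle = InputBundle(
        ontology=ont,
        population=population,
        stratum_distribution=dist,
        cvd_history=cvd_history,
        base_rates=base_rates,
        relative_risks=load_default_relative_risks(),
        pi_prevalence=prev_fix,
        bridge_params=bridge,
        history_params=history,
    )
    bundle.validate()
    return bundle


def generate_calibration_targets(bundle: InputBundle, true_factors) -> CalibrationTargetSet:
    """Targets produced by one base-year model cycle with known rate
    multipliers — the oracle for calibration-recovery tests.

    ``true_factors`` is an array broadcastable to (N_SEX, N_AGE,
    len(STREAMS)) of positive multipliers on the four calibrated streams.
    """
    from .calibration import simulate_base_year

    f = np.broadcast_to(np.asarray(true_factors, float), (N_SEX, N_AGE, len(STREAMS))).copy()
    if np.any(f <= 0):
        raise ArgumentError("true_factors must be positive")
    values = simulate_base_year(bundle, f)
    out = CalibrationTargetSet(values=values, reference_year=bundle.base_year)
    out.validate()
    return out
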