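"""Axes of the cohort state space.

The population is held as expected counts on a dense grid
``(sex, 10-year age band, risk-factor stratum, health state)``.  Risk-factor
strata are the cartesian product of categorical levels for smoking, systolic
blood pressure, HDL and LDL cholesterol, body-mass index, diabetes status and
physical-(in)activity status.  Physical inactivity is binary: accumulating
fewer than 600 MET-minutes/week of moderate-to-vigorous activity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError

SEXES: tuple[str, ...] = ("male", "female")
AGE_BANDS: tuple[str, ...] = ("35-44", "45-54", "55-64", "65-74", "75-84", "85-94")
#: age bands the headline results are reported for
REPORT_BANDS: tuple[str, ...] = AGE_BANDS[:3]
HEALTH_STATES: tuple[str, ...] = ("no_cvd", "post_chd", "post_stroke", "post_both")
OUTCOMES: tuple[str, ...] = (
    "t2d_incidence",
    "chd_incidence",
    "stroke_incidence",
    "total_mi",
    "chd_mortality",
    "stroke_mortality",
)

N_SEX = len(SEXES)
N_AGE = len(AGE_BANDS)
N_STATE = len(HEALTH_STATES)

DEFAULT_FACTORS: dict[str, tuple[str, ...]] = {
    "smoking": ("never", "current"),
    "sbp_band": ("<120", "120-139", ">=140"),
    "hdl_band": ("low", "normal"),
    "ldl_band": ("normal", "high"),
    "bmi_band": ("normal", "overweight", "obese"),
    "diabetes": ("no", "yes"),
    "pi_status": ("active", "inactive"),
}


@dataclass(frozen=True)
class StratumOntology:
    """Enumeration of risk-factor strata with index arrays for fast flips.

    ``pi_status`` and ``diabetes`` must be present and binary; the remaining
    factors are configurable.  Strata are enumerated in row-major order of
    ``factors`` with the last factor toggling fastest.
    """

    factors: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_FACTORS)
    )

    def __post_init__(self):
        for required in ("pi_status", "diabetes"):
            if required not in self.factors:
                raise ArgumentError(f"ontology must include a {required!r} factor")
            if len(self.factors[required]) != 2:
                raise ArgumentError(f"{required!r} must be binary")

    @property
    def n_strata(self) -> int:
        return int(np.prod([len(v) for v in self.factors.values()]))

    def table(self) -> pd.DataFrame:
        """One row per stratum, one column per factor."""
        rows = list(itertools.product(*self.factors.values()))
        return pd.DataFrame(rows, columns=list(self.factors))

    # cached index arrays -------------------------------------------------
    def _index_of(self) -> dict[tuple, int]:
        tab = self.table()
        return {tuple(row): i for i, row in enumerate(tab.itertuples(index=False))}

    def _mask(self, factor: str, level_pos: int) -> np.ndarray:
        tab = self.table()
        return (tab[factor] == self.factors[factor][level_pos]).to_numpy()

    @property
    def inactive_mask(self) -> np.ndarray:
        """Boolean (n_strata,) — strata whose pi_status is the second level."""
        return self._mask("pi_status", 1)

    @property
    def diabetic_mask(self) -> np.ndarray:
        return self._mask("diabetes", 1)

    @property
    def pi_partner(self) -> np.ndarray:
        """Index of the stratum identical except for flipped pi_status."""
        return self._partner("pi_status")

    @property
    def diabetes_partner(self) -> np.ndarray:
        return self._partner("diabetes")

    def _partner(self, factor: str) -> np.ndarray:
        tab = self.table()
        idx = self._index_of()
        levels = self.factors[factor]
        pos = list(tab.columns).index(factor)
        out = np.empty(len(tab), dtype=np.intp)
        for i, row in enumerate(tab.itertuples(index=False)):
            key = list(row)
            key[pos] = levels[1] if key[pos] == levels[0] else levels[0]
            out[i] = idx[tuple(key)]
        return out


@dataclass
class Cohort:
    """Expected person counts on the (sex, age, stratum, state) grid."""

    ontology: StratumOntology
    counts: np.ndarray  # (N_SEX, N_AGE, n_strata, N_STATE)

    @classmethod
    def zeros(cls, ontology: StratumOntology) -> "Cohort":
        return cls(ontology, np.zeros((N_SEX, N_AGE, ontology.n_strata, N_STATE)))

    def copy(self) -> "Cohort":
        return Cohort(self.ontology, self.counts.copy())

    def validate(self) -> None:
        if self.counts.shape != (N_SEX, N_AGE, self.ontology.n_strata, N_STATE):
            raise ArgumentError(
                f"cohort counts have shape {self.counts.shape}, expected "
                f"{(N_SEX, N_AGE, self.ontology.n_strata, N_STATE)}"
            )
        if np.any(self.counts < 0):
            raise ArgumentError("negative compartment count")

    def total(self) -> float:
        return float(self.counts.sum())

    def band_totals(self) -> np.ndarray:
        """(N_SEX, N_AGE) persons per sex and age band."""
        return self.counts.sum(axis=(2, 3))

    def inactive_share(self) -> np.ndarray:
        """(N_SEX, N_AGE) proportion physically inactive; 0 where band empty."""
        tot = self.band_totals()
        inact = self.counts[:, :, self.ontology.inactive_mask, :].sum(axis=(2, 3))
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(tot > 0, inact / np.where(tot > 0, tot, 1.0), 0.0)
        return share
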