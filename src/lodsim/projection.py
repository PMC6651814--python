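"""Lifetime-risk projection under competing mortality.

Given an aging coefficient, a population (or a fixed hazard ratio) and a
life table, the projection bookkeeping is

    D(t) = m(t) * S(t),        C(t) = sum_{s <= t} D(s),

where ``m(t)`` is the first-diagnosis mass at age ``t`` among the birth
cohort that is still disease-free (conditional incidence times the
disease-free fraction), ``S(t)`` is the all-cause survivor fraction, and
``C`` accumulates to the lifetime risk.  Mortality and polygenic risk are
treated as independent, so an individual's disease-free survival and the
population survivor curve compose multiplicatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agingcoef import AgingCoefficient, _check_pairing, _yearly_prob
from .architecture import PopulationPRS
from .demography import LifeTable, shift_life_expectancy

__all__ = [
    "ProjectionResult",
    "BeyondHorizon",
    "project_population",
    "project_fixed_hr",
    "hr_grid",
    "onset_delay_slope",
    "years_to_regain_baseline",
]


class BeyondHorizon(ValueError):
    """A threshold age lies beyond the projected age range."""


@dataclass
class ProjectionResult:
    """Per-age incidence, incidence density and cumulative incidence."""

    ages: np.ndarray
    incidence: np.ndarray  # conditional yearly incidence I(t)
    density: np.ndarray  # D(t) = first-diagnosis mass x S(t)
    cumulative: np.ndarray  # C(t), running sum of D
    meta: dict = field(default_factory=dict)

    @property
    def lifetime_risk(self) -> float:
        return float(self.cumulative[-1])

    def age_at_cumulative_fraction(self, fraction: float) -> float:
        """Age (linearly interpolated) where C reaches fraction x lifetime risk."""
        if self.lifetime_risk <= 0:
            raise BeyondHorizon("lifetime risk is zero; threshold never reached")
        target = fraction * self.lifetime_risk
        idx = np.flatnonzero(self.cumulative >= target)
        if idx.size == 0:
            raise BeyondHorizon(f"cumulative incidence never reaches {target:g}")
        t = int(idx[0])
        if t == 0:
            return float(self.ages[0])
        c0, c1 = self.cumulative[t - 1], self.cumulative[t]
        frac = (target - c0) / (c1 - c0) if c1 > c0 else 0.0
        return float(self.ages[t - 1] + frac * (self.ages[t] - self.ages[t - 1]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "incidence": self.incidence,
                "density": self.density,
                "cumulative": self.cumulative,
            }
        )


def _truncate_ages(A: AgingCoefficient, lt: LifeTable) -> np.ndarray:
    n = min(len(A.ages), len(lt.ages))
    return np.arange(n)


def project_population(
    A: AgingCoefficient, pop: PopulationPRS, lt: LifeTable, check_pairing: bool = True
) -> ProjectionResult:
    """Project a whole population's incidence and lifetime risk."""
    if check_pairing:
        _check_pairing(A, pop)
    ages = _truncate_ages(A, lt)
    g = pop.values
    w = pop.weights.copy()
    incidence = np.zeros(len(ages))
    density = np.zeros(len(ages))
    for t in ages:
        pool = w.sum()
        p = _yearly_prob(A.A[t], g, A.transform)
        mass = float(w @ p)
        incidence[t] = mass / pool if pool > 1e-14 else 0.0
        density[t] = mass * lt.S[t]
        w *= 1.0 - p
    cumulative = np.cumsum(density)
    return ProjectionResult(
        ages=ages,
        incidence=incidence,
        density=density,
        cumulative=cumulative,
        meta={"kind": "population", "normalization_key": pop.normalization_key},
    )


def project_fixed_hr(A: AgingCoefficient, hr: float, lt: LifeTable) -> ProjectionResult:
    """Project a single individual at a fixed hazard ratio.

    ``hr`` is the risk multiple relative to the population-mean score
    (reference 1.0).  The lifetime risk is
    ``sum_t p(t) * prod_{s<t}(1 - p(s)) * S(t)`` with
    ``p(t) = clamp(A(t) * hr, 0, 1)``.
    """
    if hr < 0:
        raise ValueError("hr must be >= 0")
    ages = _truncate_ages(A, lt)
    p = _yearly_prob(A.A[ages], np.full(len(ages), hr), A.transform) if hr > 0 else np.zeros(len(ages))
    disease_free = np.concatenate([[1.0], np.cumprod(1.0 - p)[:-1]])
    density = p * disease_free * lt.S[ages]
    cumulative = np.cumsum(density)
    return ProjectionResult(
        ages=ages,
        incidence=p,
        density=density,
        cumulative=cumulative,
        meta={"kind": "fixed_hr", "hr": hr},
    )


DEFAULT_HRS = (16.0, 8.0, 4.0, 2.0, 1.0, 0.5, 0.25, 0.125, 0.0625)
DEFAULT_DELTAS = (0, 5, 10, 15)


def hr_grid(
    A: AgingCoefficient,
    lt: LifeTable,
    hrs=DEFAULT_HRS,
    deltas=DEFAULT_DELTAS,
) -> pd.DataFrame:
    """Lifetime-risk table over a hazard-ratio x life-expectancy-shift grid.

    Rows are hazard ratios, columns are life-expectancy extensions in
    years (column labels ``+0y``, ``+5y``, ...).
    """
    tables = {d: shift_life_expectancy(lt, d) for d in deltas}
    data = {
        f"+{d}y": [project_fixed_hr(A, hr, tables[d]).lifetime_risk for hr in hrs]
        for d in deltas
    }
    return pd.DataFrame(data, index=pd.Index(hrs, name="hr"))


def onset_delay_slope(
    result_a: ProjectionResult, result_b: ProjectionResult, fraction: float = 0.30
) -> int:
    """Onset delay in whole years on the cumulative-incidence slope.

    The age at which each scenario's cumulative incidence reaches
    ``fraction`` of its own lifetime risk is found by linear
    interpolation; the delay is scenario B's age minus scenario A's,
    rounded to whole years.
    """
    if result_a.lifetime_risk <= 0 or result_b.lifetime_risk <= 0:
        raise BeyondHorizon("both scenarios need positive lifetime risk")
    age_a = result_a.age_at_cumulative_fraction(fraction)
    age_b = result_b.age_at_cumulative_fraction(fraction)
    return int(round(age_b - age_a))


def _lifetime_risk(A: AgingCoefficient, pop_or_hr, lt: LifeTable) -> float:
    if isinstance(pop_or_hr, PopulationPRS):
        return project_population(A, pop_or_hr, lt, check_pairing=False).lifetime_risk
    return project_fixed_hr(A, float(pop_or_hr), lt).lifetime_risk


def years_to_regain_baseline(
    A: AgingCoefficient,
    baseline,
    treated,
    lt: LifeTable,
    scan_max: int = 40,
) -> int | None:
    """Years of extra life expectancy until treated risk regains baseline.

    ``baseline`` and ``treated`` are each either a population or a fixed
    hazard ratio.  Returns the smallest integer life-expectancy extension
    ``delta`` such that the treated lifetime risk under the shifted life
    table reaches the baseline lifetime risk under the original table, or
    ``None`` when not reached within ``scan_max`` years (report as
    "> scan_max").
    """
    base_lr = _lifetime_risk(A, baseline, lt)
    for delta in range(scan_max + 1):
        if _lifetime_risk(A, treated, shift_life_expectancy(lt, delta)) >= base_lr:
            return delta
    return None
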