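"""Life tables and yearly incidence-curve functional forms.

Ages are integer years with half-open [t, t+1) intervals; all
probabilities are one-year conditional probabilities, not instantaneous
rates.  Life tables carry the one-year death probability ``q(t)`` and the
survivor fraction ``S(t)`` with ``S(0) = 1`` and
``S(t+1) = S(t) * (1 - q(t))``.  Synthetic tables follow the
Gompertz-Makeham law ``q(t) = a + b * exp(c * t)`` — an age-independent
background term plus exponentially accelerating adult mortality.

Incidence curves support three forms:

``logistic``
    ``I(t) = a / (1 + exp(-k (t - t50)))`` — sigmoid rise to plateau
    ``a``; used for most late-onset diseases.
``exp_then_linear``
    exponential growth ``c * exp(r (t - t0))`` up to a switch age, then a
    linear continuation matching the value and yearly first difference at
    the switch (the breast-cancer-like pattern).
``tabulated``
    explicit per-age values.

All forms return 0 below the onset age and clamp to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "IncidenceCurve",
    "evaluate_incidence",
    "load_life_table",
    "write_life_table",
    "synthesize_life_table",
    "shift_life_expectancy",
]


@dataclass(frozen=True)
class LifeTable:
    ages: np.ndarray
    q: np.ndarray
    S: np.ndarray

    @classmethod
    def from_q(cls, q: np.ndarray) -> "LifeTable":
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q > 1)):
            bad = int(np.argmax((q < 0) | (q > 1)))
            raise ValueError(f"death probability outside [0, 1] at age {bad}")
        S = np.empty_like(q)
        S[0] = 1.0
        np.cumprod(1.0 - q[:-1], out=S[1:])
        return cls(ages=np.arange(len(q)), q=q, S=S)

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def life_expectancy(self) -> float:
        """Expected lifespan as the sum of yearly survivor fractions."""
        return float(self.S.sum())


@dataclass(frozen=True)
class IncidenceCurve:
    """Yearly incidence rate I(t) as a parametric function of age."""

    form: str
    parameters: dict
    onset_age: int = 0

    _FORMS = ("logistic", "exp_then_linear", "tabulated")

    def __post_init__(self) -> None:
        if self.form not in self._FORMS:
            raise ValueError(f"unknown form {self.form!r}; choose from {self._FORMS}")
        if self.onset_age < 0:
            raise ValueError("onset_age must be >= 0")

    def values(self, ages: np.ndarray) -> np.ndarray:
        """Vectorized I(t); zero below onset, clamped to [0, 1]."""
        t = np.asarray(ages, dtype=float)
        p = self.parameters
        if self.form == "logistic":
            a, k, t50 = p["a"], p["k"], p["t50"]
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"logistic plateau a={a} outside [0, 1]")
            raw = a / (1.0 + np.exp(-k * (t - t50)))
        elif self.form == "exp_then_linear":
            c, r, t0, switch = p["c"], p["r"], p["t0"], p["switch_age"]
            g_switch = c * np.exp(r * (switch - t0))
            # linear slope = yearly first difference of the exponential piece
            slope = g_switch * (np.exp(r) - 1.0)
            raw = np.where(
                t <= switch,
                c * np.exp(r * (t - t0)),
                g_switch + slope * (t - switch),
            )
            if np.any(raw > 1.0):
                raise ValueError("exp_then_linear parameters give I(t) > 1")
        else:  # tabulated
            vals = np.asarray(p["values"], dtype=float)
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError("tabulated incidence outside [0, 1]")
            idx = np.clip(t.astype(int), 0, len(vals) - 1)
            raw = vals[idx]
        out = np.clip(raw, 0.0, 1.0)
        return np.where(t < self.onset_age, 0.0, out)


def evaluate_incidence(curve: IncidenceCurve, t: float) -> float:
    """I(t) at a single age."""
    return float(curve.values(np.array([t]))[0])


def load_life_table(path, sex: str = "average") -> LifeTable:
    """Read a life-table CSV.

    Accepts either ``age,q`` (optionally with an ``S`` column, ignored and
    recomputed) or the period-table dialect ``age,q_male,q_female`` with
    ``sex`` selecting ``male``, ``female`` or ``average`` (mean of the two
    one-year death probabilities).  Ages must be contiguous from 0.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    if "age" not in df.columns:
        raise ValueError(f"{path}: missing 'age' column")
    ages = df["age"].to_numpy()
    expected = np.arange(len(ages))
    if not np.array_equal(ages, expected):
        bad = int(np.argmax(ages != expected))
        raise ValueError(f"{path}: ages not contiguous from 0 at row {bad}")
    if "q" in df.columns:
        q = df["q"].to_numpy(dtype=float)
    elif {"q_male", "q_female"} <= set(df.columns):
        if sex == "male":
            q = df["q_male"].to_numpy(dtype=float)
        elif sex == "female":
            q = df["q_female"].to_numpy(dtype=float)
        elif sex == "average":
            q = 0.5 * (df["q_male"].to_numpy(dtype=float) + df["q_female"].to_numpy(dtype=float))
        else:
            raise ValueError(f"sex must be male/female/average, got {sex!r}")
    else:
        raise ValueError(f"{path}: need column 'q' or columns 'q_male','q_female'")
    bad = np.flatnonzero((q < 0) | (q > 1))
    if bad.size:
        raise ValueError(f"{path}: death probability outside [0, 1] at row {int(bad[0])}")
    return LifeTable.from_q(q)


def write_life_table(lt: LifeTable, path) -> None:
    """Write a life table as CSV with columns age, q, S (full precision)."""
    pd.DataFrame({"age": lt.ages, "q": lt.q, "S": lt.S}).to_csv(
        path, index=False, float_format="%.17g"  # round-trip exact
    )


def synthesize_life_table(
    makeham_a: float = 5e-4,
    gompertz_b: float = 3.5e-5,
    gompertz_c: float = 0.09,
    max_age: int = 119,
) -> LifeTable:
    """Gompertz-Makeham life table: q(t) = min(1, a + b * exp(c * t)).

    Defaults give a life expectancy of about 80 years, a realistic modern
    high-income population.
    """
    if makeham_a < 0 or gompertz_b < 0 or gompertz_c < 0:
        raise ValueError("Gompertz-Makeham parameters must be >= 0")
    t = np.arange(max_age + 1)
    q = np.minimum(1.0, makeham_a + gompertz_b * np.exp(gompertz_c * t))
    return LifeTable.from_q(q)


def shift_life_expectancy(lt: LifeTable, delta: int) -> LifeTable:
    """Emulate a longer life expectancy by translating mortality by ``delta`` years.

    ``q'(t) = q(t - delta)`` for ``t >= delta`` and ``q(0)`` below; for
    tables dominated by adult mortality this adds approximately ``delta``
    years of expectancy.  ``delta = 0`` is the identity.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    delta = int(delta)
    if delta == 0:
        return lt
    q = np.concatenate([np.full(delta, lt.q[0]), lt.q[:-delta]])
    return LifeTable.from_q(q)
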