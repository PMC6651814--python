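"""Discovery and application of the aging coefficient A(t).

Under the proportional-hazards frailty model an unaffected individual
with risk score ``G_u`` has a yearly diagnosis probability
``p_u(t) = clamp(A(t) * G_u, 0, 1)``.  The per-age multiplier ``A(t)``
(the aging coefficient) aggregates aging and environmental effects.  It
is *discovered* from a target incidence curve by solving, age by age,

    sum_u w_u(t) * clamp(A * G_u, 0, 1) / sum_u w_u(t) = I(t)

for ``A`` (the left side is non-decreasing in ``A``; bisection), then
depleting the unaffected pool, ``w_u(t+1) = w_u(t) * (1 - p_u(t))``.
High-risk individuals are diagnosed first, so the mean risk score among
still-unaffected individuals falls with age and ``A(t)`` must rise faster
than ``I(t)`` to keep reproducing it — the frailty-depletion signature.

Mortality does not enter the recursion: yearly incidence is conditional
on being alive and disease-free, and mortality is independent of the
risk score.  Mortality enters downstream via the incidence density
``D(t) = I(t) * S(t)``.

An alternative hazard-to-probability transform ``1 - exp(-A * G)`` is
available via ``transform="exponential"``; the direct clamp is the
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .architecture import PopulationPRS

__all__ = ["AgingCoefficient", "CohortState", "discover", "apply"]

_TRANSFORMS = ("clamp", "exponential")


def _yearly_prob(a: float, g: np.ndarray, transform: str) -> np.ndarray:
    if transform == "clamp":
        return np.minimum(a * g, 1.0)
    return 1.0 - np.exp(-a * g)


@dataclass
class AgingCoefficient:
    """Per-age hazard multiplier mapping risk score to yearly probability."""

    ages: np.ndarray
    A: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.A = np.asarray(self.A, dtype=float)
        if self.ages.shape != self.A.shape:
            raise ValueError("ages and A must have the same shape")
        if np.any(self.A < 0):
            raise ValueError("aging coefficient must be non-negative")

    @property
    def transform(self) -> str:
        return self.meta.get("transform", "clamp")

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write (age, A) CSV plus a JSON metadata sidecar."""
        import json
        import pandas as pd
        from pathlib import Path

        pd.DataFrame({"age": self.ages, "A": self.A}).to_csv(path, index=False)
        if sidecar:
            side = Path(path).with_suffix(".meta.json")
            side.write_text(json.dumps(self.meta, indent=2, default=str))

    @classmethod
    def from_csv(cls, path) -> "AgingCoefficient":
        import json
        import pandas as pd
        from pathlib import Path

        df = pd.read_csv(path)
        side = Path(path).with_suffix(".meta.json")
        meta = json.loads(side.read_text()) if side.exists() else {}
        return cls(ages=df["age"].to_numpy(), A=df["A"].to_numpy(), meta=meta)


@dataclass
class CohortState:
    """Unaffected-pool state at the end of a simulated age range."""

    values: np.ndarray  # risk scores G
    weights: np.ndarray  # unaffected mass per value (sums to <= 1)
    age: int

    @property
    def unaffected_fraction(self) -> float:
        return float(self.weights.sum())

    def mean_risk(self) -> float:
        tot = self.weights.sum()
        if tot <= 0:
            return float("nan")
        return float(self.weights @ self.values / tot)


def _check_pairing(A: AgingCoefficient, pop: PopulationPRS) -> None:
    key = A.meta.get("normalization_key")
    if key is not None and key != pop.normalization_key:
        raise ValueError(
            "population is not normalized against the reference used at "
            f"discovery (expected key {key!r}, got {pop.normalization_key!r}); "
            "re-discover on this population or pass the paired one"
        )


def discover(
    curve,
    pop: PopulationPRS,
    max_age: int = 119,
    transform: str = "clamp",
    tol: float = 1e-12,
) -> AgingCoefficient:
    """Invert an incidence curve into the aging coefficient A(t).

    For each age from 0 to ``max_age`` the population-mean yearly
    probability under ``A`` is matched to ``I(t)`` by bisection to
    absolute tolerance ``tol`` on the incidence mismatch, then the
    unaffected masses are depleted.  Ages with ``I(t) = 0`` get
    ``A(t) = 0`` and no depletion.

    Raises if ``I(t) >= 1`` anywhere (the multiplier is not identifiable
    with bounded risk-score support) and truncates with a warning if the
    unaffected pool is exhausted (cumulative risk reached 1).
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"transform must be one of {_TRANSFORMS}")
    ages = np.arange(max_age + 1)
    target = curve.values(ages)
    if np.any(target >= 1.0):
        bad = int(np.argmax(target >= 1.0))
        raise ValueError(
            f"incidence reaches 1 at age {bad}: aging coefficient not "
            "identifiable with bounded risk-score support"
        )
    g = pop.values
    w = pop.weights.copy()
    A = np.zeros_like(target)
    truncated_at: int | None = None
    for t in ages:
        it = target[t]
        if it <= 0.0:
            continue
        pool = w.sum()
        if pool <= 1e-14:
            truncated_at = int(t)
            warnings.warn(
                f"unaffected pool exhausted at age {t}; aging coefficient "
                "truncated (cumulative risk reached 1)",
                RuntimeWarning,
            )
            A[t:] = 0.0
            break
        A[t] = _solve_age(it, g, w, pool, transform, tol)
        w *= 1.0 - _yearly_prob(A[t], g, transform)
    meta = {
        "normalization_key": pop.normalization_key,
        "transform": transform,
        "max_age": int(max_age),
        "curve": {"form": curve.form, "parameters": curve.parameters, "onset_age": curve.onset_age},
        "truncated_at": truncated_at,
    }
    return AgingCoefficient(ages=ages, A=A, meta=meta)


def _solve_age(
    it: float, g: np.ndarray, w: np.ndarray, pool: float, transform: str, tol: float
) -> float:
    def mean_prob(a: float) -> float:
        return float(w @ _yearly_prob(a, g, transform)) / pool

    mean_g = float(w @ g) / pool
    # Below clamp saturation the equation is linear, mean_prob(a) = a * mean G,
    # and the bisection fixed point has the closed form a = I / mean G; taking
    # it directly avoids bisecting to the floating-point noise floor at tiny
    # incidence values.
    if transform == "clamp" and mean_g > 0:
        a_lin = it / mean_g
        if a_lin * float(g.max()) <= 1.0:
            return a_lin
    # geometric bracket growth, then bisection
    hi = it / mean_g if mean_g > 0 else it
    if hi <= 0.0:
        hi = it
    while mean_prob(hi) < it:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("bisection bracket growth failed")
    lo = 0.0
    tol_eff = min(tol, it * 1e-12)  # keep relative round-trip error ~1e-12
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f = mean_prob(mid)
        if abs(f - it) <= tol_eff:
            return mid
        if f < it:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def apply(
    A: AgingCoefficient,
    pop: PopulationPRS,
    mode: str = "expectation",
    seed: int | None = None,
    check_pairing: bool = True,
) -> tuple[np.ndarray, CohortState]:
    """Simulate aging of a population under a given aging coefficient.

    Returns the per-age conditional incidence trajectory and the final
    unaffected-pool state.  ``expectation`` mode evolves weighted masses
    deterministically; ``stochastic`` mode draws per-individual Bernoulli
    diagnosis outcomes under ``seed`` (requires an equal-weight,
    per-individual population).

    The population must carry the normalization key recorded at discovery
    (therapy-modified populations keep their pre-therapy key, since the
    normalization reference is unchanged); pass ``check_pairing=False``
    to bypass for deliberately re-referenced populations.
    """
    if mode not in ("expectation", "stochastic"):
        raise ValueError("mode must be 'expectation' or 'stochastic'")
    if check_pairing:
        _check_pairing(A, pop)
    transform = A.transform
    n_ages = len(A.ages)
    g = pop.values
    incidence = np.zeros(n_ages)
    if mode == "expectation":
        w = pop.weights.copy()
        for t in range(n_ages):
            pool = w.sum()
            if pool <= 1e-14:
                break
            p = _yearly_prob(A.A[t], g, transform)
            incidence[t] = float(w @ p) / pool
            w *= 1.0 - p
        state = CohortState(values=g, weights=w, age=n_ages - 1)
    else:
        if not np.allclose(pop.weights, pop.weights[0]):
            raise ValueError("stochastic mode requires an equal-weight individual population")
        rng = np.random.default_rng(seed)
        unaffected = np.ones(len(g), dtype=bool)
        for t in range(n_ages):
            n_pool = int(unaffected.sum())
            if n_pool == 0:
                break
            p = _yearly_prob(A.A[t], g[unaffected], transform)
            hits = rng.random(n_pool) < p
            incidence[t] = hits.sum() / n_pool
            idx = np.flatnonzero(unaffected)
            unaffected[idx[hits]] = False
        w = np.where(unaffected, pop.weights, 0.0)
        state = CohortState(values=g, weights=w, age=n_ages - 1)
    return incidence, state
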