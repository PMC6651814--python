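"""Prophylactic gene-therapy emulation: population-wide PRS lowering.

Therapy is corrective only — detrimental alleles are reverted to the
neutral state, never below — so the risk multiplier is at most 1.  Two
modes are provided:

``uniform_multiplier`` (default)
    every individual's risk score is scaled by the OR multiplier; the
    normalization reference is kept, so post-therapy risk stays expressed
    relative to the *pre-therapy* population mean.
``allele_editing``
    per individual, detrimental alleles are reverted one at a time,
    largest-OR class first, until the individual's own risk multiplier
    reaches the target (individuals with few detrimental alleles may
    overshoot the target reduction).  Requires a genotype-level
    (stochastic-mode) population.

The post-therapy population is aged under the *baseline* aging
coefficient: the aging/environment process is assumed unaffected by the
therapy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .agingcoef import AgingCoefficient
from .architecture import (
    ArchitectureScenario,
    PopulationPRS,
    multiplier_for_edits,
    n_edits_for_multiplier,
)
from .demography import LifeTable, shift_life_expectancy
from .projection import project_population

__all__ = ["TherapySpec", "apply_therapy", "therapy_scenarios"]


@dataclass(frozen=True)
class TherapySpec:
    """Specification of a PRS-lowering intervention.

    Exactly one of ``or_multiplier`` / ``n_edits`` is given; the other is
    derived from the architecture's mean per-allele effect.
    """

    mode: str = "uniform_multiplier"
    or_multiplier: float | None = None
    n_edits: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("uniform_multiplier", "allele_editing"):
            raise ValueError(f"unknown therapy mode {self.mode!r}")
        if (self.or_multiplier is None) == (self.n_edits is None):
            raise ValueError("specify exactly one of or_multiplier / n_edits")
        if self.or_multiplier is not None and not 0.0 < self.or_multiplier <= 1.0:
            raise ValueError("or_multiplier must be in (0, 1] (corrective only)")
        if self.n_edits is not None and self.n_edits < 0:
            raise ValueError("n_edits must be >= 0")

    def resolve_multiplier(self, arch: ArchitectureScenario) -> float:
        if self.or_multiplier is not None:
            return self.or_multiplier
        return multiplier_for_edits(arch, self.n_edits)

    def resolve_edits(self, arch: ArchitectureScenario) -> int:
        if self.n_edits is not None:
            return int(round(self.n_edits))
        return n_edits_for_multiplier(arch, self.or_multiplier)


def apply_therapy(
    pop: PopulationPRS, spec: TherapySpec, arch: ArchitectureScenario
) -> PopulationPRS:
    """Return the post-therapy population.

    The normalization key and reference are preserved: post-therapy
    scores remain relative to the pre-therapy population mean, so a
    multiplier ``m`` moves the population mean risk to ``m``.
    """
    m = spec.resolve_multiplier(arch)
    if m == 1.0:
        return pop
    if spec.mode == "uniform_multiplier":
        return replace(
            pop,
            values=pop.values * m,
            weights=pop.weights.copy(),
            meta={**pop.meta, "therapy_multiplier": m},
        )
    # allele_editing
    if pop.dosages is None:
        raise ValueError(
            "allele_editing requires a genotype-level population "
            "(sample_population); expectation-mode users should use "
            "mode='uniform_multiplier'"
        )
    dosages = pop.dosages.copy()
    values = pop.values.copy()
    ln_target = np.log(m)
    ln_ratio = np.zeros(len(values))  # per-individual ln of achieved multiplier
    # revert whole classes largest-OR first, partially in the last class
    order = np.argsort(arch.ln_ors)[::-1]
    edits = np.zeros(len(values))
    for k in order:
        b = arch.ln_ors[k]
        if b <= 0:
            break
        need = ln_target - ln_ratio  # still-negative amount of ln-risk to remove
        # number of alleles to revert in class k (ceil of need / -b), capped
        want = np.ceil(-need / b - 1e-12)
        e = np.clip(want, 0, dosages[:, k]).astype(int)
        e[need >= 0] = 0
        dosages[:, k] -= e
        ln_ratio -= e * b
        edits += e
    return replace(
        pop,
        values=values * np.exp(ln_ratio),
        weights=pop.weights.copy(),
        dosages=dosages,
        meta={
            **pop.meta,
            "therapy_multiplier": m,
            "mean_edits": float(edits.mean()),
        },
    )


def therapy_scenarios(
    A: AgingCoefficient,
    pop: PopulationPRS,
    spec: TherapySpec,
    lt: LifeTable,
    deltas=(0, 5, 10, 15),
    arch: ArchitectureScenario | None = None,
) -> pd.DataFrame:
    """Post-therapy lifetime risk across life-expectancy extensions.

    Reports, per extension ``delta``, the treated population's lifetime
    risk and the same as a percentage of the untreated baseline at the
    unshifted life table (baseline = 100%).
    """
    if arch is None and spec.or_multiplier is None:
        raise ValueError("arch is required when the spec is given as n_edits")
    baseline = project_population(A, pop, lt).lifetime_risk
    treated = apply_therapy(pop, spec, arch) if arch is not None else replace(
        pop, values=pop.values * spec.or_multiplier, weights=pop.weights.copy()
    )
    rows = []
    for d in deltas:
        lr = project_population(
            A, treated, shift_life_expectancy(lt, d), check_pairing=True
        ).lifetime_risk
        rows.append(
            {
                "delta_years": d,
                "lifetime_risk": lr,
                "pct_of_baseline": 100.0 * lr / baseline if baseline > 0 else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("delta_years")
    out.attrs["baseline_lifetime_risk"] = baseline
    return out
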