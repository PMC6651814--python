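"""Model genetic architectures and multiplicative polygenic risk scores.

A genetic architecture is a grid of allele classes, each defined by a minor
allele frequency (MAF) and a per-allele odds ratio (OR), together with the
number of causal SNPs assigned to each class.  An individual's polygenic
risk score is the product of per-allele ORs over their detrimental-allele
dosages, i.e. ``G = exp(sum_k ln(OR_k) * g_k)`` with ``g_k`` the
Hardy-Weinberg genotype dosage (0, 1 or 2) at SNP ``k``.  Scores are
normalized so the population mean is 1, which makes "hazard ratio 1.0"
mean population-average risk throughout the package.

Two architecture scenarios are provided: ``common_low`` (common alleles,
MAF 0.073-0.5, per-allele OR 1.05-1.15) and ``rare_medium`` (rare alleles,
MAF 0.0146-0.0998, OR 1.28-2.01).  Each scenario crosses 5 MAF values with
5 OR values into 25 allele classes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlleleClass",
    "ArchitectureScenario",
    "PopulationPRS",
    "SCENARIO_GRIDS",
    "build_architecture",
    "sample_population",
    "build_population",
    "n_edits_for_multiplier",
    "multiplier_for_edits",
    "n_snps_for_variance",
    "write_population_csv",
]

# 5 MAF x 5 OR grids defining the two architecture scenarios.
SCENARIO_GRIDS: dict[str, dict[str, tuple[float, ...]]] = {
    "common_low": {
        "maf": (0.073, 0.18, 0.286, 0.393, 0.5),
        "or_per_allele": (1.05, 1.075, 1.1, 1.125, 1.15),
    },
    "rare_medium": {
        "maf": (0.0146, 0.036, 0.0572, 0.0785, 0.0998),
        "or_per_allele": (1.28, 1.463, 1.645, 1.828, 2.01),
    },
}


@dataclass(frozen=True)
class AlleleClass:
    """One (MAF, OR) cell of the architecture grid.

    Parameters
    ----------
    maf : float
        Minor (detrimental) allele frequency, 0 < maf <= 0.5.
    or_per_allele : float
        Odds-ratio multiplier per detrimental allele, >= 1.
    """

    maf: float
    or_per_allele: float

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.or_per_allele < 1.0:
            raise ValueError(
                f"or_per_allele must be >= 1, got {self.or_per_allele}"
            )

    @property
    def ln_or(self) -> float:
        return float(np.log(self.or_per_allele))


@dataclass(frozen=True)
class ArchitectureScenario:
    """A grid of allele classes plus per-class causal SNP counts."""

    classes: tuple[AlleleClass, ...]
    snps_per_class: tuple[int, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.snps_per_class):
            raise ValueError("classes and snps_per_class length mismatch")
        if any(n < 0 for n in self.snps_per_class):
            raise ValueError("snps_per_class must be non-negative")

    @property
    def n_snps(self) -> int:
        return int(sum(self.snps_per_class))

    @property
    def mafs(self) -> np.ndarray:
        return np.array([c.maf for c in self.classes])

    @property
    def ln_ors(self) -> np.ndarray:
        return np.array([c.ln_or for c in self.classes])

    def ln_score_moments(self) -> tuple[float, float]:
        """Mean and variance of ln G under Hardy-Weinberg sampling.

        Per-SNP dosage is Binomial(2, p), so a class of n iid SNPs
        contributes ``2 n p ln(OR)`` to the mean and
        ``2 n p (1-p) ln(OR)^2`` to the variance.
        """
        n = np.asarray(self.snps_per_class, dtype=float)
        p = self.mafs
        b = self.ln_ors
        mean = float(np.sum(2.0 * n * p * b))
        var = float(np.sum(2.0 * n * p * (1.0 - p) * b**2))
        return mean, var

    def digest(self) -> str:
        """Short stable hash identifying the architecture."""
        h = hashlib.sha1()
        for c, n in zip(self.classes, self.snps_per_class):
            h.update(f"{c.maf!r}:{c.or_per_allele!r}:{n};".encode())
        return h.hexdigest()[:12]


@dataclass
class PopulationPRS:
    """Weighted distribution of multiplicative risk scores G.

    ``values`` are per-individual (stochastic mode, uniform weights) or
    per-quantile-bin (expectation mode) scores, normalized so the weighted
    mean is 1.  ``normalization_reference`` is the raw-score mean the
    values were divided by; ``normalization_key`` pairs a population with
    the aging coefficient discovered on it.
    """

    values: np.ndarray
    weights: np.ndarray
    normalization_reference: float
    normalization_key: str
    dosages: np.ndarray | None = None  # (n_individuals, n_classes), stochastic mode
    arch_digest: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.values.shape != self.weights.shape:
            raise ValueError("values and weights must have the same shape")
        if np.any(self.values <= 0):
            raise ValueError("risk scores must be positive")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 within 1e-12")

    @property
    def mean(self) -> float:
        return float(self.weights @ self.values)

    def ln_variance(self) -> float:
        ln = np.log(self.values)
        m = self.weights @ ln
        return float(self.weights @ (ln - m) ** 2)


def build_architecture(scenario_name: str, n_snps: int) -> ArchitectureScenario:
    """Build an architecture by spreading ``n_snps`` over the 25-class grid.

    SNPs are allocated as evenly as possible; any remainder is assigned one
    SNP at a time to classes in grid order (MAF-major, OR-minor).
    """
    if n_snps < 1:
        raise ValueError(f"n_snps must be >= 1, got {n_snps}")
    try:
        grid = SCENARIO_GRIDS[scenario_name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario_name!r}; "
            f"choose from {sorted(SCENARIO_GRIDS)}"
        ) from None
    classes = tuple(
        AlleleClass(maf=m, or_per_allele=o)
        for m in grid["maf"]
        for o in grid["or_per_allele"]
    )
    k = len(classes)
    base, rem = divmod(n_snps, k)
    counts = tuple(base + (1 if i < rem else 0) for i in range(k))
    return ArchitectureScenario(classes, counts, name=scenario_name)


def sample_population(
    arch: ArchitectureScenario, n_individuals: int, seed: int
) -> PopulationPRS:
    """Draw a population of individual risk scores under Hardy-Weinberg.

    For each allele class the total detrimental-allele dosage of an
    individual is Binomial(2 * n_class, maf), equivalent to summing iid
    per-SNP Binomial(2, maf) dosages.  Raw scores ``prod OR^dosage`` are
    divided by their sample mean so the population mean is exactly 1.
    """
    if n_individuals < 1:
        raise ValueError(f"n_individuals must be >= 1, got {n_individuals}")
    rng = np.random.default_rng(seed)
    n_alleles = 2 * np.asarray(arch.snps_per_class)
    dosages = rng.binomial(
        n_alleles[None, :], arch.mafs[None, :], size=(n_individuals, len(arch.classes))
    )
    ln_raw = dosages @ arch.ln_ors
    raw = np.exp(ln_raw)
    ref = float(raw.mean())
    weights = np.full(n_individuals, 1.0 / n_individuals)
    # renormalize weights exactly to 1 to absorb float accumulation
    weights /= weights.sum()
    return PopulationPRS(
        values=raw / ref,
        weights=weights,
        normalization_reference=ref,
        normalization_key=f"{arch.digest()}:sample:{n_individuals}:{seed}",
        dosages=dosages,
        arch_digest=arch.digest(),
        meta={"mode": "stochastic", "seed": seed},
    )


def build_population(arch: ArchitectureScenario, n_bins: int = 10001) -> PopulationPRS:
    """Deterministic quantile-binned population (expectation mode).

    With hundreds to thousands of small-effect SNPs, ln G is a sum of many
    independent bounded terms and is well approximated as normal with the
    analytic Hardy-Weinberg moments.  The distribution is represented by
    ``n_bins`` equal-mass midpoint quantiles of that normal, then
    renormalized to weighted mean exactly 1.
    """
    from scipy.stats import norm

    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    mean, var = arch.ln_score_moments()
    z = norm.ppf((np.arange(n_bins) + 0.5) / n_bins)
    ln_raw = mean + np.sqrt(var) * z
    raw = np.exp(ln_raw)
    weights = np.full(n_bins, 1.0 / n_bins)
    weights /= weights.sum()
    ref = float(weights @ raw)
    return PopulationPRS(
        values=raw / ref,
        weights=weights,
        normalization_reference=ref,
        normalization_key=f"{arch.digest()}:bins:{n_bins}",
        arch_digest=arch.digest(),
        meta={"mode": "expectation", "n_bins": n_bins},
    )


def _mean_ln_or(arch: ArchitectureScenario) -> float:
    # unweighted mean over grid classes: an "average" causal SNP effect
    return float(np.mean(arch.ln_ors))


def n_edits_for_multiplier(arch: ArchitectureScenario, or_multiplier: float) -> int:
    """Average number of single-allele corrections matching an OR multiplier.

    Editing one average detrimental allele divides the risk score by the
    mean per-allele OR, so a target multiplier ``m`` costs
    ``round(ln(1/m) / mean_ln_or)`` edits.
    """
    if not 0.0 < or_multiplier <= 1.0:
        raise ValueError(f"or_multiplier must be in (0, 1], got {or_multiplier}")
    if or_multiplier == 1.0:
        return 0
    mean_ln = _mean_ln_or(arch)
    if mean_ln <= 0.0:
        raise ValueError(
            "architecture has no detrimental effects (all OR = 1); "
            "a multiplier < 1 cannot be realized by editing"
        )
    return int(round(np.log(1.0 / or_multiplier) / mean_ln))


def multiplier_for_edits(arch: ArchitectureScenario, n_edits: float) -> float:
    """OR multiplier achieved by ``n_edits`` average-effect corrections."""
    if n_edits < 0:
        raise ValueError("n_edits must be >= 0")
    return float(np.exp(-n_edits * _mean_ln_or(arch)))


def n_snps_for_variance(scenario_name: str, target_ln_variance: float) -> int:
    """SNP count making a scenario's analytic ln G variance match a target.

    Used to calibrate the rare-allele scenario to the same ln-score
    variance as a common-allele architecture so their downstream risk
    projections can be compared on equal footing.
    """
    if target_ln_variance <= 0:
        raise ValueError("target_ln_variance must be positive")
    per_snp = build_architecture(scenario_name, 25).ln_score_moments()[1] / 25.0
    guess = max(1, int(round(target_ln_variance / per_snp)))
    # exact variance is stepwise in n (remainder allocation); refine locally
    best_n, best_err = guess, float("inf")
    for n in range(max(1, guess - 30), guess + 31):
        var = build_architecture(scenario_name, n).ln_score_moments()[1]
        err = abs(var - target_ln_variance)
        if err < best_err:
            best_n, best_err = n, err
    return best_n


def write_population_csv(pop: PopulationPRS, path) -> None:
    """Export a population as CSV with columns index_or_bin, G, weight."""
    import pandas as pd

    pd.DataFrame(
        {
            "index_or_bin": np.arange(len(pop.values)),
            "G": pop.values,
            "weight": pop.weights,
        }
    ).to_csv(path, index=False)
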