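"""Self-contained synthetic inputs: incidence curves, life tables, architectures.

Three incidence fixtures span the qualitative regimes of late-onset
disease epidemiology:

``cancer_like``
    low logistic plateau (0.005/yr) giving a baseline lifetime risk of
    roughly 6% — the low-lifetime-risk regime where risk scales
    proportionally with the hazard ratio.
``t2d_like``
    moderate plateau (0.025/yr) reached in middle age — a
    high-lifetime-risk metabolic-disease pattern.
``ad_like``
    steep late logistic with a high plateau (0.30/yr past age ~90) —
    the dementia pattern whose lifetime risk keeps climbing at the oldest
    ages and responds least to risk reduction.

The default life table is Gompertz-Makeham with life expectancy ~80
years.  Everything is generated programmatically; nothing is downloaded.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .architecture import ArchitectureScenario, build_architecture
from .demography import IncidenceCurve, LifeTable, synthesize_life_table, write_life_table

__all__ = [
    "FIXTURE_KINDS",
    "fixture_incidence",
    "fixture_life_table",
    "fixture_architecture",
    "generate_fixtures",
    "load_incidence_config",
    "write_incidence_config",
    "write_architecture_config",
    "load_architecture_config",
]

FIXTURE_KINDS = ("cancer_like", "t2d_like", "ad_like")

_FIXTURE_CURVES = {
    "cancer_like": {
        "form": "logistic",
        "parameters": {"a": 0.005, "k": 0.25, "t50": 70.0},
        "onset_age": 40,
    },
    "t2d_like": {
        "form": "logistic",
        "parameters": {"a": 0.025, "k": 0.15, "t50": 60.0},
        "onset_age": 25,
    },
    "ad_like": {
        "form": "logistic",
        "parameters": {"a": 0.30, "k": 0.30, "t50": 88.0},
        "onset_age": 60,
    },
}


def fixture_incidence(kind: str) -> IncidenceCurve:
    """One of the three synthetic incidence regimes."""
    try:
        return IncidenceCurve(**_FIXTURE_CURVES[kind])
    except KeyError:
        raise ValueError(
            f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}"
        ) from None


def fixture_life_table(max_age: int = 119) -> LifeTable:
    """Default Gompertz-Makeham life table (life expectancy ~80 years)."""
    return synthesize_life_table(max_age=max_age)


def fixture_architecture(
    n_snps: int = 400, scenario: str = "common_low"
) -> ArchitectureScenario:
    """Default common-allele architecture for fixture runs."""
    return build_architecture(scenario, n_snps)


def write_incidence_config(curve: IncidenceCurve, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "form": curve.form,
                "parameters": {k: float(v) for k, v in curve.parameters.items()}
                if curve.form != "tabulated"
                else {"values": [float(v) for v in curve.parameters["values"]]},
                "onset_age": int(curve.onset_age),
            }
        )
    )


def load_incidence_config(path) -> IncidenceCurve:
    cfg = yaml.safe_load(Path(path).read_text())
    return IncidenceCurve(
        form=cfg["form"],
        parameters=cfg["parameters"],
        onset_age=int(cfg.get("onset_age", 0)),
    )


def write_architecture_config(arch: ArchitectureScenario, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "name": arch.name,
                "classes": [
                    {"maf": float(c.maf), "or_per_allele": float(c.or_per_allele)}
                    for c in arch.classes
                ],
                "snps_per_class": [int(n) for n in arch.snps_per_class],
            }
        )
    )


def load_architecture_config(path) -> ArchitectureScenario:
    from .architecture import AlleleClass

    cfg = yaml.safe_load(Path(path).read_text())
    return ArchitectureScenario(
        classes=tuple(
            AlleleClass(maf=c["maf"], or_per_allele=c["or_per_allele"])
            for c in cfg["classes"]
        ),
        snps_per_class=tuple(cfg["snps_per_class"]),
        name=cfg.get("name", "custom"),
    )


def generate_fixtures(kind: str, seed: int, outdir) -> dict[str, Path]:
    """Write a self-contained fixture bundle (incidence YAML, life-table CSV,
    architecture YAML) and return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    curve = fixture_incidence(kind)
    lt = fixture_life_table()
    arch = fixture_architecture()
    paths = {
        "incidence": outdir / f"{kind}_incidence.yaml",
        "life_table": outdir / "life_table.csv",
        "architecture": outdir / "architecture.yaml",
    }
    write_incidence_config(curve, paths["incidence"])
    write_life_table(lt, paths["life_table"])
    write_architecture_config(arch, paths["architecture"])
    return paths
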