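"""Disease presets: architecture sizes, heritabilities and synthetic curves.

Eight common late-onset diseases (LODs) are shipped as presets carrying
the common-allele-architecture SNP count needed to reach each disease's
familial heritability, the heritability itself, and the sex of the
reference life table where the disease is sex-specific.  The SNP counts
are inputs (the liability-scale calibration that produces them is out of
scope here).

Each preset also carries a *synthetic* incidence curve whose form and
plateau magnitude are anchored to the disease's published maximum yearly
incidence rate.  These curves are stand-ins for clinically fitted
incidence regressions (which depend on proprietary fit parameters) and
are intended for end-to-end runs and qualitative scenario work, not for
reproducing clinical incidence itself.
"""

from __future__ import annotations

from .demography import IncidenceCurve

__all__ = ["DISEASE_PRESETS", "preset_curve"]

# name -> (snp_count, heritability, sex, curve spec)
DISEASE_PRESETS: dict[str, dict] = {
    "alzheimers": {
        "snp_count": 3575,
        "heritability": 0.795,
        "sex": "average",
        "curve": {
            "form": "logistic",
            "parameters": {"a": 0.30, "k": 0.30, "t50": 88.0},
            "onset_age": 60,
        },
    },
    "t2d": {
        "snp_count": 2125,
        "heritability": 0.69,
        "sex": "average",
        "curve": {
            "form": "logistic",
            "parameters": {"a": 0.025, "k": 0.15, "t50": 60.0},
            "onset_age": 25,
        },
    },
    "stroke": {
        "snp_count": 1175,
        "heritability": 0.55,
        "sex": "average",
        "curve": {
            "form": "logistic",
            "parameters": {"a": 0.044, "k": 0.18, "t50": 78.0},
            "onset_age": 30,
        },
    },
    "cad": {
        "snp_count": 625,
        "heritability": 0.41,
        "sex": "average",
        "curve": {
            "form": "logistic",
            "parameters": {"a": 0.036, "k": 0.16, "t50": 74.0},
            "onset_age": 30,
        },
    },
    "breast_cancer": {
        "snp_count": 1250,
        "heritability": 0.57,
        "sex": "female",
        # exponential rise through mid-life, then linear continuation
        "curve": {
            "form": "exp_then_linear",
            "parameters": {"c": 1.3e-4, "r": 0.08, "t0": 25.0, "switch_age": 65.0},
            "onset_age": 25,
        },
    },
    "prostate_cancer": {
        "snp_count": 600,
        "heritability": 0.40,
        "sex": "male",
        "curve": {
            "form": "logistic",
            "parameters": {"a": 0.008, "k": 0.22, "t50": 74.0},
            "onset_age": 45,
        },
    },
    "colorectal_cancer": {
        "snp_count": 400,
        "heritability": 0.31,
        "sex": "average",
        "curve": {
            "form": "logistic",
            "parameters": {"a": 0.006, "k": 0.20, "t50": 75.0},
            "onset_age": 40,
        },
    },
    "lung_cancer": {
        "snp_count": 100,
        "heritability": 0.10,
        "sex": "average",
        "curve": {
            "form": "logistic",
            "parameters": {"a": 0.006, "k": 0.22, "t50": 76.0},
            "onset_age": 40,
        },
    },
}


def preset_curve(name: str) -> IncidenceCurve:
    """Synthetic incidence curve for a disease preset."""
    try:
        spec = DISEASE_PRESETS[name]["curve"]
    except KeyError:
        raise ValueError(
            f"unknown disease preset {name!r}; choose from {sorted(DISEASE_PRESETS)}"
        ) from None
    return IncidenceCurve(**spec)
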