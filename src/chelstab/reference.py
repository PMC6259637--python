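"""Published reference values for the reproduction report.

These are the literature-reported connectivity indices, regression
summaries and per-complex model estimates that the ``reproduce`` command
recomputes and compares against.  They are reference data for
verification only — nothing in the computation path reads them.
"""

from __future__ import annotations

#: (metal, ligand) -> (chi mono, chi bis), printed to 2 decimals.
PUBLISHED_CHI: dict[tuple[str, str], tuple[float, float]] = {
    ("Ni", "glycine"): (1.90, 5.37),
    ("Co", "glycine"): (1.99, 5.65),
    ("Fe", "glycine"): (2.10, 5.97),
    ("Mn", "glycine"): (2.24, 6.36),
    ("Ni", "alanine"): (2.32, 6.02),
    ("Co", "alanine"): (2.42, 6.30),
    ("Fe", "alanine"): (2.55, 6.64),
    ("Mn", "alanine"): (2.70, 7.05),
    ("Ni", "valine"): (2.75, 6.89),
    ("Co", "valine"): (2.85, 7.15),
    ("Fe", "valine"): (2.96, 7.47),
    ("Mn", "valine"): (3.10, 7.85),
    ("Ni", "leucine"): (2.85, 7.08),
    ("Co", "leucine"): (2.95, 7.35),
    ("Mn", "leucine"): (3.20, 8.06),
}

#: (metal, ligand) -> (model log K1, model log beta2); None where not reported.
PUBLISHED_ESTIMATES: dict[tuple[str, str], tuple[float | None, float | None]] = {
    ("Ni", "glycine"): (6.21, 11.11),
    ("Co", "glycine"): (5.18, 9.25),
    ("Fe", "glycine"): (4.24, 7.65),
    ("Mn", "glycine"): (3.51, 6.58),
    ("Ni", "alanine"): (5.93, 10.69),
    ("Co", "alanine"): (4.79, 8.76),
    ("Fe", "alanine"): (None, 7.13),
    ("Mn", "alanine"): (3.09, 6.10),
    ("Co", "valine"): (4.59, 8.32),
    ("Fe", "valine"): (None, 6.74),
    ("Mn", "valine"): (2.91, 5.64),
    ("Ni", "leucine"): (5.57, 10.01),
    ("Co", "leucine"): (4.50, 8.16),
    ("Mn", "leucine"): (2.81, 5.48),
}

#: Regression summaries: coefficients with their standard errors, r,
#: standard error of estimate and of LOO cross-validation.
PUBLISHED_MODELS: dict[str, dict] = {
    "K1": {
        "n": 12,
        "a1": 12.2, "a1_se": 1.4,
        "a2": -12.10, "a2_se": 0.55,
        "a3": -0.676, "a3_se": 0.046,
        "intercept": 7.49, "intercept_se": 0.12,
        "r": 0.999,
        "se": 0.05,
        "se_cv": 0.08,
        "max_cv_error": 0.13,
    },
    "B2": {
        "n": 14,
        "a1": 3.10, "a1_se": 0.33,
        "a2": -7.66, "a2_se": 0.36,
        "a3": -0.646, "a3_se": 0.052,
        "intercept": 14.58, "intercept_se": 0.33,
        "r": 0.998,
        "se": 0.11,
        "se_cv": 0.15,
        "max_cv_error": 0.29,
    },
}

#: Comparison tolerances for the reproduction report: chi to half a unit in
#: the last printed decimal; coefficients to their published standard error;
#: fit statistics and per-complex estimates as listed.
TOLERANCES = {
    "chi": 0.005,
    "r": 0.001,
    "se": 0.01,
    "se_cv": 0.02,
    "max_cv_error": 0.05,
    "estimate": 0.05,
}
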