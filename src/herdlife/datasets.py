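"""Published stage-survival genetic parameters for Korean Holstein.

These are the national-scale estimates for the nine stage-wise survival
traits (three lactation stages within each of the first three parities),
obtained from averaged three-trait animal-model REML runs on uncensored
test-day records.  They serve as in-package inputs for the parity-level
aggregation and for worked examples; everything else in the package is
recomputed from data.

Trait order everywhere in this package is::

    L1.1 L1.2 L1.3 L2.1 L2.2 L2.3 L3.1 L3.2 L3.3

where ``L<parity>.<stage>`` and stages are early (days in milk 0-90),
mid (91-299) and late (300 to the next calving).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TRAITS = (
    "L1.1", "L1.2", "L1.3",
    "L2.1", "L2.2", "L2.3",
    "L3.1", "L3.2", "L3.3",
)

#: parity of each trait (1-based), aligned with TRAITS
TRAIT_PARITY = (1, 1, 1, 2, 2, 2, 3, 3, 3)

# Stage-level estimates: contributing-run count, additive variance (mean, SD),
# phenotypic variance (mean, SD), heritability (mean, SD).
_STAGE_ROWS = [
    # trait   n   va_mean   va_sd     vp_mean   vp_sd     h2     h2_sd
    ("L1.1", 27, 0.000083, 0.000004, 0.025140, 0.000001, 0.003, 0.000),
    ("L1.2", 28, 0.000157, 0.000017, 0.047193, 0.000153, 0.003, 0.000),
    ("L1.3", 28, 0.003129, 0.000314, 0.139371, 0.000115, 0.022, 0.002),
    ("L2.1", 28, 0.000117, 0.000013, 0.030623, 0.000036, 0.004, 0.000),
    ("L2.2", 28, 0.000543, 0.000044, 0.073981, 0.000163, 0.007, 0.001),
    ("L2.3", 28, 0.003783, 0.000381, 0.148158, 0.000131, 0.026, 0.003),
    ("L3.1", 28, 0.000242, 0.000033, 0.041053, 0.000026, 0.006, 0.001),
    ("L3.2", 27, 0.001269, 0.000064, 0.088283, 0.000112, 0.014, 0.001),
    ("L3.3", 27, 0.004590, 0.000845, 0.166806, 0.000253, 0.028, 0.005),
]

# Mean genetic correlations (upper triangle, row-by-row in trait order).
_RG_UPPER = {
    "L1.1": (0.94, 0.19, 0.77, 0.65, 0.25, 0.48, 0.71, 0.16),
    "L1.2": (0.42, 0.78, 0.65, 0.26, 0.72, 0.67, 0.34),
    "L1.3": (0.19, 0.57, 0.96, 0.65, 0.50, 0.95),
    "L2.1": (0.85, 0.52, 0.96, 0.30, 0.41),
    "L2.2": (0.67, 0.92, 0.99, 0.68),
    "L2.3": (0.85, 0.51, 0.99),
    "L3.1": (0.57, 0.77),
    "L3.2": (0.71,),
}


def stage_parameters() -> pd.DataFrame:
    """Stage-level variance components, one row per survival trait."""
    return pd.DataFrame(
        _STAGE_ROWS,
        columns=[
            "trait", "n_runs",
            "additive_variance", "additive_variance_sd",
            "phenotypic_variance", "phenotypic_variance_sd",
            "heritability", "heritability_sd",
        ],
    ).set_index("trait")


def genetic_correlations() -> pd.DataFrame:
    """Mean genetic correlation matrix (9 x 9, unit diagonal)."""
    C = np.eye(len(TRAITS))
    for i, t in enumerate(TRAITS[:-1]):
        for k, r in enumerate(_RG_UPPER[t]):
            j = i + 1 + k
            C[i, j] = C[j, i] = r
    return pd.DataFrame(C, index=list(TRAITS), columns=list(TRAITS))


def published_G() -> np.ndarray:
    """Additive covariance G assembled from stage variances and mean correlations."""
    va = stage_parameters()["additive_variance"].to_numpy()
    sd = np.sqrt(va)
    return genetic_correlations().to_numpy() * np.outer(sd, sd)


def published_P(*, off_diagonal_zero: bool = True) -> np.ndarray:
    """Phenotypic covariance P.

    Only stage-level phenotypic variances are published, so the off-diagonal
    defaults to zero (the assumption used for parity aggregation).
    """
    vp = stage_parameters()["phenotypic_variance"].to_numpy()
    if not off_diagonal_zero:
        raise NotImplementedError("phenotypic covariances are not published")
    return np.diag(vp)
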