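"""Accuracy/precision scoring of estimated diets against known truth.

Estimated dietary proportions (posterior medians) are regressed by ordinary
least squares onto their true values; the slope is the accuracy index (1 =
unbiased recovery) and R^2 the precision index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["EvaluationResult", "accuracy_precision"]


@dataclass(frozen=True)
class EvaluationResult:
    slope: float
    r_squared: float
    intercept: float
    n_pairs: int


def _as_mapping(diets) -> dict:
    if hasattr(diets, "proportions"):
        return dict(diets.proportions)
    if hasattr(diets, "diet_medians"):
        return diets.diet_medians()
    return dict(diets)


def accuracy_precision(estimates, truth) -> EvaluationResult:
    """OLS (with intercept) of estimates on truth over shared links.

    Both arguments are mappings (consumer, resource) -> proportion, or
    objects exposing them (``TrueDiets``, ``IsoWebResults``).  All links of
    all consumers enter one pooled regression.
    """
    est = _as_mapping(estimates)
    tru = _as_mapping(truth)
    keys = [k for k in tru if k in est]
    if len(keys) < 2:
        raise ValueError("need at least 2 paired links to regress")
    x = np.array([tru[k] for k in keys], dtype=float)
    y = np.array([est[k] for k in keys], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("true proportions have zero variance; slope undefined")
    fit = stats.linregress(x, y)
    return EvaluationResult(
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        intercept=float(fit.intercept),
        n_pairs=len(keys),
    )
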