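"""Alternative abundance models and AICc comparison.

The mechanistic model is benchmarked against log-link Poisson
regressions of site abundance on (i) site-mean derived habitat value,
(ii) site means of the original shrub and shade variables, (iii) all
four original habitat variables, and (iv) a constant (mean-abundance
null).  Models are ranked by AICc; explanatory power is summarised by a
pseudo-R2 (squared Pearson correlation of observed vs fitted, with a
deviance-based alternative behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln

from .detect import aicc_value as aicc  # same small-sample correction

__all__ = [
    "RegressionSpec",
    "fit_poisson_regression",
    "aicc",
    "pseudo_r2",
    "comparison_table",
]

#: covariate layout per model kind: (coefficient names, covariate count)
_KINDS = {
    "habitat_value": (("q0", "q1"), 1),
    "shrub_shade": (("r0", "r1", "r2"), 2),
    "all_habitat": (("r0", "r1", "r2", "r3", "r4"), 4),
    "constant": (("k",), 0),
}


@dataclass(frozen=True)
class RegressionSpec:
    """A fitted regression alternative: kind plus named coefficients."""

    kind: str
    coefficients: dict

    def __post_init__(self):
        names, _ = _KINDS[self.kind]
        if tuple(self.coefficients) != names:
            raise ValueError(
                f"kind {self.kind!r} expects coefficients {names}, "
                f"got {tuple(self.coefficients)}"
            )

    @property
    def n_params(self) -> int:
        return len(self.coefficients)


def fit_poisson_regression(
    kind: Literal["habitat_value", "shrub_shade", "all_habitat", "constant"],
    covariates,
    y: Sequence[int],
) -> tuple[RegressionSpec, float, np.ndarray]:
    """ML log-link Poisson regression (IRLS via statsmodels GLM).

    ``covariates``: per-site array of shape (n,) for habitat_value,
    (n, 2) for shrub_shade, (n, 4) for all_habitat, ignored for the
    constant model (which reduces to k = mean(y), reported on the
    natural scale).  Returns (spec, loglik, fitted values).
    """
    names, ncov = _KINDS[kind]
    y = np.asarray(y, dtype=float)
    n = y.size
    if kind == "constant":
        k = float(y.mean())
        mu = np.full(n, k)
        ll = float(
            np.sum(y * np.log(np.maximum(mu, 1e-12)) - mu - gammaln(y + 1.0))
        )
        return RegressionSpec(kind, {"k": k}), ll, mu
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape != (n, ncov):
        raise ValueError(f"{kind!r} expects covariates of shape ({n}, {ncov})")
    if n <= ncov + 1:
        raise ValueError("need more sites than coefficients")
    Xd = sm.add_constant(X)
    model = sm.GLM(y, Xd, family=sm.families.Poisson())
    try:
        res = model.fit()
    except Exception as err:  # noqa: BLE001 - flagged, not swallowed silently
        raise RuntimeError(f"Poisson regression failed to converge: {err}") from err
    if not res.converged:
        raise RuntimeError("Poisson regression did not converge (separation?)")
    coefs = dict(zip(names, (float(b) for b in res.params)))
    return RegressionSpec(kind, coefs), float(res.llf), np.asarray(res.mu)


def pseudo_r2(
    observed: Sequence[float],
    predicted: Sequence[float],
    method: Literal["pearson", "deviance"] = "pearson",
) -> float:
    """Explained variation in [0, 1].

    ``pearson``: squared Pearson correlation of observed vs predicted
    (0 by convention when the predictions are constant).  ``deviance``:
    1 - residual/null Poisson deviance.
    """
    y = np.asarray(observed, dtype=float)
    mu = np.asarray(predicted, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.var(y) == 0:
        raise ValueError("observed values have zero variance")
    if method == "pearson":
        if np.var(mu) == 0:
            return 0.0
        r = np.corrcoef(y, mu)[0, 1]
        return float(r * r)
    if method == "deviance":
        mu = np.maximum(mu, 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        dev = 2.0 * np.sum(term - (y - mu))
        ybar = y.mean()
        term0 = np.where(y > 0, y * np.log(y / ybar), 0.0)
        dev0 = 2.0 * np.sum(term0 - (y - ybar))
        return float(1.0 - dev / dev0)
    raise ValueError(f"unknown pseudo-R2 method {method!r}")


def comparison_table(
    fits: Sequence[tuple],
    y: Sequence[int],
    n: int | None = None,
    r2_method: str = "pearson",
) -> pd.DataFrame:
    """Rank models by AICc.

    ``fits``: sequence of (name, loglik, k, predictions); predictions
    may be None (R2 reported as NaN).  Returns a table with AICc,
    delta-AICc vs the best, and pseudo-R2, sorted by delta-AICc.
    """
    y = np.asarray(y, dtype=float)
    if n is None:
        n = y.size
    rows = []
    for name, ll, k, pred in fits:
        row = {"model": name, "loglik": ll, "n_params": k,
               "aicc": aicc(ll, k, n)}
        if pred is not None:
            row["r2"] = pseudo_r2(y, pred, r2_method)
        else:
            row["r2"] = float("nan")
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(["aicc", "model"]).reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    table.attrs["r2_method"] = r2_method
    return table
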