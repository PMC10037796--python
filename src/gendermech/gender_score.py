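"""Gender-diagnosis score: predict sex at birth from socio-behavioural traits.

The score G of an individual is the predicted probability of being male-born
given their socio-behavioural characteristics, from a main-effects logistic
regression of sex on the active mediator set.  It reads as a continuum from
0 ("predicted female", gendered in a feminine way) to 1 ("predicted male").

Fitting is plain maximum likelihood.  Small or degenerate tables can exhibit
complete separation, where ML estimates diverge; in that case the model is
refit with a small quadratic (ridge) penalty on the mediator coefficients and
flagged — never silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationWarning,
)

from .preprocess import SEX, VariableSet

#: ridge strength lambda for the separation fallback: the penalized
#: log-likelihood is sum(loglik) - lambda/2 * ||beta||^2 (intercept free)
SEPARATION_PENALTY = 0.1

#: an ML logit coefficient beyond this is treated as divergence/separation
_DIVERGENCE_BOUND = 15.0


@dataclass(frozen=True)
class GenderScoreModel:
    variable_set: str
    mediators: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    converged: bool
    separation: bool
    penalty: float   # 0.0 for the unpenalized ML fit


def fit_gender_model(table: pd.DataFrame, varset: VariableSet) -> GenderScoreModel:
    """Logistic regression of sex on the varset mediators (main effects only)."""
    missing = [m for m in varset.mediators if m not in table.columns]
    if missing:
        raise ValueError(f"table lacks mediator column(s): {missing}")
    sub = table[[SEX, *varset.mediators]]
    if sub.isna().any().any():
        raise ValueError("gender model requires complete sex and mediator data "
                         "(run after imputation)")
    y = sub[SEX].to_numpy(dtype=float)
    counts = pd.Series(y).value_counts()
    if set(counts.index) != {0.0, 1.0} or counts.min() < 2:
        raise ValueError("gender model needs at least 2 individuals of each sex")
    x = sub[list(varset.mediators)].to_numpy(dtype=float)
    xc = sm.add_constant(x, has_constant="add")

    separation = False
    converged = False
    params = None
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            # convergence is checked explicitly below; keep the fit quiet
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = sm.Logit(y, xc).fit(method="newton", maxiter=200, disp=0)
        converged = bool(res.mle_retvals.get("converged", False))
        params = np.asarray(res.params)
        if not converged or not np.isfinite(params).all() \
                or np.abs(params[1:]).max(initial=0.0) > _DIVERGENCE_BOUND:
            separation = True
    except Exception:
        separation = True

    if separation:
        # penalized refit: sklearn minimizes 0.5*||w||^2 + C * sum(logloss),
        # so C = 1/lambda gives loglik - lambda/2 * ||w||^2
        clf = LogisticRegression(
            C=1.0 / SEPARATION_PENALTY, solver="lbfgs",
            max_iter=1000, tol=1e-10,
        )
        clf.fit(x, y)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        converged = True
        penalty = SEPARATION_PENALTY
    else:
        penalty = 0.0

    return GenderScoreModel(
        variable_set=varset.name,
        mediators=varset.mediators,
        intercept=float(params[0]),
        coefficients={m: float(b) for m, b in zip(varset.mediators, params[1:])},
        converged=converged,
        separation=separation,
        penalty=penalty,
    )


def predict_gender_score(model: GenderScoreModel, table: pd.DataFrame) -> np.ndarray:
    """Per-individual score: inverse logit of the model's linear predictor."""
    missing = [m for m in model.mediators if m not in table.columns]
    if missing:
        raise ValueError(f"table lacks mediator column(s): {missing}")
    x = table[list(model.mediators)].to_numpy(dtype=float)
    beta = np.array([model.coefficients[m] for m in model.mediators])
    p = expit(model.intercept + x @ beta)
    # keep scores strictly inside (0,1) even under numerically saturated etas
    tiny = np.finfo(float).tiny
    return np.clip(p, tiny, 1.0 - 1e-15)


def describe_scores_by_group(scores, s, e) -> pd.DataFrame:
    """Mean score by sex (and M-F gap), overall and within deprivation strata."""
    scores = np.asarray(scores, dtype=float)
    s = np.asarray(s, dtype=float)
    e = np.asarray(e, dtype=float)
    if not (len(scores) == len(s) == len(e)):
        raise ValueError("scores, sex and environment vectors must be aligned")
    rows = {}
    for label, mask in (
        ("total", np.ones_like(s, dtype=bool)),
        ("deprived", e == 1),
        ("advantaged", e == 0),
    ):
        mean_m = float(scores[mask & (s == 1)].mean()) if (mask & (s == 1)).any() else np.nan
        mean_f = float(scores[mask & (s == 0)].mean()) if (mask & (s == 0)).any() else np.nan
        rows[label] = {"mean_male": mean_m, "mean_female": mean_f,
                       "gap": mean_m - mean_f}
    return pd.DataFrame.from_dict(rows, orient="index")


def coefficients_frame(model: GenderScoreModel) -> pd.DataFrame:
    """Model coefficients as a tidy frame (for CSV audit export)."""
    rows = [("(intercept)", model.intercept)]
    rows += list(model.coefficients.items())
    out = pd.DataFrame(rows, columns=["term", "log_odds"])
    out["variable_set"] = model.variable_set
    out["penalty"] = model.penalty
    return out
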