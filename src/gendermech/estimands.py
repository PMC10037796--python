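"""G-computation of the causal contrasts.

Every estimand is a difference of counterfactual outcome means
``E[Y_{A=a}]`` obtained by (1) fitting a linear outcome regression
``Qbar(A, L) = E[Y | A, L]`` by ordinary least squares, (2) predicting each
individual's outcome with the scenario's assignments substituted, and
(3) averaging the predictions over the empirical covariate distribution
(counterfactual standardization).

Three covariate specifications are used, mirroring the three ways of
operationalizing gender:

* ``S*E`` — sex, early-life deprivation and their product (total effect,
  stratum effects, additive interaction);
* ``S*E + G`` — adds the gender score linearly, no S x G product
  (controlled direct effect with the score fixed, CDE^G);
* ``S*E + Sigma`` — adds the socio-behavioural mediators as main effects,
  no S x mediator products (controlled direct effect with the mediator
  vector fixed at a reference profile, CDE^Sigma).

Because the models never interact sex with the mediator(s), the CDEs do not
depend on the value the mediator is fixed at; this invariance is asserted in
the test-suite rather than assumed silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import DEPRIVED, SEX, ReferenceProfile

GENDER_SCORE = "gender_score"

_SPECS = ("S*E", "S*E+G", "S*E+Sigma")


@dataclass(frozen=True)
class OutcomeModelQbar:
    """Fitted linear outcome regression and the moments behind its z scale."""

    outcome: str
    scale: str                      # "original" | "z"
    spec: str                       # one of _SPECS
    terms: tuple[str, ...]          # design column names, "const" first
    coef: np.ndarray
    mu: float                       # training-data outcome mean
    sigma: float                    # training-data outcome SD (ddof=1)
    mediators: tuple[str, ...] = ()
    score_column: str = GENDER_SCORE

    def predict(self, design: np.ndarray) -> np.ndarray:
        return design @ self.coef


@dataclass(frozen=True)
class ScenarioSpec:
    """Counterfactual assignment; unassigned covariates keep observed values."""

    s: int | None = None
    e: int | None = None
    g: float | None = None
    sigma: ReferenceProfile | None = None

    def __post_init__(self) -> None:
        if self.g is not None and self.sigma is not None:
            raise ValueError("a scenario may set the score G or the mediator "
                             "vector Sigma, never both")
        for name, v in ((SEX, self.s), (DEPRIVED, self.e)):
            if v is not None and v not in (0, 1):
                raise ValueError(f"scenario {name} must be 0 or 1, got {v}")


@dataclass
class EstimandEstimate:
    """A named counterfactual contrast with optional percentile CI."""

    estimand: str
    outcome: str
    scale: str
    point: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int | None = None
    variable_set: str | None = None
    te_reference: float | None = None   # the TE an EP was normalized by
    unstable: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.ci_low is not None and self.ci_high is not None
                and self.ci_low > self.ci_high):
            raise ValueError("ci_low must not exceed ci_high")


# ---------------------------------------------------------------------------
# Model fitting and standardization
# ---------------------------------------------------------------------------

def _design(table: pd.DataFrame, qbar_terms, overrides: dict[str, float]) -> np.ndarray:
    n = len(table)
    cols = []
    def col(name):
        if name in overrides:
            return np.full(n, float(overrides[name]))
        return table[name].to_numpy(dtype=float)
    for term in qbar_terms:
        if term == "const":
            cols.append(np.ones(n))
        elif term == f"{SEX}:{DEPRIVED}":
            cols.append(col(SEX) * col(DEPRIVED))
        else:
            cols.append(col(term))
    return np.column_stack(cols)


def fit_qbar(
    table: pd.DataFrame,
    outcome: str,
    spec: str = "S*E",
    scale: str = "original",
    mediators: tuple[str, ...] | list[str] = (),
    score_column: str = GENDER_SCORE,
) -> OutcomeModelQbar:
    """OLS fit of the outcome regression Qbar for one covariate spec.

    ``outcome`` is the analysis column (already log-transformed where
    applicable).  ``scale='z'`` fits on the table's own z-scored outcome,
    storing the moments used.  A rank-deficient design — typically an empty
    (S, E) cell — is rejected with the offending cell named.
    """
    if spec not in _SPECS:
        raise ValueError(f"spec must be one of {_SPECS}, got {spec!r}")
    if scale not in ("original", "z"):
        raise ValueError(f"scale must be 'original' or 'z', got {scale!r}")
    if spec == "S*E+Sigma" and not mediators:
        raise ValueError("spec 'S*E+Sigma' requires the mediator list")
    if table[outcome].isna().any() or table[[SEX, DEPRIVED]].isna().any().any():
        raise ValueError("fit_qbar requires a complete (imputed) table")

    terms: list[str] = ["const", SEX, DEPRIVED, f"{SEX}:{DEPRIVED}"]
    if spec == "S*E+G":
        terms.append(score_column)
    elif spec == "S*E+Sigma":
        terms.extend(mediators)

    y = table[outcome].to_numpy(dtype=float)
    mu = float(y.mean())
    sigma = float(y.std(ddof=1))
    if scale == "z":
        if sigma <= 0:
            raise ValueError(f"outcome {outcome!r} is constant; z scale undefined")
        y = (y - mu) / sigma

    x = _design(table, terms, {})
    if np.linalg.matrix_rank(x) < x.shape[1]:
        counts = table.groupby([SEX, DEPRIVED]).size()
        for s in (0, 1):
            for e in (0, 1):
                if (s, e) not in counts.index:
                    raise ValueError(
                        f"design is rank-deficient: cell (S={s}, E={e}) is empty"
                    )
        raise ValueError("design is rank-deficient (collinear covariates)")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return OutcomeModelQbar(
        outcome=outcome, scale=scale, spec=spec, terms=tuple(terms),
        coef=coef, mu=mu, sigma=sigma,
        mediators=tuple(mediators), score_column=score_column,
    )


def gcomp_mean(qbar: OutcomeModelQbar, table: pd.DataFrame, scenario: ScenarioSpec) -> float:
    """Counterfactual mean: predictions under the scenario, averaged over n."""
    overrides: dict[str, float] = {}
    if scenario.s is not None:
        overrides[SEX] = scenario.s
    if scenario.e is not None:
        overrides[DEPRIVED] = scenario.e
    if scenario.g is not None:
        if qbar.spec != "S*E+G":
            raise ValueError("scenario assigns G but the model has no score term")
        overrides[qbar.score_column] = scenario.g
    if scenario.sigma is not None:
        if qbar.spec != "S*E+Sigma":
            raise ValueError("scenario assigns Sigma but the model has no mediator terms")
        scenario.sigma.require_names(qbar.mediators)
        overrides.update({m: scenario.sigma.values[m] for m in qbar.mediators})
    x = _design(table, qbar.terms, overrides)
    return float(qbar.predict(x).mean())


# ---------------------------------------------------------------------------
# Estimands
# ---------------------------------------------------------------------------

def total_effect(qbar: OutcomeModelQbar, table: pd.DataFrame) -> EstimandEstimate:
    """TE = E[Y_{S=male}] - E[Y_{S=female}], standardized over E."""
    _require_spec(qbar, "S*E", "total_effect")
    point = gcomp_mean(qbar, table, ScenarioSpec(s=1)) - gcomp_mean(qbar, table, ScenarioSpec(s=0))
    return EstimandEstimate("TE", qbar.outcome, qbar.scale, point)


def controlled_direct_effect_score(
    qbar: OutcomeModelQbar, table: pd.DataFrame, g0: float = 0.5
) -> EstimandEstimate:
    """CDE^G: sex contrast with the gender score fixed at ``g0`` for all."""
    _require_spec(qbar, "S*E+G", "controlled_direct_effect_score")
    if not 0.0 <= g0 <= 1.0:
        raise ValueError(f"g0 must lie in [0, 1], got {g0}")
    point = (gcomp_mean(qbar, table, ScenarioSpec(s=1, g=g0))
             - gcomp_mean(qbar, table, ScenarioSpec(s=0, g=g0)))
    return EstimandEstimate("CDE_G", qbar.outcome, qbar.scale, point,
                            extras={"g0": g0})


def controlled_direct_effect_mediators(
    qbar: OutcomeModelQbar, table: pd.DataFrame, ref: ReferenceProfile
) -> EstimandEstimate:
    """CDE^Sigma: sex contrast with every mediator fixed at its reference."""
    _require_spec(qbar, "S*E+Sigma", "controlled_direct_effect_mediators")
    ref.require_names(qbar.mediators)
    point = (gcomp_mean(qbar, table, ScenarioSpec(s=1, sigma=ref))
             - gcomp_mean(qbar, table, ScenarioSpec(s=0, sigma=ref)))
    return EstimandEstimate("CDE_Sigma", qbar.outcome, qbar.scale, point)


def stratum_total_effect(qbar: OutcomeModelQbar, table: pd.DataFrame, e: int) -> EstimandEstimate:
    """TE^e: sex contrast with deprivation set to ``e`` for everyone."""
    _require_spec(qbar, "S*E", "stratum_total_effect")
    point = (gcomp_mean(qbar, table, ScenarioSpec(s=1, e=e))
             - gcomp_mean(qbar, table, ScenarioSpec(s=0, e=e)))
    return EstimandEstimate(f"TE{e}", qbar.outcome, qbar.scale, point)


def deprivation_effect_by_sex(qbar: OutcomeModelQbar, table: pd.DataFrame, s: int) -> EstimandEstimate:
    """Deprivation contrast within sex ``s``."""
    _require_spec(qbar, "S*E", "deprivation_effect_by_sex")
    point = (gcomp_mean(qbar, table, ScenarioSpec(s=s, e=1))
             - gcomp_mean(qbar, table, ScenarioSpec(s=s, e=0)))
    return EstimandEstimate(f"DeprivationEffect({s})", qbar.outcome, qbar.scale, point)


def additive_interaction(qbar: OutcomeModelQbar, table: pd.DataFrame) -> EstimandEstimate:
    """IE = (Y11 - Y10) - (Y01 - Y00): difference of sex effects across strata."""
    _require_spec(qbar, "S*E", "additive_interaction")
    cm = {(s, e): gcomp_mean(qbar, table, ScenarioSpec(s=s, e=e))
          for s in (0, 1) for e in (0, 1)}
    point = cm[(1, 1)] - cm[(1, 0)] - cm[(0, 1)] + cm[(0, 0)]
    return EstimandEstimate("IE", qbar.outcome, qbar.scale, point)


def cell_mean(qbar: OutcomeModelQbar, table: pd.DataFrame, s: int, e: int) -> EstimandEstimate:
    """Counterfactual mean with both sex and deprivation assigned."""
    point = gcomp_mean(qbar, table, ScenarioSpec(s=s, e=e))
    return EstimandEstimate(f"CellMean({s},{e})", qbar.outcome, qbar.scale, point)


def eliminated_proportion(te: float, remaining: float) -> float:
    """EP = (TE - remaining) / TE.

    Negative values mean the sex gap widens when the gendered pathway is
    blocked.  Undefined (NaN) when TE is exactly zero; callers flag rather
    than crash.
    """
    if te == 0:
        return math.nan
    return (te - remaining) / te


def _require_spec(qbar: OutcomeModelQbar, spec: str, op: str) -> None:
    if qbar.spec != spec:
        raise ValueError(f"{op} requires a {spec!r} model, got {qbar.spec!r}")
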