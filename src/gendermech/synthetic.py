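"""Synthetic birth-cohort generator with known causal structure.

Emulates a 1958-style national birth cohort at the level needed to exercise
the analysis pipeline: sex at birth ``S``, two correlated early-life
environment indicators whose conjunction defines deprivation ``E``, binary
socio-behavioural mediators whose prevalence depends on (S, E) through a
logit model ("gender pressure"), and continuous biomarkers generated from a
linear model in (S, E, S*E, mediators) with Gaussian noise — additively on
the log scale for the skewed markers.  Because the generative model is fully
specified, every causal estimand the pipeline reports has a closed-form (or
Monte-Carlo) true value, returned by :func:`compute_truth`.

Seed discipline: a single master seed; each stage draws from a child
``SeedSequence`` with a fixed ``spawn_key`` (0 = cohort, 1 = missingness,
2 = truth Monte-Carlo), so stages are independent and reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .preprocess import (
    BIOMARKERS,
    DEPRIVED,
    MEDIATORS,
    MOTHER_SHORT_EDU,
    PARENT_MANUAL,
    SEX,
    outcome_column,
)

_STAGE_COHORT = 0
_STAGE_MISSING = 1
_STAGE_TRUTH = 2

_ALWAYS_OBSERVED = (SEX, MOTHER_SHORT_EDU, PARENT_MANUAL)


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Child generator for a pipeline stage under one master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediatorModel:
    """logit P(mediator=1 | S, E) = alpha + beta*S + gamma*E."""

    alpha: float
    beta: float
    gamma: float = 0.0

    def prevalence(self, s: int, e: int) -> float:
        return float(expit(self.alpha + self.beta * s + self.gamma * e))


@dataclass(frozen=True)
class OutcomeModel:
    """Linear biomarker model on its analysis scale.

    y = a + b*S + c*E + d*S*E + sum_j w_j * mediator_j + Normal(0, sigma_y);
    for log-scale biomarkers y is the log value and the native value is
    exp(y).
    """

    a: float
    b: float
    c: float
    d: float
    sigma_y: float
    w: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class MarModel:
    """logit P(missing) = intercept + coefficients on always-observed columns."""

    intercept: float
    coef: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimParams:
    p_male: float
    p_short_edu: float
    p_manual: float
    edu_manual_odds_ratio: float
    mediator_models: dict[str, MediatorModel]
    outcome_models: dict[str, OutcomeModel]
    mar_params: dict[str, MarModel] = field(default_factory=dict)
    n_default: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_male", "p_short_edu", "p_manual"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {p}")
        if not self.edu_manual_odds_ratio > 0:
            raise ValueError("edu_manual_odds_ratio must be positive")
        unknown = set(self.mediator_models) - set(MEDIATORS)
        if unknown:
            raise ValueError(f"mediator models for unknown mediators: {sorted(unknown)}")
        if set(self.mediator_models) != set(MEDIATORS):
            missing = set(MEDIATORS) - set(self.mediator_models)
            raise ValueError(f"mediator models missing for: {sorted(missing)}")
        if set(self.outcome_models) != set(BIOMARKERS):
            raise ValueError(
                f"outcome models must cover exactly {sorted(BIOMARKERS)}, "
                f"got {sorted(self.outcome_models)}"
            )
        for bm, om in self.outcome_models.items():
            if not om.sigma_y > 0:
                raise ValueError(f"sigma_y for {bm!r} must be positive")
            unknown = set(om.w) - set(MEDIATORS)
            if unknown:
                raise ValueError(f"{bm!r}: weights on unknown mediators {sorted(unknown)}")
        for col, mm in self.mar_params.items():
            if col in _ALWAYS_OBSERVED or col == DEPRIVED:
                raise ValueError(f"column {col!r} is always observed; no MAR model allowed")
            bad = set(mm.coef) - set(_ALWAYS_OBSERVED)
            if bad:
                raise ValueError(
                    f"MAR model for {col!r} references maskable column(s) "
                    f"{sorted(bad)}; missingness must depend only on "
                    f"{_ALWAYS_OBSERVED} to stay MAR"
                )

    @property
    def p_deprived(self) -> float:
        return joint_bernoulli_p11(self.p_short_edu, self.p_manual, self.edu_manual_odds_ratio)


def joint_bernoulli_p11(p1: float, p2: float, odds_ratio: float) -> float:
    """P(X=1, Y=1) for Bernoulli margins (p1, p2) with a given odds ratio."""
    if odds_ratio == 1.0:
        return p1 * p2
    psi = odds_ratio
    b = 1.0 + (p1 + p2) * (psi - 1.0)
    disc = b * b - 4.0 * psi * (psi - 1.0) * p1 * p2
    return (b - math.sqrt(disc)) / (2.0 * (psi - 1.0))


# ---------------------------------------------------------------------------
# Default calibration
# ---------------------------------------------------------------------------

# (prevalence male %, prevalence female %, deprivation log-odds shift)
_MEDIATOR_DEFAULTS: dict[str, tuple[float, float, float]] = {
    "low_education_23": (42.6, 35.9, 0.8),
    "no_numeracy_problems_23": (94.8, 94.5, -0.3),
    "literacy_problems_23": (12.6, 7.0, 0.5),
    "rarely_reads_23": (45.6, 32.6, 0.5),
    "drivers_license_33": (92.5, 80.9, -0.3),
    "savings_above_median_23": (54.5, 45.7, -0.4),
    "paid_work_23": (90.1, 68.5, 0.0),
    "manual_class_33": (50.8, 33.4, 0.9),
    "rarely_sees_friends_23": (35.6, 27.6, 0.1),
    "not_married_23": (65.2, 45.7, -0.2),
    "no_child_23": (82.0, 66.6, -0.4),
    "no_laundry_33": (86.0, 4.2, 0.0),
    "not_religious_23": (49.6, 32.5, 0.2),
    "smoking_23": (39.9, 38.3, 0.5),
    "smoking_33": (32.6, 32.0, 0.5),
    "alcohol_daily_23": (31.4, 9.8, 0.1),
    "alcohol_daily_33": (17.6, 7.0, 0.1),
    "fried_food_33": (56.6, 35.0, 0.4),
    "sport_23": (59.3, 35.8, -0.3),
    "no_sport_33": (77.8, 77.4, 0.3),
    "accident_23_33": (58.3, 24.8, 0.2),
}

# a, b (sex), c (deprivation), d (sex x deprivation), sigma_y, mediator weights
_OUTCOME_DEFAULTS: dict[str, tuple[float, float, float, float, float, dict[str, float]]] = {
    "sbp": (118.5, 11.4, 1.2, -0.4, 14.0,
            {"smoking_33": 1.5, "alcohol_daily_33": 3.0, "fried_food_33": 2.0,
             "no_sport_33": 2.0, "manual_class_33": 1.5}),
    "triglycerides": (0.20, 0.38, 0.05, -0.04, 0.45,
                      {"fried_food_33": 0.06, "alcohol_daily_33": 0.05,
                       "no_sport_33": 0.04, "smoking_33": 0.02}),
    "ldl": (3.15, 0.26, 0.07, -0.06, 0.85,
            {"fried_food_33": 0.08, "no_sport_33": 0.05, "smoking_33": 0.03}),
    "hba1c": (5.12, 0.11, 0.06, -0.005, 0.58,
              {"fried_food_33": 0.04, "no_sport_33": 0.04,
               "savings_above_median_23": -0.02}),
    "crp": (-0.15, -0.16, 0.25, -0.14, 1.25,
            {"smoking_33": 0.15, "no_sport_33": 0.10, "fried_food_33": 0.08}),
    "cortisol": (2.92, -0.03, 0.015, 0.005, 0.50,
                 {"no_sport_33": 0.01, "smoking_33": 0.01}),
}

# missingness burden: heavy on biomarkers (home-based clinical wave),
# moderate on mediators (interview waves)
_MAR_BIOMARKER_INTERCEPT = -0.6
_MAR_MEDIATOR_INTERCEPT = -1.6
_MAR_COEF = {SEX: 0.2, MOTHER_SHORT_EDU: 0.3, PARENT_MANUAL: 0.2}


def default_params(seed: int = 0, n_default: int = 10_000) -> SimParams:
    """Default generative scenario.

    Sex ratio and environment marginals follow the cohort the generator
    emulates (51% male-born, 75% short-educated mothers, 73% manual class);
    mediator prevalences by sex reproduce the descriptive table of that
    cohort; deprivation shifts and mediator->biomarker weights are
    calibration choices documented in docs/methods.md.
    """
    mediators = {}
    for name, (pm, pf, gamma) in _MEDIATOR_DEFAULTS.items():
        alpha = float(logit(pf / 100.0))
        beta = float(logit(pm / 100.0)) - alpha
        mediators[name] = MediatorModel(alpha=alpha, beta=beta, gamma=gamma)
    outcomes = {
        bm: OutcomeModel(a=a, b=b, c=c, d=d, sigma_y=s, w=dict(w))
        for bm, (a, b, c, d, s, w) in _OUTCOME_DEFAULTS.items()
    }
    mar: dict[str, MarModel] = {}
    for m in MEDIATORS:
        mar[m] = MarModel(_MAR_MEDIATOR_INTERCEPT, dict(_MAR_COEF))
    for bm in BIOMARKERS:
        mar[bm] = MarModel(_MAR_BIOMARKER_INTERCEPT, dict(_MAR_COEF))
    return SimParams(
        p_male=0.51,
        p_short_edu=0.75,
        p_manual=0.73,
        edu_manual_odds_ratio=3.0,
        mediator_models=mediators,
        outcome_models=outcomes,
        mar_params=mar,
        n_default=n_default,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_cohort(params: SimParams, n: int | None = None, seed: int | None = None) -> pd.DataFrame:
    """Draw a complete cohort of ``n`` records from the generative model."""
    n = params.n_default if n is None else n
    seed = params.seed if seed is None else seed
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    rng = stage_rng(seed, _STAGE_COHORT)

    s = (rng.random(n) < params.p_male).astype(np.int64)
    # correlated environment indicators via their joint 2x2 distribution
    p11 = params.p_deprived
    p10 = params.p_short_edu - p11
    p01 = params.p_manual - p11
    p00 = 1.0 - p11 - p10 - p01
    cell = rng.choice(4, size=n, p=[p00, p01, p10, p11])
    short_edu = (cell >= 2).astype(np.int64)
    manual = (cell % 2).astype(np.int64)
    e = short_edu * manual

    data: dict[str, np.ndarray] = {
        "id": np.arange(n, dtype=np.int64),
        SEX: s,
        MOTHER_SHORT_EDU: short_edu,
        PARENT_MANUAL: manual,
        DEPRIVED: e,
    }
    med = {}
    for name in MEDIATORS:
        mm = params.mediator_models[name]
        p = expit(mm.alpha + mm.beta * s + mm.gamma * e)
        med[name] = (rng.random(n) < p).astype(np.int64)
        data[name] = med[name]
    for bm, om in params.outcome_models.items():
        y = om.a + om.b * s + om.c * e + om.d * s * e
        for mname, w in om.w.items():
            y = y + w * med[mname]
        y = y + rng.normal(0.0, om.sigma_y, size=n)
        data[bm] = np.exp(y) if BIOMARKERS[bm][1] else y
    return pd.DataFrame(data)


def inject_missingness(table: pd.DataFrame, params: SimParams, seed: int | None = None) -> pd.DataFrame:
    """Mask entries MAR: missingness depends only on always-observed columns."""
    if table.isna().any().any():
        raise ValueError("input table must be complete before masking")
    seed = params.seed if seed is None else seed
    rng = stage_rng(seed, _STAGE_MISSING)
    out = table.copy()
    for col, mm in params.mar_params.items():
        if col not in table.columns:
            continue
        eta = np.full(len(table), mm.intercept, dtype=float)
        for pred, coef in mm.coef.items():
            eta += coef * table[pred].to_numpy(dtype=float)
        p = expit(eta)
        mask = rng.random(len(table)) < p
        if mask.any():
            out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# True estimand values
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiomarkerTruth:
    """True estimand values for one biomarker on its analysis scale."""

    te: float
    cde_sigma: float
    te0: float
    te1: float
    ie: float
    ep_sigma: float
    ep_e: float
    sd: float            # population SD of the analysis-scale outcome
    cde_g: float | None = None
    cde_g_se: float | None = None

    def on_z_scale(self, value: float) -> float:
        return value / self.sd


@dataclass(frozen=True)
class SimTruth:
    params: SimParams
    biomarkers: dict[str, BiomarkerTruth]

    def __getitem__(self, biomarker: str) -> BiomarkerTruth:
        return self.biomarkers[biomarker]


def _mediator_mean(mm: MediatorModel, s: int, p_e: float) -> float:
    """E[mediator | S=s], marginal over deprivation."""
    return (1.0 - p_e) * mm.prevalence(s, 0) + p_e * mm.prevalence(s, 1)


def compute_truth(
    params: SimParams,
    mc_n: int = 200_000,
    mc_seed: int = 0,
    with_cde_g: bool = True,
) -> SimTruth:
    """Closed-form true estimands, plus a Monte-Carlo value for CDE^G.

    All closed-form quantities marginalize the generative model over the
    distribution of deprivation and the mediators' logit responses.  CDE^G
    has no closed form (the score is a nonlinear function of the mediators),
    so its true value is defined as the large-sample value of the estimand:
    on a simulated cohort of ``mc_n`` records the *true* Bayes score
    P(male | mediators) replaces the fitted one and the linear
    Qbar(S, G, E) contrast is evaluated; the MC standard error comes from
    chunk-splitting.
    """
    if with_cde_g and mc_n < 100_000:
        raise ValueError("mc_n must be at least 100,000 for the CDE^G oracle")
    p_e = params.p_deprived
    truths = {}
    for bm, om in params.outcome_models.items():
        med_shift = sum(
            w * (_mediator_mean(params.mediator_models[m], 1, p_e)
                 - _mediator_mean(params.mediator_models[m], 0, p_e))
            for m, w in om.w.items()
        )
        te = om.b + om.d * p_e + med_shift
        cde_sigma = om.b + om.d * p_e
        te_e = {}
        for e in (0, 1):
            shift_e = sum(
                w * (params.mediator_models[m].prevalence(1, e)
                     - params.mediator_models[m].prevalence(0, e))
                for m, w in om.w.items()
            )
            te_e[e] = om.b + om.d * e + shift_e
        ie = te_e[1] - te_e[0]
        ep_sigma = (te - cde_sigma) / te if te != 0 else math.nan
        ep_e = (te - te_e[0]) / te if te != 0 else math.nan
        truths[bm] = {
            "te": te, "cde_sigma": cde_sigma, "te0": te_e[0], "te1": te_e[1],
            "ie": ie, "ep_sigma": ep_sigma, "ep_e": ep_e,
            "sd": _outcome_sd(params, bm),
        }

    if with_cde_g:
        cde_g = _cde_g_oracle(params, mc_n, mc_seed)
        for bm, (val, se) in cde_g.items():
            truths[bm]["cde_g"] = val
            truths[bm]["cde_g_se"] = se
    return SimTruth(params, {bm: BiomarkerTruth(**t) for bm, t in truths.items()})


def _outcome_sd(params: SimParams, biomarker: str) -> float:
    """Population SD of the analysis-scale outcome by total-variance law."""
    om = params.outcome_models[biomarker]
    p_e = params.p_deprived
    cells = [(s, e, (params.p_male if s else 1 - params.p_male) * (p_e if e else 1 - p_e))
             for s in (0, 1) for e in (0, 1)]
    means, var_within = [], []
    for s, e, _ in cells:
        mu = om.a + om.b * s + om.c * e + om.d * s * e
        v = om.sigma_y ** 2
        for m, w in om.w.items():
            p = params.mediator_models[m].prevalence(s, e)
            mu += w * p
            v += w * w * p * (1.0 - p)
        means.append(mu)
        var_within.append(v)
    probs = np.array([c[2] for c in cells])
    means = np.array(means)
    var = float(probs @ np.asarray(var_within) + probs @ (means - probs @ means) ** 2)
    return math.sqrt(var)


def true_gender_score(params: SimParams, mediators: pd.DataFrame) -> np.ndarray:
    """Bayes posterior P(S=male | mediators), marginal over deprivation.

    Mediators are conditionally independent given (S, E), so the posterior
    follows from the generative logit models by direct enumeration of the
    four (S, E) cells — no model fitting involved.
    """
    x = mediators[list(MEDIATORS)].to_numpy(dtype=float)
    p_e = params.p_deprived
    loglik = {}
    for s in (0, 1):
        for e in (0, 1):
            p = np.array([params.mediator_models[m].prevalence(s, e) for m in MEDIATORS])
            loglik[(s, e)] = x @ np.log(p / (1 - p)) + np.log(1 - p).sum()
    def mix(s):
        a = loglik[(s, 0)] + math.log(1 - p_e)
        b = loglik[(s, 1)] + math.log(p_e)
        hi = np.maximum(a, b)
        return hi + np.log(np.exp(a - hi) + np.exp(b - hi))
    lm, lf = mix(1) + math.log(params.p_male), mix(0) + math.log(1 - params.p_male)
    return expit(lm - lf)


def _cde_g_oracle(params: SimParams, mc_n: int, mc_seed: int, n_chunks: int = 10) -> dict:
    """Large-sample CDE^G per biomarker via the true Bayes score."""
    rng_seed = int(np.random.SeedSequence(mc_seed, spawn_key=(_STAGE_TRUTH,)).generate_state(1)[0] % (2**31))
    cohort = generate_cohort(params, n=mc_n, seed=rng_seed)
    g = true_gender_score(params, cohort)
    s = cohort[SEX].to_numpy(dtype=float)
    e = cohort[DEPRIVED].to_numpy(dtype=float)
    out = {}
    chunks = np.array_split(np.arange(mc_n), n_chunks)
    for bm in params.outcome_models:
        col = outcome_column(bm)
        y = np.log(cohort[bm].to_numpy()) if col.startswith("log_") else cohort[bm].to_numpy()
        est = _cde_g_from_arrays(s, e, g, y)
        per_chunk = [_cde_g_from_arrays(s[i], e[i], g[i], y[i]) for i in chunks]
        out[bm] = (est, float(np.std(per_chunk, ddof=1) / math.sqrt(n_chunks)))
    return out


def _cde_g_from_arrays(s, e, g, y) -> float:
    # OLS of y on (1, S, E, S*E, G); with no S x G term the CDE^G contrast is
    # beta_S + beta_SE * mean(E)
    x = np.column_stack([np.ones_like(s), s, e, s * e, g])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return float(beta[1] + beta[3] * e.mean())


# ---------------------------------------------------------------------------
# Config round-trip
# ---------------------------------------------------------------------------

def params_to_dict(params: SimParams) -> dict:
    return {
        "p_male": params.p_male,
        "p_short_edu": params.p_short_edu,
        "p_manual": params.p_manual,
        "edu_manual_odds_ratio": params.edu_manual_odds_ratio,
        "n_default": params.n_default,
        "seed": params.seed,
        "mediator_models": {
            m: {"alpha": mm.alpha, "beta": mm.beta, "gamma": mm.gamma}
            for m, mm in params.mediator_models.items()
        },
        "outcome_models": {
            bm: {"a": om.a, "b": om.b, "c": om.c, "d": om.d,
                 "sigma_y": om.sigma_y, "w": dict(om.w)}
            for bm, om in params.outcome_models.items()
        },
        "mar_params": {
            col: {"intercept": mm.intercept, "coef": dict(mm.coef)}
            for col, mm in params.mar_params.items()
        },
    }


def params_from_dict(d: dict) -> SimParams:
    return SimParams(
        p_male=d["p_male"],
        p_short_edu=d["p_short_edu"],
        p_manual=d["p_manual"],
        edu_manual_odds_ratio=d["edu_manual_odds_ratio"],
        n_default=d.get("n_default", 10_000),
        seed=d.get("seed", 0),
        mediator_models={
            m: MediatorModel(**spec) for m, spec in d["mediator_models"].items()
        },
        outcome_models={
            bm: OutcomeModel(a=s["a"], b=s["b"], c=s["c"], d=s["d"],
                             sigma_y=s["sigma_y"], w=dict(s.get("w", {})))
            for bm, s in d["outcome_models"].items()
        },
        mar_params={
            col: MarModel(intercept=s["intercept"], coef=dict(s.get("coef", {})))
            for col, s in d.get("mar_params", {}).items()
        },
    )


def load_params(path) -> SimParams:
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))


def save_params(params: SimParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=False)
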