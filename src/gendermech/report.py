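"""Descriptive tables, results rendering and the end-to-end pipeline.

The pipeline is: simulate or ingest -> derive deprivation and log outcomes ->
bootstrap( resample -> single stochastic imputation -> refit gender score ->
g-computation of all requested estimands ) -> percentile CIs -> rendered
tables.  Estimates travel as flat ``estimand|biomarker|scale|set`` keys inside
the bootstrap and are re-assembled into :class:`EstimandEstimate` records for
rendering.
"""

from __future__ import annotations

import io
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import estimands as est
from .estimands import GENDER_SCORE, EstimandEstimate, fit_qbar
from .gender_score import fit_gender_model, predict_gender_score
from .impute import ImputationSpec, impute_stochastic
from .inference import BootstrapResult, bootstrap_pipeline, significance_flag, summarize
from .preprocess import (
    BIOMARKERS,
    DEPRIVED,
    MEDIATORS,
    SEX,
    ReferenceProfile,
    VariableSet,
    get_variable_set,
    modal_reference_profile,
    outcome_column,
    read_cohort_csv,
    transform_outcomes,
)
from .synthetic import default_params, generate_cohort, inject_missingness, load_params

_KEY_SEP = "|"


def _key(estimand: str, biomarker: str, scale: str, varset: str = "-") -> str:
    return _KEY_SEP.join((estimand, biomarker, scale, varset))


def _unkey(key: str) -> tuple[str, str, str, str]:
    estimand, biomarker, scale, varset = key.split(_KEY_SEP)
    return estimand, biomarker, scale, varset


# ---------------------------------------------------------------------------
# Descriptives (Table-2 style)
# ---------------------------------------------------------------------------

def sex_gap(value_male: float, value_female: float) -> float:
    """M - F gap used throughout the descriptive tables."""
    return value_male - value_female


def descriptive_estimator(varsets: Iterable[VariableSet]):
    """Estimator: mediator prevalences (%) and gender-score means by sex."""
    varsets = list(varsets)

    def estimator(completed: pd.DataFrame, seed: int) -> dict[str, float]:
        s = completed[SEX].to_numpy(dtype=float)
        if not ((s == 1).any() and (s == 0).any()):
            raise ValueError("descriptives need both sexes present")
        out: dict[str, float] = {}
        for m in MEDIATORS:
            if m not in completed.columns:
                continue
            col = completed[m].to_numpy(dtype=float)
            pm = 100.0 * col[s == 1].mean()
            pf = 100.0 * col[s == 0].mean()
            out[f"{m}__male"] = pm
            out[f"{m}__female"] = pf
            out[f"{m}__gap"] = sex_gap(pm, pf)
        e = completed[DEPRIVED].to_numpy(dtype=float)
        for vs in varsets:
            model = fit_gender_model(completed, vs)
            g = predict_gender_score(model, completed)
            for label, mask in (("total", np.ones_like(s, dtype=bool)),
                                ("deprived", e == 1), ("advantaged", e == 0)):
                gm = float(g[mask & (s == 1)].mean())
                gf = float(g[mask & (s == 0)].mean())
                out[f"score_{vs.name}_{label}__male"] = gm
                out[f"score_{vs.name}_{label}__female"] = gf
                out[f"score_{vs.name}_{label}__gap"] = sex_gap(gm, gf)
        return out

    return estimator


def descriptives_by_sex(boot: BootstrapResult, alpha: float = 0.05) -> pd.DataFrame:
    """Pivot a bootstrap over ``*__male/female/gap`` keys into a tidy table."""
    summary = summarize(boot, alpha)
    variables: dict[str, dict[str, float]] = {}
    for key, row in summary.iterrows():
        if "__" not in key:
            continue
        var, stat = key.rsplit("__", 1)
        cell = variables.setdefault(var, {})
        cell[stat] = row["point"]
        cell[f"{stat}_ci_low"] = row["ci_low"]
        cell[f"{stat}_ci_high"] = row["ci_high"]
    if not variables:
        raise ValueError("bootstrap result carries no descriptive keys")
    table = pd.DataFrame.from_dict(variables, orient="index")
    order = ["male", "male_ci_low", "male_ci_high",
             "female", "female_ci_low", "female_ci_high",
             "gap", "gap_ci_low", "gap_ci_high"]
    return table[[c for c in order if c in table.columns]]


# ---------------------------------------------------------------------------
# Causal-analysis estimator
# ---------------------------------------------------------------------------

def analysis_estimator(
    strategies: Iterable[str] = ("a", "b", "c"),
    varsets: Iterable[VariableSet] | None = None,
    biomarkers: Iterable[str] | None = None,
    scales: Iterable[str] = ("original", "z"),
    g0: float = 0.5,
    ref_profile: ReferenceProfile | None = None,
):
    """Estimator computing every requested estimand on one completed table.

    Refits the outcome regressions — and, for strategy (a), the gender-score
    model — inside every bootstrap replicate.  When no reference profile is
    given, strategy (b) uses each replicate's modal profile (the CDE is
    invariant to this choice under the no-S x Sigma models, which the tests
    assert).
    """
    strategies = tuple(strategies)
    varsets = list(varsets) if varsets is not None else [get_variable_set("complete")]
    biomarkers = tuple(biomarkers) if biomarkers is not None else tuple(BIOMARKERS)
    scales = tuple(scales)

    def estimator(completed: pd.DataFrame, seed: int) -> dict[str, float]:
        table = completed
        if any(outcome_column(bm) not in table.columns for bm in biomarkers):
            table = transform_outcomes(table)
        out: dict[str, float] = {}
        score_cache: dict[str, np.ndarray] = {}
        for bm in biomarkers:
            ycol = outcome_column(bm)
            for scale in scales:
                qbar = fit_qbar(table, ycol, "S*E", scale)
                te = est.total_effect(qbar, table).point
                out[_key("TE", bm, scale)] = te
                te_strat = {}
                for e in (0, 1):
                    te_strat[e] = est.stratum_total_effect(qbar, table, e).point
                    out[_key(f"TE{e}", bm, scale)] = te_strat[e]
                for s in (0, 1):
                    out[_key(f"DeprivationEffect({s})", bm, scale)] = \
                        est.deprivation_effect_by_sex(qbar, table, s).point
                    for e in (0, 1):
                        out[_key(f"CellMean({s},{e})", bm, scale)] = \
                            est.cell_mean(qbar, table, s, e).point
                out[_key("IE", bm, scale)] = est.additive_interaction(qbar, table).point
                if "c" in strategies:
                    out[_key("EP_E", bm, scale)] = \
                        100.0 * est.eliminated_proportion(te, te_strat[0])
                for vs in varsets:
                    if "a" in strategies:
                        if vs.name not in score_cache:
                            model = fit_gender_model(table, vs)
                            score_cache[vs.name] = predict_gender_score(model, table)
                        scored = table.assign(**{GENDER_SCORE: score_cache[vs.name]})
                        qbar_g = fit_qbar(scored, ycol, "S*E+G", scale)
                        cde_g = est.controlled_direct_effect_score(qbar_g, scored, g0).point
                        out[_key("CDE_G", bm, scale, vs.name)] = cde_g
                        out[_key("EP_G", bm, scale, vs.name)] = \
                            100.0 * est.eliminated_proportion(te, cde_g)
                    if "b" in strategies:
                        qbar_s = fit_qbar(table, ycol, "S*E+Sigma",
                                          scale, mediators=vs.mediators)
                        ref = ref_profile if ref_profile is not None \
                            else modal_reference_profile(table, vs)
                        cde_s = est.controlled_direct_effect_mediators(qbar_s, table, ref).point
                        out[_key("CDE_Sigma", bm, scale, vs.name)] = cde_s
                        out[_key("EP_Sigma", bm, scale, vs.name)] = \
                            100.0 * est.eliminated_proportion(te, cde_s)
        return out

    return estimator


def estimates_from_summary(summary: pd.DataFrame) -> list[EstimandEstimate]:
    """Re-assemble flat bootstrap keys into EstimandEstimate records."""
    te_points = {
        _unkey(k)[1:3]: row["point"]
        for k, row in summary.iterrows() if _unkey(k)[0] == "TE"
    }
    records = []
    for key, row in summary.iterrows():
        name, bm, scale, varset = _unkey(key)
        te_ref = te_points.get((bm, scale)) if name.startswith("EP") else None
        unstable = False
        if name.startswith("EP"):
            te_key = _key("TE", bm, scale)
            if te_key in summary.index:
                lo, hi = summary.loc[te_key, ["ci_low", "ci_high"]]
                unstable = lo <= 0.0 <= hi
        records.append(EstimandEstimate(
            estimand=name, outcome=bm, scale=scale,
            point=row["point"], ci_low=row["ci_low"], ci_high=row["ci_high"],
            n_boot=int(row["n_boot"]),
            variable_set=None if varset == "-" else varset,
            te_reference=te_ref, unstable=unstable,
        ))
    return records


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_LAYOUTS = ("TE-table", "EP-table", "interaction-table")


def _fmt(x, dec):
    return "NA" if x is None or (isinstance(x, float) and not np.isfinite(x)) \
        else f"{x:.{dec}f}"


def _star(e: EstimandEstimate) -> str:
    try:
        return "*" if significance_flag(e) else ""
    except ValueError:
        return ""


def render_results(estimates: list[EstimandEstimate], layout: str) -> tuple[str, str]:
    """Render estimates as (full-precision CSV, rounded markdown) strings.

    Pure function of its inputs: fixed row/column order, fixed decimals in
    the markdown view (2 for effects, 1 for %), significance stars where the
    95% CI excludes zero.  Missing cells render as explicit NA with a warning.
    """
    if layout not in _LAYOUTS:
        raise ValueError(f"layout must be one of {_LAYOUTS}, got {layout!r}")
    index = {(e.estimand, e.outcome, e.scale, e.variable_set or "-"): e
             for e in estimates}
    biomarkers = [bm for bm in BIOMARKERS
                  if any(k[1] == bm for k in index)] or list(BIOMARKERS)

    def get(name, bm, scale, varset="-"):
        e = index.get((name, bm, scale, varset))
        if e is None:
            warnings.warn(f"missing cell {(name, bm, scale, varset)}; rendered NA",
                          stacklevel=2)
        return e

    csv_rows: list[dict] = []
    md = io.StringIO()

    if layout == "TE-table":
        md.write("| Biomarker | TE (original) | 95% CI | TE (z) | 95% CI |\n")
        md.write("|---|---|---|---|---|\n")
        for bm in biomarkers:
            cells = {}
            for scale in ("original", "z"):
                e = get("TE", bm, scale)
                cells[scale] = e
                csv_rows.append(_csv_row(e, "TE", bm, scale))
            eo, ez = cells["original"], cells["z"]
            md.write(
                f"| {bm} | {_fmt(eo and eo.point, 2)}{eo and _star(eo) or ''} "
                f"| [{_fmt(eo and eo.ci_low, 2)} to {_fmt(eo and eo.ci_high, 2)}] "
                f"| {_fmt(ez and ez.point, 2)}{ez and _star(ez) or ''} "
                f"| [{_fmt(ez and ez.ci_low, 2)} to {_fmt(ez and ez.ci_high, 2)}] |\n"
            )
    elif layout == "EP-table":
        varsets = sorted({e.variable_set for e in estimates if e.variable_set}) or ["-"]
        md.write("| Biomarker | Strategy | Set | EP (%) | 95% CI | |\n")
        md.write("|---|---|---|---|---|---|\n")
        for bm in biomarkers:
            rows = [("c", "EP_E", "-")]
            rows += [(strat, name, vs) for vs in varsets
                     for strat, name in (("a", "EP_G"), ("b", "EP_Sigma"))]
            for strat, name, vs in rows:
                e = get(name, bm, "z", vs)
                csv_rows.append(_csv_row(e, name, bm, "z", vs))
                flag = "unstable" if (e is not None and e.unstable) else ""
                md.write(
                    f"| {bm} | ({strat}) | {vs} | {_fmt(e and e.point, 1)}"
                    f"{e and _star(e) or ''} | [{_fmt(e and e.ci_low, 1)} to "
                    f"{_fmt(e and e.ci_high, 1)}] | {flag} |\n"
                )
    else:  # interaction-table
        md.write("| Biomarker | Scale | Quantity | Estimate | 95% CI |\n")
        md.write("|---|---|---|---|---|\n")
        quantities = ["CellMean(1,0)", "CellMean(1,1)", "CellMean(0,0)",
                      "CellMean(0,1)", "TE0", "TE1",
                      "DeprivationEffect(1)", "DeprivationEffect(0)", "IE"]
        for bm in biomarkers:
            for scale in ("original", "z"):
                for q in quantities:
                    e = get(q, bm, scale)
                    csv_rows.append(_csv_row(e, q, bm, scale))
                    md.write(
                        f"| {bm} | {scale} | {q} | {_fmt(e and e.point, 2)}"
                        f"{e and _star(e) or ''} | [{_fmt(e and e.ci_low, 2)} to "
                        f"{_fmt(e and e.ci_high, 2)}] |\n"
                    )

    csv_frame = pd.DataFrame(
        csv_rows,
        columns=["estimand", "biomarker", "scale", "variable_set",
                 "point", "ci_low", "ci_high", "n_boot", "significant", "unstable"],
    )
    return csv_frame.to_csv(index=False), md.getvalue()


def _csv_row(e: EstimandEstimate | None, name, bm, scale, varset="-") -> dict:
    if e is None:
        return dict(estimand=name, biomarker=bm, scale=scale, variable_set=varset,
                    point=np.nan, ci_low=np.nan, ci_high=np.nan, n_boot=0,
                    significant="", unstable="")
    return dict(estimand=e.estimand, biomarker=e.outcome, scale=e.scale,
                variable_set=varset, point=e.point, ci_low=e.ci_low,
                ci_high=e.ci_high, n_boot=e.n_boot,
                significant=_star(e), unstable="unstable" if e.unstable else "")


# ---------------------------------------------------------------------------
# Pipeline entry point
# ---------------------------------------------------------------------------

def run_pipeline(config: Mapping, out_dir=None) -> dict:
    """Execute the full analysis described by a config mapping.

    Config keys (all optional unless noted)::

        source:           "simulate" (default) or path to a cohort CSV
        sim_params:       path to a YAML scenario (default: built-in defaults)
        n:                cohort size when simulating (default 2000)
        missingness:      bool, inject MAR missingness when simulating (default True)
        complete_cases:   bool, restrict to fully observed rows, never impute
        strategies:       subset of ["a","b","c"] (default all)
        sets:             variable-set names (default ["complete"])
        biomarkers:       biomarker names (default all six)
        scales:           ["original","z"] (default both)
        g0:               score value for CDE^G (default 0.5)
        bootstrap:        number of replicates B (default 1000)
        imputation_cycles: chained-equation cycles (default 10)
        seed:             master seed (required)

    Returns a dict of artifacts; when ``out_dir`` is given also writes the
    CSV/markdown tables and a plain-text run log there.
    """
    import pathlib

    seed = int(config["seed"])
    stage = "ingest"
    try:
        if config.get("source", "simulate") == "simulate":
            params = load_params(config["sim_params"]) if config.get("sim_params") \
                else default_params(seed=seed)
            raw = generate_cohort(params, n=int(config.get("n", 2000)), seed=seed)
            if config.get("missingness", True):
                raw = inject_missingness(raw, params, seed=seed)
        else:
            raw = read_cohort_csv(config["source"])

        stage = "preprocess"
        varsets = [get_variable_set(name) for name in config.get("sets", ["complete"])]
        strategies = tuple(config.get("strategies", ("a", "b", "c")))
        n_impute_calls = 0
        impute_spec = None
        if config.get("complete_cases", False):
            # sensitivity analysis: fully observed on the *used* variables only
            bms = list(config.get("biomarkers") or BIOMARKERS)
            used = [SEX, DEPRIVED]
            used += sorted({m for vs in varsets for m in vs.mediators})
            used += bms
            raw = raw.dropna(subset=[c for c in used if c in raw.columns])
            raw = raw.reset_index(drop=True)
        elif raw.isna().any().any():
            impute_spec = ImputationSpec(cycles=int(config.get("imputation_cycles", 10)))
            n_impute_calls = int(config.get("bootstrap", 1000))

        stage = "analysis"
        estimator = analysis_estimator(
            strategies=strategies,
            varsets=varsets,
            biomarkers=config.get("biomarkers"),
            scales=tuple(config.get("scales", ("original", "z"))),
            g0=float(config.get("g0", 0.5)),
        )
        boot = bootstrap_pipeline(
            raw, estimator, B=int(config.get("bootstrap", 1000)),
            master_seed=seed, impute_spec=impute_spec,
        )
        summary = summarize(boot)
        estimates = estimates_from_summary(summary)

        stage = "report"
        tables = {layout: render_results(estimates, layout) for layout in _LAYOUTS}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    log_lines = [
        "gendermech run log",
        f"seed: {seed}",
        f"n: {len(raw)}",
        f"bootstrap replicates: {boot.n_requested} (failed: {len(boot.failures)})",
        f"imputation calls: {n_impute_calls}",
        f"strategies: {strategies}",
        f"variable sets: {[v.name for v in varsets]}",
    ]
    artifacts = {
        "cohort": raw,
        "bootstrap": boot,
        "summary": summary,
        "estimates": estimates,
        "tables": tables,
        "log": "\n".join(log_lines),
        "n_impute_calls": n_impute_calls,
    }
    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for layout, (csv_s, md_s) in tables.items():
            (out / f"{layout}.csv").write_text(csv_s)
            (out / f"{layout}.md").write_text(md_s)
        summary.to_csv(out / "estimates.csv")
        (out / "run.log").write_text(artifacts["log"] + "\n")
    return artifacts
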