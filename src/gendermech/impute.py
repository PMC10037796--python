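"""Single stochastic imputation by chained equations.

One completed dataset per call (no multiple imputation): inside the
bootstrap-then-impute design, sampling uncertainty — including imputation
noise — is propagated by the bootstrap, not by Rubin's rules.

The chained-equations scheme is deliberately simple and fully specified:
columns are visited in order of increasing missingness; a binary column is
imputed by a logistic fit on all other columns followed by a Bernoulli draw
of the missing entries; a continuous column by a least-squares fit plus a
Gaussian residual draw.  Coefficients are not themselves drawn from a
posterior and no predictive mean matching is used — this is the package's
imputation contract.  Log-scale biomarkers are modelled (as predictors and
as targets) on the log scale, where the generative and analysis models are
linear, and mapped back afterwards; observed entries are restored exactly.

Logistic fits use a weak ridge (lambda = 1 on standardized predictors) for
numerical stability; with hundreds of observed rows this is indistinguishable
from maximum likelihood and keeps chained equations robust to near-separation
in resampled data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

#: columns never used as predictors or imputed
_EXCLUDED = ("id",)


@dataclass(frozen=True)
class ImputationSpec:
    cycles: int = 10
    visit_order: tuple[str, ...] | None = None  # default: increasing missingness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycles <= 0:
            raise ValueError(f"cycles must be positive, got {self.cycles}")


def _is_binary(col: pd.Series) -> bool:
    obs = col.dropna().unique()
    return len(obs) > 0 and np.isin(obs, (0, 1)).all()


def impute_stochastic(
    table: pd.DataFrame,
    spec: ImputationSpec | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Return a completed copy of ``table``; observed entries are untouched."""
    from .preprocess import LOG_BIOMARKERS

    spec = spec or ImputationSpec()
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    work = table.copy()
    log_cols = [c for c in LOG_BIOMARKERS if c in work.columns]
    for c in log_cols:
        work[c] = np.log(work[c])
    usable = [c for c in work.columns if c not in _EXCLUDED and not c.startswith("log_")]
    n_missing = work[usable].isna().sum()
    targets = [c for c in usable if n_missing[c] > 0]
    if not targets:
        return table.copy()
    all_missing = [c for c in targets if n_missing[c] == len(work)]
    if all_missing:
        raise ValueError(f"column(s) entirely missing, cannot impute: {all_missing}")
    if not any(n_missing[c] == 0 for c in usable):
        raise ValueError("at least one fully observed column is required")

    if spec.visit_order is not None:
        unknown = [c for c in spec.visit_order if c not in targets]
        order = [c for c in spec.visit_order if c in targets]
        if set(order) != set(targets):
            raise ValueError(
                f"visit_order must cover all incomplete columns {targets}; "
                f"extraneous entries: {unknown}"
            )
    else:
        order = sorted(targets, key=lambda c: (n_missing[c], c))

    binary = {c: _is_binary(table[c]) for c in targets}
    obs_mask = {c: table[c].notna().to_numpy() for c in targets}

    # initial fill: hot-deck draws from the observed distribution
    for c in order:
        obs_vals = table.loc[obs_mask[c], c].to_numpy()
        fill = rng.choice(obs_vals, size=(~obs_mask[c]).sum(), replace=True)
        work[c] = work[c].astype(float)
        work.loc[~obs_mask[c], c] = fill

    for _ in range(spec.cycles):
        for c in order:
            preds = [p for p in usable if p != c]
            x = work[preds].to_numpy(dtype=float)
            y = work[c].to_numpy(dtype=float)
            obs = obs_mask[c]
            mis = ~obs
            if binary[c]:
                classes = np.unique(y[obs])
                if len(classes) == 1:
                    work.loc[mis, c] = classes[0]
                    continue
                mu = x[obs].mean(axis=0)
                sd = x[obs].std(axis=0)
                sd[sd == 0] = 1.0
                clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
                clf.fit((x[obs] - mu) / sd, y[obs])
                p = clf.predict_proba((x[mis] - mu) / sd)[:, 1]
                work.loc[mis, c] = (rng.random(mis.sum()) < p).astype(float)
            else:
                xc = np.column_stack([np.ones(obs.sum()), x[obs]])
                beta, ssr, rank, _ = np.linalg.lstsq(xc, y[obs], rcond=None)
                resid = y[obs] - xc @ beta
                dof = max(obs.sum() - rank, 1)
                sd = float(np.sqrt((resid @ resid) / dof))
                xm = np.column_stack([np.ones(mis.sum()), x[mis]])
                work.loc[mis, c] = xm @ beta + rng.normal(0.0, sd, size=mis.sum())

    # back to native scale; observed entries restored exactly
    for c in log_cols:
        work[c] = np.exp(work[c])
    for c in targets:
        work.loc[obs_mask[c], c] = table.loc[obs_mask[c], c]
    # restore integer dtype for binary columns completed with float draws
    for c in order:
        if binary[c]:
            work[c] = work[c].astype(np.int64)
    return work


def missingness_report(before: pd.DataFrame, after: pd.DataFrame) -> pd.DataFrame:
    """Per-column missing counts before/after (audit log companion)."""
    rows = []
    for c in before.columns:
        rows.append((c, int(before[c].isna().sum()),
                     int(after[c].isna().sum()) if c in after.columns else 0))
    return pd.DataFrame(rows, columns=["column", "missing_before", "missing_after"])
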