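"""Bootstrap-then-impute orchestration and percentile confidence intervals.

Each of B replicates resamples n individuals with replacement, performs one
stochastic imputation of the resampled table (when it has missing values and
an imputation spec is supplied), then evaluates the estimator — which refits
everything downstream, including the gender-score model, so score-estimation
uncertainty is inside the intervals.  The reported point estimate is the mean
over replicates and the 95% CI the 2.5/97.5 empirical percentiles (linear
interpolation of order statistics, numpy's default quantile rule).

Replicates draw their randomness from child seeds spawned from one master
seed, so results are reproducible and independent of execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .impute import ImputationSpec, impute_stochastic


@dataclass
class BootstrapResult:
    estimates: pd.DataFrame        # B_successful x K replicate estimates
    master_seed: int
    child_seeds: tuple[int, ...]
    n_requested: int
    failures: tuple[tuple[int, str], ...] = ()

    @property
    def n_replicates(self) -> int:
        return len(self.estimates)


def bootstrap_pipeline(
    table: pd.DataFrame,
    estimator: Callable[[pd.DataFrame, int], Mapping[str, float]],
    B: int,
    master_seed: int,
    impute_spec: ImputationSpec | None = None,
    max_failure_frac: float = 0.05,
) -> BootstrapResult:
    """Run ``estimator`` on B bootstrapped (and singly imputed) datasets.

    ``estimator(completed_table, seed)`` must be a deterministic function of
    its arguments and return a flat name -> value mapping.  A replicate whose
    estimator raises is dropped and recorded; more than ``max_failure_frac``
    failures aborts the run.
    """
    if B < 2:
        raise ValueError(f"B must be at least 2, got {B}")
    n = len(table)
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(B)
    child_ints = tuple(int(c.generate_state(1)[0] % (2**31)) for c in children)

    rows: list[pd.Series] = []
    failures: list[tuple[int, str]] = []
    has_missing = bool(table.isna().any().any())
    for b, child in enumerate(children):
        sub = child.spawn(3)  # resample / imputation / estimator
        rng = np.random.default_rng(sub[0])
        idx = rng.integers(0, n, size=n)
        boot = table.iloc[idx].reset_index(drop=True)
        try:
            if has_missing and impute_spec is not None:
                boot = impute_stochastic(
                    boot, impute_spec,
                    seed=int(sub[1].generate_state(1)[0] % (2**31)),
                )
            est = estimator(boot, int(sub[2].generate_state(1)[0] % (2**31)))
            rows.append(pd.Series(dict(est), name=b, dtype=float))
        except Exception as exc:  # noqa: BLE001 - replicate-level fault isolation
            failures.append((b, f"{type(exc).__name__}: {exc}"))
    if len(failures) > max_failure_frac * B:
        raise RuntimeError(
            f"{len(failures)}/{B} bootstrap replicates failed "
            f"(> {max_failure_frac:.0%}); first failure: {failures[0][1]}"
        )
    estimates = pd.DataFrame(rows)
    return BootstrapResult(
        estimates=estimates,
        master_seed=master_seed,
        child_seeds=child_ints,
        n_requested=B,
        failures=tuple(failures),
    )


def percentile_ci(draws, alpha: float = 0.05) -> tuple[float, float]:
    """Empirical (alpha/2, 1 - alpha/2) quantiles, linear interpolation."""
    draws = np.asarray(draws, dtype=float)
    finite = draws[np.isfinite(draws)]
    if len(finite) < 2:
        raise ValueError("percentile CI needs at least 2 finite draws")
    lo, hi = np.quantile(finite, [alpha / 2.0, 1.0 - alpha / 2.0], method="linear")
    return float(lo), float(hi)


def summarize(result: BootstrapResult, alpha: float = 0.05) -> pd.DataFrame:
    """Point estimate (replicate mean) and percentile CI per estimand."""
    out = []
    for col in result.estimates.columns:
        draws = result.estimates[col].to_numpy()
        finite = draws[np.isfinite(draws)]
        n_bad = len(draws) - len(finite)
        if n_bad:
            warnings.warn(
                f"{n_bad} non-finite replicate estimate(s) for {col!r} "
                "excluded from the percentiles",
                stacklevel=2,
            )
        lo, hi = percentile_ci(finite, alpha)
        out.append((col, float(finite.mean()), lo, hi, len(finite)))
    return pd.DataFrame(
        out, columns=["estimand", "point", "ci_low", "ci_high", "n_boot"]
    ).set_index("estimand")


def significance_flag(estimate) -> bool:
    """True iff the 95% CI excludes zero (a CI touching 0 is not significant)."""
    if estimate.ci_low is None or estimate.ci_high is None:
        raise ValueError("estimate carries no confidence interval")
    return bool(estimate.ci_low > 0.0 or estimate.ci_high < 0.0)
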