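"""Canonical cohort data model and basic transforms.

A cohort is held as a plain :class:`pandas.DataFrame` whose columns follow a
fixed registry: sex at birth ``S`` (1 = male-born, 0 = female-born), the two
early-life environment indicators and their conjunction ``E`` (early-life
deprivation), a fixed set of binary socio-behavioural mediators measured at
ages 23/33, and six continuous biomarkers measured at 44-45.  Strongly skewed
biomarkers (triglycerides, CRP, cortisol) are analysed on the natural-log
scale; :func:`transform_outcomes` adds the log columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Column registry
# ---------------------------------------------------------------------------

SEX = "sex"
MOTHER_SHORT_EDU = "mother_short_education"
PARENT_MANUAL = "parent_manual_class"
DEPRIVED = "deprived"

#: Binary socio-behavioural mediators, grouped by the dimension of social life
#: they describe.  Each indicator is coded so that 1 is the category more
#: frequent among male-born cohort members.
MEDIATOR_GROUPS: dict[str, tuple[str, ...]] = {
    "cultural_capital": (
        "low_education_23",
        "no_numeracy_problems_23",
        "literacy_problems_23",
        "rarely_reads_23",
        "drivers_license_33",
    ),
    "economic_capital": (
        "savings_above_median_23",
        "paid_work_23",
        "manual_class_33",
    ),
    "social_capital": (
        "rarely_sees_friends_23",
        "not_married_23",
        "no_child_23",
        "no_laundry_33",
        "not_religious_23",
    ),
    "behaviours": (
        "smoking_23",
        "smoking_33",
        "alcohol_daily_23",
        "alcohol_daily_33",
        "fried_food_33",
        "sport_23",
        "no_sport_33",
        "accident_23_33",
    ),
}

MEDIATORS: tuple[str, ...] = tuple(
    name for group in MEDIATOR_GROUPS.values() for name in group
)

#: Biomarkers at 44-45: name -> (unit, analysed on log scale?)
BIOMARKERS: dict[str, tuple[str, bool]] = {
    "sbp": ("mmHg", False),
    "triglycerides": ("g/L", True),
    "ldl": ("mmol/L", False),
    "hba1c": ("%", False),
    "crp": ("mg/L", True),
    "cortisol": ("ug", True),
}

LOG_BIOMARKERS: tuple[str, ...] = tuple(
    name for name, (_, logged) in BIOMARKERS.items() if logged
)


def outcome_column(biomarker: str) -> str:
    """Analysis column for a biomarker: the log column if it is log-scaled."""
    if biomarker not in BIOMARKERS:
        raise ValueError(f"unknown biomarker {biomarker!r}")
    return f"log_{biomarker}" if BIOMARKERS[biomarker][1] else biomarker


ALL_COLUMNS: tuple[str, ...] = (
    "id",
    SEX,
    MOTHER_SHORT_EDU,
    PARENT_MANUAL,
    DEPRIVED,
    *MEDIATORS,
    *BIOMARKERS,
)


# ---------------------------------------------------------------------------
# Variable sets
# ---------------------------------------------------------------------------

_SMALL_SET = (
    "low_education_23",
    "manual_class_33",
    "rarely_sees_friends_23",
    "not_married_23",
    "no_sport_33",
    "fried_food_33",
    "smoking_33",
    "alcohol_daily_33",
)


@dataclass(frozen=True)
class VariableSet:
    """Named ordered subset of the mediator registry."""

    name: str
    mediators: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.mediators:
            raise ValueError("a variable set must contain at least one mediator")
        unknown = [m for m in self.mediators if m not in MEDIATORS]
        if unknown:
            raise ValueError(f"unknown mediator name(s): {unknown}")

    def __len__(self) -> int:
        return len(self.mediators)


COMPLETE_SET = VariableSet("complete", MEDIATORS)
BEHAVIOURAL_SET = VariableSet("behavioural", MEDIATOR_GROUPS["behaviours"])
SMALL_SET = VariableSet("small", _SMALL_SET)

NAMED_SETS: dict[str, VariableSet] = {
    "complete": COMPLETE_SET,
    "behavioural": BEHAVIOURAL_SET,
    "small": SMALL_SET,
}


def get_variable_set(name: str, custom: list[str] | None = None) -> VariableSet:
    if name == "custom":
        return VariableSet("custom", tuple(custom or ()))
    try:
        return NAMED_SETS[name]
    except KeyError:
        raise ValueError(
            f"unknown variable set {name!r}; expected one of "
            f"{sorted(NAMED_SETS)} or 'custom'"
        ) from None


@dataclass(frozen=True)
class ReferenceProfile:
    """Fixed mediator values used for the controlled direct effect CDE^Sigma.

    Maps every mediator of the active variable set to a reference value in
    {0, 1}.  The default profile uses each mediator's modal category in the
    analysis dataset.
    """

    values: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.values.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"reference values must be 0/1, got {bad}")

    def require_names(self, names) -> None:
        missing = [m for m in names if m not in self.values]
        if missing:
            raise ValueError(
                f"reference profile does not cover mediator(s): {missing}"
            )

    def require(self, varset: VariableSet) -> None:
        self.require_names(varset.mediators)


def modal_reference_profile(table: pd.DataFrame, varset: VariableSet) -> ReferenceProfile:
    """Reference profile from the modal category of each mediator."""
    values = {}
    for m in varset.mediators:
        col = table[m].dropna()
        if col.empty:
            raise ValueError(f"mediator {m!r} has no observed values")
        values[m] = int(col.mean() >= 0.5)
    return ReferenceProfile(values)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def derive_deprivation(mother_short_education, parent_manual_class):
    """Early-life deprivation: mother left school early AND other parent manual.

    Missing-aware conjunction: 0 as soon as either observed indicator is 0,
    1 only when both are 1, missing (NaN) when undeterminable.  Accepts
    scalars or aligned array-likes.
    """
    a = np.asarray(mother_short_education, dtype=float)
    b = np.asarray(parent_manual_class, dtype=float)
    for name, arr in ((MOTHER_SHORT_EDU, a), (PARENT_MANUAL, b)):
        obs = arr[~np.isnan(arr)] if arr.ndim else (np.empty(0) if np.isnan(arr) else arr[None])
        if not np.isin(obs, (0.0, 1.0)).all():
            raise ValueError(f"{name} must be binary (0/1) or missing")
    out = np.full(np.broadcast(a, b).shape, np.nan)
    a, b = np.broadcast_arrays(a, b)
    out[(a == 0) | (b == 0)] = 0.0
    out[(a == 1) & (b == 1)] = 1.0
    if out.ndim == 0 or (np.ndim(mother_short_education) == 0 and np.ndim(parent_manual_class) == 0):
        return float(out.reshape(-1)[0])
    return out


def transform_outcomes(table: pd.DataFrame) -> pd.DataFrame:
    """Add natural-log columns for the log-scaled biomarkers.

    Rejects a table that already carries log columns (double-logging guard)
    and any non-positive value in a log-targeted biomarker, reporting the
    offending rows.
    """
    existing = [f"log_{m}" for m in LOG_BIOMARKERS if f"log_{m}" in table.columns]
    if existing:
        raise ValueError(f"outcomes already transformed: {existing} present")
    out = table.copy()
    for m in LOG_BIOMARKERS:
        if m not in table.columns:
            continue
        col = table[m]
        bad = col.index[(col <= 0).fillna(False)]
        if len(bad):
            raise ValueError(
                f"non-positive {m} at rows {list(bad[:10])}; log transform undefined"
            )
        out[f"log_{m}"] = np.log(col)
    return out


def standardize_outcome(y, mu: float, sigma: float):
    """z = (y - mu) / sigma, the z-scoring used for the SD-scale estimates."""
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return (y - mu) / sigma


def select_variable_set(table: pd.DataFrame, varset: VariableSet) -> pd.DataFrame:
    """View of the table restricted to the varset's mediators.

    Exposure, environment and outcome columns are retained; mediators outside
    the set are dropped.
    """
    missing = [m for m in varset.mediators if m not in table.columns]
    if missing:
        raise ValueError(f"table lacks mediator column(s): {missing}")
    keep = [c for c in table.columns if c not in MEDIATORS]
    return table[keep + list(varset.mediators)]


# ---------------------------------------------------------------------------
# CSV interface with data dictionary
# ---------------------------------------------------------------------------

_ROLES = ("id", "sex", "environment", "mediator", "biomarker", "derived")


def default_data_dictionary() -> pd.DataFrame:
    """Data dictionary for the canonical column registry."""
    rows = [("id", "id", "integer", "")]
    rows.append((SEX, "sex", "binary", "0;1"))
    rows += [
        (MOTHER_SHORT_EDU, "environment", "binary", "0;1"),
        (PARENT_MANUAL, "environment", "binary", "0;1"),
        (DEPRIVED, "environment", "binary", "0;1"),
    ]
    rows += [(m, "mediator", "binary", "0;1") for m in MEDIATORS]
    rows += [(b, "biomarker", "continuous", "") for b in BIOMARKERS]
    return pd.DataFrame(rows, columns=["column", "role", "type", "allowed"])


def read_cohort_csv(path, dictionary: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a cohort CSV, validating every column against the dictionary.

    Errors cite 1-based data line numbers (header = line 1).
    """
    dictionary = default_data_dictionary() if dictionary is None else dictionary
    table = pd.read_csv(path)
    errors: list[str] = []
    for _, spec in dictionary.iterrows():
        col = spec["column"]
        if col not in table.columns:
            if spec["role"] in ("id", "sex", "environment"):
                errors.append(f"required column {col!r} missing")
            continue
        if spec["type"] == "binary":
            vals = table[col]
            bad = vals.index[~(vals.isin((0, 1)) | vals.isna())]
            errors.extend(
                f"line {i + 2}: column {col!r} has non-binary value {vals[i]!r}"
                for i in bad[:5]
            )
    unknown = [
        c for c in table.columns
        if c not in set(dictionary["column"]) and not c.startswith("log_")
    ]
    if unknown:
        errors.append(f"columns not in data dictionary: {unknown}")
    if errors:
        raise ValueError("invalid cohort CSV:\n  " + "\n  ".join(errors))
    return table


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
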