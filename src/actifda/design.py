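"""Shared covariate design construction for the association models.

Both the GEE score regressions and the function-on-scalar regression adjust
for the same determinant blocks: sociodemographics (age, sex, education,
partner), health and lifestyle (BMI, chronic diseases, cigarettes/day,
drinks/day), sampling factors (work/school day, season with winter as
reference), and at most one clinical characteristic at a time (diagnostic
group with 'none' as reference, symptom score, antidepressant use, or
benzodiazepine use) — clinical covariates are highly intercorrelated and
never co-occur in one model.

Continuous covariates are z-scored on the analysis sample so coefficients
read as per-SD effects; binary covariates stay 0/1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import CollinearityError, InvalidConfigError

CONTINUOUS_COVARIATES = [
    "age",
    "education",
    "bmi",
    "chronic_diseases",
    "cigarettes_per_day",
    "drinks_per_day",
]
BINARY_COVARIATES = ["male", "partner"]
SEASON_LEVELS = ("autumn", "spring", "summer")  # winter = reference
GROUP_LEVELS = ("remitted", "current")  # none = reference

CLINICAL_OPTIONS = (None, "group", "ids", "antidepressant", "benzodiazepine")

# covariate -> (display variable, display level, reference level) for tables
VARIABLE_LABELS = {
    "age": ("Age", "", None),
    "male": ("Sex", "Male", "Female"),
    "education": ("Education level", "", None),
    "partner": ("Has a partner", "Yes", "No"),
    "bmi": ("BMI", "", None),
    "chronic_diseases": ("Number of chronic diseases", "", None),
    "cigarettes_per_day": ("Number of cigarettes per day", "", None),
    "drinks_per_day": ("Number of drinks per day", "", None),
    "workday": ("Work/school day", "Yes", "No"),
    "season_autumn": ("Season", "Autumn", "Winter"),
    "season_spring": ("Season", "Spring", "Winter"),
    "season_summer": ("Season", "Summer", "Winter"),
    "group_remitted": ("Depressive and/or anxiety disorders", "Remitted", "No"),
    "group_current": ("Depressive and/or anxiety disorders", "Current", "No"),
    "ids": ("IDS", "", None),
    "antidepressant": ("Antidepressant use", "Yes", "No"),
    "benzodiazepine": ("Benzodiazepine use", "Yes", "No"),
}


def clinical_columns(clinical: str | None) -> list[str]:
    if clinical not in CLINICAL_OPTIONS:
        raise InvalidConfigError(
            f"clinical must be one of {CLINICAL_OPTIONS}, got {clinical!r}"
        )
    if clinical is None:
        return []
    if clinical == "group":
        return [f"group_{g}" for g in GROUP_LEVELS]
    return [clinical]


def build_design(
    table: pd.DataFrame,
    clinical: str | None = None,
    workday_column: str = "workday",
    standardize: bool = True,
) -> pd.DataFrame:
    """Assemble the adjusted design matrix (without intercept) as a DataFrame.

    ``table`` carries one row per analysis unit (subject-day for GEE,
    subject for FoSR) with raw covariate columns; ``workday_column`` names
    the work/school-day regressor (a 0/1 flag at day level, a proportion at
    subject level). Season enters as three winter-referenced dummies from
    either a ``season`` column or precomputed ``season_*`` dummies.
    """
    cols: dict[str, np.ndarray] = {}
    for name in CONTINUOUS_COVARIATES:
        x = table[name].to_numpy(float)
        if standardize:
            sd = x.std(ddof=1)
            x = (x - x.mean()) / (sd if sd > 0 else 1.0)
        cols[name] = x
    for name in BINARY_COVARIATES:
        cols[name] = table[name].to_numpy(float)
    cols["workday"] = table[workday_column].to_numpy(float)
    if "season" in table.columns:
        for s in SEASON_LEVELS:
            cols[f"season_{s}"] = (table["season"] == s).astype(float).to_numpy()
    else:
        for s in SEASON_LEVELS:
            cols[f"season_{s}"] = table[f"season_{s}"].to_numpy(float)
    for name in clinical_columns(clinical):
        if name.startswith("group_"):
            level = name.removeprefix("group_")
            cols[name] = (table["group"] == level).astype(float).to_numpy()
        else:
            x = table[name].to_numpy(float)
            if name == "ids" and standardize:
                sd = x.std(ddof=1)
                x = (x - x.mean()) / (sd if sd > 0 else 1.0)
            cols[name] = x
    X = pd.DataFrame(cols, index=table.index)
    check_full_rank(X, add_constant=True)
    return X


def check_full_rank(X: pd.DataFrame, add_constant: bool = True) -> None:
    """Raise :class:`CollinearityError` naming dependent columns, if any."""
    M = X.to_numpy(float)
    if add_constant:
        M = np.column_stack([np.ones(len(M)), M])
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # identify offenders by rank-revealing QR pivoting
        from scipy.linalg import qr

        _, _, piv = qr(M, pivoting=True, mode="economic")
        bad = sorted(piv[rank:])
        names = ["const"] + list(X.columns) if add_constant else list(X.columns)
        raise CollinearityError([names[j] for j in bad])
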