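"""Synthetic minute-level actigraphy with known ground truth.

The generator emulates the structure of a two-week wrist-actigraphy study in
an adult psychiatric cohort: each subject wears the device for a consecutive
block of days (default 14), producing 1440 activity values per day. Daily
curves follow a functional principal-component model

    X_ij(t) = max(0, mu(t) + sum_k xi_ijk * phi_k(t) + eps_ij(t))

where ``mu`` and the orthonormal components ``phi_k`` live in a 9-function
Fourier basis, ``eps`` is white minute-level noise, and the day-level scores
decompose as

    xi_ijk = Gamma_k . z_ij + b_ik + e_ijk

with a covariate effect, a subject random effect b_ik ~ N(0, tau_b^2) and a
day effect e_ijk ~ N(0, tau_e^2). The within-subject day-to-day score
correlation is therefore tau_b^2 / (tau_b^2 + tau_e^2). Non-wear is injected
as contiguous unobserved minute runs (Poisson count per day, geometric
lengths).

Everything is reproducible: the configuration seed drives independent
deterministic streams per stage, so identical configurations give
byte-identical outputs, and the stored truth (scores plus configuration)
reconstructs every curve exactly when the noise is off.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import MINUTES_PER_DAY, FourierBasis
from .errors import InvalidConfigError
from .preprocess import season_of

# Column order of the ground-truth covariate design that the effect matrix
# multiplies. Continuous covariates enter standardized by their *generative*
# mean/SD (not sample moments), so configured effects are exact.
TRUTH_DESIGN_COLUMNS = [
    "age",
    "male",
    "education",
    "partner",
    "bmi",
    "chronic_diseases",
    "cigarettes_per_day",
    "drinks_per_day",
    "workday",
    "season_autumn",
    "season_spring",
    "season_summer",
    "group_remitted",
    "group_current",
    "ids",
    "antidepressant",
]

# Generative location/scale used both to draw continuous covariates and to
# standardize them in the truth design.
_COVARIATE_MOMENTS = {
    "age": (50.0, 12.0),
    "education": (13.0, 3.0),
    "bmi": (26.5, 5.0),
    "chronic_diseases": (0.9, 1.0),
    "cigarettes_per_day": (2.4, 5.5),
    "drinks_per_day": (0.65, 1.0),
    "ids": (18.0, 13.0),
}

# Per-SD effect sizes (components x design columns) mirroring the magnitude
# and sign structure of multivariable GEE estimates in comparable cohorts:
# lower overall activity with age/BMI/smoking/depression, earlier morning
# activity on workdays and in spring, a strongly workday-driven biphasic
# pattern, and season-shifted timing.
_DEFAULT_STD_EFFECTS = np.array(
    [
        # age  male  educ  part  bmi  chron cigs drinks work  aut   spr   sum   rem   cur   ids   anti
        [-0.15, -0.05, -0.13, -0.17, -0.12, -0.11, -0.14, 0.08, 0.17, 0.10, 0.15, 0.29, -0.06, -0.24, -0.14, -0.17],
        [0.08, -0.02, -0.01, 0.18, 0.05, -0.01, 0.03, -0.05, 0.28, 0.19, 0.33, 0.18, -0.04, 0.02, -0.05, -0.12],
        [-0.10, -0.03, 0.04, -0.02, -0.01, -0.03, -0.05, -0.04, 0.73, 0.02, 0.14, 0.33, -0.05, 0.00, -0.02, -0.08],
        [0.10, -0.07, -0.03, 0.05, 0.01, -0.05, 0.02, -0.01, 0.19, 0.14, 0.26, 0.24, 0.08, -0.01, -0.04, -0.11],
    ]
)

# Default component shapes in Fourier-coefficient space (exactly orthonormal).
# The four leading components emulate the interpretable modes of daily
# variation: overall level (constant), early-vs-late morning (first-harmonic
# sine), biphasic-vs-monophasic (second-harmonic cosine), early-vs-late
# biphasic (second-harmonic sine). The remaining five Fourier directions act
# as low-variance "fine structure": real day-to-day variability is never
# confined to four directions, and without that remainder a descending
# 4-eigenvalue spectrum could never need four components to reach 75%
# cumulative variance (lambda_4 <= total/4 forces cum_3 >= 3/4).
_DEFAULT_COMPONENTS = np.zeros((9, 9))
for _row, _col in enumerate((0, 1, 4, 3, 2, 5, 6, 7, 8)):
    _DEFAULT_COMPONENTS[_row, _col] = 1.0

# Default score variances (activity-units^2 in coefficient space): four
# dominant modes plus an isotropic fine-structure floor sized so the
# cumulative variance of the leading modes crosses 0.75 exactly at K=4.
_DEFAULT_EIGENVALUES = np.array(
    [272_000.0, 160_000.0, 144_000.0, 120_000.0] + [36_000.0] * 5
)


def _default_mean_coefficients(basis: FourierBasis) -> np.ndarray:
    """Smooth diurnal mean: low at night, broad daytime plateau.

    Built from the first two harmonics, so the basis projection is exact.
    """
    t = basis.minute_grid()
    T = basis.period
    curve = (
        200.0
        + 120.0 * np.cos(2 * np.pi * (t - 870.0) / T)
        + 20.0 * np.cos(4 * np.pi * (t - 780.0) / T)
    )
    return basis.project(curve)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and sampling plan for one synthetic study."""

    n_subjects: int
    days_per_subject: int = 14
    period: int = MINUTES_PER_DAY
    n_basis: int = 9
    mean_coefficients: np.ndarray | None = None
    component_coefficients: np.ndarray = field(
        default_factory=lambda: _DEFAULT_COMPONENTS.copy()
    )
    subject_sd: np.ndarray | None = None
    day_sd: np.ndarray | None = None
    effect_matrix: np.ndarray | None = None
    noise_sd: float = 25.0
    gap_rate: float = 1.0
    gap_length: float = 45.0
    workday_prob: float = 0.4
    start_year: int = 2016
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidConfigError(
                f"n_subjects must be >= 1, got {self.n_subjects}"
            )
        if self.days_per_subject < 1:
            raise InvalidConfigError("days_per_subject must be >= 1")
        if self.period != MINUTES_PER_DAY:
            raise InvalidConfigError(
                f"period is fixed at {MINUTES_PER_DAY} minutes"
            )
        basis = self.basis
        object.__setattr__(
            self,
            "component_coefficients",
            np.atleast_2d(np.asarray(self.component_coefficients, float)),
        )
        comp = self.component_coefficients
        if comp.shape[1] != self.n_basis:
            raise InvalidConfigError(
                f"components must have {self.n_basis} coefficients each"
            )
        gram = comp @ comp.T
        if not np.allclose(gram, np.eye(comp.shape[0]), atol=1e-8):
            raise InvalidConfigError(
                "true components must be pairwise orthonormal "
                "in coefficient space (tolerance 1e-8)"
            )
        k = comp.shape[0]
        if self.mean_coefficients is None:
            object.__setattr__(
                self, "mean_coefficients", _default_mean_coefficients(basis)
            )
        object.__setattr__(
            self,
            "mean_coefficients",
            np.asarray(self.mean_coefficients, float),
        )
        if self.mean_coefficients.shape != (self.n_basis,):
            raise InvalidConfigError(
                f"mean_coefficients must have shape ({self.n_basis},)"
            )
        if self.subject_sd is None:
            object.__setattr__(
                self, "subject_sd", np.sqrt(_DEFAULT_EIGENVALUES[:k] / 2.0)
            )
        if self.day_sd is None:
            object.__setattr__(
                self, "day_sd", np.sqrt(_DEFAULT_EIGENVALUES[:k] / 2.0)
            )
        for name in ("subject_sd", "day_sd"):
            arr = np.broadcast_to(
                np.asarray(getattr(self, name), float), (k,)
            ).copy()
            if (arr < 0).any():
                raise InvalidConfigError(f"{name} must be nonnegative")
            object.__setattr__(self, name, arr)
        if self.effect_matrix is None:
            gamma = np.zeros((k, len(TRUTH_DESIGN_COLUMNS)))
            n_eff = min(k, _DEFAULT_STD_EFFECTS.shape[0])
            gamma[:n_eff] = _DEFAULT_STD_EFFECTS[:n_eff] * np.sqrt(
                self.eigenvalues[:n_eff]
            )[:, None]
            object.__setattr__(self, "effect_matrix", gamma)
        object.__setattr__(
            self,
            "effect_matrix",
            np.atleast_2d(np.asarray(self.effect_matrix, float)),
        )
        if self.effect_matrix.shape[0] != k:
            raise InvalidConfigError(
                "effect_matrix must have one row per component"
            )
        if self.noise_sd < 0 or self.gap_rate < 0 or self.gap_length <= 0:
            raise InvalidConfigError(
                "noise_sd and gap_rate must be >= 0, gap_length > 0"
            )

    @property
    def basis(self) -> FourierBasis:
        return FourierBasis(self.n_basis, float(self.period))

    @property
    def n_components(self) -> int:
        return self.component_coefficients.shape[0]

    @property
    def eigenvalues(self) -> np.ndarray:
        """Total stochastic score variance per component, tau_b^2 + tau_e^2."""
        return self.subject_sd**2 + self.day_sd**2

    @classmethod
    def with_eigenvalues(
        cls, eigenvalues, icc: float = 0.5, **kwargs
    ) -> "SimulationConfig":
        """Build a config from total score variances and a score ICC.

        ``icc`` is the within-subject day-to-day score correlation
        tau_b^2 / (tau_b^2 + tau_e^2); the default 0.5 splits the variance
        evenly between the subject and day levels.
        """
        lam = np.asarray(eigenvalues, float)
        if not 0.0 <= icc <= 1.0:
            raise InvalidConfigError(f"icc must be in [0, 1], got {icc}")
        return cls(
            subject_sd=np.sqrt(lam * icc),
            day_sd=np.sqrt(lam * (1.0 - icc)),
            **kwargs,
        )

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


def simulate_covariates(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw subject-level and day-level covariate tables.

    Subject covariates loosely match an adult outpatient cohort: age
    N(50, 12), BMI N(26.5, 5), about two-thirds female, diagnostic group
    with roughly a quarter current and half remitted cases, symptom scores
    and antidepressant use elevated in the affected groups. Day covariates
    are a consecutive calendar block per subject with Bernoulli work/school
    days and the season of each date.
    """
    rng = config._rng(1)
    n = config.n_subjects
    ids = np.array([f"S{i + 1:04d}" for i in range(n)])

    age = rng.normal(*_COVARIATE_MOMENTS["age"], size=n)
    male = rng.binomial(1, 0.37, size=n)
    education = np.clip(rng.normal(*_COVARIATE_MOMENTS["education"], size=n), 5, 22)
    partner = rng.binomial(1, 0.52, size=n)
    bmi = np.clip(rng.normal(*_COVARIATE_MOMENTS["bmi"], size=n), 15, None)
    chronic = rng.poisson(0.9, size=n)
    cigarettes = np.where(
        rng.random(n) < 0.22, rng.exponential(11.0, size=n), 0.0
    )
    drinks = np.round(np.clip(rng.normal(0.65, 1.0, size=n), 0, None), 1)
    group = rng.choice(
        ["none", "remitted", "current"], size=n, p=[0.25, 0.49, 0.26]
    )
    ids_mean = {"none": 6.0, "remitted": 21.0, "current": 28.5}
    ids_sd = {"none": 5.0, "remitted": 12.5, "current": 11.5}
    ids_score = np.clip(
        rng.normal(
            [ids_mean[g] for g in group], [ids_sd[g] for g in group]
        ),
        0,
        None,
    )
    anti_p = {"none": 0.02, "remitted": 0.19, "current": 0.37}
    antidepressant = rng.binomial(1, [anti_p[g] for g in group])
    benzodiazepine = rng.binomial(1, 0.04, size=n)

    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "age": np.round(age, 1),
            "male": male,
            "education": np.round(education, 1),
            "partner": partner,
            "bmi": np.round(bmi, 1),
            "chronic_diseases": chronic,
            "cigarettes_per_day": np.round(cigarettes, 1),
            "drinks_per_day": drinks,
            "group": group,
            "ids": np.round(ids_score, 1),
            "antidepressant": antidepressant,
            "benzodiazepine": benzodiazepine,
        }
    )

    start_offsets = rng.integers(0, 352, size=n)
    rows = []
    year_start = _date(config.start_year, 1, 1)
    for i, sid in enumerate(ids):
        start = year_start + timedelta(days=int(start_offsets[i]))
        for d in range(config.days_per_subject):
            day = start + timedelta(days=d)
            rows.append((sid, day.isoformat(), d))
    days = pd.DataFrame(rows, columns=["subject_id", "date", "day_index"])
    days["workday"] = rng.binomial(1, config.workday_prob, size=len(days))
    days["season"] = [season_of(d) for d in days["date"]]
    return subjects, days


def truth_design(
    subjects: pd.DataFrame, days: pd.DataFrame
) -> np.ndarray:
    """Day-level covariate design (standardized by generative moments).

    Returns an array aligned to the rows of ``days`` with columns in
    ``TRUTH_DESIGN_COLUMNS`` order.
    """
    tab = days.merge(subjects, on="subject_id", how="left", validate="m:1")
    cols = {}
    for name in ("age", "education", "bmi", "chronic_diseases",
                 "cigarettes_per_day", "drinks_per_day", "ids"):
        m, s = _COVARIATE_MOMENTS[name]
        cols[name] = (tab[name].to_numpy(float) - m) / s
    for name in ("male", "partner", "workday", "antidepressant"):
        cols[name] = tab[name].to_numpy(float)
    for season in ("autumn", "spring", "summer"):
        cols[f"season_{season}"] = (tab["season"] == season).astype(float)
    for grp in ("remitted", "current"):
        cols[f"group_{grp}"] = (tab["group"] == grp).astype(float)
    return np.column_stack([cols[c] for c in TRUTH_DESIGN_COLUMNS])


def simulate_scores(
    config: SimulationConfig,
    subjects: pd.DataFrame,
    days: pd.DataFrame,
) -> np.ndarray:
    """Realize day-level component scores xi_ijk, aligned to ``days`` rows.

    xi_ijk = Gamma_k . z_ij + b_ik + e_ijk with subject effects b and day
    effects e; the covariate design z uses the generative standardization.
    """
    z = truth_design(subjects, days)
    k = config.n_components
    if config.effect_matrix.shape != (k, z.shape[1]):
        raise ValueError(
            f"effect_matrix shape {config.effect_matrix.shape} does not "
            f"match (n_components={k}, n_covariates={z.shape[1]})"
        )
    rng = config._rng(2)
    subj_index = (
        days["subject_id"].map(
            {s: i for i, s in enumerate(subjects["subject_id"])}
        )
    ).to_numpy()
    b = rng.normal(size=(len(subjects), k)) * config.subject_sd
    e = rng.normal(size=(len(days), k)) * config.day_sd
    return z @ config.effect_matrix.T + b[subj_index] + e


def simulate_curves(
    config: SimulationConfig,
    days: pd.DataFrame,
    scores: np.ndarray,
) -> pd.DataFrame:
    """Render minute-level activity from the functional score model.

    Returns a long-format table ``subject_id, date, minute_of_day,
    activity, observed`` with 1440 fully observed minutes per subject-day;
    activity is floored at zero.
    """
    scores = np.asarray(scores, float)
    if scores.shape != (len(days), config.n_components):
        raise ValueError(
            f"scores shape {scores.shape} does not match "
            f"({len(days)}, {config.n_components})"
        )
    basis = config.basis
    coef = config.mean_coefficients + scores @ config.component_coefficients
    values = basis.reconstruct(coef)
    if config.noise_sd > 0:
        rng = config._rng(3)
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    np.maximum(values, 0.0, out=values)

    n_days = len(days)
    minutes = np.tile(np.arange(MINUTES_PER_DAY), n_days)
    return pd.DataFrame(
        {
            "subject_id": np.repeat(days["subject_id"].to_numpy(), MINUTES_PER_DAY),
            "date": np.repeat(days["date"].to_numpy(), MINUTES_PER_DAY),
            "minute_of_day": minutes,
            "activity": np.round(values.ravel(), 4),
            "observed": True,
        }
    )


def inject_gaps(
    minute_records: pd.DataFrame,
    gap_rate: float,
    gap_length: float,
    seed: int,
) -> pd.DataFrame:
    """Mark contiguous non-wear runs as unobserved.

    Each subject-day receives a Poisson(``gap_rate``) number of gaps with
    geometric lengths of mean ``gap_length`` minutes and uniform start
    positions (truncated at midnight). Activity values are left untouched;
    only the ``observed`` flag changes.
    """
    if gap_rate < 0:
        raise InvalidConfigError(f"gap_rate must be >= 0, got {gap_rate}")
    out = minute_records.copy()
    if gap_rate == 0:
        return out
    rng = np.random.default_rng([int(seed), 4])
    observed = out["observed"].to_numpy().copy()
    minute = out["minute_of_day"].to_numpy()
    day_keys, day_start = np.unique(
        out[["subject_id", "date"]].astype(str).agg("|".join, axis=1),
        return_index=True,
    )
    # iterate days in first-appearance order for seed-stable output
    order = np.argsort(day_start)
    for start_row in day_start[order]:
        n_gaps = rng.poisson(gap_rate)
        for _ in range(n_gaps):
            length = rng.geometric(1.0 / gap_length)
            start = rng.integers(0, MINUTES_PER_DAY)
            stop = min(start + length, MINUTES_PER_DAY)
            block = slice(start_row + start, start_row + stop)
            # rows within one day are contiguous and minute-ordered
            observed[block] = False
    out["observed"] = observed
    return out


@dataclass
class SimulatedDataset:
    """One realized synthetic study, with its generating truth attached."""

    minute_records: pd.DataFrame
    subject_covariates: pd.DataFrame
    day_covariates: pd.DataFrame
    scores: np.ndarray
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write CSV tables plus a JSON truth dump; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "minutes": outdir / "minute_records.csv",
            "subjects": outdir / "subject_covariates.csv",
            "days": outdir / "day_covariates.csv",
            "truth": outdir / "truth.json",
        }
        self.minute_records.to_csv(paths["minutes"], index=False)
        self.subject_covariates.to_csv(paths["subjects"], index=False)
        self.day_covariates.to_csv(paths["days"], index=False)
        truth = {
            "config": _config_to_jsonable(self.config),
            "scores": np.asarray(self.scores).tolist(),
            "score_rows": self.day_covariates[
                ["subject_id", "date"]
            ].to_dict("records"),
        }
        paths["truth"].write_text(json.dumps(truth, indent=1))
        return paths


def _config_to_jsonable(config: SimulationConfig) -> dict:
    out = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        out[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
    return out


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: covariates, scores, curves, gaps."""
    subjects, days = simulate_covariates(config)
    scores = simulate_scores(config, subjects, days)
    minutes = simulate_curves(config, days, scores)
    minutes = inject_gaps(
        minutes, config.gap_rate, config.gap_length, config.seed
    )
    return SimulatedDataset(minutes, subjects, days, scores, config)
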