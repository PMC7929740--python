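"""GEE regression of day-level component scores on determinants.

Scores from repeated days of the same subject are correlated, so the
association models are Gaussian identity-link generalized estimating
equations with the subject as the cluster, an exchangeable working
correlation by default, and robust (sandwich) standard errors. One model is
fitted per component and per clinical characteristic (clinical covariates
are mutually exclusive to avoid their collinearity), each adjusted for the
full sociodemographic, lifestyle and sampling blocks. Multiple testing is
handled with Benjamini–Hochberg FDR within each fitted model's family of
non-reference covariate tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .design import VARIABLE_LABELS, build_design
from .errors import DataIntegrityError, DegenerateInputError, InvalidConfigError


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: q-values and rejection flags.

    q_i is the smallest FDR level at which test i would be rejected
    (min over j >= i of m * p_(j) / j, capped at 1); the rejection set at
    level ``alpha`` is every p at or below the largest p_(i) with
    p_(i) <= i * alpha / m.
    """
    p = np.asarray(pvalues, float)
    if p.size and ((p < 0) | (p > 1) | np.isnan(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise InvalidConfigError(f"alpha must be in (0, 1), got {alpha}")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


@dataclass
class ScoreAssociationResults:
    """One fitted GEE: per-covariate estimates plus cluster diagnostics."""

    component: int
    clinical: str | None
    table: pd.DataFrame  # term, beta, se, z, p
    alpha_hat: float
    n_subjects: int
    n_days: int
    _sm_results: object = field(default=None, repr=False)

    def summary(self) -> str:
        head = (
            f"GEE (exchangeable, robust SE)  component {self.component}  "
            f"clinical={self.clinical or 'none'}\n"
            f"  clusters: {self.n_subjects}  days: {self.n_days}  "
            f"working correlation: {self.alpha_hat:.3f}"
        )
        body = self.table.to_string(
            index=False,
            formatters={
                "beta": "{:8.3f}".format,
                "se": "{:7.3f}".format,
                "z": "{:7.2f}".format,
                "p": "{:8.4f}".format,
            },
        )
        return head + "\n" + body


class ScoreAssociation:
    """GEE model for one component's standardized day-level scores.

    Parameters
    ----------
    score_table : DataFrame
        One row per subject-day with columns ``subject_id``, ``score_std``
        (the outcome), the day covariates ``workday`` and ``season``, and
        the subject covariates.
    clinical : str or None
        Which clinical characteristic to include: 'group', 'ids',
        'antidepressant', 'benzodiazepine', or None.
    cov_struct : str
        Working correlation: 'exchangeable' (default) or 'independence'.
    """

    def __init__(
        self,
        score_table: pd.DataFrame,
        clinical: str | None = None,
        cov_struct: str = "exchangeable",
        component: int = 1,
        outcome: str = "score_std",
    ):
        if cov_struct not in ("exchangeable", "independence"):
            raise InvalidConfigError(
                f"cov_struct must be 'exchangeable' or 'independence', "
                f"got {cov_struct!r}"
            )
        data = score_table.dropna(
            subset=[outcome]
        ).reset_index(drop=True)
        if data["subject_id"].nunique() < 2:
            raise DegenerateInputError("GEE needs at least 2 clusters")
        X = build_design(data, clinical=clinical)
        keep = X.notna().all(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            import logging

            logging.getLogger(__name__).info(
                "dropping %d rows with missing covariates (complete case)",
                n_dropped,
            )
            data = data.loc[keep].reset_index(drop=True)
            X = X.loc[keep].reset_index(drop=True)
        self.groups = data["subject_id"].to_numpy()
        if np.unique(self.groups).size < 2:
            raise DegenerateInputError("GEE needs at least 2 clusters")
        self.endog = data[outcome].to_numpy(float)
        self.exog = sm.add_constant(X, prepend=True, has_constant="add")
        self.clinical = clinical
        self.cov_struct = cov_struct
        self.component = component

    def fit(self) -> ScoreAssociationResults:
        cs = (
            sm.cov_struct.Exchangeable()
            if self.cov_struct == "exchangeable"
            else sm.cov_struct.Independence()
        )
        model = sm.GEE(
            self.endog,
            self.exog,
            groups=self.groups,
            family=sm.families.Gaussian(),
            cov_struct=cs,
        )
        res = model.fit()  # robust (sandwich) covariance is the default
        table = pd.DataFrame(
            {
                "term": self.exog.columns,
                "beta": res.params,
                "se": res.bse,
                "z": res.tvalues,
                "p": res.pvalues,
            }
        ).reset_index(drop=True)
        alpha_hat = (
            float(cs.dep_params) if self.cov_struct == "exchangeable" else 0.0
        )
        return ScoreAssociationResults(
            component=self.component,
            clinical=self.clinical,
            table=table,
            alpha_hat=alpha_hat,
            n_subjects=int(np.unique(self.groups).size),
            n_days=int(self.endog.size),
            _sm_results=res,
        )


def build_results_table(results: list[ScoreAssociationResults]) -> pd.DataFrame:
    """Combine fitted GEEs into one long results table.

    One row per (component, covariate level); reference levels of
    categorical covariates appear as 'Ref' rows; q-values are BH-FDR
    adjusted within each (component, clinical-spec) model's non-reference
    tests. All models must have been fitted on the same sample.
    """
    columns = [
        "component",
        "clinical_model",
        "variable",
        "level",
        "ref_flag",
        "beta",
        "se",
        "z",
        "p",
        "q",
        "n_subjects",
        "n_days",
    ]
    if not results:
        return pd.DataFrame(columns=columns)
    sizes = {(r.n_subjects, r.n_days) for r in results}
    if len(sizes) > 1:
        raise DataIntegrityError(
            f"inconsistent sample sizes across component models: {sorted(sizes)}"
        )
    rows = []
    for r in results:
        clin = r.clinical or "none"
        est = r.table.set_index("term")
        seen_refs = set()
        for term in est.index:
            if term == "const":
                continue
            var, level, ref = VARIABLE_LABELS.get(term, (term, "", None))
            if ref is not None and (var, ref) not in seen_refs:
                seen_refs.add((var, ref))
                rows.append(
                    dict(
                        component=r.component,
                        clinical_model=clin,
                        variable=var,
                        level=ref,
                        ref_flag=True,
                        beta=np.nan,
                        se=np.nan,
                        z=np.nan,
                        p=np.nan,
                        q=np.nan,
                        n_subjects=r.n_subjects,
                        n_days=r.n_days,
                    )
                )
            rows.append(
                dict(
                    component=r.component,
                    clinical_model=clin,
                    variable=var,
                    level=level,
                    ref_flag=False,
                    beta=est.loc[term, "beta"],
                    se=est.loc[term, "se"],
                    z=est.loc[term, "z"],
                    p=est.loc[term, "p"],
                    q=np.nan,
                    n_subjects=r.n_subjects,
                    n_days=r.n_days,
                )
            )
    out = pd.DataFrame(rows, columns=columns)
    # FDR family: non-reference tests within one (component, clinical) fit
    for _, idx in out.groupby(["component", "clinical_model"]).groups.items():
        mask = out.loc[idx, "ref_flag"] == False  # noqa: E712
        sel = out.loc[idx][mask].index
        if len(sel):
            q, _ = bh_fdr(out.loc[sel, "p"].to_numpy())
            out.loc[sel, "q"] = q
    return out


def fit_component_models(
    score_table: pd.DataFrame,
    components: list[int] | None = None,
    clinical_specs: tuple = (None, "group", "ids", "antidepressant"),
    cov_struct: str = "exchangeable",
) -> pd.DataFrame:
    """Fit every (component, clinical spec) GEE and return the long table."""
    if components is None:
        components = sorted(score_table["component"].unique())
    results = []
    for k in components:
        sub = score_table[score_table["component"] == k]
        for clin in clinical_specs:
            res = ScoreAssociation(
                sub, clinical=clin, cov_struct=cov_struct, component=int(k)
            ).fit()
            results.append(res)
    return build_results_table(results)
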