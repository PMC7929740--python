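"""Function-on-scalar regression of average diurnal curves on determinants.

Each included subject contributes one outcome curve: minute activity
aggregated into 144 ten-minute bins and averaged over the subject's valid
days. Every scalar covariate j gets a coefficient function beta_j(t),
expanded in a fixed cubic B-spline basis (default 10 functions) over the
24-hour grid and estimated by stacked least squares across subjects and
grid points. Because the stacked design is the Kronecker product of the
subject design X with the spline basis B, the normal equations factor and
the fit is a pair of small solves.

Inference: pointwise variances come from a subject-level sandwich
covariance of the basis coefficients; the per-covariate global test is a
Wald test on the covariate's full basis-coefficient block. The default
calibration uses the across-grid residual covariance in a Hotelling-style F
reference (exact under Gaussian errors); a sandwich chi-square version and
a subject-resampling bootstrap are available as alternatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .basis import MINUTES_PER_DAY, bspline_basis
from .design import check_full_rank
from .errors import DegenerateInputError, InvalidConfigError
from .preprocess import DayCurveSet

logger = logging.getLogger(__name__)

N_BINS = 144  # ten-minute bins over 24 h


def build_subject_curves(
    day_curves: DayCurveSet,
    subject_covariates: pd.DataFrame,
    bin_minutes: int = 10,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Average imputed valid days into one binned curve per subject.

    Bin value = mean of the constituent minutes; subject curve = mean over
    the subject's valid days. Day-varying covariates are collapsed to the
    subject level: ``workday`` becomes the proportion of valid days that
    are work/school days, ``season`` the modal season over valid days.

    Returns ``(subject_table, Y, grid)`` where ``Y`` is (n_subjects, bins)
    and ``grid`` the bin midpoints in minutes. Subjects with zero valid
    days are dropped with a log entry.
    """
    if MINUTES_PER_DAY % bin_minutes:
        raise InvalidConfigError(
            f"bin_minutes must divide {MINUTES_PER_DAY}, got {bin_minutes}"
        )
    n_bins = MINUTES_PER_DAY // bin_minutes
    meta = day_curves.meta
    rows = []
    curves = []
    for sid, grp in meta.groupby("subject_id", sort=False):
        vidx = grp.index[grp["valid"]].to_numpy()
        if vidx.size == 0:
            logger.info("FoSR: subject %s has no valid days; dropped", sid)
            continue
        vals = day_curves.values[vidx]
        if np.isnan(vals).any():
            raise ValueError("valid days must be imputed before averaging")
        binned = vals.reshape(vidx.size, n_bins, bin_minutes).mean(axis=2)
        curves.append(binned.mean(axis=0))
        row = {"subject_id": sid, "n_valid_days": int(vidx.size)}
        g = grp.loc[grp["valid"]]
        if g["workday"].notna().any():
            row["workday_prop"] = float(g["workday"].astype(float).mean())
        else:
            row["workday_prop"] = np.nan
        row["season"] = g["season"].mode().iloc[0]
        rows.append(row)
    subject_table = pd.DataFrame(rows).merge(
        subject_covariates, on="subject_id", how="left", validate="1:1"
    )
    Y = np.vstack(curves) if curves else np.empty((0, n_bins))
    grid = (np.arange(n_bins) + 0.5) * bin_minutes
    return subject_table, Y, grid


class FunctionOnScalarRegression:
    """FoSR model: curve outcomes ``Y`` regressed on a scalar design.

    Parameters
    ----------
    Y : ndarray (n_subjects, n_grid)
        One averaged diurnal curve per subject.
    X : DataFrame or ndarray (n_subjects, q)
        Scalar covariates *without* intercept; a constant column is added
        and its coefficient function is the reference mean curve.
    grid : ndarray, optional
        Grid midpoints in minutes (default: 144 ten-minute bins).
    n_coef_basis : int
        Size of the B-spline basis for the coefficient functions. Passing
        ``n_coef_basis == n_grid`` requests the saturated fit, in which the
        basis is the identity and the model is independent pointwise OLS.
    penalty : float
        Optional second-difference ridge penalty on the spline coefficients
        (0 = unpenalized); 'gcv' selects it by generalized cross-validation.
    """

    def __init__(
        self,
        Y: np.ndarray,
        X,
        grid: np.ndarray | None = None,
        n_coef_basis: int = 10,
        penalty: float | str = 0.0,
    ):
        self.Y = np.atleast_2d(np.asarray(Y, float))
        n, n_grid = self.Y.shape
        self.grid = (
            np.asarray(grid, float)
            if grid is not None
            else (np.arange(n_grid) + 0.5) * (MINUTES_PER_DAY / n_grid)
        )
        if self.grid.size != n_grid:
            raise InvalidConfigError("grid length must match Y columns")
        if isinstance(X, pd.DataFrame):
            check_full_rank(X, add_constant=True)
            self.columns = ["const"] + list(X.columns)
            Xm = X.to_numpy(float)
        else:
            Xm = np.atleast_2d(np.asarray(X, float))
            self.columns = ["const"] + [f"x{j}" for j in range(Xm.shape[1])]
        self.X = np.column_stack([np.ones(n), Xm])
        q = self.X.shape[1]
        if n_coef_basis == n_grid:
            self.B = np.eye(n_grid)
        else:
            self.B = bspline_basis(n_coef_basis, grid=self.grid)
        d = self.B.shape[1]
        if n <= q:
            raise DegenerateInputError(
                f"FoSR needs more subjects ({n}) than design columns ({q})"
            )
        if np.linalg.matrix_rank(self.X) < q:
            check_full_rank(
                pd.DataFrame(self.X[:, 1:], columns=self.columns[1:]),
                add_constant=True,
            )
        self.penalty = penalty
        self.n_coef_basis = d

    def fit(self) -> "FoSRResults":
        X, B, Y = self.X, self.B, self.Y
        n, q = X.shape
        d = B.shape[1]
        Sx = X.T @ X
        Sb = B.T @ B
        if self.penalty == "gcv":
            lam = self._gcv_penalty()
        else:
            lam = float(self.penalty)
        P = _second_difference_penalty(d)
        Sb_pen = Sb + lam * P
        # Theta solves (X'X) Theta (B'B + lam P) = X' Y B
        M = X.T @ Y @ B
        Theta = np.linalg.solve(Sx, np.linalg.solve(Sb_pen.T, M.T).T)
        fitted = X @ Theta @ B.T
        resid = Y - fitted
        # sandwich covariance of vec-by-row theta = (theta_1', ..., theta_q')'
        Sx_inv = np.linalg.inv(Sx)
        Sb_inv = np.linalg.inv(Sb_pen)
        bread = np.kron(Sx_inv, Sb_inv)  # (qd, qd)
        U = np.einsum("ij,ik->ijk", X, resid @ B)  # n x q x d
        Uf = U.reshape(n, q * d)
        meat = Uf.T @ Uf
        cov_sandwich = bread @ meat @ bread
        # model-based: resid rows iid with covariance Sigma across the grid
        dof = n - q
        Sigma_B = (resid @ B).T @ (resid @ B) / dof  # B' Sigma_hat B
        G = Sb_inv @ Sigma_B @ Sb_inv
        return FoSRResults(
            model=self,
            Theta=Theta,
            residuals=resid,
            cov_sandwich=cov_sandwich,
            G_model=G,
            Sx_inv=Sx_inv,
            penalty_used=lam,
        )

    def _gcv_penalty(self) -> float:
        """Second-difference penalty by generalized cross-validation."""
        X, B, Y = self.X, self.B, self.Y
        n, q = X.shape
        d = B.shape[1]
        P = _second_difference_penalty(d)
        Sb = B.T @ B
        Hx_tr = q  # trace of X(X'X)^-1X'
        best = (np.inf, 0.0)
        for lam in np.logspace(-2, 6, 17):
            Ab = np.linalg.solve(Sb + lam * P, Sb)
            tr = Hx_tr * np.trace(Ab)
            M = X.T @ Y @ B
            Theta = np.linalg.solve(
                X.T @ X, np.linalg.solve((Sb + lam * P).T, M.T).T
            )
            rss = float(((Y - X @ Theta @ B.T) ** 2).sum())
            N = Y.size
            gcv = N * rss / (N - tr) ** 2
            if gcv < best[0]:
                best = (gcv, lam)
        return best[1]


def _second_difference_penalty(d: int) -> np.ndarray:
    D = np.diff(np.eye(d), n=2, axis=0)
    return D.T @ D


@dataclass
class FoSRResults:
    """Fitted FoSR: coefficient functions with pointwise and global inference."""

    model: FunctionOnScalarRegression
    Theta: np.ndarray  # (q, d) spline coefficients per covariate
    residuals: np.ndarray
    cov_sandwich: np.ndarray  # (qd, qd), row-major covariate blocks
    G_model: np.ndarray  # (d, d) model-based coefficient covariance factor
    Sx_inv: np.ndarray
    penalty_used: float = 0.0

    @property
    def columns(self) -> list[str]:
        return self.model.columns

    @property
    def grid(self) -> np.ndarray:
        return self.model.grid

    def _jindex(self, covariate: str | int) -> int:
        if isinstance(covariate, str):
            return self.columns.index(covariate)
        return int(covariate)

    def coefficient_function(self, covariate) -> np.ndarray:
        """beta_j evaluated on the grid."""
        j = self._jindex(covariate)
        return self.model.B @ self.Theta[j]

    def se_function(self, covariate, cov_type: str = "sandwich") -> np.ndarray:
        """Pointwise standard error of beta_j(t)."""
        j = self._jindex(covariate)
        B = self.model.B
        V = self._block_cov(j, cov_type)
        return np.sqrt(np.maximum(np.einsum("td,de,te->t", B, V, B), 0.0))

    def _block_cov(self, j: int, cov_type: str) -> np.ndarray:
        d = self.Theta.shape[1]
        if cov_type == "sandwich":
            return self.cov_sandwich[j * d : (j + 1) * d, j * d : (j + 1) * d]
        if cov_type == "model":
            return self.Sx_inv[j, j] * self.G_model
        raise InvalidConfigError(f"unknown cov_type {cov_type!r}")

    def pointwise_bands(
        self, covariate, level: float = 0.95, cov_type: str = "sandwich"
    ) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise (lo, hi) confidence band for beta_j(t)."""
        if not 0.0 < level < 1.0:
            raise InvalidConfigError(f"level must be in (0, 1), got {level}")
        z = stats.norm.ppf(0.5 + level / 2.0)
        beta = self.coefficient_function(covariate)
        se = self.se_function(covariate, cov_type)
        return beta - z * se, beta + z * se

    def global_test(
        self, covariate, method: str = "f"
    ) -> tuple[float, float]:
        """Wald test that beta_j(t) == 0 everywhere.

        ``method='f'`` (default) uses the model-based covariance with a
        Hotelling-style F(d, n-q-d+1) reference, exact under Gaussian
        errors; ``method='sandwich'`` is the robust Wald chi-square(d).
        Returns (statistic, p-value).
        """
        j = self._jindex(covariate)
        theta = self.Theta[j]
        d = theta.size
        n, q = self.model.X.shape
        if method == "sandwich":
            V = self._block_cov(j, "sandwich")
            stat = float(theta @ np.linalg.solve(V, theta))
            return stat, float(stats.chi2.sf(stat, d))
        if method != "f":
            raise InvalidConfigError(f"unknown method {method!r}")
        V = self._block_cov(j, "model")
        t2 = float(theta @ np.linalg.solve(V, theta))
        m = n - q
        if m - d + 1 <= 0:
            raise DegenerateInputError(
                "too few subjects for the F-calibrated global test"
            )
        f = t2 * (m - d + 1) / (m * d)
        return f, float(stats.f.sf(f, d, m - d + 1))

    def global_tests(self, method: str = "f") -> pd.DataFrame:
        """Global test for every non-intercept covariate."""
        rows = []
        for name in self.columns[1:]:
            stat, p = self.global_test(name, method=method)
            rows.append(
                {
                    "covariate": name,
                    "statistic": stat,
                    "df": self.Theta.shape[1],
                    "p": p,
                    "method": method,
                }
            )
        return pd.DataFrame(rows)

    def bootstrap_global_tests(
        self, n_boot: int = 500, seed: int = 0
    ) -> pd.DataFrame:
        """Subject-resampling bootstrap alternative to the Wald tests.

        The p-value is the fraction of bootstrap resamples (refit under
        subject resampling, centered at the estimate) whose block Wald
        statistic exceeds the observed one.
        """
        rng = np.random.default_rng(seed)
        X, Y, B = self.model.X, self.model.Y, self.model.B
        n, q = X.shape
        d = self.Theta.shape[1]
        Sb = B.T @ B
        obs = np.empty(q - 1)
        V_blocks = []
        for j in range(1, q):
            V = self._block_cov(j, "sandwich")
            V_blocks.append(V)
            obs[j - 1] = self.Theta[j] @ np.linalg.solve(V, self.Theta[j])
        exceed = np.zeros(q - 1)
        for _ in range(n_boot):
            take = rng.integers(0, n, size=n)
            Xb, Yb = X[take], Y[take]
            Mb = Xb.T @ Yb @ B
            try:
                Tb = np.linalg.solve(Xb.T @ Xb, np.linalg.solve(Sb.T, Mb.T).T)
            except np.linalg.LinAlgError:
                continue
            for j in range(1, q):
                delta = Tb[j] - self.Theta[j]
                stat = delta @ np.linalg.solve(V_blocks[j - 1], delta)
                if stat >= obs[j - 1]:
                    exceed[j - 1] += 1
        return pd.DataFrame(
            {
                "covariate": self.columns[1:],
                "statistic": obs,
                "df": d,
                "p": (exceed + 1) / (n_boot + 1),
                "method": "bootstrap",
            }
        )

    def fitted_values(self) -> np.ndarray:
        return self.model.X @ self.Theta @ self.model.B.T

    def coefficient_table(self, level: float = 0.95) -> pd.DataFrame:
        """Long table: grid, covariate, beta, se, lo, hi."""
        frames = []
        for name in self.columns:
            beta = self.coefficient_function(name)
            se = self.se_function(name)
            lo, hi = self.pointwise_bands(name, level)
            frames.append(
                pd.DataFrame(
                    {
                        "minute": self.grid,
                        "covariate": name,
                        "beta": beta,
                        "se": se,
                        "lo": lo,
                        "hi": hi,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        n, q = self.model.X.shape
        lines = [
            "Function-on-scalar regression",
            f"  subjects: {n}  covariates: {q - 1}  "
            f"grid: {self.grid.size} bins  coefficient basis: "
            f"{self.Theta.shape[1]}",
        ]
        gt = self.global_tests()
        for _, r in gt.iterrows():
            stars = "**" if r["p"] < 0.01 else ("*" if r["p"] < 0.05 else "")
            lines.append(
                f"  {r['covariate']:<22s} F={r['statistic']:8.3f}  "
                f"p={r['p']:.4f} {stars}"
            )
        return "\n".join(lines)
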