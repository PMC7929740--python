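"""Functional PCA of daily activity curves in Fourier-coefficient space.

Each valid subject-day curve is pre-smoothed by least-squares projection
onto an orthonormal 9-function Fourier basis; fPCA is then the ordinary
eigendecomposition of the covariance of those coefficient vectors. Because
the basis is orthonormal on the minute grid, this is numerically identical
to PCA of the 1440-point discretized smooth curves — the discretized route
is kept as a test oracle only.

The day-level scores (coordinates of each curve on the eigenfunctions) are
the outcome variables of the downstream association models; they are
standardized by their pooled SD across all subject-days so regression
coefficients read as per-SD effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import FourierBasis
from .errors import DegenerateInputError, InvalidConfigError
from .preprocess import DayCurveSet


def select_num_components(
    variance_proportions, threshold: float = 0.75
) -> int:
    """Smallest K whose cumulative variance proportion reaches ``threshold``.

    ``variance_proportions`` must be sorted descending and sum to at most 1
    (within 1e-9).
    """
    if not 0.0 < threshold <= 1.0:
        raise InvalidConfigError(
            f"variance threshold must be in (0, 1], got {threshold}"
        )
    p = np.asarray(variance_proportions, float)
    if np.any(np.diff(p) > 1e-12):
        raise ValueError("variance proportions must be sorted descending")
    if p.sum() > 1.0 + 1e-9:
        raise ValueError("variance proportions must sum to at most 1")
    cum = np.cumsum(p)
    reached = np.nonzero(cum >= threshold - 1e-12)[0]
    if reached.size == 0:
        return p.size
    return int(reached[0]) + 1


class DailyFPCA:
    """Functional PCA model for a pooled set of daily activity curves.

    Parameters
    ----------
    curves : DayCurveSet or ndarray
        Imputed day curves. A :class:`DayCurveSet` contributes its valid
        days only; a plain ``(n, 1440)`` array is used as-is.
    basis : FourierBasis, optional
        Pre-smoothing basis (default: 9 Fourier functions on 1440 minutes).
    """

    def __init__(self, curves, basis: FourierBasis | None = None):
        self.basis = basis if basis is not None else FourierBasis()
        if isinstance(curves, DayCurveSet):
            valid = curves.meta["valid"].to_numpy(bool)
            values = curves.values[valid]
            self.meta = curves.meta.loc[valid, ["subject_id", "date"]].reset_index(
                drop=True
            )
        else:
            values = np.asarray(curves, float)
            self.meta = None
        self.coefficients = self.basis.project(values)

    @classmethod
    def from_coefficients(
        cls, coefficients, basis: FourierBasis | None = None, meta=None
    ) -> "DailyFPCA":
        obj = cls.__new__(cls)
        obj.basis = basis if basis is not None else FourierBasis()
        obj.coefficients = np.atleast_2d(np.asarray(coefficients, float))
        obj.meta = meta
        return obj

    def fit(self, variance_threshold: float = 0.75) -> "DailyFPCAResults":
        """Eigendecompose the coefficient covariance; retain components by
        the cumulative-variance rule."""
        C = self.coefficients
        if C.shape[0] < 2:
            raise DegenerateInputError(
                f"fPCA needs at least 2 day curves, got {C.shape[0]}"
            )
        mean = C.mean(axis=0)
        centered = C - mean
        cov = centered.T @ centered / (C.shape[0] - 1)
        eigval, eigvec = np.linalg.eigh(cov)
        order = np.argsort(eigval)[::-1]
        eigval = np.clip(eigval[order], 0.0, None)
        eigvec = eigvec[:, order].T  # rows are components
        # orient each eigenfunction so its largest-|.| coefficient is positive
        for row in eigvec:
            j = np.argmax(np.abs(row))
            if row[j] < 0:
                row *= -1.0
        total = eigval.sum()
        proportions = eigval / total if total > 0 else np.zeros_like(eigval)
        n_retained = select_num_components(proportions, variance_threshold)
        scores = centered @ eigvec.T
        score_sd = scores.std(axis=0, ddof=1)
        return DailyFPCAResults(
            basis=self.basis,
            mean_coefficients=mean,
            eigen_coefficients=eigvec,
            eigenvalues=eigval,
            variance_proportions=proportions,
            n_retained=n_retained,
            score_sd=score_sd,
            variance_threshold=variance_threshold,
            n_curves=C.shape[0],
            model=self,
        )


@dataclass
class DailyFPCAResults:
    """Fitted fPCA: mean function, eigenfunctions, eigenvalues, scores."""

    basis: FourierBasis
    mean_coefficients: np.ndarray
    eigen_coefficients: np.ndarray  # (n_basis, n_basis), rows descending
    eigenvalues: np.ndarray
    variance_proportions: np.ndarray
    n_retained: int
    score_sd: np.ndarray
    variance_threshold: float = 0.75
    n_curves: int = 0
    model: DailyFPCA | None = field(default=None, repr=False)

    def mean_curve(self) -> np.ndarray:
        """Mean daily activity on the minute grid."""
        return self.basis.reconstruct(self.mean_coefficients)

    def component_curve(self, k: int) -> np.ndarray:
        """Eigenfunction phi_k on the minute grid (k is 1-based)."""
        self._check_k(k)
        return self.basis.reconstruct(self.eigen_coefficients[k - 1])

    def scores(self, coefficients=None, standardized: bool = False) -> np.ndarray:
        """Component scores for curves given as basis coefficients.

        Defaults to the fitted sample. Raw scores are the coordinates of
        centered coefficients on the retained eigenfunctions; standardized
        scores divide by the pooled (fitted-sample) SD per component.
        """
        if coefficients is None:
            if self.model is None:
                raise ValueError("no fitted sample attached; pass coefficients")
            coefficients = self.model.coefficients
        C = np.atleast_2d(np.asarray(coefficients, float))
        xi = (C - self.mean_coefficients) @ self.eigen_coefficients[: self.n_retained].T
        if standardized:
            sd = self.score_sd[: self.n_retained]
            xi = xi / np.where(sd > 0, sd, 1.0)
        return xi

    def score_table(self, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
        """Long per-(subject-day, component) score table.

        Columns: subject_id, date, component (1-based), score,
        score_std; day/subject covariates are joined when provided.
        """
        if self.model is None or self.model.meta is None:
            raise ValueError("score_table needs a model fitted from a DayCurveSet")
        raw = self.scores()
        std = self.scores(standardized=True)
        K = self.n_retained
        base = self.model.meta
        frames = []
        for k in range(K):
            f = base.copy()
            f["component"] = k + 1
            f["score"] = raw[:, k]
            f["score_std"] = std[:, k]
            frames.append(f)
        table = pd.concat(frames, ignore_index=True)
        if covariates is not None:
            on = [c for c in ("subject_id", "date") if c in covariates.columns]
            table = table.merge(covariates, on=on, how="left")
        return table

    def effect_curves(self, k: int) -> dict[str, np.ndarray]:
        """Mean curve and the mean +/- 1 score-SD of component k (1-based).

        The plus/minus pair visualizes what a one-SD excursion along the
        component does to a day's activity profile.
        """
        self._check_k(k)
        mean = self.mean_curve()
        delta = self.score_sd[k - 1] * self.component_curve(k)
        return {"mean": mean, "plus": mean + delta, "minus": mean - delta}

    def _check_k(self, k: int) -> None:
        if not 1 <= k <= self.eigen_coefficients.shape[0]:
            raise IndexError(
                f"component index {k} out of range 1..{self.eigen_coefficients.shape[0]}"
            )

    def summary(self) -> str:
        lines = [
            "Functional PCA of daily activity curves",
            f"  curves: {self.n_curves}   basis: {self.basis.n_basis} Fourier functions",
            f"  retained components: {self.n_retained} "
            f"(>= {self.variance_threshold:.0%} cumulative variance)",
            "  k   eigenvalue   prop.   cum.",
        ]
        cum = 0.0
        for k in range(self.eigenvalues.size):
            cum += self.variance_proportions[k]
            mark = "*" if k < self.n_retained else " "
            lines.append(
                f" {mark}{k + 1}  {self.eigenvalues[k]:11.4g}  "
                f"{self.variance_proportions[k]:6.1%}  {cum:6.1%}"
            )
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "basis": {"n_basis": self.basis.n_basis, "period": self.basis.period},
            "mean_coefficients": self.mean_coefficients.tolist(),
            "eigen_coefficients": self.eigen_coefficients.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_proportions": self.variance_proportions.tolist(),
            "n_retained": self.n_retained,
            "score_sd": self.score_sd.tolist(),
            "variance_threshold": self.variance_threshold,
            "n_curves": self.n_curves,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "DailyFPCAResults":
        if isinstance(text_or_path, Path) or (
            isinstance(text_or_path, str) and text_or_path.lstrip()[:1] != "{"
        ):
            text = Path(text_or_path).read_text()
        else:
            text = str(text_or_path)
        d = json.loads(text)
        return cls(
            basis=FourierBasis(d["basis"]["n_basis"], d["basis"]["period"]),
            mean_coefficients=np.array(d["mean_coefficients"]),
            eigen_coefficients=np.array(d["eigen_coefficients"]),
            eigenvalues=np.array(d["eigenvalues"]),
            variance_proportions=np.array(d["variance_proportions"]),
            n_retained=d["n_retained"],
            score_sd=np.array(d["score_sd"]),
            variance_threshold=d["variance_threshold"],
            n_curves=d["n_curves"],
        )
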