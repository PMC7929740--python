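"""Orthonormal function bases on the 24-hour day.

The Fourier basis used for pre-smoothing daily activity curves is orthonormal
in L2[0, T] with T = 1440 minutes: a constant function 1/sqrt(T) followed by
sine/cosine pairs sqrt(2/T)*sin(2*pi*k*t/T), sqrt(2/T)*cos(2*pi*k*t/T) for
harmonics k = 1, 2, ... . Evaluated at minute midpoints the discrete Gram
matrix (with unit minute spacing) is the identity to machine precision, so
least-squares projection coincides with inner products against the basis.

A cubic B-spline basis over the same day is provided for the coefficient
functions of function-on-scalar regression.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

from .errors import InvalidConfigError

MINUTES_PER_DAY = 1440


class FourierBasis:
    """Orthonormal Fourier basis of odd size on a fixed period.

    Parameters
    ----------
    n_basis : int
        Number of basis functions; must be odd (constant plus whole
        sine/cosine pairs). Default 9 = constant + 4 harmonics.
    period : float
        Length of the day in minutes, default 1440.
    """

    def __init__(self, n_basis: int = 9, period: float = float(MINUTES_PER_DAY)):
        if n_basis < 1 or n_basis % 2 == 0:
            raise InvalidConfigError(
                f"n_basis must be a positive odd integer, got {n_basis}"
            )
        if period <= 0:
            raise InvalidConfigError(f"period must be positive, got {period}")
        self.n_basis = int(n_basis)
        self.period = float(period)
        self._grid_design: np.ndarray | None = None

    @property
    def n_harmonics(self) -> int:
        return (self.n_basis - 1) // 2

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions at times ``t`` (minutes).

        Returns an array of shape ``(len(t), n_basis)`` ordered as
        [const, sin1, cos1, sin2, cos2, ...].
        """
        t = np.asarray(t, dtype=float)
        T = self.period
        out = np.empty((t.size, self.n_basis))
        out[:, 0] = 1.0 / np.sqrt(T)
        amp = np.sqrt(2.0 / T)
        for k in range(1, self.n_harmonics + 1):
            w = 2.0 * np.pi * k * t / T
            out[:, 2 * k - 1] = amp * np.sin(w)
            out[:, 2 * k] = amp * np.cos(w)
        return out

    def minute_grid(self) -> np.ndarray:
        """Minute-midpoint evaluation grid: 0.5, 1.5, ..., period-0.5."""
        n = int(round(self.period))
        return np.arange(n) + 0.5

    def design(self) -> np.ndarray:
        """Basis evaluated on the minute grid, cached. Shape (1440, n_basis)."""
        if self._grid_design is None:
            self._grid_design = self.evaluate(self.minute_grid())
        return self._grid_design

    def gram(self) -> np.ndarray:
        """Discrete Gram matrix on the minute grid (unit spacing)."""
        B = self.design()
        return B.T @ B

    def project(self, values: np.ndarray) -> np.ndarray:
        """Least-squares projection of curves onto the basis.

        ``values`` has shape (..., 1440) with no missing entries; returns
        coefficients of shape (..., n_basis).
        """
        values = np.asarray(values, dtype=float)
        if values.shape[-1] != int(round(self.period)):
            raise ValueError(
                f"curves must have {int(round(self.period))} values, "
                f"got {values.shape[-1]}"
            )
        if np.isnan(values).any():
            raise ValueError("curves contain missing values; impute first")
        B = self.design()
        # Gram is the identity to ~1e-12 here, but solve the normal
        # equations anyway so the result is an exact least-squares fit.
        rhs = values @ B
        if rhs.ndim == 1:
            return np.linalg.solve(self.gram(), rhs)
        return np.linalg.solve(self.gram(), rhs.T).T

    def reconstruct(self, coefficients: np.ndarray) -> np.ndarray:
        """Evaluate curves with the given coefficients on the minute grid."""
        coefficients = np.asarray(coefficients, dtype=float)
        return coefficients @ self.design().T


def bspline_basis(
    n_basis: int = 10,
    period: float = float(MINUTES_PER_DAY),
    grid: np.ndarray | None = None,
    degree: int = 3,
) -> np.ndarray:
    """Cubic B-spline design matrix on a grid over one day.

    Knots are equally spaced on [0, period] with full multiplicity at the
    boundary, giving exactly ``n_basis`` basis functions.
    """
    if n_basis < degree + 1:
        raise InvalidConfigError(
            f"n_basis must be at least degree+1={degree + 1}, got {n_basis}"
        )
    if grid is None:
        grid = np.linspace(0, period, 145)[:-1] + period / 288.0
    interior = np.linspace(0, period, n_basis - degree + 1)[1:-1]
    knots = np.concatenate(
        [np.repeat(0.0, degree + 1), interior, np.repeat(period, degree + 1)]
    )
    return BSpline.design_matrix(np.asarray(grid, float), knots, degree).toarray()
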