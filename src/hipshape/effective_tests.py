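"""Effective number of independent variables among correlated mode scores.

When shapes are scored against an external reference model, modes that
were orthogonal in the reference population can become correlated in the
new one.  The spectral-decomposition estimators quantify how much
independence is lost: eigen-decompose the score correlation matrix and
summarise the spread of its eigenvalues.

Two standard estimators are provided:

* Nyholt's ``Veff = 1 + (M - 1) * (1 - Var(lambda) / M)``, where
  ``Var(lambda)`` is the *sample* variance of the eigenvalues
  (divisor M − 1);
* the Li–Ji ``Meff = sum_i [ 1(lambda_i >= 1) + frac(lambda_i) ]``.

Values are kept at full precision; reporting conventionally rounds to
one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EffectiveTestsResult",
    "correlation_matrix",
    "nyholt_veff",
    "liji_meff",
]


@dataclass(frozen=True)
class EffectiveTestsResult:
    """Spectral summary of a score correlation matrix."""

    M: int
    eigenvalues: np.ndarray        # descending, sum to M
    var_lambda: float              # sample variance, divisor M - 1
    veff_nyholt: float
    meff_liji: float
    loss_fraction: float           # (M - Veff) / M

    @property
    def veff_rounded(self) -> float:
        """Veff at the conventional 1-decimal reporting precision."""
        return round(self.veff_nyholt, 1)

    def summary(self) -> str:
        return (f"M = {self.M} variables; Veff (Nyholt) = "
                f"{self.veff_nyholt:.4f} (~{self.veff_rounded}); "
                f"Meff (Li-Ji) = {self.meff_liji:.1f}; "
                f"loss of independence = {100 * self.loss_fraction:.1f}%")


def correlation_matrix(scores) -> pd.DataFrame:
    """Pearson correlation matrix of a scores table.

    ``scores`` is an ``(n, M)`` array or DataFrame (observations in rows).
    Requires n >= 3, M >= 2 and non-constant columns; a constant column is
    reported by name.
    """
    df = pd.DataFrame(scores)
    n, M = df.shape
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if M < 2:
        raise ValueError(f"need at least 2 variables, got {M}")
    sds = df.std(ddof=1)
    dead = sds[sds == 0].index.tolist()
    if dead:
        raise ValueError(f"constant column(s): {dead}")
    R = np.corrcoef(df.to_numpy(), rowvar=False)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=df.columns, columns=df.columns)


def _validated(R) -> np.ndarray:
    A = np.asarray(R, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(A), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    return A


def nyholt_veff(R) -> EffectiveTestsResult:
    """Nyholt's effective number of independent variables.

    Eigen-decomposes the correlation matrix and applies
    ``Veff = 1 + (M - 1) * (1 - Var(lambda) / M)`` with the eigenvalue
    variance taken with divisor M − 1.  For an identity matrix
    ``Veff = M`` (no loss); as correlations grow, eigenvalue spread grows
    and ``Veff`` shrinks toward 1.
    """
    A = _validated(R)
    M = A.shape[0]
    lam = np.linalg.eigvalsh(A)[::-1]
    var_lambda = float(lam.var(ddof=1))
    veff = 1.0 + (M - 1) * (1.0 - var_lambda / M)
    return EffectiveTestsResult(
        M=M,
        eigenvalues=lam,
        var_lambda=var_lambda,
        veff_nyholt=float(veff),
        meff_liji=liji_meff(A),
        loss_fraction=float((M - veff) / M),
    )


def liji_meff(R) -> float:
    """Li–Ji effective number of independent variables.

    Eigenvalues are rounded to 12 decimals before the floor: the Li–Ji
    contribution function is discontinuous at integers, and an eigenvalue
    that is an exact integer in exact arithmetic (e.g. M for an all-ones
    matrix) must not pick up a spurious unit from rounding error.
    """
    lam = np.round(np.linalg.eigvalsh(_validated(R)), 12)
    lam = np.clip(lam, 0.0, None)
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
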