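"""Per-biomarker z-score standardization with frozen parameters.

Biomarker ranges differ by orders of magnitude (platelets in the hundreds of
10^3/uL, the CD64 index near unity), so every matrix entering subset
selection or classification is standardized column-wise to zero mean and
unit SD.  The fitted means/SDs are kept with the model so a linear decision
function can be applied to raw-unit inputs later.

By default standardization is fitted once on the full dataset before any
learning/test split (the convention of computing the mean "over all cases");
a leakage-safe variant fitted on the learning set only is available where
splits are made (see ``classifiers.repeated_evaluation``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import BIOMARKERS


@dataclass
class StandardizedMatrix:
    """Standardized matrix plus the column means/SDs that produced it."""

    Xtilde: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    names: tuple[str, ...]
    fitted_on: str = "all"

    @property
    def n(self) -> int:
        return self.Xtilde.shape[0]

    @property
    def p(self) -> int:
        return self.Xtilde.shape[1]


def standardize(X: np.ndarray, names: Sequence[str] | None = None,
                fitted_on: str = "all") -> StandardizedMatrix:
    """Column-wise z-score with the sample (n−1) SD.

    Raises if any column has zero variance, naming the offending biomarker.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 rows")
    if np.isnan(X).any():
        raise ValueError("X must not contain missing values")
    if names is None:
        names = BIOMARKERS if X.shape[1] == len(BIOMARKERS) else tuple(
            f"x{j}" for j in range(X.shape[1]))
    names = tuple(names)
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    zero = np.nonzero(sigma == 0)[0]
    if zero.size:
        raise ValueError(
            "zero-variance biomarker(s): " + ", ".join(names[j] for j in zero))
    return StandardizedMatrix(
        Xtilde=(X - mu) / sigma, mu=mu, sigma=sigma,
        names=names, fitted_on=fitted_on,
    )


def apply_standardization(X_new: np.ndarray, mu: np.ndarray,
                          sigma: np.ndarray) -> np.ndarray:
    """Apply a frozen affine standardization to new raw-unit samples."""
    X_new = np.asarray(X_new, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != mu.shape[0] or mu.shape != sigma.shape:
        raise ValueError(
            f"dimension mismatch: X has {X_new.shape[1]} columns, "
            f"mu/sigma have {mu.shape[0]}/{sigma.shape[0]}")
    return (X_new - mu) / sigma
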