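"""Redundancy analysis (RDA): constrained ordination of a multivariate
response on an explanatory design.

The algorithm is the classical one: standardize the responses, regress each
response column on the (centered, dummy-coded) explanatory design by least
squares, and eigendecompose the covariance of the fitted values.  The
constrained eigenvalues partition the variance explained by the design;
site scores are projections of the fitted values, species scores are the
(scaled) response loadings, and biplot scores are correlations of the
explanatory variables with the site scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["RDAResult", "rda_fit", "biplot_alignment"]


@dataclass(frozen=True)
class RDAResult:
    eigenvalues: np.ndarray           # constrained axis variances, descending
    site_scores: pd.DataFrame         # samples x axes
    species_scores: pd.DataFrame      # responses x axes
    biplot_scores: pd.DataFrame       # explanatory variables x axes
    constrained_proportion: float
    total_variance: float
    dropped_columns: tuple[str, ...] = ()

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def _design_matrix(explanatory: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code categorical columns; pass numeric (incl. ordinal) through."""
    parts = []
    for col in explanatory.columns:
        s = explanatory[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedily drop columns that are linear combinations of earlier ones."""
    kept_idx: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, kept_idx + [j]]
        if np.linalg.matrix_rank(trial) > len(kept_idx):
            kept_idx.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        warnings.warn(f"rank-deficient design: dropped aliased columns {dropped}", stacklevel=3)
    return X[:, kept_idx], [names[j] for j in kept_idx], dropped


def rda_fit(
    responses: pd.DataFrame | np.ndarray,
    explanatory: pd.DataFrame | np.ndarray,
    scale: str = "correlation",
) -> RDAResult:
    """Fit a redundancy analysis.

    Parameters
    ----------
    responses
        Samples x response-variables matrix.
    explanatory
        Samples x covariates design; categorical columns are dummy-coded,
        numeric (including ordinal frequency codes) used as-is.
    scale
        ``"correlation"`` standardizes responses to unit variance (default);
        ``"covariance"`` only centers them.

    Returns
    -------
    RDAResult with eigenvalues (descending), site/species/biplot scores and
    the constrained proportion of total response variance.
    """
    if scale not in ("correlation", "covariance"):
        raise DomainError(f"scale must be 'correlation' or 'covariance', got {scale!r}")

    Y_df = pd.DataFrame(responses).copy()
    X_df = _design_matrix(pd.DataFrame(explanatory))
    if len(Y_df) != len(X_df):
        raise DomainError("responses and explanatory must have the same row count")
    n = len(Y_df)
    if n < 3:
        raise DomainError("redundancy analysis needs at least 3 samples")
    if n < X_df.shape[1] + 2:
        # a (near-)saturated design constrains nothing: the fit reduces to PCA
        warnings.warn(
            f"design has {X_df.shape[1]} columns for {n} samples; "
            "constraints are saturated or nearly so",
            stacklevel=2,
        )

    Y = Y_df.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0)
    if scale == "correlation":
        sd = Y.std(axis=0, ddof=1)
        if np.any(sd == 0):
            zero = [str(c) for c, s in zip(Y_df.columns, sd) if s == 0]
            raise DomainError(f"constant response columns cannot be standardized: {zero}")
        Y = Y / sd

    X = X_df.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    X, kept_names, dropped = _drop_aliased(X, [str(c) for c in X_df.columns])

    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    Yhat = X @ B

    S = (Yhat.T @ Yhat) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(S)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    rank_x = np.linalg.matrix_rank(X) if X.size else 0
    k = int(min(rank_x, Y.shape[1]))
    eigvals = eigvals[:k]
    V = eigvecs[:, :k]

    axes = [f"RDA{i + 1}" for i in range(k)]
    site = Yhat @ V
    # scaling 2 (correlation biplot): species loadings scaled by sqrt(eigenvalue)
    species = V * np.sqrt(eigvals)

    biplot = np.zeros((X.shape[1], k))
    for j in range(X.shape[1]):
        xj = X[:, j]
        sx = xj.std(ddof=1)
        for a in range(k):
            sa = site[:, a].std(ddof=1)
            if sx > 0 and sa > 0:
                biplot[j, a] = float(np.corrcoef(xj, site[:, a])[0, 1])

    total_var = float(np.trace((Y.T @ Y) / (n - 1)))
    constrained = float(eigvals.sum())
    proportion = constrained / total_var if total_var > 0 else 0.0

    return RDAResult(
        eigenvalues=eigvals,
        site_scores=pd.DataFrame(site, index=Y_df.index, columns=axes),
        species_scores=pd.DataFrame(species, index=Y_df.columns, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=kept_names, columns=axes),
        constrained_proportion=proportion,
        total_variance=total_var,
        dropped_columns=tuple(dropped),
    )


def biplot_alignment(result: RDAResult, covariate: str, response) -> float:
    """Signed alignment between a covariate arrow and a response arrow.

    The inner product of the covariate's biplot scores and the response's
    species scores across constrained axes; its sign indicates the direction
    of association implied by the ordination.
    """
    b = result.biplot_scores.loc[covariate].to_numpy()
    s = result.species_scores.loc[response].to_numpy()
    return float(np.dot(b, s))
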