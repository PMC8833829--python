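"""Scanner-batch effect detection and removal for radiomics feature tables.

A feature table is a DataFrame with one row per patient, a batch column
(default ``"scanner"``) and numeric feature columns; non-numeric columns other
than the batch label (e.g. ``patient_id``) pass through untouched. Three
harmonizers are provided — within-batch standardization re-anchored to pooled
moments, remove-batch-effect (subtracting least-squares batch offsets) and
parametric empirical-Bayes ComBat — plus guided PCA (gPCA) as the diagnostic:
delta compares the variance of the data projected on the batch-guided
direction with the first unguided principal-component variance, and a label
permutation gives its p-value. delta near 0 with p near 1 means no detectable
batch effect, i.e. no need to harmonize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import ValidationError

__all__ = [
    "GpcaResult",
    "feature_columns",
    "standardize",
    "remove_batch_effect",
    "combat",
    "gpca_delta",
]


@dataclass(frozen=True)
class GpcaResult:
    """Guided-PCA batch-effect diagnostic."""

    delta: float
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0 + 1e-12:
            raise ValidationError(f"delta out of [0, 1]: {self.delta}")
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError(f"p-value out of (0, 1]: {self.p_value}")


def feature_columns(table: pd.DataFrame, batch_col: str = "scanner") -> list[str]:
    """Numeric feature columns of a table (everything numeric except the batch)."""
    cols = [
        c
        for c in table.columns
        if c != batch_col and pd.api.types.is_numeric_dtype(table[c])
    ]
    if not cols:
        raise ValidationError("table has no numeric feature columns")
    return cols


def _check_table(table: pd.DataFrame, batch_col: str, min_per_batch: int = 1) -> list[str]:
    if batch_col not in table.columns:
        raise ValidationError(f"table lacks batch column {batch_col!r}")
    cols = feature_columns(table, batch_col)
    if table[cols].isna().any().any():
        raise ValidationError("feature table contains missing values; imputation is not supported")
    sizes = table.groupby(batch_col, sort=False).size()
    if (sizes < min_per_batch).any():
        bad = sizes[sizes < min_per_batch].index.tolist()
        raise ValidationError(f"batches {bad} have fewer than {min_per_batch} rows")
    return cols


def standardize(table: pd.DataFrame, batch_col: str = "scanner") -> pd.DataFrame:
    """Within-batch z-score, re-anchored to the pooled mean and SD per feature.

    Features constant within some batch cannot be rescaled there; they are
    flagged with a warning and only re-centered.
    """
    cols = _check_table(table, batch_col, min_per_batch=2)
    out = table.copy()
    X = out[cols].to_numpy(dtype=float)
    batches = out[batch_col].to_numpy()
    pooled_mean = X.mean(axis=0)
    pooled_sd = X.std(axis=0, ddof=1)
    flagged: set[str] = set()
    for b in pd.unique(batches):
        rows = batches == b
        mu = X[rows].mean(axis=0)
        sd = X[rows].std(axis=0, ddof=1)
        degenerate = sd == 0
        if degenerate.any():
            flagged.update(np.asarray(cols)[degenerate].tolist())
        scale = np.where(degenerate, 1.0, pooled_sd / np.where(degenerate, 1.0, sd))
        X[rows] = (X[rows] - mu) * scale + pooled_mean
    if flagged:
        warnings.warn(
            f"features constant within a batch, centered only: {sorted(flagged)}",
            stacklevel=2,
        )
    out[cols] = X
    return out


def remove_batch_effect(table: pd.DataFrame, batch_col: str = "scanner") -> pd.DataFrame:
    """Subtract least-squares batch mean offsets (reference-coded).

    The reference batch is the first to appear in row order; its per-feature
    means are preserved, other batches are shifted onto them. Idempotent.
    """
    cols = _check_table(table, batch_col)
    out = table.copy()
    X = out[cols].to_numpy(dtype=float)
    batches = out[batch_col].to_numpy()
    order = pd.unique(batches)
    ref_mean = X[batches == order[0]].mean(axis=0)
    for b in order[1:]:
        rows = batches == b
        X[rows] -= X[rows].mean(axis=0) - ref_mean
    out[cols] = X
    return out


def combat(
    table: pd.DataFrame,
    batch_col: str = "scanner",
    parametric: bool = True,
    return_estimates: bool = False,
):
    """Parametric empirical-Bayes ComBat location/scale batch adjustment.

    Features are standardized against the batch-mean model, per-batch location
    (gamma) and scale (delta^2) estimates are shrunk toward normal /
    inverse-gamma moment-matched priors with direct (non-iterative) conditional
    posterior means, and the adjusted data are transformed back to the pooled
    scale. Moments use the n (ddof=0) denominator so that identical batches
    pass through unchanged. Requires at least two rows per batch.
    """
    if not parametric:
        raise ValidationError("only parametric ComBat is implemented")
    cols = _check_table(table, batch_col, min_per_batch=2)
    out = table.copy()
    X = out[cols].to_numpy(dtype=float)
    batches = out[batch_col].to_numpy()
    levels = pd.unique(batches)
    n_total, p = X.shape

    batch_rows = {b: np.flatnonzero(batches == b) for b in levels}
    n_b = {b: len(r) for b, r in batch_rows.items()}

    # Standardize: grand mean = size-weighted batch means; pooled variance from
    # residuals about batch means.
    batch_means = np.vstack([X[r].mean(axis=0) for r in batch_rows.values()])
    weights = np.array([n_b[b] / n_total for b in levels])
    alpha = weights @ batch_means
    resid = X.copy()
    for i, b in enumerate(levels):
        resid[batch_rows[b]] -= batch_means[i]
    sigma2 = (resid**2).mean(axis=0)
    if np.any(sigma2 <= 0):
        raise ValidationError("a feature is constant across the table; cannot ComBat-adjust")
    sigma = np.sqrt(sigma2)
    Z = (X - alpha) / sigma

    X_adj = np.empty_like(X)
    estimates: dict[str, dict] = {}
    for b in levels:
        rows = batch_rows[b]
        nb = n_b[b]
        gamma_hat = Z[rows].mean(axis=0)
        delta2_hat = Z[rows].var(axis=0, ddof=0)

        # Normal prior on gamma, moment-matched across features.
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=0)
        denom = nb * tau2 + delta2_hat
        gamma_star = np.where(denom > 0, (nb * tau2 * gamma_hat + delta2_hat * gamma_bar) / np.where(denom > 0, denom, 1.0), gamma_bar)

        # Inverse-gamma prior on delta^2, moment-matched across features.
        m = delta2_hat.mean()
        s2 = delta2_hat.var(ddof=0)
        if s2 > 1e-12 * max(m**2, 1e-300):
            a_prior = (2 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
            ss = ((Z[rows] - gamma_star) ** 2).sum(axis=0)
            delta2_star = (b_prior + 0.5 * ss) / (nb / 2 + a_prior - 1)
        else:
            # Degenerate prior (all features share one scale): no shrinkage.
            delta2_star = delta2_hat
        X_adj[rows] = sigma * (Z[rows] - gamma_star) / np.sqrt(delta2_star) + alpha
        estimates[str(b)] = {
            "gamma_hat": gamma_hat,
            "gamma_bar": float(gamma_bar),
            "gamma_star": gamma_star,
            "delta2_hat": delta2_hat,
            "delta2_star": delta2_star,
        }

    out[cols] = X_adj
    if return_estimates:
        return out, estimates
    return out


def _guided_variance(Xc: np.ndarray, batches: np.ndarray, levels: np.ndarray) -> float:
    """Variance of the data projected on the first right singular vector of Y'X."""
    Y = (batches[:, None] == levels[None, :]).astype(float)
    M = Y.T @ Xc
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    scores = Xc @ vt[0]
    return float(scores @ scores)


def gpca_delta(
    table: pd.DataFrame,
    batch_col: str = "scanner",
    n_permutations: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> GpcaResult:
    """Guided PCA batch-effect statistic with a permutation p-value.

    delta = var(X v_guided) / var(first PC of X), where v_guided is the first
    right singular vector of Y'X (Y the one-hot batch matrix, X centered per
    feature). p = (1 + #{permuted delta >= observed}) / (1 + n_permutations)
    under random batch-label permutations.
    """
    cols = _check_table(table, batch_col)
    batches = table[batch_col].to_numpy()
    levels = pd.unique(batches)
    if len(levels) < 2:
        raise ValidationError("gPCA needs at least two batches")
    X = table[cols].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)

    s = np.linalg.svd(Xc, compute_uv=False)
    unguided = float(s[0] ** 2)
    if unguided == 0:
        raise ValidationError("data matrix has no variance")
    observed = _guided_variance(Xc, batches, levels) / unguided

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(batches)
        delta_perm = _guided_variance(Xc, perm, levels) / unguided
        if delta_perm >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return GpcaResult(delta=min(observed, 1.0), p_value=p, n_permutations=n_permutations)
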