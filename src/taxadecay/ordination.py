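"""Ordination: PCA, correspondence analysis, and detrended CA.

PCA summarises correlated environmental / functional variables into a few
orthogonal axes; variables on different units are standardised to unit
variance by default, and strictly positive skewed variables may be
log-transformed first (``ln(x + 1)`` when zeros are present).

Correspondence analysis (CA) ordinates a nonnegative contingency-like table
(samples × OTUs or gene categories) by singular value decomposition of the
chi-square standardised residuals; eigenvalues are squared singular values
and sum to the table's total inertia.

CA of a single strong gradient shows the *arch effect*: axis-2 scores are an
artifactual quadratic function of axis 1.  Detrended correspondence analysis
(DCA) removes it by Hill's detrending-by-segments: while extracting each
axis after the first, the trial scores are repeatedly flattened within
equal-count segments of every previously extracted axis, so the new axis
carries no systematic (including curvilinear) trend along the old ones.
Nonlinear axis rescaling (the second half of classic DECORANA) is not
applied: the analyses here use only the score configurations, which
rescaling does not alter structurally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OrdinationResult",
    "pca",
    "correspondence_analysis",
    "dca",
    "log_transform_table",
]


@dataclass
class OrdinationResult:
    """Scores, eigenvalues and explained-variance fractions of an ordination."""

    method: str  # "pca" | "ca" | "dca"
    sample_scores: pd.DataFrame
    variable_scores: pd.DataFrame
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    n_axes: int
    notes: list[str] = field(default_factory=list)


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return pd.DataFrame(np.asarray(table, dtype=float))


def log_transform_table(df: pd.DataFrame) -> pd.DataFrame:
    """Natural-log transform; ``ln(x + 1)`` when any zeros are present.

    Negative values are rejected — a log transform is meaningless for them.
    """
    x = df.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("log transform requires nonnegative values")
    if (x == 0).any():
        return pd.DataFrame(np.log1p(x), index=df.index, columns=df.columns)
    return pd.DataFrame(np.log(x), index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(
    table,
    log_transform: bool = False,
    standardize: bool = True,
    n_axes: int | None = None,
) -> OrdinationResult:
    """Principal component analysis of a samples × variables table.

    The (optionally log-transformed) matrix is centred, optionally scaled to
    unit variance, and decomposed by singular values.  Eigenvalues are the
    variances along each component (``s_k² / (n - 1)``), and
    ``variance_fraction`` their share of the total, summing to 1 over all
    axes.  ``variable_scores`` holds the unit-norm loadings.
    """
    df = _as_frame(table)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    if log_transform:
        df = log_transform_table(df)
    X = df.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        zero = np.where(sd == 0)[0]
        if zero.size:
            raise ValueError(
                f"constant column {df.columns[zero[0]]!r} cannot be standardized"
            )
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    n = X.shape[0]
    eigenvalues = s**2 / (n - 1)
    total = eigenvalues.sum()
    fractions = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    k = len(s) if n_axes is None else min(n_axes, len(s))
    axes = [f"PC{j + 1}" for j in range(k)]
    scores = pd.DataFrame((U * s)[:, :k], index=df.index, columns=axes)
    loadings = pd.DataFrame(Vt[:k].T, index=df.columns, columns=axes)
    return OrdinationResult(
        method="pca",
        sample_scores=scores,
        variable_scores=loadings,
        eigenvalues=eigenvalues[:k],
        variance_fraction=fractions[:k],
        n_axes=k,
    )


# ---------------------------------------------------------------------------
# Correspondence analysis
# ---------------------------------------------------------------------------

def _ca_residuals(df: pd.DataFrame):
    """Chi-square standardised residual matrix plus the margins."""
    N = df.to_numpy(dtype=float)
    if (N < 0).any():
        raise ValueError("correspondence analysis requires nonnegative entries")
    total = N.sum()
    if total <= 0:
        raise ValueError("table grand total must be positive")
    zero_rows = np.where(N.sum(axis=1) == 0)[0]
    if zero_rows.size:
        raise ValueError(f"all-zero row {df.index[zero_rows[0]]!r}")
    zero_cols = np.where(N.sum(axis=0) == 0)[0]
    if zero_cols.size:
        raise ValueError(f"all-zero column {df.columns[zero_cols[0]]!r}")
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return S, r, c


def correspondence_analysis(table, n_axes: int | None = None) -> OrdinationResult:
    """CA of a nonnegative table; eigenvalues are squared singular values.

    Sample (row) scores are in principal coordinates; their
    per-axis weighted variance equals the axis eigenvalue.
    """
    df = _as_frame(table)
    S, r, c = _ca_residuals(df)
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    eigenvalues = s**2
    # trim trivial/numerically-null axes
    rank = int((s > 1e-12).sum())
    k = rank if n_axes is None else min(n_axes, rank)
    axes = [f"CA{j + 1}" for j in range(k)]
    row_pc = (U / np.sqrt(r)[:, None]) * s  # principal coordinates
    col_pc = (Vt.T / np.sqrt(c)[:, None]) * s
    total = eigenvalues.sum()
    fractions = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return OrdinationResult(
        method="ca",
        sample_scores=pd.DataFrame(row_pc[:, :k], index=df.index, columns=axes),
        variable_scores=pd.DataFrame(col_pc[:, :k], index=df.columns, columns=axes),
        eigenvalues=eigenvalues[:k],
        variance_fraction=fractions[:k],
        n_axes=k,
    )


# ---------------------------------------------------------------------------
# Detrended correspondence analysis
# ---------------------------------------------------------------------------

def _detrend_by_segments(
    x: np.ndarray, order_by: np.ndarray, weights: np.ndarray, n_segments: int
) -> np.ndarray:
    """Flatten ``x`` within equal-count segments of the ``order_by`` axis.

    Samples are ranked by ``order_by`` and split into ``n_segments``
    contiguous groups of (near-)equal size; the weighted segment mean of
    ``x`` is subtracted within each group.
    """
    order = np.argsort(order_by, kind="stable")
    out = x.copy()
    for seg in np.array_split(order, min(n_segments, order.size)):
        if seg.size == 0:
            continue
        w = weights[seg]
        out[seg] -= np.average(x[seg], weights=w)
    return out


def dca(
    table,
    n_segments: int = 26,
    n_axes: int = 4,
    tol: float = 1e-10,
    max_iter: int = 30,
) -> OrdinationResult:
    """Detrended correspondence analysis by Hill's method of segments.

    Axis 1 is the plain CA axis 1.  Each later axis is extracted by
    reciprocal averaging in which every iteration first detrends the trial
    scores against all previously extracted axes (segment-mean removal, see
    :func:`_detrend_by_segments`) before the averaging step; iteration stops
    at score convergence (``tol``) or ``max_iter``.  Axis rescaling is not
    applied.  Axes that cannot be extracted (rank exhausted) are flagged in
    ``notes`` and reported with eigenvalue 0.
    """
    if n_segments < 2:
        raise ValueError(f"n_segments must be >= 2, got {n_segments}")
    df = _as_frame(table)
    S, r, c = _ca_residuals(df)
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    rank = int((s > 1e-12).sum())
    n = df.shape[0]
    notes: list[str] = []

    sqrt_r = np.sqrt(r)
    axes_scores: list[np.ndarray] = []  # standard-coordinate row scores
    eigenvalues: list[float] = []

    def weighted_norm(x):
        return float(np.sqrt(np.sum(r * x * x)))

    # axis 1: plain CA
    if rank == 0:
        raise ValueError("table has no association structure to ordinate")
    x1 = U[:, 0] / sqrt_r  # standard coordinates, weighted variance 1
    axes_scores.append(x1)
    eigenvalues.append(float(s[0] ** 2))

    for k in range(1, n_axes):
        if k >= rank:
            notes.append(f"axis {k + 1} degenerate: table rank {rank}")
            axes_scores.append(np.zeros(n))
            eigenvalues.append(0.0)
            continue
        x = U[:, k] / sqrt_r  # CA axis k as the starting configuration
        lam = float(s[k] ** 2)
        prev = None
        for _ in range(max_iter):
            for a in axes_scores[:k]:
                if np.allclose(a, 0):
                    continue
                x = _detrend_by_segments(x, a, r, n_segments)
            # centre (weighted) and guard collapse
            x = x - np.sum(r * x)
            nrm = weighted_norm(x)
            if nrm < 1e-14:
                lam = 0.0
                notes.append(f"axis {k + 1} collapsed under detrending")
                x = np.zeros(n)
                break
            x = x / nrm
            # reciprocal averaging step through the residual operator
            u = sqrt_r * x
            u_new = S @ (S.T @ u)
            x_new = u_new / sqrt_r
            x_new = x_new - np.sum(r * x_new)
            lam = weighted_norm(x_new)
            if lam < 1e-14:
                x = np.zeros(n)
                lam = 0.0
                notes.append(f"axis {k + 1} collapsed under detrending")
                break
            x_new = x_new / lam
            if prev is not None and min(
                weighted_norm(x_new - x), weighted_norm(x_new + x)
            ) < tol:
                x = x_new
                break
            prev = x
            x = x_new
        # final detrend so the reported scores are trend-free
        for a in axes_scores[:k]:
            if not np.allclose(a, 0):
                x = _detrend_by_segments(x, a, r, n_segments)
        axes_scores.append(x)
        eigenvalues.append(lam)

    eigs = np.asarray(eigenvalues)
    total_inertia = float((s**2).sum())
    axes = [f"DCA{j + 1}" for j in range(len(axes_scores))]
    # principal-like scaling: scores carry sqrt(eigenvalue)
    score_mat = np.column_stack(
        [x * np.sqrt(e) if e > 0 else x for x, e in zip(axes_scores, eigs)]
    )
    # column scores by weighted averaging of row scores
    P = df.to_numpy(dtype=float) / df.to_numpy(dtype=float).sum()
    col_profiles = P / P.sum(axis=0, keepdims=True)
    col_scores = col_profiles.T @ score_mat
    fractions = eigs / total_inertia if total_inertia > 0 else np.zeros_like(eigs)
    return OrdinationResult(
        method="dca",
        sample_scores=pd.DataFrame(score_mat, index=df.index, columns=axes),
        variable_scores=pd.DataFrame(col_scores, index=df.columns, columns=axes),
        eigenvalues=eigs,
        variance_fraction=fractions,
        n_axes=len(axes_scores),
        notes=notes,
    )
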