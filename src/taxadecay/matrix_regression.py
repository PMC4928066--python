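"""Single and multiple regression on distance matrices (MRM).

Distance matrices cannot enter ordinary regression directly: the n(n-1)/2
pairwise entries are not independent observations.  MRM therefore fits OLS on
the vectorized lower triangles, but draws significance from a Mantel-style
permutation null — the rows *and* columns of the response matrix are permuted
jointly (preserving its internal dependence), the triangle re-vectorized and
the statistics recomputed each time.  P-values use the standard
add-one estimate

    p = (count of permuted statistic >= observed + 1) / (B + 1),

which counts the identity permutation and bounds p below by 1/(B+1).
Coefficient tests are two-sided on |coefficient| by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_tables import DistanceMatrix, SampleFrame
from .distances import scalar_difference_matrix

__all__ = [
    "MrmResult",
    "mrm",
    "single_matrix_regression",
    "build_predictor_set",
    "DEFAULT_N_PERMUTATIONS",
]

DEFAULT_N_PERMUTATIONS = 9_999


@dataclass
class MrmResult:
    """Outcome of (multiple) regression on distance matrices.

    ``coefficients`` holds the intercept first, then one slope per predictor
    in ``predictor_names`` order.  ``f_statistic`` is populated by
    :func:`single_matrix_regression` only.
    """

    predictor_names: list[str]
    coefficients: np.ndarray
    r_squared: float
    p_r_squared: float
    p_coefficients: np.ndarray
    n_permutations: int
    seed: int
    n_samples: int
    n_pairs: int
    f_statistic: float | None = None


def _vectorized_design(
    response: DistanceMatrix, predictors: list[DistanceMatrix], names: list[str]
):
    labels = list(response.labels)
    for name, p in zip(names, predictors):
        if list(p.labels) != labels:
            raise ValueError(
                f"predictor {name!r} labels do not match the response matrix"
            )
    n = response.n
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    iu = np.triu_indices(n, k=1)
    y = response.values[iu]
    X = np.column_stack([np.ones(y.size)] + [p.values[iu] for p in predictors])
    # collinearity check on the centred predictor columns
    if len(predictors) >= 1:
        cols = X[:, 1:] - X[:, 1:].mean(axis=0)
        norms = np.linalg.norm(cols, axis=0)
        zero = np.where(norms == 0)[0]
        if zero.size:
            raise ValueError(f"predictor {names[zero[0]]!r} has zero variance")
        if len(predictors) >= 2:
            corr = (cols / norms).T @ (cols / norms)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
            if abs(corr[i, j]) > 1 - 1e-10:
                raise ValueError(
                    f"collinear predictors: {names[i]!r} and {names[j]!r}"
                )
    return y, X, iu


def _fit(X_pinv: np.ndarray, X: np.ndarray, y: np.ndarray):
    coef = X_pinv @ y
    resid = y - X @ coef
    ym = y.mean()
    ss_tot = float(((y - ym) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(resid @ resid) / ss_tot
    return coef, min(max(r2, 0.0), 1.0)


def mrm(
    response: DistanceMatrix,
    predictors: list[DistanceMatrix],
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    predictor_names: list[str] | None = None,
    two_sided: bool = True,
) -> MrmResult:
    """Multiple regression of a distance matrix on predictor matrices.

    OLS on vectorized lower triangles; the permutation null jointly permutes
    rows and columns of the response matrix.  ``two_sided=False`` gives
    one-sided (observed-sign) coefficient tests.
    """
    if not predictors:
        raise ValueError("at least one predictor matrix is required")
    names = list(predictor_names) if predictor_names else [
        f"predictor_{k + 1}" for k in range(len(predictors))
    ]
    y, X, iu = _vectorized_design(response, predictors, names)
    X_pinv = np.linalg.pinv(X)
    coef, r2 = _fit(X_pinv, X, y)

    rng = np.random.default_rng(seed)
    n = response.n
    M = response.values
    exceed_r2 = 0
    exceed_coef = np.zeros(len(predictors), dtype=np.int64)
    # permutations in chunks: build permuted triangle vectors by fancy indexing
    chunk = max(1, min(n_permutations, int(2e7 // max(y.size, 1))))
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        Yp = np.empty((b, y.size))
        for k in range(b):
            perm = rng.permutation(n)
            Yp[k] = M[np.ix_(perm, perm)][iu]
        coefs_p = Yp @ X_pinv.T  # (b, 1 + n_pred)
        resid = Yp - coefs_p @ X.T
        ym = Yp.mean(axis=1, keepdims=True)
        ss_tot = ((Yp - ym) ** 2).sum(axis=1)
        ss_res = (resid**2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2_p = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
        exceed_r2 += int((r2_p >= r2 - 1e-15).sum())
        slopes_p = coefs_p[:, 1:]
        obs = coef[1:]
        if two_sided:
            exceed_coef += (np.abs(slopes_p) >= np.abs(obs) - 1e-15).sum(axis=0)
        else:
            sign = np.sign(obs)
            sign[sign == 0] = 1.0
            exceed_coef += (slopes_p * sign >= obs * sign - 1e-15).sum(axis=0)
        done += b

    p_r2 = (exceed_r2 + 1) / (n_permutations + 1)
    p_coef = (exceed_coef + 1) / (n_permutations + 1)
    return MrmResult(
        predictor_names=names,
        coefficients=coef,
        r_squared=r2,
        p_r_squared=float(p_r2),
        p_coefficients=p_coef.astype(float),
        n_permutations=n_permutations,
        seed=seed,
        n_samples=n,
        n_pairs=int(y.size),
    )


def single_matrix_regression(
    response: DistanceMatrix,
    predictor: DistanceMatrix,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    predictor_name: str = "predictor",
    two_sided: bool = True,
) -> MrmResult:
    """MRM with one predictor, plus the F statistic of the pair-level fit.

    ``F = (n_pairs - 2) * R² / (1 - R²)`` with 1 and n_pairs - 2 degrees of
    freedom (descriptive, since pairs are dependent; inference comes from the
    permutation p-values).
    """
    result = mrm(
        response,
        [predictor],
        n_permutations=n_permutations,
        seed=seed,
        predictor_names=[predictor_name],
        two_sided=two_sided,
    )
    r2 = result.r_squared
    if r2 >= 1.0:
        result.f_statistic = float("inf")
    else:
        result.f_statistic = (result.n_pairs - 2) * r2 / (1.0 - r2)
    return result


def build_predictor_set(
    frame: SampleFrame,
    geo: DistanceMatrix | None,
    scalars: list[str],
) -> tuple[list[DistanceMatrix], list[str]]:
    """Assemble predictor matrices: geographic distance + scalar differences.

    Each named metadata column becomes an absolute-difference matrix over the
    frame's samples.  Returns (matrices, names) in a stable order with the
    geographic matrix (if given) first.
    """
    matrices: list[DistanceMatrix] = []
    names: list[str] = []
    if geo is not None:
        matrices.append(geo)
        names.append("spatial_distance")
    for col in scalars:
        series = frame.column(col)  # KeyError names the missing column
        matrices.append(scalar_difference_matrix(series))
        names.append(col)
    return matrices, names
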