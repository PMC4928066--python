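"""Distance-decay exponent estimation with bootstrap significance.

The distance-decay relationship models the decline of community similarity
``S`` with geographic distance ``d`` as a power law ``S = c * d**(-2z)``.
On log-log axes this is a straight line, and the spatial turnover exponent is

    z = -(slope of the ln S on ln d regression) / 2.

``z`` is base-invariant (slope magnitude does not depend on the log base for
a log-log fit).  Significance of the slope is assessed by resampling the pair
list with replacement, refitting the slope in each replicate, and applying a
one-sample t test of the bootstrap slopes against zero:

    t = boot_mean / (boot_sd / sqrt(B))

with ``B - 1`` degrees of freedom.  Because the test statistic scales as
``sqrt(B)``, |t| is enormous at B = 9,999 for any real decay; the scale-free
ratio ``boot_mean / boot_sd`` is reported alongside for a B-independent
effect measure.  Sample pairs are not independent (each sample appears in
n - 1 pairs), so pair-level resampling understates uncertainty; a sample-level
bootstrap (resampling rows of the matrices) is available via ``unit="sample"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community_prep import subset_by_phylum
from .core_tables import DistanceMatrix, OtuTable, SampleFrame
from .distances import bray_curtis, haversine_matrix, vectorize_lower_triangle

__all__ = [
    "DecayFit",
    "BootstrapTest",
    "decay_pairs",
    "fit_distance_decay",
    "bootstrap_decay_test",
    "decay_by_taxon",
    "DEFAULT_N_BOOT",
]

DEFAULT_N_BOOT = 9_999


@dataclass
class DecayFit:
    """Log-log regression of similarity on distance.

    Attributes
    ----------
    slope, intercept
        OLS coefficients of ``ln S`` on ``ln d``.
    z
        Turnover exponent, exactly ``-slope / 2``.
    r_squared
        Fraction of ln-similarity variance explained.
    n_pairs, n_dropped
        Pairs used, and pairs excluded for nonpositive similarity or zero
        distance.
    """

    slope: float
    intercept: float
    z: float
    r_squared: float
    n_pairs: int
    n_dropped: int


@dataclass
class BootstrapTest:
    """One-sample t test on bootstrap slope replicates.

    ``degenerate`` flags a zero bootstrap standard deviation (every replicate
    identical, e.g. noiseless data); ``t`` is then signed infinity and ``p``
    the resolution floor ``1 / (n_boot + 1)``.
    """

    n_boot: int
    t_statistic: float
    p_value: float
    boot_mean: float
    boot_sd: float
    ratio: float
    seed: int
    degenerate: bool = False
    unit: str = "pair"


def decay_pairs(geo: DistanceMatrix, community: DistanceMatrix):
    """Usable (ln d, ln S) pairs for the decay fit.

    Similarity is ``S = 1 - dissimilarity``; pairs with ``S <= 0`` or
    ``d = 0`` carry no log-log information and are excluded (counted, not
    imputed).
    """
    if list(geo.labels) != list(community.labels):
        raise ValueError("geographic and community matrices must share labels")
    d, _ = vectorize_lower_triangle(geo)
    diss, _ = vectorize_lower_triangle(community)
    s = 1.0 - diss
    usable = (s > 0) & (d > 0)
    return np.log(d[usable]), np.log(s[usable]), int((~usable).sum())


def _ols_line(x: np.ndarray, y: np.ndarray):
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    varx = float(dx @ dx)
    if varx == 0.0:
        raise ValueError("all distances equal; no regression possible")
    slope = float(dx @ (y - ym)) / varx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_tot = float(((y - ym) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float((resid**2).sum()) / ss_tot
    return slope, intercept, min(max(r2, 0.0), 1.0)


def fit_distance_decay(
    geo: DistanceMatrix, community: DistanceMatrix
) -> DecayFit:
    """Fit the power-law decay of similarity with distance.

    Ordinary least squares of ``ln S`` on ``ln d`` over usable pairs;
    ``z = -slope / 2``.
    """
    x, y, n_dropped = decay_pairs(geo, community)
    if x.size < 3:
        raise ValueError(f"only {x.size} usable pairs; need at least 3")
    slope, intercept, r2 = _ols_line(x, y)
    return DecayFit(
        slope=slope,
        intercept=intercept,
        z=-slope / 2.0,
        r_squared=r2,
        n_pairs=int(x.size),
        n_dropped=n_dropped,
    )


def _bootstrap_slopes_pairs(
    x: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Slopes of ``n_boot`` with-replacement resamples of the pair list.

    Chunked and fully vectorised: for each replicate the slope is
    cov(x*, y*) / var(x*) computed from resampled sums.
    """
    m = x.size
    slopes = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(4e7 // m)))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, m, size=(b, m))
        xb = x[idx]
        yb = y[idx]
        xm = xb.mean(axis=1, keepdims=True)
        ym = yb.mean(axis=1, keepdims=True)
        dx = xb - xm
        varx = (dx * dx).sum(axis=1)
        cov = (dx * (yb - ym)).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            slopes[done:done + b] = np.where(varx > 0, cov / varx, 0.0)
        done += b
    return slopes


def bootstrap_decay_test(
    geo: DistanceMatrix,
    community: DistanceMatrix,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    unit: str = "pair",
) -> BootstrapTest:
    """Bootstrap the decay slope and test it against zero.

    Parameters
    ----------
    unit
        ``"pair"`` (default) resamples the vectorized pair list with
        replacement; ``"sample"`` resamples whole samples (rows of both
        matrices), which respects the dependence structure of pairwise data.
    """
    if unit not in ("pair", "sample"):
        raise ValueError("unit must be 'pair' or 'sample'")
    rng = np.random.default_rng(seed)
    x, y, _ = decay_pairs(geo, community)
    if x.size < 3:
        raise ValueError("too few usable pairs to bootstrap")
    _ = _ols_line(x, y)  # fail early if the full fit is impossible
    if unit == "pair":
        slopes = _bootstrap_slopes_pairs(x, y, n_boot, rng)
    else:
        n = geo.n
        slopes = np.empty(n_boot)
        for b in range(n_boot):
            take = rng.integers(0, n, size=n)
            take = np.unique(take)  # duplicated rows give zero-distance pairs
            if take.size < 3:
                slopes[b] = np.nan
                continue
            sub_geo = DistanceMatrix(
                [geo.labels[i] for i in take],
                geo.values[np.ix_(take, take)],
                geo.kind,
            )
            sub_com = DistanceMatrix(
                [community.labels[i] for i in take],
                community.values[np.ix_(take, take)],
                community.kind,
            )
            try:
                xb, yb, _ = decay_pairs(sub_geo, sub_com)
                slopes[b] = _ols_line(xb, yb)[0]
            except ValueError:
                slopes[b] = np.nan
        slopes = slopes[~np.isnan(slopes)]
        if slopes.size < 2:
            raise ValueError("sample-level bootstrap produced too few fits")
        n_boot = slopes.size
    boot_mean = float(slopes.mean())
    boot_sd = float(slopes.std(ddof=1))
    p_floor = 1.0 / (n_boot + 1)
    # noiseless data: every resample refits the same slope up to float eps
    if boot_sd <= 1e-12 * (1.0 + abs(boot_mean)):
        return BootstrapTest(
            n_boot=n_boot,
            t_statistic=math.copysign(math.inf, boot_mean) if boot_mean else 0.0,
            p_value=p_floor,
            boot_mean=boot_mean,
            boot_sd=0.0,
            ratio=math.copysign(math.inf, boot_mean) if boot_mean else 0.0,
            seed=seed,
            degenerate=True,
            unit=unit,
        )
    t = boot_mean / (boot_sd / math.sqrt(n_boot))
    p = 2.0 * stats.t.sf(abs(t), df=n_boot - 1)
    p = float(max(min(p, 1.0), p_floor))
    return BootstrapTest(
        n_boot=n_boot,
        t_statistic=float(t),
        p_value=p,
        boot_mean=boot_mean,
        boot_sd=boot_sd,
        ratio=boot_mean / boot_sd,
        seed=seed,
        unit=unit,
    )


def decay_by_taxon(
    otu: OtuTable,
    frame: SampleFrame,
    phyla: list[str] | None = None,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-taxon decay fits: all sequences plus each requested phylum.

    For every taxon the OTU table is subset, Bray-Curtis recomputed, the
    decay fit and its bootstrap test run.  Phyla with fewer than 2 non-empty
    samples are skipped with a warning.  Returns an ordered DataFrame
    mirroring a per-taxon summary table (taxon, z, slope, r², t, P, pairs).
    """
    phyla = list(phyla or [])
    geo_full = haversine_matrix(frame)
    rows = []
    for label, table in [("All sequences", otu)] + [
        (p, subset_by_phylum(otu, p)) for p in phyla
    ]:
        nonempty = table.counts.index[table.counts.sum(axis=1) > 0].tolist()
        if len(nonempty) < 2:
            warnings.warn(
                f"taxon {label!r} has <2 non-empty samples; skipped", stacklevel=2
            )
            continue
        sub = table.select_samples(nonempty)
        geo = geo_full.select(nonempty)
        bc = bray_curtis(sub)
        fit = fit_distance_decay(geo, bc)
        boot = bootstrap_decay_test(geo, bc, n_boot=n_boot, seed=seed)
        rows.append(
            {
                "taxon": label,
                "z": fit.z,
                "slope": fit.slope,
                "r_squared": fit.r_squared,
                "t": boot.t_statistic,
                "p": boot.p_value,
                "n_pairs": fit.n_pairs,
                "n_dropped": fit.n_dropped,
                "boot_ratio": boot.ratio,
            }
        )
    return pd.DataFrame(rows)
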