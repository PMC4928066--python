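"""Pairwise distance/dissimilarity matrices feeding the decay and MRM stages.

Three constructions cover every predictor and response the analyses use:
Bray-Curtis compositional dissimilarity between samples, great-circle
geographic distance between GPS-located plots, and absolute differences of a
per-sample scalar (elevation, a PC score, plant diversity) so that scalar
covariates can enter regression on distance matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_tables import DistanceMatrix, OtuTable, SampleFrame, ValidationError

__all__ = [
    "EARTH_RADIUS_KM",
    "bray_curtis",
    "haversine_matrix",
    "scalar_difference_matrix",
    "vectorize_lower_triangle",
    "matrix_from_pairs",
]

#: Mean Earth radius used for great-circle distances.
EARTH_RADIUS_KM = 6371.0


def bray_curtis(otu: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    ``BC(u, v) = sum|u_i - v_i| / sum(u_i + v_i)`` over OTUs; 0 for identical
    composition, 1 for disjoint OTU sets.  Every sample must have a positive
    total count.
    """
    counts = otu.counts.to_numpy(dtype=float)
    if counts.shape[0] < 2:
        raise ValidationError("Bray-Curtis needs at least 2 samples")
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = otu.counts.index[totals <= 0][0]
        raise ValidationError(f"sample {bad!r} has zero total count")
    condensed = pdist(counts, metric="braycurtis")
    return DistanceMatrix(otu.sample_ids, squareform(condensed), "bray-curtis")


def haversine_matrix(frame: SampleFrame) -> DistanceMatrix:
    """Great-circle distances (km) between samples via the haversine formula.

    Uses a spherical Earth of radius 6371.0 km; accurate to ~0.5% against an
    ellipsoid, ample at the scales of a field survey.
    """
    coords = frame.coordinates()
    missing = coords.index[coords.isna().any(axis=1)]
    if len(missing):
        raise ValidationError(f"sample {missing[0]!r} has a missing coordinate")
    lat = np.radians(coords["latitude"].to_numpy())
    lon = np.radians(coords["longitude"].to_numpy())
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return DistanceMatrix(frame.sample_ids, d, "geographic-km")


def scalar_difference_matrix(values, labels=None) -> DistanceMatrix:
    """Pairwise absolute differences ``|x_i - x_j|`` of a per-sample scalar."""
    if isinstance(values, pd.Series):
        labels = values.index.tolist() if labels is None else list(labels)
        x = values.to_numpy(dtype=float)
    else:
        x = np.asarray(values, dtype=float)
        labels = list(range(len(x))) if labels is None else list(labels)
    if np.isnan(x).any():
        bad = labels[int(np.argwhere(np.isnan(x))[0][0])]
        raise ValidationError(f"missing value for sample {bad!r}")
    d = np.abs(x[:, None] - x[None, :])
    return DistanceMatrix(labels, d, "scalar-difference")


def vectorize_lower_triangle(m: DistanceMatrix):
    """Flatten the strict lower triangle in deterministic (i < j) order.

    Returns
    -------
    values : ndarray of length n(n-1)/2
    pairs : list of (label_i, label_j) tuples in matching order
    """
    n = m.n
    iu = np.triu_indices(n, k=1)
    values = m.values[iu]
    pairs = [(m.labels[i], m.labels[j]) for i, j in zip(*iu)]
    return values, pairs


def matrix_from_pairs(values, labels, kind: str = "scalar-difference") -> DistanceMatrix:
    """Rebuild a square matrix from a row-major (i < j) pair vector."""
    n = len(labels)
    mat = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    values = np.asarray(values, dtype=float)
    if values.size != iu[0].size:
        raise ValidationError(
            f"pair vector length {values.size} does not match {n} labels"
        )
    mat[iu] = values
    mat = mat + mat.T
    return DistanceMatrix(labels, mat, kind)
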