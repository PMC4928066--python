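"""Count-table preprocessing and alpha diversity.

The preprocessing mirrors a standard amplicon workflow: OTUs whose pooled
count across all samples is exactly one (global singletons, typically
sequencing artifacts) are removed, then every sample is subsampled without
replacement to a common depth (20,000 reads by default) so that diversity and
dissimilarity comparisons are not confounded by sequencing effort.

Alpha diversity is the Shannon-Weaver index in natural-log units (nats),
:math:`H = -\\sum_i p_i \\ln p_i`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_tables import OtuTable, parse_phylum

__all__ = [
    "DiversityResult",
    "remove_singletons",
    "rarefy",
    "shannon_index",
    "shannon_per_sample",
    "subset_by_phylum",
    "DEFAULT_RAREFACTION_DEPTH",
]

#: Common subsampling depth (reads per sample) used to standardise samples.
DEFAULT_RAREFACTION_DEPTH = 20_000


@dataclass
class DiversityResult:
    """Per-sample alpha diversity: Shannon H (nats) and observed richness."""

    sample_id: object
    shannon: float
    richness: int


def remove_singletons(otu: OtuTable) -> OtuTable:
    """Drop OTUs whose summed count across *all* samples equals one.

    Singleton status is global (pooled across samples), the standard
    convention after pooled OTU clustering; per-sample singletons with a
    pooled total above one are untouched.  An empty result is allowed and
    warned about.
    """
    totals = otu.counts.sum(axis=0)
    keep = totals.index[totals != 1]
    if len(keep) == 0:
        warnings.warn("all OTUs are singletons; result is empty", stacklevel=2)
    return otu.select_otus(keep)


def rarefy(
    otu: OtuTable,
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    seed: int | np.random.Generator = 0,
) -> tuple[OtuTable, list]:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped and their ids
    returned.  The draw is a single multivariate hypergeometric sample per
    row, deterministic given ``seed``.

    Returns
    -------
    (rarefied OtuTable, list of dropped sample ids)
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    totals = otu.counts.sum(axis=1)
    kept = totals.index[totals >= depth].tolist()
    dropped = totals.index[totals < depth].tolist()
    if dropped:
        warnings.warn(
            f"{len(dropped)} sample(s) below depth {depth} dropped: "
            f"{dropped[:5]}",
            stacklevel=2,
        )
    rows = np.empty((len(kept), otu.counts.shape[1]), dtype=np.int64)
    counts = otu.counts.loc[kept].to_numpy()
    for i in range(len(kept)):
        rows[i] = rng.multivariate_hypergeometric(counts[i], depth)
    rarefied = OtuTable(
        pd.DataFrame(rows, index=kept, columns=otu.counts.columns),
        otu.taxonomy,
    )
    return rarefied, dropped


def shannon_index(counts_row) -> float:
    """Shannon-Weaver H in nats for one sample's counts.

    ``H = -sum(p_i * ln p_i)`` over OTUs with positive count.  Raises on an
    all-zero row.
    """
    x = np.asarray(counts_row, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("cannot compute Shannon index of an all-zero sample")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(otu: OtuTable) -> list[DiversityResult]:
    """Shannon H and observed richness for every sample in the table."""
    out = []
    for sample_id, row in otu.counts.iterrows():
        x = row.to_numpy()
        out.append(
            DiversityResult(
                sample_id=sample_id,
                shannon=shannon_index(x),
                richness=int((x > 0).sum()),
            )
        )
    return out


def subset_by_phylum(otu: OtuTable, phylum: str) -> OtuTable:
    """Restrict the table to OTUs of one phylum (case-insensitive match).

    Counts are unchanged; a phylum absent from the taxonomy yields an empty
    table with a warning.
    """
    if not phylum:
        raise ValueError("phylum name must be non-empty")
    phyla = otu.phyla().str.lower()
    keep = phyla.index[phyla == phylum.lower()]
    if len(keep) == 0:
        warnings.warn(f"phylum {phylum!r} not present; result is empty", stacklevel=2)
    return otu.select_otus(keep)
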