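"""Functional gene array (GeoChip) signal processing.

Hybridisation intensities proxy the abundance of biogeochemical-cycling
genes, but the raw table carries two artifacts: spurious single-spot
detections, and per-sample multiplicative scaling (labelling/hybridisation
efficiency).  The processing is three fixed steps:

(i)   **Detection filter** — within each site (reserve) group of samples, a
      probe detected in fewer than 6 of the group's 10 samples is treated as
      undetected throughout that group;
(ii)  **Mean normalisation** — each spot is divided by its sample's total
      signal and rescaled by the across-sample mean total, so every sample
      ends at the same total intensity in the original units;
(iii) **Category sums** — detected intensities are summed per sample within
      each of 18 registered functional gene categories spanning carbon
      fixation and degradation, nitrogen cycling and phosphorus cycling.

The order is fixed: filtering counts raw detections; normalisation then
equalises what survived.  Undetected spots contribute zero to sums but are
never silently converted to measured zeros.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_tables import SignalTable, ValidationError
from .ordination import log_transform_table

__all__ = [
    "CategoryRegistry",
    "CategoryProfile",
    "default_registry",
    "detection_filter",
    "mean_normalize",
    "category_sums",
    "function_profile_pipeline",
]

#: The 18 gene categories, keyed by element-cycle process.
DEFAULT_CATEGORIES: dict[str, str] = {
    # carbon fixation
    "FTHFS": "carbon_fixation",
    "FBPase": "carbon_fixation",
    "Rubisco": "carbon_fixation",
    # carbon degradation
    "cellobiase": "carbon_degradation",
    "endoglucanase": "carbon_degradation",
    "chitinase": "carbon_degradation",
    "mannanase": "carbon_degradation",
    "xylanase": "carbon_degradation",
    "phenol_oxidase": "carbon_degradation",
    "amyA": "carbon_degradation",
    # nitrogen cycling
    "ureC": "nitrogen",
    "narG": "nitrogen",
    "nirS_K": "nitrogen",
    "nosZ": "nitrogen",
    "nifH": "nitrogen",
    # phosphorus cycling
    "phytase": "phosphorus",
    "ppx": "phosphorus",
    "ppk": "phosphorus",
}


@dataclass(frozen=True)
class CategoryRegistry:
    """The registered functional gene categories and their cycle tags."""

    categories: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORIES)
    )

    def __post_init__(self) -> None:
        names = list(self.categories)
        if len(set(names)) != len(names):
            raise ValidationError("category names must be unique")

    @property
    def names(self) -> list[str]:
        return list(self.categories)

    def cycle_of(self, category: str) -> str:
        return self.categories[category]

    @classmethod
    def from_config(cls, path) -> "CategoryRegistry":
        """Load ``category<TAB>cycle`` lines from a plain-text config."""
        cats: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                cats[parts[0]] = parts[1] if len(parts) > 1 else "unspecified"
        return cls(cats)


def default_registry() -> CategoryRegistry:
    """Registry with the 18 default categories (see module docstring)."""
    return CategoryRegistry()


@dataclass
class CategoryProfile:
    """Per-sample summed intensities per gene category, with provenance.

    ``sums`` is samples × categories; ``provenance`` counts the probes that
    contributed at least one detected spot to each category.
    """

    sums: pd.DataFrame
    provenance: pd.Series
    log_transformed: bool = False

    @property
    def sample_ids(self) -> list:
        return self.sums.index.tolist()

    @property
    def category_names(self) -> list:
        return self.sums.columns.tolist()


# ---------------------------------------------------------------------------
# Step (i): detection filter
# ---------------------------------------------------------------------------

def detection_filter(
    signals: SignalTable, min_detected: int = 6, group_size: int = 10
) -> SignalTable:
    """Mask probes under-detected within each site group.

    Within every site, a probe detected (non-missing, positive) in fewer
    than ``min_detected`` of that site's samples is set to missing for that
    site only.  Groups whose size differs from ``group_size`` get a
    proportionally rescaled threshold ``ceil(min_detected / group_size * n)``
    and a warning.  Probes left with no detection anywhere are dropped.
    """
    if signals.site_of is None or signals.site_of.isna().any():
        raise ValidationError("detection_filter requires site_of for every sample")
    inten = signals.intensities.copy()
    detected = signals.detected()
    for site, sample_idx in signals.site_of.groupby(signals.site_of).groups.items():
        samples = list(sample_idx)
        threshold = min_detected
        if len(samples) != group_size:
            threshold = math.ceil(min_detected / group_size * len(samples))
            warnings.warn(
                f"site {site!r} has {len(samples)} samples (expected "
                f"{group_size}); detection threshold rescaled to {threshold}",
                stacklevel=2,
            )
        n_det = detected.loc[samples].sum(axis=0)
        failing = n_det.index[n_det < threshold]
        inten.loc[samples, failing] = np.nan
    keep = inten.columns[(inten.notna() & (inten > 0)).any(axis=0)]
    dropped = inten.shape[1] - len(keep)
    if dropped:
        warnings.warn(
            f"{dropped} probe(s) without any detection were dropped", stacklevel=2
        )
    return SignalTable(inten[keep], signals.category.loc[keep], signals.site_of)


# ---------------------------------------------------------------------------
# Step (ii): mean normalisation
# ---------------------------------------------------------------------------

def mean_normalize(signals: SignalTable) -> SignalTable:
    """Rescale each sample to the across-sample mean total intensity.

    ``spot' = spot / total(sample) * mean_over_samples(total)`` — relative
    abundance re-expressed on a common total, preserving intensity units.
    Missing spots contribute nothing to totals and stay missing.
    """
    totals = signals.intensities.sum(axis=1, skipna=True)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValidationError(f"sample {zero[0]!r} has zero total signal")
    mean_total = float(totals.mean())
    scaled = signals.intensities.div(totals, axis=0) * mean_total
    return SignalTable(scaled, signals.category, signals.site_of)


# ---------------------------------------------------------------------------
# Step (iii): category sums
# ---------------------------------------------------------------------------

def category_sums(
    signals: SignalTable, registry: CategoryRegistry | None = None
) -> CategoryProfile:
    """Sum detected intensities per sample within each registered category.

    Probes annotated to unregistered categories are excluded with a warning;
    categories with no contributing probes are kept as zero columns.
    """
    registry = registry or default_registry()
    known = set(registry.names)
    mapped = signals.category.index[signals.category.isin(known)]
    unmapped = signals.category.index.difference(mapped)
    if len(unmapped):
        warnings.warn(
            f"{len(unmapped)} probe(s) with unregistered categories excluded: "
            f"{unmapped[:5].tolist()}",
            stacklevel=2,
        )
    inten = signals.intensities[mapped].fillna(0.0)
    cats = signals.category.loc[mapped]
    sums = inten.T.groupby(cats).sum().T  # samples × present categories
    sums = sums.reindex(columns=registry.names, fill_value=0.0)
    empty = sums.columns[(sums == 0).all(axis=0)]
    if len(empty):
        warnings.warn(
            f"categories with no signal kept as zeros: {list(empty)}", stacklevel=2
        )
    detected_any = (signals.intensities[mapped].notna()
                    & (signals.intensities[mapped] > 0)).any(axis=0)
    provenance = (
        pd.Series(detected_any.to_numpy(), index=cats.to_numpy())
        .groupby(level=0)
        .sum()
        .reindex(registry.names, fill_value=0)
        .astype(int)
    )
    return CategoryProfile(sums=sums, provenance=provenance)


# ---------------------------------------------------------------------------
# The composed pipeline
# ---------------------------------------------------------------------------

def function_profile_pipeline(
    signals: SignalTable,
    registry: CategoryRegistry | None = None,
    min_detected: int = 6,
    group_size: int = 10,
    log: bool = False,
) -> CategoryProfile:
    """Run the fixed three-step processing, optionally ``ln(x + 1)`` at the end.

    detection_filter → mean_normalize → category_sums.  The step order is
    part of the method: filtering first means normalisation totals reflect
    only reliably detected signal.
    """
    registry = registry or default_registry()
    filtered = detection_filter(signals, min_detected=min_detected, group_size=group_size)
    normalized = mean_normalize(filtered)
    profile = category_sums(normalized, registry)
    if log:
        profile = CategoryProfile(
            sums=log_transform_table(profile.sums),
            provenance=profile.provenance,
            log_transformed=True,
        )
    return profile
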