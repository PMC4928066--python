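"""End-to-end analyses: taxonomic endemism and functional convergence.

Two orchestrated runs mirror the study design:

* :func:`run_endemism_analysis` — singleton removal, rarefaction to a common
  depth, Bray-Curtis dissimilarity, DCA of relative abundances, per-taxon
  distance-decay exponents with bootstrap tests, and regression on distance
  matrices of community dissimilarity against spatial distance and
  environmental covariates.
* :func:`run_function_analysis` — the functional-array three-step
  processing, PCA and DCA of the log category sums, and single matrix
  regressions of the function PC scores (as absolute-difference matrices)
  against spatial distance, environment and community dissimilarity.

Each run returns an :class:`AnalysisReport` whose provenance block records
the seed, parameters, input fingerprints and step log, so a report can be
reproduced exactly from its own metadata.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .community_prep import (
    DEFAULT_RAREFACTION_DEPTH,
    remove_singletons,
    rarefy,
    shannon_per_sample,
)
from .core_tables import DistanceMatrix, OtuTable, SampleFrame, SignalTable
from .distance_decay import DEFAULT_N_BOOT, decay_by_taxon
from .distances import bray_curtis, haversine_matrix, scalar_difference_matrix
from .geochip import CategoryRegistry, default_registry, function_profile_pipeline
from .matrix_regression import (
    DEFAULT_N_PERMUTATIONS,
    mrm,
    single_matrix_regression,
)
from .ordination import OrdinationResult, dca, log_transform_table, pca
from .synthetic import CLIMATE_VARIABLES, SOIL_VARIABLES

__all__ = ["AnalysisConfig", "AnalysisReport",
           "run_endemism_analysis", "run_function_analysis"]

DOMINANT_PHYLA = [
    "Acidobacteria", "Actinobacteria", "Proteobacteria", "Verrucomicrobia",
]


@dataclass
class AnalysisConfig:
    """Shared knobs for the orchestrated analyses."""

    rarefaction_depth: int = DEFAULT_RAREFACTION_DEPTH
    phyla: list[str] = field(default_factory=lambda: list(DOMINANT_PHYLA))
    n_boot: int = DEFAULT_N_BOOT
    n_permutations: int = DEFAULT_N_PERMUTATIONS
    n_segments: int = 26
    n_axes: int = 4
    soil_columns: list[str] = field(default_factory=lambda: list(SOIL_VARIABLES))
    climate_columns: list[str] = field(default_factory=lambda: list(CLIMATE_VARIABLES))
    n_climate_pcs: int = 3
    run_ordination: bool = True
    seed: int = 0

    @classmethod
    def fast(cls, seed: int = 0, **overrides) -> "AnalysisConfig":
        """Reduced replication (B = 199 bootstrap, 99 permutations) for
        quick exploratory runs; estimates are identical in expectation."""
        return cls(n_boot=199, n_permutations=99, seed=seed, **overrides)


@dataclass
class AnalysisReport:
    """Bundle of tables produced by one orchestrated run."""

    kind: str
    decay: pd.DataFrame | None
    single_regressions: pd.DataFrame | None
    multiple_regression: dict | None
    ordination: OrdinationResult | None
    pca_summary: dict | None
    diversity: pd.DataFrame | None
    provenance: dict

    def to_json(self) -> str:
        """Deterministic JSON rendering of every table in the report."""
        def df(d):
            return None if d is None else json.loads(
                d.to_json(orient="split", double_precision=12)
            )
        payload = {
            "kind": self.kind,
            "decay": df(self.decay),
            "single_regressions": df(self.single_regressions),
            "multiple_regression": self.multiple_regression,
            "pca_summary": self.pca_summary,
            "diversity": df(self.diversity),
            "ordination": None if self.ordination is None else {
                "method": self.ordination.method,
                "eigenvalues": [float(e) for e in self.ordination.eigenvalues],
                "variance_fraction": [
                    float(v) for v in self.ordination.variance_fraction
                ],
                "sample_scores": df(self.ordination.sample_scores),
            },
            "provenance": self.provenance,
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    def save(self, directory) -> None:
        from pathlib import Path

        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        if self.decay is not None:
            self.decay.to_csv(out / f"{self.kind}_decay.tsv", sep="\t", index=False)
        if self.single_regressions is not None:
            self.single_regressions.to_csv(
                out / f"{self.kind}_single_regressions.tsv", sep="\t", index=False
            )
        (out / f"{self.kind}_report.json").write_text(self.to_json())


def _fingerprint(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def _environment_pcs(
    frame: SampleFrame, config: AnalysisConfig, log: list[str]
) -> dict[str, pd.Series]:
    """Soil chemistry PC1/PC2 and climate PCs as per-sample scalars.

    Soil PCA runs on raw standardized variables; climate variables are
    log-transformed first (they are scale-ridden precipitation/temperature
    summaries).  Blocks with missing columns are skipped with a log note.
    """
    scalars: dict[str, pd.Series] = {}
    soil = [c for c in config.soil_columns if c in frame.data.columns]
    if len(soil) >= 2:
        shifted = frame.data[soil] - frame.data[soil].min() + 1.0
        res = pca(shifted, log_transform=False, standardize=True)
        for k in range(min(2, res.n_axes)):
            scalars[f"soil_PC{k + 1}"] = res.sample_scores.iloc[:, k]
        log.append(f"soil PCA on {len(soil)} variables")
    else:
        log.append("soil PCA skipped: columns missing")
    climate = [c for c in config.climate_columns if c in frame.data.columns]
    if len(climate) >= 2:
        shifted = frame.data[climate] - frame.data[climate].min() + 1.0
        res = pca(shifted, log_transform=True, standardize=True)
        for k in range(min(config.n_climate_pcs, res.n_axes)):
            scalars[f"climate_PC{k + 1}"] = res.sample_scores.iloc[:, k]
        log.append(f"climate PCA on {len(climate)} variables")
    else:
        log.append("climate PCA skipped: columns missing")
    for col in ("elevation", "plant_shannon"):
        if col in frame.data.columns:
            scalars[col] = frame.data[col]
    return scalars


def run_endemism_analysis(
    otu: OtuTable, frame: SampleFrame, config: AnalysisConfig | None = None
) -> AnalysisReport:
    """Taxonomic endemism: decay exponents, DCA, and distance-matrix regression.

    Expects sample-aligned inputs (see ``align_tables``).  Steps: singleton
    removal → rarefaction → Bray-Curtis → DCA of relative abundances →
    per-taxon decay (all sequences + configured phyla) → single matrix
    regressions per predictor and one joint multiple regression.
    """
    config = config or AnalysisConfig()
    log: list[str] = []
    otu1 = remove_singletons(otu)
    log.append(f"remove_singletons: {otu.shape[1]} -> {otu1.shape[1]} OTUs")
    otu2, dropped = rarefy(otu1, depth=config.rarefaction_depth, seed=config.seed)
    log.append(
        f"rarefy depth={config.rarefaction_depth}: kept {otu2.shape[0]} samples, "
        f"dropped {len(dropped)}"
    )
    frame2 = frame.select_samples(otu2.sample_ids)
    geo = haversine_matrix(frame2)
    bc = bray_curtis(otu2)
    log.append("bray_curtis computed on rarefied counts")

    ordination = None
    if config.run_ordination:
        rel = otu2.counts.div(otu2.counts.sum(axis=1), axis=0)
        rel = rel.loc[:, (rel > 0).any(axis=0)]
        ordination = dca(rel, n_segments=config.n_segments, n_axes=config.n_axes)
        log.append("DCA of relative abundances")

    decay = decay_by_taxon(
        otu2, frame2, config.phyla, n_boot=config.n_boot, seed=config.seed
    )
    log.append(f"decay_by_taxon: {len(decay)} taxa, B={config.n_boot}")

    scalars = _environment_pcs(frame2, config, log)
    singles_rows = []
    predictors = [geo]
    names = ["spatial_distance"]
    for name, series in scalars.items():
        predictors.append(scalar_difference_matrix(series.loc[otu2.sample_ids]))
        names.append(name)
    for name, pred in zip(names, predictors):
        res = single_matrix_regression(
            bc, pred, n_permutations=config.n_permutations,
            seed=config.seed, predictor_name=name,
        )
        singles_rows.append(
            {
                "predictor": name,
                "r_squared": res.r_squared,
                "f_statistic": res.f_statistic,
                "p_r_squared": res.p_r_squared,
                "coefficient": float(res.coefficients[1]),
                "p_coefficient": float(res.p_coefficients[0]),
            }
        )
    singles = pd.DataFrame(singles_rows)
    multi = mrm(
        bc, predictors, n_permutations=config.n_permutations,
        seed=config.seed, predictor_names=names,
    )
    multiple = {
        "predictors": multi.predictor_names,
        "coefficients": [float(c) for c in multi.coefficients],
        "r_squared": multi.r_squared,
        "p_r_squared": multi.p_r_squared,
        "p_coefficients": [float(p) for p in multi.p_coefficients],
        "n_permutations": multi.n_permutations,
    }
    log.append(f"matrix regressions: {len(names)} single + 1 multiple")

    diversity = pd.DataFrame(
        [
            {"sample_id": d.sample_id, "shannon": d.shannon, "richness": d.richness}
            for d in shannon_per_sample(otu2)
        ]
    )
    provenance = {
        "analysis": "endemism",
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if not isinstance(v, list)
        },
        "phyla": list(config.phyla),
        "input_otu_fingerprint": _fingerprint(otu.counts.to_numpy()),
        "input_frame_fingerprint": _fingerprint(
            frame.data["latitude"].to_numpy(), frame.data["longitude"].to_numpy()
        ),
        "steps": log,
    }
    return AnalysisReport(
        kind="endemism",
        decay=decay,
        single_regressions=singles,
        multiple_regression=multiple,
        ordination=ordination,
        pca_summary=None,
        diversity=diversity,
        provenance=provenance,
    )


def run_function_analysis(
    signals: SignalTable,
    frame: SampleFrame,
    community_bc: DistanceMatrix | None = None,
    config: AnalysisConfig | None = None,
    registry: CategoryRegistry | None = None,
) -> AnalysisReport:
    """Functional convergence: processed category profile, PCA/DCA, regressions.

    Function PC scores are per-sample scalars; they enter regression on
    distance matrices as absolute-difference matrices — the construction
    that makes a scalar response commensurable with distance predictors.
    """
    config = config or AnalysisConfig()
    registry = registry or default_registry()
    log: list[str] = []
    if signals.site_of is None or signals.site_of.isna().any():
        signals = signals.with_sites(frame)
    profile = function_profile_pipeline(signals, registry)
    log.append(
        f"function_profile_pipeline: {profile.sums.shape[0]} samples x "
        f"{profile.sums.shape[1]} categories"
    )
    logged = log_transform_table(profile.sums)
    pca_res = pca(logged, log_transform=False, standardize=True)
    pca_summary = {
        "variance_fraction": [float(v) for v in pca_res.variance_fraction],
        "pc1_fraction": float(pca_res.variance_fraction[0]),
        "pc2_fraction": float(pca_res.variance_fraction[1]),
        "n_axes": pca_res.n_axes,
    }
    log.append(
        "PCA of log category sums: PC1 %.3f, PC2 %.3f"
        % (pca_summary["pc1_fraction"], pca_summary["pc2_fraction"])
    )
    ordination = None
    if config.run_ordination:
        # ln(x + 1) keeps the DCA input nonnegative even for sparse categories
        dca_input = np.log1p(profile.sums.loc[:, (profile.sums > 0).any(axis=0)])
        ordination = dca(
            dca_input,
            n_segments=config.n_segments,
            n_axes=min(config.n_axes, profile.sums.shape[1] - 1),
        )
        log.append("DCA of log category sums")

    frame2 = frame.select_samples(profile.sample_ids)
    geo = haversine_matrix(frame2)
    scalars = _environment_pcs(frame2, config, log)
    predictors = {"spatial_distance": geo}
    for name, series in scalars.items():
        predictors[name] = scalar_difference_matrix(
            series.loc[profile.sample_ids]
        )
    if community_bc is not None:
        common = [s for s in profile.sample_ids if s in community_bc.labels]
        if len(common) == len(profile.sample_ids):
            predictors["community_dissimilarity"] = community_bc.select(
                profile.sample_ids
            )
        else:
            log.append("community dissimilarity skipped: sample mismatch")

    rows = []
    for k in range(min(2, pca_res.n_axes)):
        response = scalar_difference_matrix(pca_res.sample_scores.iloc[:, k])
        for name, pred in predictors.items():
            res = single_matrix_regression(
                response, pred, n_permutations=config.n_permutations,
                seed=config.seed, predictor_name=name,
            )
            rows.append(
                {
                    "response": f"function_PC{k + 1}",
                    "predictor": name,
                    "r_squared": res.r_squared,
                    "f_statistic": res.f_statistic,
                    "p_r_squared": res.p_r_squared,
                }
            )
    singles = pd.DataFrame(rows)
    log.append(f"single matrix regressions: {len(rows)}")
    provenance = {
        "analysis": "function",
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if not isinstance(v, list)
        },
        "input_signal_fingerprint": _fingerprint(
            np.nan_to_num(signals.intensities.to_numpy())
        ),
        "steps": log,
    }
    return AnalysisReport(
        kind="function",
        decay=None,
        single_regressions=singles,
        multiple_regression=None,
        ordination=ordination,
        pca_summary=pca_summary,
        diversity=None,
        provenance=provenance,
    )
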