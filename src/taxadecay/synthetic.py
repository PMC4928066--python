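"""Synthetic study-shaped data with known ground truth.

Generators emulate the statistical structure the analyses assume — a
latitudinal transect of sites each holding several plots, OTU counts whose
pairwise similarity decays as a power law of distance, a functional gene
array with per-sample scaling artifacts and site-invariant category means,
and environmental variables from a low-rank latent-factor model — so every
estimator can be exercised against a known truth without any downloads.

Ground-truth decay is controlled two ways:

* **exactly**, by simulating pairwise similarities ``S = c d^{-2z}``
  directly (:func:`simulate_pairwise_decay`) — the right harness for
  estimator unit tests;
* **mechanistically**, by Gaussian niche response curves along latitude
  (:func:`simulate_community`), where the realized exponent depends on
  turnover and is measured, not set — the right harness for ordering and
  end-to-end properties.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_tables import DistanceMatrix, OtuTable, SampleFrame, SignalTable
from .distances import haversine_matrix, matrix_from_pairs, vectorize_lower_triangle
from .geochip import default_registry

__all__ = [
    "SimulationConfig",
    "PairwiseDecayData",
    "simulate_pairwise_decay",
    "simulate_community",
    "simulate_geochip",
    "simulate_environment",
    "study_preset",
    "STUDY_CONFIG",
]

#: Dominant-phylum spatial-structure multipliers (relative niche turnover);
#: larger values mean narrower niches hence faster distance decay.
DEFAULT_PHYLA: dict[str, float] = {
    "Acidobacteria": 1.21,
    "Actinobacteria": 1.16,
    "Verrucomicrobia": 0.93,
    "Proteobacteria": 0.84,
}

SOIL_VARIABLES = ["moisture", "pH", "SOC", "TN", "AN", "NN", "AMN", "TP", "RAP"]
CLIMATE_VARIABLES = [f"bio{i}" for i in range(1, 20)]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the synthetic study.

    Defaults mirror the emulated survey design: 24 sites of 10 plots along a
    ~23–40°N latitudinal gradient, a few thousand OTUs sequenced at tens of
    thousands of reads per plot, and a functional array whose true category
    means do not vary between sites (``geochip_site_effect_sd = 0`` is the
    functional-convergence scenario; raise it to break convergence).
    """

    n_sites: int = 24
    plots_per_site: int = 10
    latitude_range: tuple[float, float] = (23.0, 40.0)
    longitude_range: tuple[float, float] = (108.0, 112.0)
    # community model
    n_otus: int = 2000
    depth_range: tuple[int, int] = (26_026, 93_786)
    turnover_rate: float = 1.0
    niche_width: float = 6.0  # degrees latitude at turnover_rate 1
    phyla: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PHYLA))
    dominant_fraction: float = 0.75  # OTU share in the named phyla
    # direct pairwise-decay model
    target_decay_z: float = 0.115
    decay_intercept: float = 0.5
    decay_noise_sd: float = 0.0
    # functional gene array
    geochip_n_probes: int = 540
    geochip_scaling_sd: float = 0.3
    geochip_dropout: float = 0.1
    geochip_spot_noise_sd: float = 0.15
    geochip_site_effect_sd: float = 0.0
    # environment latent-factor model
    env_n_factors: int = 2
    env_noise_sd: float = 0.3
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_sites * self.plots_per_site


#: Full study-shaped configuration (240 plots, 2,000 OTUs).
STUDY_CONFIG = SimulationConfig()


def _rng(config: SimulationConfig, seed: int | None, stream: int) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng((int(base) % (2**31), stream))


def _layout(config: SimulationConfig, rng: np.random.Generator):
    """Site/plot ids and jittered coordinates along the gradient."""
    lat_lo, lat_hi = config.latitude_range
    lon_lo, lon_hi = config.longitude_range
    site_lat = np.linspace(lat_lo, lat_hi, config.n_sites)
    site_lon = rng.uniform(lon_lo, lon_hi, size=config.n_sites)
    records = []
    for s in range(config.n_sites):
        for p in range(config.plots_per_site):
            records.append(
                {
                    "sample_id": f"S{s + 1:02d}P{p + 1:02d}",
                    "site_id": f"site{s + 1:02d}",
                    "plot_id": f"plot{p + 1:02d}",
                    # ~1 km of within-site plot scatter
                    "latitude": site_lat[s] + rng.normal(0, 0.01),
                    "longitude": site_lon[s] + rng.normal(0, 0.01),
                }
            )
    return pd.DataFrame(records)


@dataclass
class PairwiseDecayData:
    """Direct pairwise-similarity simulation output."""

    geo: DistanceMatrix
    community: DistanceMatrix  # 1 - similarity, Bray-Curtis-like
    similarities: np.ndarray  # lower-triangle order matching geo
    z_true: float


def simulate_pairwise_decay(
    config: SimulationConfig = STUDY_CONFIG,
    seed: int | None = None,
    n_plots: int | None = None,
) -> PairwiseDecayData:
    """Similarities following ``S = c * d**(-2 z_true)`` exactly (plus noise).

    Plots are placed along the latitudinal gradient; optional multiplicative
    lognormal noise (``decay_noise_sd``) perturbs each pair independently.
    Similarities are truncated to (0, 1]; a configuration whose similarities
    all exceed 1 is rejected.
    """
    if config.target_decay_z < 0:
        raise ValueError("target_decay_z must be >= 0")
    rng = _rng(config, seed, stream=1)
    n = config.n_samples if n_plots is None else n_plots
    lat = rng.uniform(*config.latitude_range, size=n)
    lon = rng.uniform(*config.longitude_range, size=n)
    frame = SampleFrame(
        pd.DataFrame(
            {
                "sample_id": [f"P{i + 1:03d}" for i in range(n)],
                "site_id": ["site" for _ in range(n)],
                "latitude": lat,
                "longitude": lon,
            }
        )
    )
    geo = haversine_matrix(frame)
    d, _ = vectorize_lower_triangle(geo)
    if (d <= 0).any():
        d = np.where(d <= 0, 1e-6, d)  # coincident plots: nudge, not drop
        geo = matrix_from_pairs(d, geo.labels, "geographic-km")
    s = config.decay_intercept * d ** (-2.0 * config.target_decay_z)
    if config.decay_noise_sd > 0:
        s = s * np.exp(rng.normal(0.0, config.decay_noise_sd, size=s.size))
    if (s > 1).all():
        raise ValueError("similarity exceeds 1 for every pair; lower the intercept")
    s = np.clip(s, None, 1.0)
    community = matrix_from_pairs(1.0 - s, geo.labels, "bray-curtis")
    return PairwiseDecayData(
        geo=geo, community=community, similarities=s, z_true=config.target_decay_z
    )


def simulate_community(
    config: SimulationConfig = STUDY_CONFIG, seed: int | None = None
) -> tuple[OtuTable, SampleFrame]:
    """OTU counts from Gaussian niche responses along the latitude gradient.

    Each OTU gets a response curve ``a_j(lat) = amp_j exp(-(lat - mu_j)^2 /
    (2 w_j^2))`` with centre uniform over (an extension of) the gradient and
    width ``niche_width / (turnover_rate * phylum_multiplier)``; counts are a
    multinomial draw per sample at a depth uniform over ``depth_range``.
    ``turnover_rate = 0`` gives one shared expected profile (no spatial
    structure beyond sampling noise).
    """
    if config.n_otus < 10:
        raise ValueError("n_otus must be >= 10")
    rng = _rng(config, seed, stream=2)
    meta = _layout(config, rng)
    lat = meta["latitude"].to_numpy()

    phyla = list(config.phyla)
    n_named = int(round(config.dominant_fraction * config.n_otus))
    per = n_named // max(len(phyla), 1) if phyla else 0
    assignment = []
    for p in phyla:
        assignment += [p] * per
    assignment += ["OtherPhylum"] * (config.n_otus - len(assignment))
    assignment = np.array(assignment, dtype=object)
    rng.shuffle(assignment)
    mult = np.array(
        [config.phyla.get(p, 1.0) for p in assignment], dtype=float
    )

    lo, hi = config.latitude_range
    span = hi - lo
    centers = rng.uniform(lo - 0.25 * span, hi + 0.25 * span, size=config.n_otus)
    amps = rng.lognormal(0.0, 1.0, size=config.n_otus)
    rate = config.turnover_rate * mult
    with np.errstate(divide="ignore"):
        widths = np.where(rate > 0, config.niche_width / np.maximum(rate, 1e-12), np.inf)
    # expected relative abundance per sample
    dev = lat[:, None] - centers[None, :]
    expo = np.where(
        np.isinf(widths)[None, :], 0.0, -0.5 * (dev / widths[None, :]) ** 2
    )
    expected = amps[None, :] * np.exp(expo)
    expected = expected / expected.sum(axis=1, keepdims=True)

    depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1,
                          size=len(lat))
    counts = np.empty((len(lat), config.n_otus), dtype=np.int64)
    for i in range(len(lat)):
        counts[i] = rng.multinomial(depths[i], expected[i])

    otu_ids = [f"OTU{j + 1:05d}" for j in range(config.n_otus)]
    taxonomy = pd.Series(
        [f"k__Bacteria; p__{p}; c__unclassified" for p in assignment],
        index=otu_ids,
        dtype=object,
    )
    otu = OtuTable(
        pd.DataFrame(counts, index=meta["sample_id"].tolist(), columns=otu_ids),
        taxonomy,
    )
    frame = SampleFrame(meta)
    return otu, frame


def simulate_environment(
    config: SimulationConfig = STUDY_CONFIG,
    frame: SampleFrame | None = None,
    seed: int | None = None,
    loadings: np.ndarray | None = None,
    variable_names: list[str] | None = None,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Environmental variables from a low-rank latent-factor model.

    Factor 1 is standardised latitude (the temperature/precipitation
    gradient); remaining factors are independent standard normals per
    sample.  ``observed = factors @ loadings.T + noise``.  With default
    loadings the columns are 9 soil chemistry variables, 19 bioclim-style
    climate variables and ``plant_shannon``, plus an ``elevation`` column
    tied to latitude with site-level relief.
    """
    rng = _rng(config, seed, stream=3)
    if frame is None:
        meta = _layout(config, rng)
        frame = SampleFrame(meta)
    lat = frame.column("latitude").to_numpy(dtype=float)
    n = lat.size
    f1 = (lat - lat.mean()) / (lat.std() if lat.std() > 0 else 1.0)
    factors = np.column_stack(
        [f1] + [rng.normal(size=n) for _ in range(max(config.env_n_factors - 1, 0))]
    )
    if loadings is None:
        names = SOIL_VARIABLES + CLIMATE_VARIABLES + ["plant_shannon"]
        L = rng.uniform(-1.0, 1.0, size=(len(names), factors.shape[1]))
        # the climate block leans on the latitude factor
        L[len(SOIL_VARIABLES):len(SOIL_VARIABLES) + 19, 0] = rng.uniform(
            0.7, 1.0, size=19
        ) * rng.choice([-1.0, 1.0], size=19)
    else:
        L = np.asarray(loadings, dtype=float)
        if L.shape[1] != factors.shape[1]:
            raise ValueError(
                f"loading matrix has {L.shape[1]} columns for "
                f"{factors.shape[1]} factors"
            )
        names = variable_names or [f"var{j + 1}" for j in range(L.shape[0])]
    sd = config.env_noise_sd if noise_sd is None else noise_sd
    observed = factors @ L.T + rng.normal(0.0, sd, size=(n, L.shape[0]))
    env = pd.DataFrame(observed, index=frame.sample_ids, columns=names)
    if loadings is None:
        site_relief = {
            s: rng.uniform(300.0, 2200.0) for s in frame.site_ids.unique()
        }
        env["elevation"] = (
            frame.site_ids.map(site_relief).to_numpy()
            + rng.normal(0.0, 50.0, size=n)
        )
        env["plant_shannon"] = 2.5 + 0.5 * env["plant_shannon"].to_numpy()
    return env


def simulate_geochip(
    config: SimulationConfig = STUDY_CONFIG,
    frame: SampleFrame | None = None,
    seed: int | None = None,
) -> SignalTable:
    """Functional array intensities with site-invariant true category means.

    Per-probe base intensities within each of the 18 registered categories
    are lognormal around a category mean shared by all sites;
    ``geochip_site_effect_sd > 0`` adds a per-site, per-category lognormal
    effect (functional divergence).  Each sample carries a multiplicative
    lognormal scaling artifact, each spot lognormal noise, and spots drop out
    (missing) independently at ``geochip_dropout``.
    """
    if config.geochip_n_probes < 18:
        raise ValueError("need at least one probe per category (18)")
    rng = _rng(config, seed, stream=4)
    if frame is None:
        frame = SampleFrame(_layout(config, rng))
    samples = frame.sample_ids
    sites = frame.site_ids
    registry = default_registry()
    cats = registry.names
    probe_cat = np.array(
        [cats[j % len(cats)] for j in range(config.geochip_n_probes)], dtype=object
    )
    probe_ids = [f"probe{j + 1:05d}" for j in range(config.geochip_n_probes)]
    cat_mean = {c: rng.lognormal(4.0, 0.5) for c in cats}
    probe_base = np.array(
        [cat_mean[c] * rng.lognormal(0.0, 0.4) for c in probe_cat]
    )
    # Divergence scenario: per-site, per-category lognormal effects with a
    # latitudinal gradient component, so breaking convergence also breaks it
    # *along the gradient* (half gradient-driven, half unstructured).
    site_ids = list(sites.unique())
    if config.geochip_site_effect_sd > 0:
        site_lat = frame.data.groupby(frame.site_ids)["latitude"].mean()
        lat_z = (site_lat - site_lat.mean()) / (site_lat.std() or 1.0)
        grad_load = rng.normal(size=len(cats))
        site_effect = {}
        for s in site_ids:
            for k, c in enumerate(cats):
                log_eff = config.geochip_site_effect_sd * (
                    0.7 * grad_load[k] * lat_z[s] + 0.7 * rng.normal()
                )
                site_effect[(s, c)] = float(np.exp(log_eff))
    else:
        site_effect = {(s, c): 1.0 for s in site_ids for c in cats}
    scaling = rng.lognormal(0.0, config.geochip_scaling_sd, size=len(samples))
    inten = np.empty((len(samples), config.geochip_n_probes))
    for i, sample in enumerate(samples):
        site = sites.loc[sample]
        eff = np.array([site_effect[(site, c)] for c in probe_cat])
        noise = (
            rng.lognormal(0.0, config.geochip_spot_noise_sd,
                          size=config.geochip_n_probes)
            if config.geochip_spot_noise_sd > 0
            else 1.0
        )
        inten[i] = probe_base * eff * scaling[i] * noise
    if config.geochip_dropout > 0:
        mask = rng.random(inten.shape) < config.geochip_dropout
        inten[mask] = np.nan
    table = pd.DataFrame(inten, index=samples, columns=probe_ids)
    return SignalTable(table, pd.Series(probe_cat, index=probe_ids), sites)


def study_preset(
    seed: int = 0, config: SimulationConfig = STUDY_CONFIG
) -> tuple[OtuTable, SampleFrame, SignalTable]:
    """The full study-shaped triple: OTU table, metadata (with environment
    columns), and functional array, all sharing one sample set."""
    otu, frame = simulate_community(config, seed=seed)
    env = simulate_environment(config, frame=frame, seed=seed)
    merged = frame.data.join(env)
    frame = SampleFrame(merged)
    signals = simulate_geochip(config, frame=frame, seed=seed)
    return otu, frame, signals


def scaled_config(
    n_sites: int = 8,
    plots_per_site: int = 5,
    n_otus: int = 300,
    depth: tuple[int, int] = (3_000, 6_000),
    n_probes: int = 90,
    **overrides,
) -> SimulationConfig:
    """A smaller config with the same structure, for quick runs."""
    return replace(
        STUDY_CONFIG,
        n_sites=n_sites,
        plots_per_site=plots_per_site,
        n_otus=n_otus,
        depth_range=depth,
        geochip_n_probes=n_probes,
        **overrides,
    )
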