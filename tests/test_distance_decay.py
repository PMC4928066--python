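import math

import numpy as np
import pandas as pd
import pytest

from taxadecay.core_tables import DistanceMatrix, OtuTable, SampleFrame
from taxadecay.distance_decay import (
    bootstrap_decay_test,
    decay_by_taxon,
    fit_distance_decay,
)
from taxadecay.distances import matrix_from_pairs
from taxadecay.synthetic import scaled_config, simulate_pairwise_decay


def exact_power_law(distances, z, c=1.0):
    """Geo + community matrices with S = c * d**(-2z) exactly."""
    d = np.asarray(distances, dtype=float)
    n = int((1 + math.isqrt(1 + 8 * d.size)) // 2)
    labels = [f"s{i}" for i in range(n)]
    geo = matrix_from_pairs(d, labels, "geographic-km")
    s = c * d ** (-2.0 * z)
    community = matrix_from_pairs(1.0 - s, labels, "bray-curtis")
    return geo, community


class TestFitDistanceDecay:
    def test_exact_power_law_slope_and_z(self):
        geo, com = exact_power_law([10.0, 100.0, 1000.0], z=0.1)
        fit = fit_distance_decay(geo, com)
        assert abs(fit.slope - (-0.2)) < 1e-12
        assert abs(fit.z - 0.1) < 1e-12
        assert abs(fit.r_squared - 1.0) < 1e-12

    def test_scaled_power_law(self):
        geo, com = exact_power_law([10.0, 55.0, 300.0], z=0.115, c=0.5)
        fit = fit_distance_decay(geo, com)
        assert abs(fit.z - 0.115) < 1e-12

    def test_constant_similarity_gives_zero_slope(self):
        geo, com = exact_power_law([10.0, 100.0, 1000.0], z=0.0, c=0.5)
        fit = fit_distance_decay(geo, com)
        assert abs(fit.slope) < 1e-14 and fit.z == -fit.slope / 2

    def test_z_is_exactly_minus_half_slope(self):
        data = simulate_pairwise_decay(
            scaled_config(decay_noise_sd=0.3), seed=9, n_plots=12
        )
        fit = fit_distance_decay(data.geo, data.community)
        assert fit.z == -fit.slope / 2.0

    @pytest.mark.parametrize("z_true", [0.0, 0.05, 0.115, 0.3, 0.5])
    def test_noiseless_recovery_across_exponents(self, z_true):
        data = simulate_pairwise_decay(
            scaled_config(target_decay_z=z_true), seed=3, n_plots=15
        )
        fit = fit_distance_decay(data.geo, data.community)
        assert abs(fit.z - z_true) < 1e-10
        assert fit.n_dropped == 0

    def test_scale_invariance_of_slope(self):
        d = np.array([12.0, 80.0, 400.0, 1500.0, 33.0, 250.0])
        geo, com = exact_power_law(d, z=0.2, c=0.8)
        geo10, _ = exact_power_law(d * 10, z=0.2, c=0.8)
        f1 = fit_distance_decay(geo, com)
        f2 = fit_distance_decay(geo10, com)
        assert abs(f1.slope - f2.slope) < 1e-12
        assert abs(f1.intercept - f2.intercept) > 1e-6

    def test_nonpositive_similarity_pairs_dropped_and_counted(self):
        labels = ["a", "b", "c", "d"]
        geo = matrix_from_pairs([10, 20, 30, 40, 50, 60], labels, "geographic-km")
        diss = np.array([0.5, 1.0, 0.4, 0.3, 1.0, 0.2])  # two pairs at S=0
        com = matrix_from_pairs(diss, labels, "bray-curtis")
        fit = fit_distance_decay(geo, com)
        assert fit.n_pairs == 4 and fit.n_dropped == 2

    def test_too_few_pairs_rejected(self):
        geo, com = exact_power_law([10.0], z=0.1)
        with pytest.raises(ValueError, match="usable pairs"):
            fit_distance_decay(geo, com)

    def test_equal_distances_rejected(self):
        geo, com = exact_power_law([10.0, 10.0, 10.0], z=0.0, c=0.5)
        geo = matrix_from_pairs([10.0, 10.0, 10.0], geo.labels, "geographic-km")
        with pytest.raises(ValueError, match="distances equal"):
            fit_distance_decay(geo, com)


class TestBootstrapDecayTest:
    def test_noiseless_data_is_degenerate(self):
        """Every bootstrap resample of an exact power law refits the same
        slope, so the bootstrap SD collapses to zero."""
        geo, com = exact_power_law(
            np.array([10.0, 40.0, 90.0, 200.0, 700.0, 1500.0]), z=0.2, c=0.9
        )
        res = bootstrap_decay_test(geo, com, n_boot=99, seed=0)
        assert res.degenerate
        assert res.p_value == 1.0 / 100

    def test_strong_decay_with_noise_is_significant(self):
        cfg = scaled_config(target_decay_z=0.3, decay_noise_sd=0.1)
        data = simulate_pairwise_decay(cfg, seed=21, n_plots=15)  # 105 pairs
        res = bootstrap_decay_test(data.geo, data.community, n_boot=9999, seed=1)
        assert res.p_value < 0.001
        assert res.boot_mean < 0

    def test_deterministic_given_seed(self):
        cfg = scaled_config(target_decay_z=0.2, decay_noise_sd=0.2)
        data = simulate_pairwise_decay(cfg, seed=2, n_plots=10)
        r1 = bootstrap_decay_test(data.geo, data.community, n_boot=199, seed=5)
        r2 = bootstrap_decay_test(data.geo, data.community, n_boot=199, seed=5)
        assert r1.t_statistic == r2.t_statistic and r1.p_value == r2.p_value

    def test_t_scales_as_sqrt_n_boot(self):
        """The one-sample-t-on-bootstrap-replicates form grows ~ sqrt(B),
        which is why reported |t| is enormous at B = 9,999."""
        cfg = scaled_config(target_decay_z=0.25, decay_noise_sd=0.15)
        data = simulate_pairwise_decay(cfg, seed=8, n_plots=15)
        t_small = np.mean([
            abs(bootstrap_decay_test(data.geo, data.community, 250, seed=s).t_statistic)
            for s in range(5)
        ])
        t_large = np.mean([
            abs(bootstrap_decay_test(data.geo, data.community, 4000, seed=s).t_statistic)
            for s in range(5)
        ])
        ratio = t_large / t_small
        assert 4.0 * 0.8 < ratio < 4.0 * 1.2  # B ratio 16 -> t ratio ~4

    def test_null_rejection_rate_of_scale_free_ratio(self):
        """Distances shuffled against similarities: the |ratio| > 1.96 rule
        rejects at roughly its nominal rate (band [0.02, 0.09])."""
        rng = np.random.default_rng(123)
        cfg = scaled_config(target_decay_z=0.2, decay_noise_sd=0.2)
        rejections = 0
        n_rep = 500
        for rep in range(n_rep):
            data = simulate_pairwise_decay(cfg, seed=1000 + rep, n_plots=10)
            # break the pairing: permute similarity entries across pairs
            diss = 1.0 - rng.permutation(data.similarities)
            com = matrix_from_pairs(diss, data.geo.labels, "bray-curtis")
            res = bootstrap_decay_test(data.geo, com, n_boot=120, seed=rep)
            if abs(res.ratio) > 1.96:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_sample_level_bootstrap_runs(self):
        cfg = scaled_config(target_decay_z=0.3, decay_noise_sd=0.1)
        data = simulate_pairwise_decay(cfg, seed=4, n_plots=14)
        res = bootstrap_decay_test(
            data.geo, data.community, n_boot=99, seed=3, unit="sample"
        )
        assert res.unit == "sample" and res.boot_mean < 0


class TestDecayByTaxon:
    @staticmethod
    def structured_table(seed=0):
        """Two phyla: one spatially structured, one uniform."""
        rng = np.random.default_rng(seed)
        n, k = 20, 40
        lat = np.linspace(20, 40, n)
        centers = np.linspace(20, 40, k // 2)
        structured = np.exp(-0.5 * ((lat[:, None] - centers[None, :]) / 2.0) ** 2)
        uniform = np.ones((n, k // 2))
        expected = np.hstack([structured, uniform])
        expected /= expected.sum(axis=1, keepdims=True)
        counts = np.vstack(
            [rng.multinomial(5000, expected[i]) for i in range(n)]
        )
        otu_ids = [f"o{j}" for j in range(k)]
        tax = ["k__B; p__Structured"] * (k // 2) + ["k__B; p__Uniform"] * (k // 2)
        otu = OtuTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(n)], columns=otu_ids),
            pd.Series(tax, index=otu_ids),
        )
        frame = SampleFrame(
            pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(n)],
                    "site_id": ["X"] * n,
                    "latitude": lat,
                    "longitude": np.full(n, 110.0) + rng.normal(0, 0.01, n),
                }
            )
        )
        return otu, frame

    def test_structured_phylum_has_larger_z(self):
        otu, frame = self.structured_table()
        table = decay_by_taxon(
            otu, frame, ["Structured", "Uniform"], n_boot=99, seed=0
        )
        z = table.set_index("taxon")["z"]
        assert z["Structured"] > z["Uniform"]

    def test_single_phylum_equals_all_sequence_run(self):
        otu, frame = self.structured_table()
        only = otu.select_otus(
            [o for o, t in otu.taxonomy.items() if "Structured" in t]
        )
        table = decay_by_taxon(only, frame, ["Structured"], n_boot=49, seed=1)
        assert len(table) == 2
        np.testing.assert_allclose(
            table.loc[0, ["z", "slope", "r_squared"]].astype(float),
            table.loc[1, ["z", "slope", "r_squared"]].astype(float),
            rtol=0, atol=1e-14,
        )

    def test_empty_phyla_list_gives_all_sequence_row_only(self):
        otu, frame = self.structured_table()
        table = decay_by_taxon(otu, frame, [], n_boot=49, seed=1)
        assert table["taxon"].tolist() == ["All sequences"]

    def test_sparse_phylum_skipped_with_warning(self):
        otu, frame = self.structured_table()
        tax = otu.taxonomy.copy()
        counts = otu.counts.copy()
        counts["rare"] = 0
        counts.loc[counts.index[0], "rare"] = 2
        tax["rare"] = "k__B; p__Rare"
        otu2 = OtuTable(counts, tax)
        with pytest.warns(UserWarning, match="Rare"):
            table = decay_by_taxon(otu2, frame, ["Rare"], n_boot=49, seed=1)
        assert "Rare" not in table["taxon"].tolist()


class TestUnbiasedness:
    def test_mean_z_within_two_ses_under_lognormal_noise(self):
        """200 seeded replicates at noise sd 0.2: the mean estimate brackets
        the true exponent within 2 Monte-Carlo SEs."""
        z_true = 0.115
        cfg = scaled_config(target_decay_z=z_true, decay_noise_sd=0.2)
        zs = np.empty(200)
        for s in range(200):
            data = simulate_pairwise_decay(cfg, seed=s, n_plots=15)
            zs[s] = fit_distance_decay(data.geo, data.community).z
        se = zs.std(ddof=1) / math.sqrt(zs.size)
        assert abs(zs.mean() - z_true) < 2 * se
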