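import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from taxadecay.core_tables import DistanceMatrix, SignalTable, ValidationError
from taxadecay.geochip import (
    CategoryRegistry,
    category_sums,
    default_registry,
    detection_filter,
    function_profile_pipeline,
    mean_normalize,
)
from taxadecay.matrix_regression import single_matrix_regression
from taxadecay.ordination import dca, log_transform_table
from taxadecay.synthetic import scaled_config, simulate_geochip


def make_signals(intensities: dict, categories: dict, sites: dict) -> SignalTable:
    """intensities: probe -> {sample: value}; undeclared cells are missing."""
    samples = list(sites)
    inten = pd.DataFrame(np.nan, index=samples, columns=list(intensities))
    for probe, cells in intensities.items():
        for sample, value in cells.items():
            inten.loc[sample, probe] = value
    return SignalTable(inten, pd.Series(categories), pd.Series(sites))


def hand_worked_fixture() -> SignalTable:
    """Two reserves of 10 samples, 30 probes in 3 categories, constant
    intensities so every processing step is hand-checkable.

    Sparse probes: f1 seen in 5/10 site-A samples (below threshold there,
    kept at B), u1 in 6/10 at A (kept) and 2/10 at B (masked), p10 in 3/10
    at A and 4/10 at B (masked everywhere, hence dropped).
    """
    a = [f"A{i}" for i in range(1, 11)]
    b = [f"B{i}" for i in range(1, 11)]
    sites = {s: "resA" for s in a} | {s: "resB" for s in b}
    intensities, categories = {}, {}
    for j in range(1, 11):
        probe = f"f{j}"
        categories[probe] = "FTHFS"
        seen = (a[:5] + b) if j == 1 else (a + b)
        intensities[probe] = {s: 2.0 for s in seen}
    for j in range(1, 11):
        probe = f"u{j}"
        categories[probe] = "ureC"
        seen = (a[:6] + b[:2]) if j == 1 else (a + b)
        intensities[probe] = {s: 3.0 for s in seen}
    for j in range(1, 11):
        probe = f"p{j}"
        categories[probe] = "ppx"
        seen = (a[:3] + b[:4]) if j == 10 else (a + b)
        intensities[probe] = {s: 5.0 for s in seen}
    return make_signals(intensities, categories, sites)


class TestCategoryRegistry:
    def test_default_has_18_unique_names(self):
        reg = default_registry()
        assert len(reg.names) == 18
        assert len(set(reg.names)) == 18

    def test_cycle_tags_cover_four_processes(self):
        reg = default_registry()
        cycles = {reg.cycle_of(name) for name in reg.names}
        assert cycles == {
            "carbon_fixation", "carbon_degradation", "nitrogen", "phosphorus"
        }

    def test_config_round_trip(self, tmp_path):
        path = tmp_path / "registry.tsv"
        path.write_text("# name\tcycle\nnifH\tnitrogen\nppk\tphosphorus\n")
        reg = CategoryRegistry.from_config(path)
        assert reg.names == ["nifH", "ppk"]
        assert reg.cycle_of("ppk") == "phosphorus"


class TestDetectionFilter:
    def test_five_of_ten_masked_for_that_reserve(self):
        table = hand_worked_fixture()
        out = detection_filter(table)
        assert out.intensities.loc[[f"A{i}" for i in range(1, 11)], "f1"].isna().all()
        assert (out.intensities.loc[[f"B{i}" for i in range(1, 11)], "f1"] == 2.0).all()

    def test_fully_detected_probe_untouched(self):
        out = detection_filter(hand_worked_fixture())
        assert (out.intensities["f2"] == 2.0).all()

    def test_kept_at_one_site_masked_at_other(self):
        out = detection_filter(hand_worked_fixture())
        a_vals = out.intensities.loc[[f"A{i}" for i in range(1, 7)], "u1"]
        assert (a_vals == 3.0).all()
        assert out.intensities.loc[[f"B{i}" for i in range(1, 11)], "u1"].isna().all()

    def test_probe_failing_everywhere_dropped(self):
        with pytest.warns(UserWarning, match="dropped"):
            out = detection_filter(hand_worked_fixture())
        assert "p10" not in out.probe_ids
        assert len(out.probe_ids) == 29

    def test_unequal_group_rescales_threshold_with_warning(self):
        sites = {"s1": "X", "s2": "X", "s3": "X", "s4": "X", "s5": "X"}
        intens = {
            "pr1": {"s1": 1.0, "s2": 1.0, "s3": 1.0},  # 3/5 >= ceil(6/10*5)=3
            "pr2": {"s1": 1.0, "s2": 1.0},  # 2/5 < 3 -> masked
        }
        cats = {"pr1": "nifH", "pr2": "nifH"}
        with pytest.warns(UserWarning, match="rescaled"):
            out = detection_filter(make_signals(intens, cats, sites))
        assert "pr1" in out.probe_ids
        assert "pr2" not in out.probe_ids

    def test_missing_site_mapping_rejected(self):
        table = hand_worked_fixture()
        table.site_of = None
        with pytest.raises(ValidationError, match="site_of"):
            detection_filter(table)


class TestMeanNormalize:
    def test_hand_arithmetic(self):
        # totals 100 and 300 -> mean 200; spot 10 in sample one -> 20
        sites = {"s1": "X", "s2": "X"}
        intens = {
            "pr1": {"s1": 10.0, "s2": 30.0},
            "pr2": {"s1": 90.0, "s2": 270.0},
        }
        cats = {"pr1": "nifH", "pr2": "ppk"}
        out = mean_normalize(make_signals(intens, cats, sites))
        assert abs(out.intensities.loc["s1", "pr1"] - 20.0) < 1e-12

    def test_equal_totals_identity(self):
        sites = {"s1": "X", "s2": "X"}
        intens = {"pr1": {"s1": 4.0, "s2": 6.0}, "pr2": {"s1": 6.0, "s2": 4.0}}
        cats = {"pr1": "nifH", "pr2": "ppk"}
        table = make_signals(intens, cats, sites)
        out = mean_normalize(table)
        np.testing.assert_allclose(
            out.intensities.to_numpy(), table.intensities.to_numpy(), atol=1e-12
        )

    def test_totals_equalized_to_mean(self):
        rng = np.random.default_rng(0)
        sites = {f"s{i}": "X" for i in range(6)}
        intens = {
            f"pr{j}": {f"s{i}": float(rng.uniform(1, 50)) for i in range(6)}
            for j in range(8)
        }
        cats = {f"pr{j}": "nifH" for j in range(8)}
        table = make_signals(intens, cats, sites)
        before = table.intensities.sum(axis=1)
        out = mean_normalize(table)
        after = out.intensities.sum(axis=1)
        np.testing.assert_allclose(after, before.mean(), atol=1e-9)

    def test_zero_total_sample_rejected(self):
        sites = {"s1": "X", "s2": "X"}
        intens = {"pr1": {"s1": 1.0}}
        cats = {"pr1": "nifH"}
        with pytest.raises(ValidationError, match="s2"):
            mean_normalize(make_signals(intens, cats, sites))


class TestCategorySums:
    def test_sums_detected_intensities(self):
        sites = {"s1": "X"}
        intens = {
            "pr1": {"s1": 1.0}, "pr2": {"s1": 2.0}, "pr3": {"s1": 3.0},
        }
        cats = {"pr1": "nifH", "pr2": "nifH", "pr3": "nifH"}
        with pytest.warns(UserWarning, match="no signal"):
            prof = category_sums(make_signals(intens, cats, sites))
        assert prof.sums.loc["s1", "nifH"] == 6.0
        assert prof.provenance["nifH"] == 3

    def test_masked_spot_contributes_zero(self):
        sites = {"s1": "X"}
        intens = {"pr1": {"s1": 1.0}, "pr2": {}}
        cats = {"pr1": "nifH", "pr2": "nifH"}
        with pytest.warns(UserWarning):
            prof = category_sums(make_signals(intens, cats, sites))
        assert prof.sums.loc["s1", "nifH"] == 1.0

    def test_unmapped_probes_excluded_with_warning(self):
        sites = {"s1": "X"}
        intens = {"pr1": {"s1": 1.0}, "pr2": {"s1": 9.0}}
        cats = {"pr1": "nifH", "pr2": "mystery_gene"}
        with pytest.warns(UserWarning, match="unregistered"):
            prof = category_sums(make_signals(intens, cats, sites))
        assert prof.sums.loc["s1"].sum() == 1.0

    def test_partition_conservation(self):
        """Summed over categories, the profile equals each sample's total
        over mapped probes."""
        rng = np.random.default_rng(1)
        reg = default_registry()
        sites = {f"s{i}": "X" for i in range(4)}
        intens = {
            f"pr{j}": {f"s{i}": float(rng.uniform(1, 9)) for i in range(4)}
            for j in range(36)
        }
        cats = {f"pr{j}": reg.names[j % 18] for j in range(36)}
        table = make_signals(intens, cats, sites)
        prof = category_sums(table)
        np.testing.assert_allclose(
            prof.sums.sum(axis=1), table.intensities.sum(axis=1), atol=1e-9
        )


class TestPipeline:
    def test_hand_worked_fixture_exact_profile(self):
        """Filtered probe set, equalized totals and category sums all match
        the hand computation for the 2-reserve fixture."""
        table = hand_worked_fixture()
        with pytest.warns(UserWarning):
            prof = function_profile_pipeline(table)
        # post-filter totals: A1-6 = 18+30+45 = 93; A7-10 = 90; B = 92
        mean_total = (6 * 93 + 4 * 90 + 10 * 92) / 20  # = 91.9
        np.testing.assert_allclose(prof.sums.sum(axis=1), mean_total, atol=1e-9)
        for s in [f"A{i}" for i in range(1, 7)]:
            assert abs(prof.sums.loc[s, "FTHFS"] - 18 * mean_total / 93) < 1e-9
            assert abs(prof.sums.loc[s, "ureC"] - 30 * mean_total / 93) < 1e-9
            assert abs(prof.sums.loc[s, "ppx"] - 45 * mean_total / 93) < 1e-9
        for s in [f"A{i}" for i in range(7, 11)]:
            assert abs(prof.sums.loc[s, "FTHFS"] - 18 * mean_total / 90) < 1e-9
            assert abs(prof.sums.loc[s, "ureC"] - 27 * mean_total / 90) < 1e-9
        for s in [f"B{i}" for i in range(1, 11)]:
            assert abs(prof.sums.loc[s, "FTHFS"] - 20 * mean_total / 92) < 1e-9
            assert abs(prof.sums.loc[s, "ureC"] - 27 * mean_total / 92) < 1e-9
            assert abs(prof.sums.loc[s, "ppx"] - 45 * mean_total / 92) < 1e-9
        other = [c for c in prof.sums.columns if c not in ("FTHFS", "ureC", "ppx")]
        assert (prof.sums[other] == 0).all().all()

    def test_deterministic_reruns(self):
        table = hand_worked_fixture()
        with pytest.warns(UserWarning):
            a = function_profile_pipeline(table)
        with pytest.warns(UserWarning):
            b = function_profile_pipeline(table)
        pd.testing.assert_frame_equal(a.sums, b.sums)

    def test_step_order_is_material(self):
        """Filter-then-normalize differs from normalize-then-filter: the
        pipeline's fixed order matches the former."""
        table = hand_worked_fixture()
        with pytest.warns(UserWarning):
            pipeline = function_profile_pipeline(table)
        with pytest.warns(UserWarning):
            swapped = category_sums(detection_filter(mean_normalize(table)))
        assert not np.allclose(
            pipeline.sums.to_numpy(), swapped.sums.to_numpy(), atol=1e-9
        )

    def test_normalization_shrinks_scaling_artifacts(self):
        """Per-sample lognormal scaling inflates the spread of sample totals;
        after the pipeline the coefficient of variation is strictly smaller."""
        cfg = scaled_config(n_sites=2, plots_per_site=10, n_probes=54,
                           geochip_scaling_sd=0.5, geochip_dropout=0.0)
        signals = simulate_geochip(cfg, seed=3)
        raw_prof = category_sums(signals)
        prof = function_profile_pipeline(signals)
        cv = lambda s: s.std(ddof=1) / s.mean()
        assert cv(prof.sums.sum(axis=1)) < cv(raw_prof.sums.sum(axis=1))

    def test_log_flag_applies_log1p_when_zero_categories_exist(self):
        table = hand_worked_fixture()
        with pytest.warns(UserWarning):
            prof = function_profile_pipeline(table, log=True)
        assert prof.log_transformed
        assert (prof.sums.to_numpy() >= 0).all()


class TestFunctionalConvergence:
    def test_site_invariant_means_show_no_site_clustering(self):
        """With true category means shared across sites, an MRM of the DCA
        configuration of log category sums against site membership is
        non-significant in >= 90% of 100 seeded replicates."""
        cfg = scaled_config(
            n_sites=2, plots_per_site=10, n_probes=36,
            geochip_site_effect_sd=0.0,
        )
        non_significant = 0
        n_rep = 100
        for seed in range(n_rep):
            signals = simulate_geochip(cfg, seed=seed)
            prof = function_profile_pipeline(signals)
            scores = dca(
                log_transform_table(prof.sums.loc[:, (prof.sums > 0).any()]),
                n_axes=2,
            ).sample_scores
            resp = DistanceMatrix(
                prof.sample_ids,
                squareform(pdist(scores.to_numpy())),
            )
            site = signals.site_of.loc[prof.sample_ids]
            indicator = (
                site.to_numpy()[:, None] != site.to_numpy()[None, :]
            ).astype(float)
            pred = DistanceMatrix(prof.sample_ids, indicator)
            res = single_matrix_regression(
                resp, pred, n_permutations=99, seed=seed
            )
            if res.p_r_squared > 0.05:
                non_significant += 1
        assert non_significant >= 90
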