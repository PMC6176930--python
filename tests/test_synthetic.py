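"""Generator behaviour: packing, growth, fate assignment, determinism."""

import numpy as np
import pandas as pd
import pytest

from micropat.geometry import InvalidKindError
from micropat.registration import register_colony
from micropat.spatial_stats import patterning_score, score_permutation_pvalue
from micropat.synthetic import (
    GeneratorConfig,
    PackingError,
    T_NEG,
    T_POS,
    assign_fates,
    colonies_to_table,
    grow_colony,
    sample_positions,
    simulate_experiment,
    simulate_intensities,
)


class TestSamplePositions:
    def test_zero_points(self, disc_m):
        assert sample_positions(disc_m, 0).shape == (0, 2)

    def test_all_points_inside(self, ellipse_m):
        pts = sample_positions(ellipse_m, 300, seed=0)
        rho = (pts[:, 0] / 120.0) ** 2 + (pts[:, 1] / 79.58) ** 2
        assert np.all(rho <= 1.0)

    def test_hollow_points_avoid_the_hole(self, hollow):
        pts = sample_positions(hollow, 300, seed=0)
        c = hollow.to_canonical(pts)
        rho_inner = (c[:, 0] / hollow.inner_semi_major) ** 2 + (
            c[:, 1] / hollow.inner_semi_minor
        ) ** 2
        assert np.all(rho_inner >= 1.0)

    def test_uniform_disc_mean_travel(self, disc_m):
        # E[r]/R = 2/3 for a uniform disc
        pts = sample_positions(disc_m, 10_000, profile="uniform",
                               min_separation=0.0, seed=1)
        travel = 100.0 * np.hypot(pts[:, 0], pts[:, 1]) / 97.5
        assert travel.mean() == pytest.approx(66.7, abs=1.0)

    def test_dome_profile_is_centre_weighted(self, disc_m):
        uni = sample_positions(disc_m, 10_000, profile="uniform",
                               min_separation=0.0, seed=1)
        dome = sample_positions(disc_m, 10_000, profile="dome",
                                min_separation=0.0, seed=1)
        travel = lambda p: (100.0 * np.hypot(p[:, 0], p[:, 1]) / 97.5).mean()
        assert travel(dome) < travel(uni) - 2.0

    def test_min_separation_enforced(self, disc_m):
        pts = sample_positions(disc_m, 200, min_separation=6.0, seed=2)
        from scipy.spatial.distance import pdist

        assert pdist(pts).min() >= 6.0

    def test_infeasible_packing_raises(self, disc_m):
        with pytest.raises(PackingError):
            sample_positions(disc_m, 2000, min_separation=6.0, seed=0)

    def test_deterministic_given_seed(self, ellipse_m):
        a = sample_positions(ellipse_m, 100, seed=7)
        b = sample_positions(ellipse_m, 100, seed=7)
        np.testing.assert_array_equal(a, b)


class TestGrowColony:
    @pytest.mark.parametrize(
        "seed_count,elapsed,doubling,expected",
        [(27, 0, 12, 27), (27, 24, 12, 108), (27, 48, 12, 432)],
    )
    def test_exponential_growth(self, seed_count, elapsed, doubling, expected):
        assert grow_colony(seed_count, elapsed, doubling) == expected

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            grow_colony(0, 10, 12)
        with pytest.raises(ValueError):
            grow_colony(10, 10, 0)


class TestAssignFates:
    def test_zero_fraction_all_negative(self, ellipse_m):
        pts = sample_positions(ellipse_m, 100, seed=0)
        labels = assign_fates(pts, ellipse_m, 0.0, "tips", 1.0, seed=0)
        assert set(labels) == {T_NEG}

    def test_tips_on_disc_is_invalid(self, disc_m):
        pts = sample_positions(disc_m, 50, seed=0)
        with pytest.raises(InvalidKindError):
            assign_fates(pts, disc_m, 20.0, "tips", 1.0, seed=0)

    def test_expected_count_binomial(self, ellipse_m):
        pts = sample_positions(ellipse_m, 400, seed=1)
        counts = [
            (assign_fates(pts, ellipse_m, 17.0, "tips", 1.0, seed=s) == T_POS).sum()
            for s in range(50)
        ]
        assert np.mean(counts) == pytest.approx(0.17 * 400, abs=6)

    def test_tips_bias_enriches_tips(self, ellipse_m):
        pts = sample_positions(ellipse_m, 300, seed=3)
        labels = assign_fates(pts, ellipse_m, 17.0, "tips", 1.0, seed=3)
        travel = 100.0 * np.hypot(pts[:, 0], pts[:, 1]) / 120.0
        assert travel[labels == T_POS].mean() > travel.mean() + 10

    def test_one_sided_mask(self, ellipse_m):
        pts = sample_positions(ellipse_m, 300, seed=4)
        labels = assign_fates(
            pts, ellipse_m, 17.0, "tips", 1.0, sided_mode="one_sided_B", seed=4
        )
        assert np.all(pts[labels == T_POS, 0] < 0)


class TestSimulateIntensities:
    def test_zero_spread_hits_the_mode(self):
        cells = pd.DataFrame({"t_label_true": [T_POS, T_NEG, T_POS]})
        model = {"tbra": {"neg_mode": 100.0, "pos_mode": 1000.0, "sd_log10": 1e-12}}
        out = simulate_intensities(cells, model, seed=0)
        assert out.loc[0, "tbra"] == pytest.approx(1000.0)
        assert out.loc[1, "tbra"] == pytest.approx(100.0)

    def test_empty_input(self):
        out = simulate_intensities(pd.DataFrame({"t_label_true": []}), seed=0)
        assert len(out) == 0

    def test_nonpositive_sd_rejected(self):
        cells = pd.DataFrame({"t_label_true": [T_NEG]})
        with pytest.raises(ValueError):
            simulate_intensities(cells, {"dapi": {"mode": 1.0, "sd_log10": 0.0}}, seed=0)


class TestSimulateExperiment:
    def test_colony_count_and_containment(self, disc_m):
        cfg = GeneratorConfig(shape="disc_m", n_colonies=20, seed=0)
        colonies = simulate_experiment(cfg)
        assert len(colonies) == 20
        for c in colonies:
            r = np.hypot(*c.positions().T)
            assert np.all(r <= 97.5)

    def test_determinism_byte_identical(self):
        cfg = GeneratorConfig(n_colonies=5, seed=42)
        t1 = colonies_to_table(simulate_experiment(cfg)).to_csv(sep="\t")
        t2 = colonies_to_table(simulate_experiment(GeneratorConfig(n_colonies=5, seed=42))).to_csv(sep="\t")
        assert t1 == t2

    def test_fraction_moments_recovered(self):
        cfg = GeneratorConfig(
            n_colonies=300,
            seed=1,
            t_fraction_mean=17.1,
            t_fraction_sd=7.5,
            sided_mixture={"two_sided": 0.4, "one_sided": 0.4, "undefined": 0.2, "none": 0.0},
        )
        colonies = simulate_experiment(cfg)
        pct = np.array(
            [100.0 * (c.labels("t_label_true") == T_POS).mean() for c in colonies]
        )
        # sample moments within 3 standard errors of the configured ones
        se_mean = 7.5 / np.sqrt(300)
        assert pct.mean() == pytest.approx(17.1, abs=3 * se_mean + 0.3)
        assert pct.std() == pytest.approx(7.5, abs=1.5)

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GeneratorConfig(sided_mixture={"two_sided": 0.5, "none": 0.1})

    def test_treatment_presets_cut_t_fraction(self):
        base = GeneratorConfig(n_colonies=40, seed=3)
        sb = GeneratorConfig(n_colonies=40, seed=3, treatment="SB")
        f = lambda cols: np.mean(
            [100.0 * (c.labels("t_label_true") == T_POS).mean() for c in cols]
        )
        f_base, f_sb = f(simulate_experiment(base)), f(simulate_experiment(sb))
        assert f_sb < f_base / 3.0

    def test_time_ramp_disables_bias_before_36h(self):
        cfg = GeneratorConfig(n_colonies=10, seed=4, timepoint_h=24.0,
                              sided_mixture={"two_sided": 1.0, "one_sided": 0.0,
                                             "undefined": 0.0, "none": 0.0})
        for c in simulate_experiment(cfg):
            assert c.metadata["bias_strength"] == 0.0

    def test_score_monotone_in_bias_strength(self):
        # mean patterning score non-decreasing over bias 0, 0.5, 1
        means = []
        for bias in (0.0, 0.5, 1.0):
            cfg = GeneratorConfig(
                n_colonies=300, seed=5, bias_strength=bias,
                t_fraction_mean=17.1, t_fraction_sd=7.5,
                sided_mixture={"two_sided": 1.0, "one_sided": 0.0,
                               "undefined": 0.0, "none": 0.0},
            )
            scores = []
            for c in simulate_experiment(cfg):
                c.cells["t_label"] = c.cells["t_label_true"]
                scores.append(patterning_score(register_colony(c)).score)
            means.append(np.nanmean(scores))
        assert means[0] < means[1] < means[2]

    def test_bias_zero_labels_independent_of_position(self):
        # permutation test non-significant at alpha=0.01 in >=95% of colonies
        cfg = GeneratorConfig(n_colonies=100, seed=6, bias_strength=0.0,
                              sided_mixture={"undefined": 1.0, "two_sided": 0.0,
                                             "one_sided": 0.0, "none": 0.0})
        ps = []
        for i, c in enumerate(simulate_experiment(cfg)):
            c.cells["t_label"] = c.cells["t_label_true"]
            ps.append(score_permutation_pvalue(register_colony(c), seed=i))
        assert np.mean(np.array(ps) > 0.01) >= 0.95
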