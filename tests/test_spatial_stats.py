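"""Patterning score, classification, neighbour and flower statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_colony
from micropat.geometry import Point, make_flower, make_shape
from micropat.registration import register_colony
from micropat.spatial_stats import (
    DensityFit,
    EmptyColonyError,
    FlowerStats,
    NeighbourSpec,
    UngateableError,
    classify_colony,
    concentration_proxy_map,
    density_response_fit,
    flower_stats,
    gate_t,
    neighbour_counts,
    neighbour_sweep,
    patterning_score,
    pfaffl_ratio,
    surface_coverage,
)
from micropat.synthetic import (
    GeneratorConfig,
    T_NEG,
    T_POS,
    assign_fates,
    sample_positions,
    simulate_experiment,
)


def _colony_with_travel(shape, travels_pos, travels_all_others):
    """Colony whose T+ / T- cells sit at prescribed travel percentages."""
    a = shape.semi_major
    pts, labels = [], []
    for i, t in enumerate(travels_pos):
        pts.append((a * t / 100.0, 0.0))
        labels.append(T_POS)
    for t in travels_all_others:
        pts.append((-a * t / 100.0, 0.0))
        labels.append(T_NEG)
    return make_colony(shape, pts, labels)


class TestPatterningScore:
    def test_uniform_travel_gives_zero(self, ellipse_m):
        colony = _colony_with_travel(ellipse_m, [40.0, 40.0], [40.0, 40.0])
        assert patterning_score(colony).score == pytest.approx(0.0, abs=1e-12)

    def test_double_travel_gives_one(self, ellipse_m):
        # mean travel T+ = 80, mean travel all = 40 -> score 1
        colony = _colony_with_travel(ellipse_m, [80.0], [(40.0 * 8 - 80.0) / 7.0] * 7)
        res = patterning_score(colony)
        assert res.mean_travel_t_pos == pytest.approx(80.0)
        assert res.mean_travel_all == pytest.approx(40.0)
        assert res.score == pytest.approx(1.0, abs=1e-12)

    def test_half_travel_gives_minus_one(self, ellipse_m):
        # mean travel T+ = 20, all = 40 -> score log2(0.5) = -1
        colony = _colony_with_travel(ellipse_m, [20.0], [(40.0 * 8 - 20.0) / 7.0] * 7)
        assert patterning_score(colony).score == pytest.approx(-1.0, abs=1e-12)

    def test_no_t_cells_undefined(self, ellipse_m):
        colony = make_colony(ellipse_m, [(0.0, 0.0), (10.0, 0.0)], [T_NEG, T_NEG])
        res = patterning_score(colony)
        assert math.isnan(res.score)
        assert res.category == "none"

    def test_empty_colony_raises(self, ellipse_m):
        colony = make_colony(ellipse_m, np.empty((0, 2)), [])
        with pytest.raises(EmptyColonyError):
            patterning_score(colony)

    def test_invariant_under_rigid_motion(self):
        base = make_shape("ellipse", semi_major=120.0, semi_minor=79.58)
        pts = sample_positions(base, 150, seed=0)
        labels = assign_fates(pts, base, 17.0, "tips", 1.0, seed=0)
        score0 = patterning_score(make_colony(base, pts, labels)).score
        ang, shift = 0.987, np.array([412.0, -88.0])
        rot = np.array([[math.cos(ang), -math.sin(ang)],
                        [math.sin(ang), math.cos(ang)]])
        moved_shape = make_shape(
            "ellipse", semi_major=120.0, semi_minor=79.58,
            orientation=ang, centre=Point(*shift),
        )
        moved = make_colony(moved_shape, pts @ rot.T + shift, labels)
        score1 = patterning_score(register_colony(moved)).score
        assert score1 == pytest.approx(score0, abs=1e-10)


class TestClassifyColony:
    def test_no_t_pos_is_none(self, ellipse_m):
        colony = make_colony(ellipse_m, [(0.0, 0.0)], [T_NEG])
        res = patterning_score(colony)
        assert classify_colony(res, colony) == "none"

    def test_negative_score_is_undefined(self, ellipse_m):
        colony = _colony_with_travel(ellipse_m, [20.0], [50.0] * 7)
        res = patterning_score(colony)
        assert res.score < 0
        assert classify_colony(res, colony) == "undefined"

    def test_two_sided_requires_both_tips(self, ellipse_m):
        pts = [(110.0, 0.0), (-110.0, 0.0), (105.0, 0.0), (10.0, 0.0), (-10.0, 0.0)]
        labels = [T_POS, T_POS, T_POS, T_NEG, T_NEG]
        colony = make_colony(ellipse_m, pts, labels)
        res = patterning_score(colony)
        assert classify_colony(res, colony) == "two_sided"

    def test_one_sided_generator_recovered(self, ellipse_m):
        hits = 0
        n = 100
        cfg = GeneratorConfig(
            n_colonies=n, seed=8, bias_strength=1.0,
            sided_mixture={"one_sided": 1.0, "two_sided": 0.0,
                           "undefined": 0.0, "none": 0.0},
        )
        for i, c in enumerate(simulate_experiment(cfg)):
            c.cells["t_label"] = c.cells["t_label_true"]
            reg = register_colony(c)
            res = patterning_score(reg)
            if classify_colony(res, reg, seed=i) == "one_sided":
                hits += 1
        assert hits >= 0.9 * n

    def test_disc_patterned_category(self, disc_m):
        pts = [(90.0, 0.0), (0.0, 90.0), (5.0, 0.0), (0.0, 5.0)]
        labels = [T_POS, T_POS, T_NEG, T_NEG]
        colony = make_colony(disc_m, pts, labels)
        res = patterning_score(colony)
        assert classify_colony(res, colony) == "patterned"


class TestNeighbourCounts:
    def test_single_cell(self):
        assert neighbour_counts(np.array([[0.0, 0.0]]))[0] == 0

    def test_small_cluster(self):
        pts = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 8.0]])
        np.testing.assert_array_equal(neighbour_counts(pts), [2, 2, 2])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(-200, 200, size=(500, 2))
        counts = neighbour_counts(pts, NeighbourSpec(radius=75.0))
        diffs = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        brute = (diffs <= 75.0).sum(axis=1) - 1
        np.testing.assert_array_equal(counts, brute)

    def test_symmetric_counting(self):
        rng = np.random.default_rng(10)
        pts = rng.uniform(0, 100, size=(100, 2))
        counts = neighbour_counts(pts, NeighbourSpec(radius=30.0))
        # total neighbour relations must be even (i~j counted both ways)
        assert counts.sum() % 2 == 0

    def test_3d_metric_separates_planes(self):
        pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 100.0]])
        assert neighbour_counts(pts, NeighbourSpec(radius=50.0, metric="planar_2d"))[0] == 1
        assert neighbour_counts(pts, NeighbourSpec(radius=50.0, metric="euclidean_3d"))[0] == 0


class TestNeighbourSweep:
    def test_counts_monotone_in_radius(self, ellipse_m):
        pts = sample_positions(ellipse_m, 200, seed=11)
        labels = np.array([T_NEG] * 200)
        per_cell, _ = neighbour_sweep([(pts, labels)], [25.0, 75.0, 150.0])
        wide = per_cell.pivot_table(index=per_cell.groupby("radius_um").cumcount(),
                                    columns="radius_um", values="count")
        assert (wide[75.0] >= wide[25.0]).all()
        assert (wide[150.0] >= wide[75.0]).all()

    def test_bias_zero_labels_have_similar_medians(self, ellipse_m):
        units = []
        rng = np.random.SeedSequence(12)
        for ch in rng.spawn(30):
            g = np.random.default_rng(ch)
            pts = sample_positions(ellipse_m, 200, seed=g)
            labels = assign_fates(pts, ellipse_m, 17.0, "tips", 0.0, seed=g)
            units.append((pts, labels))
        _, summary = neighbour_sweep(units, [25.0, 75.0, 150.0])
        for r in (25.0, 75.0, 150.0):
            sub = summary[summary.radius_um == r].set_index("t_label")["median"]
            overall = sub.mean()
            assert abs(sub[T_POS] - sub[T_NEG]) / overall <= 0.05

    def test_tips_mode_t_pos_in_lower_density(self, ellipse_m):
        units = []
        rng = np.random.SeedSequence(13)
        for ch in rng.spawn(30):
            g = np.random.default_rng(ch)
            pts = sample_positions(ellipse_m, 200, seed=g)
            labels = assign_fates(pts, ellipse_m, 17.0, "tips", 1.0, seed=g)
            units.append((pts, labels))
        _, summary = neighbour_sweep(units, [75.0])
        sub = summary.set_index("t_label")["median"]
        assert sub[T_POS] < sub[T_NEG]


class TestConcentrationProxy:
    def test_no_cells_all_zero(self):
        _, _, field = concentration_proxy_map(np.empty((0, 2)), 100.0, 10.0)
        assert np.all(field == 0)

    def test_flower_centre_exceeds_tips_at_long_range(self):
        from micropat.synthetic import simulate_flower_experiment

        layout = make_flower()
        flowers = simulate_flower_experiment(layout, 1, seed=3, n_cells_per_petal=200)
        pos = np.vstack([p.positions() for p in flowers[0]])
        a, d = layout.petal.semi_major, layout.centre_offset

        def node_value(field, xs, ys, x, y):
            return field[np.argmin(np.abs(ys - y)), np.argmin(np.abs(xs - x))]

        xs, ys, f100 = concentration_proxy_map(pos, 100.0, 10.0)
        centre = node_value(f100, xs, ys, 0.0, 0.0)
        tips = [
            node_value(f100, xs, ys, (d + a) * math.cos(t), (d + a) * math.sin(t))
            for t in layout.petal_angles
        ]
        assert centre > max(tips)
        xs, ys, f25 = concentration_proxy_map(pos, 25.0, 10.0)
        centre25 = node_value(f25, xs, ys, 0.0, 0.0)
        assert centre25 <= f25.max()  # petal interiors reach at least as high


class TestFlowerStats:
    def _flower(self, pcts, layout, seed=0):
        """One flower with prescribed per-petal T+ percentages (registered)."""
        petals = []
        rng = np.random.SeedSequence(seed)
        for j, (pct, ch) in enumerate(zip(pcts, rng.spawn(4))):
            g = np.random.default_rng(ch)
            shape = layout.petal.canonical()
            pts = sample_positions(shape, 100, seed=g)
            labels = assign_fates(pts, shape, pct, "random", 0.0, seed=g)
            # force the exact count for a deterministic percentage
            labels[:] = T_NEG
            k = round(pct)
            labels[:k] = T_POS
            petals.append(make_colony(shape, pts, labels, colony_id=f"p{j}"))
        return petals

    def test_within_flower_mad_worked_example(self):
        layout = make_flower()
        stats = flower_stats([self._flower([10, 10, 20, 20], layout)])
        assert stats.within_flower_mad.iloc[0] == pytest.approx(5.0)

    def test_identical_petals_zero_mads(self):
        layout = make_flower()
        flowers = [self._flower([15, 15, 15, 15], layout, seed=s) for s in range(3)]
        stats = flower_stats(flowers)
        assert np.allclose(stats.within_flower_mad, 0.0)
        assert stats.across_flower_mad == pytest.approx(0.0)

    def test_across_flower_mad_hand_computed(self):
        layout = make_flower()
        flowers = [
            self._flower(p, layout, seed=s)
            for s, p in enumerate([[10, 10, 10, 10], [20, 20, 20, 20], [30, 30, 30, 30]])
        ]
        stats = flower_stats(flowers)
        # flower means 10, 20, 30 -> MAD = mean(|x - 20|) = 20/3
        assert stats.across_flower_mad == pytest.approx(20.0 / 3.0)

    def test_identical_tip_percentages_zero_ratio(self):
        layout = make_flower()
        a = layout.petal.semi_major
        shape = layout.petal.canonical()
        pts = [(-0.9 * a, 0.0), (0.9 * a, 0.0), (0.0, 0.0), (0.0, 10.0)]
        labels = [T_POS, T_POS, T_NEG, T_NEG]
        petals = [make_colony(shape, pts, labels, colony_id=f"p{j}") for j in range(4)]
        stats = flower_stats([petals])
        assert np.allclose(stats.petals["log2_inner_outer"], 0.0)

    def test_incomplete_flower_raises(self):
        layout = make_flower()
        with pytest.raises(ValueError):
            flower_stats([self._flower([10, 10, 20, 20], layout)[:3]])


class TestGateT:
    def test_bimodal_recovery_within_one_point(self):
        rng = np.random.default_rng(14)
        n = 5000
        truth = rng.uniform(size=n) < 0.17
        log_int = np.where(truth, 3.0, 2.0) + rng.normal(0, 0.2, size=n)
        table = pd.DataFrame({"tbra": 10.0**log_int})
        labels = gate_t(table)
        recovered = 100.0 * (labels == T_POS).mean()
        assert recovered == pytest.approx(100.0 * truth.mean(), abs=1.0)

    def test_fixed_threshold_strict_inequality(self):
        table = pd.DataFrame({"tbra": [100.0, 100.0001, 50.0]})
        labels = gate_t(table, method="fixed_threshold", threshold=100.0)
        assert list(labels) == [T_NEG, T_POS, T_NEG]

    def test_all_below_threshold_zero_positive(self):
        table = pd.DataFrame({"tbra": np.full(100, 10.0)})
        labels = gate_t(table, method="fixed_threshold", threshold=50.0)
        assert (labels == T_POS).sum() == 0

    def test_degenerate_unimodal_falls_back_or_raises(self):
        rng = np.random.default_rng(15)
        table = pd.DataFrame({"tbra": 10 ** rng.normal(2.0, 0.05, size=500)})
        with pytest.raises(UngateableError):
            gate_t(table)
        labels = gate_t(table, threshold=1e4)
        assert (labels == T_POS).sum() == 0


class TestSurfaceCoverage:
    def test_unconfined_unit_conversion(self):
        # 5,000 nuclei in 1 mm^2 -> 5e5 cells/cm^2
        assert surface_coverage("unconfined", n_cells=5000, area_um2=1e6) == pytest.approx(5e5)

    def test_micropatterned_product(self):
        assert surface_coverage(
            "micropatterned", colonies_per_cm2=550, mean_cells_per_colony=110
        ) == pytest.approx(60_500)

    def test_zero_nuclei(self):
        assert surface_coverage("unconfined", n_cells=0, area_um2=1e6) == 0.0

    def test_zero_area_invalid(self):
        with pytest.raises(ValueError):
            surface_coverage("unconfined", n_cells=10, area_um2=0.0)


class TestDensityFit:
    def test_collinear_points_zero_residuals(self):
        x = np.array([2e3, 1e4, 5e4])
        y = 30.0 - 8.0 * np.log10(x)
        fit = density_response_fit(x, y)
        assert fit.slope == pytest.approx(-8.0)
        pred = fit.predict(x)
        np.testing.assert_allclose(pred["fit"], y, atol=1e-8)
        np.testing.assert_allclose(pred["ci_high"] - pred["ci_low"], 0.0, atol=1e-6)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            density_response_fit([1e3, 1e4], [10.0, 5.0])

    def test_constant_covariate_singular(self):
        with pytest.raises(np.linalg.LinAlgError):
            density_response_fit([1e4, 1e4, 1e4], [1.0, 2.0, 3.0])

    def test_negative_slope_on_density_like_data(self):
        rng = np.random.default_rng(16)
        x = 10 ** rng.uniform(3.3, 4.7, size=30)
        y = 25.0 - 6.0 * np.log10(x) + rng.normal(0, 1.0, size=30)
        fit = density_response_fit(x, y)
        assert fit.slope < 0
        lo, hi = fit.slope_ci()
        assert lo < -6.0 < hi


class TestHollowInversion:
    def test_central_mode_median_score_negative(self):
        cfg = GeneratorConfig(shape="hollow_ellipse", n_colonies=40, seed=17)
        scores = []
        for c in simulate_experiment(cfg):
            c.cells["t_label"] = c.cells["t_label_true"]
            scores.append(patterning_score(register_colony(c)).score)
        assert np.nanmedian(scores) < 0


class TestPfaffl:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((2.0, 0.0, 2.0, 0.0), 1.0),
            ((2.0, 2.0, 2.0, 1.0), 2.0),
            ((1.9, 3.0, 2.0, 0.0), 6.859),
        ],
    )
    def test_worked_examples(self, args, expected):
        assert pfaffl_ratio(*args) == pytest.approx(expected, abs=1e-3)

    def test_efficiency_must_exceed_one(self):
        with pytest.raises(ValueError):
            pfaffl_ratio(1.0, 1.0, 2.0, 1.0)
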