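"""Focality and somatotopy metrics against enumeration oracles."""

import numpy as np
import pytest

from tmsfocal import (
    CoilPose,
    IPReport,
    MetricConfig,
    aad,
    ard,
    field_loss,
    focality_improvement,
    peak_deviation,
    summarize_batch,
)
from tmsfocal.forward import FieldMap
from tmsfocal.metrics import suprathreshold_nodes
from tmsfocal.phantom import TargetSet


def fmap(points, mags, direction=(1.0, 0.0, 0.0)):
    points = np.asarray(points, float)
    mags = np.asarray(mags, float)
    return FieldMap(points=points, E=np.outer(mags, np.asarray(direction)))


def grid_field(seed=0, n=200, scale=30.0):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-scale, scale, size=(n, 3))
    center = np.array([5.0, -3.0, 2.0])
    mags = 100.0 * np.exp(-np.linalg.norm(pts - center, axis=1) ** 2 / 300.0)
    return fmap(pts, mags)


class TestAad:
    def test_only_target_node_suprathreshold(self):
        f = fmap([[0, 0, 0], [9, 0, 0]], [100.0, 10.0])
        assert aad(f, [0, 0, 0], 0.8) == 0.0

    def test_two_nodes_arithmetic_mean(self):
        f = fmap([[3, 0, 0], [0, 5, 0], [20, 0, 0]], [100.0, 95.0, 1.0])
        assert np.isclose(aad(f, [0, 0, 0], 0.9), 4.0)

    def test_matches_enumeration_oracle(self):
        f = grid_field()
        target = np.array([1.0, 2.0, -4.0])
        for thr in (0.7, 0.8, 0.9):
            mags = f.magnitude
            sel = mags >= thr * mags.max()
            expected = np.linalg.norm(f.points[sel] - target, axis=1).mean()
            assert abs(aad(f, target, thr) - expected) < 1e-12

    def test_threshold_set_nesting(self):
        f = grid_field(seed=3)
        sets = [set(suprathreshold_nodes(f, t)) for t in (0.7, 0.8, 0.9)]
        assert sets[2] <= sets[1] <= sets[0]
        assert len(sets[2]) >= 1

    def test_zero_field_rejected(self):
        f = fmap([[0, 0, 0]], [0.0])
        with pytest.raises(ValueError, match="zero"):
            aad(f, [0, 0, 0], 0.8)


def three_target_set():
    targets = np.array([[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]])
    return TargetSet(targets=targets, neighbors=[[1], [0, 2], [1]],
                     nearest_obs_nodes=None, spacing_mean=10.0, spacing_std=0.0)


class TestArd:
    def setup_method(self):
        # one observation node per target (n_avg_nodes=1 isolates the ratio)
        self.ts = three_target_set()

    def field(self, mags):
        return fmap(self.ts.targets, mags)

    def test_equal_neighbor_fields_give_zero(self):
        assert ard(self.field([80, 80, 80]), self.ts, 1, 1) == 0.0

    def test_vanishing_neighbors_give_one(self):
        assert ard(self.field([0.0, 90.0, 0.0]), self.ts, 1, 1) == 1.0

    def test_arithmetic_example(self):
        # target 100 V/m, neighbours 80 and 60 -> 1 - (0.8 + 0.6)/2 = 0.30
        assert np.isclose(ard(self.field([80, 100, 60]), self.ts, 1, 1), 0.30)

    def test_invariant_to_global_rescaling(self):
        a = ard(self.field([70, 90, 50]), self.ts, 1, 1)
        b = ard(self.field([700, 900, 500]), self.ts, 1, 1)
        assert np.isclose(a, b, rtol=1e-12)

    def test_edge_target_uses_existing_neighbors(self):
        val = ard(self.field([100, 50, 100]), self.ts, 1, target_index=0)
        assert np.isclose(val, 0.5)

    def test_errors(self):
        lonely = TargetSet(targets=np.array([[0.0, 0, 0]]), neighbors=[[]],
                           nearest_obs_nodes=None, spacing_mean=0, spacing_std=0)
        with pytest.raises(ValueError, match="neighbour"):
            ard(fmap([[0, 0, 0]], [1.0]), lonely, 1, 0)
        with pytest.raises(ValueError, match="zero field"):
            ard(self.field([50, 0.0, 50]), self.ts, 1, 1)


class TestFieldLoss:
    def test_identical_fields(self):
        f = grid_field()
        assert field_loss(f, f, [0, 0, 0]) == 0.0

    def test_before_100_after_80(self):
        pts = [[0.0, 0, 0]]
        assert np.isclose(field_loss(fmap(pts, [100.0]), fmap(pts, [80.0]),
                                     [0, 0, 0], 1), 25.0)

    def test_gain_is_negative(self):
        pts = [[0.0, 0, 0]]
        assert np.isclose(field_loss(fmap(pts, [90.0]), fmap(pts, [100.0]),
                                     [0, 0, 0], 1), -10.0)

    def test_swap_antisymmetry_mapping(self):
        pts = [[0.0, 0, 0]]
        a, b = fmap(pts, [87.0]), fmap(pts, [119.0])
        x = field_loss(a, b, [0, 0, 0], 1)
        y = field_loss(b, a, [0, 0, 0], 1)
        assert np.isclose(y, 100.0 * (1.0 / (1.0 + x / 100.0) - 1.0), rtol=1e-12)


class TestPeakDeviation:
    def test_single_dominant_node(self):
        # 51 nodes: the 0.99 quantile falls between the dominant node and
        # the uniform background, so only the dominant node is selected
        pts = np.concatenate([[[6.0, 0.0, 0.0]], np.zeros((50, 3))])
        mags = np.concatenate([[100.0], np.ones(50)])
        assert np.isclose(peak_deviation(fmap(pts, mags), [0, 0, 0], 0.99), 6.0)

    def test_symmetric_pair_centers_on_target(self):
        pts = np.concatenate([[[5.0, 0, 0], [-5.0, 0, 0]], np.zeros((198, 3))])
        mags = np.concatenate([[100.0, 100.0], np.ones(198)])
        assert peak_deviation(fmap(pts, mags), [0, 0, 0], 0.99) < 1e-12

    def test_matches_enumeration_oracle(self):
        f = grid_field(seed=5)
        target = np.array([-2.0, 1.0, 3.0])
        mags = f.magnitude
        cut = np.quantile(mags, 0.99)
        expected = np.linalg.norm(f.points[mags >= cut].mean(axis=0) - target)
        assert abs(peak_deviation(f, target, 0.99) - expected) < 1e-12


def report(aad_i, aad_f, df_i, df_f, ard_i=0.1, ard_f=0.12):
    return IPReport(target=(0, 0, 0), aad_initial=aad_i, aad_final=aad_f,
                    df_initial=df_i, df_final=df_f, ard_initial=ard_i,
                    ard_final=ard_f, field_loss=5.0, peak_dev_initial=7.0,
                    peak_dev_final=5.0, improvement=0.0,
                    pose_initial=CoilPose(center=(0, 0, 0)),
                    pose_final=CoilPose(center=(0, 0, 0)))


class TestFocalityImprovement:
    def test_identity_gives_zero(self):
        assert focality_improvement(report(10.0, 10.0, 1.0, 1.0)) == 0.0

    def test_zero_final_gives_one(self):
        assert focality_improvement(report(10.0, 0.0, 1.0, 1.0)) == 1.0

    def test_arithmetic_example(self):
        val = focality_improvement(report(10.0, 6.27, 1.015, 1.02))
        assert np.isclose(val, 1.0 - 6.3954 / 10.15, atol=1e-10)
        assert round(val, 4) == 0.3699

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            focality_improvement(report(0.0, 1.0, 1.0, 1.0))


class TestSummarizeBatch:
    def test_identical_ard_gives_p_one(self):
        reps = [report(6.0, 5.0, 1.0, 1.0, 0.2, 0.2),
                report(8.0, 6.0, 1.0, 1.0, 0.3, 0.3)]
        s = summarize_batch(reps)
        assert s.loc["ard_paired_ttest_p", "mean"] == 1.0
        assert np.isclose(s.loc["aad_initial", "mean"], 7.0)
        assert np.isclose(s.loc["aad_initial", "std"], np.sqrt(2.0))

    def test_map_value_products(self):
        s = summarize_batch([report(6.27, 6.27, 1.02, 1.02)])
        assert np.isclose(s.loc["map_value_final", "mean"], 1.05 * 1.02 * 6.27)
        assert "ard_paired_ttest_p" not in s.index  # single run: no t-test

    def test_paired_ttest_detects_shift(self):
        rng = np.random.default_rng(0)
        reps = [report(8.0, 6.0, 1.0, 1.0, a, a + 0.05 + 0.01 * rng.standard_normal())
                for a in rng.uniform(0.1, 0.3, 8)]
        s = summarize_batch(reps)
        assert s.loc["ard_paired_ttest_p", "mean"] < 0.05
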