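"""Dice / overlap set arithmetic and the permutation machinery."""

from __future__ import annotations

import numpy as np
import pytest

from fcnm import dice, null_networks, overlap_proportion, perm_test_dice
from fcnm.compare import (
    CanonicalAtlas,
    CompareError,
    OverlapResult,
    report,
    sample_random_foci,
)


def _vol(shape, idx):
    v = np.zeros(shape, bool)
    for i in idx:
        v[i] = True
    return v


class TestDice:
    def test_identical_nonempty_is_one(self):
        a = _vol((4, 4, 4), [(0, 0, 0), (1, 1, 1)])
        assert dice(a, a.copy()) == 1.0

    def test_disjoint_is_zero(self):
        a = _vol((4, 4, 4), [(0, 0, 0)])
        b = _vol((4, 4, 4), [(3, 3, 3)])
        assert dice(a, b) == 0.0

    def test_counting_example(self):
        a = np.zeros(20, bool)
        b = np.zeros(20, bool)
        a[:10] = True
        b[5:15] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.uniform(size=(6, 6, 6)) > 0.6
            b = rng.uniform(size=(6, 6, 6)) > 0.6
            d = dice(a, b)
            assert d == dice(b, a)
            assert 0.0 <= d <= 1.0

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(1)
        shape = (30, 30, 30)
        for _ in range(5):
            a = rng.uniform(size=shape) > 0.7
            b = rng.uniform(size=shape) > 0.7
            sa = {tuple(v) for v in np.argwhere(a)}
            sb = {tuple(v) for v in np.argwhere(b)}
            expect = 2 * len(sa & sb) / (len(sa) + len(sb))
            assert dice(a, b) == pytest.approx(expect, abs=1e-12)

    def test_both_empty_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert dice(np.zeros(3, bool), np.zeros(3, bool)) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(CompareError):
            dice(np.zeros(3, bool), np.zeros(4, bool))


class TestOverlapProportion:
    def _atlas(self, shape=(6, 6, 6)):
        vol = np.zeros(shape, np.int16)
        vol[:3] = 1
        vol[3:] = 7
        return CanonicalAtlas(volume=vol, labels={1: "visual", 7: "default"})

    def test_superset_gives_one(self):
        atlas = self._atlas()
        net = np.ones((6, 6, 6), bool)
        assert overlap_proportion(net, atlas, 1) == 1.0

    def test_disjoint_gives_zero(self):
        atlas = self._atlas()
        net = _vol((6, 6, 6), [(5, 0, 0)])
        assert overlap_proportion(net, atlas, 1) == 0.0

    def test_counting(self):
        atlas = self._atlas()
        net = np.zeros((6, 6, 6), bool)
        net[0, :3, :3] = True  # 9 voxels inside label 1 (108 voxels)
        assert overlap_proportion(net, atlas, 1) == pytest.approx(9 / 108)

    def test_monotone_in_network(self):
        rng = np.random.default_rng(2)
        atlas = self._atlas()
        net = rng.uniform(size=(6, 6, 6)) > 0.8
        grown = net | (rng.uniform(size=(6, 6, 6)) > 0.8)
        assert overlap_proportion(grown, atlas, 7) >= overlap_proportion(net, atlas, 7)

    def test_empty_label_rejected(self):
        atlas = CanonicalAtlas(volume=np.zeros((3, 3, 3), np.int16), labels={1: "visual"})
        with pytest.raises(CompareError, match="no voxels"):
            overlap_proportion(np.ones((3, 3, 3), bool), atlas, 1)

    def test_set_arithmetic_oracle(self):
        rng = np.random.default_rng(3)
        vol = rng.integers(0, 3, size=(30, 30, 30)).astype(np.int16)
        atlas = CanonicalAtlas(volume=vol, labels={1: "visual", 2: "somatomotor"})
        net = rng.uniform(size=(30, 30, 30)) > 0.5
        for label in (1, 2):
            c = {tuple(v) for v in np.argwhere(vol == label)}
            n = {tuple(v) for v in np.argwhere(net)}
            assert overlap_proportion(net, atlas, label) == pytest.approx(
                len(n & c) / len(c), abs=1e-12
            )


class TestPermTest:
    def _setup(self, small_grid):
        atlas_vol = np.zeros(small_grid.shape, np.int16)
        atlas_vol[:5] = 1
        atlas_vol[5:] = 7
        atlas = CanonicalAtlas(volume=atlas_vol, labels={1: "visual", 7: "default"})
        return atlas

    def test_observed_above_all_nulls_gives_minimum_p(self, small_grid):
        atlas = self._setup(small_grid)
        network = atlas.label_mask(1)  # observed dice = 1
        nulls = [_vol(small_grid.shape, [(9, 0, 0)]) for _ in range(199)]
        p = perm_test_dice(
            network, atlas, 1, [2], None, small_grid, null_masks=nulls
        )
        assert p == pytest.approx(1 / 200)

    def test_observed_below_all_nulls_gives_p_one(self, small_grid):
        atlas = self._setup(small_grid)
        network = _vol(small_grid.shape, [(9, 11, 9)])  # dice ~ 0 with label 1
        nulls = [atlas.label_mask(1) for _ in range(199)]
        p = perm_test_dice(network, atlas, 1, [2], None, small_grid, null_masks=nulls)
        assert p == 1.0

    def test_determinism(self, small_grid, tiny_engine):
        atlas = self._setup(small_grid)
        net = tiny_engine.derive_network(
            sample_random_foci([2, 2], small_grid, np.random.default_rng(5))
        )
        args = (net, atlas, 1, [2, 2], tiny_engine.derive_network, small_grid)
        p1 = perm_test_dice(*args, n_perm=100, rng_seed=11)
        p2 = perm_test_dice(*args, n_perm=100, rng_seed=11)
        assert p1 == p2

    def test_degenerate_null_is_error(self, small_grid):
        atlas = self._setup(small_grid)
        nulls = [np.zeros(small_grid.shape, bool) for _ in range(150)]
        with pytest.raises(CompareError, match="degenerate"):
            perm_test_dice(
                atlas.label_mask(1), atlas, 1, [2], None, small_grid, null_masks=nulls
            )

    def test_too_few_permutations_rejected(self, small_grid):
        atlas = self._setup(small_grid)
        with pytest.raises(CompareError, match="n_perm"):
            perm_test_dice(
                atlas.label_mask(1), atlas, 1, [2], None, small_grid, n_perm=10
            )


class TestNullNetworks:
    def test_reproducible_given_seed(self, small_grid, tiny_engine):
        actual = tiny_engine.derive_network(
            sample_random_foci([2, 2], small_grid, np.random.default_rng(1))
        )
        nd1 = null_networks(actual, [2, 2], tiny_engine.derive_network, small_grid, 5, 3)
        nd2 = null_networks(actual, [2, 2], tiny_engine.derive_network, small_grid, 5, 3)
        np.testing.assert_array_equal(nd1.dice, nd2.dice)

    def test_empty_actual_gives_all_zero_dice(self, small_grid, tiny_engine):
        actual = np.zeros(small_grid.shape, bool)
        nd = null_networks(actual, [2], tiny_engine.derive_network, small_grid, 4, 0)
        np.testing.assert_array_equal(nd.dice, 0.0)

    def test_replicate_equal_to_actual_scores_one(self, small_grid):
        target = _vol(small_grid.shape, [(3, 3, 3), (4, 4, 4)])
        nd = null_networks(target, [2], lambda foci: target, small_grid, 3, 0)
        np.testing.assert_array_equal(nd.dice, 1.0)

    def test_zero_replicates_rejected(self, small_grid):
        with pytest.raises(CompareError):
            null_networks(np.zeros(small_grid.shape, bool), [2], None, small_grid, 0, 0)


class TestReport:
    def _overlaps(self):
        out = []
        for direction in ("increase", "decrease"):
            for label in range(1, 9):
                out.append(
                    OverlapResult(
                        direction=direction,
                        label=label,
                        label_name=f"net{label}",
                        overlap_proportion=label / 10,
                        dice=label / 20,
                        p_perm=0.5,
                    )
                )
        return out

    def test_two_directions_times_eight_labels(self):
        frame = report(self._overlaps())
        assert len(frame) == 16

    def test_proportions_echoed_exactly_on_percent_scale(self):
        frame = report(self._overlaps())
        assert frame["overlap_pct"].iloc[0] == pytest.approx(10.0)

    def test_roundtrip_through_tsv(self, tmp_path):
        import pandas as pd

        frame = report(self._overlaps())
        path = tmp_path / "report.tsv"
        frame.to_csv(path, sep="\t", index=False)
        again = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(frame, again, check_dtype=False)

    def test_empty_rejected(self):
        with pytest.raises(CompareError):
            report([])
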