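"""Aggregation: time profiles, susceptibility, correlation maps, pair extraction."""

import numpy as np
import pytest
from scipy.stats import pearsonr

import nonaffine as na
from nonaffine import stats, synthetic as syn


@pytest.fixture(scope="module")
def helix_nbs(helix):
    nbs, failures = na.build_neighborhoods(
        helix, np.arange(helix.n_atoms), 6.5
    )
    return nbs


class TestChiTimeseries:
    def test_repeated_reference_gives_zero_series(self, helix, helix_nbs):
        ens = na.ConformationEnsemble(frames=np.repeat(helix.positions[None], 4, 0))
        series = stats.chi_timeseries(helix, ens, np.arange(20), helix_nbs)
        np.testing.assert_array_equal(series.chi_t, 0.0)

    def test_affine_ensemble_gives_zero_series(self, helix, helix_nbs):
        rng = np.random.default_rng(0)
        D_t = np.eye(3) + 0.05 * rng.normal(size=(6, 3, 3))
        ens = syn.affine_ensemble(helix, D_t)
        series = stats.chi_timeseries(helix, ens, np.arange(40, 60), helix_nbs)
        msd = np.mean((ens.frames - helix.positions) ** 2)
        assert series.chi_t.max() < 1e-10 * max(msd, 1e-30)

    def test_soft_mode_series_tracks_squared_amplitude(self, helix, helix_nb):
        e = syn.nonaffine_unit_mode(helix_nb, seed=1)
        mode = syn.PlantedMode(helix_nb, e, per_atom_rms=1.0)
        ens, info = syn.mode_ensemble(helix, [mode], noise_sigma=0.1, T=400, seed=2)
        series = stats.chi_timeseries(
            helix, ens, [helix_nb.center_index], {helix_nb.center_index: helix_nb}
        )
        a = next(iter(info["amplitudes"].values())) * mode.stacked_std
        r = pearsonr(series.chi_t, a**2).statistic
        assert r >= 0.95

    def test_no_valid_neighborhood_raises(self, helix):
        with pytest.raises(ValueError):
            stats.chi_timeseries(helix, syn.isotropic_ensemble(helix, 0.1, 3), [0], {})


class TestSiteStatistics:
    def test_constant_series(self):
        out = stats.site_statistics({"a": np.full(10, 3.5)})
        assert out.mean_chi[0] == 3.5
        assert out.susceptibility[0] == 0.0

    def test_two_frame_hand_case(self):
        # series (0, 2): mean 1, population variance 1
        out = stats.site_statistics({"a": np.array([0.0, 2.0])})
        assert out.mean_chi[0] == 1.0
        assert out.susceptibility[0] == 1.0

    def test_population_variance_convention(self):
        series = np.array([1.0, 2.0, 3.0, 4.0])
        out = stats.site_statistics({"a": series})
        assert out.susceptibility[0] == pytest.approx(series.var(ddof=0))

    def test_gaps_attached(self):
        out = stats.site_statistics({"a": np.arange(5.0)}, gaps={"a": 0.7})
        assert out.gap[0] == 0.7

    def test_frame_reordering_invariance(self):
        rng = np.random.default_rng(3)
        series = rng.exponential(size=50)
        a = stats.site_statistics({"s": series})
        b = stats.site_statistics({"s": series[rng.permutation(50)]})
        assert a.mean_chi[0] == pytest.approx(b.mean_chi[0])
        assert a.susceptibility[0] == pytest.approx(b.susceptibility[0])


class TestCorrelationMap:
    def test_symmetric_diagonal_is_susceptibility(self):
        rng = np.random.default_rng(4)
        series = {r: rng.exponential(size=30) for r in range(1, 6)}
        cmap = stats.correlation_map(series)
        np.testing.assert_array_equal(cmap.matrix, cmap.matrix.T)
        site_stats = stats.site_statistics(series)
        np.testing.assert_array_equal(np.diag(cmap.matrix), site_stats.susceptibility)

    def test_independent_series_have_small_off_diagonal(self):
        rng = np.random.default_rng(5)
        T = 2000
        series = {r: rng.exponential(size=T) for r in range(1, 7)}
        cmap = stats.correlation_map(series)
        off = cmap.matrix[~np.eye(6, dtype=bool)]
        # each series has unit variance; covariance SE ~ 1/sqrt(T)
        assert np.abs(off).max() < 3.5 / np.sqrt(T)

    def test_shared_driver_dominates_map(self):
        rng = np.random.default_rng(6)
        T = 500
        shared = rng.standard_normal(T) ** 2
        series = {r: rng.exponential(0.05, size=T) for r in range(1, 9)}
        series[2] = series[2] + shared
        series[7] = series[7] + shared
        cmap = stats.correlation_map(series)
        off = cmap.matrix.copy()
        np.fill_diagonal(off, -np.inf)
        i, j = np.unravel_index(np.argmax(off), off.shape)
        assert {cmap.residue_ids[i], cmap.residue_ids[j]} == {2, 7}


class TestThresholdPairs:
    def _planted_map(self, helix):
        rids = np.array(sorted(set(helix.residue_id)))
        n = len(rids)
        rng = np.random.default_rng(7)
        M = 0.01 * np.abs(rng.normal(size=(n, n)))
        M = 0.5 * (M + M.T)
        M[4, 40] = M[40, 4] = 1.0  # distal planted pair, 10x above background
        np.fill_diagonal(M, 2.0)
        return stats.NapCorrelationMap(residue_ids=rids, matrix=M)

    def test_planted_distal_pair_returned_first(self, helix):
        cmap = self._planted_map(helix)
        pairs = stats.threshold_pairs(cmap, helix)
        assert len(pairs) >= 1
        top = pairs.iloc[0]
        assert {int(top.residue_i), int(top.residue_j)} == {5, 41}

    def test_threshold_uses_off_diagonal_maximum(self, helix):
        """The 4%-of-maximum cut is relative to the off-diagonal maximum,
        not the (always larger) diagonal susceptibilities."""
        cmap = self._planted_map(helix)
        pairs = stats.threshold_pairs(cmap, helix, fraction=0.5)
        # 0.5 * diag-max (=1.0) would exclude everything except the pair;
        # 0.5 * off-diag max (=0.5) keeps exactly the planted pair
        assert len(pairs) == 1

    def test_fraction_one_returns_at_most_argmax(self, helix):
        cmap = self._planted_map(helix)
        pairs = stats.threshold_pairs(cmap, helix, fraction=1.0)
        assert len(pairs) <= 1

    def test_huge_seq_sep_returns_empty(self, helix):
        cmap = self._planted_map(helix)
        pairs = stats.threshold_pairs(cmap, helix, min_seq_sep=1000)
        assert len(pairs) == 0

    def test_sequence_adjacent_pairs_excluded(self, helix):
        rids = np.array(sorted(set(helix.residue_id)))
        n = len(rids)
        M = np.zeros((n, n))
        M[10, 12] = M[12, 10] = 5.0  # strong but sequence-adjacent
        M[4, 40] = M[40, 4] = 1.0
        cmap = stats.NapCorrelationMap(residue_ids=rids, matrix=M)
        pairs = stats.threshold_pairs(cmap, helix, min_seq_sep=10)
        assert not (
            (pairs.residue_i == rids[10]) & (pairs.residue_j == rids[12])
        ).any()


class TestInterhelixDistance:
    def test_two_single_atoms(self):
        frame = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        assert stats.interhelix_distance(frame, [0], [1]) == 5.0

    def test_hand_computed_average(self):
        frame = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 4.0, 0]])
        assert stats.interhelix_distance(frame, [0], [1, 2]) == pytest.approx(3.5)

    def test_rigid_translation_invariance(self):
        rng = np.random.default_rng(8)
        frame = rng.normal(size=(10, 3))
        d0 = stats.interhelix_distance(frame, [0, 1, 2], [5, 6])
        d1 = stats.interhelix_distance(frame + [7.0, -3.0, 2.0], [0, 1, 2], [5, 6])
        assert d1 == pytest.approx(d0)

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError):
            stats.interhelix_distance(np.zeros((3, 3)), [], [1])


class TestHotspotScale:
    def test_three_values(self):
        np.testing.assert_allclose(
            stats.hotspot_scale(np.array([1.0, 2.0, 3.0])), [0.0, 50.0, 100.0]
        )

    def test_single_value_is_zero(self):
        np.testing.assert_array_equal(stats.hotspot_scale(np.array([4.2])), [0.0])

    def test_all_equal_is_zero(self):
        np.testing.assert_array_equal(
            stats.hotspot_scale(np.full(4, 2.0)), np.zeros(4)
        )

    def test_ranking_preserved(self):
        rng = np.random.default_rng(9)
        s = rng.exponential(size=20)
        scaled = stats.hotspot_scale(s)
        np.testing.assert_array_equal(np.argsort(scaled), np.argsort(s))

    def test_nan_sites_stay_nan(self):
        out = stats.hotspot_scale(np.array([1.0, np.nan, 3.0]))
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.0, 100.0])
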