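"""Permutation contrast maps, peak extraction, overlap counts, k-means."""

import numpy as np
import pandas as pd
import pytest

import vocalstm as v
from vocalstm import DataError, ParameterError
from vocalstm.contrast import PeakSet, StatMap, pair_differences

from conftest import exact_signflip_pvalues, make_stm_dataset


def _paired_dataset(rng, n_pairs=12, shape=(9, 11), block=None, shift=0.0, n_groups=3):
    """Random paired dataset; optionally add `shift` to song rows inside a
    (row-slice, col-slice) block of the grid."""
    cells = shape[0] * shape[1]
    X = rng.standard_normal((2 * n_pairs, cells))
    if block is not None:
        mask2d = np.zeros(shape, dtype=bool)
        mask2d[block] = True
        X[::2, mask2d.ravel()] += shift  # song rows come first per speaker
    sa = np.linspace(0, 8, shape[0])
    ta = np.linspace(-10, 10, shape[1])
    return make_stm_dataset(X, sa, ta, n_groups=n_groups), (
        None if block is None else mask2d
    )


class TestPairedPermutationMap:
    def test_identical_sets_give_zero_statistic_and_empty_mask(self):
        rng = np.random.default_rng(0)
        stm, _ = _paired_dataset(rng, n_pairs=8)
        stm.X[1::2] = stm.X[::2]  # speech rows identical to song rows
        m = v.paired_permutation_map(stm, n_perm=200, alpha=0.05, seed=1)
        assert np.all(m.statistic[np.isfinite(m.statistic)] == 0)
        assert not m.mask.any()

    def test_label_swap_negates_statistic_same_mask(self):
        rng = np.random.default_rng(1)
        stm, _ = _paired_dataset(rng, n_pairs=10, block=(slice(2, 5), slice(3, 6)), shift=1.5)
        m1 = v.paired_permutation_map(stm, n_perm=1000, alpha=0.05, seed=2)
        swapped = stm.meta.copy()
        swapped["category"] = swapped["category"].map({"song": "speech", "speech": "song"})
        stm2 = v.STMDataset(stm.X, stm.spectral_axis, stm.temporal_axis, swapped)
        m2 = v.paired_permutation_map(stm2, n_perm=1000, alpha=0.05, seed=2)
        np.testing.assert_allclose(m2.statistic, -m1.statistic, equal_nan=True)
        np.testing.assert_array_equal(m2.mask, m1.mask)

    def test_monte_carlo_matches_exhaustive_signflip_oracle(self):
        """At n=8 pairs the permutation p of each cell must agree with exact
        enumeration of all 2^8 sign assignments within Monte-Carlo error."""
        rng = np.random.default_rng(3)
        n_pairs, n_perm = 8, 4000
        stm, block = _paired_dataset(
            rng, n_pairs=n_pairs, shape=(6, 7), block=(slice(1, 4), slice(2, 5)), shift=1.2
        )
        m = v.paired_permutation_map(stm, n_perm=n_perm, alpha=0.05, seed=4)
        D, _ = pair_differences(stm)
        p_exact = exact_signflip_pvalues(D).reshape(stm.shape2d)
        p_mc = m.p
        ok = np.isfinite(p_mc)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm) + 2.0 / n_perm
        assert np.all(np.abs(p_mc[ok] - p_exact[ok]) <= 3 * se[ok] + 1e-12)

    def test_seed_determinism_and_min_permutations(self):
        rng = np.random.default_rng(5)
        stm, _ = _paired_dataset(rng, n_pairs=6)
        m1 = v.paired_permutation_map(stm, n_perm=300, seed=9)
        m2 = v.paired_permutation_map(stm, n_perm=300, seed=9)
        np.testing.assert_array_equal(m1.p, m2.p)
        with pytest.raises(ParameterError):
            v.paired_permutation_map(stm, n_perm=50)

    def test_no_pairs_is_an_error(self):
        rng = np.random.default_rng(6)
        stm, _ = _paired_dataset(rng, n_pairs=4)
        solo = v.STMDataset(
            stm.X[:4], stm.spectral_axis, stm.temporal_axis,
            stm.meta.iloc[:4].assign(category="song"),
        )
        with pytest.raises(DataError):
            v.paired_permutation_map(solo, n_perm=200)

    def test_injected_hotspots_recovered_in_study_corpus(self, study):
        """The corpus contrast is positive (song > speech) at the injected
        song coordinate and negative at the injected speech coordinate."""
        stm, sm = study["stm"], study["statmap"]
        i = np.unravel_index(stm.cell_index(3.5, 0.7), stm.shape2d)
        j = np.unravel_index(stm.cell_index(0.1, 6.0), stm.shape2d)
        assert sm.mask[i] and sm.statistic[i] > 0
        assert sm.mask[j] and sm.statistic[j] < 0


class TestFindPeaks:
    def _map_from(self, stat, mask, sa=None, ta=None):
        stat = np.asarray(stat, dtype=float)
        sa = np.arange(stat.shape[0], dtype=float) if sa is None else sa
        ta = np.arange(stat.shape[1], dtype=float) - stat.shape[1] // 2 if ta is None else ta
        return StatMap(
            statistic=stat, p=np.full_like(stat, 0.5), mask=np.asarray(mask, dtype=bool),
            spectral_axis=sa, temporal_axis=ta, alpha=0.05, n_permutations=100, n_pairs=8,
        )

    def test_empty_mask_yields_empty_peakset(self):
        m = self._map_from(np.ones((5, 5)), np.zeros((5, 5)))
        assert len(v.find_peaks(m, sign=1)) == 0

    def test_single_significant_cell(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True
        m = self._map_from(np.ones((5, 5)), mask)
        ps = v.find_peaks(m, sign=1)
        assert len(ps) == 1
        assert ps.peaks.iloc[0]["spectral_cyc_per_khz"] == 2.0

    def test_two_constructed_maxima_found_exactly(self):
        stat = np.zeros((9, 9))
        stat[2, 2], stat[6, 7] = 5.0, 4.0
        # a faint shoulder beside the first peak must be suppressed
        stat[2, 3] = 3.0
        m = self._map_from(stat, stat > 0)
        ps = v.find_peaks(m, sign=1, min_separation=2)
        got = {(r["spectral_cyc_per_khz"], r["temporal_hz"]) for _, r in ps.peaks.iterrows()}
        assert got == {(2.0, -2.0), (6.0, 3.0)}

    def test_peaks_respect_sign_and_mask_membership(self):
        stat = np.zeros((5, 5))
        stat[1, 1], stat[3, 3] = 4.0, -6.0
        m = self._map_from(stat, stat != 0)
        pos = v.find_peaks(m, sign=1).peaks
        neg = v.find_peaks(m, sign=-1).peaks
        assert len(pos) == 1 and pos.iloc[0]["stat"] == 4.0
        assert len(neg) == 1 and neg.iloc[0]["stat"] == -6.0
        with pytest.raises(ParameterError):
            v.find_peaks(m, sign=0)


class TestSocietyOverlap:
    def test_counts_bounded_and_hotspot_unanimous(self):
        """Groups drawn from one strongly separated distribution all show the
        effect at the injected song cell."""
        spec = v.CorpusSpec(
            n_groups=5, speakers_per_group=15, duration_s=(3.0, 4.0), seed=21,
            clarity_sd=0.0, speaker_clarity_sd=0.0, group_sd=(0.05, 0.1),
            speaker_sd=(0.15, 0.2), voc_sd=(0.05, 0.1), texture_depth=0.02,
        )
        stm = v.batch_stm(v.synth_corpus(spec), v.analysis_grid())
        counts, corpus_map, per_group = v.society_overlap_map(
            stm, n_perm=3000, alpha=0.05, seed=3
        )
        assert counts.max() <= 5 and counts.min() >= 0
        i, j = np.unravel_index(stm.cell_index(3.5, 0.7), stm.shape2d)
        neighborhood = counts[max(i - 1, 0): i + 2, max(j - 1, 0): j + 2]
        assert neighborhood.max() == 5
        assert len(per_group) == 5

    def test_single_pair_group_skipped(self, caplog):
        import logging

        rng = np.random.default_rng(2)
        stm, _ = _paired_dataset(rng, n_pairs=9, n_groups=3)
        # give one group only a single pair
        meta = stm.meta.copy()
        keep = ~((meta["fieldsite"] == "site02") & (meta["speaker_id"] != "s002"))
        stm2 = v.STMDataset(stm.X[keep.to_numpy()], stm.spectral_axis, stm.temporal_axis,
                            meta[keep].reset_index(drop=True))
        with caplog.at_level(logging.WARNING, logger="vocalstm.contrast"):
            counts, _, per_group = v.society_overlap_map(stm2, n_perm=200, alpha=0.05, seed=0)
        assert "site02" not in per_group
        assert any("single pair" in rec.message for rec in caplog.records)


class TestKmeansStatPeaks:
    def _peaksets(self, pts):
        df = pd.DataFrame(pts, columns=["spectral_cyc_per_khz", "temporal_hz"])
        df["stat"] = 1.0
        df["sign"] = 1
        return [PeakSet(peaks=df)]

    def test_two_cloud_recovery(self):
        rng = np.random.default_rng(0)
        song = rng.normal((3.5, 0.7), 0.2, size=(30, 2))
        speech = rng.normal((0.3, 6.3), 0.2, size=(30, 2))
        speech[:, 0] = np.abs(speech[:, 0])
        cents, labels, pts = v.kmeans_stat_peaks(self._peaksets(np.vstack([song, speech])), k=2, seed=0)
        assert np.linalg.norm(cents[0] - [3.5, 0.7]) < 0.15
        assert np.linalg.norm(cents[1] - [0.3, 6.3]) < 0.15
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1

    def test_absolute_temporal_coordinates(self):
        """Peaks at -6.33 and +6.33 Hz describe the same structure and map to
        one clustered coordinate."""
        cents, _, pts = v.kmeans_stat_peaks(
            self._peaksets([(0.3, 6.33), (0.3, -6.33)]), k=1, seed=0
        )
        assert np.allclose(pts[:, 1], 6.33)
        assert np.allclose(cents[0], [0.3, 6.33])

    def test_degenerate_single_point_cluster(self):
        cents, labels, _ = v.kmeans_stat_peaks(self._peaksets([(2.0, 1.0)] * 4), k=1, seed=0)
        assert np.allclose(cents[0], [2.0, 1.0])

    def test_fewer_points_than_clusters_rejected(self):
        with pytest.raises(ParameterError):
            v.kmeans_stat_peaks(self._peaksets([(1.0, 1.0)]), k=2)
        with pytest.raises(ParameterError):
            v.kmeans_stat_peaks([PeakSet(peaks=pd.DataFrame(
                columns=["spectral_cyc_per_khz", "temporal_hz", "stat", "sign"]))], k=1)
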