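"""Occupancy, localization score, grouping, and peak-caller tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from zfstall.footprint_analysis import (
    CodonTrack,
    DomainMask,
    ZeroCoverageError,
    assign_asite,
    call_peaks_simple,
    disome_occupancy,
    group_by_score,
    localization_score,
    masks_from_hits,
    region_read_fraction,
    site_occupancy_pairs,
)
from zfstall.synthetic_data import reverse_translate


def track(disome, mono=None, tid="t"):
    d = np.asarray(disome)
    m = np.zeros_like(d) if mono is None else np.asarray(mono)
    return CodonTrack(tid, m, d)


class TestAssignAsite:
    @pytest.mark.parametrize(
        "pos,cls,expected", [(0, "monosome", 5), (3, "disome", 16)]
    )
    def test_fixed_offsets(self, pos, cls, expected):
        assert assign_asite(pos, 30, cls) == expected

    def test_negative_position_rejected(self):
        with pytest.raises(ValueError):
            assign_asite(-1, 30, "monosome")


class TestDisomeOccupancy:
    def test_uniform_track_self_normalizes(self):
        occ = disome_occupancy(track([3, 3, 3, 3]))
        np.testing.assert_allclose(occ, 1.0)

    def test_single_spike_hand_oracle(self):
        occ = disome_occupancy(track([0, 0, 6, 0, 0, 0]))
        np.testing.assert_allclose(occ, [0, 0, 6, 0, 0, 0])

    def test_scale_invariance(self):
        t1 = track([1, 2, 3, 4])
        t2 = track([2, 4, 6, 8])
        np.testing.assert_allclose(disome_occupancy(t1), disome_occupancy(t2))

    def test_mean_over_normalization_region_is_one(self):
        rng = np.random.default_rng(0)
        t = track(rng.poisson(2.0, 50))
        mask = DomainMask("t", ((10, 20), (30, 40)))
        assert disome_occupancy(t).mean() == pytest.approx(1.0, abs=1e-9)
        occ_dom = disome_occupancy(t, mask, region="domains")
        sel = mask.selector(50)
        assert occ_dom[sel].mean() == pytest.approx(1.0, abs=1e-9)

    def test_zero_region_is_skipped_with_diagnostic(self):
        with pytest.raises(ZeroCoverageError):
            disome_occupancy(track([0, 0, 0]))


class TestLocalizationScore:
    def test_filter_boundary_at_exactly_ten_reads(self):
        d = np.zeros(20, int)
        d[5:8] = [3, 3, 2]  # 8 in domain
        d[0] = 2            # 2 outside
        s = localization_score(track(d), DomainMask("t", ((5, 10),)))
        assert s.total_reads == 10 and s.score == pytest.approx(0.8)
        assert s.group != "unscored"

    def test_nine_reads_is_unscored(self):
        d = np.zeros(20, int)
        d[5] = 9
        s = localization_score(track(d), DomainMask("t", ((5, 10),)))
        assert s.group == "unscored"
        assert s.score == pytest.approx(1.0)  # still reported

    def test_empty_mask_flags_domain_free(self):
        s = localization_score(track([1] * 20), DomainMask("t", ()))
        assert s.score == 0.0 and s.domain_free

    def test_matches_brute_force_on_random_tracks(self):
        """Score equals an interval-sum oracle on 1,000 random track/mask pairs."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(5, 120))
            d = rng.poisson(1.0, n)
            n_iv = int(rng.integers(0, 4))
            bounds = sorted(rng.choice(n + 1, size=2 * n_iv, replace=False))
            ivs = [
                (bounds[2 * i], bounds[2 * i + 1])
                for i in range(n_iv)
                if bounds[2 * i] < bounds[2 * i + 1]
            ]
            mask = DomainMask("t", tuple(ivs))
            s = localization_score(track(d), mask)
            dom = sum(int(d[a:b].sum()) for a, b in ivs)
            tot = int(d.sum())
            assert s.domain_reads == dom and s.total_reads == tot
            if ivs and tot > 0:
                assert s.score == pytest.approx(dom / tot)

    @settings(max_examples=50, deadline=None)
    @given(scale=st.integers(1, 20), seed=st.integers(0, 1000))
    def test_invariant_under_count_scaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        d = rng.poisson(2.0, 40)
        mask = DomainMask("t", ((5, 15), (25, 35)))
        s1 = localization_score(track(d), mask)
        s2 = localization_score(track(d * scale), mask)
        assert s1.score == pytest.approx(s2.score)

    def test_complementary_masks_partition_reads(self):
        rng = np.random.default_rng(5)
        d = rng.poisson(3.0, 30)
        left = DomainMask("t", ((0, 12),))
        right = DomainMask("t", ((12, 30),))
        s_l = localization_score(track(d), left)
        s_r = localization_score(track(d), right)
        assert s_l.domain_reads + s_r.domain_reads == s_l.total_reads


class TestRegionReadFraction:
    def test_clustered_region_fraction(self):
        d = np.zeros(100, int)
        d[40:43] = [10, 5, 3]  # 18 reads inside the region of interest
        d[0] = 30
        d[99] = 11             # 59 total
        frac = region_read_fraction(track(d), (40, 60))
        assert frac == pytest.approx(18 / 59)
        assert round(100 * frac, 1) == 30.5

    def test_whole_orf_is_one_and_empty_interval_zero(self):
        t = track([1, 2, 3])
        assert region_read_fraction(t, (0, 3)) == 1.0
        assert region_read_fraction(t, (1, 1)) == 0.0

    def test_zero_reads_is_an_error(self):
        with pytest.raises(ZeroCoverageError):
            region_read_fraction(track([0, 0]), (0, 1))


def scored(tid, score):
    from zfstall.footprint_analysis import LocalizationScore

    return LocalizationScore(tid, 0, 100, score, "ungrouped")


class TestGroupByScore:
    def test_three_scores_map_to_three_groups(self):
        out = group_by_score([scored("a", 0.9), scored("b", 0.5), scored("c", 0.1)])
        assert [s.group for s in out] == ["high", "middle", "low"]

    def test_balanced_split_of_ten(self):
        out = group_by_score([scored(f"t{i:02d}", i / 10) for i in range(10)])
        from collections import Counter

        sizes = Counter(s.group for s in out)
        assert sizes == {"high": 4, "middle": 3, "low": 3}

    def test_all_equal_scores_tie_break_by_id(self):
        out = group_by_score([scored(f"t{i}", 0.5) for i in range(6)])
        by_id = {s.transcript_id: s.group for s in out}
        assert by_id == {"t0": "high", "t1": "high", "t2": "middle",
                         "t3": "middle", "t4": "low", "t5": "low"}

    def test_partition_property(self):
        rng = np.random.default_rng(9)
        scores = [scored(f"t{i:03d}", float(rng.random())) for i in range(50)]
        out = group_by_score(scores)
        assert sorted(s.transcript_id for s in out) == sorted(
            s.transcript_id for s in scores
        )
        assert all(s.group in {"high", "middle", "low"} for s in out)

    def test_unscored_pass_through_and_too_few_error(self):
        from zfstall.footprint_analysis import LocalizationScore

        un = LocalizationScore("u", 0, 3, 0.5, "unscored")
        out = group_by_score([scored("a", 0.1), scored("b", 0.2), scored("c", 0.3), un])
        assert [s for s in out if s.transcript_id == "u"][0].group == "unscored"
        with pytest.raises(ValueError):
            group_by_score([scored("a", 0.1), un])


class TestCallPeaksSimple:
    def test_uniform_track_has_no_peaks(self):
        assert call_peaks_simple(track([3] * 20)) == []

    def test_single_spike_is_called(self):
        d = np.zeros(50, int)
        d[17] = 100
        assert call_peaks_simple(track(d)) == [17]

    def test_hand_z_scores(self):
        d = np.array([1, 1, 1, 1, 1, 1, 1, 1, 1, 21])
        mean, sd = d.mean(), d.std(ddof=0)
        assert (21 - mean) / sd > 2.9  # hand z-score ~ 3.0: below threshold 4
        assert call_peaks_simple(track(d), z_threshold=4) == []
        assert call_peaks_simple(track(d), z_threshold=2.5) == [9]


class TestSiteOccupancyPairs:
    def _toy(self):
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        cds = reverse_translate(seq, rng)
        d = rng.poisson(2.0, 61)
        tracks = {"t": CodonTrack("t", np.zeros(61, int), d)}
        masks = {"t": DomainMask("t", ((10, 38),))}
        return tracks, masks, {"t": cds}

    def test_identical_regions_give_rho_one(self):
        tracks, masks, cds = self._toy()
        # make occupancy identical in both regions: mask covers the whole ORF
        masks = {"t": DomainMask("t", ((0, 61),))}
        table, rho = site_occupancy_pairs(tracks, masks, cds)
        for site in "APE":
            assert rho[site] == pytest.approx(1.0)

    def test_toy_rho_matches_scipy_on_table(self):
        tracks, masks, cds = self._toy()
        table, rho = site_occupancy_pairs(tracks, masks, cds)
        sub = table[(table.site == "A")].dropna()
        expected = stats.spearmanr(sub.occ_all, sub.occ_domain).statistic
        assert rho["A"] == pytest.approx(expected)

    def test_missing_codons_reported_as_nan(self):
        tracks, masks, cds = self._toy()
        table, _ = site_occupancy_pairs(tracks, masks, cds)
        assert table.occ_all.isna().any()  # 60-codon toy cannot cover 61 codons
        assert set(table.codon).issuperset({"AAA", "TGG"})


class TestMasksFromHits:
    def test_overlapping_frames_are_merged(self):
        from zfstall.domain_annotation import DomainHit

        hits = [
            DomainHit("p", 2, 23, 0, 28, True),
            DomainHit("p", 26, 47, 24, 52, True),
        ]
        masks = masks_from_hits(hits)
        assert masks["p"].intervals == ((0, 52),)
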