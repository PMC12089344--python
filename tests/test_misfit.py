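"""Error profiles, misfit-region calling, annotation overlap, correlations."""

import numpy as np
import pandas as pd
import pytest

from replikit import (
    GenomeGrid,
    TimingProfile,
    apparent_speed_profile,
    correlate_tracks,
    detect_misfit_regions,
    error_profile,
    expected_timing_profile,
    normalize_error,
    overlap_fraction,
)
from replikit.io import IntervalTrack
from replikit.misfit import DEFAULT_MISFIT_THRESHOLD, ErrorProfile, misfit_site_mask


def _timing(values, mask=None, name="chr1"):
    grid = GenomeGrid.from_sizes({name: len(values)}, valid_mask=mask)
    return TimingProfile(np.asarray(values, float), grid)


def _error(values, name="chr1"):
    grid = GenomeGrid.from_sizes({name: len(values)})
    return ErrorProfile(np.asarray(values, float), grid)


class TestErrorProfile:
    def test_identical_profiles_zero(self):
        a = _timing(np.linspace(10, 100, 20))
        assert np.all(error_profile(a, a).squared_error == 0.0)

    def test_single_difference_squared(self):
        a = _timing(np.full(20, 50.0))
        b = a.copy()
        b.times = b.times.copy()
        b.times[4] += 10.0
        err = error_profile(a, b).squared_error
        assert err[4] == pytest.approx(100.0)
        assert np.all(np.delete(err, 4) == 0.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        a = _timing(rng.uniform(0, 500, 50))
        b = _timing(rng.uniform(0, 500, 50))
        np.testing.assert_allclose(
            error_profile(a, b).squared_error, (a.times - b.times) ** 2
        )

    def test_mask_propagates(self):
        mask = np.ones(10, bool)
        mask[3] = False
        a = _timing(np.full(10, 5.0), mask=mask)
        b = _timing(np.full(10, 7.0))
        err = error_profile(a, b)
        assert np.isnan(err.squared_error[3])
        assert not err.grid.valid_mask[3]


class TestNormalizeError:
    def test_constant_maps_to_zero(self):
        assert np.all(normalize_error(_error(np.full(10, 42.0))) == 0.0)

    def test_two_values_map_to_unit_interval_ends(self):
        out = normalize_error(_error([1.0, 1.0, 99.0, 99.0]))
        assert set(np.round(out, 12)) == {0.0, 1.0}

    def test_hand_computed_triple(self):
        e = np.array([0.0, 9.0, 99.0])
        out = normalize_error(_error(e))
        le = np.log10(e + 1)
        np.testing.assert_allclose(out, (le - le[0]) / (le[2] - le[0]))


class TestDetectMisfitRegions:
    def test_all_below_threshold_empty(self):
        assert detect_misfit_regions(_error(np.full(1000, 10.0))) == []

    def test_single_run_extent_and_peak(self):
        e = np.zeros(1000)
        e[100:150] = 1e4
        e[120] = 5e4
        (region,) = detect_misfit_regions(_error(e))
        assert (region.start_site, region.end_site) == (100, 149)
        assert region.length_kb == 50
        assert region.peak_error == 5e4
        assert (region.start_bp, region.end_bp) == (100_000, 150_000)

    def test_merge_rule(self):
        e = np.zeros(2000)
        e[100:110] = 1e4
        e[310:320] = 1e4  # gap 200 kb < 300 -> merged
        e[800:810] = 1e4  # gap 480 kb > 300 -> separate
        regions = detect_misfit_regions(_error(e))
        assert [(r.start_site, r.end_site) for r in regions] == [(100, 319), (800, 809)]

    def test_threshold_monotone(self):
        rng = np.random.default_rng(0)
        e = rng.lognormal(5, 2, 3000)
        low = detect_misfit_regions(_error(e), threshold=500, merge_radius=50)
        high = detect_misfit_regions(_error(e), threshold=5000, merge_radius=50)
        for r in high:
            assert any(
                q.start_site <= r.start_site and r.end_site <= q.end_site for q in low
            )


class TestOverlapFraction:
    @staticmethod
    def _annotations(rows):
        return IntervalTrack(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "class_label"])
        )

    def test_exact_cover_gives_one(self):
        grid = GenomeGrid.from_sizes({"chr1": 100})
        mask = np.zeros(100, bool)
        mask[10:20] = True
        ann = self._annotations([("chr1", 10_000, 20_000, "a", "X")])
        table = overlap_fraction(mask, ann, grid)
        row = table.set_index("class_label").loc["X"]
        assert row["misfit_fraction"] == 1.0
        assert row["complement_fraction"] == 0.0

    def test_no_overlap_gives_zero(self):
        grid = GenomeGrid.from_sizes({"chr1": 100})
        mask = np.zeros(100, bool)
        mask[50:60] = True
        ann = self._annotations([("chr1", 0, 10_000, "a", "X")])
        assert (
            overlap_fraction(mask, ann, grid).set_index("class_label").loc["X", "misfit_fraction"]
            == 0.0
        )

    def test_hand_computed_three_intervals(self):
        grid = GenomeGrid.from_sizes({"chr1": 100})
        mask = np.zeros(100, bool)
        mask[0:10] = True  # 10 misfit sites
        ann = self._annotations(
            [
                ("chr1", 0, 5000, "a", "X"),  # 5 sites, all misfit
                ("chr1", 5000, 20_000, "b", "Y"),  # 15 sites, 5 misfit
                ("chr1", 50_000, 60_000, "c", "X"),  # 10 sites, 0 misfit
            ]
        )
        table = overlap_fraction(mask, ann, grid).set_index("class_label")
        assert table.loc["X", "misfit_fraction"] == pytest.approx(5 / 15)
        assert table.loc["Y", "misfit_fraction"] == pytest.approx(5 / 15)
        assert table.loc["X", "complement_fraction"] == pytest.approx(5 / 85)

    def test_class_and_complement_counts_partition(self):
        grid = GenomeGrid.from_sizes({"chr1": 200})
        rng = np.random.default_rng(4)
        mask = rng.random(200) < 0.3
        ann = self._annotations([("chr1", 30_000, 90_000, "a", "X")])
        table = overlap_fraction(mask, ann, grid).set_index("class_label")
        inside = table.loc["X", "misfit_sites_in_class"]
        outside = table.loc["X", "complement_fraction"] * (200 - table.loc["X", "sites_in_class"])
        assert inside + round(outside) == mask.sum()


class TestCorrelations:
    def test_identity_is_plus_one(self):
        a = np.random.default_rng(1).uniform(0, 1, 50)
        for method in ("spearman", "pearson", "kendall"):
            coef, p = correlate_tracks(a, a, method)
            assert coef == pytest.approx(1.0)
            assert p < 1e-10

    def test_rank_reversal_spearman(self):
        a = np.random.default_rng(2).uniform(0, 1, 50)
        coef, _ = correlate_tracks(a, -a, "spearman")
        assert coef == pytest.approx(-1.0)

    def test_matches_manual_rank_formula(self):
        rng = np.random.default_rng(7)
        a, b = rng.uniform(0, 1, 10), rng.uniform(0, 1, 10)
        ra = np.argsort(np.argsort(a)).astype(float)
        rb = np.argsort(np.argsort(b)).astype(float)
        manual = 1 - 6 * np.sum((ra - rb) ** 2) / (10 * 99)
        coef, _ = correlate_tracks(a, b, "spearman")
        assert coef == pytest.approx(manual)

    def test_pairwise_complete_masking(self):
        a = np.array([1.0, 2, 3, np.nan, 5, 6])
        b = np.array([2.0, 4, 6, 8, np.nan, 12])
        coef, _ = correlate_tracks(a, b, "pearson")
        assert coef == pytest.approx(1.0)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            correlate_tracks(np.array([1.0, 2]), np.array([3.0, 4]), "spearman")


class TestApparentSpeed:
    def test_single_fork_profile(self):
        t = _timing(np.arange(50) / 1.4)
        np.testing.assert_allclose(apparent_speed_profile(t), 1.4)

    def test_flat_profile_infinite(self):
        t = _timing(np.full(10, 100.0))
        assert np.all(np.isinf(apparent_speed_profile(t)))

    def test_predicted_profile_respects_fork_speed_bound(self, sparse_landscape, config):
        predicted = expected_timing_profile(sparse_landscape, config)
        sp = apparent_speed_profile(predicted)
        assert np.nanmin(sp) >= config.fork_speed_v - 1e-6

    def test_stall_produces_sub_speed_values(self):
        t = np.arange(100) / 1.4
        t[50:] += 30.0  # 30-min jump between adjacent sites
        sp = apparent_speed_profile(_timing(t))
        assert sp[49] < 1.4
        assert np.nanmin(sp) == sp[49]

    def test_misfit_site_mask_threshold(self):
        e = np.array([0.0, DEFAULT_MISFIT_THRESHOLD * 0.99, DEFAULT_MISFIT_THRESHOLD * 1.01])
        mask = misfit_site_mask(_error(e))
        assert mask.tolist() == [False, False, True]
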