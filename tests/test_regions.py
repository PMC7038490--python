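"""Word-frequency sorting, quantile multipliers and elliptical regions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from cloudtongue import (
    OUTSIDE,
    WordFrequencyTable,
    build_region_set,
    build_region_set_explicit,
    central_multiplier,
    forward_cloud_2d,
    locate,
    ring_multiplier,
    sort_frequencies,
)
from cloudtongue.errors import (
    DegenerateDataError,
    InvalidConfigError,
    InvalidValueError,
    RegionConstructionError,
)
from cloudtongue.fixtures import jiang_panel_counts

WORDS = ("w1", "w2", "w3", "w4", "w5")


def table_from_counts(counts, flavor="jiang", words=WORDS):
    return WordFrequencyTable(flavor, tuple(zip(words, counts)), sum(counts))


class TestSortFrequencies:
    def test_published_jiang_counts_give_published_frequencies(self):
        table = table_from_counts(jiang_panel_counts())
        assert [f for _, f in sort_frequencies(table)] == [50, 25, 10, 10, 5]

    def test_ties_keep_lexicon_order(self):
        table = table_from_counts((8, 8, 8, 8, 8))
        assert sort_frequencies(table) == [(w, 20.0) for w in WORDS]

    def test_unanimous_vote(self):
        table = table_from_counts((40, 0, 0, 0, 0))
        assert [f for _, f in sort_frequencies(table)] == [100, 0, 0, 0, 0]

    def test_count_sum_mismatch_rejected(self):
        with pytest.raises(InvalidConfigError):
            WordFrequencyTable("jiang", tuple(zip(WORDS, (1, 1, 1, 1, 1))), 40)


class TestQuantileMultipliers:
    def test_central_half_mass(self):
        assert central_multiplier(50) == pytest.approx(norm.ppf(0.75), abs=1e-10)
        assert central_multiplier(50) == pytest.approx(0.6745, abs=1e-4)

    def test_one_sigma_mass(self):
        assert central_multiplier(68.27) == pytest.approx(1.0, abs=1e-3)

    def test_small_mass_limit(self):
        assert central_multiplier(1e-6) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize(
        "cum,expected", [(75, 1.1503), (95, 1.9600)]
    )
    def test_ring_quantiles(self, cum, expected):
        assert ring_multiplier(cum) == pytest.approx(expected, abs=1e-4)

    def test_full_mass_maps_to_cap(self):
        assert ring_multiplier(100) == 3.0
        assert ring_multiplier(100, cap=2.5) == 2.5

    @pytest.mark.parametrize("bad", [0, -5, 101])
    def test_out_of_range_mass_rejected(self, bad):
        with pytest.raises(InvalidValueError):
            ring_multiplier(bad)

    @given(
        freqs=st.lists(st.integers(1, 30), min_size=5, max_size=5)
    )
    @settings(max_examples=80, deadline=None)
    def test_multipliers_strictly_increase_for_positive_frequencies(self, freqs):
        cum = np.cumsum(100 * np.array(sorted(freqs, reverse=True)) / sum(freqs))
        ks = [ring_multiplier(c) for c in cum[:-1]]
        assert all(b > a for a, b in zip(ks, ks[1:]))


class TestBuildRegionSet:
    def test_frequency_path_reproduces_center_and_cap(self, descriptors):
        table = table_from_counts(jiang_panel_counts())
        rs = build_region_set(descriptors["jiang"], table)
        assert rs.center == (41.6501, -23.6840)
        assert len(rs.multipliers) == 5
        assert rs.semi_axes(5)[0] == pytest.approx(8.2518, abs=1e-4)

    def test_single_word_at_full_mass_keeps_only_cap_boundaries(self, descriptors):
        rs = build_region_set(descriptors["jiang"], table_from_counts((40, 0, 0, 0, 0)))
        # zero-frequency words collapse onto the cap ellipse
        assert rs.multipliers[0] == pytest.approx(3.0)
        assert rs.multipliers[-1] == 3.0

    def test_published_multipliers_reproduce_published_semi_axes(
        self, descriptors, published_multipliers
    ):
        rs = build_region_set_explicit(
            descriptors["jiang"], published_multipliers["jiang"], WORDS
        )
        expected_pc1 = [2.8881, 4.1259, 4.8411, 6.1613, 8.2518]
        expected_pc2 = [2.4452, 3.4932, 4.0987, 5.2165, 6.9864]
        for i, (a, b) in enumerate([rs.semi_axes(i) for i in range(1, 6)]):
            assert a == pytest.approx(expected_pc1[i], abs=5e-4)
            assert b == pytest.approx(expected_pc2[i], abs=5e-4)

    def test_feng_first_boundary_semi_axes(self, descriptors, published_multipliers):
        rs = build_region_set_explicit(
            descriptors["feng"], published_multipliers["feng"], WORDS
        )
        a, b = rs.semi_axes(1)
        assert a == pytest.approx(2.2081, abs=1e-4)
        assert b == pytest.approx(2.9945, abs=1e-4)

    def test_explicit_path_requires_strict_monotonicity(self, descriptors):
        with pytest.raises(RegionConstructionError):
            build_region_set_explicit(
                descriptors["jiang"], (1.0, 1.0, 2.0, 2.5, 3.0), WORDS
            )

    def test_zero_entropy_descriptor_rejected(self, descriptors):
        from cloudtongue import CloudDescriptor2D

        flat = CloudDescriptor2D.from_values((0.0, 0.0), (0.0, 1.0))
        with pytest.raises(DegenerateDataError):
            build_region_set(flat, table_from_counts(jiang_panel_counts()))

    def test_entry_order_never_changes_geometry(self, descriptors, rng):
        counts = (12, 9, 9, 6, 4)
        base = build_region_set(descriptors["nong"], table_from_counts(counts))
        perm = rng.permutation(5)
        shuffled = table_from_counts(
            tuple(np.array(counts)[perm]), words=tuple(np.array(WORDS)[perm])
        )
        other = build_region_set(descriptors["nong"], shuffled)
        assert other.multipliers == base.multipliers
        assert other.center == base.center


class TestLocate:
    @pytest.fixture()
    def jiang_regions(self, descriptors, published_multipliers):
        return build_region_set_explicit(
            descriptors["jiang"], published_multipliers["jiang"], WORDS
        )

    def test_center_is_region_one(self, jiang_regions, descriptors):
        assert locate(jiang_regions, descriptors["jiang"].ex) == 1

    def test_offset_between_first_and_second_boundary(self, jiang_regions):
        cx, cy = jiang_regions.center
        point = (cx + 1.2 * jiang_regions.scales[0], cy)
        assert locate(jiang_regions, point) == 2  # 1.05 < 1.2 <= 1.50

    def test_boundary_points_belong_to_inner_region(self, jiang_regions):
        cx, cy = jiang_regions.center
        k1 = jiang_regions.multipliers[0]
        assert locate(jiang_regions, (cx + k1 * jiang_regions.scales[0], cy)) == 1

    def test_far_point_is_outside_the_cap(self, jiang_regions):
        cx, cy = jiang_regions.center
        assert locate(jiang_regions, (cx + 5 * jiang_regions.scales[0], cy)) == OUTSIDE

    def test_matches_brute_force_membership_scan(self, jiang_regions, rng):
        cx, cy = jiang_regions.center
        s1, s2 = jiang_regions.scales
        pts = np.column_stack(
            [cx + rng.uniform(-4, 4, 500) * s1, cy + rng.uniform(-4, 4, 500) * s2]
        )
        for p in pts:
            inside = [
                ((p[0] - cx) / (k * s1)) ** 2 + ((p[1] - cy) / (k * s2)) ** 2 <= 1
                for k in jiang_regions.multipliers
            ]
            expected = inside.index(True) + 1 if any(inside) else OUTSIDE
            assert locate(jiang_regions, p) == expected

    def test_zero_frequency_word_is_never_selected(self, descriptors, rng):
        rs = build_region_set(descriptors["mild"], table_from_counts((20, 10, 6, 4, 0)))
        cloud = forward_cloud_2d(descriptors["mild"].with_zero_he(), 3000, seed=0)
        hits = {locate(rs, p) for p in cloud.points}
        assert 5 not in hits  # degenerate annulus of the zero-frequency word

    def test_monte_carlo_coverage_follows_rayleigh_law(self, descriptors):
        # For he = 0 droplets the chance of landing inside the k-ellipse is
        # 1 - exp(-k^2/2); check within 3-sigma binomial error.
        desc = descriptors["jiang"].with_zero_he()
        cloud = forward_cloud_2d(desc, 20_000, seed=0)
        r = np.hypot(
            (cloud.x1 - desc.dim1.ex) / desc.dim1.en,
            (cloud.x2 - desc.dim2.ex) / desc.dim2.en,
        )
        for k in (0.6745, 1.05, 1.76, 3.0):
            p = 1 - np.exp(-(k**2) / 2)
            tol = 3 * np.sqrt(p * (1 - p) / r.size)
            assert abs(np.mean(r <= k) - p) <= tol
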