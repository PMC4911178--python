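"""Morphometry rules: internuclear distance, SNC/SNA calls, censuses."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from synclust import (
    GeneratorSpec,
    PointPattern,
    detect_sna,
    detect_snc,
    filter_particles,
    generate_cell_population,
    generate_clustered_pattern,
    internuclear_distances,
    large_syncytium_stats,
    shedding_fraction,
    sna_density_and_size,
)
from synclust.morphometry import MorphometryReport


def _chain(n, gap, radius=5.0):
    """n discs in a row with consecutive edge-to-edge gaps `gap`."""
    xs = np.arange(n) * (2 * radius + gap)
    return PointPattern(np.column_stack([xs, np.zeros(n)]), np.full(n, radius))


def _nn_oracle(pattern):
    """Exhaustive all-pairs nearest-neighbour edge distances."""
    c, r = pattern.centroids, pattern.radii
    n = c.shape[0]
    out = np.full(n, np.inf)
    for i in range(n):
        for j in range(n):
            if i != j:
                d = np.hypot(*(c[i] - c[j])) - r[i] - r[j]
                out[i] = min(out[i], max(d, 0.0))
    return out


class TestInternuclearDistance:
    def test_two_discs_edge_gap(self):
        p = PointPattern([[0, 0], [13, 0]], [5.0, 5.0])
        assert np.allclose(internuclear_distances(p), [3.0, 3.0])

    def test_overlapping_profiles_floored_at_zero(self):
        p = PointPattern([[0, 0], [0, 0]], [5.0, 5.0])
        assert np.allclose(internuclear_distances(p), [0.0, 0.0])

    def test_matches_all_pairs_oracle(self, rng):
        c = rng.uniform(0, 300, size=(200, 2))
        r = rng.uniform(3, 6, size=200)
        p = PointPattern(c, r)
        assert np.allclose(internuclear_distances(p), _nn_oracle(p))

    def test_single_nucleus_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            internuclear_distances(PointPattern([[0, 0]], [5.0]))

    def test_excluded_nuclei_ignored(self):
        p = PointPattern(
            [[0, 0], [13, 0], [14, 0]], [5.0, 5.0, 5.0],
            excluded=[False, False, True],
        )
        assert np.allclose(internuclear_distances(p), [3.0, 3.0])


class TestDetectSNC:
    def test_six_in_tight_chain_is_one_cluster(self):
        out = detect_snc(_chain(6, gap=2.0))
        assert out.n_clusters == 1 and out.sizes[0] == 6

    def test_five_in_tight_chain_below_floor(self):
        assert detect_snc(_chain(5, gap=2.0)).n_clusters == 0

    def test_two_separated_groups_are_two_clusters(self):
        a = _chain(6, gap=2.0)
        b = _chain(6, gap=2.0)
        offset = a.centroids[:, 0].max() + 50.0 + 2 * 5.0
        cent = np.vstack([a.centroids, b.centroids + [offset, 0.0]])
        p = PointPattern(cent, np.full(12, 5.0))
        out = detect_snc(p)
        assert out.n_clusters == 2
        assert sorted(out.sizes.tolist()) == [6, 6]

    def test_gap_above_three_microns_breaks_the_chain(self):
        assert detect_snc(_chain(6, gap=3.5)).n_clusters == 0

    def test_rigid_motion_invariance(self, rng):
        pattern, _ = generate_clustered_pattern(GeneratorSpec(seed=4))
        base = detect_snc(pattern)
        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = PointPattern(pattern.centroids @ rot.T + [1000.0, -40.0],
                             pattern.radii)
        out = detect_snc(moved)
        assert sorted(out.sizes.tolist()) == sorted(base.sizes.tolist())
        assert np.array_equal(out.labels >= 0, base.labels >= 0)

    def test_membership_is_a_partition(self):
        pattern, _ = generate_clustered_pattern(GeneratorSpec(seed=9))
        out = detect_snc(pattern)
        flat = np.concatenate(out.members) if out.members else np.empty(0)
        assert flat.size == np.unique(flat).size

    def test_strict_mode_prunes_peripheral_nucleus(self):
        # 6-chain plus a hanger-on at 2.9 um from the end: the lenient call
        # absorbs it; strict mode removes nothing here (its own NN is within
        # 3 um) but does remove a nucleus whose nearest neighbour is beyond
        # the gap
        p = _chain(6, gap=2.0)
        out = detect_snc(p, strict=True)
        assert out.n_clusters == 1 and out.sizes[0] == 6


class TestDetectSNA:
    def test_ten_nuclei_form_an_aggregate(self):
        out = detect_sna(_chain(10, gap=2.0))
        assert out.n_clusters == 1 and out.requires_annotation

    def test_nine_nuclei_below_floor(self):
        assert detect_sna(_chain(9, gap=2.0)).n_clusters == 0

    def test_planted_sizes_12_10_4_give_two_aggregates(self):
        spec = GeneratorSpec(n_clusters=3, cluster_sizes=(12, 10, 4),
                            background_nuclei=0, seed=2)
        pattern, _ = generate_clustered_pattern(spec)
        out = detect_sna(pattern)
        assert out.n_clusters == 2
        assert sorted(out.sizes.tolist()) == [10, 12]


class TestDensityAndSize:
    def test_abstract_unit_convention_54_over_half_mm2(self):
        # 54 aggregates over 0.5 mm^2 of villous area -> 108 per mm^2
        spec = GeneratorSpec(
            n_clusters=54, cluster_size=10, background_nuclei=0,
            inter_cluster_spacing=100.0, field=(2000.0, 400.0), seed=3,
        )
        pattern, _ = generate_clustered_pattern(spec)
        clusters = detect_sna(pattern)
        out = sna_density_and_size(clusters, pattern, field_area_mm2=0.5)
        assert clusters.n_clusters == 54
        assert out["density_per_mm2"] == pytest.approx(108.0)

    def test_no_clusters_zero_density(self):
        p = PointPattern([[0, 0], [100, 0]], [5.0, 5.0], field_area_mm2=0.25)
        out = sna_density_and_size(detect_sna(p), p)
        assert out["density_per_mm2"] == 0.0 and out["areas_um2"] == []

    def test_hull_area_of_disc_pair_analytic(self):
        # hull of two discs radius r, centres d apart: pi r^2 + 2 r d
        r, d = 5.0, 8.0
        p = PointPattern([[0, 0], [d, 0]], [r, r], field_area_mm2=1.0)
        clusters = detect_snc(p, min_size=2)
        out = sna_density_and_size(clusters, p)
        expected = np.pi * r**2 + 2 * r * d
        assert out["areas_um2"][0] == pytest.approx(expected, rel=0.01)

    def test_missing_field_area_rejected(self):
        p = PointPattern([[0, 0], [13, 0]], [5.0, 5.0])
        with pytest.raises(ValueError):
            sna_density_and_size(detect_sna(p), p)


class TestLargeSyncytia:
    def test_area_per_nucleus_square_polygon(self):
        square = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])
        p = PointPattern([[20, 20], [20, 80], [80, 20], [80, 80]],
                         np.full(4, 4.5), boundary_polygon=square)
        out = large_syncytium_stats([p])
        assert out["per_cell"]["area_per_nucleus_um2"].iloc[0] == pytest.approx(2500.0)

    def test_five_nuclei_not_a_large_syncytium(self):
        square = Polygon([(0, 0), (60, 0), (60, 60), (0, 60)])
        cents = np.column_stack([np.linspace(10, 50, 5), np.full(5, 30.0)])
        p = PointPattern(cents, np.full(5, 4.5), boundary_polygon=square)
        out = large_syncytium_stats([p])
        assert not out["per_cell"]["is_large_syncytium"].iloc[0]
        assert out["percent_nuclei_in_large_syncytia"] == 0.0

    def test_known_population_percentages_recovered(self):
        cells = generate_cell_population(
            n_mononucleate=4, syncytium_sizes=(6, 10), seed=0
        )
        out = large_syncytium_stats(cells)
        # 16 of 20 nuclei sit in the two >=6-nucleus syncytia
        assert out["percent_nuclei_in_large_syncytia"] == pytest.approx(80.0)

    def test_cells_without_polygon_skipped_with_count(self):
        p1 = PointPattern([[0, 0]], [4.5])
        out = large_syncytium_stats([p1])
        assert out["n_skipped"] == 1 and len(out["per_cell"]) == 0


class TestParticles:
    def test_threshold_is_inclusive(self):
        assert filter_particles([50.0, 80.0, 100.0]).tolist() == [80.0, 100.0]

    def test_all_below_threshold_empty(self):
        assert filter_particles([10.0, 79.9]).size == 0

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            filter_particles([-1.0, 100.0])

    def test_retained_count_matches_counting_oracle(self, rng):
        areas = rng.lognormal(5.55, 0.55, size=10_000)
        kept = filter_particles(areas, 80.0)
        oracle = sum(1 for a in areas if a >= 80.0)
        assert kept.size == oracle


class TestSheddingFraction:
    def test_discussion_worked_numbers(self):
        # 77 particles/mg/48h over ~3800 SNAs/mg ~= 2%
        assert shedding_fraction(77.0, 3800.0) == pytest.approx(2.026, abs=0.001)

    def test_edge_values(self):
        assert shedding_fraction(0.0, 1000.0) == 0.0
        assert shedding_fraction(123.0, 123.0) == 100.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            shedding_fraction(10.0, 0.0)


def test_report_bundles_standard_measurements():
    pattern, labels = generate_clustered_pattern(
        GeneratorSpec(n_clusters=2, cluster_size=8, background_nuclei=5, seed=6)
    )
    report = MorphometryReport.from_pattern(pattern)
    assert report.summary["n_snc"] == 2
    assert report.summary["n_nuclei"] == labels.size
    assert 0 < report.summary["percent_nuclei_in_snc"] < 100
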