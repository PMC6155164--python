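"""Overlap counting, Monte Carlo randomization, the coefficient, and population summaries."""

import numpy as np
import pytest
from scipy import stats

import nanofoci as nf
from nanofoci._util import PlacementError, spawn_rng
from nanofoci.coloc import (
    build_timecourse_heatmap,
    colocalization_coefficient,
    count_overlaps,
    normalize_overlap,
    randomize_clusters,
    significance_stars,
    summarize_population,
)
from nanofoci.render import GridSpec, NucleusROI, disc_cluster_set

from conftest import make_disc_set


class TestCountOverlaps:
    def test_identity_overlap(self, square_roi, square_grid):
        cs = make_disc_set([[1000, 1000], [3000, 2500]], [120, 200], square_grid, roi=square_roi)
        n, area = count_overlaps(cs, cs)
        assert n == len(cs)
        assert area == cs.total_area_nm2

    def test_disjoint_sets(self, square_roi, square_grid):
        a = make_disc_set([[800, 800]], [150], square_grid, roi=square_roi)
        b = make_disc_set([[3000, 3000]], [150], square_grid, roi=square_roi)
        assert count_overlaps(a, b) == (0, 0.0)

    def test_hand_drawn_intersection(self):
        # two 5x5-pixel squares with a 2x3-pixel intersection
        from nanofoci.render import Cluster, ClusterSet

        grid = GridSpec(origin_nm=(0.0, 0.0), shape=(20, 20), pixel_nm=20.0)

        def square(r0, c0, cid):
            rr, cc = np.mgrid[r0 : r0 + 5, c0 : c0 + 5]
            rr, cc = rr.ravel(), cc.ravel()
            labels = np.zeros(grid.shape, int)
            labels[rr, cc] = cid
            cl = Cluster(id=cid, channel="x", rows=rr, cols=cc, intensities=np.ones(rr.size), area_nm2=rr.size * 400.0, com_nm=(0, 0))
            return ClusterSet(channel="x", grid=grid, clusters=[cl], label_image=labels, threshold=0.5)

        a = square(5, 5, 1)  # rows 5-9, cols 5-9
        b = square(8, 3, 2)  # rows 8-12, cols 3-7 -> intersection rows 8-9 x cols 5-7
        n, area = count_overlaps(a, b)
        assert n == 1
        assert area == 6 * 400.0

    def test_grid_mismatch_raises(self, square_roi, square_grid):
        a = make_disc_set([[800, 800]], [150], square_grid, roi=square_roi)
        other = GridSpec(origin_nm=(0.0, 0.0), shape=(10, 10), pixel_nm=20.0)
        b = make_disc_set([[100, 100]], [60], other)
        with pytest.raises(ValueError):
            count_overlaps(a, b)


class TestRandomizeClusters:
    def test_conservation_of_count_and_areas(self, square_roi, square_grid):
        cs = make_disc_set([[500, 500], [1500, 2500], [3200, 900]], [80, 150, 220], square_grid, roi=square_roi)
        out = randomize_clusters(cs, square_roi, np.random.default_rng(0))
        assert len(out) == len(cs)
        assert sorted(c.area_nm2 for c in out.clusters) == sorted(c.area_nm2 for c in cs.clusters)
        roi_mask = square_roi.mask(square_grid)
        for c in out.clusters:
            assert roi_mask[c.rows, c.cols].all()

    def test_single_pixel_cluster_uniform_over_roi(self):
        grid = GridSpec(origin_nm=(0.0, 0.0), shape=(10, 10), pixel_nm=20.0)
        roi = NucleusROI(polygon=[(0, 0), (200, 0), (200, 200), (0, 200)])
        cs = make_disc_set([[30, 30]], [10], grid, roi=roi)
        assert cs.clusters[0].n_pixels == 1
        rng = np.random.default_rng(1)
        counts = np.zeros(grid.shape)
        n_draws = 4000
        for _ in range(n_draws):
            out = randomize_clusters(cs, roi, rng)
            c = out.clusters[0]
            counts[c.rows[0], c.cols[0]] += 1
        chi = stats.chisquare(counts.ravel())
        assert chi.pvalue > 0.01

    def test_forced_placement_in_tight_roi(self):
        grid = GridSpec(origin_nm=(0.0, 0.0), shape=(30, 30), pixel_nm=20.0)
        full = NucleusROI(polygon=[(0, 0), (600, 0), (600, 600), (0, 600)])
        cs = make_disc_set([[300, 300]], [100], grid, roi=full)
        # mask-type ROI exactly equal to the cluster's own pixels: unique placement
        mask = np.zeros(grid.shape, bool)
        c = cs.clusters[0]
        mask[c.rows, c.cols] = True
        tight = NucleusROI(mask=mask, grid=grid)
        out = randomize_clusters(cs, tight, np.random.default_rng(2))
        np.testing.assert_array_equal(np.sort(out.clusters[0].rows), np.sort(c.rows))
        np.testing.assert_array_equal(np.sort(out.clusters[0].cols), np.sort(c.cols))

    def test_unplaceable_cluster_raises(self):
        grid = GridSpec(origin_nm=(0.0, 0.0), shape=(40, 40), pixel_nm=20.0)
        big_roi = NucleusROI(polygon=[(0, 0), (800, 0), (800, 800), (0, 800)])
        cs = make_disc_set([[400, 400]], [300], grid, roi=big_roi)
        tiny = NucleusROI(polygon=[(0, 0), (100, 0), (100, 100), (0, 100)])
        with pytest.raises(PlacementError):
            randomize_clusters(cs, tiny, np.random.default_rng(3), max_tries=500)


class TestCoefficient:
    def test_doubling_gives_exactly_two(self):
        sims = [5, 5, 5, 5, 5] * 4  # 20 simulated counts with mean 5
        assert normalize_overlap(10, sims) == 2.0

    def test_unity_when_observation_equals_sim_mean(self):
        assert normalize_overlap(7.0, [6.0, 8.0]) == 1.0

    def test_seed_determinism(self, square_roi, square_grid):
        a = make_disc_set([[1000, 1000], [2500, 2000]], [150, 200], square_grid, "naDNA", roi=square_roi)
        b = make_disc_set([[1100, 1050], [3000, 800]], [140, 180], square_grid, "RPA", roi=square_roi)
        r1 = colocalization_coefficient(a, b, square_roi, seed=17)
        r2 = colocalization_coefficient(a, b, square_roi, seed=17)
        np.testing.assert_array_equal(r1.sim_counts, r2.sim_counts)
        np.testing.assert_array_equal(r1.sim_areas_nm2, r2.sim_areas_nm2)
        assert r1.coefficient_area == r2.coefficient_area

    def test_full_overlap_in_sparse_roi_enriched(self):
        roi = NucleusROI(polygon=[(0, 0), (4000, 0), (4000, 4000), (0, 4000)])
        grid = roi.default_grid(20.0)
        centers = [[1000, 1000], [2500, 2500], [3200, 1200]]
        a = make_disc_set(centers, [300, 300, 300], grid, "naDNA", roi=roi)
        b = make_disc_set(centers, [300, 300, 300], grid, "RPA", roi=roi)
        res = colocalization_coefficient(a, b, roi, seed=3)
        assert res.coefficient_area > 5

    def test_empty_fixed_set_flagged_not_infinite(self, square_roi, square_grid):
        from nanofoci.render import ClusterSet

        empty = ClusterSet(channel="naDNA", grid=square_grid, clusters=[], label_image=np.zeros(square_grid.shape, int), threshold=1.0)
        b = make_disc_set([[1000, 1000]], [150], square_grid, "RPA", roi=square_roi)
        res = colocalization_coefficient(empty, b, square_roi, seed=4)
        assert res.insufficient_randomization_overlap
        assert np.isnan(res.coefficient_area)

    def test_translation_invariance_whole_pixels(self):
        grid = GridSpec(origin_nm=(0.0, 0.0), shape=(300, 300), pixel_nm=20.0)
        roi_a = NucleusROI(polygon=[(200, 200), (3200, 200), (3200, 3200), (200, 3200)])
        shift = 40.0 * 20  # 40 pixels
        roi_b = NucleusROI(polygon=[(200 + shift, 200 + shift), (3200 + shift, 200 + shift), (3200 + shift, 3200 + shift), (200 + shift, 3200 + shift)])
        centers = np.array([[1000.0, 1500.0], [2200.0, 900.0], [1400.0, 2600.0]])
        radii = [150, 220, 180]
        pcents = centers + [[120, -60], [400, 300], [-200, 150]]
        a1 = make_disc_set(centers, radii, grid, "naDNA", roi=roi_a)
        b1 = make_disc_set(pcents, radii, grid, "RPA", roi=roi_a)
        a2 = make_disc_set(centers + shift, radii, grid, "naDNA", roi=roi_b)
        b2 = make_disc_set(pcents + shift, radii, grid, "RPA", roi=roi_b)
        r1 = colocalization_coefficient(a1, b1, roi_a, seed=11)
        r2 = colocalization_coefficient(a2, b2, roi_b, seed=11)
        assert r1.n_real == r2.n_real
        assert r1.area_real_nm2 == r2.area_real_nm2
        np.testing.assert_array_equal(r1.sim_areas_nm2, r2.sim_areas_nm2)

    def test_monotone_in_colocalized_fraction(self):
        from nanofoci.synthetic import DisplacementModel, SceneConfig, generate_nucleus_scene

        means = []
        for f in (0.0, 0.3, 0.6, 0.9):
            coefs = []
            for rep in range(4):
                cfg = SceneConfig(
                    nucleus_axes_nm=(3000.0, 3000.0),
                    n_nadna_foci=30,
                    n_protein_clusters={"RPA": 30},
                    colocalized_fraction=f,
                    # colocalized clusters sit on their foci so that area
                    # enrichment tracks the colocalized fraction directly
                    displacement=DisplacementModel(center_nm=0.0, fwhm_nm=60.0),
                    seed=1000 + int(f * 10) * 7 + rep,
                )
                scene = generate_nucleus_scene(cfg)
                grid = scene.roi.default_grid(20.0)
                a = nf.segment_channel(nf.render(scene.locs, grid, channel="naDNA"), scene.roi)
                b = nf.segment_channel(nf.render(scene.locs, grid, channel="RPA"), scene.roi)
                coefs.append(colocalization_coefficient(a, b, scene.roi, seed=rep).coefficient_area)
            means.append(float(np.nanmean(coefs)))
        assert means[0] < means[1] < means[2] < means[3]


class TestPopulationSummary:
    def test_identical_groups_t_zero_p_one(self):
        out = summarize_population({("ctrl", 0.0): [1.0, 2.0, 3.0], ("cpt", 0.0): [1.0, 2.0, 3.0]}, reference_condition="ctrl")
        s = next(x for x in out if x.condition == "cpt")
        assert s.t_statistic == pytest.approx(0.0)
        assert s.p_value == pytest.approx(1.0)

    def test_zero_variance_guard(self):
        out = summarize_population({("ctrl", 0.0): [1.0, 1.0, 1.0], ("cpt", 0.0): [2.0, 2.0, 2.0]}, reference_condition="ctrl")
        s = next(x for x in out if x.condition == "cpt")
        assert s.p_value < 0.001

    def test_separated_groups_strongly_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 0.1, 20)
        b = rng.normal(1.5, 0.1, 20)
        out = summarize_population({("ctrl", 2.0): a, ("cpt", 2.0): b}, reference_condition="ctrl")
        s = next(x for x in out if x.condition == "cpt")
        assert s.p_value < 1e-4
        assert s.significance == "****"
        assert s.sem == pytest.approx(np.std(b, ddof=1) / np.sqrt(20))

    def test_small_group_flagged_without_sem(self):
        out = summarize_population({("cpt", 1.0): [1.3]}, reference_condition="ctrl")
        assert out[0].flagged and out[0].sem is None and out[0].p_value is None

    def test_significance_tiers(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.00004) == "****"
        assert significance_stars(0.2) == "ns"


class TestHeatmap:
    def test_single_cell_matrix(self):
        summ = summarize_population({("RAD51", 2.0): [1.5, 1.6]})
        mat = build_timecourse_heatmap(summ)
        assert mat.shape == (1, 1)
        assert mat.loc["RAD51", 2.0] == pytest.approx(1.55)

    def test_duplicate_entries_raise(self):
        summ = summarize_population({("RAD51", 2.0): [1.0, 1.2]})
        with pytest.raises(ValueError):
            build_timecourse_heatmap(summ + summ)

    def test_empty_input_gives_empty_matrix(self):
        assert build_timecourse_heatmap([]).empty

    def test_unimodal_timecourse_recovered(self):
        # arrival/accumulation/departure: coefficients rise then fall
        groups = {("RAD51", float(t)): [m + d for d in (-0.05, 0.0, 0.05)] for t, m in zip((0, 2, 4, 8, 16), (1.0, 1.8, 2.5, 1.9, 1.2))}
        mat = build_timecourse_heatmap(summarize_population(groups))
        row = mat.loc["RAD51"].to_numpy()
        peak = row.argmax()
        assert np.all(np.diff(row[: peak + 1]) > 0) and np.all(np.diff(row[peak:]) < 0)
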