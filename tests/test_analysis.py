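"""RMSD clustering, arrangement classification and distance statistics."""

import numpy as np
import pandas as pd
import pytest

from tmbundle import (
    Ensemble,
    arrangement_table,
    classify_arrangement,
    classify_ensemble,
    cluster,
    crossing_angle,
    distance_stats,
    enumerate_arrangements,
    gen_bundle_ensemble,
    gen_clustered_confs,
    pairwise_rmsd,
)
from tmbundle.analysis import UNCLASSIFIABLE, crossing_angle_filter, rmsd_matrix
from tmbundle.geometry import HelixSpec, build_ideal_helix


class TestPairwiseRmsd:
    def test_identical_zero(self, rng):
        c = rng.normal(size=(10, 3))
        assert pairwise_rmsd(c, c) == 0.0

    def test_uniform_translation_is_exact_shift(self, rng):
        c = rng.normal(size=(10, 3))
        assert np.isclose(pairwise_rmsd(c, c + np.array([3.0, 4.0, 0.0])), 5.0)

    def test_matches_naive_loop_oracle(self, rng):
        a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        naive = np.sqrt(
            sum(np.sum((a[i] - b[i]) ** 2) for i in range(10)) / 10.0
        )
        assert abs(pairwise_rmsd(a, b) - naive) < 1e-9

    def test_atom_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pairwise_rmsd(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))

    def test_superposed_rmsd_removes_rigid_motion(self, rng):
        c = rng.normal(size=(12, 3))
        theta = np.deg2rad(30)
        rz = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1.0],
        ])
        moved = c @ rz.T + np.array([1.0, 2.0, 3.0])
        assert pairwise_rmsd(c, moved) > 1.0
        assert pairwise_rmsd(c, moved, superpose=True) < 1e-9

    def test_condensed_matrix_matches_pairwise(self, rng):
        coords = rng.normal(size=(5, 8, 3))
        cond = rmsd_matrix(coords)
        k = 0
        for i in range(5):
            for j in range(i + 1, 5):
                assert np.isclose(cond[k], pairwise_rmsd(coords[i], coords[j]))
                k += 1


class TestClustering:
    def test_identical_conformations_single_cluster(self, specs):
        ens, _, _ = gen_clustered_confs(1, spread_A=0.0, n_per_cluster=6, seed=0)
        assert cluster(ens, cutoff=2.0).n_clusters == 1

    def test_two_planted_groups_recovered(self):
        ens, ids, _ = gen_clustered_confs(2, separation_A=20.0, spread_A=0.5,
                                          n_per_cluster=8, seed=3)
        result = cluster(ens, cutoff=2.0)
        assert result.n_clusters == 2
        # membership matches the planted ids up to relabeling
        for planted in (0, 1):
            found = result.labels[ids == planted]
            assert len(set(found)) == 1

    def test_complete_linkage_intra_cluster_bound(self):
        ens, _, _ = gen_clustered_confs(3, separation_A=12.0, spread_A=0.6,
                                        n_per_cluster=6, seed=5)
        result = cluster(ens, cutoff=2.0)
        for cl in range(result.n_clusters):
            members = result.members(cl)
            for i in members:
                for j in members:
                    assert pairwise_rmsd(ens.coords[i], ens.coords[j]) <= 2.0 + 1e-9

    def test_cluster_count_non_increasing_in_cutoff(self):
        ens, _, _ = gen_clustered_confs(4, separation_A=8.0, spread_A=1.0,
                                        n_per_cluster=5, seed=9)
        counts = [cluster(ens, cutoff=c).n_clusters for c in (0.5, 1.0, 2.0, 5.0, 40.0)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 1

    def test_centroid_minimizes_summed_rmsd(self):
        ens, _, _ = gen_clustered_confs(1, spread_A=0.8, n_per_cluster=7, seed=2)
        result = cluster(ens, cutoff=50.0)
        dm = rmsd_matrix(ens.coords)
        from scipy.spatial.distance import squareform
        sums = squareform(dm).sum(axis=1)
        assert result.centroid_indices[0] == int(np.argmin(sums))

    def test_empty_ensemble_rejected(self, specs):
        with pytest.raises(ValueError):
            cluster(Ensemble(specs, np.empty((0, sum(s.n_residues for s in specs), 3))))

    def test_two_stage_matches_exact_on_separated_groups(self):
        ens, ids, _ = gen_clustered_confs(3, separation_A=20.0, spread_A=0.4,
                                          n_per_cluster=10, seed=11)
        from tmbundle import RmsdClustering
        exact = RmsdClustering(cutoff=2.0).fit(ens.coords)
        staged = RmsdClustering(cutoff=2.0, exact_limit=5).fit(ens.coords)
        assert exact.n_clusters_ == staged.n_clusters_ == 3


class TestArrangements:
    def test_enumeration_matches_expected_set(self):
        labels = enumerate_arrangements()
        assert len(labels) == 6  # 3! cyclic orders anchored at A
        assert len(set(labels)) == 6
        assert set(labels) == {"ABCD", "ADBC", "ACDB", "ABDC", "ACBD", "ADCB"}

    def test_square_corner_examples(self):
        assert classify_arrangement(np.array([[-1, 1], [1, 1], [1, -1], [-1, -1]])) == "ABCD"
        assert classify_arrangement(np.array([[-1, 1], [-1, -1], [1, -1], [1, 1]])) == "ADCB"

    def test_global_z_rotation_invariance(self, rng):
        for _ in range(20):
            pts = rng.normal(scale=5.0, size=(4, 2))
            label = classify_arrangement(pts)
            if label == UNCLASSIFIABLE:
                continue
            theta = rng.uniform(0, 2 * np.pi)
            rz = np.array([
                [np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]
            ])
            assert classify_arrangement(pts @ rz.T) == label

    def test_degenerate_geometry_unclassifiable(self):
        coincident = np.array([[0, 0], [0, 0], [1, 1], [2, 0]], float)
        assert classify_arrangement(coincident) == UNCLASSIFIABLE
        collinear = np.array([[0, 0], [1, 0], [2, 0], [3, 0]], float)
        assert classify_arrangement(collinear) == UNCLASSIFIABLE


class TestArrangementTable:
    def test_reported_distribution_worked_example(self):
        # population counts with three dominant types out of 3520 members
        counts = {"ABDC": 1330, "ACBD": 862, "ADCB": 778,
                  "ABCD": 281, "ADBC": 213, "ACDB": 56}
        labels = [l for l, n in counts.items() for _ in range(n)]
        table = arrangement_table(labels, scores=None, top_k=100)
        assert table.n_total == 3520
        assert table.top3_share_all() == 84.4

    def test_top100_worked_example(self):
        counts = {"ABDC": 44, "ACBD": 27, "ADCB": 15, "ABCD": 9, "ADBC": 4, "ACDB": 1}
        labels = [l for l, n in counts.items() for _ in range(n)]
        scores = np.arange(len(labels))
        table = arrangement_table(labels, scores, top_k=100)
        assert sum(table.counts_top.values()) == 100
        assert table.top3_count_top() == 86

    def test_uniform_counts_top3_share(self):
        labels = [l for l in enumerate_arrangements() for _ in range(10)]
        assert arrangement_table(labels).top3_share_all() == 50.0

    def test_counts_sum_to_inputs(self, rng):
        labels = rng.choice(enumerate_arrangements(), size=57)
        scores = rng.normal(size=57)
        table = arrangement_table(labels, scores, top_k=20)
        assert sum(table.counts_all.values()) == 57
        assert sum(table.counts_top.values()) == 20

    def test_top_k_takes_lowest_scores(self):
        labels = ["ABCD"] * 3 + ["ADCB"] * 3
        scores = [5.0, 6.0, 7.0, 0.0, 1.0, 2.0]
        table = arrangement_table(labels, scores, top_k=3)
        assert table.counts_top == {"ADCB": 3}


class TestDistanceStats:
    def test_constructed_single_conformation(self, specs):
        ens, labels, _ = gen_bundle_ensemble(1, jitter_A=0.0, seed=0)
        # move Pro85 CA to exactly 15.6 A from Pro231 CA
        sl = ens.slices
        tm2, tm3 = ens.specs[1], ens.specs[2]
        i85 = sl["TM2"].start + tm2.index_of(85)
        i231 = sl["TM3"].start + tm3.index_of(231)
        direction = ens.coords[0, i85] - ens.coords[0, i231]
        direction /= np.linalg.norm(direction)
        ens.coords[0, i85] = ens.coords[0, i231] + 15.6 * direction
        stats = distance_stats(ens, labels)
        row = stats.loc[labels[0]]
        assert row.res_pair_mean == pytest.approx(15.6, abs=1e-9)
        assert row.res_pair_sd == 0.0

    def test_mean_sd_match_hand_computation(self, specs):
        ens, labels, _ = gen_bundle_ensemble(3, jitter_A=0.2, seed=8)
        labels[:] = "ABCD"
        sl = ens.slices
        tm2, tm3 = ens.specs[1], ens.specs[2]
        d = np.linalg.norm(
            ens.coords[:, sl["TM2"].start + tm2.index_of(85)]
            - ens.coords[:, sl["TM3"].start + tm3.index_of(231)],
            axis=1,
        )
        stats = distance_stats(ens, labels)
        assert stats.loc["ABCD", "res_pair_mean"] == pytest.approx(d.mean())
        assert stats.loc["ABCD", "res_pair_sd"] == pytest.approx(d.std(ddof=0))

    def test_interval_fraction_fully_inside(self, specs):
        ens, labels, _ = gen_bundle_ensemble(5, jitter_A=0.0, seed=1)
        stats = distance_stats(ens, labels, interval=(0.0, 1e6))
        assert (stats["frac_in_interval"] == 1.0).all()

    def test_missing_residue_rejected(self, specs):
        ens, labels, _ = gen_bundle_ensemble(2, jitter_A=0.0, seed=1)
        with pytest.raises(KeyError):
            distance_stats(ens, labels, res_i=999)


class TestCrossingAngle:
    def test_parallel_identical_zero(self):
        spec = HelixSpec("T", "A" * 15, 1, 15)
        c = build_ideal_helix(spec)
        assert abs(crossing_angle(c, c + np.array([9.0, 0, 0]))) < 1e-6

    def test_constructed_twenty_degree_tilt(self):
        spec = HelixSpec("T", "A" * 15, 1, 15)
        c = build_ideal_helix(spec)
        rot = np.deg2rad(20.0)
        ry = np.array([
            [np.cos(rot), 0, np.sin(rot)], [0, 1, 0], [-np.sin(rot), 0, np.cos(rot)]
        ])
        ang = crossing_angle(c, (c @ ry.T) + np.array([9.0, 0, 0]))
        assert abs(abs(ang) - 20.0) < 0.5  # discrete-trace axis wobble

    def test_antiparallel_untilted_zero_magnitude(self):
        # axes are unsigned lines: an exactly antiparallel pair crosses at 0
        line = np.column_stack([np.zeros(15), np.zeros(15), np.linspace(-10, 10, 15)])
        flipped = line[::-1] @ np.diag([1.0, -1.0, -1.0]) + np.array([9.0, 0, 0])
        assert abs(crossing_angle(line, flipped)) < 1e-9
        # real helical traces add only the discrete trace's axis wobble
        spec = HelixSpec("T", "A" * 15, 1, 15)
        c = build_ideal_helix(spec)
        anti = c @ np.diag([1.0, -1.0, -1.0]) + np.array([9.0, 0, 0])
        assert abs(crossing_angle(c, anti)) < 2.5

    def test_filter_keeps_untilted_bundles(self, specs):
        ens, _, _ = gen_bundle_ensemble(4, jitter_A=0.1, seed=2)
        assert crossing_angle_filter(ens, max_abs_deg=40.0).all()
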