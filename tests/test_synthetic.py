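"""Synthetic cohort generator tests: meshes, atlases, warps, sessions."""

import numpy as np
import pytest
import scipy.sparse.csgraph as csgraph

from msgcn import (
    ParcellationMap,
    SyntheticCohortConfig,
    build_adjacency,
    connectivity_fingerprint,
    dice_parcellation,
    initial_parcellation,
    intra_inter_dice,
    make_behavior,
    make_cohort,
    make_group_atlas,
    make_mesh,
    make_session,
    make_subject_truth,
)


class TestMakeMesh:
    @pytest.mark.parametrize(
        "sub, n_vertices, n_faces", [(0, 12, 20), (1, 42, 80), (2, 162, 320)]
    )
    def test_subdivision_counts(self, sub, n_vertices, n_faces):
        mesh = make_mesh(sub)
        assert mesh.n_vertices == n_vertices
        assert mesh.triangles.shape[0] == n_faces

    def test_euler_characteristic(self):
        for sub in (0, 1, 2, 3):
            mesh = make_mesh(sub)
            edges = set()
            for t in mesh.triangles:
                for a, b in ((0, 1), (1, 2), (0, 2)):
                    edges.add(tuple(sorted((t[a], t[b]))))
            assert mesh.n_vertices - len(edges) + mesh.triangles.shape[0] == 2

    def test_radius_and_size_guard(self):
        mesh = make_mesh(1)
        np.testing.assert_allclose(
            np.linalg.norm(mesh.coordinates, axis=1), 100.0, rtol=1e-6
        )
        with pytest.raises(ValueError, match="refused"):
            make_mesh(8)

    def test_medial_wall_cap(self):
        mesh = make_mesh(2, medial_wall_angle_deg=30.0)
        assert 0 < (~mesh.cortex_mask).sum() < mesh.n_vertices
        polar = mesh.coordinates[:, 2] > 100.0 * np.cos(np.radians(30.0))
        np.testing.assert_array_equal(~mesh.cortex_mask, polar)


class TestMakeGroupAtlas:
    def test_single_parcel_covers_cortex(self):
        mesh = make_mesh(1)
        atlas = make_group_atlas(mesh, 1, seed=0)
        assert (atlas.labels == 1).all()

    def test_labels_cover_exact_range(self):
        mesh = make_mesh(2, medial_wall_angle_deg=25.0)
        atlas = make_group_atlas(mesh, 6, seed=1)
        assert set(np.unique(atlas.labels[mesh.cortex_mask])) == set(range(1, 7))
        assert (atlas.labels[~mesh.cortex_mask] == 0).all()

    def test_every_parcel_connected_bfs_oracle(self):
        mesh = make_mesh(2)
        graph = build_adjacency(mesh)
        atlas = make_group_atlas(mesh, 10, seed=2, graph=graph)
        for k in range(1, 11):
            members = np.flatnonzero(atlas.labels == k)
            sub = graph.adjacency[np.ix_(members, members)]
            n_comp, _ = csgraph.connected_components(sub, directed=False)
            assert n_comp == 1

    def test_association_zone_tagged(self):
        mesh = make_mesh(2)
        atlas = make_group_atlas(mesh, 10, seed=3, association_fraction=0.4)
        assert (atlas.parcel_class == "association").sum() == 4

    def test_too_many_parcels_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_group_atlas(make_mesh(0), 13, seed=0)


@pytest.fixture(scope="module")
def setup():
    mesh = make_mesh(2)
    graph = build_adjacency(mesh)
    atlas = make_group_atlas(mesh, 8, seed=4, graph=graph)
    return mesh, graph, atlas


class TestMakeSubjectTruth:

    def test_zero_warp_is_identity(self, setup):
        _, graph, atlas = setup
        config = SyntheticCohortConfig(
            mesh_subdivisions=2, n_parcels=8,
            warp_steps_primary=0.0, warp_steps_association=0.0,
        )
        truth = make_subject_truth(atlas, graph, config, subject_seed=1)
        np.testing.assert_array_equal(truth.labels, atlas.labels)
        assert dice_parcellation(truth, ParcellationMap(labels=atlas.labels))[1] == 1.0

    def test_label_set_preserved_and_no_empty_parcel(self, setup):
        _, graph, atlas = setup
        config = SyntheticCohortConfig(mesh_subdivisions=2, n_parcels=8,
                                       warp_steps_primary=1.0,
                                       warp_steps_association=2.0)
        truth = make_subject_truth(atlas, graph, config, subject_seed=2)
        assert set(np.unique(truth.labels)) == set(np.unique(atlas.labels))

    def test_warp_reduces_dice_monotonically_in_expectation(self, setup):
        _, graph, atlas = setup
        am = ParcellationMap(labels=atlas.labels)
        means = []
        for warp in (0.1, 0.5, 1.5):
            config = SyntheticCohortConfig(
                mesh_subdivisions=2, n_parcels=8,
                warp_steps_primary=warp, warp_steps_association=warp,
                subject_scale_range=(1.0, 1.0),
            )
            d = [
                dice_parcellation(
                    make_subject_truth(atlas, graph, config, subject_seed=s), am
                )[1]
                for s in range(12)
            ]
            means.append(np.mean(d))
        assert means[0] > means[1] > means[2]

    def test_association_parcels_deviate_more(self, setup):
        """Across 20 subjects, association parcels have lower Dice to atlas."""
        _, graph, atlas = setup
        config = SyntheticCohortConfig(mesh_subdivisions=2, n_parcels=8)
        am = ParcellationMap(labels=atlas.labels)
        per_class = {"primary": [], "association": []}
        for s in range(20):
            truth = make_subject_truth(atlas, graph, config, subject_seed=s)
            per_k, _ = dice_parcellation(truth, am)
            for k, v in per_k.items():
                per_class[str(atlas.parcel_class[k - 1])].append(v)
        assert np.mean(per_class["association"]) < np.mean(per_class["primary"])

    def test_reproducible_from_seed(self, setup):
        _, graph, atlas = setup
        config = SyntheticCohortConfig(mesh_subdivisions=2, n_parcels=8)
        t1 = make_subject_truth(atlas, graph, config, subject_seed=9)
        t2 = make_subject_truth(atlas, graph, config, subject_seed=9)
        np.testing.assert_array_equal(t1.labels, t2.labels)


class TestMakeSession:
    def test_noise_free_limit_perfect_within_parcel_correlation(self, tiny_cohort):
        truth = tiny_cohort.subject_truths[0]
        config = SyntheticCohortConfig(
            mesh_subdivisions=2, n_parcels=8, n_timepoints=200, snr=1e6
        )
        ts = make_session(truth, config, session_seed=0)
        for k in (1, 4, 8):
            rows = ts.data[truth.labels == k]
            cc = np.corrcoef(rows)
            assert cc[np.triu_indices_from(cc, 1)].min() >= 0.99

    def test_within_exceeds_between_parcel_correlation(self, tiny_cohort):
        truth = tiny_cohort.subject_truths[0]
        config = SyntheticCohortConfig(
            mesh_subdivisions=2, n_parcels=8, n_timepoints=300, snr=1.0
        )
        ts = make_session(truth, config, session_seed=1)
        z = (ts.data - ts.data.mean(1, keepdims=True))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        cc = z @ z.T
        same = truth.labels[:, None] == truth.labels[None, :]
        off = ~np.eye(len(cc), dtype=bool)
        assert cc[same & off].mean() > cc[~same].mean()

    def test_sessions_share_truth_but_not_data(self, tiny_cohort):
        truth = tiny_cohort.subject_truths[0]
        config = SyntheticCohortConfig(mesh_subdivisions=2, n_parcels=8,
                                       n_timepoints=200)
        ts1 = make_session(truth, config, session_seed=1)
        ts2 = make_session(truth, config, session_seed=2)
        assert not np.allclose(ts1.data, ts2.data)
        # both sessions point to the same optimal parcellation
        for ts in (ts1, ts2):
            pm = initial_parcellation(
                connectivity_fingerprint(ts, tiny_cohort.atlas),
                tiny_cohort.atlas,
            )
            assert (pm.labels == truth.labels).mean() > 0.8

    def test_too_few_timepoints_rejected(self, tiny_cohort):
        config = SyntheticCohortConfig(mesh_subdivisions=2, n_parcels=8,
                                       n_timepoints=50)
        config.n_timepoints = 10  # bypass dataclass check to hit the guard
        with pytest.raises(ValueError, match="50"):
            make_session(tiny_cohort.subject_truths[0], config, session_seed=0)


class TestMakeBehavior:
    def test_zero_effect_gives_pure_noise(self, tiny_cohort):
        config = SyntheticCohortConfig(
            mesh_subdivisions=2, n_parcels=8, behavior_effect=0.0,
            behavior_noise=1.0,
        )
        scores, _ = make_behavior(
            tiny_cohort.subject_truths, tiny_cohort.atlas, config, seed=0
        )
        assert scores.std() > 0  # noise only, but not constant

    def test_duplicated_subject_same_score_without_noise(self, tiny_cohort):
        config = SyntheticCohortConfig(mesh_subdivisions=2, n_parcels=8,
                                       behavior_noise=0.0)
        truths = [tiny_cohort.subject_truths[0]] * 2 + tiny_cohort.subject_truths[1:3]
        scores, _ = make_behavior(truths, tiny_cohort.atlas, config, seed=0)
        assert scores[0] == pytest.approx(scores[1], rel=1e-12)


class TestCohortStructure:
    def test_bit_reproducible(self):
        config = SyntheticCohortConfig(mesh_subdivisions=2, n_parcels=6,
                                       n_subjects=3, n_timepoints=100, seed=5)
        c1 = make_cohort(config)
        c2 = make_cohort(config)
        np.testing.assert_array_equal(c1.atlas.labels, c2.atlas.labels)
        for t1, t2 in zip(c1.subject_truths, c2.subject_truths):
            np.testing.assert_array_equal(t1.labels, t2.labels)
        np.testing.assert_array_equal(c1.sessions[0][0].data, c2.sessions[0][0].data)
        np.testing.assert_array_equal(c1.behavior_scores, c2.behavior_scores)

    def test_initial_maps_intra_exceeds_inter(self, tiny_cohort):
        """Similarity-based maps already show the intra > inter structure."""
        maps = []
        for s, sessions in enumerate(tiny_cohort.sessions):
            for ts in sessions:
                pm = initial_parcellation(
                    connectivity_fingerprint(ts, tiny_cohort.atlas),
                    tiny_cohort.atlas,
                )
                pm.subject_id = f"sub{s}"
                maps.append(pm)
        sim = intra_inter_dice(maps)
        assert sim.intra.mean() > sim.inter.mean()

    def test_default_snr_fingerprints_identify_truth(self, tiny_cohort):
        """At the default SNR the fingerprint argmax recovers >90% of labels."""
        hits = []
        for s in range(3):
            truth = tiny_cohort.subject_truths[s]
            sig = connectivity_fingerprint(
                tiny_cohort.sessions[s][0], tiny_cohort.atlas
            )
            pm = initial_parcellation(sig, tiny_cohort.atlas)
            hits.append((pm.labels == truth.labels).mean())
        assert np.mean(hits) > 0.9
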