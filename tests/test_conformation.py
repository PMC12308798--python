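"""g3 fingerprints, SSIM similarity, embedding/clustering, motif taxonomy."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity as sk_ssim

from lamella.conformation import (
    G3_BINS,
    G3_CUTOFF,
    ClusterResult,
    MotifClusterer,
    SimilarityMatrix,
    build_similarity_matrix,
    characterize_clusters,
    compute_g3,
    compute_g3_all,
    conformation_scores,
    embed_and_cluster,
    ssim_score,
)
from lamella.core import TrajectoryData, mmg_topology
from lamella.synthetic import SyntheticSystemSpec, generate_membrane_trajectory


def g3_oracle(points, cutoff=G3_CUTOFF):
    """Exhaustive triple-loop enumeration: B over all atoms, A = nearest
    (ties to lowest index), C over every atom except B within the cutoff."""
    n_r, n_a = G3_BINS
    hist = np.zeros(G3_BINS)
    n = len(points)
    for b in range(n):
        dists = [
            np.linalg.norm(points[c] - points[b]) if c != b else np.inf for c in range(n)
        ]
        a = int(np.argmin(dists))
        ba = (points[a] - points[b]) / dists[a]
        for c in range(n):
            if c == b:
                continue
            r = np.linalg.norm(points[c] - points[b])
            if r > cutoff:
                continue
            cos = np.clip(ba @ (points[c] - points[b]) / r, -1.0, 1.0)
            ri = min(int(r / cutoff * n_r), n_r - 1)
            ci = min(int((cos + 1.0) / 2.0 * n_a), n_a - 1)
            hist[ri, ci] += 1.0
    return hist / hist.sum()


def traj_from_points(points):
    """Single-lipid, single-frame trajectory whose g3 selection sits at
    ``points`` (padded with far-away atoms for the rest of the lipid)."""
    topo = mmg_topology()
    apl = topo.atoms_per_lipid
    coords = np.zeros((1, apl, 3), dtype=np.float64)
    coords[0, :, 0] = np.arange(apl) * 1000.0 + 5e5  # park everything far away
    sel = topo.indices_of(topo.g3_selection[: len(points)])
    coords[0, sel] = points
    return (
        TrajectoryData(
            times=[0.0],
            box=np.array([[1e7, 1e7, 1e7]]),
            coords=coords,
            topology=topo,
            n_lipids=1,
            molecule_index=np.repeat(0, apl),
            atom_names=np.array(sorted(topo.name_map, key=topo.name_map.get)),
        ),
        tuple(topo.g3_selection[: len(points)]),
    )


class TestComputeG3:
    def test_collinear_triple_matches_oracle(self):
        pts = np.array([[0, 0, 0], [0, 0, 1.53], [0, 0, 3.06]])
        traj, sel = traj_from_points(pts)
        h = compute_g3(traj, 0, selection=sel)
        np.testing.assert_array_equal(h.values, g3_oracle(pts))
        # expected occupied cells: nearest-neighbour deposits at
        # (1.53, cos=+1) and (1.53, cos=-1), plus the far end at (3.06, +1)
        nz = {tuple(ij) for ij in np.argwhere(h.values > 0)}
        r_bin = lambda r: min(int(r / G3_CUTOFF * 201), 200)
        c_bin = lambda c: min(int((c + 1) / 2 * 101), 100)
        assert nz == {
            (r_bin(1.53), c_bin(-1.0)),
            (r_bin(1.53), c_bin(1.0)),
            (r_bin(3.06), c_bin(1.0)),
        }

    def test_equilateral_triangle_cells(self):
        d = 2.0
        pts = np.array([[0, 0, 0], [d, 0, 0], [d / 2, d * np.sqrt(3) / 2, 0]])
        traj, sel = traj_from_points(pts)
        h = compute_g3(traj, 0, selection=sel)
        np.testing.assert_array_equal(h.values, g3_oracle(pts))
        nz = np.argwhere(h.values > 0)
        r_centres = (nz[:, 0] + 0.5) * (G3_CUTOFF / 201)
        cos_centres = -1 + (nz[:, 1] + 0.5) * (2 / 101)
        # all pair distances are d; angles are 0 (C = A) or 60 deg
        assert np.all(np.abs(r_centres - d) < G3_CUTOFF / 201)
        assert set(np.round(cos_centres, 1)) <= {0.5, 1.0}

    def test_atom_beyond_cutoff_excluded(self):
        pts = np.array([[0, 0, 0], [0, 0, 1.53], [0, 0, 20.0]])
        traj, sel = traj_from_points(pts)
        h = compute_g3(traj, 0, selection=sel)
        np.testing.assert_array_equal(h.values, g3_oracle(pts))
        r_centres = (np.argwhere(h.values > 0)[:, 0] + 0.5) * (G3_CUTOFF / 201)
        assert r_centres.max() < 15.0  # the 20 A atom never appears as C

    def test_random_cloud_matches_oracle_cell_exact(self):
        rng = np.random.default_rng(12)
        for trial in range(3):
            pts = rng.uniform(0, 12, size=(rng.integers(5, 30), 3))
            traj, sel = traj_from_points(pts)
            h = compute_g3(traj, 0, selection=sel)
            np.testing.assert_allclose(h.values, g3_oracle(pts), atol=1e-12)

    def test_selection_too_small_rejected(self):
        pts = np.array([[0, 0, 0], [0, 0, 1.53]])
        traj, sel = traj_from_points(pts)
        with pytest.raises(ValueError):
            compute_g3(traj, 0, selection=sel)

    def test_unit_mass_and_grid(self, small_bilayer):
        traj, _ = small_bilayer
        h = compute_g3(traj, 3)
        assert h.values.shape == G3_BINS
        assert h.values.sum() == pytest.approx(1.0)
        assert np.all(h.values >= 0)


class TestSsim:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.random(G3_BINS)
        assert ssim_score(x, x) == pytest.approx(1.0)

    def test_equal_constants_give_one(self):
        x = np.full(G3_BINS, 3.7)
        assert ssim_score(x, x.copy()) == pytest.approx(1.0)

    def test_flat_shift_matches_luminance_closed_form(self):
        mu1, mu2, dr = 1.0, 1.5, 2.0
        x = np.full(G3_BINS, mu1)
        y = np.full(G3_BINS, mu2)
        c1 = (0.01 * dr) ** 2
        lum = (2 * mu1 * mu2 + c1) / (mu1**2 + mu2**2 + c1)
        assert ssim_score(x, y, data_range=dr) == pytest.approx(lum, rel=1e-12)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(1)
        for _ in range(4):
            x = rng.random(G3_BINS)
            y = x + 0.5 * rng.random(G3_BINS)
            dr = float(max(x.max(), y.max()) - min(x.min(), y.min()))
            mine = ssim_score(x, y, window=7, data_range=dr)
            ref = sk_ssim(x, y, win_size=7, data_range=dr)
            assert mine == pytest.approx(ref, abs=1e-9)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(G3_BINS), rng.random(G3_BINS)
        assert ssim_score(x, y) == pytest.approx(ssim_score(y, x), abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim_score(np.zeros(G3_BINS), np.zeros((10, 10)))


class TestSimilarityMatrix:
    def test_identical_histograms_all_ones(self):
        x = np.tile(np.random.default_rng(3).random(G3_BINS)[None], (5, 1, 1))
        m = build_similarity_matrix(x)
        np.testing.assert_allclose(m.values, 1.0, atol=1e-6)

    def test_two_histograms_off_diagonal(self):
        rng = np.random.default_rng(4)
        h = rng.random((2,) + G3_BINS)
        m = build_similarity_matrix(h)
        dr = float(h.max() - h.min())
        expected = ssim_score(h[0].astype(np.float32), h[1].astype(np.float32),
                              data_range=dr)
        assert m.values[0, 1] == pytest.approx(expected, abs=1e-6)
        assert m.values[0, 1] == m.values[1, 0]
        np.testing.assert_array_equal(np.diag(m.values), 1.0)

    def test_permutation_consistency(self):
        rng = np.random.default_rng(5)
        h = rng.random((8,) + G3_BINS).astype(np.float32)
        m = build_similarity_matrix(h).values
        perm = rng.permutation(8)
        mp = build_similarity_matrix(h[perm]).values
        np.testing.assert_allclose(mp, m[np.ix_(perm, perm)], atol=1e-7)

    def test_within_family_exceeds_between_family(self, motif_families_small):
        H, gt = motif_families_small
        fam = gt.motif.values
        m = build_similarity_matrix(H).values
        a, b = fam == 1, fam == 2
        within = np.concatenate([m[np.ix_(a, a)].ravel(), m[np.ix_(b, b)].ravel()])
        between = m[np.ix_(a, b)].ravel()
        assert within.mean() > between.mean()


@pytest.fixture(scope="session")
def motif_families_small():
    """g3 histograms of a 2-family system (motifs 1 and 2, 50 lipids each)."""
    spec = SyntheticSystemSpec(
        n_per_leaflet=50, motif_fractions=(0.0, 0.5, 0.5, 0.0), n_frames=6, seed=31
    )
    traj, gt = generate_membrane_trajectory(spec)
    return compute_g3_all(traj), gt


class TestEmbedAndCluster:
    def test_two_planted_families_recovered(self, motif_families_small):
        H, gt = motif_families_small
        sim = build_similarity_matrix(H)
        res = embed_and_cluster(sim, perplexity=25, min_cluster_size=20, seed=0)
        assert res.n_clusters == 2
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(gt.motif.values, res.labels) > 0.9

    def test_single_family_single_cluster(self):
        spec = SyntheticSystemSpec(
            n_per_leaflet=60, motif_fractions=(0.0, 1.0, 0.0, 0.0), n_frames=6, seed=33
        )
        traj, _ = generate_membrane_trajectory(spec)
        H = compute_g3_all(traj)
        res = embed_and_cluster(build_similarity_matrix(H), perplexity=25,
                                min_cluster_size=50, seed=0)
        assert res.n_clusters == 1

    def test_min_cluster_size_forces_noise(self):
        rng = np.random.default_rng(6)
        h = rng.random((40,) + G3_BINS).astype(np.float32)
        res = embed_and_cluster(build_similarity_matrix(h), perplexity=10,
                                min_cluster_size=50, seed=0)
        assert np.all(res.labels == -1)

    def test_too_few_samples_names_perplexity(self):
        rng = np.random.default_rng(7)
        h = rng.random((50,) + G3_BINS).astype(np.float32)
        with pytest.raises(ValueError, match="perplexity"):
            embed_and_cluster(build_similarity_matrix(h), perplexity=100)

    def test_pca_validation_separates_tsne_clusters(self, motif_families_small):
        """Clusters found in t-SNE space stay separated in the independent
        PCA embedding (silhouette > 0)."""
        from sklearn.metrics import silhouette_score

        H, _ = motif_families_small
        sim = build_similarity_matrix(H)
        res = embed_and_cluster(sim, perplexity=25, min_cluster_size=20, seed=0)
        mask = res.labels >= 0
        assert silhouette_score(res.pca_embedding[mask], res.labels[mask]) > 0


class TestCharacterize:
    def test_pure_motif_scores_follow_taxonomy(self):
        """All-trans closed lipids score highest on both axes -> motif 1;
        gauche-rich splayed lipids lowest trans/gauche -> motif 2."""
        mean_h = {}
        for motif in (0, 1, 2, 3):
            fr = [0.0] * 4
            fr[motif] = 1.0
            spec = SyntheticSystemSpec(
                n_per_leaflet=30, motif_fractions=tuple(fr), n_frames=6, seed=40 + motif
            )
            traj, _ = generate_membrane_trajectory(spec)
            mean_h[motif] = compute_g3_all(traj).mean(axis=0).astype(float)
        scores = {m: conformation_scores(h) for m, h in mean_h.items()}
        tg, pk = zip(*[scores[m] for m in range(4)])
        assert np.argmax(tg) == 1 and np.argmax(pk) == 1
        assert np.argmin(tg) == 2
        # full quadrant assignment through the cluster characteriser
        labels = np.repeat(np.arange(4), 30)
        H = np.stack([mean_h[m] for m in range(4)]).repeat(30, axis=0)
        res = ClusterResult(
            embedding=np.zeros((120, 2)), labels=labels, pca_embedding=np.zeros((120, 2))
        )
        characterize_clusters(res, H)
        assert res.motif_map == {0: 0, 1: 1, 2: 2, 3: 3}

    def test_fraction_bookkeeping(self):
        rng = np.random.default_rng(8)
        labels = np.repeat(np.arange(4), 25)
        H = rng.random((100,) + G3_BINS)
        res = ClusterResult(
            embedding=np.zeros((100, 2)), labels=labels, pca_embedding=np.zeros((100, 2))
        )
        characterize_clusters(res, H)
        frac = res.fractions[0]
        total = sum(frac.values())
        assert total == pytest.approx(100.0)
        non_noise = {k: v for k, v in frac.items() if k != "noise"}
        assert sum(non_noise.values()) == pytest.approx(100.0)

    def test_all_noise_rejected(self):
        res = ClusterResult(
            embedding=np.zeros((10, 2)),
            labels=np.full(10, -1),
            pca_embedding=np.zeros((10, 2)),
        )
        with pytest.raises(ValueError):
            characterize_clusters(res, np.zeros((10,) + G3_BINS))


class TestMotifClusterer:
    def test_estimator_params_round_trip(self):
        est = MotifClusterer(perplexity=25, min_cluster_size=20)
        params = est.get_params()
        assert params["perplexity"] == 25
        est.set_params(random_state=7)
        assert est.random_state == 7
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_fit_exposes_sklearn_style_attributes(self, motif_families_small):
        H, gt = motif_families_small
        est = MotifClusterer(perplexity=25, min_cluster_size=20, random_state=0)
        labels = est.fit_predict(H)
        assert labels.shape == (len(H),)
        assert est.embedding_.shape == (len(H), 2)
        assert est.pca_embedding_.shape == (len(H), 2)
        assert set(est.motif_map_.values()) <= {0, 1, 2, 3}
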