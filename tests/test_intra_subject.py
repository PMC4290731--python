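import numpy as np
import pytest

from dsfiber.dominant_sets import DominantSet
from dsfiber.evaluation import adjusted_rand_index
from dsfiber.fiber_model import resample
from dsfiber.intra_subject import (
    SubjectClustering,
    cluster_subject,
    medoid,
    normalize_cohesiveness,
    select_clusters,
)
from dsfiber.synthetic_data import SyntheticConfig, generate_bundle, generate_subject


class TestClusterSubject:
    def test_well_separated_bundles_recovered_exactly(self):
        cfg = SyntheticConfig(n_bundles=3, fibers_per_bundle=20, seed=3)
        tractogram, labels = generate_subject(cfg)
        fibers = [resample(f, 12) for f in tractogram.fibers]
        clustering = cluster_subject(fibers)
        non_residual = [c for c in clustering.clusters if not c.residual]
        assert len(non_residual) == 3
        assert adjusted_rand_index(labels, clustering.labels()) == 1.0

    def test_duplicate_fibers_always_co_clustered(self, random_fiber_factory):
        fibers = [random_fiber_factory() for _ in range(10)]
        doubled = fibers + fibers
        clustering = cluster_subject(doubled)
        labels = clustering.labels()
        for i in range(10):
            assert labels[i] == labels[i + 10]

    def test_tight_bundle_forms_one_cluster_at_dataset_scale(self, rng):
        """When within-bundle distances are small relative to the affinity
        normalization (the multi-bundle regime), the whole bundle is one
        dominant set."""
        from dsfiber.dominant_sets import peel
        from dsfiber.metrics import build_affinity, pairwise_distance_matrix

        centerline = np.c_[np.linspace(0, 30, 30), np.zeros(30), np.zeros(30)]
        bundle = generate_bundle(centerline, 60, spread=0.5, rng=rng)
        fibers = [resample(f, 12) for f in bundle]
        d = pairwise_distance_matrix(fibers, metric="pp")
        # sigma as a larger dataset would set it: far above intra distances
        aff = build_affinity(d, sigma=10.0 * float(d.max()))
        clusters = peel(aff.values)
        assert clusters[0].size >= 0.95 * len(fibers)

    def test_fewer_than_two_fibers_rejected(self, random_fiber_factory):
        with pytest.raises(ValueError):
            cluster_subject([random_fiber_factory()])


class TestNormalizeCohesiveness:
    def test_exact_quadratic_leaves_zero_residuals(self):
        ranks = np.arange(20.0)
        curve = 3.0 - 0.1 * ranks + 0.002 * ranks**2
        res = normalize_cohesiveness(curve)
        assert np.abs(res).max() < 1e-10

    def test_planted_dip_survives_detrending(self):
        ranks = np.arange(40.0)
        curve = 5.0 - 0.05 * ranks + 0.001 * ranks**2
        curve[10] -= 0.5
        res = normalize_cohesiveness(curve)
        assert res[10] == pytest.approx(-0.5, abs=0.05)

    def test_residuals_sum_to_zero(self, rng):
        curve = rng.random(15)
        assert normalize_cohesiveness(curve).sum() == pytest.approx(0.0, abs=1e-9)

    def test_short_curve_fallback_centers(self):
        res = normalize_cohesiveness(np.array([1.0, 3.0]))
        np.testing.assert_allclose(res, [-1.0, 1.0])


def _fake_clustering(curve, residual_flags=None):
    n = len(curve)
    flags = residual_flags or [False] * n
    clusters = [
        DominantSet(
            support=np.array([i]),
            x=np.array([1.0]),
            cohesiveness=float(c),
            extraction_rank=i,
            residual=flags[i],
        )
        for i, c in enumerate(curve)
    ]
    return SubjectClustering(
        subject_id="s",
        clusters=clusters,
        distance_matrix=np.zeros((n, n)),
        sigma=1.0,
    )


class TestSelectClusters:
    def test_five_percent_tail_count(self):
        curve = np.linspace(5.0, 1.0, 40)
        out = select_clusters(_fake_clustering(curve), tail_fraction=0.05, alpha=0.0)
        dropped = np.flatnonzero(~out.kept_mask)
        assert dropped.tolist() == [38, 39]  # ceil(0.05 * 40) = 2, last ranks

    def test_planted_negative_outlier_rejected(self):
        ranks = np.arange(40.0)
        curve = 5.0 - 0.05 * ranks + 0.001 * ranks**2
        curve[10] -= 10 * 0.01  # far below the residual spread of the rest
        out = select_clusters(_fake_clustering(curve), tail_fraction=0.05, alpha=0.05)
        dropped = set(np.flatnonzero(~out.kept_mask).tolist())
        assert dropped == {10, 38, 39}

    def test_alpha_zero_skips_gaussian_rejection(self):
        curve = np.concatenate([np.linspace(5, 4, 19), [0.1]])
        out = select_clusters(_fake_clustering(curve), tail_fraction=0.0, alpha=0.0)
        assert out.kept_mask.all()

    def test_residual_singletons_always_dropped(self):
        curve = np.array([3.0, 2.5, 0.0])
        clustering = _fake_clustering(curve, residual_flags=[False, False, True])
        out = select_clusters(clustering, tail_fraction=0.0, alpha=0.0)
        assert out.kept_mask.tolist() == [True, True, False]

    def test_never_increases_cluster_count_and_preserves_order(self):
        curve = np.linspace(4.0, 1.0, 25)
        out = select_clusters(_fake_clustering(curve))
        assert len(out.clusters) == 25
        kept = out.kept_clusters
        ranks = [c.extraction_rank for c in kept]
        assert ranks == sorted(ranks)
        assert len(kept) <= 25

    def test_medoids_belong_to_their_clusters(self, small_subject):
        fibers, _ = small_subject
        out = select_clusters(cluster_subject(fibers))
        for cluster in out.kept_clusters:
            m = out.medoid_indices[cluster.extraction_rank]
            assert m in cluster.support.tolist()


class TestMedoid:
    def test_singleton(self):
        assert medoid([3], np.zeros((5, 5))) == 3

    def test_collinear_offsets_pick_middle(self):
        d = np.abs(np.subtract.outer([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]))
        assert medoid([0, 1, 2], d) == 1

    def test_matches_brute_force_row_sums(self, rng):
        d = rng.random((12, 12))
        d = np.triu(d, 1)
        d = d + d.T
        members = rng.choice(12, size=10, replace=False)
        sub = d[np.ix_(sorted(members), sorted(members))]
        expected = sorted(members)[int(np.argmin(sub.sum(axis=1)))]
        assert medoid(members, d) == expected

    def test_invariant_to_member_ordering(self, rng):
        d = rng.random((8, 8))
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0)
        members = [5, 1, 7, 2]
        assert medoid(members, d) == medoid(sorted(members), d)
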