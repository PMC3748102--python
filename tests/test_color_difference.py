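"""Earth Mover's Distance, group comparisons and distance embeddings."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from floracolor.color_difference import (
    Signature,
    emd,
    make_signature,
    binned_signature,
    pairwise_euclidean,
    species_emd_profile,
    tukey_hsd,
)
from floracolor.color_difference import _emd_lp
from floracolor.colorspace import PixelCloudLab


def emd_oracle_by_expansion(points_a, ints_a, points_b, ints_b):
    """Exact EMD for rational weights: expand to unit masses and solve assignment.

    Weights are given as positive integers (numerators over a common total);
    both totals must match.  Independent of the package's LP/assignment
    code path: builds the expanded cost matrix explicitly.
    """
    assert sum(ints_a) == sum(ints_b)
    total = sum(ints_a)
    ea = np.repeat(np.asarray(points_a, float), ints_a, axis=0)
    eb = np.repeat(np.asarray(points_b, float), ints_b, axis=0)
    cost = cdist(ea, eb)
    r, c = linear_sum_assignment(cost)
    return cost[r, c].sum() / total


def _random_signature(rng, k, integer_weights=True):
    pts = rng.uniform([0, -60, -60], [100, 60, 60], size=(k, 3))
    if integer_weights:
        ints = rng.integers(1, 6, size=k)
        return Signature(points=pts, weights=ints / ints.sum()), ints
    w = rng.uniform(0.1, 1.0, size=k)
    return Signature(points=pts, weights=w / w.sum()), None


class TestSignature:
    def test_small_cloud_kept_in_full(self, rng):
        cloud = PixelCloudLab(points=rng.uniform([0, -50, -50], [100, 50, 50], (100, 3)))
        sig = make_signature(cloud, max_points=500)
        assert sig.k == 100
        np.testing.assert_allclose(sig.weights, 0.01)

    def test_subsample_deterministic_under_seed(self, rng):
        cloud = PixelCloudLab(points=rng.uniform([0, -50, -50], [100, 50, 50], (5000, 3)))
        s1 = make_signature(cloud, max_points=100, seed=42)
        s2 = make_signature(cloud, max_points=100, seed=42)
        np.testing.assert_array_equal(s1.points, s2.points)
        assert s1.provenance["subsampled"]

    def test_subsampling_error_small_on_gaussian_cloud(self, rng):
        # subsampled signature must sit close to the full-cloud signature
        pts = rng.normal([50.0, 5.0, 40.0], 3.0, size=(20_000, 3))
        cloud = PixelCloudLab(points=np.clip(pts, [0, -128, -128], [100, 128, 128]))
        full = make_signature(cloud, max_points=1000, seed=0)
        errs = [
            emd(make_signature(cloud, max_points=500, seed=s), full).distance
            for s in range(5)
        ]
        assert max(errs) < 2.0

    def test_weight_normalisation_and_validation(self):
        sig = Signature(points=[[0, 0, 0], [1, 0, 0]], weights=[2.0, 2.0])
        np.testing.assert_allclose(sig.weights, [0.5, 0.5])
        with pytest.raises(ValueError):
            Signature(points=[[0, 0, 0]], weights=[-1.0])

    def test_binned_signature_mass_and_support(self, rng):
        cloud = PixelCloudLab(points=rng.normal([50, 0, 40], 5, (5000, 3)))
        sig = binned_signature(cloud, bins_per_axis=8)
        assert sig.weights.sum() == pytest.approx(1.0)
        assert sig.k <= 8**3
        # binned EMD to the subsampled signature stays within a bin diagonal
        sub = make_signature(cloud, max_points=500, seed=0)
        assert emd(sig, sub).distance < np.linalg.norm([100 / 8, 256 / 8, 256 / 8])


class TestEmd:
    def test_identical_signatures(self, rng):
        sig, _ = _random_signature(rng, 5)
        assert emd(sig, sig).distance == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_closed_form(self):
        a = Signature(points=[[0.0, 0.0, 0.0]], weights=[1.0])
        b = Signature(points=[[3.0, 4.0, 0.0]], weights=[1.0])
        assert emd(a, b).distance == pytest.approx(5.0, abs=1e-12)

    def test_two_point_unbalanced_weights(self):
        # half the mass at distance 10 must move 0.25 of total weight
        a = Signature(points=[[0, 0, 0], [10, 0, 0]], weights=[0.5, 0.5])
        b = Signature(points=[[0, 0, 0], [10, 0, 0]], weights=[0.25, 0.75])
        res = emd(a, b, return_flow=True)
        assert res.distance == pytest.approx(2.5, abs=1e-9)
        np.testing.assert_allclose(res.flow.sum(axis=1), a.weights, atol=1e-9)
        np.testing.assert_allclose(res.flow.sum(axis=0), b.weights, atol=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_expansion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ka, kb = rng.integers(2, 7, size=2)
        ints_a = rng.integers(1, 5, size=ka)
        ints_b = rng.integers(1, 5, size=kb)
        # rescale to a common total mass
        total = int(np.lcm(ints_a.sum(), ints_b.sum()))
        ints_a = ints_a * (total // ints_a.sum())
        ints_b = ints_b * (total // ints_b.sum())
        pts_a = rng.uniform([0, -60, -60], [100, 60, 60], size=(ka, 3))
        pts_b = rng.uniform([0, -60, -60], [100, 60, 60], size=(kb, 3))
        sig_a = Signature(points=pts_a, weights=ints_a / total)
        sig_b = Signature(points=pts_b, weights=ints_b / total)
        expected = emd_oracle_by_expansion(pts_a, ints_a, pts_b, ints_b)
        assert emd(sig_a, sig_b).distance == pytest.approx(expected, abs=1e-9)

    def test_uniform_fast_path_equals_lp(self, rng):
        pts_a = rng.uniform(0, 50, (8, 3))
        pts_b = rng.uniform(0, 50, (8, 3))
        sig_a = Signature(points=pts_a, weights=np.full(8, 1 / 8))
        sig_b = Signature(points=pts_b, weights=np.full(8, 1 / 8))
        fast = emd(sig_a, sig_b).distance
        lp, _, _ = _emd_lp(cdist(pts_a, pts_b), sig_a.weights, sig_b.weights, False)
        assert fast == pytest.approx(lp, abs=1e-9)

    def test_metric_axioms(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            sigs = [_random_signature(rng, int(rng.integers(2, 6)))[0] for _ in range(3)]
            d01 = emd(sigs[0], sigs[1]).distance
            d10 = emd(sigs[1], sigs[0]).distance
            assert d01 == pytest.approx(d10, abs=1e-9)  # symmetry
            d12 = emd(sigs[1], sigs[2]).distance
            d02 = emd(sigs[0], sigs[2]).distance
            assert d02 <= d01 + d12 + 1e-9  # triangle inequality
            assert d01 >= 0

    def test_translation_property(self, rng):
        pts = rng.normal([50, 0, 30], 4, size=(64, 3))
        sig = Signature(points=pts, weights=np.full(64, 1 / 64))
        v = np.array([3.0, -4.0, 12.0])
        shifted = Signature(points=pts + v, weights=np.full(64, 1 / 64))
        assert emd(sig, shifted).distance == pytest.approx(np.linalg.norm(v), abs=1e-9)


class TestSpeciesProfile:
    @staticmethod
    def _clouds(rng, mean, n_specimens=4, n=500):
        return [
            PixelCloudLab(points=rng.normal(mean, 2.0, size=(n, 3)), specimen_id=f"s{i}")
            for i in range(n_specimens)
        ]

    def test_identical_specimens_give_zero(self):
        # max_points large enough that nothing is subsampled: each specimen's
        # signature then equals the pooled-target distribution exactly
        pts = np.random.default_rng(1).normal([50, 5, 40], 2, (50, 3))
        clouds = [PixelCloudLab(points=pts.copy(), specimen_id=f"s{i}") for i in range(3)]
        prof = species_emd_profile(clouds, clouds, max_points=500, seed=0)
        assert prof["mean"] == pytest.approx(0.0, abs=1e-9)
        assert prof["sd"] == pytest.approx(0.0, abs=1e-9)

    def test_translation_recovered_in_mean(self, rng):
        base = self._clouds(rng, [50.0, 5.0, 40.0])
        shifted = [PixelCloudLab(points=c.points + [10.0, 0, 0], specimen_id=c.specimen_id) for c in base]
        prof = species_emd_profile(base, shifted, max_points=300, seed=0)
        assert prof["mean"] == pytest.approx(10.0, abs=1.0)
        lo, hi = prof["ci95"]
        assert lo < prof["mean"] < hi

    def test_single_comparison_specimen_has_no_ci(self, rng):
        prof = species_emd_profile(self._clouds(rng, [50, 5, 40]), self._clouds(rng, [55, 5, 40], 1))
        assert prof["ci95"] is None and np.isnan(prof["sd"])

    def test_specimen_vs_specimen_flag(self, rng):
        target = self._clouds(rng, [50, 5, 40], 2, 200)
        other = self._clouds(rng, [60, 5, 40], 2, 200)
        pooled = species_emd_profile(target, other, max_points=200, seed=0)
        pairwise = species_emd_profile(target, other, max_points=200, seed=0, specimen_vs_specimen=True)
        assert pooled["mean"] == pytest.approx(10.0, abs=1.5)
        assert pairwise["mean"] == pytest.approx(10.0, abs=1.5)


class TestTukeyHsd:
    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        out = tukey_hsd({"a": g, "b": g.copy()})
        row = out.iloc[0]
        assert row.mean_difference == 0.0
        assert row.p_adjusted == pytest.approx(1.0, abs=1e-9)
        assert not row.significant

    @pytest.mark.parametrize("seed", range(50))
    def test_two_balanced_groups_match_pooled_t_test(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.4, 1.0, 10)
        p_tukey = tukey_hsd({"a": a, "b": b}).iloc[0].p_adjusted
        p_t = stats.ttest_ind(a, b).pvalue  # pooled-variance two-sample t
        assert p_tukey == pytest.approx(p_t, abs=1e-9)

    def test_shifted_group_detected(self, rng):
        groups = {
            "a": rng.normal(0, 1, 8),
            "b": rng.normal(0, 1, 8),
            "c": rng.normal(10, 1, 8),  # 10 SDs away
        }
        out = tukey_hsd(groups)
        pc = out[(out.group_a == "a") & (out.group_b == "c")].iloc[0]
        assert pc.p_adjusted < 1e-6 and pc.significant
        pab = out[(out.group_a == "a") & (out.group_b == "b")].iloc[0]
        assert pab.p_adjusted > 0.05

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(ValueError):
            tukey_hsd({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            tukey_hsd({"a": [1.0, 2.0], "b": [3.0]})


class TestPairwiseEuclidean:
    def test_three_four_five(self):
        D = pairwise_euclidean([[0, 0, 0], [3, 4, 0]], labels=["a", "b"])
        assert D.loc["a", "b"] == pytest.approx(5.0)
        assert D.loc["a", "a"] == 0.0

    def test_metric_properties_on_random_means(self, rng):
        X = rng.uniform(-50, 80, size=(20, 3))
        D = pairwise_euclidean(X).to_numpy()
        np.testing.assert_allclose(D, D.T)
        assert np.all(np.diag(D) == 0)
        for i, j, k in itertools.combinations(range(20), 3):
            assert D[i, k] <= D[i, j] + D[j, k] + 1e-12
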