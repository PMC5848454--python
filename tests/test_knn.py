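import numpy as np
import pytest

from rbpknn.exceptions import InputError
from rbpknn.knn import KnnPwm, infer_novel, knn_infer_pwm, select_opt_k
from rbpknn.motifs import PROBABILITY, PWM, RBPRecord
from rbpknn.scoring import ProbeSet
from rbpknn.synthetic import SynthConfig, generate_family, generate_probes

from conftest import random_probability_pwm, random_protein


def make_pool(rng, n, seq_len=50):
    """Homologs sharing one sequence family, each with a random PWM."""
    from conftest import AA20

    base = random_protein(rng, seq_len)
    homologs = []
    for i in range(n):
        seq = list(base)
        for pos in rng.choice(seq_len, size=2 * (i + 1), replace=False):
            seq[pos] = AA20[(AA20.index(seq[pos]) + 5) % 20]
        homologs.append(
            RBPRecord(f"H{i:02d}", "".join(seq), pwm=random_probability_pwm(rng, 7, f"H{i:02d}"))
        )
    return RBPRecord("query", base), homologs


class TestWeightedAverage:
    def test_k1_returns_nearest_neighbor_pwm_bit_exact(self, rng):
        query, homologs = make_pool(rng, 4)
        res = knn_infer_pwm(query, homologs, K=1)
        nearest = next(h for h in homologs if h.rbp_id == res.neighbor_ids[0])
        assert np.array_equal(res.inferred_pwm.weights, nearest.pwm.weights)

    def test_equal_weights_give_arithmetic_mean(self, rng):
        seq = random_protein(rng, 40)
        a = np.tile(np.array([[0.97], [0.01], [0.01], [0.01]]), (1, 7))
        b = np.tile(np.array([[0.01], [0.97], [0.01], [0.01]]), (1, 7))
        homologs = [
            RBPRecord("a", seq, pwm=PWM(a, PROBABILITY, "a")),
            RBPRecord("b", seq, pwm=PWM(b, PROBABILITY, "b")),
        ]
        res = knn_infer_pwm(RBPRecord("q", seq), homologs, K=2)
        np.testing.assert_allclose(res.inferred_pwm.weights, (a + b) / 2, atol=1e-12)

    def test_matches_cell_by_cell_oracle(self, rng):
        query, homologs = make_pool(rng, 3)
        weights = [0.9, 0.6, 0.3]
        ranked = [(h.rbp_id, w) for h, w in zip(homologs, weights)]
        res = knn_infer_pwm(query, homologs, K=3, _ranked=ranked)
        expected = np.zeros((4, 7))
        for h, w in zip(homologs, weights):
            expected += w * h.pwm.weights
        expected /= sum(weights)
        np.testing.assert_allclose(res.inferred_pwm.weights, expected, atol=1e-12)

    def test_convexity_and_scale_conservation(self, rng):
        query, homologs = make_pool(rng, 6)
        res = knn_infer_pwm(query, homologs, K=6)
        stack = np.stack([h.pwm.weights for h in homologs])
        assert np.all(res.inferred_pwm.weights >= stack.min(axis=0) - 1e-12)
        assert np.all(res.inferred_pwm.weights <= stack.max(axis=0) + 1e-12)
        np.testing.assert_allclose(res.inferred_pwm.weights.sum(axis=0), 1.0, atol=1e-9)
        assert res.inferred_pwm.scale == PROBABILITY

    def test_homolog_order_permutation_invariance(self, rng):
        query, homologs = make_pool(rng, 6)
        res_fwd = knn_infer_pwm(query, homologs, K=4)
        shuffled = [homologs[i] for i in rng.permutation(6)]
        res_shuf = knn_infer_pwm(query, shuffled, K=4)
        assert res_fwd.neighbor_ids == res_shuf.neighbor_ids
        np.testing.assert_array_equal(
            res_fwd.inferred_pwm.weights, res_shuf.inferred_pwm.weights
        )

    def test_k_out_of_range_rejected(self, rng):
        query, homologs = make_pool(rng, 3)
        with pytest.raises(InputError):
            knn_infer_pwm(query, homologs, K=4)
        with pytest.raises(InputError):
            knn_infer_pwm(query, homologs, K=0)

    def test_noise_averages_out_as_k_grows(self):
        """Neighbor PWMs are noisy copies of one truth; averaging more of them
        shrinks the per-cell error on average (seed-averaged trend)."""
        errs = np.zeros(8)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            truth = random_probability_pwm(rng, 7, "truth")
            query, homologs = make_pool(rng, 8)
            noisy = []
            for h in homologs:
                w = truth.weights + rng.normal(0, 0.05, size=(4, 7))
                w = np.clip(w, 1e-3, None)
                w /= w.sum(axis=0)
                noisy.append(h.with_pwm(PWM(w, PROBABILITY, h.rbp_id)))
            for K in range(1, 9):
                res = knn_infer_pwm(query, noisy, K=K)
                errs[K - 1] += np.abs(res.inferred_pwm.weights - truth.weights).mean()
        errs /= 20
        assert errs[-1] < errs[0]
        assert np.all(np.diff(errs) < 0.005)  # weakly decreasing trend


class TestSelectOptK:
    def test_single_candidate_grid(self, rng):
        cfg = SynthConfig(n_proteins=6, probe_count=60, seed=3)
        fam = generate_family(cfg)
        probes = generate_probes(fam[0].pwm, cfg)
        opt_k, table = select_opt_k(fam[0], fam[1:], probes, k_grid=[3], seed=0)
        assert opt_k == 3
        assert list(table["K"]) == [3]

    def test_requires_intensities_and_enough_probes(self, rng):
        cfg = SynthConfig(n_proteins=5, probe_count=10, seed=1)
        fam = generate_family(cfg)
        probes = generate_probes(fam[0].pwm, cfg)
        unlabeled = ProbeSet(probes.sequences)
        with pytest.raises(InputError):
            select_opt_k(fam[0], fam[1:], unlabeled, k_grid=[1])
        one = probes.subset([0])
        with pytest.raises(InputError):
            select_opt_k(fam[0], fam[1:], one, k_grid=[1], folds=2)

    def test_deterministic_given_seed(self):
        cfg = SynthConfig(n_proteins=8, probe_count=200, seed=5)
        fam = generate_family(cfg)
        probes = generate_probes(fam[0].pwm, cfg)
        r1 = select_opt_k(fam[0], fam[1:], probes, seed=11)
        r2 = select_opt_k(fam[0], fam[1:], probes, seed=11)
        assert r1[0] == r2[0]
        assert r1[1].equals(r2[1])


class TestInferNovel:
    def test_default_k_is_seven(self, rng):
        query, homologs = make_pool(rng, 10)
        res = infer_novel(query, homologs)
        assert res.K == 7
        assert res.k_source == "fixed"

    def test_k_clipped_to_pool_size(self, rng):
        query, homologs = make_pool(rng, 4)
        assert infer_novel(query, homologs).K == 4

    def test_empty_pool_rejected(self, rng):
        with pytest.raises(InputError):
            infer_novel(RBPRecord("q", "MKV"), [])


class TestModelInterface:
    def test_fit_with_explicit_k_matches_function(self, rng):
        query, homologs = make_pool(rng, 5)
        model = KnnPwm(query, homologs)
        res = model.fit(K=3)
        direct = knn_infer_pwm(query, homologs, K=3)
        np.testing.assert_array_equal(
            res.inferred_pwm.weights, direct.inferred_pwm.weights
        )
        assert "KNN motif inference" in res.summary()

    def test_fit_cv_records_table(self):
        cfg = SynthConfig(n_proteins=8, probe_count=200, seed=2)
        fam = generate_family(cfg)
        probes = generate_probes(fam[0].pwm, cfg)
        res = KnnPwm(fam[0], fam[1:]).fit(probes=probes, seed=0)
        assert res.k_source == "cv"
        assert len(res.cv_table) == 7
        assert "cross-validation" in res.summary()

    def test_fit_without_data_uses_fixed_path(self, rng):
        query, homologs = make_pool(rng, 9)
        res = KnnPwm(query, homologs).fit()
        assert res.K == 7 and res.k_source == "fixed"
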