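import numpy as np
import pandas as pd
import pytest

from corrbic import (SeedState, align_signs, alpha_score, compute_cv,
                     compute_pc1, correlated_gene_set, correlation_matrix,
                     extend_seed, fork_classify, order_and_threshold,
                     project_scores)
from corrbic.search import correlation_values

from conftest import make_matrix


class TestCorrelatedGeneSet:
    def test_recovers_anticorrelated_blocks_from_noise(self):
        # 30 samples keep the largest chance |corr| of a noise gene with the
        # factor well under the block's internal coherence
        rng = np.random.default_rng(2)
        f = rng.normal(size=30)
        block = np.vstack([np.outer(np.ones(20), f), np.outer(-np.ones(20), f)])
        block += 0.01 * rng.normal(size=block.shape)
        noise = rng.normal(size=(60, 30))
        m = make_matrix(np.vstack([block, noise]), normalized=True)
        C = correlation_matrix(m, m.gene_ids, m.sample_ids)
        chosen = correlated_gene_set(C)
        assert set(chosen) == set(m.gene_ids[:40])

    def test_fully_correlated_input_returned_whole(self):
        f = np.linspace(-1, 1, 8)
        m = make_matrix(np.outer([1, 2, -1, 0.5], f), normalized=True)
        C = correlation_matrix(m, m.gene_ids, m.sample_ids)
        assert set(correlated_gene_set(C)) == set(m.gene_ids)

    def test_alpha_never_below_full_input(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            values = rng.normal(size=(30, 8))
            m = make_matrix(values, normalized=True)
            C = correlation_matrix(m, m.gene_ids, m.sample_ids)
            chosen = correlated_gene_set(C)
            idx = [m.gene_ids.index(g) for g in chosen]
            assert alpha_score(C.values[np.ix_(idx, idx)]) >= alpha_score(C.values) - 1e-12


class TestComputePc1:
    def test_exact_rank_one_case(self):
        w = np.array([3.0, -1.0, 2.0])
        f = np.array([1.0, -2.0, 0.5, 1.5])
        m = make_matrix(np.outer(w, f), normalized=True)
        loadings, scores = compute_pc1(m, m.gene_ids, m.sample_ids)
        np.testing.assert_allclose(np.abs(loadings), np.abs(w) / np.linalg.norm(w),
                                   atol=1e-10)
        centered = f - f.mean()
        ratio = scores.to_numpy() / (centered * np.linalg.norm(w))
        np.testing.assert_allclose(ratio, ratio[0], atol=1e-10)

    def test_unit_norm_loadings(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(6, 10)), normalized=True)
        loadings, _ = compute_pc1(m, m.gene_ids, m.sample_ids)
        assert np.linalg.norm(loadings) == pytest.approx(1.0, abs=1e-12)

    def test_variance_maximal_over_random_directions(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(size=(8, 15)), normalized=True)
        loadings, scores = compute_pc1(m, m.gene_ids, m.sample_ids)
        centered = m.values - m.values.mean(axis=1, keepdims=True)
        pc1_var = scores.to_numpy().var()
        for _ in range(100):
            v = rng.normal(size=8)
            v /= np.linalg.norm(v)
            assert (v @ centered).var() <= pc1_var + 1e-12

    def test_constant_submatrix_is_error(self):
        m = make_matrix(np.ones((3, 5)), normalized=True)
        with pytest.raises(ValueError, match="no variance"):
            compute_pc1(m, m.gene_ids, m.sample_ids)


class TestOrderAndThreshold:
    def test_direct_rule(self):
        scores = pd.Series([5, -4, 3, -0.1, 0.05],
                           index=[f"s{i}" for i in range(5)])
        order, threshold, in_bic = order_and_threshold(scores, 0.2)
        assert order == ["s0", "s1", "s2", "s3", "s4"]
        assert threshold == pytest.approx(0.05)
        assert list(in_bic) == [True, True, True, True, False]

    def test_all_equal_scores_give_empty_bicluster(self, caplog):
        scores = pd.Series([1.0, -1.0, 1.0, 1.0], index=list("abcd"))
        with caplog.at_level("WARNING"):
            _, _, in_bic = order_and_threshold(scores, 0.25)
        assert not in_bic.any()

    def test_background_size_437_samples(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.normal(size=437),
                           index=[f"s{i}" for i in range(437)])
        order, threshold, in_bic = order_and_threshold(scores, 0.10)
        background = order[-44:]  # ceil(0.1 * 437) = 44
        assert threshold == scores.loc[background].abs().max()
        assert sorted(order) == sorted(scores.index)  # permutation
        # membership consistent with threshold by definition
        assert (in_bic == (scores.abs() > threshold)).all()

    def test_tiny_fraction_rounds_to_one_sample(self):
        scores = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        _, threshold, _ = order_and_threshold(scores, 0.01)
        assert threshold == pytest.approx(1.0)


class TestComputeCv:
    def test_gene_equal_to_scores(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=8)
        m = make_matrix(np.vstack([s, -s, rng.normal(size=8)]), normalized=True)
        scores = pd.Series(s, index=m.sample_ids)
        cv = compute_cv(m, scores, m.sample_ids)
        assert cv.iloc[0] == pytest.approx(1.0)
        assert cv.iloc[1] == pytest.approx(-1.0)

    def test_constant_gene_gets_zero(self):
        m = make_matrix([[1, 1, 1, 1], [1, 2, 3, 4]])
        scores = pd.Series([1.0, 2, 3, 4], index=m.sample_ids)
        cv = compute_cv(m, scores, m.sample_ids)
        assert cv.iloc[0] == 0.0

    def test_factor_model_closed_form(self):
        # gene = lam*w*f + noise, scores ~ f  =>  cv ~ w * lam/sqrt(lam^2+1)
        lam, reps = 3.0, 50
        means = []
        rng = np.random.default_rng(6)
        for _ in range(reps):
            f = rng.normal(size=40)
            pos = lam * f + rng.normal(size=40)
            neg = -lam * f + rng.normal(size=40)
            m = make_matrix(np.vstack([pos, neg]), normalized=True)
            scores = pd.Series(f, index=m.sample_ids)
            means.append(compute_cv(m, scores, m.sample_ids).to_numpy())
        mean_cv = np.mean(means, axis=0)
        expected = lam / np.sqrt(lam**2 + 1)
        assert mean_cv[0] == pytest.approx(expected, abs=0.05)
        assert mean_cv[1] == pytest.approx(-expected, abs=0.05)


class TestAlignAndFork:
    def _result(self, planted_instance):
        Xn, truth = planted_instance
        seed = SeedState(gene_subset=Xn.gene_ids,
                         sample_subset=truth.blocks[0].sample_ids[:10], alpha=1.0)
        return Xn, truth, extend_seed(Xn, seed)

    def test_align_idempotent_and_positive_pivot(self, planted_instance):
        _, _, res = self._result(planted_instance)
        assert res.cv.loc[res.cv.abs().idxmax()] > 0
        again = align_signs(res)
        pd.testing.assert_series_equal(again.cv, res.cv)
        pd.testing.assert_series_equal(again.fork, res.fork)

    def test_sign_flipped_data_same_aligned_cv(self, planted_instance):
        Xn, truth, res = self._result(planted_instance)
        flipped = make_matrix(-Xn.values, gene_ids=Xn.gene_ids,
                              sample_ids=Xn.sample_ids, normalized=True)
        seed = SeedState(gene_subset=Xn.gene_ids,
                         sample_subset=truth.blocks[0].sample_ids[:10], alpha=1.0)
        res_flip = extend_seed(flipped, seed)
        np.testing.assert_allclose(res_flip.cv.to_numpy(), res.cv.to_numpy(),
                                   atol=1e-9)

    def test_fork_rule(self):
        scores = pd.Series([2.0, -1.0, 0.5, 0.0], index=list("abcd"))
        assert list(fork_classify(scores)) == ["upper", "lower", "upper", "lower"]
        assert list(fork_classify(-scores.abs())) == ["lower"] * 4

    def test_fork_matches_planted_factor_sign(self):
        # aggregate over replicates: at lambda/sigma = 3 the fork label of a
        # planted member sample should match its factor sign ~98% of the time
        from corrbic import PlantedBicluster, simulate_matrix
        from corrbic.preprocess import filter_low_expression, normalize
        total, agreed = 0, 0
        for rep in range(8):
            rng = np.random.default_rng(300 + rep)
            block_spec = PlantedBicluster(n_genes=60, n_samples=30, strength=3.0)
            raw, truth = simulate_matrix(200, 100, [block_spec], rng)
            Xn = normalize(filter_low_expression(raw)[0])
            block = truth.blocks[0]
            seed = SeedState(gene_subset=Xn.gene_ids,
                             sample_subset=block.sample_ids[:10], alpha=1.0)
            res = extend_seed(Xn, seed)
            factor = dict(zip(block.sample_ids, block.factor))
            members = [s for s in block.sample_ids if res.in_bicluster.loc[s]]
            flags = [(res.fork.loc[s] == "upper") == (factor[s] > 0)
                     for s in members]
            # fork orientation is defined only up to one global flip per run
            agreed += max(sum(flags), len(flags) - sum(flags))
            total += len(flags)
        assert agreed / total >= 0.95


class TestMembershipRecovery:
    def test_rank_one_block_membership_exact(self):
        # planted samples fill all but the background fraction; factor kept
        # away from zero so every member's |score| clears the noise floor
        rng = np.random.default_rng(8)
        n_genes, n_samples, n_block = 120, 100, 90
        values = rng.normal(size=(n_genes, n_samples))
        f = rng.uniform(1.0, 2.0, size=n_block) * rng.choice([-1, 1], size=n_block)
        signs = rng.choice([-1.0, 1.0], size=40)
        cols = rng.choice(n_samples, size=n_block, replace=False)
        values[np.ix_(np.arange(40), cols)] += 5.0 * np.outer(signs, f)
        m = make_matrix(values, normalized=True)
        seed_cols = [m.sample_ids[c] for c in cols[:10]]
        res = extend_seed(m, SeedState(gene_subset=m.gene_ids,
                                       sample_subset=seed_cols, alpha=1.0))
        planted = {m.sample_ids[c] for c in cols}
        assert set(res.in_bicluster.index[res.in_bicluster]) == planted
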