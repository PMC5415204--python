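import math

import numpy as np
import pytest
from scipy.stats import spearmanr

import mutstab as ms
from mutstab.msa import Msa, compute_weights, read_alignment
from mutstab.potts import (
    PottsModel,
    _pl_objective,
    fit_independent,
    fit_potts,
    sample_msa,
    score_variant,
)

from conftest import all_substitution_scores


class TestWeights:
    def test_identical_sequences_share_unit_weight(self):
        msa = Msa(["ACD-", "ACD-", "ACD-"])
        w = compute_weights(msa, theta=0.8)
        assert np.allclose(w.weights, 1 / 3)
        assert w.m_eff == pytest.approx(1.0)

    def test_distant_sequences_keep_full_weight(self):
        msa = Msa(["ACDE", "AGHE"])  # 50% identity < 0.8
        w = compute_weights(msa, theta=0.8)
        assert np.allclose(w.weights, 1.0)
        assert w.m_eff == pytest.approx(2.0)

    def test_matches_bruteforce_pairwise_counts(self):
        rng = np.random.default_rng(8)
        matrix = rng.integers(0, 4, size=(20, 30))
        msa = Msa(matrix, alphabet="ACDE")
        w = compute_weights(msa, theta=0.6)
        # O(n^2) oracle
        expected = np.empty(20)
        for i in range(20):
            count = sum(
                (matrix[i] == matrix[j]).mean() >= 0.6 for j in range(20)
            )
            expected[i] = 1.0 / count
        assert np.allclose(w.weights, expected)

    def test_gaps_count_in_identity(self):
        msa = Msa(["A---", "C---"])  # 3/4 identical through shared gaps
        w = compute_weights(msa, theta=0.75)
        assert w.m_eff == pytest.approx(1.0)


class TestMsaContainer:
    def test_rejects_ragged_and_foreign_symbols(self):
        with pytest.raises(ValueError, match="lengths"):
            Msa(["ACD", "AC"])
        with pytest.raises(ValueError, match="alphabet"):
            Msa(["ABD"])  # B is not a canonical residue

    def test_column_map_skips_gapped_query_columns(self):
        msa = Msa(["AC-DE", "ACCDE"], query_index=0)
        # query gap at column 2: positions 1,2 then 3,4 at columns 3,4
        assert msa.column_for_position(3) == 3
        assert msa.column_for_position(2) == 1
        assert 2 not in msa.column_map

    def test_a2m_reader_drops_inserts(self, tmp_path):
        path = tmp_path / "aln.a2m"
        path.write_text(">q\nACdEF\n>h\nAGa-F\n")
        msa = read_alignment(path, fmt="a2m")
        assert msa.length == 4  # lowercase insert column dropped
        assert msa.sequence_str(0) == "ACEF"
        assert msa.sequence_str(1) == "AG-F"

    def test_fasta_reader_and_query_selection(self, tmp_path):
        path = tmp_path / "aln.fasta"
        path.write_text(">a\nACDE\n>b\nACGE\n")
        msa = read_alignment(path, query_id="b")
        assert msa.query_index == 1


class TestIndependentModel:
    def test_equal_split_log_frequency(self):
        msa = Msa(["AAAA", "AAAA", "VVVV", "VVVV"], alphabet="AV-")
        w = compute_weights(msa, theta=1.0)
        model = fit_independent(msa, w, pseudocount=0.0, gauge_fix=False)
        assert model.h[0, 0] == pytest.approx(math.log(0.5))
        assert model.h[0, 1] == pytest.approx(math.log(0.5))

    def test_uniform_column_is_flat_after_gauge(self):
        msa = Msa(["A", "V", "L", "I"], alphabet="AVLI")
        w = compute_weights(msa, theta=1.0)
        model = fit_independent(msa, w, pseudocount=0.0)
        assert np.allclose(model.h, 0.0, atol=1e-12)

    def test_weighted_frequencies_match_hand_computation(self):
        # seqs 1,2 identical -> weight 1/2 each; seqs 3,4 distinct -> weight 1
        msa = Msa(["AA", "AA", "VA", "LV"], alphabet="AVL")
        w = compute_weights(msa, theta=1.0)
        assert np.allclose(w.weights, [0.5, 0.5, 1.0, 1.0])
        model = fit_independent(msa, w, pseudocount=0.0, gauge_fix=False)
        # column 0: A carries weight 1, V 1, L 1 -> each 1/3
        for state in range(3):
            assert model.h[0, state] == pytest.approx(math.log(1 / 3))
        # column 1: A carries 2 of 3 total weight, V 1 of 3
        assert model.h[1, 0] == pytest.approx(math.log(2 / 3))
        assert model.h[1, 1] == pytest.approx(math.log(1 / 3))

    def test_score_is_log_frequency_ratio(self):
        q = 2
        h = np.log(np.array([[0.9, 0.05], [0.5, 0.5]]))
        model = PottsModel(h, np.zeros((2, 2, q, q)), alphabet="AV")
        msa = Msa(["AA", "AV"], alphabet="AV")
        score = score_variant(model, msa, ms.VariantKey("A", 1, "V"))
        assert score.delta_loglik == pytest.approx(math.log(0.9 / 0.05))
        assert score.delta_loglik == pytest.approx(2.89, abs=0.01)


class TestPseudolikelihood:
    def test_objective_matches_bruteforce_enumeration(self):
        """The vectorized objective equals a direct per-site conditional sum."""
        rng = np.random.default_rng(9)
        L, q, n = 3, 2, 6
        matrix = rng.integers(0, q, size=(n, L))
        msa = Msa(matrix, alphabet="AV")
        w = rng.random(n) + 0.5
        h = rng.normal(size=(L, q))
        iu, ju = np.triu_indices(L, k=1)
        Jb = rng.normal(size=(iu.size, q, q))
        theta = np.concatenate([h.ravel(), Jb.ravel()])

        # independent brute-force: loop sequences, sites, states
        J = np.zeros((L, L, q, q))
        for p in range(iu.size):
            J[iu[p], ju[p]] = Jb[p]
            J[ju[p], iu[p]] = Jb[p].T
        npll = 0.0
        for s_i, seq in enumerate(matrix):
            for i in range(L):
                logits = np.array(
                    [
                        h[i, a] + sum(J[i, j, a, seq[j]] for j in range(L) if j != i)
                        for a in range(q)
                    ]
                )
                npll -= w[s_i] * (logits[seq[i]] - np.log(np.exp(logits).sum()))
        npll /= w.sum()
        lam_h, lam_j = 0.013, 0.031
        expected = npll + lam_h * (h ** 2).sum() + lam_j * (Jb ** 2).sum()

        from mutstab.potts import _one_hot

        Xf = _one_hot(matrix, q).reshape(n, L * q)
        got, grad = _pl_objective(theta, Xf, matrix, w, L, q, lam_h, lam_j, iu, ju)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_objective_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(10)
        L, q, n = 3, 3, 8
        matrix = rng.integers(0, q, size=(n, L))
        w = np.ones(n)
        iu, ju = np.triu_indices(L, k=1)
        theta = rng.normal(scale=0.3, size=L * q + iu.size * q * q)

        from mutstab.potts import _one_hot

        Xf = _one_hot(matrix, q).reshape(n, L * q)
        args = (Xf, matrix, w, L, q, 0.01, 0.02, iu, ju)
        f0, g = _pl_objective(theta, *args)
        eps = 1e-6
        for k in rng.choice(theta.size, size=10, replace=False):
            t_plus = theta.copy()
            t_plus[k] += eps
            f1, _ = _pl_objective(t_plus, *args)
            assert (f1 - f0) / eps == pytest.approx(g[k], abs=1e-4)

    def test_perfectly_covarying_pair_gets_top_coupling(self):
        rng = np.random.default_rng(12)
        n = 400
        half = rng.random(n) < 0.5
        matrix = rng.integers(0, 4, size=(n, 5))
        matrix[:, 0] = np.where(half, 0, 2)  # columns 0 and 1 co-vary perfectly
        matrix[:, 1] = np.where(half, 1, 3)
        msa = Msa(matrix, alphabet="ACDE")
        w = compute_weights(msa, theta=1.0)
        model = fit_potts(msa, w, lambda_h=0.01)
        norms = model.coupling_norms()
        iu = np.triu_indices(5, k=1)
        pair_norms = {(i, j): norms[i, j] for i, j in zip(*iu)}
        assert max(pair_norms, key=pair_norms.get) == (0, 1)

    def test_coupling_shrinks_with_regularization(self):
        rng = np.random.default_rng(13)
        matrix = rng.integers(0, 3, size=(150, 4))  # independent columns
        msa = Msa(matrix, alphabet="ACD")
        w = compute_weights(msa, theta=1.0)
        weak = fit_potts(msa, w, lambda_h=0.01, lambda_J=0.01)
        strong = fit_potts(msa, w, lambda_h=0.01, lambda_J=1.0)
        assert np.abs(strong.J).sum() < np.abs(weak.J).sum()


class TestScoring:
    def test_score_equals_bruteforce_energy_difference(self, potts_recovery):
        _, msa, fitted = potts_recovery
        query = msa.query_row()
        for col in (0, 3, 7):
            wt = msa.alphabet[query[col]]
            mut = next(c for c in msa.alphabet if c != wt)
            pos = msa.column_map[col]  # map column back to a 1-based position
            score = score_variant(fitted, msa, ms.VariantKey(wt, pos, mut))
            mutated = query.copy()
            mutated[col] = msa.alphabet.index(mut)
            brute = fitted.energy(query) - fitted.energy(mutated)
            assert score.delta_loglik == pytest.approx(brute, abs=1e-9)

    def test_scores_invariant_under_regauging(self, potts_recovery):
        _, msa, fitted = potts_recovery
        # perturb the gauge arbitrarily, then re-fix: scores must not move
        regauged = fitted.to_zero_sum()
        a = all_substitution_scores(fitted, msa)
        b = all_substitution_scores(regauged, msa)
        assert np.allclose(a, b, atol=1e-9)

    def test_wild_type_mismatch_rejected(self, potts_recovery):
        _, msa, fitted = potts_recovery
        query = msa.query_row()
        wrong_wt = next(c for c in msa.alphabet if c != msa.alphabet[query[0]])
        target = next(c for c in msa.alphabet if c not in (wrong_wt,))
        with pytest.raises(ValueError, match="mismatch"):
            score_variant(fitted, msa, ms.VariantKey(wrong_wt, 1, target))

    def test_unmapped_position_gives_no_prediction(self, potts_recovery):
        _, msa, fitted = potts_recovery
        wt = msa.alphabet[msa.query_row()[0]]
        mut = next(c for c in msa.alphabet if c != wt)
        assert score_variant(fitted, msa, ms.VariantKey(wt, 999, mut)) is None


class TestGibbsSampler:
    def test_independent_model_frequencies_converge(self):
        rng = np.random.default_rng(14)
        h = rng.normal(scale=0.8, size=(4, 4))
        model = PottsModel(h, np.zeros((4, 4, 4, 4)), alphabet="ACDE")
        msa = sample_msa(model, 5000, burn_in=50, thin=1, seed=15)
        expected = np.exp(h) / np.exp(h).sum(axis=1, keepdims=True)
        for i in range(4):
            counts = np.bincount(msa.matrix[:, i], minlength=4)
            freq = counts / counts.sum()
            se = np.sqrt(expected[i] * (1 - expected[i]) / 5000)
            assert np.all(np.abs(freq - expected[i]) <= 3 * se + 1e-9)

    def test_positive_coupling_raises_joint_frequency(self):
        q = 3
        J = np.zeros((2, 2, q, q))
        J[0, 1, 0, 1] = 2.0
        J[1, 0, 1, 0] = 2.0
        model = PottsModel(np.zeros((2, q)), J, alphabet="ACD")
        msa = sample_msa(model, 4000, burn_in=50, thin=1, seed=16)
        f0 = (msa.matrix[:, 0] == 0).mean()
        f1 = (msa.matrix[:, 1] == 1).mean()
        joint = ((msa.matrix[:, 0] == 0) & (msa.matrix[:, 1] == 1)).mean()
        assert joint > f0 * f1

    def test_seeded_determinism(self, potts_recovery):
        truth, _, _ = potts_recovery
        a = sample_msa(truth, 50, burn_in=20, thin=2, seed=17)
        b = sample_msa(truth, 50, burn_in=20, thin=2, seed=17)
        assert np.array_equal(a.matrix, b.matrix)


class TestParameterRecovery:
    def test_mutant_scores_recovered(self, potts_recovery):
        truth, msa, fitted = potts_recovery
        rho = spearmanr(
            all_substitution_scores(truth, msa), all_substitution_scores(fitted, msa)
        ).statistic
        assert rho >= 0.9

    def test_coupled_pair_has_top_norm(self, potts_recovery):
        _, _, fitted = potts_recovery
        norms = fitted.coupling_norms()
        iu = np.triu_indices(fitted.length, k=1)
        pair_norms = {(i, j): norms[i, j] for i, j in zip(*iu)}
        assert max(pair_norms, key=pair_norms.get) == (2, 5)


def test_model_json_round_trip(tmp_path, potts_recovery):
    _, msa, fitted = potts_recovery
    path = tmp_path / "model.json"
    fitted.to_json(path)
    back = PottsModel.from_json(path)
    assert np.allclose(back.h, fitted.h)
    assert np.allclose(back.J, fitted.J)
    assert back.alphabet == fitted.alphabet
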