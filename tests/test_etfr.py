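"""Gapless register alignment, substitution matrix, and Gumbel null."""

import math

import numpy as np
import pytest

from thermomimic.etfr import (SubstitutionMatrix,
                              _best_scores_shuffled, _register_scores,
                              build_substitution_matrix, calibrate_null,
                              etfr_align, n_registers, register_significance,
                              scan_database, score_register)
from thermomimic.profiles import (AA_INDEX, AMINO_ACIDS, EncodedProfile,
                                  ProteinSequence)


def brute_force_register_scores(scores, env, aa_idx):
    """Independent double-loop oracle for all-register raw scores."""
    lq, lt = len(env), len(aa_idx)
    out = []
    if lq <= lt:
        for off in range(lt - lq + 1):
            out.append(sum(scores[env[i], aa_idx[off + i]] for i in range(lq)))
    else:
        for off in range(lq - lt + 1):
            out.append(sum(scores[env[off + j], aa_idx[j]] for j in range(lt)))
    return np.array(out)


def _random_encoded(rng, length, prefix="q"):
    letters = rng.choice(list(AMINO_ACIDS), size=length)
    seq = ProteinSequence(id=f"{prefix}{length}", residues="".join(letters))
    env = rng.integers(0, 8, size=length)
    return EncodedProfile(sequence=seq, native_env=env,
                          denatured_env=rng.integers(0, 8, size=length))


class TestSubstitutionMatrix:
    def test_perfect_association_is_maximum(self):
        # environment 2 only ever co-occurs with tryptophan
        seq = ProteinSequence(id="w", residues="W" * 30)
        enc = EncodedProfile(sequence=seq, native_env=np.full(30, 2),
                             denatured_env=np.full(30, 2))
        mat = build_substitution_matrix([enc], "native")
        w = AA_INDEX["W"]
        assert mat.scores[2, w] == mat.scores.max()

    def test_uniform_counts_give_zero_scores(self):
        # every (environment, amino acid) cell observed exactly once
        residues = AMINO_ACIDS * 8
        env = np.repeat(np.arange(8), 20)
        enc = EncodedProfile(sequence=ProteinSequence(id="u", residues=residues),
                             native_env=env, denatured_env=env)
        mat = build_substitution_matrix([enc], "native")
        np.testing.assert_allclose(mat.scores, 0.0, atol=1e-12)

    def test_matches_count_and_log_oracle(self, encoded_corpus):
        mat = build_substitution_matrix(encoded_corpus, "denatured",
                                        pseudocount=1.0)
        # independent oracle: dict-based counting and explicit log-odds
        counts = {}
        total = 0
        for enc in encoded_corpus:
            for e, aa in zip(enc.denatured_env, enc.sequence.residues):
                counts[(int(e), aa)] = counts.get((int(e), aa), 0) + 1
                total += 1
        denom = total + 160.0
        for e in range(8):
            p_e = sum(counts.get((e, a), 0) + 1 for a in AMINO_ACIDS) / denom
            for aa in AMINO_ACIDS:
                p_a = sum(counts.get((i, aa), 0) + 1 for i in range(8)) / denom
                p_ea = (counts.get((e, aa), 0) + 1) / denom
                expected = math.log2(p_ea / (p_e * p_a))
                assert mat.scores[e, AA_INDEX[aa]] == pytest.approx(expected, abs=1e-12)

    def test_expected_score_under_independence_nonpositive(self, matrices):
        for mat in matrices.values():
            expectation = float(np.outer(mat.env_freq, mat.aa_freq).ravel()
                                @ mat.scores.ravel())
            assert expectation <= 0

    def test_tsv_round_trip(self, matrices, tmp_path):
        path = tmp_path / "mat.tsv"
        matrices["native"].to_tsv(path)
        loaded = SubstitutionMatrix.from_tsv(path)
        assert loaded.state == "native"
        np.testing.assert_allclose(loaded.scores, matrices["native"].scores,
                                   atol=5e-7)
        np.testing.assert_allclose(loaded.env_freq, matrices["native"].env_freq,
                                   rtol=1e-6)


class TestScoreRegister:
    def test_zero_matrix_zero_score(self, matrices):
        rng = np.random.default_rng(0)
        enc = _random_encoded(rng, 12)
        target = ProteinSequence(id="t", residues="MKVLAWYHICDE")
        zero = SubstitutionMatrix(state="native", scores=np.zeros((8, 20)),
                                  env_freq=np.full(8, 0.125),
                                  aa_freq=np.full(20, 0.05))
        assert score_register(enc, target, 0, zero, "native") == 0.0

    def test_hand_computed_two_residue_sum(self):
        seq = ProteinSequence(id="q", residues="AA")
        enc = EncodedProfile(sequence=seq, native_env=np.array([3, 5]),
                             denatured_env=np.array([0, 0]))
        scores = np.zeros((8, 20))
        scores[3, AA_INDEX["M"]] = 1.5
        scores[5, AA_INDEX["K"]] = -0.5
        mat = SubstitutionMatrix(state="native", scores=scores,
                                 env_freq=np.full(8, 0.125),
                                 aa_freq=np.full(20, 0.05))
        target = ProteinSequence(id="t", residues="MK")
        assert score_register(enc, target, 0, mat, "native") == pytest.approx(1.0)

    def test_offset_out_of_range(self, matrices):
        rng = np.random.default_rng(1)
        enc = _random_encoded(rng, 10)
        target = ProteinSequence(id="t", residues="MKVLAWYHICDE")
        with pytest.raises(ValueError):
            score_register(enc, target, 3, matrices["native"], "native")

    def test_all_registers_match_brute_force_oracle(self, matrices):
        """100 random pairs, both orientations, exact agreement."""
        rng = np.random.default_rng(2)
        scores = matrices["native"].scores
        for _ in range(100):
            lq = int(rng.integers(5, 60))
            lt = int(rng.integers(5, 60))
            env = rng.integers(0, 8, size=lq)
            aa_idx = rng.integers(0, 20, size=lt)
            fast = _register_scores(scores, env, aa_idx)
            slow = brute_force_register_scores(scores, env, aa_idx)
            assert len(fast) == n_registers(lq, lt)
            np.testing.assert_allclose(fast, slow, atol=1e-10)


class TestNullModel:
    def test_gumbel_location_identity(self, nulls):
        null = nulls["native"]
        p = register_significance(null.mu(80, 120), 80, 120, null)
        assert p == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_inverse_cdf_identity(self, nulls):
        null = nulls["native"]
        raw = null.mu(80, 120) + null.beta * math.log(-1 / math.log(0.95))
        assert register_significance(raw, 80, 120, null) == pytest.approx(0.05,
                                                                          abs=1e-10)

    def test_low_score_limit_p_one(self, nulls):
        assert register_significance(-1e6, 80, 120, nulls["native"]) == 1.0

    def test_huge_score_floored_not_zero(self, nulls):
        p = register_significance(1e6, 80, 120, nulls["native"])
        assert 0 < p <= 1e-300

    def test_location_grows_with_search_space(self, nulls):
        for null in nulls.values():
            assert null.b > 0
            assert null.mu(200, 400) > null.mu(100, 200)

    def test_reproducible_for_fixed_seed(self, matrices, uniform_composition):
        grid = [(40, 80), (40, 160)]
        n1 = calibrate_null(matrices["native"], uniform_composition, grid,
                            n_shuffles=100, seed=5)
        n2 = calibrate_null(matrices["native"], uniform_composition, grid,
                            n_shuffles=100, seed=5)
        assert (n1.a, n1.b, n1.beta) == (n2.a, n2.b, n2.beta)

    def test_fresh_shuffle_pvalues_roughly_uniform(self, matrices, nulls,
                                                   uniform_composition):
        """Moderate-n sanity check; the full 2,000-replicate version is an
        acceptance test."""
        from scipy import stats

        rng = np.random.default_rng(23)
        best = _best_scores_shuffled(matrices["native"], uniform_composition,
                                     60, 500, 400, rng)
        pvals = [register_significance(b, 60, 500, nulls["native"]) for b in best]
        ks = stats.kstest(pvals, "uniform")
        assert ks.statistic < 0.09


class TestEtfrAlign:
    def test_equal_length_single_register(self, encoded_corpus, matrices, nulls):
        enc = encoded_corpus[0]
        target = enc.sequence
        aln = etfr_align(enc, target, matrices, nulls)
        assert aln.offset == 0
        assert n_registers(len(enc), len(target)) == 1
        assert aln.S >= 0

    def test_missing_state_models_error(self, encoded_corpus, matrices, nulls):
        with pytest.raises(ValueError, match="denatured"):
            etfr_align(encoded_corpus[0], encoded_corpus[1].sequence,
                       {"native": matrices["native"]}, nulls)

    def test_best_register_maximizes_combined_significance(self, matrices, nulls):
        """The returned offset attains the maximum S over explicit per-offset
        evaluation, with the lowest offset on ties; the shorter member slides
        regardless of which side is the profile."""
        rng = np.random.default_rng(8)
        for lq, lt in [(30, 50), (50, 30)]:
            enc = _random_encoded(rng, lq)
            target = ProteinSequence(
                id=f"t{lt}", residues="".join(rng.choice(list(AMINO_ACIDS), size=lt)))
            aln = etfr_align(enc, target, matrices, nulls)
            per_offset = []
            for off in range(n_registers(lq, lt)):
                s = 0.0
                for state in ("native", "denatured"):
                    raw = score_register(enc, target, off, matrices[state], state)
                    p = register_significance(raw, lq, lt, nulls[state])
                    s -= math.log10(p)
                per_offset.append(s)
            best = max(per_offset)
            assert aln.S == pytest.approx(best, rel=1e-12)
            assert aln.offset == per_offset.index(best)

    def test_self_recognition_against_decoys(self, corpus_profiles, env_model,
                                             matrices, nulls):
        """A profile finds its own generating sequence above shuffled decoys."""
        from thermomimic.profiles import assign_environments

        prof = corpus_profiles[0]
        enc = assign_environments(prof, env_model)
        rng = np.random.default_rng(13)
        own = prof.sequence
        decoys = []
        for i in range(20):
            letters = list(own.residues)
            rng.shuffle(letters)
            decoys.append(ProteinSequence(id=f"decoy{i:02d}",
                                          residues="".join(letters)))
        ranked = scan_database(enc, [own] + decoys, matrices, nulls)
        assert ranked[0].target_id == own.id

    def test_scan_deterministic_and_sorted(self, encoded_corpus, corpus_sequences,
                                           matrices, nulls):
        enc = encoded_corpus[0]
        targets = corpus_sequences[:10]
        r1 = scan_database(enc, targets, matrices, nulls)
        r2 = scan_database(enc, targets, matrices, nulls)
        assert [a.target_id for a in r1] == [a.target_id for a in r2]
        ss = [a.S for a in r1]
        assert ss == sorted(ss, reverse=True)
        assert len(r1) == 10

    def test_significance_monotone_in_p(self, encoded_corpus, matrices, nulls):
        aln = etfr_align(encoded_corpus[0], encoded_corpus[1].sequence,
                         matrices, nulls)
        expected = -math.log10(aln.p_native) - math.log10(aln.p_denatured)
        assert aln.S == pytest.approx(expected)
        assert 0 < aln.p_native <= 1 and 0 < aln.p_denatured <= 1
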