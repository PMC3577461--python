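import numpy as np
import pytest

from cmf import (
    DoublyStochasticMatrix,
    PairPairMatrix,
    blosum62_score,
    count_pair_substitutions,
    is_formal_dissimilar_compensatory,
    phase2_signal_counts,
    phase3_compmut,
    phase4_log_odds,
    phase5_sinkhorn,
    read_dcm,
    sinkhorn_normalize,
    train_dcm,
    write_dcm,
)
from cmf.dcm import dissimilar_mask
from cmf.msa_io import AA_INDEX, AMINO_ACIDS
from cmf.synthetic import (
    DISSIMILAR_STATE_SETS,
    SIMILAR_STATE_SETS,
    SyntheticSpec,
    generate_corpus,
)
from conftest import make_alignment


def pair_state(a, b):
    return 20 * AA_INDEX[a] + AA_INDEX[b]


class TestBlosum62:
    # frozen from the published BLOSUM62 table
    @pytest.mark.parametrize(
        "a,b,score",
        [("A", "A", 4), ("D", "R", -2), ("W", "W", 11), ("A", "N", -2),
         ("I", "V", 3), ("G", "F", -3)],
    )
    def test_published_values(self, a, b, score):
        assert blosum62_score(a, b) == score

    def test_symmetry(self):
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                assert blosum62_score(a, b) == blosum62_score(b, a)

    def test_nonstandard_rejected(self):
        with pytest.raises(ValueError):
            blosum62_score("X", "A")


class TestFormalDissimilar:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (("D", "R"), ("R", "D"), True),  # both exchanges score -2
            (("A", "A"), ("A", "A"), False),  # identity scores 4
            (("A", "N"), ("S", "N"), False),  # A<->S scores 1
        ],
    )
    def test_rule(self, p1, p2, expected):
        assert is_formal_dissimilar_compensatory(p1, p2) is expected

    def test_mask_agrees_with_scalar_rule(self):
        mask = dissimilar_mask()
        rng = np.random.default_rng(0)
        for _ in range(200):
            ai, aj, ak, al = (AMINO_ACIDS[k] for k in rng.integers(20, size=4))
            expected = is_formal_dissimilar_compensatory((ai, aj), (ak, al))
            assert bool(mask[pair_state(ai, aj), pair_state(ak, al)]) == expected


class TestCounting:
    def test_single_comparison(self):
        aln = make_alignment(["AR", "ND"])  # two sequences: states (A,N), (R,D)
        m = count_pair_substitutions([(aln, 0, 1)])
        s, t = pair_state("A", "N"), pair_state("R", "D")
        assert m.values[s, t] == 1 and m.values[t, s] == 1
        assert m.values.sum() == 2

    def test_identical_sequences_count_on_diagonal(self):
        aln = make_alignment(["AAA", "NNN"])  # three sequences, all (A,N)
        m = count_pair_substitutions([(aln, 0, 1)])
        s = pair_state("A", "N")
        assert m.values[s, s] == 6  # C(3,2)=3 comparisons, doubled
        assert m.values.sum() == 6

    def test_total_mass_conservation(self, small_synthetic):
        aln, _ = small_synthetic
        pairs = [(aln, 0, 1), (aln, 2, 3)]
        m = count_pair_substitutions(pairs, max_rows=None)
        expected = 0
        codes = aln.codes()
        for _, i, j in pairs:
            n = int(((codes[:, i] >= 0) & (codes[:, j] >= 0)).sum())
            expected += n * (n - 1)
        assert m.values.sum() == expected

    def test_symmetric(self, small_synthetic):
        aln, _ = small_synthetic
        m = count_pair_substitutions([(aln, 0, 1), (aln, 5, 9)], max_rows=100)
        assert np.abs(m.values - m.values.T).max() <= 1e-9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            count_pair_substitutions([])


def _counts(entries):
    m = np.zeros((400, 400))
    for (s, t), v in entries.items():
        m[s, t] = m[t, s] = v
    return PairPairMatrix(values=m)


class TestPhases:
    def test_phase2_diagonal_always_kept(self):
        s = pair_state("A", "N")
        alt = _counts({(s, s): 1, (0, 1): 2})
        null = _counts({(s, s): 100, (0, 1): 1})
        sig = phase2_signal_counts(alt, null)
        assert sig.values[s, s] == 1  # kept although null is richer there

    def test_phase2_relative_frequency_rule(self):
        # entry with rel. freq. 0.02 in alt vs 0.03 in null is zeroed
        alt = _counts({(0, 1): 2, (2, 3): 98})
        null = _counts({(0, 1): 3, (2, 3): 97})
        sig = phase2_signal_counts(alt, null)
        assert sig.values[0, 1] == 0
        assert sig.values[2, 3] == 98

    def test_phase2_equal_counts_leave_only_diagonal(self):
        alt = _counts({(0, 1): 5, (7, 7): 2})
        sig = phase2_signal_counts(alt, alt)
        off = sig.values.copy()
        np.fill_diagonal(off, 0)
        assert off.sum() == 0
        assert sig.values[7, 7] == 2

    def test_phase3_masks_non_compensatory(self):
        s_an, s_sn = pair_state("A", "N"), pair_state("S", "N")
        s_dr, s_rd = pair_state("D", "R"), pair_state("R", "D")
        c_sig = _counts({(s_an, s_sn): 4, (s_dr, s_rd): 6})
        c_compmut, p_compmut = phase3_compmut(c_sig)
        assert c_compmut.values[s_an, s_sn] == 0
        assert c_compmut.values[s_dr, s_rd] == 6
        assert p_compmut.values.sum() == pytest.approx(1.0)

    def test_phase3_all_masked_is_error(self):
        s_an, s_sn = pair_state("A", "N"), pair_state("S", "N")
        with pytest.raises(ValueError, match="compensatory"):
            phase3_compmut(_counts({(s_an, s_sn): 4}))

    def test_phase4_independence_gives_zero(self):
        # P = outer(Pb, Pb) for a two-state marginal -> log-odds all zero
        p = np.zeros((400, 400))
        marg = np.zeros(400)
        marg[[3, 8]] = [0.4, 0.6]
        p = np.outer(marg, marg)
        s = phase4_log_odds(PairPairMatrix(values=p))
        finite = np.isfinite(s.values)
        assert np.abs(s.values[finite]).max() < 1e-12

    def test_phase4_doubling_gives_log2(self):
        # mixture: half independent, half perfectly correlated on 2 states
        marg = np.zeros(400)
        marg[[3, 8]] = 0.5
        p = 0.5 * np.outer(marg, marg)
        p[3, 3] += 0.25
        p[8, 8] += 0.25
        s = phase4_log_odds(PairPairMatrix(values=p))
        # P(3,3) = 0.375 = 1.5 * Pb(3)*Pb(3) -> log 1.5
        assert s.values[3, 3] == pytest.approx(np.log(1.5))
        assert s.values[3, 8] == pytest.approx(np.log(0.5))

    def test_phase4_zero_entries_vanish_after_phase5(self):
        marg = np.zeros(400)
        marg[[3, 8]] = 0.5
        p = np.outer(marg, marg) * 0.5
        p[3, 3] += 0.25
        p[8, 8] += 0.25
        s = phase4_log_odds(PairPairMatrix(values=p))
        d = phase5_sinkhorn(s)
        assert d.values[0, 1] == 0.0  # P = 0 there -> sentinel -> zero


class TestSinkhorn:
    def test_fixed_point(self):
        d = np.eye(5)
        out = sinkhorn_normalize(d)
        assert (out == d).all()

    def test_2x2_closed_form(self):
        # symmetric scaling of [[1,1],[1,3]]: d1^2 = 3*d2^2 and
        # d1*(d1+d2) = 1 give the stationary matrix below
        out = sinkhorn_normalize(np.array([[1.0, 1.0], [1.0, 3.0]]), tol=1e-12)
        expected = np.array(
            [[0.6339745962, 0.3660254038], [0.3660254038, 0.6339745962]]
        )
        assert np.abs(out - expected).max() < 1e-3

    def test_random_matrices_converge(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.random((30, 30))
            np.fill_diagonal(a, a.diagonal() + 0.5)
            out = sinkhorn_normalize(a, tol=1e-8)
            assert np.abs(out.sum(0) - 1).max() <= 1e-8
            assert np.abs(out.sum(1) - 1).max() <= 1e-8

    def test_symmetric_input_symmetric_output(self):
        rng = np.random.default_rng(5)
        a = rng.random((20, 20))
        a = a + a.T
        out = sinkhorn_normalize(a, tol=1e-10)
        assert np.abs(out - out.T).max() < 1e-6

    def test_zero_row_rejected(self):
        a = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="support"):
            sinkhorn_normalize(a, max_iter=50)

    def test_phase5_repairs_empty_rows(self):
        s = np.full((400, 400), -np.inf)
        s[0, 1] = s[1, 0] = 1.0  # only one positive off-diagonal entry
        d = phase5_sinkhorn(PairPairMatrix(values=s))
        assert d.values.min() >= 0
        assert np.abs(d.values.sum(0) - 1).max() <= 1e-8
        assert np.abs(d.values - d.values.T).max() <= 1e-9


class TestPersistence:
    def test_roundtrip_exact(self, tmp_path, random_dcm):
        path = tmp_path / "d.tsv"
        random_dcm.provenance = {"kind": "test", "seed": 1}
        write_dcm(random_dcm, path)
        back = read_dcm(path)
        assert np.abs(back.values - random_dcm.values).max() == 0
        assert back.provenance["kind"] == "test"

    def test_identity_roundtrip(self, tmp_path):
        path = tmp_path / "i.tsv"
        ident = DoublyStochasticMatrix.identity()
        write_dcm(ident, path)
        back = read_dcm(path)
        assert (back.values == np.eye(400)).all()
        assert back.provenance["kind"] == "identity"

    def test_invalid_sums_rejected_on_load(self, tmp_path):
        path = tmp_path / "bad.tsv"
        bad = np.eye(400)
        bad[0, 0] = 1.5
        write_dcm(DoublyStochasticMatrix(values=bad), path)
        with pytest.raises(ValueError, match="deviate"):
            read_dcm(path)

    def test_wrong_shape_rejected(self, tmp_path):
        path = tmp_path / "short.tsv"
        path.write_text("# alphabet=" + AMINO_ACIDS + "\n1 0\n0 1\n")
        with pytest.raises(ValueError, match="shape"):
            read_dcm(path)


@pytest.fixture(scope="module")
def tiny_corpora():
    """Matched corpora: dissimilar-compensatory vs similar couplings."""
    template = SyntheticSpec()
    dis, _ = generate_corpus(
        3, template, seed=11, n_coupled=8, rho=1.0,
        state_sets=DISSIMILAR_STATE_SETS,
    )
    sim, _ = generate_corpus(
        3, template, seed=11, n_coupled=8, rho=1.0,
        state_sets=SIMILAR_STATE_SETS,
    )
    return dis, sim


class TestTraining:
    def test_deterministic(self, tiny_corpora):
        dis, _ = tiny_corpora
        d1 = train_dcm(dis, fdr=0.01, seed=5)
        d2 = train_dcm(dis, fdr=0.01, seed=5)
        assert (d1.values == d2.values).all()

    def test_output_is_doubly_stochastic(self, tiny_corpora):
        dis, _ = tiny_corpora
        d = train_dcm(dis, fdr=0.01, seed=5)
        d.validate()
        assert np.abs(d.values - d.values.T).max() <= 1e-9

    def test_discriminates_planted_transitions(self, tiny_corpora):
        dis, sim = tiny_corpora
        d_dis = train_dcm(dis, fdr=0.01, seed=5)
        d_sim = train_dcm(sim, fdr=0.01, seed=5)

        def planted_mass(d):
            total = 0.0
            for ss in DISSIMILAR_STATE_SETS:
                states = [pair_state(a, b) for a, b in ss]
                for s in states:
                    for t in states:
                        if s != t:
                            total += d.values[s, t]
            return total

        assert planted_mass(d_dis) > planted_mass(d_sim)

    def test_uncoupled_corpus_has_no_signal(self):
        template = SyntheticSpec(n_seqs=150, n_cols=40)
        alns, _ = generate_corpus(2, template, seed=3, n_coupled=0)
        with pytest.raises(ValueError, match="significant"):
            train_dcm(alns, fdr=0.001, seed=1)
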