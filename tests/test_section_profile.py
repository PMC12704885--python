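import numpy as np
import pytest

from entroread.corpus_io import Group, RawDocument, TokenSequence
from entroread.section_profile import (
    SECTION_LABELS,
    TermLexicon,
    read_lexicon,
    section_delta_table,
    section_spectra,
    tt_density,
    tt_entropy_correlation,
)
from entroread.synthetic import (
    PairedCorpusSpec,
    ZipfMandelbrotParams,
    demo_lexicon,
    generate_paired_corpus,
    inject_terms,
    sample_document,
)


def _sectioned_doc(doc_id, group, tokens, pair_id):
    n = len(tokens)
    third = n // 3
    sections = [("s1", (0, third)), ("s2", (third, n))]
    return RawDocument(doc_id, group, tokens, pair_id=pair_id, sections=sections)


class TestTtDensity:
    def test_formula(self):
        seq = TokenSequence("d", ["化疗", "方案", "知情"])
        assert tt_density(seq, TermLexicon(frozenset({"化疗"}))) == pytest.approx(1 / 3)

    def test_no_match_and_full_match(self):
        seq = TokenSequence("d", ["a", "b"])
        assert tt_density(seq, TermLexicon(frozenset({"z"}))) == 0.0
        assert tt_density(seq, TermLexicon(frozenset({"a", "b"}))) == 1.0

    def test_empty_lexicon_warns_not_errors(self):
        seq = TokenSequence("d", ["a"])
        with pytest.warns(UserWarning, match="empty lexicon"):
            assert tt_density(seq, TermLexicon(frozenset())) == 0.0

    def test_multi_token_terms_count_their_length(self):
        # "basal cell carcinoma" as a 3-token term: 3 of 5 tokens match
        seq = TokenSequence("d", ["basal", "cell", "carcinoma", "was", "found"])
        lex = TermLexicon(frozenset({"basal cell carcinoma"}))
        assert tt_density(seq, lex) == pytest.approx(3 / 5)

    def test_greedy_longest_match_wins(self):
        seq = TokenSequence("d", ["a", "b", "c"])
        lex = TermLexicon(frozenset({"a", "a b"}))
        assert tt_density(seq, lex) == pytest.approx(2 / 3)

    def test_concatenation_is_weighted_mean(self):
        lex = TermLexicon(frozenset({"t"}))
        xs = ["t", "a", "a", "a"]
        ys = ["t", "t", "b"]
        d_cat = tt_density(TokenSequence("c", xs + ys), lex)
        d_x = tt_density(TokenSequence("x", xs), lex)
        d_y = tt_density(TokenSequence("y", ys), lex)
        assert d_cat == pytest.approx((4 * d_x + 3 * d_y) / 7)

    def test_order_invariance(self, rng):
        tokens = ["t1", "a", "t2", "b", "c", "t1"]
        lex = TermLexicon(frozenset({"t1", "t2"}))
        base = tt_density(TokenSequence("d", tokens), lex)
        perm = list(tokens)
        rng.shuffle(perm)
        assert tt_density(TokenSequence("d", perm), lex) == pytest.approx(base)

    def test_lexicon_file_round_trip(self, tmp_path):
        path = tmp_path / "lex.txt"
        path.write_text("化疗\nterm2\n\n", encoding="utf-8")
        assert read_lexicon(path).terms == frozenset({"化疗", "term2"})


class TestSectionDeltas:
    def test_identical_sections_give_zero(self):
        tokens = list("abcabcabd")
        pairs = {
            "p1": (
                _sectioned_doc("m", Group.MINOR, tokens, "p1"),
                _sectioned_doc("g", Group.GUARDIAN, tokens, "p1"),
            )
        }
        table = section_delta_table(pairs, (0.0, 1.5))
        assert np.allclose(table.to_numpy(), 0.0)

    def test_shape_sections_by_alphas(self):
        docs = generate_paired_corpus(
            PairedCorpusSpec(n_pairs=3, minor_length=400, guardian_length=900, seed=5)
        )
        pairs = {
            d.pair_id: (d, g)
            for d, g in zip(docs[::2], docs[1::2])
        }
        table = section_delta_table(pairs, (0.0, 0.5, 1.0, 1.5))
        assert table.shape == (4, 4)
        assert set(table.index) == set(SECTION_LABELS)

    def test_richer_guardian_sections_shrinking_with_alpha(self):
        # doubled vocabulary in every guardian section: delta > 0 and the
        # alpha=0 gap exceeds the alpha=1.5 gap
        spec = PairedCorpusSpec(
            n_pairs=8,
            minor_params=ZipfMandelbrotParams(400, 1.0, 2.0),
            guardian_params=ZipfMandelbrotParams(800, 1.0, 2.0),
            minor_length=10000,
            guardian_length=10000,
            seed=3,
        )
        docs = generate_paired_corpus(spec)
        pairs = {d.pair_id: (d, g) for d, g in zip(docs[::2], docs[1::2])}
        table = section_delta_table(pairs, (0.0, 1.5))
        assert (table[0.0] > table[1.5]).all()
        assert (table[1.5] > 0).all()

    def test_mismatched_section_labels_name_pair(self):
        m = _sectioned_doc("m", Group.MINOR, list("abcdef"), "p1")
        g = RawDocument("g", Group.GUARDIAN, list("abcdef"), "p1",
                        sections=[("other", (0, 6))])
        with pytest.raises(ValueError, match="p1"):
            section_delta_table({"p1": (m, g)})

    def test_section_spectra_monotone_in_alpha(self):
        doc = generate_paired_corpus(
            PairedCorpusSpec(n_pairs=1, minor_length=600, guardian_length=600, seed=1)
        )[0]
        for rec in section_spectra(doc, (0.0, 0.5, 1.0, 1.5)):
            vals = rec.spectrum.as_array()
            assert np.all(np.diff(vals) <= 1e-9)


class TestTtEntropyCorrelation:
    def test_monotone_injection_gives_positive_rho(self):
        params = ZipfMandelbrotParams(300, 1.1, 2.0)
        lex = demo_lexicon(40)
        rng = np.random.default_rng(8)
        docs = []
        for k in range(15):
            seq = sample_document(params, 4000, rng, f"d{k}")
            docs.append(inject_terms(seq, lex, rate=0.01 * k, rng=rng))
        rho, p = tt_entropy_correlation(docs, lex, alpha=1.5)
        assert rho > 0
        assert p < 0.05

    def test_constant_tt_is_an_error(self):
        lex = TermLexicon(frozenset({"z"}))
        docs = [TokenSequence(f"d{k}", ["a", "b", "c", f"x{k}"]) for k in range(4)]
        with pytest.raises(ValueError, match="constant"):
            tt_entropy_correlation(docs, lex)

    def test_two_documents_rejected(self):
        lex = demo_lexicon(5)
        docs = [TokenSequence("d1", ["a", "term1"]), TokenSequence("d2", ["b"])]
        with pytest.raises(ValueError, match="at least 3"):
            tt_entropy_correlation(docs, lex)
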