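import numpy as np
import pytest

from semkos.lexicon_tokenizer import (
    Lexicon,
    Term,
    build_lexicon,
    corpus_counts,
    filter_lexicon,
    normalize_surface,
    read_lexicon_tsv,
    read_token_streams,
    recognize_terms,
    tokenize_corpus,
    write_lexicon_tsv,
    write_token_streams,
)
from conftest import make_article, make_lexicon

PAPER_SENTENCE = (
    "visual short-term memory for high-resolution associations is impaired "
    "in patients with medial temporal lobe damage."
)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Hippocampus", "hippocampus"),
        ("  short-term   memory ", "short-term memory"),
        ("fMRI", "fmri"),
        ("Statistical\tAnalysis", "statistical analysis"),
        ("", ""),
    ],
)
def test_normalize_surface(raw, expected):
    assert normalize_surface(raw) == expected


def _counting_corpus():
    arts = []
    # "hippocampus" 3x keyword, "memory" 2x, "anova" both keyword and method
    arts.append(make_article("a1", keywords=["Hippocampus", "Memory", "ANOVA"]))
    arts.append(make_article("a2", keywords=["hippocampus", "memory"]))
    arts.append(make_article("a3", keywords=["Hippocampus"], methods_subtitles=["Statistical analysis", "ANOVA"]))
    arts.append(make_article("a4", methods_subtitles=["Statistical analysis"]))
    return arts


def test_build_lexicon_ranks_and_ids():
    lex = build_lexicon(_counting_corpus())
    assert lex.by_surface["hippocampus"].term_id == "kwd1"
    assert lex.by_surface["hippocampus"].source_count == 3
    assert lex.by_surface["memory"].term_id == "kwd2"
    assert lex.by_surface["statistical analysis"].term_id == "mtd1"


def test_surface_in_both_lists_kept_only_as_method():
    lex = build_lexicon(_counting_corpus())
    assert lex.by_surface["anova"].kind == "method"
    assert all(t.surface != "anova" for t in lex.of_kind("keyword"))


def test_rank_ties_broken_lexicographically():
    arts = [make_article("a", keywords=["zeta", "alpha"])]
    lex = build_lexicon(arts)
    assert lex.by_surface["alpha"].term_id == "kwd1"
    assert lex.by_surface["zeta"].term_id == "kwd2"


def test_rank_bijection_on_generated_corpus(small_tokenized):
    _, _, lexicon, _ = small_tokenized
    for kind in ("keyword", "method"):
        terms = lexicon.of_kind(kind)
        ranks = sorted(int(t.term_id[3:]) for t in terms)
        assert ranks == list(range(1, len(terms) + 1))
        by_rank = sorted(terms, key=lambda t: int(t.term_id[3:]))
        counts = [t.source_count for t in by_rank]
        assert counts == sorted(counts, reverse=True)


@pytest.mark.parametrize(
    "kind,source,corpus,kept",
    [
        ("keyword", 5, 100, False),  # "more than five" is strict
        ("keyword", 6, 11, True),
        ("keyword", 6, 10, False),
        ("method", 3, 11, True),
        ("method", 2, 50, False),
    ],
)
def test_filter_thresholds_strict(kind, source, corpus, kept):
    prefix = "kwd" if kind == "keyword" else "mtd"
    lex = Lexicon([Term("x", kind, f"{prefix}1", source, corpus)])
    out = filter_lexicon(lex)
    assert ("x" in out) is kept


def test_filter_keeps_ids_unchanged():
    lex = Lexicon(
        [
            Term("a", "keyword", "kwd1", 100, 100),
            Term("b", "keyword", "kwd2", 2, 100),  # filtered out
            Term("c", "keyword", "kwd3", 50, 50),
        ]
    )
    out = filter_lexicon(lex)
    assert sorted(out.by_id) == ["kwd1", "kwd3"]


def test_filter_monotone_in_thresholds():
    rng = np.random.default_rng(0)
    terms = [
        Term(f"t{i}", "keyword", f"kwd{i + 1}", int(rng.integers(0, 20)), int(rng.integers(0, 40)))
        for i in range(50)
    ]
    lex = Lexicon(terms)
    base = {t.surface for t in filter_lexicon(lex).terms}
    for ks, mc in [(6, 10), (5, 11), (8, 15)]:
        tighter = {
            t.surface
            for t in filter_lexicon(lex, keyword_min_source=ks, min_corpus=mc).terms
        }
        assert tighter <= base


def test_longest_phrase_first_on_example_sentence():
    lex = make_lexicon(keywords=["visual short-term memory", "short-term memory"])
    tokens = recognize_terms(PAPER_SENTENCE, lex)
    assert len(tokens) == 1
    tid, start, end = tokens[0]
    assert lex.by_id[tid].surface == "visual short-term memory"
    assert PAPER_SENTENCE[start:end] == "visual short-term memory"


def test_greedy_left_to_right_consumes_overlap():
    lex = make_lexicon(keywords=["a b", "b c"])
    tokens = recognize_terms("a b c", lex)
    assert [lex.by_id[t[0]].surface for t in tokens] == ["a b"]


def test_no_lexicon_phrase_yields_no_tokens():
    lex = make_lexicon(keywords=["hippocampus"])
    assert recognize_terms("the quick brown fox", lex) == []


def test_matches_do_not_cross_sentence_boundaries():
    lex = make_lexicon(keywords=["delta gamma"])
    assert recognize_terms("alpha delta. gamma beta", lex) == []
    assert len(recognize_terms("alpha delta gamma beta", lex)) == 1


def test_case_and_punctuation_insensitive_matching():
    lex = make_lexicon(keywords=["short-term memory"])
    tokens = recognize_terms("We studied Short-Term Memory, extensively", lex)
    assert len(tokens) == 1


def _assert_valid_tokenization(text, lex, tokens):
    # spans strictly increasing and non-overlapping, each surface matches
    prev_end = -1
    surfaces_by_first = {}
    for t in lex.terms:
        words = t.surface.split()
        surfaces_by_first.setdefault(words[0], []).append(words)
    for tid, start, end in tokens:
        assert start > prev_end
        prev_end = end
        covered = " ".join(text[start:end].lower().replace("  ", " ").split())
        assert covered == lex.by_id[tid].surface


def test_fuzz_spans_nonoverlapping_and_maximal():
    rng = np.random.default_rng(42)
    vocab = [f"w{i}" for i in range(12)]
    for _ in range(200):
        n_phrases = int(rng.integers(2, 7))
        phrases = set()
        while len(phrases) < n_phrases:
            ln = int(rng.integers(1, 4))
            phrases.add(" ".join(rng.choice(vocab, size=ln)))
        lex = make_lexicon(keywords=sorted(phrases))
        text = " ".join(rng.choice(vocab, size=int(rng.integers(5, 40))))
        tokens = recognize_terms(text, lex)
        _assert_valid_tokenization(text, lex, tokens)
        # maximality: no emitted token extends to a longer phrase at its start
        words = text.split()
        starts = {}
        pos = 0
        for i, w in enumerate(words):
            starts[pos] = i
            pos += len(w) + 1
        for tid, start, end in tokens:
            i = starts[start]
            ln = len(lex.by_id[tid].surface.split())
            for phrase in phrases:
                pw = phrase.split()
                if len(pw) > ln and words[i : i + len(pw)] == pw:
                    pytest.fail(f"token {lex.by_id[tid].surface!r} not maximal at {start}")


def test_tokenize_corpus_discards_nonterms_and_is_deterministic():
    lex = make_lexicon(keywords=["hippocampus", "memory"])
    art = make_article("a1", body="hippocampus is required for memory")
    streams = tokenize_corpus([art], lex)
    assert [lex.by_id[t].surface for t in streams[0].term_ids()] == ["hippocampus", "memory"]
    assert tokenize_corpus([art], lex)[0] == streams[0]
    empty = make_article("a2", body="")
    assert tokenize_corpus([empty], lex)[0].tokens == []


def test_lexicon_and_stream_serialization_round_trip(tmp_path, small_tokenized):
    _, _, lexicon, streams = small_tokenized
    lex = lexicon.with_corpus_counts(corpus_counts(streams, lexicon))
    lex_path = tmp_path / "lexicon.tsv"
    write_lexicon_tsv(lex, lex_path)
    assert read_lexicon_tsv(lex_path).terms == lex.terms
    st_path = tmp_path / "streams.jsonl"
    write_token_streams(streams[:20], st_path)
    assert read_token_streams(st_path) == streams[:20]
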