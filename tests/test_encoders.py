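"""Lexicon construction, the order/context update rules, and training."""

import numpy as np
import pytest

from holoperm.corpus import Document
from holoperm.encoders import (
    EncoderConfig,
    SemanticSpace,
    beagle_config,
    build_frequency_stats,
    default_stoplist,
    init_lexicon,
    rpm_config,
    encode_rpm_sentence,
    train_semantic_model,
    update_context,
    update_order_convolution,
    update_order_rp,
)
from holoperm.vectors import circular_convolve, cosine, permute_power, rc_transform


def _lexicon(words, config):
    return init_lexicon({w: 1 for w in words}, config)


# ---------------------------------------------------------------------------
# lexicon init
# ---------------------------------------------------------------------------


def test_init_is_deterministic():
    cfg = EncoderConfig(D=128, master_seed=4)
    a = _lexicon(["a", "b", "c"], cfg)
    b = _lexicon(["a", "b", "c"], cfg)
    assert np.array_equal(a.signal, b.signal)
    assert np.array_equal(a.placeholder, b.placeholder)
    assert np.array_equal(a.perm.target_index, b.perm.target_index)


def test_init_gaussian_norms():
    cfg = EncoderConfig(D=1024, vector_kind="gaussian", master_seed=0)
    lex = _lexicon([f"w{i}" for i in range(500)], cfg)
    assert abs((lex.signal ** 2).sum(axis=1).mean() - 1.0) < 0.1


def test_init_sparse_signals():
    cfg = EncoderConfig(D=256, vector_kind="sparse_ternary", master_seed=0)
    lex = _lexicon([f"w{i}" for i in range(50)], cfg)
    assert (np.count_nonzero(lex.signal, axis=1) == 4).all()
    assert np.allclose(lex.signal.sum(axis=1), 0)


def test_init_rejects_empty_vocab():
    with pytest.raises(ValueError):
        init_lexicon({}, EncoderConfig(D=64))


def test_memory_starts_zeroed():
    lex = _lexicon(["a", "b"], EncoderConfig(D=64))
    assert not lex.memory.any()


# ---------------------------------------------------------------------------
# frequency stats
# ---------------------------------------------------------------------------


def test_frequency_stats_counts_and_ranking():
    docs = [Document([["a", "a", "b"]])]
    counts, ranked = build_frequency_stats(docs)
    assert counts == {"a": 2, "b": 1}
    assert ranked[0] == "a"


def test_frequency_ties_break_lexicographically():
    docs = [Document([["zeta", "alpha"]])]
    _, ranked = build_frequency_stats(docs)
    assert ranked == ["alpha", "zeta"]


def test_frequency_stats_empty_corpus():
    with pytest.raises(ValueError):
        build_frequency_stats([])


# ---------------------------------------------------------------------------
# convolution order updates
# ---------------------------------------------------------------------------


def test_order_convolution_matches_manual_ngram_expansion():
    """'one two three' with the target in first position and λ=3 adds the
    bigram Φ⊛e_two plus the trigram (Φ⊛e_two)⊛e_three."""
    cfg = EncoderConfig(D=64, operator="convolution", max_ngram=3, master_seed=1)
    lex = _lexicon(["one", "two", "three"], cfg)
    update_order_convolution(lex, ["one", "two", "three"], 0, cfg)
    phi = lex.placeholder
    e2 = lex.signal_vector("two")
    e3 = lex.signal_vector("three")
    expected = circular_convolve(phi, e2) + circular_convolve(
        circular_convolve(phi, e2), e3
    )
    assert np.allclose(lex.memory_vector("one"), expected, atol=1e-10)


def test_order_convolution_middle_target_counts_all_ngrams():
    # target 'b' in 'a b c', λ=5: bigrams a-b and b-c plus the trigram
    cfg = EncoderConfig(D=32, operator="convolution", max_ngram=5, master_seed=2)
    lex = _lexicon(["a", "b", "c"], cfg)
    update_order_convolution(lex, ["a", "b", "c"], 1, cfg)
    phi = lex.placeholder
    ea, ec = lex.signal_vector("a"), lex.signal_vector("c")
    expected = (
        circular_convolve(ea, phi)
        + circular_convolve(phi, ec)
        + circular_convolve(circular_convolve(ea, phi), ec)
    )
    assert np.allclose(lex.memory_vector("b"), expected, atol=1e-10)


def test_order_convolution_two_word_sentence():
    cfg = EncoderConfig(D=32, operator="convolution", max_ngram=5, master_seed=3)
    lex = _lexicon(["a", "b"], cfg)
    update_order_convolution(lex, ["a", "b"], 1, cfg)
    expected = circular_convolve(lex.signal_vector("a"), lex.placeholder)
    assert np.allclose(lex.memory_vector("b"), expected, atol=1e-10)


def test_order_convolution_single_word_noop():
    cfg = EncoderConfig(D=32, operator="convolution", master_seed=4)
    lex = _lexicon(["a"], cfg)
    update_order_convolution(lex, ["a"], 0, cfg)
    assert not lex.memory.any()


def test_order_update_rejects_bad_position():
    cfg = EncoderConfig(D=32, operator="convolution", master_seed=5)
    lex = _lexicon(["a", "b"], cfg)
    with pytest.raises(IndexError):
        update_order_convolution(lex, ["a", "b"], 2, cfg)


# ---------------------------------------------------------------------------
# permutation order updates
# ---------------------------------------------------------------------------


def test_order_rp_following_words_get_positive_powers():
    cfg = EncoderConfig(D=64, operator="random_permutation", max_ngram=3,
                        master_seed=6)
    lex = _lexicon(["one", "two", "three"], cfg)
    update_order_rp(lex, ["one", "two", "three"], 0, cfg)
    expected = permute_power(lex.signal_vector("two"), lex.perm, 1) + permute_power(
        lex.signal_vector("three"), lex.perm, 2
    )
    assert np.allclose(lex.memory_vector("one"), expected)


def test_order_rp_preceding_words_get_negative_powers():
    cfg = EncoderConfig(D=64, operator="random_permutation", max_ngram=3,
                        master_seed=7)
    lex = _lexicon(["one", "two", "three"], cfg)
    update_order_rp(lex, ["one", "two", "three"], 2, cfg)
    expected = permute_power(lex.signal_vector("one"), lex.perm, -2) + permute_power(
        lex.signal_vector("two"), lex.perm, -1
    )
    assert np.allclose(lex.memory_vector("three"), expected)


def test_order_rp_single_word_noop():
    cfg = EncoderConfig(D=64, operator="random_permutation", master_seed=8)
    lex = _lexicon(["one"], cfg)
    update_order_rp(lex, ["one"], 0, cfg)
    assert not lex.memory.any()


def test_order_rp_decodes_by_inverse_power():
    # the neighbour stored at power j is recoverable by permuting back
    cfg = EncoderConfig(D=512, operator="random_permutation", max_ngram=5,
                        master_seed=9)
    words = [f"w{i}" for i in range(5)]
    lex = _lexicon(words, cfg)
    update_order_rp(lex, words, 0, cfg)
    m = lex.memory_vector("w0")
    unbound = permute_power(m, lex.perm, -2)
    sims = [cosine(unbound, lex.signal_vector(w)) for w in words[1:]]
    assert int(np.argmax(sims)) == 1  # w2 sat at offset +2


# ---------------------------------------------------------------------------
# context updates
# ---------------------------------------------------------------------------


def test_context_sums_other_signal_vectors():
    cfg = EncoderConfig(D=64, use_context=True, master_seed=10)
    lex = _lexicon(["a", "b", "c"], cfg)
    update_context(lex, ["a", "b", "c"], 1, cfg)
    expected = lex.signal_vector("a") + lex.signal_vector("c")
    assert np.allclose(lex.memory_vector("b"), expected)


def test_context_respects_stoplist():
    cfg = EncoderConfig(D=64, use_context=True, stoplist=frozenset({"a"}),
                        master_seed=11)
    lex = _lexicon(["a", "b", "c"], cfg)
    update_context(lex, ["a", "b", "c"], 1, cfg)
    assert np.allclose(lex.memory_vector("b"), lex.signal_vector("c"))


def test_context_never_adds_target_to_itself():
    cfg = EncoderConfig(D=64, use_context=True, master_seed=12)
    lex = _lexicon(["a", "b"], cfg)
    update_context(lex, ["a", "b", "a"], 0, cfg)
    # the other 'a' occurrence counts, the target occurrence does not
    expected = lex.signal_vector("b") + lex.signal_vector("a")
    assert np.allclose(lex.memory_vector("a"), expected)


# ---------------------------------------------------------------------------
# direction-only (window ±2) encoding
# ---------------------------------------------------------------------------


def test_direction_only_rp_components():
    cfg = rpm_config(D=128, master_seed=13, use_context=False, freq_threshold_n=0)
    words = ["a", "b", "c", "d", "e"]
    lex = _lexicon(words, cfg)
    encode_rpm_sentence(lex, words, cfg)
    before = lex.signal_vector("a") + lex.signal_vector("b")
    after = lex.signal_vector("d") + lex.signal_vector("e")
    expected = permute_power(before, lex.perm, -1) + permute_power(after, lex.perm, 1)
    assert np.allclose(lex.memory_vector("c"), expected)


def test_direction_only_sim1_components():
    cfg = rpm_config(D=128, operator="random_connection_sim1", master_seed=14,
                     use_context=False, freq_threshold_n=0)
    words = ["a", "b", "c", "d", "e"]
    lex = _lexicon(words, cfg)
    encode_rpm_sentence(lex, words, cfg)
    before = lex.signal_vector("a") + lex.signal_vector("b")
    after = lex.signal_vector("d") + lex.signal_vector("e")
    expected = rc_transform(before, lex.rc, 1) + after
    assert np.allclose(lex.memory_vector("c"), expected)


def test_direction_only_sim2_components():
    cfg = rpm_config(D=128, operator="random_connection_sim2", master_seed=15,
                     use_context=False, freq_threshold_n=0)
    words = ["a", "b", "c", "d", "e"]
    lex = _lexicon(words, cfg)
    encode_rpm_sentence(lex, words, cfg)
    before = lex.signal_vector("a") + lex.signal_vector("b")
    after = lex.signal_vector("d") + lex.signal_vector("e")
    expected = rc_transform(before, lex.rc, 1) + rc_transform(after, lex.rc, 2)
    assert np.allclose(lex.memory_vector("c"), expected)


def test_frequency_threshold_words_skipped_as_cues_but_still_trained():
    cfg = rpm_config(D=128, freq_threshold_n=1, master_seed=16, use_context=False)
    counts = {"common": 100, "rare1": 1, "rare2": 1}
    lex = init_lexicon(counts, cfg)
    assert lex.excluded_cues == {"common"}
    encode_rpm_sentence(lex, ["rare1", "common", "rare2"], cfg)
    # 'common' contributes nothing to its neighbours...
    expected = permute_power(lex.signal_vector("rare1"), lex.perm, -1)
    assert np.allclose(lex.memory_vector("rare2"), expected)
    # ...but its own memory vector is still trained
    assert lex.memory_vector("common").any()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def test_training_is_deterministic(synthetic_fixture):
    cfg = EncoderConfig(D=128, operator="random_permutation", master_seed=17)
    docs = str(synthetic_fixture["corpus"])
    a = train_semantic_model(docs, cfg)
    b = train_semantic_model(docs, cfg)
    assert np.array_equal(a.memory, b.memory)


def test_order_only_training_is_local():
    """Tokens farther than λ−1 positions away never touch a word's
    order-only memory vector."""
    cfg = EncoderConfig(D=128, operator="random_permutation", max_ngram=3,
                        master_seed=18)
    s1 = [["t", "n1", "n2", "far_a"]]
    s2 = [["t", "n1", "n2", "far_b"]]
    vocab = {"t": 1, "n1": 1, "n2": 1, "far_a": 1, "far_b": 1}
    lex1 = init_lexicon(vocab, cfg)
    lex2 = init_lexicon(vocab, cfg)
    update_order_rp(lex1, s1[0], 0, cfg)
    update_order_rp(lex2, s2[0], 0, cfg)
    assert np.array_equal(lex1.memory_vector("t"), lex2.memory_vector("t"))


def test_document_order_invariance(synthetic_fixture):
    from holoperm.corpus import read_plaintext_corpus

    docs = list(read_plaintext_corpus(synthetic_fixture["corpus"]))[:60]
    cfg = EncoderConfig(D=128, operator="random_permutation", master_seed=19)
    fwd = train_semantic_model(docs, cfg)
    rev = train_semantic_model(docs[::-1], cfg)
    assert np.allclose(fwd.memory, rev.memory, atol=1e-6)


@pytest.mark.parametrize("operator", ["convolution", "random_permutation"])
def test_planted_synonyms_recovered_by_order_training(
    synthetic_fixture, operator, rng
):
    """Synonyms share sentence templates, so order-only training must give
    synonym pairs higher cosine than random word pairs by ≥ 3 SEs."""
    import json

    cfg = EncoderConfig(D=1024, operator=operator, master_seed=20)
    lex = train_semantic_model(str(synthetic_fixture["corpus"]), cfg)
    groups = json.loads(synthetic_fixture["truth"].read_text())["groups"]
    syn_cos = [
        cosine(lex.memory_vector(a), lex.memory_vector(b)) for a, b in groups
    ]
    rand_cos = []
    for _ in range(200):
        a, b = rng.choice(len(groups), 2, replace=False)
        rand_cos.append(
            cosine(
                lex.memory_vector(groups[a][0]), lex.memory_vector(groups[b][1])
            )
        )
    se = np.sqrt(np.var(syn_cos) / len(syn_cos) + np.var(rand_cos) / len(rand_cos))
    assert np.mean(syn_cos) - np.mean(rand_cos) > 3 * se


def test_rp_and_rc_sim2_agree_on_synthetic_corpus(synthetic_fixture):
    from holoperm.evaluate import score_synonymy_test

    accs = {}
    for op in ("random_permutation", "random_connection_sim2"):
        cfg = rpm_config(D=1024, operator=op, master_seed=21)
        lex = train_semantic_model(str(synthetic_fixture["corpus"]), cfg)
        accs[op], _ = score_synonymy_test(lex, synthetic_fixture["synonymy"])
    n = len(synthetic_fixture["synonymy"])
    p = np.mean(list(accs.values()))
    se = np.sqrt(max(p * (1 - p), 1e-9) * 2 / n)
    assert abs(accs["random_permutation"] - accs["random_connection_sim2"]) <= 3 * se


# ---------------------------------------------------------------------------
# sklearn estimator facade
# ---------------------------------------------------------------------------


def test_semantic_space_sklearn_contract(synthetic_fixture):
    from sklearn.base import clone

    model = SemanticSpace(D=128, operator="random_permutation", master_seed=22)
    params = model.get_params()
    assert params["D"] == 128
    cloned = clone(model)
    assert cloned.get_params() == params

    model.fit(str(synthetic_fixture["corpus"]))
    assert hasattr(model, "lexicon_")
    words = list(model.vocabulary_)[:5]
    X = model.transform(words)
    assert X.shape == (5, 128)
    with pytest.raises(KeyError):
        model.transform(["not-a-word"])


def test_semantic_space_unfitted_raises():
    with pytest.raises(RuntimeError, match="not fitted"):
        SemanticSpace(D=64).transform(["a"])


def test_config_factories_and_stoplist():
    assert len(default_stoplist()) == 280
    b = beagle_config(D=256)
    assert b.operator == "convolution" and b.use_context and b.max_ngram == 5
    r = rpm_config(D=256)
    assert r.direction_only and r.freq_threshold_n == 87
    assert r.vector_kind == "sparse_ternary"
    with pytest.raises(ValueError):
        EncoderConfig(operator="nope")
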