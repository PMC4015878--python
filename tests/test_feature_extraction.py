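"""Dependency paths, distance bins, and the four feature-set modes."""

import random
from collections import deque

import pytest

from ratechange_miner import resources
from ratechange_miner.feature_extraction import (
    DependencyParse,
    bin_path_length,
    extract_gene_keyword_distance,
    extract_keyword_tag,
    extract_word_relation_word,
    featurize,
    ontology_keywords,
    shortest_dependency_path,
)
from ratechange_miner.preprocess import (
    Sentence,
    normalize,
    recognize_genes,
    tokenize_and_tag,
)
from ratechange_miner.synthetic_corpus import GeneratorConfig, generate


def chain_parse(n, label="dep", root=0):
    return DependencyParse(
        n_tokens=n,
        edges=tuple((i, i + 1, label) for i in range(n - 1)),
        root=root,
    )


# ---------------------------------------------------------------------------
# shortest path


def test_path_to_self_has_length_zero():
    p = chain_parse(3)
    assert shortest_dependency_path(p, 1, 1) == [1]


def test_chain_path_length_two():
    p = chain_parse(3)
    path = shortest_dependency_path(p, 0, 2)
    assert path == [0, 1, 2]
    assert len(path) - 1 == 2


def test_disconnected_parse_errors():
    p = DependencyParse(n_tokens=4, edges=((0, 1, "dep"),), root=0)
    with pytest.raises(ValueError, match="disconnected"):
        shortest_dependency_path(p, 0, 3)


def bfs_oracle(edges, n, a, b):
    """Independent breadth-first shortest-path length."""
    adj = {i: [] for i in range(n)}
    for h, d, _ in edges:
        adj[h].append(d)
        adj[d].append(h)
    dist = {a: 0}
    q = deque([a])
    while q:
        u = q.popleft()
        if u == b:
            return dist[u]
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return None


def test_path_length_matches_bfs_oracle_on_random_trees():
    rng = random.Random(777)
    for _ in range(200):
        n = rng.randint(2, 10)
        # random tree: attach each node to a random earlier node
        edges = tuple(
            (rng.randint(0, i - 1), i, rng.choice(["nsubj", "dobj", "prep"]))
            for i in range(1, n)
        )
        parse = DependencyParse(n_tokens=n, edges=edges, root=0)
        a, b = rng.randrange(n), rng.randrange(n)
        got = shortest_dependency_path(parse, a, b)
        assert len(got) - 1 == bfs_oracle(edges, n, a, b)


def test_tie_break_is_lexicographically_smallest():
    # square: 0-1, 1-3, 0-2, 2-3 -> two paths of length 2 from 0 to 3
    parse = DependencyParse(
        n_tokens=4,
        edges=((0, 1, "a"), (1, 3, "b"), (0, 2, "c"), (2, 3, "d")),
        root=0,
    )
    assert shortest_dependency_path(parse, 0, 3) == [0, 1, 3]


# ---------------------------------------------------------------------------
# distance bins


@pytest.mark.parametrize("length,bin_", [
    (0, "near"), (2, "near"), (3, "near"),
    (4, "moderate"), (5, "moderate"), (6, "moderate"),
    (7, "far"), (20, "far"),
])
def test_bins_partition_lengths(length, bin_):
    assert bin_path_length(length) == bin_


def test_negative_length_rejected():
    with pytest.raises(ValueError):
        bin_path_length(-1)


# ---------------------------------------------------------------------------
# feature families on a hand-built toy parse


@pytest.fixture()
def toy(gene_dictionary, norm_dictionary):
    # tokens: MTH1 slowed repression of HXT3 promoter activity .
    raw = "MTH1 slowed repression of HXT3 promoter activity."
    sent = tokenize_and_tag(Sentence(pmid="T", index=0, raw=raw))
    sent = recognize_genes(sent, gene_dictionary)
    sent = normalize(sent, norm_dictionary)
    parse = DependencyParse(
        n_tokens=8,
        edges=(
            (2, 0, "nsubj"), (2, 1, "amod"), (2, 3, "prep"), (3, 4, "pobj"),
            (4, 5, "nn"), (5, 6, "nn"), (2, 7, "punct"),
        ),
        root=2,
    )
    return sent, parse


def test_keyword_tag_features(toy, rate_ontology, negative_ontology):
    sent, _ = toy
    kws = ontology_keywords(rate_ontology, negative_ontology)
    feats = extract_keyword_tag(sent, kws)
    assert "kw|promoter|NN" in feats
    assert "kw|activity|NN" in feats
    assert not any(f.startswith("kw|genename") for f in feats)


def test_keyword_tag_empty_without_keywords(rate_ontology, negative_ontology):
    sent = tokenize_and_tag(Sentence(pmid="T", index=0, raw="Nothing to see."))
    sent = normalize(sent, resources.normalization_dictionary())
    kws = ontology_keywords(rate_ontology, negative_ontology)
    assert extract_keyword_tag(sent, kws) == set()


def test_word_relation_word_raw_and_generalized(toy, rate_ontology, negative_ontology):
    sent, parse = toy
    kws = ontology_keywords(rate_ontology, negative_ontology)
    raw_feats = extract_word_relation_word(parse, sent, kws)
    assert "wrw|genename|nn|promoter" in raw_feats  # HXT3 -nn-> promoter
    hier = resources.dependency_type_hierarchy()
    gen_feats = extract_word_relation_word(parse, sent, kws, type_map=hier)
    assert "wrw|genename|mod|promoter" in gen_feats  # nn generalizes to mod
    assert len(gen_feats) <= len(raw_feats)


def test_gene_keyword_distance_bins(toy, rate_ontology, negative_ontology):
    sent, parse = toy
    kws = ontology_keywords(rate_ontology, negative_ontology)
    feats = extract_gene_keyword_distance(parse, sent, kws, binned=True)
    # HXT3(4) -> promoter(5): length 1 -> near; MTH1(0) -> activity(6): 0-2-3-4-5-6 -> 5 -> moderate
    assert "gkd|genename|promoter|near" in feats
    assert "gkd|genename|activity|moderate" in feats
    raw = extract_gene_keyword_distance(parse, sent, kws, binned=False)
    assert "gkd|genename|promoter|len1" in raw


# ---------------------------------------------------------------------------
# featurize modes


def test_all_rules_mode_fires_negative_pattern(
    gene_dictionary, norm_dictionary, rate_ontology, negative_ontology
):
    raw = ("Here we show that two highly conserved ATP-dependent "
           "chromatin-remodeling complexes in Saccharomyces cerevisiae, Isw2 "
           "and Ino80, function in parallel to promote replication fork "
           "progression.")
    sent = tokenize_and_tag(Sentence(pmid="18408730", index=0, raw=raw))
    sent = recognize_genes(sent, gene_dictionary)
    sent = normalize(sent, norm_dictionary)
    fv = featurize(sent, None, "all_rules", rate_ontology, negative_ontology)
    assert any(
        f.startswith("rule|negative|dna_replication_repair") for f in fv.features
    )


def test_combined_mode_empty_on_keyword_free_sentence(
    rate_ontology, negative_ontology, norm_dictionary
):
    sent = tokenize_and_tag(Sentence(pmid="T", index=0, raw="Cats sit quietly."))
    sent = normalize(sent, norm_dictionary)
    parse = chain_parse(4)
    fv = featurize(sent, parse, "combined", rate_ontology, negative_ontology)
    assert len(fv) == 0


def test_postprocessing_is_a_collapse(toy, rate_ontology, negative_ontology):
    """Generalized types + binned lengths never increase the feature count."""
    sent, parse = toy
    combined = featurize(sent, parse, "combined", rate_ontology, negative_ontology)
    original = featurize(sent, parse, "original_combined", rate_ontology,
                         negative_ontology)
    assert len(combined) <= len(original)


def test_featurize_deterministic_and_local(small_corpus, rate_ontology,
                                           negative_ontology):
    ls = next(s for s in small_corpus if s.parse is not None)
    fv1 = featurize(ls.sentence, ls.parse, "combined", rate_ontology, negative_ontology)
    fv2 = featurize(ls.sentence, ls.parse, "combined", rate_ontology, negative_ontology)
    assert fv1.features == fv2.features


def test_unknown_mode_rejected(toy, rate_ontology, negative_ontology):
    sent, parse = toy
    with pytest.raises(ValueError):
        featurize(sent, parse, "bogus", rate_ontology, negative_ontology)


def test_baseline_mode_has_between_words_and_path(toy, rate_ontology,
                                                  negative_ontology):
    sent, parse = toy
    fv = featurize(sent, parse, "baseline_ace", rate_ontology, negative_ontology)
    assert any(f.startswith("ace|bw|") for f in fv.features)
    assert any(f.startswith("ace|path|") for f in fv.features)
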