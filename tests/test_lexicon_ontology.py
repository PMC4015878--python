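"""Lexicon loading, rate-direction classes, relation closure, pattern matching."""

import itertools
import random
from collections import defaultdict

import pytest

from ratechange_miner import resources
from ratechange_miner.lexicon_ontology import (
    COMPOSITION,
    Ontology,
    OntologyNode,
    OntologyRelation,
    TextualPattern,
    classify_rate_direction,
    infer_relation_closure,
    load_lexicon,
    match_patterns,
)


# ---------------------------------------------------------------------------
# load_lexicon


def test_load_lexicon_counts_unique_entries(tmp_path):
    p = tmp_path / "lex.txt"
    p.write_text("activate\naccelerate\nincrease\n")
    lex = load_lexicon(p)
    assert lex.size_n == 3
    assert set(lex.heads) == {"activate", "accelerate", "increase"}


def test_load_lexicon_empty_file_errors(tmp_path):
    p = tmp_path / "empty.txt"
    p.write_text("\n\n")
    with pytest.raises(ValueError, match="empty lexicon"):
        load_lexicon(p)


def test_load_lexicon_collapses_duplicate_heads_with_warning(tmp_path, caplog):
    p = tmp_path / "dup.txt"
    p.write_text("activated\tactivate\nactivated\tactivate\n")
    with caplog.at_level("WARNING"):
        lex = load_lexicon(p)
    assert lex.size_n == 1
    assert "duplicate" in caplog.text


def test_shipped_quicken_words_present(rate_change_lexicon):
    # the quicken-class trigger words are in the rate-change lexicon
    assert "accelerate" in rate_change_lexicon
    assert "enhance" in rate_change_lexicon


def test_lexicon_entries_map_through_normalizer(tmp_path, norm_dictionary):
    p = tmp_path / "lex.txt"
    p.write_text("rapidly\nslowed\n")
    lex = load_lexicon(p, normalizer=norm_dictionary.head)
    assert set(lex.heads) == {"rapid", "slow"}


# ---------------------------------------------------------------------------
# rate-direction classes


@pytest.mark.parametrize("word,expected", [
    ("accelerate", "Quicken"),
    ("enhance", "Quicken"),
    ("delay", "Delay"),
    ("slow", "Delay"),
    ("alter", "Change"),
    ("ribosome", None),
])
def test_classify_rate_direction(word, expected):
    classes = resources.rate_direction_classes()
    assert classify_rate_direction(word, classes) == expected


def test_rate_direction_classes_partition_the_lexicon_words():
    """Every rate-change trigger word belongs to exactly one direction class."""
    classes = resources.rate_direction_classes()
    all_words = [w for ws in classes.members.values() for w in ws]
    assert len(all_words) == len(set(all_words))  # disjoint
    lex = resources.rate_change_lexicon()
    for head in lex.heads:
        assert classify_rate_direction(head, classes) is not None


# ---------------------------------------------------------------------------
# relation closure


def rel(s, r, o):
    return OntologyRelation(s, r, o)


def closure_oracle(relations):
    """Brute force: fold the composition table over every relation-labeled
    directed path (all paths are simple in a DAG)."""
    edges = defaultdict(list)
    for r in relations:
        edges[r.subject].append((r.relation, r.object))
    out = set(relations)

    def walk(start, node, label, visited):
        for l2, nxt in edges[node]:
            if nxt in visited:
                continue
            comp = COMPOSITION.get((label, l2))
            if comp is None:
                continue
            out.add(OntologyRelation(start, comp, nxt))
            walk(start, nxt, comp, visited | {nxt})

    for r in relations:
        walk(r.subject, r.object, r.relation, {r.subject, r.object})
    return out


def test_part_of_then_result_from_composes():
    got = infer_relation_closure({rel("A", "part_of", "B"), rel("B", "result_from", "C")})
    assert rel("A", "result_from", "C") in got


def test_empty_input_gives_empty_closure():
    assert infer_relation_closure(set()) == set()


def test_chain_closure_matches_enumeration():
    asserted = {rel("A", "is_a", "B"), rel("B", "part_of", "C"), rel("C", "part_of", "D")}
    got = infer_relation_closure(asserted)
    assert got == asserted | {
        rel("A", "part_of", "C"),
        rel("A", "part_of", "D"),
        rel("B", "part_of", "D"),
    }


def test_undefined_composition_infers_nothing():
    got = infer_relation_closure({rel("A", "result_from", "B"), rel("B", "result_from", "C")})
    assert got == {rel("A", "result_from", "B"), rel("B", "result_from", "C")}


def _random_dag_relations(rng, max_nodes=8):
    n = rng.randint(2, max_nodes)
    nodes = [f"N{i}" for i in range(n)]
    rels = set()
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < 0.35:  # edges follow index order: acyclic
            rels.add(rel(nodes[i], rng.choice(["is_a", "part_of", "result_from"]), nodes[j]))
    return rels


def test_closure_equals_bruteforce_oracle_on_random_dags():
    rng = random.Random(12345)
    for _ in range(200):
        rels = _random_dag_relations(rng)
        assert infer_relation_closure(rels) == closure_oracle(rels)


def test_closure_idempotent_and_monotone():
    rng = random.Random(54321)
    for _ in range(50):
        rels = _random_dag_relations(rng)
        closed = infer_relation_closure(rels)
        assert closed >= rels
        assert infer_relation_closure(closed) == closed
        sub = set(list(rels)[: len(rels) // 2])
        assert infer_relation_closure(sub) <= closed


def test_is_a_cycle_retained_and_logged(caplog):
    with caplog.at_level("WARNING"):
        got = infer_relation_closure({rel("X", "is_a", "Y"), rel("Y", "is_a", "X")})
    assert rel("X", "is_a", "X") in got
    assert "self-relation" in caplog.text


# ---------------------------------------------------------------------------
# pattern matching


def test_promoter_activity_pattern_fires_on_reduced_promoter_activity(rate_ontology):
    tokens = ("genename", "mutate", "exhibit", "g1", "delay", "and",
              "reduce", "genename", "promoter", "activity")
    assert "promoter_activity" in match_patterns(tokens, rate_ontology)


def test_no_lexicon_words_matches_nothing(rate_ontology):
    assert match_patterns(("the", "cat", "sat"), rate_ontology) == set()


def test_match_patterns_order_and_duplicate_insensitive(rate_ontology):
    tokens = ["reduce", "promoter", "activity", "genename"]
    base = match_patterns(tuple(tokens), rate_ontology)
    rng = random.Random(3)
    for _ in range(10):
        shuffled = tokens[:] + [rng.choice(tokens)]
        rng.shuffle(shuffled)
        got = match_patterns(tuple(shuffled), rate_ontology)
        # single-word patterns are order-free; the multiword bigram check is
        # the only order-sensitive construct and none is involved here
        assert got == base


def test_multiword_keyword_requires_adjacency(negative_ontology):
    assert "dna_replication_repair" in match_patterns(
        ("promote", "replication", "fork", "progression"), negative_ontology)
    assert "dna_replication_repair" not in match_patterns(
        ("promote", "replication", "of", "fork"), negative_ontology)


def test_planted_patterns_match_exactly(rate_ontology):
    """A sentence planted with the keywords of exactly two nodes matches them."""
    tokens = ("genename", "slow", "regulate", "of", "genename",
              "promoter", "activity", "chromatin")
    got = match_patterns(tokens, rate_ontology)
    assert got == {"promoter_activity", "chromatin_remodeling"}


def test_pattern_requires_nonempty_keywords():
    with pytest.raises(ValueError):
        TextualPattern(node_id="x", keywords=frozenset(), polarity="rate_change")


def test_ontology_rejects_pattern_for_unknown_node():
    node = OntologyNode(id="a", label="a", polarity="rate_change")
    with pytest.raises(ValueError):
        Ontology(
            name="t", polarity="rate_change", nodes={"a": node},
            patterns=(TextualPattern("b", frozenset({"x"}), "rate_change"),),
        )
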