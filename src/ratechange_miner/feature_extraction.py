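"""Ontology-driven dependency-path features for direct-evidence detection.

Three feature families are built over a sentence's dependency parse:

1. ``keyword_tag`` — each ontology keyword occurring in the sentence,
   combined with its POS tag (normalized head form, so morphological
   variants collapse).
2. ``word_rel_word`` — along the shortest dependency path between every
   gene and every ontology keyword, each consecutive token pair joined by
   the name of the dependency relation between them.
3. ``gene_kw_dist`` — per gene-keyword pair, the triplet (gene placeholder,
   keyword, shortest-path length).

Post-processing reduces feature diversity: specific dependency types are
generalized to the second level of the typed-dependency hierarchy (an
editable mapping table ships with the package), and raw path lengths are
binned into three nominal values — near (length <= 3), moderate (4-6) and
far (>= 7).

Feature-set modes mirror the evaluated variants: ``combined`` (all three
families with post-processing), ``original_combined`` (same families, no
post-processing), ``all_rules`` (one binary feature per firing ontology
pattern), and ``baseline_ace`` (ACE-style inter-entity bag-of-words plus
parse-path features; an approximation of the classical content-extraction
feature set, documented as such).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from ratechange_miner.lexicon_ontology import Ontology, match_patterns
from ratechange_miner.preprocess import Sentence

__all__ = [
    "DependencyParse", "FeatureVector", "MODES", "bin_path_length",
    "shortest_dependency_path", "ontology_keywords", "keyword_token_indices",
    "extract_keyword_tag", "extract_word_relation_word",
    "extract_gene_keyword_distance", "featurize",
]

MODES = ("baseline_ace", "all_rules", "original_combined", "combined")


@dataclass
class DependencyParse:
    """Typed head-dependent edges over a sentence's tokens (a toy or real parse)."""

    n_tokens: int
    edges: tuple[tuple[int, int, str], ...]  # (head index, dependent index, type)
    root: int

    def __post_init__(self) -> None:
        for h, d, _ in self.edges:
            if not (0 <= h < self.n_tokens and 0 <= d < self.n_tokens):
                raise ValueError("edge index out of bounds")
        if not (0 <= self.root < self.n_tokens):
            raise ValueError("root index out of bounds")
        self._graph = nx.Graph()
        self._graph.add_nodes_from(range(self.n_tokens))
        self._labels: dict[tuple[int, int], str] = {}
        for h, d, label in self.edges:
            self._graph.add_edge(h, d)
            self._labels[(h, d)] = label
            self._labels[(d, h)] = label

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    def edge_label(self, u: int, v: int) -> str:
        return self._labels[(u, v)]

    def is_connected(self) -> bool:
        return self.n_tokens == 0 or nx.is_connected(self._graph)


def shortest_dependency_path(parse: DependencyParse, a: int, b: int) -> list[int]:
    """Undirected shortest path between token indices, as a token-index list.

    Length (edge count) is ``len(path) - 1``.  Among equally short paths the
    lexicographically smallest token-index sequence is returned, making the
    choice deterministic.
    """
    if not (0 <= a < parse.n_tokens and 0 <= b < parse.n_tokens):
        raise ValueError("token index out of bounds")
    try:
        paths = nx.all_shortest_paths(parse.graph, a, b)
        return min(list(paths))
    except nx.NetworkXNoPath as exc:
        raise ValueError(f"malformed parse: tokens {a} and {b} disconnected") from exc


def bin_path_length(length: int) -> str:
    """Nominal distance bin: near (<=3), moderate (4-6), far (>=7)."""
    if length < 0:
        raise ValueError("path length must be nonnegative")
    if length <= 3:
        return "near"
    if length <= 6:
        return "moderate"
    return "far"


def ontology_keywords(*ontologies: Ontology) -> frozenset[str]:
    """Single-word keyword inventory of the ontologies' textual patterns.

    Multiword keywords contribute their component words so token-level
    features can still anchor on them.
    """
    words: set[str] = set()
    for ont in ontologies:
        for kw in ont.keywords:
            words.update(kw.split())
    return frozenset(words)


def keyword_token_indices(sentence: Sentence, keywords: frozenset[str]) -> list[int]:
    return [
        i for i, t in enumerate(sentence.tokens)
        if not t.is_gene and t.normalized in keywords
    ]


def gene_token_indices(sentence: Sentence) -> list[int]:
    return [i for i, t in enumerate(sentence.tokens) if t.is_gene]


def extract_keyword_tag(sentence: Sentence, keywords: frozenset[str]) -> set[str]:
    """One ``kw|<head>|<tag>`` feature per ontology-keyword occurrence (dedup)."""
    return {
        f"kw|{sentence.tokens[i].normalized}|{sentence.tokens[i].pos}"
        for i in keyword_token_indices(sentence, keywords)
    }


def _pair_paths(
    parse: DependencyParse, sentence: Sentence, keywords: frozenset[str]
) -> Iterable[tuple[int, int, list[int]]]:
    for g in gene_token_indices(sentence):
        for k in keyword_token_indices(sentence, keywords):
            yield g, k, shortest_dependency_path(parse, g, k)


def extract_word_relation_word(
    parse: DependencyParse,
    sentence: Sentence,
    keywords: frozenset[str],
    type_map: Optional[dict[str, str]] = None,
) -> set[str]:
    """``wrw|<w1>|<reltype>|<w2>`` per consecutive token pair on gene-keyword paths.

    With ``type_map`` given, specific dependency types generalize to their
    parent type (post-processing); unmapped types pass through unchanged.
    """
    feats: set[str] = set()
    for _, _, path in _pair_paths(parse, sentence, keywords):
        for u, v in zip(path, path[1:]):
            rel = parse.edge_label(u, v)
            if type_map is not None:
                rel = type_map.get(rel, rel)
            w1 = sentence.tokens[u].normalized
            w2 = sentence.tokens[v].normalized
            feats.add(f"wrw|{w1}|{rel}|{w2}")
    return feats


def extract_gene_keyword_distance(
    parse: DependencyParse,
    sentence: Sentence,
    keywords: frozenset[str],
    binned: bool = True,
) -> set[str]:
    """``gkd|genename|<keyword>|<near/moderate/far or raw length>`` per pair."""
    feats: set[str] = set()
    for _, k, path in _pair_paths(parse, sentence, keywords):
        length = len(path) - 1
        value = bin_path_length(length) if binned else f"len{length}"
        feats.add(f"gkd|genename|{sentence.tokens[k].normalized}|{value}")
    return feats


def _all_rules_features(
    sentence: Sentence, rate_ontology: Ontology, negative_ontology: Ontology
) -> set[str]:
    feats: set[str] = set()
    tokens = sentence.normalized_tokens
    for ont in (rate_ontology, negative_ontology):
        for pat in ont.patterns:
            if pat.fires(tokens):
                key = "+".join(sorted(pat.keywords)).replace(" ", "_")
                feats.add(f"rule|{pat.polarity}|{pat.node_id}|{key}")
    return feats


def _baseline_ace_features(
    parse: Optional[DependencyParse],
    sentence: Sentence,
    keywords: frozenset[str],
) -> set[str]:
    """ACE-style approximation: inter-mention words + parse-path label strings."""
    feats: set[str] = set()
    genes = gene_token_indices(sentence)
    kws = keyword_token_indices(sentence, keywords)
    anchors = sorted(set(genes) | set(kws))
    # bag of words strictly between consecutive anchor mentions
    for a, b in zip(anchors, anchors[1:]):
        for i in range(a + 1, b):
            tok = sentence.tokens[i]
            if tok.surface[0].isalnum():
                feats.add(f"ace|bw|{tok.normalized}")
    if parse is not None:
        for g in genes:
            for k in kws:
                path = shortest_dependency_path(parse, g, k)
                labels = "-".join(
                    parse.edge_label(u, v) for u, v in zip(path, path[1:])
                )
                feats.add(f"ace|path|{labels or 'self'}")
                feats.add(f"ace|trig|{sentence.tokens[k].normalized}")
    return feats


@dataclass(frozen=True)
class FeatureVector:
    """Binary string-keyed feature set for one sentence, tagged with its mode."""

    sentence_id: str
    mode: str
    features: frozenset[str]

    def __len__(self) -> int:
        return len(self.features)


def featurize(
    sentence: Sentence,
    parse: Optional[DependencyParse],
    mode: str,
    rate_ontology: Ontology,
    negative_ontology: Ontology,
    type_map: Optional[dict[str, str]] = None,
) -> FeatureVector:
    """Build the feature vector for one sentence under the given mode."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    keywords = ontology_keywords(rate_ontology, negative_ontology)
    if mode == "all_rules":
        feats = _all_rules_features(sentence, rate_ontology, negative_ontology)
    elif mode == "baseline_ace":
        feats = _baseline_ace_features(parse, sentence, keywords)
    else:
        if parse is None:
            raise ValueError(f"mode {mode!r} requires a dependency parse")
        post = mode == "combined"
        if post and type_map is None:
            from ratechange_miner import resources
            type_map = resources.dependency_type_hierarchy()
        feats = extract_keyword_tag(sentence, keywords)
        feats |= extract_word_relation_word(
            parse, sentence, keywords, type_map=type_map if post else None
        )
        feats |= extract_gene_keyword_distance(parse, sentence, keywords, binned=post)
    sid = f"{sentence.pmid}:{sentence.index}"
    return FeatureVector(sentence_id=sid, mode=mode, features=frozenset(feats))
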