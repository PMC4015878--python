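"""Synthetic labeled corpus generator plus the packaged example fixtures.

The generator emits sentences with the statistical and textual structure the
pipeline assumes, so every stage is testable without PubMed downloads.  Each
generated sentence contains at least two dictionary gene mentions, one
"regulate"-lexicon word and one rate-change-lexicon word (so all sentences
satisfy the corpus preconditions).  Positive sentences embed the keywords of
a rate-change-ontology pattern and no negative-ontology keywords; negative
sentences embed a negative-ontology pattern drawn from a configurable mix of
event types, optionally alongside positive-looking keywords to mimic the
false-positive phenomenon the negative ontology exists to veto.

Direct-evidence positives place gene and ontology keyword within toy-parse
distance <= 3; indirect ones push the keyword farther down a prepositional
chain, and genetic-engineering (Subclass II) sentences additionally carry
marker tokens ("multicopy plasmid" / "construct").  Sentences are built from
slot templates, emulating trigger co-occurrence rather than fluent English:
the pipeline consumes tokens, not grammar.  A toy dependency parse is built
alongside each sentence so feature extraction needs no parser model.

Default proportions mirror the annotated-corpus class structure: 1309
sentences of which 357 are positive (27.3%), 211 of the positives direct
evidence (59.1%); the negative mix leans toward cell-cycle and
DNA-replication events, the most frequent confounders.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from ratechange_miner import resources
from ratechange_miner.feature_extraction import DependencyParse
from ratechange_miner.lexicon_ontology import Ontology, match_patterns
from ratechange_miner.preprocess import (
    NormalizationDictionary,
    GeneDictionary,
    Sentence,
    normalize,
    recognize_genes,
    tokenize_and_tag,
)

__all__ = ["GeneratorConfig", "LabeledSentence", "generate", "fixtures"]

POSITIVE = "positive"
NEGATIVE = "negative"

DEFAULT_NEGATIVE_MIX = {
    "cell_cycle": 0.35,
    "dna_replication": 0.25,
    "translation": 0.20,
    "other_process": 0.20,
}

#: negative-mix key -> negative-ontology node id
_MIX_NODE = {
    "cell_cycle": "cell_cycle_regulation",
    "dna_replication": "dna_replication_repair",
    "translation": "translation",
    "other_process": "other_process",
}

_FILLERS = ("level", "amount", "presence", "response", "condition", "stage")
_SUBCLASS_II_MARKERS = (("multicopy", "plasmid"), ("engineered", "construct"))

PARSE_TEMPLATES = ("direct", "indirect_chain")


@dataclass(frozen=True)
class GeneratorConfig:
    n_sentences: int = 1309
    positive_fraction: float = 357 / 1309
    direct_fraction: float = 211 / 357  # within positives
    negative_mix: dict = field(default_factory=lambda: dict(DEFAULT_NEGATIVE_MIX))
    confusable_fraction: float = 0.5  # negatives that also carry positive keywords
    label_noise: float = 0.0
    parse_templates: tuple[str, ...] = PARSE_TEMPLATES
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("positive_fraction", self.positive_fraction),
                        ("direct_fraction", self.direct_fraction),
                        ("label_noise", self.label_noise),
                        ("confusable_fraction", self.confusable_fraction)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.negative_mix.values()) - 1.0) > 1e-9:
            raise ValueError("negative_mix must sum to 1")
        unknown = set(self.negative_mix) - set(_MIX_NODE)
        if unknown:
            raise ValueError(f"unknown negative_mix keys: {sorted(unknown)}")


@dataclass
class LabeledSentence:
    sentence: Sentence
    label: str  # gold label, after any noise flip
    evidence_subtype: str  # direct | indirect_I | indirect_II | n/a
    planted_nodes: frozenset[str]
    parse: Optional[DependencyParse] = None


def _single_word_heads(lexicon, exclude: frozenset[str] = frozenset()) -> list[str]:
    """Single-word lexicon heads usable as template slot fillers.

    Ontology pattern keywords are excluded from the trigger slots so that
    pattern fires come only from deliberately planted keywords; otherwise
    the confusable-negative fraction would not mean what it says.
    """
    return sorted(h for h in lexicon.heads if " " not in h and h not in exclude)


def _plantable_patterns(ontology: Ontology) -> list:
    """Patterns whose keywords are all single words (tokens plant cleanly)."""
    return [p for p in ontology.patterns
            if all(" " not in kw or len(kw.split()) == 2 for kw in p.keywords)]


def _pattern_tokens(pattern) -> list[str]:
    toks: list[str] = []
    for kw in sorted(pattern.keywords):
        toks.extend(kw.split())
    return toks


def _build_sentence(
    pmid: str,
    words: Sequence[str],
    gene_dict: GeneDictionary,
    norm: NormalizationDictionary,
) -> Sentence:
    raw = " ".join(words) + "."
    sent = Sentence(pmid=pmid, index=0, raw=raw)
    sent = tokenize_and_tag(sent)
    sent = recognize_genes(sent, gene_dict)
    return normalize(sent, norm)


def _direct_parse(n_core: int, n_total: int) -> DependencyParse:
    """Root verb at 2; keyword chain hangs off the object gene at 4.

    Token layout: [G1, rate, reg, of, G2, kw..., (extras...), '.'].
    Gene-keyword distance for G2 is 1..len(kw): "near".
    """
    edges = [(2, 0, "nsubj"), (2, 1, "advmod"), (2, 3, "prep"), (3, 4, "pobj")]
    for i in range(5, n_core):
        edges.append((i - 1, i, "nn"))
    for i in range(n_core, n_total - 1):
        edges.append((i - 1, i, "dep"))
    edges.append((2, n_total - 1, "punct"))
    return DependencyParse(n_tokens=n_total, edges=tuple(edges), root=2)


def _indirect_parse(n_fillers: int, n_kw: int, n_total: int) -> DependencyParse:
    """Keyword at the end of a prepositional chain: gene-keyword distance >= 4.

    Token layout: [G1, rate, reg, of, G2, f1..fk, kw..., (extras...), '.'].
    """
    edges = [(2, 0, "nsubj"), (2, 1, "advmod"), (2, 3, "prep"), (3, 4, "pobj")]
    pos = 5
    prev = 4
    for j in range(n_fillers):
        edges.append((prev, pos, "prep" if j % 2 == 0 else "pobj"))
        prev = pos
        pos += 1
    for _ in range(n_kw):
        edges.append((prev, pos, "nn"))
        prev = pos
        pos += 1
    while pos < n_total - 1:
        edges.append((prev, pos, "dep"))
        prev = pos
        pos += 1
    edges.append((2, n_total - 1, "punct"))
    return DependencyParse(n_tokens=n_total, edges=tuple(edges), root=2)


def generate(config: GeneratorConfig) -> list[LabeledSentence]:
    """Generate a labeled corpus; deterministic under ``config.seed``."""
    rng = random.Random(config.seed)
    rate_ont = resources.rate_change_ontology()
    neg_ont = resources.negative_ontology()
    gene_dict = resources.gene_dictionary()
    norm = resources.normalization_dictionary()
    from ratechange_miner.feature_extraction import ontology_keywords

    kw_exclude = ontology_keywords(rate_ont, neg_ont)
    reg_words = _single_word_heads(resources.regulate_lexicon(), kw_exclude)
    rate_words = _single_word_heads(resources.rate_change_lexicon(), kw_exclude)
    gene_ids = sorted(gene_dict.entries)
    pos_patterns = _plantable_patterns(rate_ont)
    neg_patterns_by_node: dict[str, list] = {}
    for p in _plantable_patterns(neg_ont):
        neg_patterns_by_node.setdefault(p.node_id, []).append(p)
    mix_keys = sorted(config.negative_mix)
    mix_weights = [config.negative_mix[k] for k in mix_keys]
    if all(w == 0.0 for w in mix_weights):
        raise ValueError("impossible negative mix: all weights zero")

    out: list[LabeledSentence] = []
    for i in range(config.n_sentences):
        pmid = f"SYN{i:06d}"
        g1, g2 = rng.sample(gene_ids, 2)
        rate_w = rng.choice(rate_words)
        reg_w = rng.choice(reg_words)
        core = [g1, rate_w, reg_w, "of", g2]

        if rng.random() < config.positive_fraction:
            gold = POSITIVE
            pattern = rng.choice(pos_patterns)
            kw_tokens = _pattern_tokens(pattern)
            planted = frozenset({pattern.node_id})
            if rng.random() < config.direct_fraction:
                subtype = "direct"
                words = core + kw_tokens
                n_total = len(words) + 1
                parse = _direct_parse(len(words), n_total)
            else:
                subtype = "indirect_I" if rng.random() < 0.5 else "indirect_II"
                fillers = [rng.choice(_FILLERS) for _ in range(3)]
                words = core + fillers + kw_tokens
                if subtype == "indirect_II":
                    words = words + ["on"] + list(rng.choice(_SUBCLASS_II_MARKERS))
                n_total = len(words) + 1
                parse = _indirect_parse(3, len(kw_tokens), n_total)
        else:
            gold = NEGATIVE
            subtype = "n/a"
            key = rng.choices(mix_keys, weights=mix_weights, k=1)[0]
            node_id = _MIX_NODE[key]
            pattern = rng.choice(neg_patterns_by_node[node_id])
            kw_tokens = _pattern_tokens(pattern)
            planted = frozenset({pattern.node_id})
            words = list(core)
            if rng.random() < config.confusable_fraction:
                # positive-looking keywords alongside the negative pattern:
                # the false-positive phenomenon the veto rule handles
                pos_pat = rng.choice(pos_patterns)
                words += _pattern_tokens(pos_pat)
                planted |= {pos_pat.node_id}
            words += kw_tokens
            n_total = len(words) + 1
            parse = _direct_parse(len(words), n_total)

        sent = _build_sentence(pmid, words, gene_dict, norm)
        assert len(sent.tokens) == parse.n_tokens, "template/parse misalignment"

        label = gold
        if config.label_noise > 0.0 and rng.random() < config.label_noise:
            label = NEGATIVE if gold == POSITIVE else POSITIVE
        out.append(LabeledSentence(
            sentence=sent,
            label=label,
            evidence_subtype=subtype,
            planted_nodes=planted,
            parse=parse,
        ))
    return out


def fixtures() -> list[LabeledSentence]:
    """The packaged example sentences (PMID-attributed), fully preprocessed.

    Covers the worked positive/negative event instances, the rate-change
    pattern examples, the negative-pattern examples, and the two indirect
    evidence examples (incomplete-information and genetic-engineering
    subclasses).  No toy parse is attached; these exercise the lexical and
    rule stages.
    """
    gene_dict = resources.gene_dictionary()
    norm = resources.normalization_dictionary()
    rate_ont = resources.rate_change_ontology()
    path = resources.data_path("fixture_sentences.tsv")
    lines = path.read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    out: list[LabeledSentence] = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        row = dict(zip(header, ln.split("\t")))
        sent = Sentence(pmid=row["pmid"], index=0, raw=row["text"])
        sent = tokenize_and_tag(sent)
        sent = recognize_genes(sent, gene_dict)
        sent = normalize(sent, norm)
        out.append(LabeledSentence(
            sentence=sent,
            label=row["label"],
            evidence_subtype=row["evidence_subtype"],
            planted_nodes=frozenset(
                match_patterns(sent.normalized_tokens, rate_ont)
            ),
            parse=None,
        ))
    return out
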