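"""Lexicon cosine-similarity sentence filter.

A candidate sentence for the corpus must satisfy all three conditions:
(i) at least ``min_noun_genes`` occurrences of gene/protein names tagged as
noun; (ii) cosine similarity to the "regulate" trigger list exceeding
``theta_regulate``; (iii) cosine similarity to the rate-change (temporal)
trigger list exceeding ``theta_temporal``.  "Exceeds" is strict.

The trigger list is represented as the uniform unit vector y over its n
entries and the sentence as the binary indicator vector x over the same
dimensions (1 where the entry occurs among the sentence's normalized
tokens), so cos(x, y) = x.y / (||x|| ||y||) = sqrt(m/n) for m matched
entries.  Binary indicators make the score invariant to within-sentence
keyword repetition, removing long-sentence bias that raw counts would add.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ratechange_miner.lexicon_ontology import TriggerLexicon
from ratechange_miner.preprocess import RawAbstract, Sentence

__all__ = [
    "FilterConfig", "SentenceVector", "FilterResult",
    "sentence_vector", "cosine_similarity", "passes_filters", "filter_corpus",
]


@dataclass(frozen=True)
class FilterConfig:
    theta_regulate: float = 0.1
    theta_temporal: float = 0.15
    min_noun_genes: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_regulate <= 1.0 and 0.0 <= self.theta_temporal <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.min_noun_genes < 0:
            raise ValueError("min_noun_genes must be >= 0")


@dataclass
class SentenceVector:
    lexicon_name: str
    indicator: np.ndarray  # binary, dimension = lexicon size_n

    @property
    def match_count_m(self) -> int:
        return int(self.indicator.sum())


def _entry_occurs(head: str, tokens: Sequence[str], token_set: set[str]) -> bool:
    if " " in head:
        parts = head.split()
        k = len(parts)
        return any(list(tokens[i:i + k]) == parts for i in range(len(tokens) - k + 1))
    return head in token_set


def sentence_vector(sentence: Sentence | Sequence[str], lexicon: TriggerLexicon) -> SentenceVector:
    """Binary indicator of lexicon entries occurring among normalized tokens."""
    if lexicon.size_n == 0:
        raise ValueError("empty lexicon")
    tokens = (
        sentence.normalized_tokens if isinstance(sentence, Sentence) else tuple(sentence)
    )
    token_set = set(tokens)
    indicator = np.array(
        [1 if _entry_occurs(h, tokens, token_set) else 0 for h in lexicon.heads],
        dtype=np.int8,
    )
    return SentenceVector(lexicon_name=lexicon.name, indicator=indicator)


def cosine_similarity(x: SentenceVector, lexicon: TriggerLexicon) -> float:
    """cos(x, y) with y the uniform unit vector over the lexicon entries."""
    if x.indicator.shape[0] != lexicon.size_n:
        raise ValueError(
            f"vector dimension {x.indicator.shape[0]} != lexicon size {lexicon.size_n}"
        )
    xv = x.indicator.astype(float)
    norm_x = float(np.linalg.norm(xv))
    if norm_x == 0.0:
        return 0.0
    y = np.full(lexicon.size_n, 1.0 / np.sqrt(lexicon.size_n))
    return float(xv @ y) / norm_x


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    regulate_score: float
    temporal_score: float
    noun_gene_count: int


def count_noun_genes(sentence: Sentence) -> int:
    """Gene-name occurrences whose mention starts with a noun-class (NN*) token."""
    count = 0
    for m in sentence.gene_mentions:
        if sentence.tokens[m.start].pos.startswith("NN"):
            count += 1
    return count


def passes_filters(
    sentence: Sentence,
    config: FilterConfig,
    regulate_lexicon: TriggerLexicon,
    temporal_lexicon: TriggerLexicon,
) -> FilterResult:
    """Apply the three corpus-inclusion conditions (strict score inequalities)."""
    reg = cosine_similarity(sentence_vector(sentence, regulate_lexicon), regulate_lexicon)
    temp = cosine_similarity(sentence_vector(sentence, temporal_lexicon), temporal_lexicon)
    noun_genes = count_noun_genes(sentence)
    passed = (
        noun_genes >= config.min_noun_genes
        and reg > config.theta_regulate
        and temp > config.theta_temporal
    )
    return FilterResult(passed, reg, temp, noun_genes)


def filter_corpus(
    abstracts: Iterable[RawAbstract],
    config: FilterConfig,
    regulate_lexicon: TriggerLexicon,
    temporal_lexicon: TriggerLexicon,
    gene_dict=None,
    norm=None,
) -> tuple[list[Sentence], list[dict]]:
    """Filter abstracts to candidate sentences, with a per-sentence score report.

    Returns the surviving sentences in stable (pmid, index) order and one
    report row per examined sentence with columns pmid, sent_index,
    reg_score, temp_score, noun_genes, pass.
    """
    from ratechange_miner import resources
    from ratechange_miner.preprocess import preprocess_abstract

    gene_dict = gene_dict or resources.gene_dictionary()
    norm = norm or resources.normalization_dictionary()

    survivors: list[Sentence] = []
    report: list[dict] = []
    for abstract in sorted(abstracts, key=lambda a: a.pmid):
        for sent in preprocess_abstract(abstract, gene_dict, norm):
            res = passes_filters(sent, config, regulate_lexicon, temporal_lexicon)
            report.append({
                "pmid": sent.pmid,
                "sent_index": sent.index,
                "reg_score": round(res.regulate_score, 6),
                "temp_score": round(res.temporal_score, 6),
                "noun_genes": res.noun_gene_count,
                "pass": res.passed,
            })
            if res.passed:
                survivors.append(sent)
    return survivors, report
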