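"""Deterministic ontology rule classification of rate-change events.

Two rules are provided.  The *regulation-based rule* calls a sentence
positive iff any sub-event of the rate-change ontology fires in it.  The
*combined rule* additionally consults the negative ontology as a veto:

* only rate-change sub-events fire          -> positive
* rate-change and negative sub-events fire  -> negative
* no rate-change sub-event fires            -> negative

The veto is unconditional: a single firing negative pattern outweighs any
number of firing positive patterns.  Both decisions are pure functions of
the sentence's normalized tokens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ratechange_miner.lexicon_ontology import Ontology, match_patterns
from ratechange_miner.preprocess import Sentence

__all__ = ["RuleDecision", "classify_regulation_rule", "classify_combined_rule"]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class RuleDecision:
    label: str  # "positive" | "negative"
    rule_name: str  # "regulation_based" | "combined"
    fired_positive_nodes: frozenset[str] = field(default_factory=frozenset)
    fired_negative_nodes: frozenset[str] = field(default_factory=frozenset)


def _tokens(sentence: Sentence | Sequence[str]) -> tuple[str, ...]:
    if isinstance(sentence, Sentence):
        return sentence.normalized_tokens
    return tuple(sentence)


def classify_regulation_rule(
    sentence: Sentence | Sequence[str],
    rate_change_ontology: Ontology,
) -> RuleDecision:
    """Positive iff the sentence contains any rate-change ontology sub-event."""
    tokens = _tokens(sentence)
    fired = frozenset(match_patterns(tokens, rate_change_ontology))
    return RuleDecision(
        label=POSITIVE if fired else NEGATIVE,
        rule_name="regulation_based",
        fired_positive_nodes=fired,
    )


def classify_combined_rule(
    sentence: Sentence | Sequence[str],
    rate_change_ontology: Ontology,
    negative_ontology: Ontology,
) -> RuleDecision:
    """Positive iff rate-change sub-events fire and no negative sub-event does."""
    tokens = _tokens(sentence)
    fired_pos = frozenset(match_patterns(tokens, rate_change_ontology))
    fired_neg = frozenset(match_patterns(tokens, negative_ontology))
    return RuleDecision(
        label=POSITIVE if (fired_pos and not fired_neg) else NEGATIVE,
        rule_name="combined",
        fired_positive_nodes=fired_pos,
        fired_negative_nodes=fired_neg,
    )
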