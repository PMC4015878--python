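"""Sentence segmentation, tokenization, POS tagging, gene recognition, normalization.

The pipeline order is: segment -> tokenize_and_tag -> recognize_genes ->
normalize.  Normalization runs *after* tagging so tags reflect original
surface forms (the "genename" placeholder would mislead any tagger).

Word normalization follows two rules: (i) every token covered by a gene
mention becomes the placeholder "genename", eliminating differences between
diverse genes; (ii) every keyword listed in the normalization dictionary is
replaced by its head form (the first column of its dictionary row); all
remaining tokens are lower-cased.

The segmenter and tagger are pluggable backends behind small callables; the
shipped defaults are deterministic rule-based implementations so results are
stable across environments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class RawAbstract:
    pmid: str
    text: str

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be nonempty")
        if not self.text or not self.text.strip():
            raise ValueError("abstract text must be nonempty")


@dataclass(frozen=True)
class Token:
    surface: str
    pos: str = ""
    normalized: str = ""
    is_gene: bool = False


@dataclass(frozen=True)
class GeneMention:
    start: int  # token index, inclusive
    end: int    # token index, exclusive
    gene_id: str


@dataclass
class Sentence:
    """One abstract sentence with provenance and per-token annotations."""

    pmid: str
    index: int
    raw: str
    tokens: tuple[Token, ...] = ()
    gene_mentions: tuple[GeneMention, ...] = ()

    @property
    def normalized_tokens(self) -> tuple[str, ...]:
        return tuple(t.normalized for t in self.tokens)

    @property
    def surfaces(self) -> tuple[str, ...]:
        return tuple(t.surface for t in self.tokens)


# ---------------------------------------------------------------------------
# Dictionaries


class GeneDictionary:
    """Canonical gene id -> synonyms, with case-insensitive token lookup."""

    def __init__(self, entries: dict[str, set[str]]):
        self.entries = {k: {s.lower() for s in v} for k, v in entries.items()}
        self._index: dict[str, str] = {}
        for gene_id, syns in sorted(self.entries.items()):
            for syn in syns:
                # first (alphabetical) id wins for shared synonyms
                self._index.setdefault(syn, gene_id)
        self.max_words = max(
            (len(s.split()) for s in self._index), default=1
        )

    def lookup(self, phrase: str) -> Optional[str]:
        return self._index.get(phrase.lower())

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneDictionary":
        entries: dict[str, set[str]] = {}
        for ln in Path(path).read_text(encoding="utf-8").splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = [p.strip() for p in ln.split("\t") if p.strip()]
            gene_id, syns = parts[0], parts[1:] or [parts[0]]
            entries.setdefault(gene_id, set()).update(syns)
            entries[gene_id].add(gene_id)
        return cls(entries)


class NormalizationDictionary:
    """Keyword clusters: head word first column, variants after (TAB-separated)."""

    def __init__(self, head_to_variants: dict[str, set[str]]):
        self.head_to_variants = head_to_variants
        self._variant_to_head: dict[str, str] = {}
        for head, variants in head_to_variants.items():
            self._variant_to_head[head.lower()] = head.lower()
            for v in variants:
                self._variant_to_head[v.lower()] = head.lower()

    def head(self, word: str) -> str:
        """Normalized head form of a (non-gene) word; lower-cased surface if unlisted."""
        w = word.lower()
        return self._variant_to_head.get(w, w)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._variant_to_head

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NormalizationDictionary":
        mapping: dict[str, set[str]] = {}
        for ln in Path(path).read_text(encoding="utf-8").splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = [p.strip() for p in ln.split("\t") if p.strip()]
            mapping.setdefault(parts[0], set()).update(parts[1:])
        return cls(mapping)


# ---------------------------------------------------------------------------
# Sentence segmentation

#: Tokens before a period that never end a sentence (biomedical abbreviations).
ABBREVIATIONS = {"sp.", "spp.", "e.g.", "i.e.", "cf.", "vs.", "ca.", "al.", "et."}

# a boundary needs an upper-case/digit follower, so "S. cerevisiae" never splits
_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9(\"])")


def segment_sentences(abstract: RawAbstract) -> list[Sentence]:
    """Split an abstract into sentences (raw text only), abbreviation-safe.

    Concatenating the returned raw strings reconstructs the abstract modulo
    whitespace; sentence indices run consecutively from 0.
    """
    text = abstract.text.strip()
    pieces: list[str] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        prev_word = text[:m.start()].rsplit(None, 1)[-1]
        if prev_word.lower() in ABBREVIATIONS:
            continue
        pieces.append(text[start:m.start()])
        start = m.end()
    pieces.append(text[start:])
    return [
        Sentence(pmid=abstract.pmid, index=i, raw=piece.strip())
        for i, piece in enumerate(pieces)
        if piece.strip()
    ]


# ---------------------------------------------------------------------------
# Tokenization and POS tagging

_TOKEN = re.compile(r"[A-Za-z0-9]+|[^\sA-Za-z0-9]")


def word_tokenize(text: str) -> list[str]:
    """Split into alphanumeric tokens and single punctuation symbols.

    Hyphenated compounds ("chromatin-remodeling") split into their parts so
    dictionary keywords inside them remain matchable.
    """
    return _TOKEN.findall(text)


_CLOSED_CLASS = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "these": "DT",
    "those": "DT", "that": "IN", "which": "WDT", "who": "WP",
    "of": "IN", "in": "IN", "on": "IN", "at": "IN", "by": "IN",
    "with": "IN", "from": "IN", "to": "TO", "via": "IN", "for": "IN",
    "between": "IN", "within": "IN", "during": "IN", "after": "IN",
    "before": "IN", "among": "IN", "into": "IN", "over": "IN",
    "under": "IN", "as": "IN", "although": "IN", "when": "WRB",
    "where": "WRB", "and": "CC", "or": "CC", "but": "CC",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD",
    "be": "VB", "been": "VBN", "being": "VBG", "am": "VBP",
    "has": "VBZ", "have": "VBP", "had": "VBD",
    "can": "MD", "may": "MD", "must": "MD", "will": "MD",
    "would": "MD", "could": "MD", "should": "MD",
    "not": "RB", "also": "RB", "here": "RB", "thus": "RB",
    "however": "RB", "instead": "RB", "there": "EX",
    "it": "PRP", "they": "PRP", "we": "PRP", "its": "PRP$", "their": "PRP$",
    "no": "DT", "all": "DT", "each": "DT", "some": "DT", "both": "DT",
    "due": "JJ", "such": "JJ", "more": "JJR", "most": "JJS",
}

_COMMON_VERBS_S = {
    "regulates", "controls", "induces", "represses", "activates", "inhibits",
    "suppresses", "binds", "promotes", "mediates", "modulates", "affects",
    "enhances", "reduces", "increases", "decreases", "results", "indicates",
    "shows", "suggests", "causes", "undergoes", "constructs", "exhibits",
    "slows", "delays", "prevents", "blocks", "degrades", "functions",
}


def rule_based_tagger(tokens: Sequence[str]) -> list[str]:
    """Deterministic Penn-Treebank tagger: closed-class lexicon + suffix rules.

    Symbols with digits or in upper case (gene symbols, identifiers) receive
    noun-class tags.  The tagger is intentionally small; it is one pluggable
    backend satisfying the tagging contract, and the pipeline only relies on
    the noun-class (``NN`` prefix) distinction for its filter condition.
    """
    tags: list[str] = []
    for tok in tokens:
        low = tok.lower()
        if not tok[0].isalnum():
            tags.append(tok if tok in {",", ".", ":", ";"} else "SYM")
        elif tok.isdigit():
            tags.append("CD")
        elif low in _CLOSED_CLASS:
            tags.append(_CLOSED_CLASS[low])
        elif any(c.isdigit() for c in tok) or (tok.isupper() and len(tok) > 1):
            tags.append("NN")
        elif low in _COMMON_VERBS_S:
            tags.append("VBZ")
        elif low.endswith("ly"):
            tags.append("RB")
        elif low.endswith("ing"):
            tags.append("VBG")
        elif low.endswith("ed"):
            tags.append("VBN")
        elif low.endswith("s") and not low.endswith("ss") and len(low) > 3:
            tags.append("NNS")
        elif tok[0].isupper():
            tags.append("NNP")
        else:
            tags.append("NN")
    return tags


Tagger = Callable[[Sequence[str]], list[str]]


def tokenize_and_tag(sentence: Sentence, tagger: Optional[Tagger] = None) -> Sentence:
    """Tokenize the raw sentence and attach a Penn-Treebank tag per token."""
    if not sentence.raw or not sentence.raw.strip():
        raise ValueError("cannot tokenize an empty sentence")
    tagger = tagger or rule_based_tagger
    words = word_tokenize(sentence.raw)
    tags = tagger(words)
    tokens = tuple(Token(surface=w, pos=t) for w, t in zip(words, tags))
    return replace(sentence, tokens=tokens)


# ---------------------------------------------------------------------------
# Gene recognition and normalization


def recognize_genes(sentence: Sentence, gene_dict: GeneDictionary) -> Sentence:
    """Longest non-overlapping case-insensitive dictionary matches.

    Scans left to right trying the longest token n-gram first; every token
    covered by a match is flagged ``is_gene``.
    """
    if not sentence.tokens:
        raise ValueError("recognize_genes requires tokens")
    surfaces = sentence.surfaces
    mentions: list[GeneMention] = []
    i = 0
    n = len(surfaces)
    while i < n:
        matched = False
        for k in range(min(gene_dict.max_words, n - i), 0, -1):
            phrase = " ".join(surfaces[i:i + k])
            gene_id = gene_dict.lookup(phrase)
            if gene_id is not None:
                mentions.append(GeneMention(start=i, end=i + k, gene_id=gene_id))
                i += k
                matched = True
                break
        if not matched:
            i += 1
    covered = {j for m in mentions for j in range(m.start, m.end)}
    tokens = tuple(
        replace(t, is_gene=(j in covered)) for j, t in enumerate(sentence.tokens)
    )
    return replace(sentence, tokens=tokens, gene_mentions=tuple(mentions))


GENE_PLACEHOLDER = "genename"


def normalize(sentence: Sentence, norm: NormalizationDictionary) -> Sentence:
    """Apply word normalization: gene placeholder + dictionary head forms.

    Token mapping is 1:1 (a multi-token gene name yields one "genename" per
    covered token), and the operation is idempotent.
    """
    tokens = tuple(
        replace(t, normalized=GENE_PLACEHOLDER if t.is_gene else norm.head(t.surface if not t.normalized else t.normalized))
        for t in sentence.tokens
    )
    return replace(sentence, tokens=tokens)


def preprocess_abstract(
    abstract: RawAbstract,
    gene_dict: GeneDictionary,
    norm: NormalizationDictionary,
    tagger: Optional[Tagger] = None,
) -> list[Sentence]:
    """Run the full per-abstract pipeline: segment, tag, recognize, normalize."""
    out = []
    for sent in segment_sentences(abstract):
        sent = tokenize_and_tag(sent, tagger=tagger)
        sent = recognize_genes(sent, gene_dict)
        sent = normalize(sent, norm)
        out.append(sent)
    return out
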