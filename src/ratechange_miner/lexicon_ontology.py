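"""Trigger lexicons, rate-direction classes, and the two event ontologies.

A *trigger lexicon* is a named list of keywords whose presence in a sentence
signals a regulation mention or a rate change.  The *rate-change ontology*
catalogs sub-processes of transcriptional regulation (promoter activity,
transcription behavior, chromatin remodeling, histone modification, ...)
whose mention is positive evidence for a rate-change event; the *negative
ontology* catalogs look-alike processes (cell cycle, DNA replication,
translation, ...) whose mention vetoes the positive call.  Each ontology node
owns textual patterns: sets of normalized keywords that must co-occur in a
sentence for the node to fire.

Ontology relations use three types — ``is_a`` (subtype), ``part_of``
(part-whole) and ``result_from`` (causal/explanatory) — with a composition
table for transitive inference:

    r . is_a -> r               (for every relation r)
    is_a . r -> r
    part_of . result_from -> result_from
    result_from . part_of -> result_from
    part_of . part_of -> part_of

Compositions outside this table (e.g. ``result_from . result_from``) infer
nothing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

RELATION_TYPES = ("is_a", "part_of", "result_from")

#: Composition table r1 . r2 -> r3 (A r1 B, B r2 C  =>  A r3 C).
COMPOSITION: dict[tuple[str, str], str] = {("is_a", "is_a"): "is_a"}
for _r in RELATION_TYPES:
    COMPOSITION[(_r, "is_a")] = _r
    COMPOSITION[("is_a", _r)] = _r
COMPOSITION[("part_of", "result_from")] = "result_from"
COMPOSITION[("result_from", "part_of")] = "result_from"
COMPOSITION[("part_of", "part_of")] = "part_of"


@dataclass(frozen=True)
class LexiconEntry:
    """A lexicon entry: surface form plus its normalized head form."""

    surface: str
    head: str


@dataclass
class TriggerLexicon:
    """A named trigger-word list; the basis of filter vectors.

    Entries are stored deduplicated by normalized head form, so ``size_n``
    is the dimension of the binary sentence vectors built against this
    lexicon.  Multiword entries ("shut down", "rate change") are kept as
    space-separated units and matched as contiguous token n-grams.
    """

    name: str
    entries: tuple[LexiconEntry, ...]

    @property
    def heads(self) -> tuple[str, ...]:
        return tuple(e.head for e in self.entries)

    @property
    def size_n(self) -> int:
        return len(self.entries)

    def __contains__(self, head: str) -> bool:
        return head in set(self.heads)


def load_lexicon(
    path: str | Path,
    name: Optional[str] = None,
    normalizer: Optional[Callable[[str], str]] = None,
) -> TriggerLexicon:
    """Load a lexicon file: one entry per line, optional TAB-separated head.

    Every entry is mapped to exactly one normalized head form (the explicit
    TAB column if present, else ``normalizer`` applied to the surface, else
    the lower-cased surface).  Duplicate heads are collapsed with a warning.
    Multiword entries are normalized word by word.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty lexicon: {path}")

    def norm(word: str) -> str:
        word = word.lower()
        if normalizer is None:
            return word
        return " ".join(normalizer(w) for w in word.split())

    seen: dict[str, LexiconEntry] = {}
    for ln in lines:
        if "\t" in ln:
            surface, head = ln.split("\t", 1)
            surface, head = surface.strip(), norm(head.strip())
        else:
            surface = ln
            head = norm(surface)
        if head in seen:
            logger.warning("duplicate lexicon head %r in %s collapsed", head, path)
            continue
        seen[head] = LexiconEntry(surface=surface, head=head)
    return TriggerLexicon(name=name or path.stem, entries=tuple(seen.values()))


@dataclass
class RateDirectionClasses:
    """The three disjoint rate-direction classes: Quicken, Delay, Change.

    A rate-change trigger word's class gives the qualitative direction of
    the event it signals (shorter / longer / altered time delay).
    """

    members: Mapping[str, frozenset[str]]  # class label -> normalized words

    LABELS = ("Quicken", "Delay", "Change")

    def __post_init__(self) -> None:
        labels = list(self.members)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                overlap = self.members[a] & self.members[b]
                if overlap:
                    raise ValueError(
                        f"rate-direction classes must be disjoint; "
                        f"{sorted(overlap)} in both {a} and {b}"
                    )

    def classify(self, word: str) -> Optional[str]:
        for label, words in self.members.items():
            if word in words:
                return label
        return None

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        normalizer: Optional[Callable[[str], str]] = None,
    ) -> "RateDirectionClasses":
        members: dict[str, set[str]] = {}
        for ln in Path(path).read_text(encoding="utf-8").splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            label, word = ln.split("\t", 1)
            word = word.strip().lower()
            if normalizer is not None:
                word = " ".join(normalizer(w) for w in word.split())
            members.setdefault(label.strip(), set()).add(word)
        return cls(members={k: frozenset(v) for k, v in members.items()})


def classify_rate_direction(
    word: str, classes: RateDirectionClasses
) -> Optional[str]:
    """Return the unique rate-direction class containing ``word``, or None.

    ``word`` must already be normalized (head form).
    """
    return classes.classify(word)


@dataclass(frozen=True)
class OntologyNode:
    id: str
    label: str
    polarity: str  # "rate_change" | "negative"
    count: Optional[int] = None  # corpus instance count, when known


@dataclass(frozen=True, order=True)
class OntologyRelation:
    subject: str
    relation: str
    object: str

    def __post_init__(self) -> None:
        if self.relation not in RELATION_TYPES:
            raise ValueError(f"unknown relation type: {self.relation!r}")


@dataclass(frozen=True)
class TextualPattern:
    """A set of normalized keywords that must all occur for a node to fire.

    Keywords containing a space are multiword units matched as contiguous
    token n-grams; all other keywords match order-free at sentence scope.
    """

    node_id: str
    keywords: frozenset[str]
    polarity: str

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError(f"pattern for {self.node_id} has no keywords")

    def fires(self, tokens: Sequence[str]) -> bool:
        token_set = set(tokens)
        for kw in self.keywords:
            if " " in kw:
                parts = kw.split()
                k = len(parts)
                if not any(
                    list(tokens[i:i + k]) == parts
                    for i in range(len(tokens) - k + 1)
                ):
                    return False
            elif kw not in token_set:
                return False
        return True


@dataclass
class Ontology:
    """Nodes, typed relations and polarized textual patterns."""

    name: str
    polarity: str
    nodes: dict[str, OntologyNode] = field(default_factory=dict)
    relations: set[OntologyRelation] = field(default_factory=set)
    patterns: tuple[TextualPattern, ...] = ()

    def __post_init__(self) -> None:
        for pat in self.patterns:
            if pat.node_id not in self.nodes:
                raise ValueError(f"pattern references unknown node {pat.node_id!r}")

    @property
    def keywords(self) -> frozenset[str]:
        """All pattern keywords (multiword units included as such)."""
        return frozenset(kw for p in self.patterns for kw in p.keywords)

    def closure(self) -> set[OntologyRelation]:
        return infer_relation_closure(self.relations)


def load_ontology(path: str | Path) -> Ontology:
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    nodes = {
        n["id"]: OntologyNode(
            id=n["id"], label=n["label"],
            polarity=n.get("polarity", raw.get("polarity", "rate_change")),
            count=n.get("count"),
        )
        for n in raw["nodes"]
    }
    if len(nodes) != len(raw["nodes"]):
        raise ValueError(f"duplicate node ids in {path}")
    relations = {
        OntologyRelation(r["subject"], r["relation"], r["object"])
        for r in raw.get("relations", [])
    }
    for rel in relations:
        if rel.subject == rel.object:
            raise ValueError(f"asserted self-relation {rel} in {path}")
    patterns = tuple(
        TextualPattern(
            node_id=p["node_id"],
            keywords=frozenset(p["keywords"]),
            polarity=nodes[p["node_id"]].polarity,
        )
        for p in raw.get("patterns", [])
    )
    return Ontology(
        name=raw.get("name", Path(path).stem),
        polarity=raw.get("polarity", "rate_change"),
        nodes=nodes,
        relations=relations,
        patterns=patterns,
    )


def save_ontology(ontology: Ontology, path: str | Path) -> None:
    raw = {
        "name": ontology.name,
        "polarity": ontology.polarity,
        "nodes": [
            {"id": n.id, "label": n.label, "polarity": n.polarity, "count": n.count}
            for n in ontology.nodes.values()
        ],
        "relations": [
            {"subject": r.subject, "relation": r.relation, "object": r.object}
            for r in sorted(ontology.relations)
        ],
        "patterns": [
            {"node_id": p.node_id, "keywords": sorted(p.keywords)}
            for p in ontology.patterns
        ],
    }
    Path(path).write_text(json.dumps(raw, indent=2) + "\n", encoding="utf-8")


def infer_relation_closure(
    relations: Iterable[OntologyRelation],
) -> set[OntologyRelation]:
    """Least fixed point of the relation set under the composition table.

    Repeatedly composes A-r1->B with B-r2->C into A-r3->C until nothing new
    can be added.  Compositions not in the table infer nothing.  A cycle may
    infer a self-relation (X is_a X); such edges are retained but logged.
    """
    closed: set[OntologyRelation] = set(relations)
    changed = True
    while changed:
        changed = False
        by_subject: dict[str, list[OntologyRelation]] = {}
        for rel in closed:
            by_subject.setdefault(rel.subject, []).append(rel)
        new: set[OntologyRelation] = set()
        for r1 in closed:
            for r2 in by_subject.get(r1.object, ()):
                r3 = COMPOSITION.get((r1.relation, r2.relation))
                if r3 is None:
                    continue
                inferred = OntologyRelation(r1.subject, r3, r2.object)
                if inferred not in closed:
                    if inferred.subject == inferred.object:
                        logger.warning("inferred self-relation %s retained", inferred)
                    new.add(inferred)
        if new:
            closed |= new
            changed = True
    return closed


def match_patterns(tokens: Sequence[str], ontology: Ontology) -> set[str]:
    """Ids of all ontology nodes with at least one firing textual pattern.

    ``tokens`` must already be normalized (gene placeholder, head forms).
    A pattern fires iff all its required keywords occur among the tokens
    (order-free at sentence scope; multiword keywords as contiguous n-grams).
    """
    return {p.node_id for p in ontology.patterns if p.fires(tokens)}
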