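"""Access to the packaged default lexicons, dictionaries and ontologies."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources as _ir
from pathlib import Path

from ratechange_miner.lexicon_ontology import (
    Ontology,
    RateDirectionClasses,
    TriggerLexicon,
    load_lexicon,
    load_ontology,
)
from ratechange_miner.preprocess import GeneDictionary, NormalizationDictionary


def data_path(filename: str) -> Path:
    return Path(str(_ir.files("ratechange_miner").joinpath("data", filename)))


@lru_cache(maxsize=None)
def normalization_dictionary() -> NormalizationDictionary:
    return NormalizationDictionary.from_tsv(data_path("normalization_dict.tsv"))


@lru_cache(maxsize=None)
def gene_dictionary() -> GeneDictionary:
    return GeneDictionary.from_tsv(data_path("gene_dictionary.tsv"))


@lru_cache(maxsize=None)
def regulate_lexicon() -> TriggerLexicon:
    return load_lexicon(
        data_path("regulate_lexicon.txt"),
        name="regulate",
        normalizer=normalization_dictionary().head,
    )


@lru_cache(maxsize=None)
def rate_change_lexicon() -> TriggerLexicon:
    return load_lexicon(
        data_path("rate_change_lexicon.txt"),
        name="rate_change",
        normalizer=normalization_dictionary().head,
    )


@lru_cache(maxsize=None)
def rate_direction_classes() -> RateDirectionClasses:
    return RateDirectionClasses.from_tsv(
        data_path("rate_direction_classes.tsv"),
        normalizer=normalization_dictionary().head,
    )


@lru_cache(maxsize=None)
def rate_change_ontology() -> Ontology:
    return load_ontology(data_path("rate_change_ontology.json"))


@lru_cache(maxsize=None)
def negative_ontology() -> Ontology:
    return load_ontology(data_path("negative_ontology.json"))


@lru_cache(maxsize=None)
def dependency_type_hierarchy() -> dict[str, str]:
    """Specific dependency type -> generic (second-level) type."""
    mapping: dict[str, str] = {}
    for ln in data_path("dependency_type_hierarchy.tsv").read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        specific, generic = ln.split("\t")
        mapping[specific] = generic
    return mapping
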