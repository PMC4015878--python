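"""File formats: corpus TSV, abstract TSV / MEDLINE flat files, features, config.

Everything is TSV (sentences contain commas), UTF-8, header row mandatory.
Readers validate and report malformed rows with line numbers; writers and
readers are mutual inverses on valid data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from ratechange_miner.evaluation import CVConfig
from ratechange_miner.feature_extraction import FeatureVector
from ratechange_miner.preprocess import RawAbstract
from ratechange_miner.sentence_filter import FilterConfig

__all__ = [
    "CorpusRecord", "PipelineConfig", "read_corpus", "write_corpus",
    "read_abstracts_tsv", "read_medline", "write_features_tsv",
    "read_features_tsv", "write_arff",
]

VALID_LABELS = {"positive", "negative"}
VALID_SUBTYPES = {"direct", "indirect_I", "indirect_II", "n/a"}


@dataclass(frozen=True)
class CorpusRecord:
    pmid: str
    sentence_index: int
    text: str
    label: Optional[str] = None
    evidence_subtype: Optional[str] = None


_CORPUS_COLUMNS = ("pmid", "sentence_index", "text", "label", "evidence_subtype")


def read_corpus(path: str | Path) -> list[CorpusRecord]:
    """Read an annotated corpus TSV; malformed rows are reported by line number."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty corpus file")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header[:3] != _CORPUS_COLUMNS[:3]:
        raise ValueError(
            f"{path}:1: expected header starting with {_CORPUS_COLUMNS[:3]}, got {header}"
        )
    records: list[CorpusRecord] = []
    seen_keys: set[tuple[str, int]] = set()
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 TSV fields, got {len(parts)}")
        row = dict(zip(header, parts))
        try:
            idx = int(row["sentence_index"])
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: sentence_index {row['sentence_index']!r} is not an integer"
            ) from None
        label = row.get("label") or None
        if label is not None and label not in VALID_LABELS:
            raise ValueError(f"{path}:{lineno}: unknown label {label!r}")
        subtype = row.get("evidence_subtype") or None
        if subtype is not None and subtype not in VALID_SUBTYPES:
            raise ValueError(f"{path}:{lineno}: unknown evidence subtype {subtype!r}")
        key = (row["pmid"], idx)
        if key in seen_keys:
            raise ValueError(f"{path}:{lineno}: duplicate (pmid, sentence_index) {key}")
        seen_keys.add(key)
        records.append(CorpusRecord(
            pmid=row["pmid"], sentence_index=idx, text=row["text"],
            label=label, evidence_subtype=subtype,
        ))
    return records


def write_corpus(records: Iterable[CorpusRecord], path: str | Path) -> None:
    rows = ["\t".join(_CORPUS_COLUMNS)]
    for r in records:
        rows.append("\t".join([
            r.pmid, str(r.sentence_index), r.text,
            r.label or "", r.evidence_subtype or "",
        ]))
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def read_abstracts_tsv(path: str | Path) -> list[RawAbstract]:
    """Abstracts as two-column TSV: pmid TAB text (header optional)."""
    out: list[RawAbstract] = []
    for lineno, ln in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not ln.strip():
            continue
        parts = ln.split("\t", 1)
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'pmid<TAB>text'")
        if lineno == 1 and parts[0].lower() == "pmid":
            continue
        out.append(RawAbstract(pmid=parts[0].strip(), text=parts[1].strip()))
    return out


def read_medline(path: str | Path) -> list[RawAbstract]:
    """MEDLINE flat-file records (PMID / AB fields) via Biopython."""
    from Bio import Medline

    out: list[RawAbstract] = []
    with open(path, encoding="utf-8") as handle:
        for record in Medline.parse(handle):
            pmid = record.get("PMID")
            text = record.get("AB")
            if pmid and text:
                out.append(RawAbstract(pmid=pmid, text=text))
    return out


def write_features_tsv(vectors: Sequence[FeatureVector], path: str | Path) -> None:
    """Sparse feature TSV: sentence id, mode, then sorted feature keys."""
    rows = ["sentence_id\tmode\tfeatures"]
    for fv in vectors:
        rows.append(f"{fv.sentence_id}\t{fv.mode}\t" + " ".join(sorted(fv.features)))
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def read_features_tsv(path: str | Path) -> list[FeatureVector]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    out: list[FeatureVector] = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        sid, mode, feats = (ln.split("\t") + [""])[:3]
        out.append(FeatureVector(
            sentence_id=sid, mode=mode,
            features=frozenset(feats.split()) if feats else frozenset(),
        ))
    return out


def write_arff(
    vectors: Sequence[FeatureVector],
    labels: Sequence[str],
    path: str | Path,
    relation: str = "ratechange",
) -> None:
    """Attribute-relation text format for interoperability with tree learners."""
    keys = sorted(set().union(*(fv.features for fv in vectors))) if vectors else []
    lines = [f"@relation {relation}", ""]
    for k in keys:
        safe = k.replace(" ", "_").replace("'", "")
        lines.append(f"@attribute '{safe}' {{0,1}}")
    lines.append("@attribute class {positive,negative}")
    lines.append("")
    lines.append("@data")
    for fv, lab in zip(vectors, labels):
        row = ",".join("1" if k in fv.features else "0" for k in keys)
        lines.append(f"{row},{lab}" if keys else lab)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (YAML-loadable)."""

    abstracts_path: Optional[str] = None  # TSV or MEDLINE; None -> synthetic corpus
    medline_format: bool = False
    regulate_lexicon_path: Optional[str] = None
    rate_change_lexicon_path: Optional[str] = None
    rate_change_ontology_path: Optional[str] = None
    negative_ontology_path: Optional[str] = None
    gene_dictionary_path: Optional[str] = None
    normalization_dict_path: Optional[str] = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    feature_mode: str = "combined"
    cv: CVConfig = field(default_factory=CVConfig)
    synthetic: Optional[dict] = None  # GeneratorConfig overrides
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        filt = FilterConfig(**raw.pop("filter", {}))
        cv = CVConfig(**raw.pop("cv", {}))
        cfg = cls(filter=filt, cv=cv, **raw)
        for attr in ("abstracts_path", "regulate_lexicon_path",
                     "rate_change_lexicon_path", "rate_change_ontology_path",
                     "negative_ontology_path", "gene_dictionary_path",
                     "normalization_dict_path"):
            p = getattr(cfg, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")
        return cfg


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
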