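"""End-to-end pipeline: preprocess -> filter -> rule classify -> featurize -> CV.

Stage boundaries are logged with in/out counts, mirroring the corpus funnel
(abstracts -> sentences -> candidates).  The run is reproducible under the
configured seeds; any stage failure aborts with the stage name.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

from ratechange_miner import resources
from ratechange_miner.corpus_io import PipelineConfig, write_json
from ratechange_miner.evaluation import (
    ConfusionMatrix,
    compute_metrics,
    run_cv,
)
from ratechange_miner.feature_extraction import featurize
from ratechange_miner.lexicon_ontology import load_lexicon, load_ontology
from ratechange_miner.preprocess import GeneDictionary, NormalizationDictionary
from ratechange_miner.rule_classifier import (
    classify_combined_rule,
    classify_regulation_rule,
)
from ratechange_miner.sentence_filter import passes_filters
from ratechange_miner.synthetic_corpus import GeneratorConfig, generate

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _metrics_block(cm: ConfusionMatrix) -> dict:
    m = compute_metrics(cm).rounded()
    return {
        "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
        "precision": m.precision, "recall": m.recall,
        "f1": m.f1, "accuracy": m.accuracy,
    }


def run_pipeline(config: PipelineConfig, out_dir: Optional[str | Path] = None) -> dict:
    """Execute all stages in order and return (and optionally write) the report."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))

    def load(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # abort with stage name per contract
            raise StageError(stage, exc) from exc

    norm = (NormalizationDictionary.from_tsv(config.normalization_dict_path)
            if config.normalization_dict_path else resources.normalization_dictionary())
    gene_dict = (GeneDictionary.from_tsv(config.gene_dictionary_path)
                 if config.gene_dictionary_path else resources.gene_dictionary())
    regulate_lex = (load_lexicon(config.regulate_lexicon_path, normalizer=norm.head)
                    if config.regulate_lexicon_path else resources.regulate_lexicon())
    temporal_lex = (load_lexicon(config.rate_change_lexicon_path, normalizer=norm.head)
                    if config.rate_change_lexicon_path else resources.rate_change_lexicon())
    rate_ont = (load_ontology(config.rate_change_ontology_path)
                if config.rate_change_ontology_path else resources.rate_change_ontology())
    neg_ont = (load_ontology(config.negative_ontology_path)
               if config.negative_ontology_path else resources.negative_ontology())

    report: dict = {"stages": {}}

    # --- stage: corpus ------------------------------------------------------
    if config.abstracts_path:
        from ratechange_miner.corpus_io import read_abstracts_tsv, read_medline
        from ratechange_miner.preprocess import preprocess_abstract

        abstracts = load(
            "corpus",
            read_medline if config.medline_format else read_abstracts_tsv,
            config.abstracts_path,
        )
        labeled = []
        sentences = []
        for ab in abstracts:
            sentences.extend(
                load("preprocess", preprocess_abstract, ab, gene_dict, norm)
            )
        report["stages"]["corpus"] = {
            "abstracts": len(abstracts), "sentences": len(sentences)
        }
    else:
        gen_cfg = GeneratorConfig(**(config.synthetic or {}))
        labeled = load("corpus", generate, gen_cfg)
        sentences = [ls.sentence for ls in labeled]
        report["stages"]["corpus"] = {
            "abstracts": 0, "sentences": len(sentences), "synthetic": True
        }
    logger.info("corpus: %d sentences in", len(sentences))

    # --- stage: filter ------------------------------------------------------
    keep_mask = [
        load("filter", passes_filters, s, config.filter, regulate_lex, temporal_lex).passed
        for s in sentences
    ]
    candidates = [s for s, keep in zip(sentences, keep_mask) if keep]
    labeled = [ls for ls, keep in zip(labeled, keep_mask) if keep] if labeled else []
    report["stages"]["filter"] = {
        "in": len(sentences), "out": len(candidates),
        "theta_regulate": config.filter.theta_regulate,
        "theta_temporal": config.filter.theta_temporal,
        "min_noun_genes": config.filter.min_noun_genes,
    }
    logger.info("filter: %d -> %d candidate sentences", len(sentences), len(candidates))

    # --- stage: rule classification ----------------------------------------
    rule_block: dict = {"n": len(candidates)}
    reg_pred = [classify_regulation_rule(s, rate_ont).label for s in candidates]
    comb_pred = [
        classify_combined_rule(s, rate_ont, neg_ont).label for s in candidates
    ]
    rule_block["predicted_positive"] = {
        "regulation_based": sum(p == "positive" for p in reg_pred),
        "combined": sum(p == "positive" for p in comb_pred),
    }
    if labeled:
        gold = [ls.label for ls in labeled]
        rule_block["regulation_based"] = _metrics_block(
            ConfusionMatrix.from_labels(gold, reg_pred)
        )
        rule_block["combined"] = _metrics_block(
            ConfusionMatrix.from_labels(gold, comb_pred)
        )
    report["stages"]["rule_classifier"] = rule_block

    # --- stage: featurize + train-eval -------------------------------------
    if labeled and any(ls.parse is not None for ls in labeled):
        with_parse = [ls for ls in labeled if ls.parse is not None]
        vectors = [
            load("featurize", featurize, ls.sentence, ls.parse,
                 config.feature_mode, rate_ont, neg_ont)
            for ls in with_parse
        ]
        gold = [ls.label for ls in with_parse]
        if len(gold) >= config.cv.k and len(set(gold)) == 2:
            cm, _, _ = load("train_eval", run_cv, vectors, gold, config.cv)
            report["stages"]["train_eval"] = {
                "mode": config.feature_mode, "k": config.cv.k,
                "seed": config.cv.seed, **_metrics_block(cm),
            }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_json(report, out_dir / "pipeline_report.json")
    return report
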