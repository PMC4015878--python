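{
  "description": "Confusion-matrix rows reported for the original manually annotated corpus of yeast transcriptional-regulation rate-change sentences (1309 sentences for event classification; 357 positive sentences, 211 of them direct evidence, for the direct-evidence task). Counts are inputs for metric computation; the metric columns are the published values for cross-checking.",
  "event_classification": {
    "corpus_size": 1309,
    "rows": [
      {"model": "BioInfer ontology rules + decision tree", "tp": 223, "fp": 121, "fn": 134, "tn": 831,
       "published": {"precision": 64.83, "recall": 62.46, "f1": 63.62, "accuracy": 80.52}},
      {"model": "GeneReg ontology rules + decision tree", "tp": 235, "fp": 109, "fn": 122, "tn": 843,
       "published": {"precision": 68.31, "recall": 65.83, "f1": 67.05, "accuracy": 82.35}},
      {"model": "Regulation rate change ontology + decision tree", "tp": 276, "fp": 107, "fn": 81, "tn": 845,
       "published": {"precision": 72.06, "recall": 77.31, "f1": 74.59, "accuracy": 85.64}},
      {"model": "Combined ontologies + decision tree", "tp": 277, "fp": 99, "fn": 80, "tn": 853,
       "published": {"precision": 73.67, "recall": 77.59, "f1": 75.58, "accuracy": 86.33}},
      {"model": "Regulation-based Rule", "tp": 335, "fp": 223, "fn": 22, "tn": 729,
       "published": {"precision": 60.04, "recall": 93.84, "f1": 73.22, "accuracy": 81.28}},
      {"model": "Combined Rule", "tp": 322, "fp": 158, "fn": 35, "tn": 794,
       "published": {"precision": 67.08, "recall": 90.20, "f1": 76.94, "accuracy": 85.26}}
    ]
  },
  "direct_evidence": {
    "corpus_size": 357,
    "direct_count": 211,
    "rows": [
      {"model": "Baseline (ACE-style) features", "tp": 131, "fp": 88, "fn": 80, "tn": 58,
       "published": {"precision": 59.82, "recall": 62.09, "f1": 60.93, "accuracy": 52.94}},
      {"model": "All rules features", "tp": 149, "fp": 102, "fn": 62, "tn": 44,
       "published": {"precision": 59.36, "recall": 70.62, "f1": 64.50, "accuracy": 54.06}},
      {"model": "Original combined features", "tp": 175, "fp": 121, "fn": 36, "tn": 25,
       "published": {"precision": 59.12, "recall": 82.94, "f1": 69.03, "accuracy": 56.02}},
      {"model": "Combined features", "tp": 185, "fp": 122, "fn": 26, "tn": 24,
       "published": {"precision": 60.26, "recall": 87.68, "f1": 71.43, "accuracy": 58.54}}
    ]
  }
}
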