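{
  "name": "negative_transcriptional_regulation",
  "polarity": "negative",
  "nodes": [
    {"id": "non_transcription_regulation", "label": "non-transcription regulation process", "polarity": "negative", "count": null},
    {"id": "cell_cycle_regulation", "label": "cell cycle regulation", "polarity": "negative", "count": 71},
    {"id": "dna_replication_repair", "label": "DNA replication and repair", "polarity": "negative", "count": 49},
    {"id": "translation", "label": "translation", "polarity": "negative", "count": 35},
    {"id": "other_process", "label": "other biological process", "polarity": "negative", "count": null}
  ],
  "relations": [
    {"subject": "cell_cycle_regulation", "relation": "is_a", "object": "non_transcription_regulation"},
    {"subject": "dna_replication_repair", "relation": "is_a", "object": "non_transcription_regulation"},
    {"subject": "translation", "relation": "is_a", "object": "non_transcription_regulation"},
    {"subject": "other_process", "relation": "is_a", "object": "non_transcription_regulation"}
  ],
  "patterns": [
    {"node_id": "cell_cycle_regulation", "keywords": ["cell cycle"]},
    {"node_id": "cell_cycle_regulation", "keywords": ["anaphase"]},
    {"node_id": "cell_cycle_regulation", "keywords": ["spindle"]},
    {"node_id": "cell_cycle_regulation", "keywords": ["mitosis"]},
    {"node_id": "cell_cycle_regulation", "keywords": ["mitotic"]},
    {"node_id": "cell_cycle_regulation", "keywords": ["segregate"]},
    {"node_id": "cell_cycle_regulation", "keywords": ["cytokinesis"]},
    {"node_id": "dna_replication_repair", "keywords": ["replication fork"]},
    {"node_id": "dna_replication_repair", "keywords": ["dna replication"]},
    {"node_id": "dna_replication_repair", "keywords": ["dna repair"]},
    {"node_id": "dna_replication_repair", "keywords": ["origin", "firing"]},
    {"node_id": "translation", "keywords": ["codon"]},
    {"node_id": "translation", "keywords": ["translation"]},
    {"node_id": "translation", "keywords": ["ribosome"]},
    {"node_id": "translation", "keywords": ["trna"]},
    {"node_id": "other_process", "keywords": ["glycolysis"]},
    {"node_id": "other_process", "keywords": ["secretion"]},
    {"node_id": "other_process", "keywords": ["sporulation"]}
  ]
}
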