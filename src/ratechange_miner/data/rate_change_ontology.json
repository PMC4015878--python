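{
  "name": "transcriptional_regulation_rate_change",
  "polarity": "rate_change",
  "nodes": [
    {"id": "trr_rate_change", "label": "transcriptional regulation rate change", "polarity": "rate_change", "count": null},
    {"id": "chromatin_domains", "label": "chromatin domains", "polarity": "rate_change", "count": null},
    {"id": "transcription", "label": "transcription", "polarity": "rate_change", "count": null},
    {"id": "promoter_activity", "label": "promoter activity", "polarity": "rate_change", "count": 101},
    {"id": "rna_polymerase_activity", "label": "RNA polymerase activity and binding", "polarity": "rate_change", "count": null},
    {"id": "transcription_behavior", "label": "transcription behavior", "polarity": "rate_change", "count": 343},
    {"id": "histone_modification", "label": "histone chemical modification", "polarity": "rate_change", "count": null},
    {"id": "chemical_reaction", "label": "chemical reaction on chromatin proteins", "polarity": "rate_change", "count": 11},
    {"id": "chromatin_remodeling", "label": "chromatin remodeling", "polarity": "rate_change", "count": 12},
    {"id": "nuclear_change", "label": "nuclear change", "polarity": "rate_change", "count": 13},
    {"id": "dna_structure_change", "label": "DNA structure changes", "polarity": "rate_change", "count": 1}
  ],
  "relations": [
    {"subject": "promoter_activity", "relation": "part_of", "object": "transcription"},
    {"subject": "rna_polymerase_activity", "relation": "part_of", "object": "transcription"},
    {"subject": "transcription_behavior", "relation": "is_a", "object": "transcription"},
    {"subject": "histone_modification", "relation": "part_of", "object": "chromatin_domains"},
    {"subject": "chemical_reaction", "relation": "is_a", "object": "histone_modification"},
    {"subject": "chromatin_remodeling", "relation": "part_of", "object": "chromatin_domains"},
    {"subject": "nuclear_change", "relation": "part_of", "object": "chromatin_domains"},
    {"subject": "dna_structure_change", "relation": "part_of", "object": "chromatin_domains"},
    {"subject": "trr_rate_change", "relation": "result_from", "object": "transcription"},
    {"subject": "trr_rate_change", "relation": "result_from", "object": "chromatin_domains"}
  ],
  "patterns": [
    {"node_id": "promoter_activity", "keywords": ["promoter", "activity"]},
    {"node_id": "rna_polymerase_activity", "keywords": ["polymerase"]},
    {"node_id": "transcription_behavior", "keywords": ["transcription"]},
    {"node_id": "transcription_behavior", "keywords": ["express"]},
    {"node_id": "transcription_behavior", "keywords": ["mrna"]},
    {"node_id": "histone_modification", "keywords": ["ubiquitinate"]},
    {"node_id": "histone_modification", "keywords": ["methylate"]},
    {"node_id": "histone_modification", "keywords": ["acetylate"]},
    {"node_id": "chemical_reaction", "keywords": ["histone"]},
    {"node_id": "chromatin_remodeling", "keywords": ["chromatin"]},
    {"node_id": "chromatin_remodeling", "keywords": ["nucleosome"]},
    {"node_id": "nuclear_change", "keywords": ["nuclear", "export"]},
    {"node_id": "nuclear_change", "keywords": ["nuclear", "import"]},
    {"node_id": "dna_structure_change", "keywords": ["dna", "structure"]}
  ]
}
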