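"""Transitive relation inference and pattern coverage of the ontologies.

Computes the closure of the rate-change ontology's typed relations under the
composition rules, then the average cumulative pattern-coverage curve over a
synthetic corpus.
"""

from ratechange_miner import coverage_curve, infer_relation_closure, resources
from ratechange_miner.synthetic_corpus import GeneratorConfig, generate

ont = resources.rate_change_ontology()
closed = infer_relation_closure(ont.relations)
inferred = sorted(closed - ont.relations)
print(f"{len(ont.relations)} asserted relations -> {len(closed)} after closure")
for r in inferred:
    print(f"  inferred: {r.subject} {r.relation} {r.object}")

corpus = generate(GeneratorConfig(n_sentences=400, seed=7))
tokens = [ls.sentence.normalized_tokens for ls in corpus]
curve = coverage_curve(tokens, ont, n_shuffles=100, seed=7)
for frac in (0.1, 0.2, 0.5, 1.0):
    j = max(1, int(frac * len(tokens)))
    print(f"after {frac:4.0%} of sentences: {curve[j - 1]:.2f} of patterns seen")
# The curve says how quickly a random read-through of the corpus encounters
# the ontology's textual patterns: a fast rise means good pattern coverage.
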