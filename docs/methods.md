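# Methods

## Problem setting

A sentence-level pipeline extracts *rate changes in transcriptional
regulation* from abstracts: qualitative evidence (speed-up / slow-down /
altered duration) for time delays on gene-regulatory-network edges. The
working assumption throughout is sentence resolution — an event and its
participants are expected inside one sentence — which is the standard
trade-off for abstract-level relation extraction: it loses cross-sentence
events but keeps precision manageable.

## Preprocessing

Abstracts are segmented with a rule-based splitter (sentence-final
punctuation followed by an upper-case or digit onset, with an abbreviation
guard list; "S. cerevisiae" never splits because the follower is lower
case). Tokens are alphanumeric runs plus single punctuation symbols;
hyphenated compounds split into parts so "chromatin-remodeling" still
matches the "chromatin" keyword.

POS tagging uses a small deterministic tagger (closed-class lexicon, suffix
rules, noun-class default; symbols with digits or in upper case are tagged
`NN`). Both the segmenter and the tagger sit behind pluggable callables, so
a heavier backend can be dropped in; the shipped defaults are deterministic,
which keeps every downstream result reproducible. The pipeline relies only
on the noun-class (`NN` prefix) distinction — the "gene tagged as noun"
filter condition — so tagger quality beyond that is not load-bearing.

Gene mentions come from case-insensitive longest-match dictionary lookup
against a yeast gene-symbol dictionary (canonical id → synonyms; ~60 symbols
ship for tests and the generator — real deployments would load the full SGD
synonym table in the same format). Word normalization then (i) replaces
every token covered by a gene mention with the placeholder `genename` and
(ii) replaces keyword variants with their dictionary head form ("slowed" →
"slow", "ubiquitylation" → "ubiquitinate"); other tokens are lower-cased.
Normalization runs *after* tagging, so tags reflect surface forms; it is
idempotent and token-count preserving (each covered token of a multi-token
gene name becomes one placeholder).

## Sentence filter

Each trigger list is a unit vector `y` over its `n` entries; a sentence is
the binary indicator `x` of matched entries (multiword entries such as "shut
down" or "rate change" match as contiguous token bigrams). Then
`cos(x, y) = √(m/n)` for `m` matches; binary indicators make the score
invariant to keyword repetition, avoiding long-sentence bias. Corpus
inclusion requires all of: ≥ 2 noun-tagged gene mentions, regulate-list
cosine > 0.1, rate-change-list cosine > 0.15, with *strict* inequalities
("exceeds"). The weaker both-scores-above-zero stage is the same code at
thresholds (0, 0). Defaults: θ_regulate = 0.1, θ_temporal = 0.15,
min_noun_genes = 2.

Note the thresholds interact with lexicon size: with the shipped 20-entry
regulate list a single match scores √(1/20) ≈ 0.22 > 0.1, whereas the
original lists were large enough that 0.1 implied several matches. The
thresholds are configuration, not constants.

## Ontologies and deterministic rules

Two ontologies ship as editable JSON (nodes with instance counts where
known, typed relations, textual patterns). The exact pattern inventories of
the original figures are not machine-recoverable from text, so the shipped
patterns are a curated approximation seeded from the recoverable subclass
names/counts (promoter activity 101, transcription behavior 343, nuclear
change 13, chromatin remodeling 12, DNA structure changes 1, chemical
reaction 11; negatives: cell cycle 71, DNA replication/repair 49,
translation 35) and from the published example sentences. A pattern is a
set of normalized keywords that must co-occur anywhere in the sentence
(order-free; multiword keywords as adjacent bigrams). Sentence scope, not
clause scope, is assumed — the simplest reading consistent with
keyword-co-occurrence matching.

Relation closure is the least fixed point under
`r ∘ is_a → r`, `is_a ∘ r → r`, `part_of ∘ result_from → result_from`,
`result_from ∘ part_of → result_from`, `part_of ∘ part_of → part_of`;
undefined compositions (e.g. `result_from ∘ result_from`) infer nothing,
because the rule table is treated as exhaustive. Inferred self-relations
(from an `is_a` cycle) are retained but logged. Tests verify the closure
against a brute-force path-composition oracle on random DAGs; on DAGs the
table is associative along paths, so fixed-point and path-fold agree.

The *regulation-based rule* is "any rate-change pattern fires"; the
*combined rule* adds the unconditional negative veto. Both are pure
functions of normalized tokens, so predicted positives of the combined rule
are always a subset of the regulation rule's — the veto can only remove
false (and some true) positives, which is the observed precision/recall
trade in the reported confusion tables (FP 223 → 158, TP 335 → 322).

## Direct-evidence features

Features are built over a dependency parse (undirected shortest paths;
deterministic lexicographic tie-break). Families: `kw|head|TAG` for every
ontology-keyword occurrence; `wrw|w1|rel|w2` for consecutive token pairs
along each gene–keyword shortest path; `gkd|genename|keyword|⟨distance⟩` per
gene–keyword pair. Post-processing generalizes dependency types to the
second level of the typed-dependency hierarchy (editable mapping table:
nsubj/nsubjpass/csubj → subj, dobj/iobj/pobj → obj, amod/advmod/prep/… →
mod, …) and bins path lengths near/moderate/far. The stated bin boundaries
("less than three", "four to six", "larger than six") leave length 3
unassigned; it is placed in *near* so the bins partition all lengths — the
minimal contiguous extension.

Modes: `combined` (all three families, post-processed), `original_combined`
(specific types, raw lengths — post-processing is a pure many-to-one
collapse, so the combined feature count never exceeds the original),
`all_rules` (one binary feature per firing ontology pattern), and
`baseline_ace` (ACE-style approximation: bag of words between consecutive
entity/keyword mentions plus dependency-path label strings; the original
ACE inventory is only summarized in the literature, so this mode documents
itself as an approximation).

The parser is a pluggable provider. Tests and the generator use
deterministic toy parses built from the sentence templates, so no parser
model is needed; undirected distances are assumed, the standard convention
for shortest dependency paths.

## Evaluation

`compute_metrics` uses precision = 100·TP/(TP+FP), recall = 100·TP/(TP+FN),
F1 = harmonic mean, accuracy = 100·(TP+TN)/total, zero-denominator cases
defined as 0; printed values round half-up to 2 decimals, which reproduces
every metric cell of the published tables from its row's counts.
Cross-validation is stratified 10-fold (shuffled, seeded; plain k-fold when
a class is smaller than k, e.g. leave-one-out); per-fold test confusion
matrices are summed so the aggregate total equals the corpus size, matching
how the whole-corpus tables were produced. The default tree learner is
scikit-learn's CART wrapped behind a two-method fit/predict contract, with
a minimal dependency-free gini tree (`MinimalCART`) kept as a cross-check;
which tree variant the original study used is unstated, and any learner
satisfying the contract is acceptable. Trees act as automatic rule pruning
over the binary rule/feature space; no additional regularization is
applied. The coverage curve shuffles sentence order (default 100 shuffles,
seeded) and averages the cumulative fraction of patterns seen per prefix.

## Synthetic corpus

The generator builds slot-template sentences —
`⟨GENE⟩ ⟨rate-word⟩ ⟨regulate-word⟩ of ⟨GENE⟩ ⟨planted keywords⟩` — with a
toy parse constructed alongside. This emulates trigger co-occurrence, class
structure and parse distances, not fluent English: the pipeline consumes
tokens, not grammar. Defaults mirror the annotated corpus: 1309 sentences,
27.3% positive (357/1309), 59.1% of positives direct (211/357), negative
mix weighted toward cell-cycle (0.35) and DNA-replication (0.25) events
with translation and other processes at 0.20 each — the relative ordering
of the reported negative subclass counts with a modest "other" share. Half
of the negatives also carry positive-looking keywords (the false-positive
phenomenon the veto exists for). Ontology keywords are excluded from the
trigger-word slots so pattern fires come only from deliberate planting.
Direct positives put the planted keyword at parse distance ≤ 3 from a gene;
indirect ones at ≥ 4 via a filler chain; genetic-engineering positives add
"multicopy plasmid"/"construct" markers. Label noise flips gold labels
independently with the configured probability.

Because synthetic labels are generated by the same pattern logic the
combined rule implements, noise-free rule recovery is exact by construction
(F1 = 100%): that checks wiring (normalization, matching, veto), not
real-world accuracy. Under label noise ε the rule's accuracy concentrates
at 1 − ε, and a cross-validated tree on rule features reaches ≈ 94% at the
default corpus size with ε = 0.05. What the synthetic checks do *not* show:
robustness to paraphrase, anaphora, cross-sentence events, tagger/parser
errors, or gene-name ambiguity — real abstracts are harder on every one of
these axes, which is why the published whole-corpus scores (F1 76.94% for
the combined rule) are far below the synthetic ceiling and are reproduced
here only as metric arithmetic from the reported confusion matrices.

## Problem sizes and numerical choices

Test and acceptance runs use n = 500 for noise-free rule recovery, n = 1500
for the noise-tracking check (binomial 99% interval), and the default
n = 1309 for tree cross-validation — sizes at which every stochastic check
is stable across seeds while the whole suite stays fast. Cosine scores are
exact to 1e-12 against the closed form; closure and path computations are
exact. Tie-breaks: lexicographically smallest token-index path; majority
leaves break toward the negative class in `MinimalCART`. Degenerate inputs:
empty lexicons, empty sentences, empty confusion matrices and disconnected
parses raise `ValueError`; single-class training sets return a constant
predictor with a warning.

## Known limitations

- Dictionary-based gene recognition only (no NER model, no species
  disambiguation); longest-match, case-insensitive, exact tokens.
- Sentence-scope pattern matching can conflate clauses; the original
  clause-scope question is open and sentence scope was chosen.
- The shipped ontology patterns are a curated approximation of the original
  inventories; they are data files, meant to be edited and extended.
- The ACE-style baseline mode approximates a feature set that is only
  summarized, not enumerated, in the literature.
- Regulator/regulatee role assignment (which gene is agent, which patient)
  is out of scope; rate-change *direction* is available via the
  Quicken/Delay/Change trigger classes.
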