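"""Filter abstract sentences with the trigger-word cosine filter.

Builds two tiny abstracts, scores every sentence against the "regulate" and
rate-change lexicons, and applies the three corpus-inclusion conditions.
"""

from ratechange_miner import FilterConfig, RawAbstract, filter_corpus, resources

abstracts = [
    RawAbstract("16400179", (
        "Degradation of MTH1 is slowed when glucose repression of MTH1 "
        "expression is prevented, and this results in a delay in induction "
        "of HXT3 expression. Glucose sensing remains an open question."
    )),
    RawAbstract("99999001", "S. cerevisiae cells were grown in rich medium."),
]

survivors, report = filter_corpus(
    abstracts, FilterConfig(),
    resources.regulate_lexicon(), resources.rate_change_lexicon(),
)

for row in report:
    print(f"pmid={row['pmid']} sent={row['sent_index']} "
          f"reg={row['reg_score']:.3f} temp={row['temp_score']:.3f} "
          f"noun_genes={row['noun_genes']} pass={row['pass']}")
print(f"\n{len(survivors)} of {len(report)} sentences become corpus candidates.")
# A sentence passes only with >= 2 noun-tagged gene mentions and cosine scores
# strictly above 0.1 (regulate list) and 0.15 (rate-change list); the growth
# sentence has genes, triggers or both missing and is filtered out.
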