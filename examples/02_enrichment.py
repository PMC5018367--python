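"""Annotation enrichment of an NSAID input set against a screened library.

Six anti-inflammatory drugs are tested against a 12-drug background; each
annotation term gets a one-sided Fisher's exact test and Benjamini-Hochberg
FDR correction across all databases jointly.
"""

import chemannot as ca
from chemannot import demo

space = demo.nsaid_space()
bundle = demo.nsaid_bundle()

matches = ca.match_all(list(demo.DEMO_QUERIES), space)
input_ids = {m.unique_id() for m in matches if m.unique_id() is not None}

results = ca.run_enrichment(input_ids, set(demo.DEMO_BACKGROUND), bundle, alpha=0.05)
print(f"{'database':<9} {'term':<11} {'k/n':<6} {'K/N':<6} {'p':<10} {'adj p':<10} enriched")
for r in results:
    t = r.table
    print(
        f"{r.term.database:<9} {r.term.term_id:<11} {t.k}/{t.n:<4} {t.K}/{t.N:<4} "
        f"{r.p_value:<10.3g} {r.adjusted_p:<10.3g} {r.enriched}"
    )

# k/n are input chemicals carrying the term over the input size; K/N the
# same in the background. A small adjusted p says the term is carried by
# far more input chemicals than a random draw of n from the background
# would give: here the shared target (PTGS2), the shared therapeutic class
# (M01A) and two class-typical side effects come out enriched, while
# unspecific terms (nausea) do not.
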