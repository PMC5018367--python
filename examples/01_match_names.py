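"""Disambiguate a mixed list of chemical names and identifiers.

The query list deliberately mixes an exact synonym, a salt form that is not
in the dictionary, a misspelling, and a structural key; each resolves
through a different stage of the matching cascade.
"""

import chemannot as ca
from chemannot import demo

space = demo.nsaid_space()
queries = list(demo.DEMO_QUERIES) + ["mercaptopurine-like-unknown"]

results = ca.match_all(queries, space)
print(f"{'query':<30} {'stage':<12} {'score':<7} matched")
for r in results:
    label = ",".join(r.matched_ids) or "-"
    print(f"{r.query:<30} {r.match_type:<12} {r.score:<7.3f} {label}")

# The stage column shows how each query was resolved: "exact" is a verbatim
# synonym hit, "salt_acid" means a salt->acid rewrite found the dictionary
# name, "approximate" is a fuzzy hit scored by normalized edit similarity
# (1.0 = identical), "structural" is an InChIKey/SMILES lookup, and
# "unmatched" means nothing reached the 0.85 similarity threshold.
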