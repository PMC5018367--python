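"""Export the enrichment result as a bipartite chemical-annotation network.

Writes node-link JSON, SIF and GraphML files that external graph viewers
(e.g. Cytoscape) can open directly.
"""

import os

import chemannot as ca
from chemannot import demo

space = demo.nsaid_space()
bundle = demo.nsaid_bundle()
matches = ca.match_all(list(demo.DEMO_QUERIES), space)
input_ids = {m.unique_id() for m in matches if m.unique_id() is not None}
results = ca.run_enrichment(input_ids, set(demo.DEMO_BACKGROUND), bundle)

net = ca.build_network(results, only_enriched=True, space=space)
os.makedirs("scratch", exist_ok=True)
for fmt, name in (("json_graph", "net.json"), ("sif", "net.sif"), ("graphml", "net.graphml")):
    path = os.path.join("scratch", name)
    ca.write_network(net, path, fmt)
    print("wrote", path)

chems = net.node_ids("chemical")
terms = net.node_ids("term")
print(f"{len(chems)} chemical nodes, {len(terms)} term nodes, {len(net.edges)} edges")
# Every edge links an input chemical to an enriched term it carries; term
# node ids are namespaced as database:term_id so identical codes from
# different databases stay distinct.
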