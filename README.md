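# chemannot

Integrative analysis of chemical bioactivity data is routinely blocked at
step zero: the same compound appears under dozens of names, trade names and
identifiers, and bioactivity databases rarely cross-reference each other.
`chemannot` is a toolkit for researchers in systems pharmacology, chemical
biology and toxicology who need to take a list of chemicals — say, the hits
of a high-throughput screen — and answer "what do these compounds have in
common?". It:

1. **disambiguates** free-text chemical names and structural identifiers
   (InChIKeys, SMILES) into a unified reference space of chemical
   identifiers, using a cascade of exact synonym lookup, salt/acid name
   heuristics (salicylate ↔ salicylic acid), and approximate string matching
   (character-trigram candidate generation rescored by normalized
   Levenshtein similarity, acceptance threshold 0.85);
2. **retrieves** bioactivity annotations for the resolved chemicals from
   any number of categorized annotation databases (molecular targets, gene
   interactions, metabolization, therapeutic classes such as ATC codes,
   side effects, toxicity);
3. **tests enrichment** of each annotation term in the input set against a
   user-specified background (e.g. the full screened library). For a term
   carried by `k` of `n` input chemicals and `K` of `N` background
   chemicals, significance is the one-sided Fisher's exact test — the
   hypergeometric upper tail P(X ≥ k) for X ~ Hypergeom(N, K, n) — with
   Benjamini–Hochberg FDR correction applied jointly across all databases;
4. **exports** the result as a bipartite chemical–annotation network
   (node-link JSON, SIF or GraphML) for external graph viewers.

Automatic matches can be reviewed in a file-based curation round-trip
before anything downstream runs. A seeded workspace simulator generates
complete synthetic inputs (dictionary with typo-tolerant pseudo-names and
salt-form synonym families, annotation bundle with a planted enriched term,
query and background lists, gold standard), so everything can be exercised
and benchmarked without external downloads.

## Worked example

`examples/02_enrichment.py` matches six NSAID queries (an exact synonym, a
salt form, a misspelling, an InChIKey, ...) and tests their annotations
against a 12-drug background:

```
database  term        k/n    K/N    p          adj p      enriched
TARGETS   PTGS2       6/6    6/12   0.00108    0.00649    True
ATC       M01A        5/6    5/12   0.00758    0.0114     True
SIDEFX    nephritis   5/6    5/12   0.00758    0.0114     True
SIDEFX    vasculitis  5/6    5/12   0.00758    0.0114     True
ATC       N02B        1/6    2/12   0.773      0.773      False
SIDEFX    nausea      4/6    8/12   0.727      0.773      False
```

All six input drugs share the PTGS2 target (k/n = 6/6) while only they
carry it in the background (K/N = 6/12), giving the hypergeometric tail
p = 1/C(12,6) ≈ 0.00108; after FDR correction the shared target, the
anti-inflammatory ATC class M01A and two class-typical side effects are
flagged enriched, while unspecific terms (nausea, carried by 8 of 12
background drugs) are not. `examples/03_network_export.py` turns the same
result into a 6-chemical × 4-term network with 21 edges.

## Command line

```sh
chemannot simulate --out ws --seed 0          # synthetic workspace
chemannot run --config ws/config.yaml         # match -> annotate -> enrich -> network
chemannot match --dict D.tsv --queries Q.txt --out matches.tsv
chemannot enrich --bundle manifest.yaml --input matches.tsv --out enrichment.tsv
chemannot network --bundle manifest.yaml --input matches.tsv --format sif --out net.sif
```

`run` writes `matches.tsv`, `annotations.tsv`, `enrichment.tsv`,
`network.json` and a run log; if a `matches.curated.tsv` is placed next to
the match table, the curated assignments replace the automatic ones on the
next run.

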