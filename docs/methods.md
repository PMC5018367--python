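# Methods

## The disambiguation model

A *reference space* is a set of chemical records, each with a stable opaque
identifier, a set of (synonym, source) pairs, and sets of structural keys
(InChIKeys in the 14-10-1 uppercase-letter layout, and SMILES strings).
Names are matched after normalization: NFKC compatibility normalization,
case folding, whitespace trimming and collapse. Punctuation (hyphens,
digits, commas, parentheses) is preserved because it is chemically
meaningful — collapsing it at the exact-match stage would merge distinct
compounds such as "2,4-d" and "24d". An alphanumeric-only "aggressive" key
is used solely as an extra candidate-generation key for approximate search.

Because the dictionary TSV has no column for a display name, a record's
`preferred_name` is *defined* as its lexicographically smallest synonym;
the fixture generator follows the same rule, which makes write → load an
exact identity on reference spaces.

### Matching cascade

Queries resolve through four stages, cheapest and most precise first;
the first stage producing a match wins:

1. **structural** — exact string lookup (whitespace-trimmed, no
   canonicalization) of InChIKey- or SMILES-shaped queries. A query is
   routed here when it matches the InChIKey pattern or is verbatim present
   in the key index; SMILES are not syntactically distinguishable from
   names, so an exact index hit is the only reliable routing signal.
2. **exact** — normalized-synonym lookup. A synonym carried by several
   identifiers yields an *ambiguous* result; ambiguity is reported, never
   auto-resolved, because resolution belongs to curation.
3. **salt/acid** — heuristic rewrites tried against the exact index:
   "-ate" ↔ "-ic acid", "-ite" ↔ "-ous acid", and stripping of a leading or
   trailing counterion token (sodium, potassium, hydrochloride, ...;
   configurable). Rules compose to depth two (strip, then convert), which
   covers forms like "sodium salicylate" → "salicylic acid".
4. **approximate** — candidate generation over an inverted character
   n-gram index (default trigrams of "#"-padded normalized synonyms):
   candidates are the top 50 synonyms by n-gram-set Jaccard similarity,
   plus any synonym sharing the query's aggressive key. Each candidate is
   rescored by normalized Levenshtein similarity, 1 − d/max(len); that
   similarity is the final score. The best candidate is accepted iff its
   score reaches `approx_threshold` (default **0.85**); ties break by
   higher score, then larger synonym count of the chemical (preferring
   better-described chemicals), then smaller identifier. The top-k
   (default 5) candidates are always retained for curation.

The 0.85 threshold accepts one edit in a 7-character name (score 6/7 ≈
0.857) but rejects one edit in shorter names and two edits in names up to
13 characters — a reasonable operating point for drug-name typos, and
configurable. Edit distances are computed with edlib; the test suite
verifies the indexed matcher against a brute-force full scan that uses an
independent pure-Python dynamic-programming distance.

### Curation

Matches export to a TSV with a `curated_id` column. A user-supplied
identifier overrides the assignment (flagged curated, type exact); a
literal `-` clears it to unmatched. Importing validates curated ids
against the reference space when one is supplied.

## Annotation model

An annotation database is a named map chemical → term set with one of six
categories (molecular target, gene interaction, metabolization, therapeutic
class, side effect, toxicity). Gene-interaction terms are structurally
identical to target terms (term id = gene symbol). Term identity is
(term id, database): identical ATC codes from two sources remain distinct
terms because testing and the network view are per-database. Coverage
reporting gives per-database chemical/term counts and a cumulative
histogram of how many chemicals are annotated in ≥ k databases.

## Enrichment statistics

For each term, the contingency counts are k (input carriers), n (input
size), K (background carriers), N (background size). Significance is the
one-sided upper tail P(X ≥ k), X ~ Hypergeom(N, K, n) — enrichment is an
over-representation question, so only the upper tail is tested; depletion
is out of scope. The tail is summed over the exact support via log-gamma
binomial coefficients: this is stable deep into the tail (validated to a
relative error ≈ 1e-13 against exact integer arithmetic over all ~1.2M
tables with N ≤ 60) and exact at the support boundaries (k = 0, or k at
the support minimum max(0, n+K−N), returns exactly 1).

FDR control is Benjamini–Hochberg step-up, adj₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j
capped at 1, applied **jointly across all databases** — the simplest
defensible scope when databases are heterogeneous; per-database correction
would trade global FDR control for per-source power. The implementation is
permutation-equivariant (ties get identical adjusted values).

Defaults: `alpha = 0.05`; `min_term_size = 2` drops singleton terms, whose
tests are uninformative (set to 1 to disable). The background is either
user-supplied (a name list matched through the same cascade) or "auto" =
all annotated chemicals in the bundle. Input chemicals missing from the
background are added with a warning, or rejected in strict mode. Ambiguous
and unmatched queries never enter the tested input set; their counts are
logged so pipeline shrinkage is auditable.

## Network construction

One term node per retained (by default, enriched) result with members; one
chemical node per distinct member; one edge per (member, term) pair. The
graph is strictly bipartite with no isolated term nodes, |edges| = Σ k over
retained terms. Term node ids are namespaced `database:term_id`. Exports
(node-link JSON, SIF, GraphML) are byte-deterministic for equal networks;
layout and interactive rendering are intentionally out of scope.

## Synthetic data

The fixture generator emulates the *shape* of a real synonym dictionary at
desk scale, not its content: pronounceable consonant-vowel pseudo-names
(7–11 characters, ending in a consonant so the salt/acid suffix rules can
never fire accidentally), a configurable fraction of chemicals carrying a
salt/acid synonym family (`<stem>ic acid`, `<stem>ate`,
`<ion> <stem>ate`), and one synthetic InChIKey-shaped key plus one
SMILES-like string per record (random strings with the right syntax — keys
are matched by string identity only, so no hash semantics are needed).

Gold standards sample synonyms with replacement and perturb them with
probability `typo_rate` by exactly one random edit: substitution, deletion,
insertion or adjacent transposition. A transposition is two plain
Levenshtein edits, so on short names it can legitimately fall below the
acceptance threshold; with `typo_rate = 0.1` this costs ≈ 2–3 points of
sensitivity, which is part of the intended difficulty of the benchmark.

The simulated workspace (120 chemicals, 3 synonyms each, salt fraction
0.25) plants one target term carried by exactly the 10 input chemicals
(hypergeometric tail 1/C(120,10) ≈ 9e-15), an ATC-like class term on the
input plus two extras, and two side-effect terms on input subsets, against
~33 random null terms; the query list exercises every match type, including
an injected ambiguous synonym shared by two background chemicals and a
garbage query.

What the synthetic fixtures do *not* model: real-world synonym skew (a few
compounds with hundreds of trade names), cross-language names, systematic
IUPAC strings, stereo/merged identifier splits, or correlated annotation
structure between databases. Passing benchmarks on these fixtures
therefore demonstrates algorithmic correctness and calibration, not
performance on any particular public dictionary.

### Null-simulation design

The hypergeometric test is discrete, so its attained type-I level depends
on the table sizes: for small terms (K ≈ 10–60) the attainable p-values
near 0.05 are sparse and the test is strongly conservative (attained level
1–3%). The null benchmark therefore uses sizes where the p-value support
is dense — background N = 600, input n = 150, term sizes K uniform in
100–400 — for which the analytic attained level (Σ pmf(k) over k with
P(X ≥ k) ≤ 0.05, averaged over K) is ≈ 0.041. Observed null fractions
around 4% on 4000 tests reflect this discreteness, not miscalibration.

## Problem sizes and determinism

All stochastic components take explicit integer seeds (numpy Generator);
equal seeds give byte-identical fixtures and pipeline artifacts (run logs
record versions, parameters and per-stage counts, never timestamps). The
standard verification sizes — a 100–110-chemical space (≈ 450–500
synonyms) with 200–500 gold queries, the full N ≤ 60 contingency grid,
1000 BH vectors, 4000 null tests and 100 workspace replicates — were
chosen so the whole suite and the acceptance script each complete in tens
of seconds while keeping every estimate's Monte-Carlo error far from its
acceptance margin.

## Known limitations

- Approximate candidate generation is capped at the top 50 Jaccard
  candidates; in adversarial dictionaries the true nearest synonym could be
  missed (not observed on any tested fixture — the indexed matcher agreed
  with the brute-force scan on 100% of seeded batteries).
- SMILES are compared as strings; two different notations of the same
  structure do not match (canonicalization is deliberately out of scope).
- The salt/acid table covers common English suffix pairs and counterions
  only; exotic salt nomenclature passes through untouched.
- Fisher/BH assume independent sampling of chemicals; strongly correlated
  annotation assignments (e.g. near-duplicate terms within one database)
  inflate the effective number of tests like in any enrichment tool.
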