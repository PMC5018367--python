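"""Name and structural-identifier matching into the chemical reference space.

Queries are resolved by a fixed cascade of stages, cheapest and most precise
first:

1. **structural** — exact string lookup of InChIKeys/SMILES (no
   canonicalization; a key either is or is not in the space verbatim);
2. **exact** — normalized-synonym lookup;
3. **salt_acid** — heuristic rewrites between salt and acid name forms
   (e.g. "salicylate" <-> "salicylic acid", counterion stripping), each
   rewrite tried against the exact index;
4. **approximate** — candidate generation by character-trigram Jaccard
   similarity over an inverted n-gram index, rescored by normalized
   Levenshtein similarity; the best candidate is accepted when its score
   reaches ``approx_threshold``.

A synonym mapping to several identifiers yields an *ambiguous* result; these
are reported, never auto-resolved — resolution belongs to the curation
round-trip (:func:`export_match_table` / :func:`import_curated_table`).
"""

from __future__ import annotations

import csv
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple

import edlib

from ._text import aggressive_key, is_inchikey_shaped, ngrams, normalize_name
from .reference_space import GoldStandard, ReferenceSpace

logger = logging.getLogger(__name__)

MATCH_TYPES = ("exact", "salt_acid", "approximate", "structural", "ambiguous", "unmatched")

DEFAULT_COUNTERIONS = (
    "sodium",
    "potassium",
    "calcium",
    "magnesium",
    "hydrochloride",
    "hydrobromide",
    "sulfate",
    "sulphate",
    "mesylate",
    "maleate",
    "tartrate",
    "citrate",
    "phosphate",
    "monohydrate",
    "dihydrate",
)

#: Maximum candidates kept after trigram-Jaccard generation, before rescoring.
N_GENERATION_CANDIDATES = 50


@dataclass
class MatcherConfig:
    """Tunable knobs of the matching cascade."""

    approx_threshold: float = 0.85
    ngram_size: int = 3
    top_k: int = 5
    counterion_list: tuple[str, ...] = DEFAULT_COUNTERIONS
    enable_salt_acid: bool = True
    enable_approximate: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.approx_threshold <= 1.0:
            raise ValueError("approx_threshold must lie in (0, 1]")
        if self.ngram_size < 2:
            raise ValueError("ngram_size must be >= 2")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class MatchResult:
    """Outcome of matching one query into the reference space."""

    query: str
    normalized_query: str
    matched_ids: list[str]
    match_type: str
    score: float
    candidate_list: list[tuple[str, str, float]] = field(default_factory=list)
    curated: bool = False

    def is_matched(self) -> bool:
        return self.match_type != "unmatched"

    def unique_id(self) -> str | None:
        return self.matched_ids[0] if len(self.matched_ids) == 1 else None


def _unmatched(query: str, norm: str, score: float = 0.0, candidates=None) -> MatchResult:
    return MatchResult(query, norm, [], "unmatched", score, candidates or [])


def exact_match(query: str, space: ReferenceSpace) -> MatchResult:
    """Exact lookup of the normalized query in the synonym index."""
    norm = normalize_name(query)
    ids = space.synonym_to_ids.get(norm)
    if not ids:
        return _unmatched(query, norm)
    ordered = sorted(ids)
    mtype = "exact" if len(ordered) == 1 else "ambiguous"
    return MatchResult(query, norm, ordered, mtype, 1.0)


def match_structural(key: str, space: ReferenceSpace) -> MatchResult:
    """Exact lookup of an InChIKey or SMILES string (whitespace-trimmed)."""
    trimmed = key.strip()
    ids = space.key_to_id.get(trimmed)
    if not ids:
        return _unmatched(key, trimmed)
    return MatchResult(key, trimmed, sorted(ids), "structural", 1.0)


# ---------------------------------------------------------------------------
# Salt / acid heuristics
# ---------------------------------------------------------------------------


def _suffix_swaps(name: str) -> list[str]:
    out = []
    if name.endswith("ic acid") and len(name) > 7:
        out.append(name[:-7] + "ate")
    if name.endswith("ous acid") and len(name) > 8:
        out.append(name[:-8] + "ite")
    if name.endswith("ate") and len(name) > 3:
        out.append(name[:-3] + "ic acid")
    if name.endswith("ite") and len(name) > 3:
        out.append(name[:-3] + "ous acid")
    return out


def salt_acid_variants(name: str, config: MatcherConfig | None = None) -> list[str]:
    """Candidate rewrites between salt and acid name forms.

    Three rule families: "-ate" <-> "-ic acid", "-ite" <-> "-ous acid", and
    stripping a leading or trailing counterion token.  Rules compose to depth
    two (strip a counterion, then convert the suffix).  The original name is
    never returned; the order is deterministic.
    """
    config = config or MatcherConfig()
    ions = set(config.counterion_list)
    variants: list[str] = []

    def add(v: str) -> None:
        if v and v != name and v not in variants:
            variants.append(v)

    stripped: list[str] = []
    tokens = name.split(" ")
    if len(tokens) > 1:
        if tokens[0] in ions:
            stripped.append(" ".join(tokens[1:]))
        if tokens[-1] in ions:
            stripped.append(" ".join(tokens[:-1]))
    for v in _suffix_swaps(name):
        add(v)
    for s in stripped:
        add(s)
        for v in _suffix_swaps(s):
            add(v)
    return variants


# ---------------------------------------------------------------------------
# Approximate matching
# ---------------------------------------------------------------------------


def edit_similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity, 1 - d(a, b) / max(|a|, |b|)."""
    if a == b:
        return 1.0
    longest = max(len(a), len(b))
    if longest == 0:
        return 1.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / longest


class NGramIndex:
    """Inverted character n-gram index over the normalized synonyms of a space.

    Synonyms are padded with one ``#`` on each side before gram extraction.
    An auxiliary map keyed by the aggressive (alphanumeric-only) form of each
    synonym supplies extra candidates that pure gram overlap could miss.
    """

    def __init__(self, space: ReferenceSpace, ngram_size: int = 3):
        self.ngram_size = ngram_size
        self.synonyms: list[str] = []          # normalized, unique, sorted
        self.syn_ids: list[list[str]] = []     # chemical ids per synonym
        self.gram_sizes: list[int] = []
        self.inverted: dict[str, list[int]] = {}
        self.aggressive: dict[str, list[int]] = {}
        self._syn_count = {
            cid: len(rec.synonyms) for cid, rec in space.records.items()
        }
        for i, norm in enumerate(sorted(space.synonym_to_ids)):
            self.synonyms.append(norm)
            self.syn_ids.append(sorted(space.synonym_to_ids[norm]))
            grams = ngrams(norm, ngram_size)
            self.gram_sizes.append(len(grams))
            for g in grams:
                self.inverted.setdefault(g, []).append(i)
            self.aggressive.setdefault(aggressive_key(norm), []).append(i)

    def synonym_count(self, chemical_id: str) -> int:
        return self._syn_count.get(chemical_id, 0)

    def candidates(self, norm_query: str) -> list[int]:
        """Synonym indices ranked by trigram-Jaccard similarity to the query."""
        grams = ngrams(norm_query, self.ngram_size)
        overlap: Counter[int] = Counter()
        for g in grams:
            for i in self.inverted.get(g, ()):
                overlap[i] += 1
        scored = [
            (ov / (len(grams) + self.gram_sizes[i] - ov), i)
            for i, ov in overlap.items()
        ]
        scored.sort(key=lambda t: (-t[0], t[1]))
        picked = [i for _j, i in scored[:N_GENERATION_CANDIDATES]]
        extra = self.aggressive.get(aggressive_key(norm_query), ())
        picked.extend(i for i in extra if i not in picked)
        return picked


def _index_for(space: ReferenceSpace, ngram_size: int) -> NGramIndex:
    # Cache on the space: the matcher is typically called many times per space.
    cache = getattr(space, "_ngram_cache", None)
    if cache is None:
        cache = {}
        space._ngram_cache = cache  # type: ignore[attr-defined]
    if ngram_size not in cache:
        cache[ngram_size] = NGramIndex(space, ngram_size)
    return cache[ngram_size]


def approximate_match(
    query: str,
    space: ReferenceSpace,
    config: MatcherConfig | None = None,
    index: NGramIndex | None = None,
) -> MatchResult:
    """Fuzzy matching against all synonyms of the space.

    Candidates come from the n-gram index; each is rescored by normalized
    edit similarity, which is also the final score.  Ties are broken by
    higher score, then larger synonym count of the chemical (better-described
    chemicals win), then lexicographically smaller chemical id.  The top-k
    candidates are always retained for curation.
    """
    config = config or MatcherConfig()
    norm = normalize_name(query)
    if not norm:
        return _unmatched(query, norm)
    index = index or _index_for(space, config.ngram_size)
    triples: list[tuple[float, int, str, str]] = []
    for i in index.candidates(norm):
        synonym = index.synonyms[i]
        sim = edit_similarity(norm, synonym)
        for cid in index.syn_ids[i]:
            triples.append((sim, -index.synonym_count(cid), cid, synonym))
    triples.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    candidate_list = [
        (cid, synonym, sim) for sim, _neg, cid, synonym in triples[: config.top_k]
    ]
    if not triples:
        return _unmatched(query, norm)
    best_sim, _neg, best_cid, _syn = triples[0]
    if best_sim < config.approx_threshold:
        return _unmatched(query, norm, best_sim, candidate_list)
    return MatchResult(query, norm, [best_cid], "approximate", best_sim, candidate_list)


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------


def match_one(
    query: str,
    space: ReferenceSpace,
    config: MatcherConfig | None = None,
    index: NGramIndex | None = None,
) -> MatchResult:
    """Run the full cascade for one query; the first stage that matches wins."""
    config = config or MatcherConfig()
    trimmed = query.strip()
    if is_inchikey_shaped(trimmed) or trimmed in space.key_to_id:
        result = match_structural(query, space)
        if result.is_matched():
            return result
    result = exact_match(query, space)
    if result.is_matched():
        return result
    if config.enable_salt_acid:
        for variant in salt_acid_variants(result.normalized_query, config):
            hit = exact_match(variant, space)
            if hit.is_matched():
                mtype = "salt_acid" if len(hit.matched_ids) == 1 else "ambiguous"
                return MatchResult(
                    query, result.normalized_query, hit.matched_ids, mtype, 1.0
                )
    if config.enable_approximate:
        return approximate_match(query, space, config, index)
    return result


def match_all(
    queries: list[str],
    space: ReferenceSpace,
    config: MatcherConfig | None = None,
) -> list[MatchResult]:
    """Match a list of queries; output order equals input order."""
    config = config or MatcherConfig()
    index = (
        _index_for(space, config.ngram_size) if config.enable_approximate else None
    )
    results = [match_one(q, space, config, index) for q in queries]
    counts = Counter(r.match_type for r in results)
    logger.info(
        "matched %d queries: %s",
        len(results),
        ", ".join(f"{t}={counts.get(t, 0)}" for t in MATCH_TYPES),
    )
    return results


# ---------------------------------------------------------------------------
# Curation round-trip
# ---------------------------------------------------------------------------

MATCH_TABLE_COLUMNS = (
    "query",
    "normalized_query",
    "match_type",
    "score",
    "matched_ids",
    "candidates",
    "curated_id",
)


def _fmt_candidates(candidates: list[tuple[str, str, float]]) -> str:
    return ";".join(f"{cid}|{syn}|{sim:.6f}" for cid, syn, sim in candidates)


def _parse_candidates(text: str) -> list[tuple[str, str, float]]:
    if not text:
        return []
    out = []
    for part in text.split(";"):
        cid, syn, sim = part.split("|")
        out.append((cid, syn, float(sim)))
    return out


def export_match_table(results: list[MatchResult], path: str) -> None:
    """Write match results as a TSV the user can edit (the curation table).

    The ``curated_id`` column is left blank; the user fills it with a
    chemical id to override a match, or a literal ``-`` to clear it.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(MATCH_TABLE_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    (
                        r.query,
                        r.normalized_query,
                        r.match_type,
                        f"{r.score:.6f}",
                        ";".join(r.matched_ids),
                        _fmt_candidates(r.candidate_list),
                        "",
                    )
                )
                + "\n"
            )


def import_curated_table(
    path: str, space: ReferenceSpace | None = None
) -> list[MatchResult]:
    """Read back a (possibly edited) match table.

    A non-empty ``curated_id`` overrides the assignment (match type becomes
    ``exact`` with the curated flag set); a literal ``-`` clears the match to
    unmatched.  When a reference space is supplied, unknown curated ids raise
    a ``ValueError`` naming the row.
    """
    results = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if tuple(reader.fieldnames or ()) != MATCH_TABLE_COLUMNS:
            raise ValueError(f"{path}: bad match-table header {reader.fieldnames!r}")
        for rowno, row in enumerate(reader, start=2):
            result = MatchResult(
                query=row["query"],
                normalized_query=row["normalized_query"],
                matched_ids=[x for x in row["matched_ids"].split(";") if x],
                match_type=row["match_type"],
                score=float(row["score"]),
                candidate_list=_parse_candidates(row["candidates"]),
            )
            curated = row["curated_id"].strip()
            if curated == "-":
                result.matched_ids = []
                result.match_type = "unmatched"
                result.score = 0.0
                result.curated = True
            elif curated:
                if space is not None and curated not in space.records:
                    raise ValueError(
                        f"{path}:{rowno}: curated_id {curated!r} not in reference space"
                    )
                result.matched_ids = [curated]
                result.match_type = "exact"
                result.score = 1.0
                result.curated = True
            results.append(result)
    return results


# ---------------------------------------------------------------------------
# Benchmark evaluation
# ---------------------------------------------------------------------------


class MatchEvaluation(NamedTuple):
    sensitivity: float
    precision: float
    n_correct: int
    n_matched: int
    n_queries: int


def evaluate_matching(results: list[MatchResult], gold: GoldStandard) -> MatchEvaluation:
    """Sensitivity and precision of match results against a gold standard.

    A result is correct iff the true id is its *unique* matched id (an
    uncurated ambiguous result counts as matched but incorrect).  Sensitivity
    is correct / total queries; precision is correct / matched.  With zero
    matched results precision is not applicable and reported as NaN.
    """
    if len(results) != len(gold.pairs):
        raise ValueError(
            f"results ({len(results)}) and gold standard ({len(gold.pairs)}) "
            "have different lengths"
        )
    n_matched = sum(r.is_matched() for r in results)
    n_correct = sum(
        r.unique_id() == true_id for r, (_q, true_id) in zip(results, gold.pairs)
    )
    sensitivity = n_correct / len(gold.pairs) if gold.pairs else 0.0
    precision = n_correct / n_matched if n_matched else math.nan
    return MatchEvaluation(sensitivity, precision, n_correct, n_matched, len(gold.pairs))


# ---------------------------------------------------------------------------
# Query-file input
# ---------------------------------------------------------------------------


def read_query_file(path: str) -> list[tuple[str, str]]:
    """Read a query list: one name/key per line, ``#`` comments ignored, or a
    2-column TSV ``label<TAB>query``.  Returns (label, query) pairs; for the
    1-column form the label equals the query."""
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "\t" in line:
                label, query = line.split("\t", 1)
                pairs.append((label, query))
            else:
                pairs.append((line, line))
    return pairs
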