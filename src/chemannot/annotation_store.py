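"""Bioactivity annotation databases over the unified chemical identifier space.

Each database is a named, categorized map from chemical identifiers to
annotation terms — molecular targets, gene interactions, metabolizing
enzymes, therapeutic classes (e.g. ATC codes), drug side effects or toxicity
endpoints.  Term identity is ``(term_id, database)``: the same code loaded
from two databases stays two distinct terms, because enrichment and the
network view are keyed per source database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd
import yaml

from .reference_space import ReferenceSpace, _read_tsv_rows

logger = logging.getLogger(__name__)

CATEGORIES = frozenset(
    {
        "molecular_target",
        "gene_interaction",
        "metabolization",
        "therapeutic_class",
        "side_effect",
        "toxicity",
    }
)

ANNOTATION_HEADER = ("chemical_id", "term_id", "term_label")


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    label: str
    database: str
    category: str


@dataclass
class AnnotationDatabase:
    """One annotation source: chemicals -> term ids, plus term metadata."""

    name: str
    category: str
    chem_to_terms: dict[str, set[str]] = field(default_factory=dict)
    terms: dict[str, AnnotationTerm] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of "
                f"{sorted(CATEGORIES)}"
            )

    @property
    def n_chemicals(self) -> int:
        return len(self.chem_to_terms)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def add(self, chemical_id: str, term_id: str, label: str) -> None:
        existing = self.terms.get(term_id)
        if existing is not None and existing.label != label:
            logger.warning(
                "database %s: term %s label conflict (%r -> %r); last wins",
                self.name,
                term_id,
                existing.label,
                label,
            )
        self.terms[term_id] = AnnotationTerm(term_id, label, self.name, self.category)
        self.chem_to_terms.setdefault(chemical_id, set()).add(term_id)

    def term_to_chems(self) -> dict[str, set[str]]:
        """Inverted map: term id -> set of annotated chemicals."""
        inv: dict[str, set[str]] = {t: set() for t in self.terms}
        for cid, term_ids in self.chem_to_terms.items():
            for t in term_ids:
                inv[t].add(cid)
        return inv

    def annotated_chemicals(self) -> set[str]:
        return set(self.chem_to_terms)


@dataclass
class AnnotationBundle:
    """An ordered collection of annotation databases with unique names."""

    databases: dict[str, AnnotationDatabase] = field(default_factory=dict)

    def add(self, db: AnnotationDatabase) -> None:
        if db.name in self.databases:
            raise ValueError(f"duplicate database name {db.name!r}")
        self.databases[db.name] = db

    def __iter__(self) -> Iterable[AnnotationDatabase]:
        return iter(self.databases.values())

    def __len__(self) -> int:
        return len(self.databases)

    def annotated_chemicals(self) -> set[str]:
        out: set[str] = set()
        for db in self:
            out |= db.annotated_chemicals()
        return out


def load_annotation_db(path: str, name: str, category: str) -> AnnotationDatabase:
    """Load one annotation TSV (chemical_id, term_id, term_label).

    Duplicate (chemical, term) rows collapse; conflicting labels for a term
    resolve last-wins with a logged warning.
    """
    db = AnnotationDatabase(name=name, category=category)
    for _lineno, (cid, term_id, label) in _read_tsv_rows(path, ANNOTATION_HEADER):
        db.add(cid, term_id, label)
    return db


def write_annotation_db(db: AnnotationDatabase, path: str) -> None:
    """Deterministic TSV serialization (rows sorted by chemical, term)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(ANNOTATION_HEADER) + "\n")
        for cid in sorted(db.chem_to_terms):
            for term_id in sorted(db.chem_to_terms[cid]):
                fh.write(f"{cid}\t{term_id}\t{db.terms[term_id].label}\n")


def load_bundle(manifest_path: str) -> AnnotationBundle:
    """Load a bundle from a YAML manifest: a list of {path, name, category}.

    Relative paths are resolved against the manifest's directory.
    """
    import os

    with open(manifest_path, encoding="utf-8") as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ValueError(f"{manifest_path}: manifest must be a list of entries")
    base = os.path.dirname(os.path.abspath(manifest_path))
    bundle = AnnotationBundle()
    for entry in entries:
        path = entry["path"]
        if not os.path.isabs(path):
            path = os.path.join(base, path)
        bundle.add(load_annotation_db(path, entry["name"], entry["category"]))
    return bundle


def retrieve_annotations(
    chemical_ids: Iterable[str], bundle: AnnotationBundle
) -> pd.DataFrame:
    """All annotations of the given chemicals across the bundle.

    Returns a DataFrame (chemical_id, database, category, term_id, label),
    sorted by (chemical_id, database, term_id).  Unknown ids contribute zero
    rows; the number of un-annotated input chemicals is logged.
    """
    ids = list(dict.fromkeys(chemical_ids))
    rows = []
    annotated: set[str] = set()
    for db in bundle:
        for cid in ids:
            for term_id in db.chem_to_terms.get(cid, ()):
                annotated.add(cid)
                rows.append(
                    (cid, db.name, db.category, term_id, db.terms[term_id].label)
                )
    df = pd.DataFrame(
        rows, columns=["chemical_id", "database", "category", "term_id", "label"]
    )
    df = df.sort_values(["chemical_id", "database", "term_id"], ignore_index=True)
    logger.info(
        "retrieved %d annotation rows for %d/%d chemicals (%d without annotations)",
        len(df),
        len(annotated),
        len(ids),
        len(ids) - len(annotated),
    )
    return df


def get_synonyms(chemical_id: str, space: ReferenceSpace) -> list[str]:
    """All synonyms of a chemical, sorted, preferred name first."""
    rec = space.records.get(chemical_id)
    if rec is None:
        raise KeyError(f"unknown chemical_id {chemical_id!r}")
    names = sorted(rec.synonym_names())
    if rec.preferred_name in names:
        names.remove(rec.preferred_name)
        names.insert(0, rec.preferred_name)
    return names


class CoverageSummary(NamedTuple):
    per_database: pd.DataFrame
    coverage_histogram: dict[int, int]


def coverage_summary(bundle: AnnotationBundle) -> CoverageSummary:
    """Per-database chemical/term counts plus a cumulative coverage histogram.

    The histogram entry ``h[k]`` counts chemicals annotated in at least ``k``
    of the bundle's databases (k = 1..|bundle|).
    """
    rows = [
        (db.name, db.category, db.n_chemicals, db.n_terms) for db in bundle
    ]
    per_db = pd.DataFrame(
        rows, columns=["database", "category", "n_chemicals", "n_terms"]
    )
    db_count: dict[str, int] = {}
    for db in bundle:
        for cid in db.annotated_chemicals():
            db_count[cid] = db_count.get(cid, 0) + 1
    hist = {
        k: sum(1 for v in db_count.values() if v >= k)
        for k in range(1, len(bundle) + 1)
    }
    return CoverageSummary(per_db, hist)
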