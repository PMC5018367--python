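"""Chemical reference space: records, TSV serialization and synthetic fixtures.

The reference space is the unified set of chemical identifiers together with
all their synonyms and structural keys (InChIKeys, SMILES).  User-supplied
names are disambiguated *into* this space; everything downstream (annotation
retrieval, enrichment, networks) operates on its identifiers.

Real deployments would populate the space from a large public aggregate of
chemical synonyms; this module also ships a seeded generator that produces
realistic fixture spaces (pronounceable pseudo-names, salt/acid synonym
families, InChIKey-shaped structural keys) so the whole toolkit can be
exercised and benchmarked without any external download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._text import is_inchikey_shaped, normalize_name

logger = logging.getLogger(__name__)

DICT_HEADER = ("chemical_id", "synonym", "source")
STRUCT_HEADER = ("chemical_id", "key_type", "key")
GOLD_HEADER = ("query", "true_chemical_id")

# Vowel 'e' is kept out of final position and 'z' out of the consonant pool:
# generated names then never end in "-ate"/"-ite" (so the salt/acid suffix
# rules only ever fire on deliberately generated salt synonyms) and a
# "zz"-prefixed injected synonym always sorts after every generated name.
_CONSONANTS = "bcdfghklmnprstv"
_VOWELS = "aeiou"
_FINALS = "nlrsm"
_SMILES_ATOMS = list("CNOSP") + ["Cl", "Br", "c", "n", "o"]


@dataclass
class ChemicalRecord:
    """One chemical in the reference space.

    ``synonyms`` is a set of ``(name, source)`` pairs; ``preferred_name`` is
    the synonym designated for display (by convention the lexicographically
    smallest synonym name, which is also what :func:`load_reference_space`
    reconstructs, so serialization round-trips).
    """

    chemical_id: str
    synonyms: set[tuple[str, str]] = field(default_factory=set)
    inchikeys: set[str] = field(default_factory=set)
    smiles: set[str] = field(default_factory=set)
    preferred_name: str = ""

    def synonym_names(self) -> set[str]:
        return {name for name, _ in self.synonyms}

    def validate(self) -> None:
        if not self.chemical_id:
            raise ValueError("chemical_id must be non-empty")
        if self.synonyms and self.preferred_name not in self.synonym_names():
            raise ValueError(
                f"preferred_name {self.preferred_name!r} is not a synonym of "
                f"{self.chemical_id}"
            )
        for key in self.inchikeys:
            if not is_inchikey_shaped(key):
                raise ValueError(f"invalid InChIKey {key!r} on {self.chemical_id}")


class ReferenceSpace:
    """A collection of :class:`ChemicalRecord` with lookup indexes.

    ``synonym_to_ids`` maps each *normalized* synonym to the set of chemical
    identifiers carrying it; a synonym mapping to more than one identifier is
    ambiguous (permitted, flagged downstream).  ``key_to_id`` maps structural
    keys (InChIKey or SMILES strings, matched by exact string identity) to
    identifier sets.
    """

    def __init__(self, records: list[ChemicalRecord] | None = None):
        self.records: dict[str, ChemicalRecord] = {}
        self.synonym_to_ids: dict[str, set[str]] = {}
        self.key_to_id: dict[str, set[str]] = {}
        for rec in records or []:
            self.add_record(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceSpace):
            return NotImplemented
        return self.records == other.records

    def add_record(self, rec: ChemicalRecord) -> None:
        if rec.synonyms and not rec.preferred_name:
            rec.preferred_name = min(rec.synonym_names())
        rec.validate()
        if rec.chemical_id in self.records:
            raise ValueError(f"duplicate chemical_id {rec.chemical_id!r}")
        self.records[rec.chemical_id] = rec
        for name, _src in rec.synonyms:
            self.synonym_to_ids.setdefault(normalize_name(name), set()).add(
                rec.chemical_id
            )
        for key in rec.inchikeys | rec.smiles:
            self.key_to_id.setdefault(key, set()).add(rec.chemical_id)

    def rebuild_synonym_index(self) -> dict[str, set[str]]:
        """Recompute the synonym index from the records (consistency check)."""
        index: dict[str, set[str]] = {}
        for rec in self.records.values():
            for name, _src in rec.synonyms:
                index.setdefault(normalize_name(name), set()).add(rec.chemical_id)
        return index

    @property
    def n_synonyms(self) -> int:
        return sum(len(r.synonyms) for r in self.records.values())


@dataclass
class GoldStandard:
    """Query strings paired with their true chemical identifiers."""

    pairs: list[tuple[str, str]]
    provenance: str = ""


# ---------------------------------------------------------------------------
# TSV serialization
# ---------------------------------------------------------------------------


def _read_tsv_rows(path: str, header: tuple[str, ...]) -> list[tuple[int, list[str]]]:
    try:
        fh = open(path, encoding="utf-8")
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"no such file: {path}") from exc
    with fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file, expected header {list(header)}")
    got = tuple(lines[0].split("\t"))
    if got != header:
        raise ValueError(f"{path}: bad header {got!r}, expected {header!r}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
            )
        rows.append((lineno, fields))
    return rows


def load_reference_space(
    dictionary_path: str, structures_path: str | None = None
) -> ReferenceSpace:
    """Load a reference space from its dictionary (and optional structures) TSV.

    Duplicate ``(chemical_id, synonym)`` rows collapse to a single entry.
    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` (with
    the offending line number) for malformed rows or invalid InChIKeys.
    """
    by_id: dict[str, ChemicalRecord] = {}
    n_rows = 0
    for _lineno, (cid, synonym, source) in _read_tsv_rows(dictionary_path, DICT_HEADER):
        rec = by_id.setdefault(cid, ChemicalRecord(chemical_id=cid))
        rec.synonyms.add((synonym, source))
        n_rows += 1
    if structures_path is not None:
        for lineno, (cid, key_type, key) in _read_tsv_rows(
            structures_path, STRUCT_HEADER
        ):
            rec = by_id.setdefault(cid, ChemicalRecord(chemical_id=cid))
            if key_type == "inchikey":
                if not is_inchikey_shaped(key):
                    raise ValueError(
                        f"{structures_path}:{lineno}: invalid InChIKey {key!r}"
                    )
                rec.inchikeys.add(key)
            elif key_type == "smiles":
                rec.smiles.add(key)
            else:
                raise ValueError(
                    f"{structures_path}:{lineno}: unknown key_type {key_type!r}"
                )
    space = ReferenceSpace()
    for cid in sorted(by_id):
        rec = by_id[cid]
        if rec.synonyms:
            rec.preferred_name = min(rec.synonym_names())
        space.add_record(rec)
    logger.info(
        "loaded %d dictionary rows into %d records", n_rows, len(space.records)
    )
    return space


def write_reference_space(
    space: ReferenceSpace, dictionary_path: str, structures_path: str | None = None
) -> None:
    """Write a space back to TSV; rows are sorted so output is deterministic."""
    with open(dictionary_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(DICT_HEADER) + "\n")
        for cid in sorted(space.records):
            for name, source in sorted(space.records[cid].synonyms):
                fh.write(f"{cid}\t{name}\t{source}\n")
    if structures_path is not None:
        with open(structures_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(STRUCT_HEADER) + "\n")
            for cid in sorted(space.records):
                rec = space.records[cid]
                rows = [("inchikey", k) for k in sorted(rec.inchikeys)]
                rows += [("smiles", k) for k in sorted(rec.smiles)]
                for key_type, key in rows:
                    fh.write(f"{cid}\t{key_type}\t{key}\n")


def write_gold_standard(gold: GoldStandard, path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(GOLD_HEADER) + "\n")
        for query, cid in gold.pairs:
            fh.write(f"{query}\t{cid}\n")


def load_gold_standard(path: str) -> GoldStandard:
    pairs = [
        (q, cid) for _ln, (q, cid) in _read_tsv_rows(path, GOLD_HEADER)
    ]
    return GoldStandard(pairs=pairs, provenance=f"loaded from {path}")


# ---------------------------------------------------------------------------
# Synthetic fixture generation
# ---------------------------------------------------------------------------


def _pseudo_name(rng: np.random.Generator, used: set[str]) -> str:
    """A pronounceable pseudo-name, unique within ``used``.

    Built from consonant-vowel syllables plus a final consonant, 7-11
    characters: long enough that a single-character typo keeps the edit
    similarity above typical acceptance thresholds.
    """
    while True:
        n_syll = int(rng.integers(3, 6))
        name = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syll)
        ) + _FINALS[rng.integers(len(_FINALS))]
        if name not in used:
            used.add(name)
            return name


def _synthetic_inchikey(rng: np.random.Generator) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    pick = lambda n: "".join(letters[i] for i in rng.integers(0, 26, size=n))
    return f"{pick(14)}-{pick(10)}-{pick(1)}"


def _synthetic_smiles(rng: np.random.Generator) -> str:
    n = int(rng.integers(6, 16))
    return "".join(_SMILES_ATOMS[i] for i in rng.integers(0, len(_SMILES_ATOMS), n))


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

# Counterions used as prefixes on generated salt synonyms (cation-like only).
_SALT_PREFIX_IONS = ("sodium", "potassium", "calcium", "magnesium")


def generate_fixture_space(
    n_chemicals: int,
    synonyms_per_chemical: int,
    salt_fraction: float,
    seed: int,
) -> ReferenceSpace:
    """Generate a deterministic synthetic reference space.

    Each chemical gets ``synonyms_per_chemical`` pseudo-name synonyms, one
    InChIKey-shaped key and one SMILES-like key.  A ``salt_fraction`` of
    chemicals additionally carries a salt/acid synonym family derived from a
    fresh stem: ``<stem>ic acid``, ``<stem>ate`` and a counterion-prefixed
    ``<ion> <stem>ate`` variant.
    """
    if n_chemicals <= 0 or synonyms_per_chemical <= 0:
        raise ValueError("n_chemicals and synonyms_per_chemical must be positive")
    if not 0.0 <= salt_fraction <= 1.0:
        raise ValueError("salt_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    space = ReferenceSpace()
    for i in range(n_chemicals):
        cid = f"CID{i + 1:09d}"
        synonyms = {
            (_pseudo_name(rng, used), "synthetic")
            for _ in range(synonyms_per_chemical)
        }
        if rng.random() < salt_fraction:
            stem = _pseudo_name(rng, used)
            ion = _SALT_PREFIX_IONS[rng.integers(len(_SALT_PREFIX_IONS))]
            synonyms |= {
                (f"{stem}ic acid", "salt_rule"),
                (f"{stem}ate", "salt_rule"),
                (f"{ion} {stem}ate", "salt_rule"),
            }
        rec = ChemicalRecord(
            chemical_id=cid,
            synonyms=synonyms,
            inchikeys={_synthetic_inchikey(rng)},
            smiles={_synthetic_smiles(rng)},
        )
        rec.preferred_name = min(rec.synonym_names())
        space.add_record(rec)
    return space


_TYPO_OPS = ("substitute", "delete", "insert", "transpose")
_TYPO_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def _apply_typo(name: str, rng: np.random.Generator) -> str:
    """Apply exactly one random single-character edit to ``name``."""
    op = _TYPO_OPS[rng.integers(4)]
    if len(name) < 2 and op in ("delete", "transpose"):
        op = "substitute"
    if op == "substitute":
        pos = int(rng.integers(len(name)))
        choices = [c for c in _TYPO_ALPHABET if c != name[pos]]
        return name[:pos] + choices[rng.integers(len(choices))] + name[pos + 1 :]
    if op == "delete":
        pos = int(rng.integers(len(name)))
        return name[:pos] + name[pos + 1 :]
    if op == "insert":
        pos = int(rng.integers(len(name) + 1))
        return name[:pos] + _TYPO_ALPHABET[rng.integers(26)] + name[pos:]
    pos = int(rng.integers(len(name) - 1))  # adjacent transposition
    return name[:pos] + name[pos + 1] + name[pos] + name[pos + 2 :]


def generate_gold_standard(
    space: ReferenceSpace, n_queries: int, typo_rate: float, seed: int
) -> GoldStandard:
    """Sample (possibly typo-perturbed) queries with known true identifiers.

    Synonyms are sampled with replacement across all records; with
    probability ``typo_rate`` a single random character edit (substitution,
    deletion, insertion or adjacent transposition) is applied.  The true
    identifier is that of the record the unperturbed synonym was drawn from.
    """
    if not space.records:
        raise ValueError("reference space is empty")
    if n_queries <= 0:
        raise ValueError("n_queries must be positive")
    if not 0.0 <= typo_rate <= 0.5:
        raise ValueError("typo_rate must lie in [0, 0.5]")
    pool = [
        (name, cid)
        for cid in sorted(space.records)
        for name in sorted(space.records[cid].synonym_names())
    ]
    rng = np.random.default_rng(seed)
    pairs = []
    for idx in rng.integers(0, len(pool), size=n_queries):
        name, cid = pool[int(idx)]
        if rng.random() < typo_rate:
            name = _apply_typo(name, rng)
        pairs.append((name, cid))
    return GoldStandard(
        pairs=pairs,
        provenance=(
            f"synthetic: {n_queries} queries, typo_rate={typo_rate}, seed={seed}"
        ),
    )
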