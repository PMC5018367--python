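"""End-to-end workflow: match -> curate -> annotate -> enrich -> network.

Also home of the workspace simulator, which emits a complete synthetic
analysis workspace (dictionary, structures, an annotation bundle with one
planted enriched term, a query list exercising every match type, a
background list and a gold standard) so the whole pipeline runs with no
external data.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import yaml

from . import __version__
from .annotation_store import (
    AnnotationBundle,
    AnnotationDatabase,
    load_bundle,
    retrieve_annotations,
    write_annotation_db,
)
from .enrichment import EnrichmentResult, run_enrichment, write_enrichment_table
from .name_matcher import (
    MatcherConfig,
    MatchResult,
    evaluate_matching,
    export_match_table,
    import_curated_table,
    match_all,
    read_query_file,
)
from .network_export import build_network, write_network
from .reference_space import (
    ReferenceSpace,
    generate_fixture_space,
    generate_gold_standard,
    load_reference_space,
    write_gold_standard,
    write_reference_space,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    dictionary: str
    manifest: str
    queries: str
    outdir: str
    structures: str | None = None
    background: str = "auto"  # "auto" or a path to a background query list
    matcher: MatcherConfig = field(default_factory=MatcherConfig)
    alpha: float = 0.05
    min_term_size: int = 2
    strict_background: bool = False

    def validate(self) -> None:
        for label, path in (
            ("dictionary", self.dictionary),
            ("manifest", self.manifest),
            ("queries", self.queries),
        ):
            if not os.path.exists(path):
                raise FileNotFoundError(f"{label} file not found: {path}")
        if self.structures is not None and not os.path.exists(self.structures):
            raise FileNotFoundError(f"structures file not found: {self.structures}")
        if self.background != "auto" and not os.path.exists(self.background):
            raise FileNotFoundError(f"background file not found: {self.background}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p):
            if p in (None, "auto") or os.path.isabs(p):
                return p
            return os.path.join(base, p)

        matcher = MatcherConfig(**raw.pop("matcher", {}))
        for key in ("dictionary", "structures", "manifest", "queries", "background"):
            if key in raw and raw[key] is not None:
                raw[key] = resolve(raw[key])
        raw["outdir"] = resolve(raw.get("outdir", "."))
        return cls(matcher=matcher, **raw)


class PipelineOutputs(NamedTuple):
    matches_path: str
    annotations_path: str
    enrichment_path: str
    network_path: str
    log_path: str
    match_results: list[MatchResult]
    input_ids: list[str]
    enrichment_results: list[EnrichmentResult]


def _resolved_ids(results: list[MatchResult]) -> list[str]:
    """Uniquely matched ids, deduplicated, in first-seen order.

    Ambiguous and unmatched results are excluded: only resolved identifiers
    can enter annotation retrieval and enrichment.
    """
    seen: dict[str, None] = {}
    for r in results:
        uid = r.unique_id()
        if uid is not None:
            seen.setdefault(uid)
    return list(seen)


def run_pipeline(config: PipelineConfig) -> PipelineOutputs:
    """Run the full workflow and write its artifact files.

    If a curated table (``matches.curated.tsv``) exists beside the match
    table in the output directory, it replaces the automatic matches —
    that file is the curation round-trip.  All outputs are deterministic
    for equal inputs.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)
    log_lines = [f"chemannot {__version__}"]

    space = load_reference_space(config.dictionary, config.structures)
    log_lines.append(
        f"reference space: {len(space)} records, {space.n_synonyms} synonyms"
    )

    queries = [q for _label, q in read_query_file(config.queries)]
    results = match_all(queries, space, config.matcher)
    export_match_table(results, out("matches.tsv"))
    curated_path = out("matches.curated.tsv")
    if os.path.exists(curated_path):
        results = import_curated_table(curated_path, space)
        log_lines.append(f"curation: imported {curated_path}")
    from collections import Counter

    counts = Counter(r.match_type for r in results)
    log_lines.append(
        f"matching: {len(queries)} queries -> "
        + ", ".join(f"{t}={c}" for t, c in sorted(counts.items()))
    )

    input_ids = _resolved_ids(results)
    log_lines.append(f"resolved input set: {len(input_ids)} chemicals")

    bundle = load_bundle(config.manifest)
    annotations = retrieve_annotations(input_ids, bundle)
    annotations.to_csv(out("annotations.tsv"), sep="\t", index=False, lineterminator="\n")
    log_lines.append(
        f"annotation: {len(bundle)} databases, {len(annotations)} annotation rows"
    )

    if config.background == "auto":
        background: set[str] | str = "auto"
        log_lines.append("background: auto (all annotated chemicals)")
    else:
        bg_queries = [q for _l, q in read_query_file(config.background)]
        bg_results = match_all(bg_queries, space, config.matcher)
        background = set(_resolved_ids(bg_results))
        log_lines.append(
            f"background: {len(bg_queries)} queries -> {len(background)} chemicals"
        )

    enr = run_enrichment(
        set(input_ids),
        background,
        bundle,
        alpha=config.alpha,
        min_term_size=config.min_term_size,
        strict_background=config.strict_background,
    )
    write_enrichment_table(enr, out("enrichment.tsv"))
    n_enriched = sum(r.enriched for r in enr)
    log_lines.append(
        f"enrichment: {len(enr)} tests, {n_enriched} enriched at alpha={config.alpha}"
    )

    net = build_network(enr, only_enriched=True, space=space)
    write_network(net, out("network.json"), "json_graph")
    log_lines.append(
        f"network: {len(net.node_ids('chemical'))} chemicals, "
        f"{len(net.node_ids('term'))} terms, {len(net.edges)} edges"
    )

    with open(out("run_log.txt"), "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return PipelineOutputs(
        matches_path=out("matches.tsv"),
        annotations_path=out("annotations.tsv"),
        enrichment_path=out("enrichment.tsv"),
        network_path=out("network.json"),
        log_path=out("run_log.txt"),
        match_results=results,
        input_ids=input_ids,
        enrichment_results=enr,
    )


# ---------------------------------------------------------------------------
# Workspace simulation
# ---------------------------------------------------------------------------


class Workspace(NamedTuple):
    """Paths and ground truth of a simulated analysis workspace."""

    outdir: str
    config_path: str
    dictionary: str
    structures: str
    manifest: str
    queries: str
    background: str
    gold: str
    input_ids: list[str]
    planted_term: tuple[str, str]  # (database, term_id)


# Fixed study conditions of the simulated workspace.
N_CHEMICALS = 120
SYNONYMS_PER_CHEMICAL = 3
SALT_FRACTION = 0.25
N_INPUT = 10
PLANTED_DB, PLANTED_TERM = "TARGETS", "PTGS"

_SALT_IONS = ("sodium", "potassium", "calcium", "magnesium")


def _salt_stem(rec) -> str | None:
    for name in sorted(rec.synonym_names()):
        if name.endswith("ic acid"):
            return name[:-7]
    return None


def _random_term_block(
    rng: np.random.Generator,
    db: AnnotationDatabase,
    term_ids: list[str],
    all_ids: list[str],
    k_range: tuple[int, int],
) -> None:
    for term_id in term_ids:
        size = int(rng.integers(k_range[0], k_range[1] + 1))
        carriers = rng.choice(len(all_ids), size=size, replace=False)
        for idx in carriers:
            db.add(all_ids[int(idx)], term_id, term_id.lower())


def simulate_workspace(outdir: str, seed: int = 0) -> Workspace:
    """Emit a complete synthetic workspace under ``outdir``.

    The workspace contains a 120-chemical reference space, a three-database
    annotation bundle (molecular targets, therapeutic classes, side effects)
    with one planted term carried by exactly the 10 input chemicals, a query
    list that exercises every match type (exact, salt/acid, approximate,
    structural, ambiguous, unmatched), a background list naming every
    chemical, a gold standard and a ready-to-run pipeline config.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    space = generate_fixture_space(
        N_CHEMICALS, SYNONYMS_PER_CHEMICAL, SALT_FRACTION, seed=int(rng.integers(2**31))
    )
    all_ids = sorted(space.records)

    # Input chemicals: prefer two with salt-form synonyms so the query list
    # can exercise the salt/acid stage.
    salt_ids = [cid for cid in all_ids if _salt_stem(space.records[cid])]
    plain_ids = [cid for cid in all_ids if cid not in set(salt_ids[:2])]
    chosen = list(salt_ids[:2])
    extra = rng.choice(len(plain_ids), size=N_INPUT - len(chosen), replace=False)
    chosen += [plain_ids[int(i)] for i in sorted(extra)]
    input_ids = chosen  # salt-form chemicals first: query slots 0-1 use them

    # Ambiguous synonym: inject one shared name into two non-input chemicals.
    # "zz"-prefixed, so it can never become a record's preferred name.
    non_input = [cid for cid in all_ids if cid not in set(input_ids)]
    shared = "zz" + "".join("bdglmnprst"[int(i)] for i in rng.integers(0, 10, 6))
    amb_pair = [non_input[int(i)] for i in rng.choice(len(non_input), 2, replace=False)]
    rebuilt = ReferenceSpace()
    for cid in all_ids:
        rec = space.records[cid]
        if cid in amb_pair:
            rec.synonyms.add((shared, "synthetic"))
        rebuilt.add_record(rec)
    space = rebuilt

    dictionary = os.path.join(outdir, "dictionary.tsv")
    structures = os.path.join(outdir, "structures.tsv")
    write_reference_space(space, dictionary, structures)

    # Annotation bundle with the planted enriched term.
    targets = AnnotationDatabase("TARGETS", "molecular_target")
    for cid in input_ids:
        targets.add(cid, PLANTED_TERM, "prostaglandin-endoperoxide synthase")
    _random_term_block(
        rng, targets, [f"GENE{i:02d}" for i in range(1, 13)], all_ids, (5, 25)
    )
    atc = AnnotationDatabase("ATC", "therapeutic_class")
    atc_extra = [non_input[int(i)] for i in rng.choice(len(non_input), 2, replace=False)]
    for cid in input_ids + atc_extra:
        atc.add(cid, "M01A", "anti-inflammatory, non-steroid")
    _random_term_block(
        rng, atc, [f"C{i:02d}X" for i in range(1, 11)], all_ids, (5, 25)
    )
    sidefx = AnnotationDatabase("SIDEFX", "side_effect")
    for cid in input_ids[:7]:
        sidefx.add(cid, "nephritis", "nephritis")
    for cid in input_ids[3:10]:
        sidefx.add(cid, "vasculitis", "vasculitis")
    for cid in (non_input[int(i)] for i in rng.choice(len(non_input), 3, replace=False)):
        sidefx.add(cid, "nephritis", "nephritis")
    _random_term_block(
        rng, sidefx, [f"effect{i:02d}" for i in range(1, 11)], all_ids, (5, 30)
    )

    manifest = os.path.join(outdir, "manifest.yaml")
    entries = []
    for db, fname in ((targets, "targets.tsv"), (atc, "atc.tsv"), (sidefx, "sidefx.tsv")):
        write_annotation_db(db, os.path.join(outdir, fname))
        entries.append({"path": fname, "name": db.name, "category": db.category})
    with open(manifest, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(entries, fh, sort_keys=True)

    # Query list exercising every match type.  Input chemicals resolve
    # uniquely; the ambiguous and unmatched queries contribute nothing to
    # the enrichment input set.
    query_lines = ["# simulated query list"]
    for pos, cid in enumerate(input_ids):
        rec = space.records[cid]
        stem = _salt_stem(rec)
        if pos < 2 and stem is not None:
            own = {n.split(" ")[0] for n, _s in rec.synonyms if " " in n}
            ion = next(i for i in _SALT_IONS if i not in own)
            query_lines.append(f"{ion} {stem}ate")  # salt/acid stage
        elif pos in (2, 3):
            name = rec.preferred_name
            p = int(rng.integers(len(name)))
            sub = "abcdefghijklmnopqrstuvwxyz"[int(rng.integers(26))]
            while sub == name[p]:
                sub = "abcdefghijklmnopqrstuvwxyz"[int(rng.integers(26))]
            query_lines.append(name[:p] + sub + name[p + 1 :])  # approximate
        elif pos == 4:
            query_lines.append(sorted(rec.inchikeys)[0])  # structural
        else:
            query_lines.append(rec.preferred_name)  # exact
    query_lines.append(shared)  # ambiguous
    query_lines.append("xqxqxqxqxq")  # unmatched
    queries = os.path.join(outdir, "queries.txt")
    with open(queries, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(query_lines) + "\n")

    background = os.path.join(outdir, "background.txt")
    with open(background, "w", encoding="utf-8", newline="\n") as fh:
        for cid in all_ids:
            fh.write(space.records[cid].preferred_name + "\n")

    gold = os.path.join(outdir, "gold.tsv")
    write_gold_standard(
        generate_gold_standard(space, 200, 0.1, seed=int(rng.integers(2**31))), gold
    )

    config_path = os.path.join(outdir, "config.yaml")
    with open(config_path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(
            {
                "dictionary": "dictionary.tsv",
                "structures": "structures.tsv",
                "manifest": "manifest.yaml",
                "queries": "queries.txt",
                "background": "background.txt",
                "outdir": "results",
            },
            fh,
            sort_keys=True,
        )
    return Workspace(
        outdir=outdir,
        config_path=config_path,
        dictionary=dictionary,
        structures=structures,
        manifest=manifest,
        queries=queries,
        background=background,
        gold=gold,
        input_ids=input_ids,
        planted_term=(PLANTED_DB, PLANTED_TERM),
    )
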