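"""A hand-built NSAID demonstration workspace (synthetic toy data).

Twelve drugs — six non-steroidal anti-inflammatory compounds and six
unrelated background drugs — with a small three-database annotation bundle.
The NSAID input set is enriched for the PTGS2 molecular target, the M01A
therapeutic class and the nephritis/vasculitis side effects, so the demo
reproduces the qualitative structure of a typical enrichment network.

All annotations here are toy curations for demonstration and testing, not
excerpts of any real database.
"""

from __future__ import annotations

from .annotation_store import AnnotationBundle, AnnotationDatabase
from .reference_space import ChemicalRecord, ReferenceSpace

ASPIRIN = "CID000002244"
SALICYLIC_ACID = "CID000000338"
IBUPROFEN = "CID000003672"
NAPROXEN = "CID000156391"
DICLOFENAC = "CID000003033"
CELECOXIB = "CID000002662"
PARACETAMOL = "CID000001983"
OMEPRAZOLE = "CID000004594"
METFORMIN = "CID000004091"
ATORVASTATIN = "CID000060823"
SERTRALINE = "CID000068617"
LORATADINE = "CID000003957"

NSAIDS = (ASPIRIN, SALICYLIC_ACID, IBUPROFEN, NAPROXEN, DICLOFENAC, CELECOXIB)

# Structural keys (14-10-1 uppercase-letter InChIKey layout).
_KEYS = {
    ASPIRIN: "BSYNRYMUTXBXSQ-UHFFFAOYSA-N",
    NAPROXEN: "CMWTZPSULFXXJA-VIFPVBQESA-N",
}

_RECORDS: dict[str, tuple[list[str], str | None]] = {
    ASPIRIN: (["aspirin", "acetylsalicylic acid", "asa"], "CC(=O)Oc1ccccc1C(=O)O"),
    SALICYLIC_ACID: (["salicylic acid", "2-hydroxybenzoic acid"], "O=C(O)c1ccccc1O"),
    IBUPROFEN: (["ibuprofen"], "CC(C)Cc1ccc(C(C)C(=O)O)cc1"),
    NAPROXEN: (["naproxen"], None),
    DICLOFENAC: (["diclofenac"], None),
    CELECOXIB: (["celecoxib"], None),
    PARACETAMOL: (["paracetamol", "acetaminophen"], None),
    OMEPRAZOLE: (["omeprazole"], None),
    METFORMIN: (["metformin"], None),
    ATORVASTATIN: (["atorvastatin"], None),
    SERTRALINE: (["sertraline"], None),
    LORATADINE: (["loratadine"], None),
}


def nsaid_space() -> ReferenceSpace:
    space = ReferenceSpace()
    for cid, (names, smiles) in _RECORDS.items():
        rec = ChemicalRecord(
            chemical_id=cid,
            synonyms={(n, "demo") for n in names},
            inchikeys={_KEYS[cid]} if cid in _KEYS else set(),
            smiles={smiles} if smiles else set(),
            preferred_name=names[0] if names[0] == min(names) else min(names),
        )
        space.add_record(rec)
    return space


def nsaid_bundle() -> AnnotationBundle:
    targets = AnnotationDatabase("TARGETS", "molecular_target")
    for cid in NSAIDS:
        targets.add(cid, "PTGS2", "prostaglandin-endoperoxide synthase 2")
    targets.add(ATORVASTATIN, "HMGCR", "HMG-CoA reductase")
    targets.add(SERTRALINE, "SLC6A4", "serotonin transporter")
    targets.add(OMEPRAZOLE, "ATP4A", "gastric proton pump")
    targets.add(LORATADINE, "HRH1", "histamine H1 receptor")
    targets.add(METFORMIN, "PRKAA1", "AMP-activated kinase")
    targets.add(PARACETAMOL, "PTGS1", "prostaglandin-endoperoxide synthase 1")

    atc = AnnotationDatabase("ATC", "therapeutic_class")
    for cid in (ASPIRIN, IBUPROFEN, NAPROXEN, DICLOFENAC, CELECOXIB):
        atc.add(cid, "M01A", "anti-inflammatory, non-steroids")
    atc.add(ASPIRIN, "N02B", "other analgesics and antipyretics")
    atc.add(PARACETAMOL, "N02B", "other analgesics and antipyretics")
    atc.add(OMEPRAZOLE, "A02BC", "proton pump inhibitors")
    atc.add(METFORMIN, "A10BA", "biguanides")
    atc.add(ATORVASTATIN, "C10AA", "HMG-CoA reductase inhibitors")
    atc.add(SERTRALINE, "N06AB", "selective serotonin reuptake inhibitors")
    atc.add(LORATADINE, "R06AX", "antihistamines for systemic use")

    sider = AnnotationDatabase("SIDEFX", "side_effect")
    for cid in (ASPIRIN, SALICYLIC_ACID, IBUPROFEN, NAPROXEN, DICLOFENAC):
        sider.add(cid, "nephritis", "nephritis")
    for cid in (ASPIRIN, IBUPROFEN, NAPROXEN, DICLOFENAC, CELECOXIB):
        sider.add(cid, "vasculitis", "vasculitis")
    for cid in (
        ASPIRIN,
        IBUPROFEN,
        SALICYLIC_ACID,
        CELECOXIB,
        PARACETAMOL,
        OMEPRAZOLE,
        METFORMIN,
        SERTRALINE,
    ):
        sider.add(cid, "nausea", "nausea")

    bundle = AnnotationBundle()
    for db in (targets, atc, sider):
        bundle.add(db)
    return bundle


#: Queries exercising the exact, salt/acid, approximate and structural stages.
DEMO_QUERIES = (
    "Aspirin",
    "salicylate",
    "ibuprofin",
    _KEYS[NAPROXEN],
    "diclofenac",
    "celecoxib",
)

#: The screened library: every demo chemical.
DEMO_BACKGROUND = tuple(sorted(_RECORDS))
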