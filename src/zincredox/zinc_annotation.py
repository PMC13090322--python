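"""Per-protein zinc-binding calls from annotation sources and coordination classes.

Evidence sources mirror the annotation channels of UniProt-style exports
(GO molecular-function terms, Cofactor text, Binding-site ligands,
Zinc-finger regions, Keywords) plus structure-derived zinc-site tables
keyed by PDB cross-references.  The per-protein verdict is the union over
sources; per-source provenance is retained.
"""

from __future__ import annotations

import io
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence, TextIO

import math

import pandas as pd

from .proteome_io import ProteinRecord, Proteome

__all__ = [
    "EvidenceSource",
    "CoordinationClass",
    "ZincEvidence",
    "ZincCall",
    "extract_zinc_evidence",
    "merge_evidence",
    "classify_coordination",
    "zbp_fraction",
    "load_structure_table",
]


class EvidenceSource(str, Enum):
    GO_MF = "GO_MF"
    COFACTOR = "Cofactor"
    BINDING_SITE = "BindingSite"
    ZINC_FINGER = "ZincFinger"
    KEYWORDS = "Keywords"
    STRUCTURE_TABLE = "StructureTable"


class CoordinationClass(str, Enum):
    C4 = "C4"
    C3H1 = "C3H1"
    C2H2 = "C2H2"
    OTHER = "Other"


@dataclass(frozen=True)
class ZincEvidence:
    source: EvidenceSource
    is_zinc_binding: bool
    sites: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.sites and not self.is_zinc_binding:
            raise ValueError("sites may be non-empty only on positive evidence")


@dataclass
class CoordinationSite:
    residues: tuple[str, ...]
    coordination_class: CoordinationClass
    source: str = ""


@dataclass
class ZincCall:
    accession: str
    is_zinc_binding: bool
    evidence: list[ZincEvidence] = field(default_factory=list)
    coordination_sites: list[CoordinationSite] = field(default_factory=list)


def classify_coordination(residues: Iterable[str]) -> CoordinationClass:
    """Classify one zinc site from the multiset of its ligand residues.

    ``{C,C,C,C}`` is C4, ``{C,C,C,H}`` C3H1, ``{C,C,H,H}`` C2H2; every
    other composition (1-8 ligands) is Other.  Order-insensitive.
    """
    counts = Counter(r.upper() for r in residues)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("empty residue multiset")
    if n > 8:
        raise ValueError(f"implausible coordination number {n}")
    if counts == Counter("CCCC"):
        return CoordinationClass.C4
    if counts == Counter("CCCH"):
        return CoordinationClass.C3H1
    if counts == Counter("CCHH"):
        return CoordinationClass.C2H2
    return CoordinationClass.OTHER


def extract_zinc_evidence(record: ProteinRecord) -> list[ZincEvidence]:
    """Scan one record's annotation channels for zinc-binding evidence.

    Matching is case-insensitive substring search: "zinc" in GO MF term
    names and keywords, "Zn" in Cofactor text and binding-site ligand
    labels; any zinc-finger region counts as positive.  Binding-site
    evidence carries (position, residue-at-position) pairs; positions
    outside the sequence are skipped with a warning.
    """
    ev: list[ZincEvidence] = []
    ev.append(ZincEvidence(EvidenceSource.GO_MF,
                           any("zinc" in t.lower() for t in record.go_mf_terms)))
    ev.append(ZincEvidence(EvidenceSource.COFACTOR, "zn" in record.cofactor_text.lower()))

    sites = []
    positive = False
    for pos, ligand in record.binding_site_entries:
        if "zn" not in ligand.lower():
            continue
        positive = True
        if 1 <= pos <= len(record.sequence):
            sites.append((pos, record.sequence[pos - 1]))
        else:
            warnings.warn(
                f"{record.accession}: binding-site position {pos} outside sequence; skipped",
                stacklevel=2,
            )
    ev.append(ZincEvidence(EvidenceSource.BINDING_SITE, positive, tuple(sites)))
    ev.append(ZincEvidence(EvidenceSource.ZINC_FINGER, bool(record.zinc_finger_regions)))
    ev.append(ZincEvidence(EvidenceSource.KEYWORDS,
                           any("zinc" in k.lower() for k in record.keywords)))
    return ev


# ---------------------------------------------------------------------------
# structure-derived zinc-site tables

@dataclass(frozen=True)
class StructureSite:
    pdb_id: str
    site_id: str
    residue_letters: str
    positions: tuple[int, ...] = ()


def load_structure_table(stream: TextIO | str) -> list[StructureSite]:
    """Read a structure-derived zinc-site TSV (pdb_id, site_id, residue_letters, positions)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    sites = []
    for _, row in df.iterrows():
        positions = tuple(int(p) for p in str(row.get("positions", "")).split(";") if p.strip())
        sites.append(StructureSite(row["pdb_id"].upper(), str(row.get("site_id", "")),
                                   row["residue_letters"].upper(), positions))
    return sites


def merge_evidence(
    evidence_by_accession: dict[str, list[ZincEvidence]],
    structure_table: Sequence[StructureSite] | None = None,
    proteome: Proteome | None = None,
) -> tuple[list[ZincCall], list[StructureSite]]:
    """Merge per-source evidence into one ZincCall per accession (union semantics).

    Structure-table sites are attached through each record's PDB
    cross-references (``proteome`` required for the mapping) and both flip
    the verdict positive and populate coordination sites.  Sites whose PDB
    id matches no record are returned in the unmatched report.
    """
    calls: dict[str, ZincCall] = {}
    for acc, evidence in evidence_by_accession.items():
        call = ZincCall(acc, any(e.is_zinc_binding for e in evidence), list(evidence))
        for e in evidence:
            if e.source is EvidenceSource.BINDING_SITE and e.sites:
                residues = tuple(res for _, res in e.sites)
                call.coordination_sites.append(
                    CoordinationSite(residues, classify_coordination(residues), source="BindingSite"))
        calls[acc] = call

    unmatched: list[StructureSite] = []
    if structure_table:
        if proteome is None:
            raise ValueError("a proteome is required to map structure-table PDB ids")
        pdb_to_acc: dict[str, list[str]] = {}
        for record in proteome:
            for pdb in record.pdb_ids:
                pdb_to_acc.setdefault(pdb.upper(), []).append(record.accession)
        for site in structure_table:
            accs = pdb_to_acc.get(site.pdb_id, [])
            if not accs:
                unmatched.append(site)
                continue
            residues = tuple(site.residue_letters)
            for acc in accs:
                call = calls.setdefault(acc, ZincCall(acc, False))
                call.is_zinc_binding = True
                call.evidence.append(ZincEvidence(EvidenceSource.STRUCTURE_TABLE, True))
                call.coordination_sites.append(
                    CoordinationSite(residues, classify_coordination(residues),
                                     source=f"StructureTable:{site.pdb_id}"))
    return list(calls.values()), unmatched


def zbp_fraction(proteome: Proteome, calls: Iterable[ZincCall]) -> float:
    """Fraction of proteome records with a positive zinc-binding call (NaN if empty)."""
    if len(proteome) == 0:
        return math.nan
    accessions = {r.accession for r in proteome}
    positive = {c.accession for c in calls if c.is_zinc_binding} & accessions
    return len(positive) / len(proteome)


def calls_table(calls: Iterable[ZincCall]) -> pd.DataFrame:
    """Flatten calls for TSV export (accession, verdict, sources, classes)."""
    rows = []
    for c in calls:
        rows.append({
            "accession": c.accession,
            "is_zinc_binding": c.is_zinc_binding,
            "positive_sources": ";".join(e.source.value for e in c.evidence if e.is_zinc_binding),
            "coordination_classes": ";".join(s.coordination_class.value for s in c.coordination_sites),
        })
    return pd.DataFrame(rows, columns=["accession", "is_zinc_binding", "positive_sources",
                                       "coordination_classes"])
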