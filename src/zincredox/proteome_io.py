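"""Reading, writing and non-redundancy filtering of UniProt-style proteome exports.

The expected input is a tab-separated export with one row per protein entry
and a header row.  Sequences may live in the table itself or in a FASTA
companion keyed by accession.  List-valued columns (GO terms, keywords,
PDB cross-references) are ``;``-separated; binding sites are encoded as
``pos:ligand`` pairs and zinc-finger regions as ``start-end`` ranges.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

__all__ = [
    "DomainGroup",
    "ProteinRecord",
    "Proteome",
    "ProteomeFormatError",
    "parse_proteome_table",
    "parse_fasta",
    "filter_nonredundant",
    "proteome_summary",
    "write_proteome_table",
    "write_removal_log",
]

_ISOFORM_RE = re.compile(r"-\d+$")

#: canonical internal column names -> accepted header aliases (lower-cased)
DEFAULT_COLUMN_MAP: dict[str, tuple[str, ...]] = {
    "accession": ("accession", "entry"),
    "entry_name": ("entry_name", "entry name"),
    "gene_name": ("gene_name", "gene names (primary)", "gene"),
    "sequence": ("sequence",),
    "reviewed": ("reviewed", "status"),
    "fragment": ("fragment",),
    "ec_number": ("ec_number", "ec number"),
    "go_mf": ("go_mf", "gene ontology (molecular function)"),
    "cofactor": ("cofactor",),
    "binding_site": ("binding_site", "binding site"),
    "zinc_finger": ("zinc_finger", "zinc finger"),
    "keywords": ("keywords",),
    "pdb_ids": ("pdb_ids", "pdb"),
}


class ProteomeFormatError(ValueError):
    """Raised when a proteome table violates the expected dialect."""


class DomainGroup(str, Enum):
    BACTERIA = "Bacteria"
    ARCHAEA = "Archaea"
    PROTISTS = "Protists"
    ARCHAEPLASTIDA = "Archaeplastida"
    FUNGI = "Fungi"
    SIMPLE_ANIMALS = "SimpleAnimals"
    DEUTEROSTOMIA = "Deuterostomia"
    OTHER = "Other"


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry with the annotation fields used downstream."""

    accession: str
    sequence: str
    entry_name: str = ""
    gene_name: str = ""
    reviewed: bool = False
    is_fragment: bool = False
    ec_number: str = ""
    go_mf_terms: tuple[str, ...] = ()
    cofactor_text: str = ""
    binding_site_entries: tuple[tuple[int, str], ...] = ()
    zinc_finger_regions: tuple[tuple[int, int], ...] = ()
    keywords: tuple[str, ...] = ()
    pdb_ids: tuple[str, ...] = ()

    @property
    def is_isoform(self) -> bool:
        """UniProt isoform accessions carry a ``-<n>`` suffix."""
        return bool(_ISOFORM_RE.search(self.accession))

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        for pos, _ in self.binding_site_entries:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"{self.accession}: binding-site position {pos} outside "
                    f"sequence of length {len(self.sequence)}"
                )


@dataclass
class Proteome:
    records: list[ProteinRecord]
    species_id: str = ""
    domain_group: DomainGroup = DomainGroup.OTHER

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dupes = sorted({r.accession for r in self.records if r.accession in seen or seen.add(r.accession)})
        if dupes:
            raise ProteomeFormatError(f"duplicate accessions: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, accession: str) -> ProteinRecord | None:
        for r in self.records:
            if r.accession == accession:
                return r
        return None


# ---------------------------------------------------------------------------
# parsing helpers

def _split_list(text: str) -> tuple[str, ...]:
    return tuple(t.strip() for t in str(text).split(";") if t.strip()) if text else ()


def _parse_binding_sites(text: str) -> tuple[tuple[int, str], ...]:
    out = []
    for chunk in _split_list(text):
        pos_s, _, ligand = chunk.partition(":")
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise ProteomeFormatError(f"bad binding-site entry {chunk!r}") from exc
        out.append((pos, ligand.strip()))
    return tuple(out)


def _parse_regions(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for chunk in _split_list(text):
        start_s, _, end_s = chunk.partition("-")
        try:
            out.append((int(start_s), int(end_s)))
        except ValueError as exc:
            raise ProteomeFormatError(f"bad region entry {chunk!r}") from exc
    return tuple(out)


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    return s in {"1", "true", "yes", "reviewed", "y"}


def parse_fasta(stream: TextIO | str) -> dict[str, str]:
    """Read a FASTA stream into {accession: sequence}.

    Headers in the UniProt ``>db|ACC|NAME`` style yield ``ACC``; bare
    ``>ACC`` headers are used as-is (first whitespace-delimited token).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    seqs: dict[str, list[str]] = {}
    acc: str | None = None
    for line in stream:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            token = line[1:].split()[0]
            parts = token.split("|")
            acc = parts[1] if len(parts) >= 3 else token
            seqs.setdefault(acc, [])
        elif acc is not None:
            seqs[acc].append(line)
    return {a: "".join(chunks).upper() for a, chunks in seqs.items()}


def _resolve_columns(columns: Sequence[str], column_map: Mapping[str, tuple[str, ...]]) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for canonical, aliases in column_map.items():
        for alias in aliases:
            if alias in lower:
                resolved[canonical] = lower[alias]
                break
    return resolved


def parse_proteome_table(
    tsv_stream: TextIO | str,
    fasta_stream: TextIO | str | None = None,
    *,
    species_id: str = "",
    domain_group: DomainGroup = DomainGroup.OTHER,
    column_map: Mapping[str, tuple[str, ...]] | None = None,
) -> Proteome:
    """Parse a tab-separated proteome export (plus optional FASTA companion).

    Raises :class:`ProteomeFormatError` when a required column (accession,
    reviewed status, or sequence without FASTA fallback) is missing, or on
    accession collisions.
    """
    if isinstance(tsv_stream, str):
        tsv_stream = io.StringIO(tsv_stream)
    df = pd.read_csv(tsv_stream, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns, column_map or DEFAULT_COLUMN_MAP)

    for required in ("accession", "reviewed"):
        if required not in cols:
            raise ProteomeFormatError(f"missing required column: {required}")
    fasta = parse_fasta(fasta_stream) if fasta_stream is not None else {}
    if "sequence" not in cols and not fasta:
        raise ProteomeFormatError("missing required column: sequence (and no FASTA companion)")

    records = []
    for idx, row in df.iterrows():
        acc = row[cols["accession"]].strip()
        seq = row[cols["sequence"]].strip().upper() if "sequence" in cols else ""
        if not seq:
            seq = fasta.get(acc, "")
        if not seq:
            raise ProteomeFormatError(f"row {idx + 2}: no sequence for accession {acc!r}")

        def col(name: str) -> str:
            return row[cols[name]] if name in cols else ""

        records.append(
            ProteinRecord(
                accession=acc,
                sequence=seq,
                entry_name=col("entry_name"),
                gene_name=col("gene_name").strip(),
                reviewed=_parse_bool(col("reviewed")),
                is_fragment=_parse_bool(col("fragment")),
                ec_number=col("ec_number").strip(),
                go_mf_terms=_split_list(col("go_mf")),
                cofactor_text=col("cofactor"),
                binding_site_entries=_parse_binding_sites(col("binding_site")),
                zinc_finger_regions=_parse_regions(col("zinc_finger")),
                keywords=_split_list(col("keywords")),
                pdb_ids=_split_list(col("pdb_ids")),
            )
        )
    return Proteome(records, species_id=species_id, domain_group=domain_group)


# ---------------------------------------------------------------------------
# non-redundancy filter

@dataclass(frozen=True)
class RemovalEntry:
    record: ProteinRecord
    rule: str


def filter_nonredundant(proteome: Proteome) -> tuple[Proteome, list[RemovalEntry]]:
    """Apply the ordered non-redundancy rules and return (filtered, removal log).

    Rules, in order:
      1. ``fragment`` — drop entries flagged as sequence fragments;
      2. ``isoform`` — drop isoform accessions (``-<n>`` suffix), keeping canonical;
      3. ``duplicate_sequence`` — collapse exact (case-normalised) duplicate
         sequences to the lexicographically smallest accession;
      4. ``gene_ec_duplicate`` — collapse records sharing a non-empty
         (gene_name, ec_number) pair to one representative;
      5. ``unreviewed_shadowed`` / ``shorter_unreviewed`` — within a gene,
         keep only reviewed entries when any exist, otherwise the longest
         sequence (ties broken by smallest accession).

    Records are processed in accession order so the result is independent of
    input ordering.  Each removed record appears once, tagged with the first
    rule that fired.  The filter is idempotent.
    """
    removed: list[RemovalEntry] = []
    alive = sorted(proteome.records, key=lambda r: r.accession)

    def drop(record: ProteinRecord, rule: str) -> None:
        removed.append(RemovalEntry(record, rule))

    # rule 1: fragments  (drop() returns None, so the record is excluded)
    alive = [r for r in alive if not r.is_fragment or drop(r, "fragment")]

    # rule 2: isoforms
    alive = [r for r in alive if not r.is_isoform or drop(r, "isoform")]

    # rule 3: exact duplicate sequences
    by_seq: dict[str, ProteinRecord] = {}
    for r in alive:
        key = r.sequence.upper()
        if key not in by_seq:
            by_seq[key] = r
        else:
            drop(r, "duplicate_sequence")
    alive = sorted(by_seq.values(), key=lambda r: r.accession)

    # rule 4: same gene name + EC number (both non-empty)
    by_gene_ec: dict[tuple[str, str], ProteinRecord] = {}
    survivors = []
    for r in alive:
        if r.gene_name and r.ec_number:
            key = (r.gene_name, r.ec_number)
            if key in by_gene_ec:
                drop(r, "gene_ec_duplicate")
                continue
            by_gene_ec[key] = r
        survivors.append(r)
    alive = survivors

    # rule 5: reviewed precedence within a gene, else longest sequence
    by_gene: dict[str, list[ProteinRecord]] = {}
    no_gene: list[ProteinRecord] = []
    for r in alive:
        (by_gene.setdefault(r.gene_name, []) if r.gene_name else no_gene).append(r)
    survivors = list(no_gene)
    for members in by_gene.values():
        reviewed = [r for r in members if r.reviewed]
        if reviewed:
            for r in members:
                if not r.reviewed:
                    drop(r, "unreviewed_shadowed")
            survivors.extend(reviewed)
        elif len(members) > 1:
            best = min(members, key=lambda r: (-len(r.sequence), r.accession))
            for r in members:
                if r is not best:
                    drop(r, "shorter_unreviewed")
            survivors.append(best)
        else:
            survivors.extend(members)

    survivors.sort(key=lambda r: r.accession)
    filtered = Proteome(survivors, species_id=proteome.species_id, domain_group=proteome.domain_group)
    return filtered, removed


def proteome_summary(proteome: Proteome) -> dict[str, float]:
    """Counts of total and reviewed entries; fraction is NaN for an empty proteome."""
    n_total = len(proteome)
    n_reviewed = sum(1 for r in proteome if r.reviewed)
    fraction = n_reviewed / n_total if n_total else math.nan
    return {"n_total": n_total, "n_reviewed": n_reviewed, "fraction_reviewed": fraction}


# ---------------------------------------------------------------------------
# writing

def _format_record(r: ProteinRecord) -> dict[str, str]:
    return {
        "accession": r.accession,
        "entry_name": r.entry_name,
        "gene_name": r.gene_name,
        "sequence": r.sequence,
        "reviewed": "yes" if r.reviewed else "no",
        "fragment": "yes" if r.is_fragment else "no",
        "ec_number": r.ec_number,
        "go_mf": ";".join(r.go_mf_terms),
        "cofactor": r.cofactor_text,
        "binding_site": ";".join(f"{p}:{lig}" for p, lig in r.binding_site_entries),
        "zinc_finger": ";".join(f"{a}-{b}" for a, b in r.zinc_finger_regions),
        "keywords": ";".join(r.keywords),
        "pdb_ids": ";".join(r.pdb_ids),
    }


def write_proteome_table(proteome: Proteome, stream: TextIO) -> None:
    """Write a Proteome back to the TSV dialect ``parse_proteome_table`` reads."""
    df = pd.DataFrame([_format_record(r) for r in proteome.records],
                      columns=list(_format_record(ProteinRecord("X", "M")).keys()))
    df.to_csv(stream, sep="\t", index=False)


def write_removal_log(log: Iterable[RemovalEntry], stream: TextIO) -> None:
    df = pd.DataFrame([{"accession": e.record.accession, "rule": e.rule} for e in log],
                      columns=["accession", "rule"])
    df.to_csv(stream, sep="\t", index=False)
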