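"""Packaged reference list of CxxC-containing cytosolic ribosomal proteins.

The budding-yeast families carrying at least one CxxC/CxxxC motif, with
their unified ribosomal nomenclature, paralog letters, and whether zinc
binding is annotated for the family.  Counting paralogs resolves the nine
families into seventeen proteins (eight A/B pairs plus the single-copy
ubiquitin-fusion RPS31).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_ribosomal_cxxc_table", "count_families_and_paralogs", "paralog_accessions"]


def load_ribosomal_cxxc_table() -> pd.DataFrame:
    """The packaged family table (family, unified_name, paralogs, zinc_annotated)."""
    with resources.files("zincredox.data").joinpath("ribosomal_cxxc_yeast.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def paralog_accessions(table: pd.DataFrame) -> list[str]:
    """Paralog-resolved protein names (``RPL34A``, ``RPL34B``, ... ``RPS31``)."""
    names: list[str] = []
    for _, row in table.iterrows():
        letters = [p for p in row["paralogs"].split(";") if p]
        if letters:
            names.extend(f"{row['family']}{p}" for p in letters)
        else:
            names.append(row["family"])
    return names


def count_families_and_paralogs(table: pd.DataFrame | None = None) -> dict[str, int]:
    """Number of motif-carrying families and of paralog-resolved proteins."""
    if table is None:
        table = load_ribosomal_cxxc_table()
    return {
        "n_families": len(table),
        "n_paralog_resolved": len(paralog_accessions(table)),
    }
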