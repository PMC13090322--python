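"""CxxC/CxxxC motif scanning, cysteine statistics, species summaries and
positional residue enrichment around zinc-binding sites.

The enrichment statistic is a one-sided binomial tail on 13-mer windows
centred on annotated zinc-binding residues, against whole-proteome residue
frequencies — a transparent reimplementation of the sequence-logo style of
positional over-representation analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .proteome_io import Proteome
from .zinc_annotation import ZincCall

__all__ = [
    "MotifPattern",
    "MotifHit",
    "SpeciesSummary",
    "EnrichmentResult",
    "scan_motifs",
    "cysteine_content",
    "species_summary",
    "pearson_correlation",
    "site_context_enrichment",
]


class MotifPattern(str, Enum):
    CXXC = "CxxC"     # C-x-x-C : cysteines 3 apart
    CXXXC = "CxxxC"   # C-x-x-x-C : cysteines 4 apart


_SPACING = {MotifPattern.CXXC: 3, MotifPattern.CXXXC: 4}


@dataclass(frozen=True)
class MotifHit:
    accession: str
    pattern: MotifPattern
    start: int                      # 1-based position of the first cysteine
    cys_positions: tuple[int, int]  # 1-based positions of both cysteines

    @property
    def end(self) -> int:
        return self.start + _SPACING[self.pattern]


def scan_motifs(
    sequence: str,
    patterns: Iterable[MotifPattern] = (MotifPattern.CXXC, MotifPattern.CXXXC),
    accession: str = "",
) -> list[MotifHit]:
    """Report every (possibly overlapping) CxxC / CxxxC window in a sequence.

    ``x`` matches any residue, including cysteine, so e.g. ``CCCC``
    contains a single CxxC hit at position 1.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for pattern in patterns:
        gap = _SPACING[pattern]
        for i in range(len(seq) - gap):
            if seq[i] == "C" and seq[i + gap] == "C":
                hits.append(MotifHit(accession, pattern, i + 1, (i + 1, i + 1 + gap)))
    hits.sort(key=lambda h: (h.start, _SPACING[h.pattern]))
    return hits


def cysteine_content(sequence: str) -> dict[str, float]:
    """Cysteine count and percentage of sequence length."""
    if not sequence:
        raise ValueError("empty sequence")
    count = sequence.upper().count("C")
    return {"count": count, "percent_of_length": 100.0 * count / len(sequence)}


@dataclass(frozen=True)
class SpeciesSummary:
    species_id: str
    n_proteins: int
    n_zbp: int
    fraction_zbp: float
    n_with_cys: int
    fraction_with_cys: float
    n_with_cxxc: int
    fraction_with_cxxc: float
    mean_cys_per_protein: float
    n_zbp_with_cxxc: int


def species_summary(
    proteome: Proteome,
    calls: Iterable[ZincCall],
    hits: Iterable[MotifHit],
    cxxc_patterns: tuple[MotifPattern, ...] = (MotifPattern.CXXC,),
) -> SpeciesSummary:
    """Cross-species summary row: ZBP, cysteine and CxxC content of one proteome."""
    n = len(proteome)
    zbp = {c.accession for c in calls if c.is_zinc_binding}
    with_cxxc = {h.accession for h in hits if h.pattern in cxxc_patterns}
    cys_counts = {r.accession: r.sequence.upper().count("C") for r in proteome}
    n_with_cys = sum(1 for c in cys_counts.values() if c > 0)
    return SpeciesSummary(
        species_id=proteome.species_id,
        n_proteins=n,
        n_zbp=len(zbp),
        fraction_zbp=len(zbp) / n if n else float("nan"),
        n_with_cys=n_with_cys,
        fraction_with_cys=n_with_cys / n if n else float("nan"),
        n_with_cxxc=len(with_cxxc),
        fraction_with_cxxc=len(with_cxxc) / n if n else float("nan"),
        mean_cys_per_protein=float(np.mean(list(cys_counts.values()))) if n else float("nan"),
        n_zbp_with_cxxc=len(zbp & with_cxxc),
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Pearson r plus the least-squares trend line (slope, intercept).

    Requires equal lengths >= 3 and nonzero variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    slope, intercept = np.polyfit(x, y, 1)
    return {"r": r, "slope": float(slope), "intercept": float(intercept)}


@dataclass(frozen=True)
class EnrichmentResult:
    position: int          # offset from the zinc-binding residue (position 0)
    residue: str
    foreground_count: int
    foreground_n: int
    background_freq: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _background_frequencies(proteome: Proteome) -> dict[str, float]:
    counts: Counter[str] = Counter()
    for record in proteome:
        counts.update(record.sequence.upper())
    total = sum(counts.values())
    return {aa: c / total for aa, c in counts.items()}


def site_context_enrichment(
    binding_sites: Iterable[tuple[str, int]],
    proteome: Proteome,
    half_window: int = 6,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Positional residue enrichment in windows around zinc-binding residues.

    ``binding_sites`` are (accession, 1-based position) pairs.  Foreground
    windows span ±``half_window`` residues; windows truncated by either
    terminus are dropped and duplicate windows are removed.  Each
    (position, residue) cell is tested with a one-sided binomial tail
    P(X >= k | n, f_bg) where f_bg is the whole-proteome frequency of the
    residue.  Raw p < ``alpha`` marks significance (no multiple-testing
    correction).
    """
    seqs = {r.accession: r.sequence.upper() for r in proteome}
    windows: set[str] = set()
    for acc, pos in binding_sites:
        seq = seqs.get(acc)
        if seq is None:
            continue
        lo, hi = pos - 1 - half_window, pos - 1 + half_window
        if lo < 0 or hi >= len(seq):
            continue  # too close to a terminus
        windows.add(seq[lo:hi + 1])
    if not windows:
        raise ValueError("empty foreground: no full-width windows")

    background = _background_frequencies(proteome)
    n = len(windows)
    results: list[EnrichmentResult] = []
    width = 2 * half_window + 1
    for offset in range(-half_window, half_window + 1):
        column = Counter(w[offset + half_window] for w in windows)
        for residue, k in sorted(column.items()):
            f_bg = background.get(residue, 0.0)
            p = float(stats.binom.sf(k - 1, n, f_bg)) if f_bg > 0 else (0.0 if k else 1.0)
            results.append(EnrichmentResult(offset, residue, k, n, f_bg, p))
    assert all(len(w) == width for w in windows)
    return results
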