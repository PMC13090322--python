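"""Integration of site-level reversible cysteine-oxidation tables.

Measurements are percentages of TCEP-reversibly oxidized peptide for one
cysteine site under one condition (e.g. the chronological-aging grid
LOG / day0 / day3 / day6 / day9, or stress pairs control / H2O2).
Operations cover control normalisation, rule-based kinetic classification
of aging profiles, stress-responder flagging, 2x2 zinc/CxxC
categorisation and cross-dataset site joins.

Paralog-ambiguous peptides labelled ``NAMEA/B`` are matched to either
paralog in joins and counted once in protein-level tallies.
"""

from __future__ import annotations

import io
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .motif_stats import MotifHit
from .zinc_annotation import ZincCall

__all__ = [
    "AGING_GRID",
    "KineticClass",
    "OxidationMeasurement",
    "OxidationProfile",
    "SiteCategory",
    "OxidationCategory",
    "load_oxidation_table",
    "normalize_to_control",
    "classify_profile",
    "flag_oxidation_increase",
    "categorize_sites",
    "group_median_oxidation",
    "map_sites_across_datasets",
    "expand_paralog_label",
]

#: ordered chronological-aging condition grid
AGING_GRID: tuple[str, ...] = ("LOG", "day0", "day3", "day6", "day9")


class KineticClass(str, Enum):
    EARLY = "EarlyOxidized"
    MIDDLE = "MiddleOxidized"
    LATE = "LateOxidized"
    HIGH = "ConstitutivelyHigh"
    MIXED = "Mixed"


@dataclass(frozen=True)
class OxidationMeasurement:
    accession: str          # may be a paralog-ambiguous label like "RPS27A/B"
    cys_position: int
    condition: str
    percent_oxidized: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_oxidized <= 100.0:
            raise ValueError(f"percent_oxidized out of range: {self.percent_oxidized}")

    @property
    def site(self) -> tuple[str, int]:
        return (self.accession, self.cys_position)


@dataclass
class OxidationProfile:
    accession: str
    cys_position: int
    timepoints: tuple[str, ...]
    values: tuple[float, ...]
    kinetic_class: KineticClass | None = None


class OxidationCategory(str, Enum):
    ZN_CXXC = "Zn_CxxC"
    ZN_NOCXXC = "Zn_noCxxC"
    NOZN_CXXC = "noZn_CxxC"
    NOZN_NOCXXC = "noZn_noCxxC"


@dataclass(frozen=True)
class SiteCategory:
    accession: str
    cys_position: int
    is_zbp: bool
    has_cxxc: bool
    is_ribosomal: bool

    @property
    def category(self) -> OxidationCategory:
        if self.is_zbp:
            return OxidationCategory.ZN_CXXC if self.has_cxxc else OxidationCategory.ZN_NOCXXC
        return OxidationCategory.NOZN_CXXC if self.has_cxxc else OxidationCategory.NOZN_NOCXXC


# ---------------------------------------------------------------------------
# loading & normalisation

def load_oxidation_table(
    stream: TextIO | str,
) -> tuple[list[OxidationMeasurement], list[dict]]:
    """Read a site-level oxidation TSV (accession, cys_position, condition, percent_oxidized).

    Returns (measurements, rejected-row report).  Rows whose percentage is
    outside [0, 100] are rejected with their row number; a duplicated
    (site, condition) pair raises ``ValueError``.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", dtype={"accession": str, "condition": str})
    measurements: list[OxidationMeasurement] = []
    rejected: list[dict] = []
    seen: set[tuple[str, int, str]] = set()
    for idx, row in df.iterrows():
        percent = float(row["percent_oxidized"])
        rownum = idx + 2  # 1-based, counting the header
        if not 0.0 <= percent <= 100.0:
            rejected.append({"row": rownum, "reason": f"percent out of range: {percent}"})
            continue
        key = (row["accession"], int(row["cys_position"]), row["condition"])
        if key in seen:
            raise ValueError(f"row {rownum}: duplicate site/condition {key}")
        seen.add(key)
        measurements.append(OxidationMeasurement(key[0], key[1], key[2], percent))
    return measurements, rejected


def normalize_to_control(
    measurements: Iterable[OxidationMeasurement],
    control_condition: str,
) -> tuple[dict[tuple[str, int], dict[str, float]], list[tuple[str, int]]]:
    """Delta-oxidation per site per condition vs. the site's internal control.

    Delta(site, cond) = percent(cond) - percent(control); the control
    condition itself maps to 0.  Sites lacking a control row are excluded
    and returned in the log.  Adding a constant to every condition of a
    site leaves all deltas unchanged.
    """
    by_site: dict[tuple[str, int], dict[str, float]] = defaultdict(dict)
    for m in measurements:
        by_site[m.site][m.condition] = m.percent_oxidized
    deltas: dict[tuple[str, int], dict[str, float]] = {}
    missing: list[tuple[str, int]] = []
    for site, conds in by_site.items():
        if control_condition not in conds:
            missing.append(site)
            continue
        control = conds[control_condition]
        deltas[site] = {cond: value - control for cond, value in conds.items()}
    return deltas, missing


# ---------------------------------------------------------------------------
# kinetic classification

def classify_profile(
    values: Sequence[float] | OxidationProfile,
    timepoints: Sequence[str] = AGING_GRID,
    *,
    high_threshold: float = 70.0,
    rise_threshold: float = 15.0,
) -> KineticClass:
    """Rule-based kinetic class of one aging oxidation profile.

    Rules fire in order: ConstitutivelyHigh if every value exceeds
    ``high_threshold`` (70%); otherwise the rise Delta(t) = value(t) -
    value(LOG) decides — Early if the rise reaches ``rise_threshold``
    (15 percentage points) by day0 or day3, Middle if first reached at
    day6, Late if only at day9, else Mixed.  Missing timepoints are
    tolerated down to 3 points.
    """
    if isinstance(values, OxidationProfile):
        timepoints = values.timepoints
        values = values.values
    if len(values) != len(timepoints):
        raise ValueError("values and timepoints differ in length")
    if len(values) < 3:
        raise ValueError("need at least 3 timepoints to classify")
    order = {t: i for i, t in enumerate(AGING_GRID)}
    unknown = [t for t in timepoints if t not in order]
    if unknown:
        raise ValueError(f"unknown timepoints: {unknown}")
    series = dict(sorted(zip(timepoints, values), key=lambda kv: order[kv[0]]))

    if all(v > high_threshold for v in series.values()):
        return KineticClass.HIGH
    baseline = next(iter(series.values()))  # earliest available point (LOG if present)
    risen = {t for t, v in series.items() if v - baseline >= rise_threshold}
    if risen & {"day0", "day3"}:
        return KineticClass.EARLY
    if "day6" in risen:
        return KineticClass.MIDDLE
    if "day9" in risen:
        return KineticClass.LATE
    return KineticClass.MIXED


def flag_oxidation_increase(
    deltas: Mapping[tuple[str, int], Mapping[str, float]],
    condition: str,
    threshold: float = 7.0,
) -> set[tuple[str, int]]:
    """Sites whose delta-oxidation under ``condition`` strictly exceeds ``threshold`` points."""
    return {site for site, conds in deltas.items()
            if condition in conds and conds[condition] > threshold}


# ---------------------------------------------------------------------------
# categorisation & group medians

def expand_paralog_label(label: str) -> tuple[str, ...]:
    """Expand a paralog-ambiguous label into the accessions it may denote.

    ``"RPS27A/B"`` -> ("RPS27A", "RPS27B"); labels without "/" map to
    themselves.  Each alternative after the first replaces the trailing
    characters of the first name.
    """
    parts = [p.strip() for p in label.split("/")]
    first = parts[0]
    names = [first]
    for alt in parts[1:]:
        names.append(alt if len(alt) >= len(first) else first[: len(first) - len(alt)] + alt)
    return tuple(dict.fromkeys(names))


def categorize_sites(
    sites: Iterable[tuple[str, int]],
    zinc_calls: Iterable[ZincCall],
    motif_hits: Iterable[MotifHit],
    ribosomal_list: Iterable[str] = (),
    known_accessions: Iterable[str] | None = None,
) -> tuple[list[SiteCategory], list[tuple[str, int]]]:
    """Assign each cysteine site to the 2x2 zinc-binding x CxxC category.

    The ribosomal flag is independent of the category.  When
    ``known_accessions`` is given, sites mapping to no known accession go
    to the unassigned log instead.
    """
    zbp = {c.accession for c in zinc_calls if c.is_zinc_binding}
    with_motif = {h.accession for h in motif_hits}
    ribosomal = set(ribosomal_list)
    known = set(known_accessions) if known_accessions is not None else None

    categories: list[SiteCategory] = []
    unassigned: list[tuple[str, int]] = []
    for acc, pos in sites:
        aliases = expand_paralog_label(acc)
        if known is not None and not (set(aliases) & known):
            unassigned.append((acc, pos))
            continue
        categories.append(SiteCategory(
            accession=acc,
            cys_position=pos,
            is_zbp=any(a in zbp for a in aliases),
            has_cxxc=any(a in with_motif for a in aliases),
            is_ribosomal=any(a in ribosomal for a in aliases),
        ))
    return categories, unassigned


def group_median_oxidation(
    measurements: Iterable[OxidationMeasurement],
    categories: Iterable[SiteCategory],
    condition: str,
) -> dict[OxidationCategory, float]:
    """Median % oxidation per 2x2 category under one condition (midpoint for even counts).

    Categories with no measured site are omitted.
    """
    cat_by_site = {(c.accession, c.cys_position): c.category for c in categories}
    pools: dict[OxidationCategory, list[float]] = defaultdict(list)
    for m in measurements:
        if m.condition == condition and m.site in cat_by_site:
            pools[cat_by_site[m.site]].append(m.percent_oxidized)
    return {cat: float(np.median(vals)) for cat, vals in pools.items()}


# ---------------------------------------------------------------------------
# cross-dataset joins

def map_sites_across_datasets(
    dataset_a: Iterable[OxidationMeasurement],
    dataset_b: Iterable[OxidationMeasurement],
) -> dict:
    """Inner join of two datasets on (accession, cys_position).

    Paralog-ambiguous labels match either paralog, so ``RPS27A/B`` at
    position 23 joins ``RPS27B`` at 23.  The result is symmetric in its
    inputs and reports the matched site pairs plus the number of common
    sites and common proteins (ambiguous labels counted once).
    """
    def site_index(ds: Iterable[OxidationMeasurement]):
        index: dict[int, list[str]] = defaultdict(list)
        for m in ds:
            if m.accession not in index[m.cys_position]:
                index[m.cys_position].append(m.accession)
        return index

    ia, ib = site_index(dataset_a), site_index(dataset_b)
    pairs: list[tuple[tuple[str, int], tuple[str, int]]] = []
    proteins: set[str] = set()
    for pos in sorted(set(ia) & set(ib)):
        for label_a in ia[pos]:
            ex_a = set(expand_paralog_label(label_a))
            for label_b in ib[pos]:
                if ex_a & set(expand_paralog_label(label_b)):
                    pairs.append(((label_a, pos), (label_b, pos)))
                    # one protein-level key per matched pair: the shared paralog set
                    proteins.add(min(ex_a & set(expand_paralog_label(label_b))))
    return {
        "pairs": pairs,
        "n_common_sites": len(set(pairs)),
        "n_common_proteins": len(proteins),
    }
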