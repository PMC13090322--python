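"""Classification of protein-abundance trajectories under zinc depletion.

Trajectories are log2 fold changes versus the moment of the shift to
zinc-deficient medium (t0, value 0 by construction).  A protein is Up at a
timepoint when its value strictly exceeds +0.5, Down below -0.5, else
Unchanged; the overlap table crosses the regulation class with ribosomal
membership, CxxC content, double-motif content and zinc-binding calls.
"""

from __future__ import annotations

import io
from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, TextIO

import pandas as pd

from .motif_stats import MotifHit
from .redox_integration import expand_paralog_label
from .zinc_annotation import ZincCall

__all__ = [
    "RegulationClass",
    "AbundanceTrajectory",
    "load_abundance_table",
    "classify_regulation",
    "regulation_counts",
    "overlap_with_categories",
]

UP_THRESHOLD = 0.5
DOWN_THRESHOLD = -0.5


class RegulationClass(str, Enum):
    UP = "Up"
    DOWN = "Down"
    UNCHANGED = "Unchanged"


@dataclass(frozen=True)
class AbundanceTrajectory:
    accession: str                   # may be a paralog-ambiguous "A/B" label
    timepoints: tuple[float, ...]    # hours, strictly increasing, containing 0
    values: tuple[float, ...]        # log2 fold change vs t0

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.values):
            raise ValueError("timepoints and values differ in length")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if 0.0 in self.timepoints and abs(self.values[self.timepoints.index(0.0)]) > 1e-12:
            raise ValueError("value at t0 must be 0")

    def value_at(self, at_time: float) -> float:
        try:
            return self.values[self.timepoints.index(at_time)]
        except ValueError:
            raise KeyError(f"{self.accession}: no timepoint {at_time} h") from None


def load_abundance_table(stream: TextIO | str) -> list[AbundanceTrajectory]:
    """Read a long-format abundance TSV (accession, time_h, value) into trajectories."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", dtype={"accession": str})
    out = []
    for acc, group in df.groupby("accession", sort=True):
        group = group.sort_values("time_h")
        out.append(AbundanceTrajectory(acc, tuple(group["time_h"].astype(float)),
                                       tuple(group["value"].astype(float))))
    return out


def classify_regulation(trajectory: AbundanceTrajectory, at_time: float) -> RegulationClass:
    """Up if value > 0.5, Down if < -0.5 (both strict), else Unchanged."""
    value = trajectory.value_at(at_time)
    if value > UP_THRESHOLD:
        return RegulationClass.UP
    if value < DOWN_THRESHOLD:
        return RegulationClass.DOWN
    return RegulationClass.UNCHANGED


def regulation_counts(
    trajectories: Iterable[AbundanceTrajectory], at_time: float
) -> dict[str, int]:
    """Counts of Up / Down / Unchanged at one timepoint; they partition the input."""
    counts = Counter(classify_regulation(t, at_time) for t in trajectories)
    return {
        "n_up": counts[RegulationClass.UP],
        "n_down": counts[RegulationClass.DOWN],
        "n_unchanged": counts[RegulationClass.UNCHANGED],
    }


def overlap_with_categories(
    classified: dict[str, RegulationClass],
    motif_hits: Iterable[MotifHit],
    zinc_calls: Iterable[ZincCall],
    ribosomal_list: Iterable[str] = (),
) -> pd.DataFrame:
    """Cross-tab of regulation class x protein categories.

    Columns: ``n`` (all proteins in the class), ``ribosomal``,
    ``cxxc`` (>=1 motif hit of either pattern), ``double_motif``
    (>=2 hits), ``zbp``, ``no_motif``.  Paralog-ambiguous trajectory
    labels are attributed to both paralogs for category membership but
    counted once per trajectory.
    """
    hits_per_protein: dict[str, int] = defaultdict(int)
    for h in motif_hits:
        hits_per_protein[h.accession] += 1
    zbp = {c.accession for c in zinc_calls if c.is_zinc_binding}
    ribosomal = set(ribosomal_list)

    rows = {cls: Counter() for cls in RegulationClass}
    for label, cls in classified.items():
        aliases = expand_paralog_label(label)
        n_hits = max(hits_per_protein.get(a, 0) for a in aliases)
        row = rows[cls]
        row["n"] += 1
        row["ribosomal"] += any(a in ribosomal for a in aliases)
        row["cxxc"] += n_hits >= 1
        row["double_motif"] += n_hits >= 2
        row["zbp"] += any(a in zbp for a in aliases)
        row["no_motif"] += n_hits == 0
    df = pd.DataFrame(
        [{"regulation": cls.value, **{k: rows[cls][k] for k in
          ("n", "ribosomal", "cxxc", "double_motif", "zbp", "no_motif")}}
         for cls in RegulationClass]
    ).set_index("regulation")
    return df
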