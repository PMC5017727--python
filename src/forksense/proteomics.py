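"""IP-MS post-processing: SAINT filtering, NSAF, NSAF/PAX and phase calls.

Spectral counts from bait (helicase-GFP) and control (NLS-GFP)
purifications, already scored for interaction specificity by SAINT, are
filtered at a confidence threshold (default 0.80, inclusive).  Relative
abundance within the retained interactome is quantified by the normalised
spectral abundance factor, NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j),
with spectral counts summed over the bait replicates, and then normalised
to each protein's proteome-wide abundance (PAX) to give an enrichment
ratio.  Phase dependence compares summed bait counts between S and G2
purifications of the same bait: S-limited (detected in S only),
S-enriched (fewer counts in G2), unchanged, or G2-enriched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "ProteinRecord",
    "InteractorCall",
    "saint_filter",
    "nsaf",
    "nsaf_pax",
    "phase_comparison",
    "interaction_table",
]

PHASE_CLASSES = ("S-limited", "S-enriched", "unchanged", "G2-enriched", "unclassified")


@dataclass
class ProteinRecord:
    """One co-purified protein with its spectral-count evidence."""

    protein_id: str
    length_aa: int
    spc_bait: tuple[int, ...]
    spc_control: tuple[int, ...]
    saint_score: float
    spc_g2: tuple[int, ...] | None = None
    pax: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_aa <= 0:
            raise ValueError(f"{self.protein_id}: length_aa must be > 0")
        if not 0 <= self.saint_score <= 1:
            raise ValueError(f"{self.protein_id}: SAINT score must be in [0, 1]")
        for counts in (self.spc_bait, self.spc_control, self.spc_g2 or ()):
            if any(c < 0 or int(c) != c for c in counts):
                raise ValueError(f"{self.protein_id}: spectral counts must be ints >= 0")

    @property
    def total_bait(self) -> int:
        return sum(self.spc_bait)

    @property
    def total_g2(self) -> int | None:
        return None if self.spc_g2 is None else sum(self.spc_g2)


@dataclass
class InteractorCall:
    protein_id: str
    passes_threshold: bool
    nsaf: float | None
    nsaf_pax: float | None
    phase_class: str

    def __post_init__(self) -> None:
        if self.phase_class not in PHASE_CLASSES:
            raise ValueError(f"unknown phase class {self.phase_class!r}")


def saint_filter(
    records: Sequence[ProteinRecord], threshold: float = 0.80
) -> list[ProteinRecord]:
    """Records with SAINT score >= threshold (inclusive)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    return [r for r in records if r.saint_score >= threshold]


def nsaf(records: Sequence[ProteinRecord]) -> dict[str, float]:
    """Normalised spectral abundance factor per protein; values sum to 1.

    Spectral counts are summed across bait replicates before dividing by
    protein length (replicate averaging gives identical values after
    normalisation when replicates have equal depth, and summing is robust
    to a zero-count replicate).
    """
    saf = {r.protein_id: r.total_bait / r.length_aa for r in records}
    total = sum(saf.values())
    if total <= 0:
        raise ValueError("total bait spectral counts are zero; NSAF undefined")
    return {pid: v / total for pid, v in saf.items()}


def nsaf_pax(
    records: Sequence[ProteinRecord],
) -> tuple[dict[str, float], list[str]]:
    """NSAF / proteome-abundance ratio per protein.

    Proteins lacking a PAX value (or with PAX = 0) cannot be normalised;
    they are excluded from the ratios and returned in the second element.
    """
    values = nsaf(records)
    ratios: dict[str, float] = {}
    excluded: list[str] = []
    for r in records:
        if r.pax is None or r.pax <= 0:
            excluded.append(r.protein_id)
        else:
            ratios[r.protein_id] = values[r.protein_id] / r.pax
    return ratios, excluded


def phase_comparison(
    records_s: Sequence[ProteinRecord],
    records_g2: Sequence[ProteinRecord] | None = None,
) -> dict[str, str]:
    """Classify each S-phase interactor by its G2 behaviour.

    On summed bait counts: S-limited when the protein is undetected in G2,
    S-enriched when detected with fewer counts, unchanged on equal counts,
    G2-enriched when G2 counts exceed S counts.  Proteins with no G2 data
    are unclassified.  ``records_g2`` may be omitted when the S-phase
    records carry embedded G2 counts (``spc_g2``).
    """
    g2_totals: dict[str, int] = {}
    if records_g2 is not None:
        g2_totals = {r.protein_id: r.total_bait for r in records_g2}
    out: dict[str, str] = {}
    for r in records_s:
        if records_g2 is not None:
            g2 = g2_totals.get(r.protein_id)
        else:
            g2 = r.total_g2
        s = r.total_bait
        if g2 is None:
            out[r.protein_id] = "unclassified"
        elif g2 == 0 and s > 0:
            out[r.protein_id] = "S-limited"
        elif g2 < s:
            out[r.protein_id] = "S-enriched"
        elif g2 == s:
            out[r.protein_id] = "unchanged"
        else:
            out[r.protein_id] = "G2-enriched"
    return out


def interaction_table(
    records: Sequence[ProteinRecord],
    saint_threshold: float = 0.80,
    records_g2: Sequence[ProteinRecord] | None = None,
    known_edges: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SAINT-filtered interactor table plus network edges.

    Returns ``(table, edges)``.  The table has one row per retained
    interactor, sorted by NSAF/PAX descending (proteins without PAX last);
    edges are taken from a user-supplied known-interaction table (columns
    ``protein_a``, ``protein_b``) restricted to retained interactors -- no
    online lookup is ever performed.
    """
    retained = saint_filter(records, saint_threshold)
    columns = [
        "protein_id", "saint_score", "total_spc", "length_aa",
        "nsaf", "nsaf_pax", "phase_class",
    ]
    if not retained:
        return pd.DataFrame(columns=columns), pd.DataFrame(columns=["protein_a", "protein_b"])
    values = nsaf(retained)
    ratios, _excluded = nsaf_pax(retained)
    phases = phase_comparison(retained, records_g2)
    rows = [
        {
            "protein_id": r.protein_id,
            "saint_score": r.saint_score,
            "total_spc": r.total_bait,
            "length_aa": r.length_aa,
            "nsaf": values[r.protein_id],
            "nsaf_pax": ratios.get(r.protein_id),
            "phase_class": phases[r.protein_id],
        }
        for r in retained
    ]
    table = pd.DataFrame(rows, columns=columns).sort_values(
        "nsaf_pax", ascending=False, na_position="last", ignore_index=True
    )
    ids = set(table["protein_id"])
    if known_edges is not None:
        edges = known_edges[
            known_edges["protein_a"].isin(ids) & known_edges["protein_b"].isin(ids)
        ].reset_index(drop=True)
    else:
        edges = pd.DataFrame(columns=["protein_a", "protein_b"])
    return table, edges
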