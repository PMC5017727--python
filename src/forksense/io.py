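"""Readers and writers for the plain-text formats the pipeline touches.

FASTA goes through Biopython; interval files are BED (0-based half-open,
read as-is) or GFF3 (1-based inclusive, converted on read); tabular inputs
and outputs are TSV with a header row.  Every parse error names the file
and the offending line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval

__all__ = [
    "ParseError",
    "GenomeSequence",
    "PeakTable",
    "read_fasta",
    "write_fasta",
    "read_intervals",
    "read_peak_table",
    "write_peak_table",
    "read_spectral_counts",
    "read_pax_table",
    "write_results",
]


class ParseError(ValueError):
    """Raised for malformed input files; message names file and line."""


@dataclass
class GenomeSequence:
    """Per-chromosome nucleotide strings over {A, C, G, T, N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for chrom, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {chrom!r} has empty sequence")

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or end <= start:
            raise ValueError(
                f"interval {chrom}:{start}-{end} out of bounds (length {len(seq)})"
            )
        return seq[start:end]


@dataclass
class PeakTable:
    """Peak calls for one experimental condition (e.g. Cdc20 in WT cells)."""

    condition: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.condition:
            raise ValueError("condition label must be nonempty")

    @property
    def n(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def has_strengths(self) -> bool:
        return all(iv.strength is not None for iv in self.intervals)


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load all FASTA records, upper-casing bases."""
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ParseError(f"{path}: duplicate chromosome name {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ParseError(f"{path}: no FASTA records found")
    return GenomeSequence(sequences)


def write_fasta(path: str | Path, genome: GenomeSequence, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _parse_strength(token: str) -> float | None:
    if token in (".", "", "NA"):
        return None
    return float(token)


def read_intervals(path: str | Path, format: str = "bed") -> list[GenomicInterval]:
    """Read BED (3-6 col) or GFF3 into 0-based half-open intervals.

    BED score column 5 / GFF3 score column 6, when present and not ".",
    is mapped to ``strength``; the BED name / GFF3 type provides the label.
    """
    path = Path(path)
    if format not in ("bed", "gff3"):
        raise ValueError(f"unknown interval format {format!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track "):
                continue
            cols = line.split("\t")
            try:
                if format == "bed":
                    if len(cols) < 3:
                        raise ValueError("expected at least 3 tab-separated columns")
                    chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                    label = cols[3] if len(cols) > 3 and cols[3] != "." else None
                    strength = _parse_strength(cols[4]) if len(cols) > 4 else None
                else:  # gff3: seqid source type start end score strand phase attrs
                    if len(cols) < 8:
                        raise ValueError("expected at least 8 tab-separated columns")
                    chrom = cols[0]
                    start, end = int(cols[3]) - 1, int(cols[4])
                    label = cols[2] or None
                    strength = _parse_strength(cols[5])
                out.append(GenomicInterval(chrom, start, end, strength, label))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


_PEAK_COLUMNS = ("chrom", "start", "end")


def read_peak_table(path: str | Path, condition: str) -> PeakTable:
    """Read a headered TSV of peaks (chrom, start, end[, strength])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in _PEAK_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    has_strength = "strength" in df.columns
    intervals = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            strength = float(row.strength) if has_strength else None
            if has_strength and pd.isna(strength):
                strength = None
            intervals.append(
                GenomicInterval(str(row.chrom), int(row.start), int(row.end), strength)
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: {exc}") from exc
    return PeakTable(condition, intervals)


def write_peak_table(path: str | Path, table: PeakTable) -> None:
    rows = [
        {
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "strength": iv.strength if iv.strength is not None else float("nan"),
        }
        for iv in table.intervals
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "strength"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_spectral_counts(path: str | Path) -> list["ProteinRecord"]:
    """Read an IP-MS spectral-count TSV into ProteinRecords.

    Required columns: ``protein_id``, ``length_aa``, ``saint_score``, plus
    one or more replicate columns named ``bait_*`` and ``control_*``.
    Optional ``g2_*`` columns carry G2-phase bait counts.  Unknown columns
    are preserved as opaque per-record metadata.
    """
    from .proteomics import ProteinRecord  # local import to avoid a cycle

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "length_aa", "saint_score"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    bait_cols = [c for c in df.columns if c.startswith("bait_")]
    control_cols = [c for c in df.columns if c.startswith("control_")]
    g2_cols = [c for c in df.columns if c.startswith("g2_")]
    if not bait_cols or not control_cols:
        raise ParseError(f"{path}: need at least one bait_* and one control_* column")
    known = {"protein_id", "length_aa", "saint_score", *bait_cols, *control_cols, *g2_cols}
    extra = [c for c in df.columns if c not in known]
    records = []
    for i, row in df.iterrows():
        records.append(
            ProteinRecord(
                protein_id=str(row["protein_id"]),
                length_aa=int(row["length_aa"]),
                spc_bait=tuple(int(row[c]) for c in bait_cols),
                spc_control=tuple(int(row[c]) for c in control_cols),
                spc_g2=tuple(int(row[c]) for c in g2_cols) if g2_cols else None,
                saint_score=float(row["saint_score"]),
                meta={c: row[c] for c in extra},
            )
        )
    return records


def read_pax_table(path: str | Path) -> dict[str, float]:
    """Read a proteome-abundance table (protein_id, pax) into a mapping."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "pax"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return {str(r.protein_id): float(r.pax) for r in df.itertuples(index=False)}


def write_results(path: str | Path, table: pd.DataFrame) -> None:
    """Write a result table as TSV, floats at 6 significant digits."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
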