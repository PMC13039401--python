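"""Cytosolic loop/tail statistics from multipass membrane-protein topologies.

FtsH-type membrane quality control classically requires an unstructured
cytosolic stretch of roughly 10-20 residues as a "pulling handle".  This
module parses topology-prediction tables, applies confidence filters, and
computes for each multipass protein the length of its longest cytosolic
extension, to ask what fraction of the membrane proteome lacks such a
handle (longest extension < 20 aa).

Topologies are ordered segment lists over three compartment labels:
``i`` (cytosolic), ``M`` (membrane-spanning) and ``o`` (extracytosolic),
with 1-based inclusive residue coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "TopologySegmentTable",
    "LoopConfig",
    "LoopSummary",
    "FilterReport",
    "TopologyParseError",
    "parse_topology_string",
    "parse_topology_table",
    "read_topology_tsv",
    "filter_by_confidence",
    "longest_cytosolic_loop",
    "short_loop_fraction",
    "summarize_loops",
]

LABELS = {"i": "cytosolic", "M": "membrane", "o": "extracytosolic"}
GRADES = ("high", "medium", "low")


class TopologyParseError(ValueError):
    """Raised when a topology record violates the segment invariants."""


@dataclass(frozen=True)
class Segment:
    label: str  # 'cytosolic' | 'membrane' | 'extracytosolic'
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TopologySegmentTable:
    """One protein's predicted topology plus prediction-confidence grades."""

    protein_id: str
    segments: list[Segment]
    orientation_quality: str = "low"
    tm_count_quality: str = "low"
    termini_certain: bool = False

    @property
    def n_tm(self) -> int:
        return sum(1 for s in self.segments if s.label == "membrane")

    @property
    def length(self) -> int:
        return self.segments[-1].end if self.segments else 0

    def validate(self) -> None:
        if not self.segments:
            raise TopologyParseError(f"{self.protein_id}: no segments")
        prev_end = 0
        prev_label = None
        for seg in self.segments:
            if seg.label not in LABELS.values():
                raise TopologyParseError(
                    f"{self.protein_id}: unknown label {seg.label!r}")
            if seg.end < seg.start:
                raise TopologyParseError(
                    f"{self.protein_id}: segment end {seg.end} < start {seg.start}")
            if seg.start != prev_end + 1:
                raise TopologyParseError(
                    f"{self.protein_id}: segments not contiguous at residue "
                    f"{seg.start} (previous segment ended at {prev_end})")
            if seg.label == "membrane" and prev_label == "membrane":
                raise TopologyParseError(
                    f"{self.protein_id}: adjacent membrane segments at "
                    f"residue {seg.start}")
            prev_end = seg.end
            prev_label = seg.label


@dataclass(frozen=True)
class LoopConfig:
    """Thresholds for the loop analysis.

    short_threshold
        A protein is "short-loop" when its longest cytosolic extension is
        strictly below this many residues (default 20 aa).
    count_termini
        Whether cytosolic N-/C-terminal tails count as extensions
        (default True: tails and loops are treated interchangeably as
        potential degradation handles).
    min_tm
        Minimum membrane-spanning segments for a protein to count as
        multipass (default 2).
    """

    short_threshold: int = 20
    count_termini: bool = True
    min_tm: int = 2

    def __post_init__(self) -> None:
        if self.short_threshold <= 0:
            raise ValueError("short_threshold must be positive")


@dataclass(frozen=True)
class LoopSummary:
    protein_id: str
    longest_cytosolic: int
    n_tm: int
    is_short: bool


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    dropped_orientation: int = 0
    dropped_tm_count: int = 0
    dropped_termini: int = 0
    dropped_min_tm: int = 0
    unknown_grade_warnings: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def parse_topology_string(protein_id: str, topology: str) -> list[Segment]:
    """Parse ``i:1-10,M:11-30,o:31-40`` into a validated segment list."""
    segments: list[Segment] = []
    for token in topology.split(","):
        token = token.strip()
        if not token:
            continue
        try:
            code, span = token.split(":")
            lo, hi = span.split("-")
            label = LABELS[code.strip()]
            segments.append(Segment(label, int(lo), int(hi)))
        except (ValueError, KeyError) as exc:
            raise TopologyParseError(
                f"{protein_id}: malformed topology token {token!r}") from exc
    return segments


def _coerce_grade(value: object, report: FilterReport | None = None) -> str:
    grade = str(value).strip().lower()
    if grade not in GRADES:
        if report is not None:
            report.unknown_grade_warnings += 1
        return "low"  # unknown grades are conservatively dropped downstream
    return grade


def _coerce_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in {"true", "1", "yes", "t"}


def parse_topology_table(rows: Iterable[dict]) -> list[TopologySegmentTable]:
    """Build validated records from tabular rows.

    Each row needs keys ``protein_id``, ``topology``, ``orientation_quality``,
    ``tm_count_quality``, ``termini_certain``.  Invariant-violating rows
    raise :class:`TopologyParseError` naming the protein and row number.
    """
    records = []
    for i, row in enumerate(rows):
        try:
            rec = TopologySegmentTable(
                protein_id=str(row["protein_id"]),
                segments=parse_topology_string(
                    str(row["protein_id"]), str(row["topology"])),
                # grades are kept verbatim (lowercased); unknown grades are
                # coerced to "low" at filter time, where they are counted
                orientation_quality=str(
                    row["orientation_quality"]).strip().lower(),
                tm_count_quality=str(
                    row["tm_count_quality"]).strip().lower(),
                termini_certain=_coerce_bool(row["termini_certain"]),
            )
            rec.validate()
        except TopologyParseError as exc:
            raise TopologyParseError(f"row {i + 1}: {exc}") from exc
        records.append(rec)
    return records


def read_topology_tsv(path) -> list[TopologySegmentTable]:
    """Read the documented TSV dialect (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "topology", "orientation_quality",
                "tm_count_quality", "termini_certain"}
    missing = required - set(df.columns)
    if missing:
        raise TopologyParseError(f"missing columns: {sorted(missing)}")
    return parse_topology_table(df.to_dict("records"))


def filter_by_confidence(
    records: Sequence[TopologySegmentTable],
    config: LoopConfig = LoopConfig(),
) -> tuple[list[TopologySegmentTable], FilterReport]:
    """Keep high-confidence multipass predictions.

    A record passes when orientation quality is high, TM-count quality is
    medium or high, both termini localizations are certain, and it has at
    least ``config.min_tm`` membrane segments.  Returns the kept subset and
    a per-criterion drop count (a record is counted once, at the first
    criterion it fails, in the order above).
    """
    report = FilterReport(n_input=len(records))
    kept: list[TopologySegmentTable] = []
    for rec in records:
        orientation = _coerce_grade(rec.orientation_quality, report)
        tm_quality = _coerce_grade(rec.tm_count_quality, report)
        if orientation != "high":
            report.dropped_orientation += 1
        elif tm_quality not in ("high", "medium"):
            report.dropped_tm_count += 1
        elif not rec.termini_certain:
            report.dropped_termini += 1
        elif rec.n_tm < config.min_tm:
            report.dropped_min_tm += 1
        else:
            kept.append(rec)
    report.n_kept = len(kept)
    return kept, report


def longest_cytosolic_loop(
    record: TopologySegmentTable,
    config: LoopConfig = LoopConfig(),
) -> int:
    """Length of the longest cytosolic segment, 0 if none exists.

    Terminal cytosolic tails are included when ``config.count_termini``;
    otherwise only inter-TM loops count.
    """
    n = len(record.segments)
    best = 0
    for idx, seg in enumerate(record.segments):
        if seg.label != "cytosolic":
            continue
        if not config.count_termini and (idx == 0 or idx == n - 1):
            continue
        best = max(best, seg.length)
    return best


def summarize_loops(
    records: Sequence[TopologySegmentTable],
    config: LoopConfig = LoopConfig(),
) -> list[LoopSummary]:
    return [
        LoopSummary(
            protein_id=rec.protein_id,
            longest_cytosolic=(n := longest_cytosolic_loop(rec, config)),
            n_tm=rec.n_tm,
            is_short=n < config.short_threshold,
        )
        for rec in records
    ]


# Histogram bins follow the figure convention: 10-aa bins up to 200 aa
# plus an open overflow bin.
HIST_EDGES = list(range(0, 201, 10)) + [np.inf]


def short_loop_fraction(
    summaries: Sequence[LoopSummary],
    config: LoopConfig = LoopConfig(),
) -> dict:
    """Fraction of proteins with longest cytosolic extension < threshold.

    The inequality is strict (a 20-aa extension is not "short" under the
    default 20-aa threshold).  Returns the fraction together with
    histogram bin edges/counts of the longest-extension distribution.
    """
    if not summaries:
        raise ValueError("short_loop_fraction of an empty summary list "
                         "is undefined")
    lengths = np.array([s.longest_cytosolic for s in summaries])
    n_short = int((lengths < config.short_threshold).sum())
    counts, _ = np.histogram(lengths, bins=HIST_EDGES)
    return {
        "n": len(summaries),
        "n_short": n_short,
        "fraction_short": n_short / len(summaries),
        "threshold": config.short_threshold,
        "bin_edges": [float(e) for e in HIST_EDGES],
        "bin_counts": [int(c) for c in counts],
    }


def loop_summary_frame(summaries: Sequence[LoopSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [s.__dict__ for s in summaries],
        columns=["protein_id", "longest_cytosolic", "n_tm", "is_short"],
    )


def write_loop_report(summaries, config, tsv_path, json_path=None,
                      filter_report: FilterReport | None = None) -> None:
    loop_summary_frame(summaries).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        report = short_loop_fraction(summaries, config)
        if filter_report is not None:
            report["filter"] = filter_report.to_dict()
        with open(json_path, "w") as fh:
            json.dump(report, fh, indent=2)
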