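"""Additive membrane-insertion free-energy scoring for TM segments.

A candidate transmembrane segment inserts spontaneously via the Sec
translocon when its apparent insertion free energy dG_app is negative.
Here dG_app of a segment is the plain sum of per-residue contributions on
the biological hydrophobicity scale; the window scan enumerates all
segment placements in a sequence and reports the minimum.  This additive
form deliberately drops the position-dependent profile and length
corrections of the full predictor — it preserves the ordering needed for
binary "will this TM still insert after a polar mutation" assessments,
which is what it is used for here.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import pandas as pd

__all__ = [
    "HydrophobicityScale",
    "InsertionScan",
    "Window",
    "load_default_scale",
    "segment_dG",
    "scan_min_dG",
]

DEFAULT_WINDOW_LENGTHS = range(19, 24)  # 19-23 aa, bracketing ~20 to span ~30 A


@dataclass(frozen=True)
class HydrophobicityScale:
    name: str
    dg_per_residue: dict[str, float]

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.dg_per_residue)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues "
                             f"{sorted(missing)}")

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "HydrophobicityScale":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(name or str(path),
                   dict(zip(df["residue"], df["dg_app"].astype(float))))


def load_default_scale() -> HydrophobicityScale:
    """The bundled biological dG_app scale (kcal/mol per residue)."""
    ref = resources.files("memdegron") / "data" / "dg_scale.tsv"
    with resources.as_file(ref) as path:
        return HydrophobicityScale.from_tsv(path, name="dg_app_biological")


@dataclass(frozen=True)
class Window:
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    dg: float   # kcal/mol


@dataclass(frozen=True)
class InsertionScan:
    sequence_id: str
    windows: tuple[Window, ...]
    best: Window
    predicted_insertion: bool  # best.dg < 0


def segment_dG(segment: str, scale: HydrophobicityScale | None = None) -> float:
    """Apparent insertion free energy (kcal/mol) of a segment: sum of
    per-residue scale values.  Nonstandard residues raise ``ValueError``."""
    if scale is None:
        scale = load_default_scale()
    if len(segment) < 1:
        raise ValueError("segment must contain at least one residue")
    total = 0.0
    for aa in segment.upper():
        try:
            total += scale.dg_per_residue[aa]
        except KeyError:
            raise ValueError(f"nonstandard residue {aa!r}") from None
    return total


def scan_min_dG(
    sequence: str,
    scale: HydrophobicityScale | None = None,
    window_lengths: Iterable[int] = DEFAULT_WINDOW_LENGTHS,
    sequence_id: str = "seq",
    insertion_threshold: float = 0.0,
) -> InsertionScan:
    """Scan all windows of the allowed lengths for the minimum-dG segment.

    Ties are broken by smaller start, then smaller length.  The sequence
    must be at least as long as the smallest window.
    """
    if scale is None:
        scale = load_default_scale()
    sequence = sequence.upper()
    lengths = sorted(set(int(w) for w in window_lengths))
    if not lengths or min(lengths) < 1:
        raise ValueError("window lengths must be positive")
    if len(sequence) < min(lengths):
        raise ValueError(
            f"sequence length {len(sequence)} shorter than minimum window "
            f"{min(lengths)}")
    values = [scale.dg_per_residue.get(aa) for aa in sequence]
    if None in values:
        bad = sequence[values.index(None)]
        raise ValueError(f"nonstandard residue {bad!r}")

    # math.fsum is exactly rounded, so windows holding the same residue
    # multiset score bit-identically and the tie-break is well defined
    import math as _math

    windows: list[Window] = []
    for length in lengths:
        for start in range(0, len(sequence) - length + 1):
            dg = _math.fsum(values[start : start + length])
            windows.append(Window(start + 1, start + length, dg))
    # minimal dg; tie-break: smaller start, then smaller length
    # (dg rounded to 1e-9 kcal/mol so float noise cannot decide a tie)
    best = min(windows,
               key=lambda w: (round(w.dg, 9), w.start, w.end - w.start))
    return InsertionScan(
        sequence_id=sequence_id,
        windows=tuple(windows),
        best=best,
        predicted_insertion=best.dg < insertion_threshold,
    )
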