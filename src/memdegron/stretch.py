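"""Longest-hydrophobic-stretch statistics over aligned TM regions.

The membrane anchor of the FtsH protease has an unusual architecture: its
first transmembrane helix (TM1) is delimited by polar caps (K6/N7 on the
cytosolic side and Q23 on the periplasmic side under the +3 numbering
convention), leaving a hydrophobic core of only ~15 residues — shorter
than the ~20 residues needed to span the ~30 Å hydrophobic thickness of
the bilayer.  This module measures that architecture across a homolog
family: for each sequence and each annotated TM region it computes the
longest contiguous stretch free of highly polar residues
(K/R/N/Q/H/D/E), and compares the TM1 and TM2 distributions with a
two-sided Mann-Whitney rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from scipy import stats as _sps  # normal CDF only

__all__ = [
    "DEFAULT_POLAR",
    "PolarSet",
    "AlignedFamily",
    "StretchResult",
    "RankTestResult",
    "longest_nonpolar_run",
    "family_stretch_distribution",
    "mann_whitney_u",
    "tm1_vs_tm2_report",
]

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
#: The paper-defined "highly polar" residues delimiting hydrophobic cores.
DEFAULT_POLAR = frozenset("KRNQHDE")
GAP = "-"


@dataclass(frozen=True)
class PolarSet:
    """Residues that terminate a hydrophobic stretch.

    ``x_breaks_run`` controls the unknown residue X: by default it is
    treated as potentially polar (conservative lower bound on stretch
    length).
    """

    residues: frozenset[str] = DEFAULT_POLAR
    x_breaks_run: bool = True

    def __post_init__(self) -> None:
        if not set(self.residues) <= AA20:
            raise ValueError(
                f"polar set contains non-standard codes: "
                f"{sorted(set(self.residues) - AA20)}")

    def breaks(self, aa: str) -> bool:
        if aa == "X":
            return self.x_breaks_run
        return aa in self.residues


@dataclass
class AlignedFamily:
    """An MSA with named TM column ranges (1-based inclusive columns)."""

    sequences: list[tuple[str, str]]  # (seq_id, aligned residues)
    tm_regions: dict[str, tuple[int, int]]
    reference_id: str | None = None
    numbering_offset: int = 0

    @property
    def width(self) -> int:
        return len(self.sequences[0][1]) if self.sequences else 0

    def validate(self) -> None:
        if not self.sequences:
            raise ValueError("empty alignment")
        w = self.width
        for seq_id, seq in self.sequences:
            if len(seq) != w:
                raise ValueError(
                    f"{seq_id}: aligned length {len(seq)} != {w}")
        for name, (lo, hi) in self.tm_regions.items():
            if not (1 <= lo <= hi <= w):
                raise ValueError(
                    f"{name}: column range {lo}-{hi} outside alignment "
                    f"width {w}")
        if self.reference_id is not None and self.reference_id not in {
            s for s, _ in self.sequences
        }:
            raise ValueError(f"reference {self.reference_id!r} not in MSA")

    def region_sequence(self, seq_id: str, tm_name: str) -> str:
        """Ungapped residues of one sequence inside a TM column range."""
        lo, hi = self.tm_regions[tm_name]
        aligned = dict(self.sequences)[seq_id]
        return aligned[lo - 1 : hi].replace(GAP, "").replace(".", "")

    @classmethod
    def from_fasta(cls, path, tm_regions: Mapping[str, tuple[int, int]],
                   reference_id: str | None = None,
                   numbering_offset: int = 0) -> "AlignedFamily":
        seqs = [(rec.id, str(rec.seq).upper())
                for rec in SeqIO.parse(str(path), "fasta")]
        fam = cls(seqs, dict(tm_regions), reference_id, numbering_offset)
        fam.validate()
        return fam


@dataclass(frozen=True)
class StretchResult:
    seq_id: str
    tm_name: str
    stretch_len: int
    n_ungapped: int


@dataclass(frozen=True)
class RankTestResult:
    U: float
    p_two_sided: float
    method: str  # 'exact' | 'normal_approx'
    n1: int
    n2: int
    median1: float
    median2: float
    iqr1: tuple[float, float]
    iqr2: tuple[float, float]


def longest_nonpolar_run(sequence: str,
                         polar: PolarSet = PolarSet()) -> int:
    """Longest contiguous run containing no highly polar residue.

    The input is an ungapped residue string over the 20 standard codes
    plus X; any other character raises ``ValueError``.
    """
    best = run = 0
    for aa in sequence.upper():
        if aa not in AA20 and aa != "X":
            raise ValueError(f"unknown residue character {aa!r}")
        if polar.breaks(aa):
            run = 0
        else:
            run += 1
            if run > best:
                best = run
    return best


def family_stretch_distribution(
    family: AlignedFamily,
    polar: PolarSet = PolarSet(),
) -> tuple[list[StretchResult], dict]:
    """Per-sequence, per-TM stretch lengths plus per-TM summaries.

    Gaps are stripped per sequence within each column range before the
    run computation (a stretch is a property of the residue chain, not of
    alignment columns), so gap-column injection never changes a result.
    Fully gapped regions are recorded with ``n_ungapped = 0`` and excluded
    from summaries.
    """
    family.validate()
    results: list[StretchResult] = []
    summaries: dict = {}
    for tm_name in family.tm_regions:
        lengths = []
        n_empty = 0
        for seq_id, _ in family.sequences:
            region = family.region_sequence(seq_id, tm_name)
            res = StretchResult(seq_id, tm_name,
                                longest_nonpolar_run(region, polar),
                                len(region))
            results.append(res)
            if res.n_ungapped == 0:
                n_empty += 1
            else:
                lengths.append(res.stretch_len)
        arr = np.asarray(lengths, dtype=float)
        summaries[tm_name] = {
            "n": len(lengths),
            "n_fully_gapped": n_empty,
            "median": float(np.median(arr)) if len(arr) else math.nan,
            "iqr": (float(np.percentile(arr, 25)),
                    float(np.percentile(arr, 75))) if len(arr) else
                   (math.nan, math.nan),
            "min": float(arr.min()) if len(arr) else math.nan,
            "max": float(arr.max()) if len(arr) else math.nan,
        }
    return results, summaries


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for sample x via midranks (ties get half credit)."""
    pooled = np.concatenate([x, y])
    ranks = _sps.rankdata(pooled)  # midranks
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2)


EXACT_LIMIT = 12  # n1+n2 above this -> normal approximation


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney rank test.

    Exact two-sided p by full enumeration of all C(n1+n2, n1) group
    labelings when ``n1 + n2 <= 12`` and the pooled data are tie-free;
    otherwise the normal approximation with tie correction and continuity
    correction.  The method actually used is always reported.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("mann_whitney_u requires non-empty samples")
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)

    if n1 + n2 <= EXACT_LIMIT and not has_ties:
        dev = abs(u_obs - mu)
        total = 0
        extreme = 0
        idx = range(n1 + n2)
        for comb in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= dev - 1e-9:
                extreme += 1
        p = extreme / total
        method = "exact"
    else:
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum() / (n * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var <= 0:  # all values identical
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)  # continuity corr.
            z = max(z, 0.0)
            p = 2.0 * _sps.norm.sf(z)
        p = min(p, 1.0)
        method = "normal_approx"

    def _q(a):
        return (float(np.percentile(a, 25)), float(np.percentile(a, 75)))

    return RankTestResult(
        U=u_obs, p_two_sided=p, method=method, n1=n1, n2=n2,
        median1=float(np.median(x)), median2=float(np.median(y)),
        iqr1=_q(x), iqr2=_q(y),
    )


def tm1_vs_tm2_report(
    family: AlignedFamily,
    polar: PolarSet = PolarSet(),
    tm_a: str = "TM1",
    tm_b: str = "TM2",
) -> dict:
    """Compare hydrophobic-stretch distributions between two TM regions.

    Combines :func:`family_stretch_distribution` with
    :func:`mann_whitney_u` and reports the variability comparison
    (IQR widths) alongside medians.
    """
    results, summaries = family_stretch_distribution(family, polar)
    a = [r.stretch_len for r in results
         if r.tm_name == tm_a and r.n_ungapped > 0]
    b = [r.stretch_len for r in results
         if r.tm_name == tm_b and r.n_ungapped > 0]
    if len(a) == 1 and len(b) == 1:
        # single-sequence family: no power, degenerate exact test
        test = RankTestResult(
            U=0.5, p_two_sided=1.0, method="exact", n1=1, n2=1,
            median1=float(a[0]), median2=float(b[0]),
            iqr1=(float(a[0]), float(a[0])), iqr2=(float(b[0]), float(b[0])))
    else:
        test = mann_whitney_u(a, b)
    iqr_width = lambda iqr: iqr[1] - iqr[0]
    return {
        "results": results,
        "summaries": summaries,
        "test": test,
        "iqr_width": {tm_a: iqr_width(test.iqr1), tm_b: iqr_width(test.iqr2)},
        "less_variable": tm_a if iqr_width(test.iqr1) <= iqr_width(test.iqr2)
                         else tm_b,
    }


def stretch_frame(results: Iterable[StretchResult]):
    import pandas as pd

    return pd.DataFrame(
        [r.__dict__ for r in results],
        columns=["seq_id", "tm_name", "stretch_len", "n_ungapped"],
    )
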