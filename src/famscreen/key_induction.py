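"""Induce a PROSITE-dialect consensus key from a protein multiple alignment.

A column whose top residue reaches the conservation threshold (computed over
non-gap rows) becomes a fixed token; maximal runs of non-conserved columns
collapse to a bounded wildcard ``X(min,max)`` whose bounds are the fewest and
most residues any single row contributes across the run.  Two emission modes:

``strict``
    Conserved columns always emit their single top residue.  The resulting
    key may fail rows carrying a minority residue.
``cover`` (default)
    Conserved columns that are not unanimous widen to a residue class of all
    residues observed in the column, and any conserved column containing a
    gap is demoted to the wildcard run (a fixed token cannot absorb a gap).
    The induced key is then guaranteed to match every training sequence.

Gap-dominated columns (> 50 % gaps) carry no consensus signal and are always
treated as part of a wildcard run.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

from Bio import SeqIO

from .pattern_engine import (
    ElementKind,
    MotifPattern,
    PatternElement,
    count_matches,
)

__all__ = [
    "AlignmentColumnProfile",
    "InducedKey",
    "CoverageReport",
    "read_alignment",
    "column_profiles",
    "induce_key",
    "validate_key",
]

GAP = "-"


@dataclass(frozen=True)
class AlignmentColumnProfile:
    index: int
    residue_counts: dict[str, int]
    gap_count: int
    top_residue: str
    top_fraction: float


@dataclass(frozen=True)
class InducedKey:
    pattern: MotifPattern
    coverage: float
    region: tuple[int, int] | None = None


@dataclass(frozen=True)
class CoverageReport:
    matched: dict[str, bool]
    coverage: float

    @property
    def n_matched(self) -> int:
        return sum(self.matched.values())


def read_alignment(path) -> list[tuple[str, str]]:
    """Read an aligned FASTA file into ``(id, row)`` pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def _rows(msa) -> list[str]:
    rows = [r[1] if isinstance(r, tuple) else str(r) for r in msa]
    rows = [r.upper() for r in rows]
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment: rows have unequal lengths")
    return rows


def column_profiles(msa) -> list[AlignmentColumnProfile]:
    """Per-column residue counts, gap count, and top residue/fraction.

    The top fraction is computed over non-gap rows only; residue ties break
    alphabetically so profiles are deterministic.
    """
    rows = _rows(msa)
    profiles = []
    for j in range(len(rows[0])):
        col = [r[j] for r in rows]
        gaps = col.count(GAP)
        counts = Counter(c for c in col if c != GAP)
        if counts:
            top = min(counts, key=lambda c: (-counts[c], c))
            frac = counts[top] / (len(col) - gaps)
        else:
            top, frac = "", 0.0
        profiles.append(
            AlignmentColumnProfile(j, dict(counts), gaps, top, frac)
        )
    return profiles


def _conserved(p: AlignmentColumnProfile, n_rows: int, threshold: float,
               strict_greater: bool, mode: str) -> bool:
    if p.gap_count * 2 > n_rows:  # gap-dominated: no consensus signal
        return False
    if not p.residue_counts:
        return False
    if mode == "cover" and p.gap_count > 0:
        return False
    return p.top_fraction > threshold if strict_greater else p.top_fraction >= threshold


def induce_key(
    msa,
    threshold: float = 0.90,
    region: tuple[int, int] | None = None,
    mode: str = "cover",
    strict_greater: bool = False,
    name: str = "induced-key",
) -> InducedKey:
    """Induce a consensus key from an alignment at a conservation threshold.

    Parameters
    ----------
    msa : iterable of ``(id, row)`` pairs or of aligned strings
    threshold : conservation threshold in (0.5, 1]
    region : optional 0-based half-open column interval to induce over
    mode : ``"cover"`` or ``"strict"`` (see module docstring)
    strict_greater : require top fraction strictly above the threshold
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    if mode not in ("strict", "cover"):
        raise ValueError(f"unknown mode {mode!r}")
    msa = list(msa)
    rows = _rows(msa)
    ids = [r[0] if isinstance(r, tuple) else f"seq{i}" for i, r in enumerate(msa)]
    if len(rows) < 2:
        raise ValueError("need at least two rows to induce a key")
    if region is not None:
        a, b = region
        if not 0 <= a < b <= len(rows[0]):
            raise ValueError(f"empty or out-of-range region {region}")
        rows = [r[a:b] for r in rows]
    if any(r.count(GAP) == len(r) for r in rows):
        raise ValueError("a row contributes no residues in the selected region")

    profiles = column_profiles(rows)
    n = len(rows)
    elements: list[PatternElement] = []
    run: list[int] = []  # column indices of the current wildcard run

    def flush_run() -> None:
        if not run:
            return
        per_row = [sum(r[j] != GAP for j in run) for r in rows]
        lo, hi = min(per_row), max(per_row)
        run.clear()
        if hi == 0:
            return  # all-gap stretch: contributes nothing
        elements.append(PatternElement(ElementKind.WILDCARD, frozenset(), lo, hi))

    for p in profiles:
        if _conserved(p, n, threshold, strict_greater, mode):
            flush_run()
            observed = frozenset(p.residue_counts)
            if mode == "cover" and len(observed) > 1:
                elements.append(PatternElement(ElementKind.CLASS, observed))
            else:
                elements.append(PatternElement(ElementKind.FIXED, frozenset(p.top_residue)))
        else:
            run.append(p.index)
    flush_run()

    if not elements:
        raise ValueError("no informative columns: cannot induce a key")
    pattern = MotifPattern(tuple(elements), name=name, source=f"induced@{threshold:g}")
    seqs = [r.replace(GAP, "") for r in rows]
    report = validate_key(pattern, seqs, ids=ids)
    return InducedKey(pattern=pattern, coverage=report.coverage, region=region)


def validate_key(key: MotifPattern, seqs, ids=None) -> CoverageReport:
    """Check which (unaligned) sequences a key matches; coverage fraction.

    Raises ``ValueError`` on an empty sequence set (coverage is undefined).
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("coverage undefined for an empty sequence set")
    if seqs and isinstance(seqs[0], tuple):
        ids = [s[0] for s in seqs]
        seqs = [s[1] for s in seqs]
    if ids is None:
        ids = [f"seq{i}" for i in range(len(seqs))]
    matched = {i: count_matches(key, s) > 0 for i, s in zip(ids, seqs)}
    return CoverageReport(matched=matched, coverage=sum(matched.values()) / len(matched))
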