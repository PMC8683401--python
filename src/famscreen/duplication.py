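"""Tandem-duplication detection from gene coordinates and family grouping.

Two family genes form a tandem pair when they lie on the same chromosome,
belong to the same (phylogenetic) group, sit within ``max_gap`` base pairs of
each other, and have at most ``max_intervening`` family genes between them.
The defaults (50 kb, 1 intervening gene) are deliberately generous: genuine
tandem arrays in compact plant genomes sit a few kilobases apart, so the
result is robust over a wide threshold range.

Genes that are not tandem but share a group with a family member on a
*different* chromosome are labelled ``candidate-segmental`` — an explicitly
heuristic label, since proper segmental-duplication calling needs collinearity
blocks, which are out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TandemPair", "find_tandem_pairs", "label_duplication_classes"]


@dataclass(frozen=True)
class TandemPair:
    gene_a: str
    gene_b: str
    chromosome: str
    gap_bp: int
    group: str | None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("a gene cannot pair with itself")
        if self.gap_bp < 0:
            raise ValueError("gap must be non-negative")


def _require_coords(rec) -> None:
    if rec.chromosome is None or rec.start is None or rec.stop is None:
        raise ValueError(f"record {rec.label} is missing coordinates")


def find_tandem_pairs(records, max_gap: int = 50_000, max_intervening: int = 1) -> list[TandemPair]:
    """All tandem pairs among coordinate records (each pair reported once).

    ``records`` need ``chromosome``, ``start``, ``stop``, ``group`` and a
    ``label`` (gene name or accession).  Pair members are ordered
    lexicographically; the pair list is sorted by chromosome and position.
    """
    records = list(records)
    for r in records:
        _require_coords(r)
    by_chrom: dict[str, list] = {}
    for r in records:
        by_chrom.setdefault(r.chromosome, []).append(r)
    pairs = []
    for chrom, recs in sorted(by_chrom.items()):
        recs.sort(key=lambda r: (r.start, r.stop))
        for i, a in enumerate(recs):
            for j in range(i + 1, len(recs)):
                b = recs[j]
                if j - i - 1 > max_intervening:
                    break
                if a.group is None or a.group != b.group:
                    continue
                gap = max(0, b.start - a.stop)
                if gap > max_gap:
                    continue
                ga, gb = sorted((a.label, b.label))
                pairs.append(TandemPair(ga, gb, chrom, gap, a.group))
    return pairs


def label_duplication_classes(records, pairs) -> dict[str, str]:
    """Per-gene duplication label: ``tandem``, ``candidate-segmental`` or
    ``singleton``.

    Tandem membership comes from ``pairs``; candidate-segmental genes share a
    group with at least one family gene on a different chromosome (heuristic);
    everything else is a singleton.
    """
    records = list(records)
    tandem = {g for p in pairs for g in (p.gene_a, p.gene_b)}
    labels = {}
    for r in records:
        if r.label in tandem:
            labels[r.label] = "tandem"
            continue
        cross = any(
            o is not r
            and o.group is not None
            and o.group == r.group
            and o.chromosome != r.chromosome
            for o in records
        )
        labels[r.label] = "candidate-segmental" if cross else "singleton"
    return labels
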