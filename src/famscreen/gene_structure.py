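"""Gene models from GFF3: exon counts, intron phases, chromosome summaries.

Internally all intervals are 0-based half-open; the GFF3 boundary (1-based
inclusive) is converted exactly once on input.  Exon and CDS lists are kept in
transcription order (reversed genomic order on the minus strand), so intron
indices, lengths and phases read 5'->3' along the mRNA.

Intron phase is defined on coding sequence only: phase = (number of coding
bases upstream of the intron) mod 3, i.e. phase 0 introns sit between intact
codons, phase 1 after the first base of a codon, phase 2 after the second.
Introns lying outside the CDS (UTR introns) carry phase ``None`` and are
reported as ``"-"``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import gffutils
import pandas as pd

__all__ = [
    "GeneModel",
    "IntronRecord",
    "load_gff",
    "intron_phases",
    "family_structure_summary",
    "chromosome_summary",
]

Interval = tuple[int, int]  # 0-based half-open


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[Interval, ...]  # transcription order
    cds: tuple[Interval, ...]    # transcription order

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            genomic = sorted(ivs)
            if any(a >= b for a, b in ivs):
                raise ValueError(f"{self.gene_id}: empty {name} interval")
            if any(p[1] > q[0] for p, q in zip(genomic, genomic[1:])):
                raise ValueError(f"{self.gene_id}: overlapping {name} intervals")

    @property
    def n_exons(self) -> int:
        return len(self.exons) or len(self.cds)

    @property
    def segments(self) -> tuple[Interval, ...]:
        """Exons when annotated, else the CDS segments stand in for them."""
        return self.exons or self.cds


@dataclass(frozen=True)
class IntronRecord:
    gene_id: str
    index: int          # 0-based, transcription order
    length: int         # bp
    phase: int | None   # 0/1/2 within CDS, None for UTR introns

    @property
    def phase_label(self) -> str:
        return "-" if self.phase is None else str(self.phase)


def load_gff(path) -> list[GeneModel]:
    """Load gene models from a GFF3 file.

    When a gene has several transcripts the one with the longest total CDS
    represents the gene.  Genes without CDS features raise ``ValueError``, as
    does a gene whose features disagree on strand.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, level=1))
        if not transcripts:
            transcripts = [gene]
        best: tuple[int, list, list] | None = None
        for tx in transcripts:
            exons = [(f.start - 1, f.end) for f in db.children(tx, featuretype="exon")]
            cds = [(f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")]
            strands = {f.strand for f in db.children(tx)} | {tx.strand, gene.strand}
            if len(strands - {"."}) > 1:
                raise ValueError(f"{gene.id}: inconsistent strand within gene")
            total = sum(e - s for s, e in cds)
            if cds and (best is None or total > best[0]):
                best = (total, exons, cds)
        if best is None:
            raise ValueError(f"{gene.id}: no CDS features")
        _, exons, cds = best
        reverse = gene.strand == "-"
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                exons=tuple(sorted(exons, reverse=reverse)),
                cds=tuple(sorted(cds, reverse=reverse)),
            )
        )
    return models


def intron_phases(model: GeneModel) -> list[IntronRecord]:
    """Introns of a gene model with lengths and CDS-based phases.

    A warning is attached (via ``warnings``) when the total CDS length is not
    a multiple of three; phases are still reported.
    """
    if not model.cds:
        raise ValueError(f"{model.gene_id}: CDS required for phase computation")
    total_cds = sum(e - s for s, e in model.cds)
    if total_cds % 3:
        import warnings

        warnings.warn(
            f"{model.gene_id}: CDS length {total_cds} not divisible by 3",
            stacklevel=2,
        )
    segs = model.segments
    cds_lo = min(s for s, _ in model.cds)
    cds_hi = max(e for _, e in model.cds)
    records = []
    for i, (up, down) in enumerate(zip(segs, segs[1:])):
        if model.strand == "+":
            gap_start, gap_end = up[1], down[0]
        else:
            gap_start, gap_end = down[1], up[0]
        length = gap_end - gap_start
        if length < 1:
            raise ValueError(f"{model.gene_id}: adjacent segments without intron")
        inside_cds = gap_start >= cds_lo and gap_end <= cds_hi
        if inside_cds:
            if model.strand == "+":
                upstream = sum(e - s for s, e in model.cds if e <= gap_start)
            else:
                upstream = sum(e - s for s, e in model.cds if s >= gap_end)
            phase: int | None = upstream % 3
        else:
            phase = None
        records.append(IntronRecord(model.gene_id, i, length, phase))
    return records


def family_structure_summary(models) -> dict:
    """Exon-count per gene plus a family-wide intron phase histogram."""
    models = list(models)
    exon_counts = {m.gene_id: m.n_exons for m in models}
    hist: Counter = Counter()
    for m in models:
        for rec in intron_phases(m):
            hist[rec.phase_label] += 1
    histogram = {label: hist.get(label, 0) for label in ("0", "1", "2", "-")}
    return {"exon_counts": exon_counts, "phase_histogram": histogram}


def chromosome_summary(records) -> dict:
    """Per-chromosome gene counts and forward/reverse strand totals.

    Accepts a list of objects with ``chromosome``/``strand`` attributes (e.g.
    candidate records) or a DataFrame with those columns; entries without
    coordinates are ignored.
    """
    if isinstance(records, pd.DataFrame):
        chroms = records["chromosome"].dropna().tolist()
        strands = records["strand"].dropna().tolist()
    else:
        chroms = [r.chromosome for r in records if r.chromosome]
        strands = [r.strand for r in records if r.strand]
    return {
        "per_chromosome": dict(sorted(Counter(chroms).items())),
        "forward": strands.count("+"),
        "reverse": strands.count("-"),
    }
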