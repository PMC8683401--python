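"""Packaged family tables and seeded synthetic-data generators.

The packaged tables transcribe the published family summary (29 members plus
the discarded truncated accession) and the protein-property table, so every
module is testable without network access.  The generators emit synthetic
protein families with planted motifs, GFF3 gene models with known intron
phases, and FPKM matrices with planted up/down effects — each alongside a
machine-readable truth object, so downstream modules can be tested against
ground truth by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .family_screen import CandidateRecord, read_candidates_tsv
from .pattern_engine import (
    ElementKind,
    MotifPattern,
    parse_pattern,
)

__all__ = [
    "load_table1",
    "load_table3",
    "load_consensus_key",
    "SyntheticFamilySpec",
    "FamilySample",
    "generate_family",
    "generate_gff",
    "generate_expression",
    "to_fasta",
]

AA = "ACDEFGHIKLMNPQRSTVWY"


def _data(name: str):
    return resources.files("famscreen").joinpath(f"data/{name}")


def load_table1() -> list[CandidateRecord]:
    """The 29 family members plus the truncated rejection record (30 rows)."""
    with resources.as_file(_data("brcngc_genes.tsv")) as path:
        return read_candidates_tsv(path)


def load_table3() -> pd.DataFrame:
    """The published protein-property table (29 rows)."""
    with resources.as_file(_data("brcngc_properties.tsv")) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_consensus_key() -> MotifPattern:
    """The family-specific consensus motif key, parsed from its printed form."""
    text = _data("brcngc_key.txt").read_text()
    lines = [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]
    return parse_pattern(lines[0], name="BrCNGC-key", source="family consensus, PBC+hinge")


def to_fasta(seqs: dict[str, str]) -> str:
    return "".join(f">{name}\n{seq}\n" for name, seq in seqs.items())


# ---------------------------------------------------------------------------
# synthetic protein family with a planted motif


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Conditions for a synthetic family: a fixed-length motif planted into
    random flanks at a guaranteed per-column conservation level."""

    n_members: int = 29
    motif: str = "L-X(2)-G-X(3)-G-L-L-X-W"
    conservation: float = 0.90
    flank_length: tuple[int, int] = (10, 60)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.conservation <= 1.0:
            raise ValueError("conservation must lie in (0, 1]")
        if self.flank_length[0] < 0 or self.flank_length[1] < self.flank_length[0]:
            raise ValueError("bad flank length range")


@dataclass(frozen=True)
class FamilySample:
    """Generator output: sequences, a gapped alignment, and the truth."""

    sequences: dict[str, str]
    alignment: list[tuple[str, str]]
    motif_columns: tuple[int, int]           # half-open column interval
    fixed_columns: dict[int, str]            # column -> planted consensus residue
    spec: SyntheticFamilySpec


def generate_family(spec: SyntheticFamilySpec) -> FamilySample:
    """Plant a motif into ``n_members`` random sequences, deterministically.

    The motif must be fixed-length (every element with min_repeat ==
    max_repeat).  For each fixed (single-residue) motif position, exactly
    ``floor((1 - conservation) * n)`` members receive a substitute residue, so
    the realized column conservation is at least the requested level by
    construction — a deterministic guarantee rather than a sampling average.
    Wildcard and class positions draw uniformly from their allowed letters.
    Flanks are uniform-random residues with per-member lengths drawn from
    ``flank_length``; in the emitted alignment flanks are edge-padded with
    gaps.  Identical specs (same seed) yield identical output.
    """
    motif = spec.motif if isinstance(spec.motif, MotifPattern) else parse_pattern(spec.motif)
    if motif.min_span != motif.max_span:
        raise ValueError("planted motifs must be fixed-length")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_members
    if n == 0:
        return FamilySample({}, [], (0, 0), {}, spec)

    # expand motif into per-column matchers
    columns: list[frozenset | None] = []  # None = wildcard
    for el in motif.elements:
        for _ in range(el.min_repeat):
            if el.kind is ElementKind.WILDCARD:
                columns.append(None)
            elif el.kind is ElementKind.EXCLUDED:
                columns.append(frozenset(set(AA) - el.residues))
            else:
                columns.append(el.residues)

    span = len(columns)
    core = np.empty((n, span), dtype="<U1")
    fixed_cols: dict[int, str] = {}
    n_mut = int((1.0 - spec.conservation) * n)
    for j, allowed in enumerate(columns):
        if allowed is not None and len(allowed) == 1:
            consensus = next(iter(allowed))
            core[:, j] = consensus
            if n_mut:
                rows = rng.choice(n, size=n_mut, replace=False)
                others = sorted(set(AA) - {consensus})
                for r in rows:
                    core[r, j] = others[rng.integers(len(others))]
            fixed_cols[j] = consensus
        else:
            letters = sorted(allowed) if allowed is not None else list(AA)
            core[:, j] = [letters[k] for k in rng.integers(len(letters), size=n)]

    lo, hi = spec.flank_length
    left_len = rng.integers(lo, hi + 1, size=n)
    right_len = rng.integers(lo, hi + 1, size=n)
    lmax, rmax = int(left_len.max()), int(right_len.max())
    sequences: dict[str, str] = {}
    alignment: list[tuple[str, str]] = []
    for i in range(n):
        name = f"member{i + 1:03d}"
        left = "".join(AA[k] for k in rng.integers(20, size=int(left_len[i])))
        right = "".join(AA[k] for k in rng.integers(20, size=int(right_len[i])))
        mid = "".join(core[i])
        sequences[name] = left + mid + right
        aligned = "-" * (lmax - len(left)) + left + mid + right + "-" * (rmax - len(right))
        alignment.append((name, aligned))

    offset = lmax
    return FamilySample(
        sequences=sequences,
        alignment=alignment,
        motif_columns=(offset, offset + span),
        fixed_columns={offset + j: aa for j, aa in fixed_cols.items()},
        spec=spec,
    )


# ---------------------------------------------------------------------------
# synthetic GFF3 with known intron phases


def generate_gff(
    n_genes: int,
    exon_count_range: tuple[int, int] = (1, 11),
    exon_length_range: tuple[int, int] = (30, 300),
    intron_length_range: tuple[int, int] = (60, 500),
    seed: int = 0,
) -> tuple[str, dict]:
    """Fully-coding synthetic gene models as GFF3 text plus a truth table.

    Exon lengths are drawn uniformly, then the last exon is adjusted so the
    coding length is a multiple of three.  The truth maps each gene to its
    strand, exon count and the intron phases in transcription order (the
    phases are fixed at generation time from the cumulative coding length, so
    downstream phase computation can be checked against construction).
    """
    rng = np.random.default_rng(seed)
    lines = ["##gff-version 3"]
    truth: dict[str, dict] = {}
    pos = 1000
    for g in range(n_genes):
        gid = f"syng{g + 1:03d}"
        chrom = f"chr{g % 3 + 1}"
        strand = "+" if rng.integers(2) else "-"
        n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        lengths = [int(rng.integers(*exon_length_range)) for _ in range(n_exons)]
        excess = sum(lengths) % 3
        lengths[-1] += (3 - excess) % 3
        phases = [sum(lengths[: i + 1]) % 3 for i in range(n_exons - 1)]

        # lay exons down in genomic order; transcription order depends on strand
        genomic_lengths = lengths if strand == "+" else lengths[::-1]
        start = pos
        intervals = []
        for L in genomic_lengths:
            intervals.append((start, start + L - 1))  # 1-based inclusive
            start += L + int(rng.integers(*intron_length_range))
        gene_start, gene_end = intervals[0][0], intervals[-1][1]
        pos = gene_end + 2000

        def feat(ftype, s, e, attrs, phase="."):
            return f"{chrom}\tfamscreen_sim\t{ftype}\t{s}\t{e}\t.\t{strand}\t{phase}\t{attrs}"

        lines.append(feat("gene", gene_start, gene_end, f"ID={gid}"))
        mid = f"{gid}.t1"
        lines.append(feat("mRNA", gene_start, gene_end, f"ID={mid};Parent={gid}"))
        tx_intervals = intervals if strand == "+" else intervals[::-1]
        cum = 0
        for k, (s, e) in enumerate(tx_intervals):
            gff_phase = (3 - cum % 3) % 3
            lines.append(feat("exon", s, e, f"ID={mid}.exon{k + 1};Parent={mid}"))
            lines.append(feat("CDS", s, e, f"ID={mid}.cds;Parent={mid}", str(gff_phase)))
            cum += e - s + 1
        truth[gid] = {
            "chromosome": chrom,
            "strand": strand,
            "n_exons": n_exons,
            "phases": phases,
        }
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# synthetic FPKM matrix with planted effects


def generate_expression(
    n_genes: int = 30,
    n_pairs: int = 2,
    effect: float = 4.0,
    frac_up: float = 0.3,
    frac_down: float = 0.2,
    frac_silent: float = 0.1,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """FPKM matrix with ``n_pairs`` treatment/control column pairs and a truth
    table of planted calls.

    Planted "up" genes have treatment = control * effect, "down" genes
    treatment = control / effect, "unchanged" genes identical values, and
    "not-expressed" genes sit below the expressed-gene threshold in both
    columns.  Effect genes get a control floor well above the threshold so
    the planted class is recoverable exactly.
    """
    if effect <= 1.0:
        raise ValueError("effect must exceed 1")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i + 1:03d}" for i in range(n_genes)]
    n_up = int(frac_up * n_genes)
    n_down = int(frac_down * n_genes)
    n_silent = int(frac_silent * n_genes)
    labels = (["up"] * n_up + ["down"] * n_down + ["not-expressed"] * n_silent)
    labels += ["unchanged"] * (n_genes - len(labels))
    rng.shuffle(labels)

    values = {}
    truth_rows = []
    for p in range(n_pairs):
        treat, ctrl = f"treat{p + 1}", f"control{p + 1}"
        c = np.empty(n_genes)
        t = np.empty(n_genes)
        for i, lab in enumerate(labels):
            if lab == "not-expressed":
                c[i] = t[i] = rng.uniform(0.0, 0.8)
            else:
                c[i] = rng.lognormal(mean=2.5, sigma=0.5) + 5.0
                if lab == "up":
                    t[i] = c[i] * effect
                elif lab == "down":
                    t[i] = c[i] / effect
                else:
                    t[i] = c[i]
            truth_rows.append({"gene": genes[i], "condition": treat, "call": lab})
        values[ctrl] = c
        values[treat] = t

    df = pd.DataFrame(values, index=genes)
    pairing = {f"treat{p + 1}": f"control{p + 1}" for p in range(n_pairs)}
    return ExpressionMatrix(values=df, pairing=pairing), pd.DataFrame(truth_rows)
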