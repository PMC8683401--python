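"""FPKM expression matrices: expressed-gene calling and fold-change classes.

Follows the conventions of transcriptome re-analysis work on gene families:
a gene is "expressed" in a condition when FPKM strictly exceeds ``min_fpkm``
(default 1); fold change against the paired control is computed on
pseudo-counted values, fc = log2((t + pseudo) / (c + pseudo)); the call is
``up`` for fc > 0, ``down`` for fc < 0 and ``unchanged`` for fc = 0 (a
threshold of 0 in the fold-change sense).  When both treatment and control
sit at or below ``min_fpkm`` the gene is called ``not-expressed`` for that
comparison instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "FoldChangeCall",
    "expressed_genes",
    "fold_change",
    "condition_summary",
    "read_matrix_tsv",
    "read_pairing",
    "calls_to_frame",
]

CALLS = ("up", "down", "unchanged", "not-expressed")


@dataclass
class ExpressionMatrix:
    """Gene x condition FPKM values plus treatment->control column pairing."""

    values: pd.DataFrame
    pairing: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        missing = (set(self.pairing) | set(self.pairing.values())) - set(self.values.columns)
        if missing:
            raise ValueError(f"pairing references unknown column(s): {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class FoldChangeCall:
    gene: str
    condition: str
    fc: float          # log2 ratio vs paired control
    call: str

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")

    @property
    def linear_fc(self) -> float:
        """The same ratio on the linear scale (2**fc), for reports that
        quote fold changes as plain ratios."""
        return 2.0 ** self.fc


def expressed_genes(matrix: ExpressionMatrix, min_fpkm: float = 1.0) -> dict[str, set[str]]:
    """Per-condition sets of genes with FPKM strictly above ``min_fpkm``."""
    out = {}
    for cond in matrix.conditions:
        col = matrix.values[cond]
        out[cond] = set(col.index[col > min_fpkm])
    return out


def fold_change(
    matrix: ExpressionMatrix,
    pseudo: float = 1.0,
    min_fpkm: float = 1.0,
) -> list[FoldChangeCall]:
    """Fold-change calls for every gene in every paired treatment column.

    Raises ``ValueError`` when the matrix declares no pairing.
    """
    if not matrix.pairing:
        raise ValueError("no treatment->control pairing defined")
    calls = []
    for treat, ctrl in matrix.pairing.items():
        for gene in matrix.genes:
            t = float(matrix.values.at[gene, treat])
            c = float(matrix.values.at[gene, ctrl])
            fc = math.log2((t + pseudo) / (c + pseudo))
            if t <= min_fpkm and c <= min_fpkm:
                call = "not-expressed"
            elif fc > 0:
                call = "up"
            elif fc < 0:
                call = "down"
            else:
                call = "unchanged"
            calls.append(FoldChangeCall(gene, treat, fc, call))
    return calls


def condition_summary(calls) -> pd.DataFrame:
    """Counts of each call class per condition (classes always present)."""
    df = calls_to_frame(calls)
    if df.empty:
        return pd.DataFrame(columns=list(CALLS))
    table = (
        df.pivot_table(index="condition", columns="call", aggfunc="size", fill_value=0)
        .reindex(columns=list(CALLS), fill_value=0)
    )
    table.columns.name = None
    return table


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "condition": [c.condition for c in calls],
            "log2_fc": [c.fc for c in calls],
            "linear_fc": [c.linear_fc for c in calls],
            "call": [c.call for c in calls],
        }
    )


def read_matrix_tsv(path, pairing: dict[str, str] | None = None) -> ExpressionMatrix:
    """Read a genes x conditions FPKM table (first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return ExpressionMatrix(values=df.astype(float), pairing=pairing or {})


def read_pairing(path) -> dict[str, str]:
    """Read treatment->control pairing from YAML (mapping) or 2-column TSV."""
    text = open(path).read()
    if str(path).endswith((".yaml", ".yml")):
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("pairing YAML must be a mapping treatment: control")
        return {str(k): str(v) for k, v in data.items()}
    pairs = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"bad pairing line: {line!r}")
        pairs[fields[0].strip()] = fields[1].strip()
    return pairs
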