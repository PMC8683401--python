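"""Family-membership screening of candidate proteins.

A candidate is accepted when it is full-length (strictly more than
``min_length`` residues), carries every required primary domain (by default
the cyclic-nucleotide-binding domain ``cNMP`` and the ion-transport domain
``IT``), and — when a consensus key and the sequence are both available —
matches the family-specific motif key.  Rejections carry machine-readable
reason labels (``short-sequence``, ``missing-domain:<name>``,
``key-mismatch``).

Domain calls are inputs (e.g. an InterProScan/SMART/Pfam-style table); this
module performs no domain detection of its own.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .pattern_engine import MotifPattern, count_matches

__all__ = [
    "CandidateRecord",
    "ScreenDecision",
    "screen",
    "summarize",
    "read_candidates_tsv",
    "decisions_to_frame",
]

KNOWN_DOMAINS = frozenset({"cNMP", "IT", "CaMBD", "IQ"})


@dataclass(frozen=True)
class CandidateRecord:
    """One putative family member and its annotations."""

    accession: str
    length: int | None = None
    domain_calls: frozenset[str] = frozenset()
    sequence: str | None = None
    gene: str | None = None
    chromosome: str | None = None
    start: int | None = None
    stop: int | None = None
    strand: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "domain_calls", frozenset(self.domain_calls))
        if self.length is not None and self.length <= 0:
            raise ValueError(f"{self.accession}: non-positive length")
        if self.start is not None and self.stop is not None and self.start >= self.stop:
            raise ValueError(f"{self.accession}: start must precede stop")
        if self.strand is not None and self.strand not in "+-":
            raise ValueError(f"{self.accession}: strand must be '+' or '-'")

    @property
    def label(self) -> str:
        """Preferred display id: gene name when assigned, else accession."""
        return self.gene or self.accession


@dataclass(frozen=True)
class ScreenDecision:
    accession: str
    accepted: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.accepted == (len(self.reasons) == 0)


def screen(
    candidates,
    min_length: int = 500,
    required_domains=frozenset({"cNMP", "IT"}),
    key: MotifPattern | None = None,
    strict_length: bool = True,
) -> list[ScreenDecision]:
    """Apply the membership rules to each candidate, in input order.

    ``strict_length`` keeps the published "> min_length" reading; set it to
    False for ">=".  Key validation is applied only to candidates that carry
    a sequence.  A candidate without a length raises ``ValueError`` naming
    its accession.
    """
    required = frozenset(required_domains)
    decisions = []
    for c in candidates:
        if c.length is None:
            raise ValueError(f"candidate {c.accession} has no length")
        reasons: list[str] = []
        long_enough = c.length > min_length if strict_length else c.length >= min_length
        if not long_enough:
            reasons.append("short-sequence")
        for dom in sorted(required - c.domain_calls):
            reasons.append(f"missing-domain:{dom}")
        if key is not None and c.sequence is not None:
            if count_matches(key, c.sequence) == 0:
                reasons.append("key-mismatch")
        decisions.append(
            ScreenDecision(c.accession, accepted=not reasons, reasons=tuple(reasons))
        )
    return decisions


def summarize(decisions) -> dict:
    """Counts of accepted/rejected decisions and of each rejection reason."""
    decisions = list(decisions)
    accepted = sum(d.accepted for d in decisions)
    by_reason = Counter(r for d in decisions for r in d.reasons)
    return {
        "total": len(decisions),
        "accepted": accepted,
        "rejected": len(decisions) - accepted,
        "by_reason": dict(by_reason),
    }


def read_candidates_tsv(path, sequences: dict[str, str] | None = None) -> list[CandidateRecord]:
    """Read a candidate table (columns as in the packaged family fixture).

    Recognized columns: accession (required), length_aa, primary_domains,
    secondary_domains (comma-separated), gene, chromosome, start, stop,
    strand, group.  ``sequences`` optionally attaches protein sequences by
    accession.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "accession" not in df.columns:
        raise ValueError("candidate table needs an 'accession' column")
    records = []
    for row in df.itertuples(index=False):
        get = lambda col: getattr(row, col, None)
        domains: set[str] = set()
        for col in ("primary_domains", "secondary_domains"):
            val = get(col)
            if isinstance(val, str) and val.strip():
                domains |= {d.strip() for d in val.split(",") if d.strip()}
        length = get("length_aa")
        start, stop = get("start"), get("stop")
        strand = get("strand")
        records.append(
            CandidateRecord(
                accession=row.accession,
                length=int(float(length)) if _present(length) else None,
                domain_calls=frozenset(domains),
                sequence=(sequences or {}).get(row.accession),
                gene=get("gene") if _present(get("gene")) else None,
                chromosome=get("chromosome") if _present(get("chromosome")) else None,
                start=int(float(start)) if _present(start) else None,
                stop=int(float(stop)) if _present(stop) else None,
                strand=strand.strip() if _present(strand) else None,
                group=get("group") if _present(get("group")) else None,
            )
        )
    return records


def _present(val) -> bool:
    return isinstance(val, str) and val.strip() != "" or (
        not isinstance(val, str) and val is not None and pd.notna(val)
    )


def decisions_to_frame(decisions) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "accession": [d.accession for d in decisions],
            "accepted": [d.accepted for d in decisions],
            "reasons": [";".join(d.reasons) for d in decisions],
        }
    )
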