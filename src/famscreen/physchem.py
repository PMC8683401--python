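"""Per-protein physicochemical properties in the ProtParam tradition.

Computes length, average molecular weight, theoretical pI, net charge at a
given pH, instability index (Guruprasad dipeptide weights), aliphatic index,
GRAVY (mean Kyte-Doolittle hydropathy), average residue weight, and amino-acid
and atomic compositions.

Molecular weight, GRAVY and amino-acid composition are delegated to
Biopython's ``ProteinAnalysis``; the Kyte-Doolittle, DIWV and Bjellqvist pKa
constants are taken from the same library so that swapping in an alternative
pKa set remains a one-line configuration.  Net charge is a
Henderson-Hasselbalch sum over the side chains D, E, C, Y, H, K, R and the two
termini (with the Bjellqvist residue-specific terminal pKa adjustments); the
theoretical pI is the pH at which that sum vanishes, found by bisection on
[0, 14] — net charge is strictly decreasing in pH, so the root is unique.

Ambiguity policy: ``strict`` (default) raises on non-standard letters, which
is what faithful reproduction of published property tables requires;
``lenient`` gives unknown letters the mean residue mass, zero hydropathy, and
excludes them from composition-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils.ProtParamData import DIWV, kd
from Bio.SeqUtils import IsoelectricPoint as _ip

import pandas as pd

__all__ = [
    "PhyschemReport",
    "molecular_weight",
    "gravy",
    "aliphatic_index",
    "instability_index",
    "net_charge",
    "isoelectric_point",
    "amino_acid_composition",
    "atomic_composition",
    "full_report",
    "table_report",
]

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
WATER = 18.0153  # average mass of one water, added once per chain

# residue (free amino acid minus water) elemental formulas: (C, H, N, O, S)
_RESIDUE_ATOMS: dict[str, tuple[int, int, int, int, int]] = {
    "A": (3, 5, 1, 1, 0), "R": (6, 12, 4, 1, 0), "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0), "C": (3, 5, 1, 1, 1), "E": (5, 7, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0), "G": (2, 3, 1, 1, 0), "H": (6, 7, 3, 1, 0),
    "I": (6, 11, 1, 1, 0), "L": (6, 11, 1, 1, 0), "K": (6, 12, 2, 1, 0),
    "M": (5, 9, 1, 1, 1), "F": (9, 9, 1, 1, 0), "P": (5, 7, 1, 1, 0),
    "S": (3, 5, 1, 2, 0), "T": (4, 7, 1, 2, 0), "W": (11, 10, 2, 1, 0),
    "Y": (9, 9, 1, 2, 0), "V": (5, 9, 1, 1, 0),
}

_MEAN_RESIDUE_MASS = 110.0  # lenient-mode stand-in mass for unknown letters

# Bjellqvist pKa constants as shipped with Biopython's IsoelectricPoint
_POS_PK = dict(_ip.positive_pKs)      # {'Nterm': .., 'K': .., 'R': .., 'H': ..}
_NEG_PK = dict(_ip.negative_pKs)      # {'Cterm': .., 'D': .., 'E': .., 'C': .., 'Y': ..}
_PK_NTERM = dict(_ip.pKnterminal)     # residue-specific N-terminal overrides
_PK_CTERM = dict(_ip.pKcterminal)     # residue-specific C-terminal overrides


def _prepare(seq: str, policy: str) -> str:
    seq = seq.upper().replace("*", "")
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    unknown = set(seq) - STANDARD_AA
    if unknown and policy == "strict":
        raise ValueError(
            f"non-standard letter(s) {''.join(sorted(unknown))!r}; "
            "use policy='lenient' to tolerate them"
        )
    return seq


def molecular_weight(seq: str, policy: str = "strict") -> float:
    """Average-isotope molecular weight in Da (residue masses + one water)."""
    seq = _prepare(seq, policy)
    clean = "".join(c for c in seq if c in STANDARD_AA)
    n_unknown = len(seq) - len(clean)
    if not clean and not n_unknown:
        raise ValueError("empty sequence")
    mw = ProteinAnalysis(clean).molecular_weight() if clean else WATER
    return mw + n_unknown * _MEAN_RESIDUE_MASS


def gravy(seq: str, policy: str = "strict") -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle over all residues."""
    seq = _prepare(seq, policy)
    if not seq:
        raise ValueError("empty sequence")
    return sum(kd.get(c, 0.0) for c in seq) / len(seq)


def aliphatic_index(seq: str, policy: str = "strict") -> float:
    """Ikai aliphatic index: 100*(fA + 2.9*fV + 3.9*(fI + fL)), mole fractions."""
    seq = _prepare(seq, policy)
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    f = {aa: seq.count(aa) / n for aa in "AVIL"}
    return 100.0 * (f["A"] + 2.9 * f["V"] + 3.9 * (f["I"] + f["L"]))


def instability_index(seq: str, policy: str = "strict") -> float:
    """Guruprasad instability index: (10/L) * sum of DIWV dipeptide weights.

    A value above 40 predicts an unstable protein in vitro.  Sequences shorter
    than two residues have no dipeptides; the index is defined as 0 for them.
    Under the lenient policy, dipeptides touching an unknown letter contribute
    a neutral weight of 0.
    """
    seq = _prepare(seq, policy)
    if len(seq) < 2:
        return 0.0
    total = 0.0
    for a, b in zip(seq, seq[1:]):
        try:
            total += DIWV[a][b]
        except KeyError:
            pass  # lenient: unknown-letter dipeptides are neutral
    return 10.0 / len(seq) * total


def net_charge(seq: str, pH: float = 7.0, policy: str = "strict") -> float:
    """Henderson-Hasselbalch net charge of the chain at the given pH."""
    seq = _prepare(seq, policy)
    if not seq:
        raise ValueError("empty sequence")
    pos_pk = dict(_POS_PK)
    neg_pk = dict(_NEG_PK)
    if seq[0] in _PK_NTERM:
        pos_pk["Nterm"] = _PK_NTERM[seq[0]]
    if seq[-1] in _PK_CTERM:
        neg_pk["Cterm"] = _PK_CTERM[seq[-1]]
    counts = {aa: seq.count(aa) for aa in "KRHDECY"}
    charge = 0.0
    for group, pk in pos_pk.items():
        n = 1 if group == "Nterm" else counts.get(group, 0)
        charge += n / (1.0 + 10.0 ** (pH - pk))
    for group, pk in neg_pk.items():
        n = 1 if group == "Cterm" else counts.get(group, 0)
        charge -= n / (1.0 + 10.0 ** (pk - pH))
    return charge


def isoelectric_point(seq: str, tol: float = 1e-3, policy: str = "strict") -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14]."""
    seq = _prepare(seq, policy)
    lo, hi = 0.0, 14.0
    if net_charge(seq, lo) < 0:
        return lo
    if net_charge(seq, hi) > 0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def amino_acid_composition(seq: str, policy: str = "strict") -> dict[str, float]:
    """Residue mole fractions over the standard letters (sums to 1)."""
    seq = _prepare(seq, policy)
    clean = [c for c in seq if c in STANDARD_AA]
    if not clean:
        raise ValueError("no standard residues in sequence")
    n = len(clean)
    return {aa: clean.count(aa) / n for aa in sorted(STANDARD_AA)}


def atomic_composition(seq: str, policy: str = "strict") -> dict[str, int]:
    """Element counts C/H/N/O/S of the chain (residues + one water)."""
    seq = _prepare(seq, policy)
    totals = [0, 0, 0, 0, 0]
    for c in seq:
        if c in _RESIDUE_ATOMS:
            for i, v in enumerate(_RESIDUE_ATOMS[c]):
                totals[i] += v
    totals[1] += 2  # H2O closing the chain
    totals[3] += 1
    return dict(zip("CHNOS", totals))


@dataclass(frozen=True)
class PhyschemReport:
    """One protein's property vector (one published-table row's worth)."""

    name: str
    length: int
    mw: float                      # Da
    pI: float
    instability: float
    aliphatic: float
    gravy: float
    avg_residue_weight: float      # g/mol, = mw / length
    net_charge: float              # at charge_pH
    charge_pH: float
    aa_composition: dict[str, float] = field(repr=False)
    atomic_composition: dict[str, int] = field(repr=False)

    @property
    def mw_kda(self) -> float:
        return self.mw / 1000.0


def full_report(seq: str, name: str = "", charge_pH: float = 7.0,
                policy: str = "strict") -> PhyschemReport:
    seq = _prepare(seq, policy)
    if not seq:
        raise ValueError("empty sequence")
    mw = molecular_weight(seq, policy)
    return PhyschemReport(
        name=name,
        length=len(seq),
        mw=mw,
        pI=isoelectric_point(seq, policy=policy),
        instability=instability_index(seq, policy),
        aliphatic=aliphatic_index(seq, policy),
        gravy=gravy(seq, policy),
        avg_residue_weight=mw / len(seq),
        net_charge=net_charge(seq, charge_pH, policy),
        charge_pH=charge_pH,
        aa_composition=amino_acid_composition(seq, policy),
        atomic_composition=atomic_composition(seq, policy),
    )


def table_report(named_seqs, charge_pH: float = 7.0,
                 policy: str = "strict") -> pd.DataFrame:
    """Property table for many proteins, mirroring the published column order.

    ``named_seqs`` is an iterable of ``(name, sequence)`` pairs.  Rounding
    follows the published precision (MW in kDa to 2 decimals, indices to 2,
    GRAVY to 3); raw values are available through :func:`full_report`.
    """
    rows = []
    for name, seq in named_seqs:
        r = full_report(seq, name=name, charge_pH=charge_pH, policy=policy)
        rows.append(
            {
                "protein": r.name,
                "length_aa": r.length,
                "mw_kda": round(r.mw_kda, 2),
                "pi": round(r.pI, 2),
                "instability": round(r.instability, 2),
                "aliphatic": round(r.aliphatic, 2),
                "gravy": round(r.gravy, 3),
                "avg_residue_weight": round(r.avg_residue_weight, 3),
                "charge": round(r.net_charge, 1),
            }
        )
    return pd.DataFrame(rows)
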