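"""Physicochemical properties: closed-form cases, invariants, and
cross-checks against Biopython's independent ProtParam implementations."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

from famscreen.physchem import (
    WATER,
    aliphatic_index,
    amino_acid_composition,
    atomic_composition,
    full_report,
    gravy,
    instability_index,
    isoelectric_point,
    molecular_weight,
    net_charge,
    table_report,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
seqs = st.text(alphabet=AA, min_size=1, max_size=40)


class TestMolecularWeight:
    def test_glycine(self):
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    def test_diglycine(self):
        assert molecular_weight("GG") == pytest.approx(132.12, abs=0.01)

    @settings(max_examples=60, derandomize=True)
    @given(seqs, seqs)
    def test_additivity_minus_one_water(self, a, b):
        assert molecular_weight(a + b) == pytest.approx(
            molecular_weight(a) + molecular_weight(b) - WATER, abs=1e-3
        )

    def test_strict_policy_rejects_ambiguity_codes(self):
        with pytest.raises(ValueError, match="non-standard"):
            molecular_weight("AXC")
        assert molecular_weight("AXC", policy="lenient") > molecular_weight(
            "AC", policy="lenient"
        )


class TestGravy:
    def test_extremes(self):
        assert gravy("I") == 4.5
        assert gravy("R") == -4.5

    @settings(max_examples=60, derandomize=True)
    @given(seqs, seqs)
    def test_concatenation_is_length_weighted_mean(self, a, b):
        expected = (gravy(a) * len(a) + gravy(b) * len(b)) / (len(a) + len(b))
        assert gravy(a + b) == pytest.approx(expected)

    @settings(max_examples=40, derandomize=True)
    @given(seqs)
    def test_bounded_by_hydropathy_scale(self, s):
        assert -4.5 <= gravy(s) <= 4.5

    @settings(max_examples=40, derandomize=True)
    @given(seqs)
    def test_matches_biopython(self, s):
        assert gravy(s) == pytest.approx(ProteinAnalysis(s).gravy(), abs=1e-9)


class TestAliphaticIndex:
    def test_pure_alanine_and_valine(self):
        assert aliphatic_index("AAAAA") == pytest.approx(100.0)
        assert aliphatic_index("VVV") == pytest.approx(290.0)

    def test_ile_leu_weight(self):
        assert aliphatic_index("IL") == pytest.approx(390.0)
        assert aliphatic_index("GGGG") == 0.0


class TestInstabilityIndex:
    def test_no_dipeptides_defined_as_zero(self):
        assert instability_index("A") == 0.0

    @pytest.mark.parametrize("n", [2, 5, 20])
    def test_poly_alanine_closed_form(self, n):
        # DIWV(A,A) = 1.0, so the index is 10*(n-1)/n
        assert instability_index("A" * n) == pytest.approx(10.0 * (n - 1) / n)

    @settings(max_examples=40, derandomize=True)
    @given(seqs.filter(lambda s: len(s) >= 2))
    def test_matches_biopython(self, s):
        assert instability_index(s) == pytest.approx(
            ProteinAnalysis(s).instability_index(), abs=1e-6
        )


class TestCharge:
    def test_lysine_positive_at_neutral_pH(self):
        assert net_charge("K", 7.0) == pytest.approx(1.0, abs=0.35)
        assert net_charge("K", 7.0) > 0

    @pytest.mark.parametrize("seq", ["KRDE", "ACDY", "MKHHE", "GGG"])
    def test_strictly_decreasing_in_pH(self, seq):
        charges = [net_charge(seq, pH) for pH in (0, 2, 4, 6, 8, 10, 12, 14)]
        assert all(a > b for a, b in zip(charges, charges[1:]))

    @settings(max_examples=40, derandomize=True)
    @given(seqs, st.floats(0.0, 14.0))
    def test_matches_biopython_henderson_hasselbalch(self, s, pH):
        assert net_charge(s, pH) == pytest.approx(
            IsoelectricPoint(s).charge_at_pH(pH), abs=1e-9
        )


class TestIsoelectricPoint:
    def test_charge_vanishes_at_pI(self):
        for seq in ("KRDE", "ACDY", "MKHHE", "KKKK", "DDDD"):
            assert net_charge(seq, isoelectric_point(seq)) == pytest.approx(0.0, abs=0.01)

    def test_bisection_agrees_with_grid_scan_oracle(self):
        rng = random.Random(42)
        for _ in range(25):
            seq = "".join(rng.choices(AA, k=30))
            # oracle: fine grid scan for the sign change of the charge curve
            grid = (i * 1e-3 for i in range(14001))
            # charge is monotone decreasing in pH, so the oracle value is the
            # first grid pH at which the charge is non-positive
            first_nonpos = next(pH for pH in grid if net_charge(seq, pH) <= 0)
            assert isoelectric_point(seq) == pytest.approx(first_nonpos, abs=2e-3)

    @settings(max_examples=25, derandomize=True)
    @given(seqs)
    def test_matches_biopython_pi(self, s):
        # Biopython's pi() bisects on |charge| rather than on pH width (and
        # clamps to [4.05, 12] by default), so agreement is looser than the
        # grid-scan oracle above
        reference = IsoelectricPoint(s).pi(min_=0.0, max_=14.0)
        assert isoelectric_point(s) == pytest.approx(reference, abs=0.05)

    @settings(max_examples=30, derandomize=True)
    @given(seqs)
    def test_basic_residue_never_lowers_acidic_never_raises(self, s):
        base = isoelectric_point(s)
        assert isoelectric_point(s + "K") >= base - 2e-3
        assert isoelectric_point(s + "D") <= base + 2e-3


class TestReport:
    def test_composition_sums_to_one(self):
        comp = amino_acid_composition("AAG")
        assert comp["A"] == pytest.approx(2 / 3)
        assert comp["G"] == pytest.approx(1 / 3)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_atomic_composition_of_glycine_is_free_amino_acid(self):
        assert atomic_composition("G") == {"C": 2, "H": 5, "N": 1, "O": 2, "S": 0}

    def test_full_report_consistency(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ"
        r = full_report(seq, name="demo")
        assert r.length == len(seq)
        assert r.avg_residue_weight == pytest.approx(r.mw / r.length)
        assert r.mw_kda == pytest.approx(r.mw / 1000)
        assert sum(r.aa_composition.values()) == pytest.approx(1.0, abs=1e-9)
        # hydrogen dominates the elemental makeup of ordinary globular protein
        assert max(r.atomic_composition, key=r.atomic_composition.get) == "H"

    def test_table_report_column_order(self):
        df = table_report([("p1", "MKTAYIAK"), ("p2", "GGSSEE")])
        assert list(df.columns) == [
            "protein", "length_aa", "mw_kda", "pi", "instability",
            "aliphatic", "gravy", "avg_residue_weight", "charge",
        ]
        assert len(df) == 2
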