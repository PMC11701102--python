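"""HX-MS uptake, relative protection and residue consolidation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ringstat.hxms import (
    PeptideExchange,
    apply_baseline_filter,
    protection_table,
    read_peptide_table,
    residue_consolidation,
    uptake_fraction,
    write_protection_table,
)
from ringstat.synthetic import HxSpec, make_hx_tables


def pep(pid, start, end, condition, exchange_pct, m0=1000.0, span=10.0):
    """Peptide whose noise-free uptake equals ``exchange_pct``."""
    return PeptideExchange(
        peptide_id=pid,
        start=start,
        end=end,
        condition=condition,
        m0=m0,
        m_t=m0 + span * exchange_pct / 100.0,
        m100=m0 + span,
    )


class TestUptakeFraction:
    @pytest.mark.parametrize(
        "m_t, expected",
        [(1000.0, 0.0), (1010.0, 1.0), (1005.0, 0.5)],
    )
    def test_interpolation(self, m_t, expected):
        assert uptake_fraction(m_t, 1000.0, 1010.0) == pytest.approx(expected)

    def test_clamped_to_unit_interval(self):
        assert uptake_fraction(999.0, 1000.0, 1010.0) == 0.0
        assert uptake_fraction(1011.0, 1000.0, 1010.0) == 1.0

    def test_invalid_controls(self):
        with pytest.raises(ValueError):
            uptake_fraction(1005.0, 1010.0, 1000.0)


class TestProtectionTable:
    def _records(self, baseline_pct, ligand_pct):
        base = [pep("p1", 5, 14, "baseline", baseline_pct)]
        lig = [pep("p1", 5, 14, "ligand", ligand_pct)]
        records, unmatched = protection_table(base, lig)
        assert unmatched == []
        return records[0]

    def test_full_protection_scores_100(self):
        r = self._records(40.0, 0.0)
        assert r.relative_protection == pytest.approx(100.0)
        assert r.relative_exchange == pytest.approx(0.0)

    def test_no_protection_scores_0(self):
        r = self._records(40.0, 40.0)
        assert r.relative_protection == pytest.approx(0.0)
        assert r.relative_exchange == pytest.approx(100.0)

    def test_partial_protection(self):
        r = self._records(40.0, 30.0)
        assert r.relative_protection == pytest.approx(25.0)
        assert r.relative_exchange == pytest.approx(75.0)

    def test_deprotection_is_negative(self):
        r = self._records(40.0, 50.0)
        assert r.relative_protection == pytest.approx(-25.0)

    @given(
        baseline=st.floats(1.0, 100.0),
        ligand=st.floats(0.0, 100.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_exchange_plus_protection_identity(self, baseline, ligand):
        r = self._records(baseline, ligand)
        assert r.relative_exchange + r.relative_protection == pytest.approx(100.0, abs=1e-9)

    def test_zero_baseline_yields_nan_not_shown(self):
        r = self._records(0.0, 0.0)
        assert math.isnan(r.relative_exchange)
        assert not r.shown

    def test_charge_states_averaged_before_scoring(self):
        base = [
            PeptideExchange("p1", 5, 14, "baseline", m0=1000.0, m_t=1004.0, m100=1010.0, charge=2),
            PeptideExchange("p1", 5, 14, "baseline", m0=1000.0, m_t=1006.0, m100=1010.0, charge=3),
        ]
        lig = [pep("p1", 5, 14, "ligand", 25.0)]
        records, _ = protection_table(base, lig)
        assert records[0].baseline_exchange == pytest.approx(50.0)
        assert records[0].relative_protection == pytest.approx(50.0)

    def test_unmatched_peptides_reported(self):
        base = [pep("p1", 5, 14, "baseline", 40.0), pep("p2", 20, 29, "baseline", 40.0)]
        lig = [pep("p1", 5, 14, "ligand", 10.0)]
        records, unmatched = protection_table(base, lig)
        assert len(records) == 1
        assert unmatched == [(20, 29, "")]

    def test_no_matches_raises(self):
        with pytest.raises(ValueError):
            protection_table(
                [pep("p1", 5, 14, "baseline", 40.0)],
                [pep("p2", 50, 59, "ligand", 40.0)],
            )


class TestBaselineFilter:
    @pytest.mark.parametrize(
        "baseline, shown", [(9.9, False), (10.0, True), (10.1, True)]
    )
    def test_threshold_boundary_inclusive(self, baseline, shown):
        base = [pep("p1", 1, 10, "baseline", baseline)]
        lig = [pep("p1", 1, 10, "ligand", baseline / 2)]
        records, _ = protection_table(base, lig)
        assert records[0].shown is shown

    def test_filter_idempotent_and_preserves_records(self):
        base = [pep(f"p{i}", i, i + 9, "baseline", float(i)) for i in range(1, 21)]
        lig = [pep(f"p{i}", i, i + 9, "ligand", float(i) / 2) for i in range(1, 21)]
        records, _ = protection_table(base, lig)
        once = apply_baseline_filter(records)
        twice = apply_baseline_filter(once)
        assert once == twice
        assert len(once) == 20
        assert sum(r.shown for r in once) == 11  # baselines 10..20

    def test_synthetic_table_shown_count_matches_generator(self):
        _, _, truth = make_hx_tables(HxSpec(seed=11))
        baseline, ligand, _ = make_hx_tables(HxSpec(seed=11))
        records, _ = protection_table(baseline, ligand)
        assert sum(r.shown for r in records) == sum(p["shown"] for p in truth.peptides)


class TestResidueConsolidation:
    def _record(self, start, end, rel_ex, shown=True):
        base = [pep("x", start, end, "baseline", 50.0)]
        lig = [pep("x", start, end, "ligand", 50.0 * rel_ex / 100.0)]
        r, _ = protection_table(base, lig)
        return r[0]

    def test_single_peptide_paints_its_residues(self):
        values = residue_consolidation([self._record(5, 8, 60.0)], length=12)
        assert np.allclose(values[4:8], 60.0)
        assert np.isnan(values[:4]).all() and np.isnan(values[8:]).all()

    def test_overlap_averages(self):
        records = [self._record(5, 8, 60.0), self._record(7, 10, 80.0)]
        values = residue_consolidation(records, length=12)
        assert np.allclose(values[4:6], 60.0)
        assert np.allclose(values[6:8], 70.0)
        assert np.allclose(values[8:10], 80.0)

    def test_hidden_peptides_excluded(self):
        base = [pep("x", 1, 4, "baseline", 5.0)]  # below display threshold
        lig = [pep("x", 1, 4, "ligand", 1.0)]
        hidden, _ = protection_table(base, lig)
        records = [self._record(5, 8, 60.0)] + hidden
        values = residue_consolidation(records, length=10)
        assert np.isnan(values[:4]).all()

    def test_synthetic_profile_recovered(self):
        spec = HxSpec(seed=11)
        baseline, ligand, truth = make_hx_tables(spec)
        records, _ = protection_table(baseline, ligand)
        values = residue_consolidation(records, spec.protein_length)
        expected = truth.residue_relative_exchange
        both = ~np.isnan(values) & ~np.isnan(expected)
        assert (np.isnan(values) == np.isnan(expected)).all()
        assert np.allclose(values[both], expected[both], atol=1e-9)

    def test_constant_profile_returns_constant(self):
        spec = HxSpec(seed=4, baseline_profile=lambda r: 50.0,
                      protection_profile=lambda r: 30.0)
        baseline, ligand, _ = make_hx_tables(spec)
        records, _ = protection_table(baseline, ligand)
        values = residue_consolidation(records, spec.protein_length)
        covered = ~np.isnan(values)
        assert np.allclose(values[covered], 70.0, atol=1e-9)


class TestTableIO:
    def test_tsv_roundtrip(self, tmp_path):
        baseline, ligand, _ = make_hx_tables(HxSpec(seed=2, noise_sd=0.01))
        rows = ["peptide_id\tstart\tend\tsequence\tcondition\tcharge\tm0\tm_t\tm100"]
        for p in baseline + ligand:
            rows.append(
                f"{p.peptide_id}\t{p.start}\t{p.end}\t{p.sequence}\t{p.condition}"
                f"\t{p.charge}\t{p.m0!r}\t{p.m_t!r}\t{p.m100!r}"
            )
        path = tmp_path / "peptides.tsv"
        path.write_text("\n".join(rows) + "\n")
        back = read_peptide_table(path)
        assert len(back) == len(baseline) + len(ligand)
        records, _ = protection_table(
            [p for p in back if p.condition == "baseline"],
            [p for p in back if p.condition == "ligand"],
        )
        out = tmp_path / "protection.tsv"
        write_protection_table(records, out)
        assert out.read_text().startswith("peptide_id\t")
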