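import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrotemp.amino_acids import AMINO_ACIDS, CLASSES, MAX_ASA_THEORETICAL, REFERENCE_TYPES
from hydrotemp.errors import EmptyBin, ZeroArea, ZeroCell, ZeroContacts
from hydrotemp.potentials import (
    BinCounts,
    aggregate_bin_counts,
    area_energy,
    chain_to_counts,
    compute_potential_table,
    contact_energy,
    get_cell,
    reference_correct,
    reference_energy,
    surface_energy,
)

from conftest import chain_from_alphas


def make_counts(n, buried, alpha_sum, q=4.0):
    return BinCounts("test", np.asarray(n), np.asarray(buried),
                     np.asarray(alpha_sum, dtype=float), q=q)


def two_type_counts(q=4.0):
    """Types ALA (2 residues, alpha 0.5 each) and ARG (2 residues, alpha 0.1)."""
    n = np.zeros(20, dtype=np.int64)
    buried = np.zeros(20, dtype=np.int64)
    alpha = np.zeros(20)
    n[0] = 2; alpha[0] = 1.0      # ALA
    n[1] = 2; alpha[1] = 0.2      # ARG
    return make_counts(n, buried, alpha, q=q)


class TestAggregation:
    def test_strict_burial_cutoff(self):
        chain = chain_from_alphas(
            [("ALA", 0.0), ("ALA", 0.069), ("ALA", 0.07), ("ALA", 0.5)]
        )
        counts = aggregate_bin_counts([chain])
        assert counts.total_buried == 2  # 0.07 itself is NOT buried

    def test_water_contacts(self):
        chain = chain_from_alphas([("ALA", 0.25)])
        counts = aggregate_bin_counts([chain], q=4.0)
        assert counts.contacts[0] == pytest.approx(1.0)
        assert counts.total_water_contacts == pytest.approx(1.0)

    def test_additivity(self):
        a = [chain_from_alphas([("ALA", 0.2), ("GLY", 0.8)])]
        b = [chain_from_alphas([("VAL", 0.05), ("GLY", 0.4)])]
        joint = aggregate_bin_counts(a + b)
        sep_a = aggregate_bin_counts(a)
        sep_b = aggregate_bin_counts(b)
        assert np.array_equal(joint.n, sep_a.n + sep_b.n)
        assert np.array_equal(joint.buried, sep_a.buried + sep_b.buried)
        assert np.allclose(joint.alpha_sum, sep_a.alpha_sum + sep_b.alpha_sum)

    def test_empty_bin(self):
        with pytest.raises(EmptyBin):
            aggregate_bin_counts([])

    def test_invariants(self, simple_chain):
        counts = aggregate_bin_counts([simple_chain])
        assert counts.total_buried + counts.total_nonburied == counts.total_residues
        assert np.allclose(counts.contacts, counts.q * counts.alpha_sum)


class TestContactEnergy:
    def test_derived_two_type_example(self):
        # oracle: c_ALA=4, c_ARG=0.8, W=4.8, denominator q*N + W = 20.8
        counts = two_type_counts()
        expected_ala = -math.log(4.0 / (2 * 4 * 4.8 / 20.8))
        expected_arg = -math.log(0.8 / (2 * 4 * 4.8 / 20.8))
        assert contact_energy(counts, ("ALA",)) == pytest.approx(expected_ala, abs=1e-12)
        assert contact_energy(counts, ("ARG",)) == pytest.approx(expected_arg, abs=1e-12)
        assert contact_energy(counts, ("ALA",)) == pytest.approx(-0.7732, abs=5e-4)
        assert contact_energy(counts, ("ARG",)) == pytest.approx(0.8362, abs=5e-4)

    def test_identical_alpha_same_energy_across_types(self):
        n = np.array([3] * 20)
        alpha = np.array([3 * 0.4] * 20)
        counts = make_counts(n, np.zeros(20, dtype=int), alpha)
        values = {contact_energy(counts, (aa,)) for aa in AMINO_ACIDS}
        assert max(values) - min(values) < 1e-12

    def test_zero_contacts(self):
        counts = two_type_counts()
        with pytest.raises(ZeroContacts):
            contact_energy(counts, ("GLY",))

    @given(st.integers(min_value=2, max_value=1000))
    def test_scale_invariance(self, factor):
        counts = two_type_counts()
        scaled = make_counts(
            counts.n * factor, counts.buried * factor, counts.alpha_sum * factor
        )
        assert contact_energy(scaled, ("ALA",)) == pytest.approx(
            contact_energy(counts, ("ALA",)), abs=1e-12
        )


class TestSurfaceEnergy:
    def test_type_matches_background(self):
        n = np.zeros(20, dtype=int); b = np.zeros(20, dtype=int)
        n[0], b[0] = 20, 10          # ALA: 10 buried / 10 not
        n[1], b[1] = 180, 90         # totals: 100 buried / 100 not
        counts = make_counts(n, b, n * 0.5)
        # ALA ratio 10/10 vs totals 100/100
        assert surface_energy(counts, ("ALA",)) == pytest.approx(0.0, abs=1e-12)

    def test_derived_ln3(self):
        n = np.zeros(20, dtype=int); b = np.zeros(20, dtype=int)
        n[0], b[0] = 40, 30          # ALA 30 buried, 10 non-buried
        n[1], b[1] = 560, 270        # totals: 300 buried, 300 non-buried
        counts = make_counts(n, b, n * 0.5)
        assert surface_energy(counts, ("ALA",)) == pytest.approx(math.log(3.0), abs=1e-12)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(7)
        n = rng.integers(10, 100, size=20)
        b = rng.integers(1, 9, size=20)
        counts = make_counts(n, b, n * 0.3)
        swapped = make_counts(n, n - b, n * 0.3)
        for entity in ("ALA", "hydrophobic", "charged"):
            assert surface_energy(swapped, entity) == pytest.approx(
                -surface_energy(counts, entity), abs=1e-12
            )

    def test_zero_cell(self):
        n = np.zeros(20, dtype=int); b = np.zeros(20, dtype=int)
        n[0], b[0] = 10, 10  # no non-buried ALA
        n[1], b[1] = 10, 5
        counts = make_counts(n, b, n * 0.2)
        with pytest.raises(ZeroCell):
            surface_energy(counts, ("ALA",))


class TestAreaEnergy:
    def test_derived_example(self):
        # N=4: ALA alphas {0.5,0.5}; ARG alphas {0.1,0.3}
        n = np.zeros(20, dtype=int)
        alpha = np.zeros(20)
        n[0], alpha[0] = 2, 1.0
        n[1], alpha[1] = 2, 0.4
        counts = make_counts(n, np.zeros(20, dtype=int), alpha)
        assert area_energy(counts, ("ALA",)) == pytest.approx(-math.log(10 / 7), abs=1e-12)
        assert area_energy(counts, ("ARG",)) == pytest.approx(-math.log(4 / 7), abs=1e-12)

    def test_uniform_alpha_zero(self):
        n = np.array([5] * 20)
        counts = make_counts(n, np.zeros(20, dtype=int), n * 0.33)
        for aa in AMINO_ACIDS:
            assert area_energy(counts, (aa,)) == pytest.approx(0.0, abs=1e-12)

    def test_scaled_single_type(self):
        n = np.zeros(20, dtype=int); alpha = np.zeros(20)
        n[0], alpha[0] = 2, 1.0
        n[1], alpha[1] = 2, 0.4
        counts = make_counts(n, np.zeros(20, dtype=int), alpha)
        assert area_energy(counts, ("ALA",), scaled=True) == pytest.approx(
            MAX_ASA_THEORETICAL["ALA"] * area_energy(counts, ("ALA",)), abs=1e-12
        )

    def test_scaled_pool_count_weighted(self):
        n = np.zeros(20, dtype=int); alpha = np.zeros(20)
        n[0], alpha[0] = 3, 0.9   # ALA
        n[9], alpha[9] = 1, 0.2   # ILE
        n[1], alpha[1] = 4, 1.0   # ARG background
        counts = make_counts(n, np.zeros(20, dtype=int), alpha)
        base = area_energy(counts, ("ALA", "ILE"))
        mean_asa = (3 * MAX_ASA_THEORETICAL["ALA"] + 1 * MAX_ASA_THEORETICAL["ILE"]) / 4
        assert area_energy(counts, ("ALA", "ILE"), scaled=True) == pytest.approx(
            base * mean_asa, abs=1e-12
        )

    def test_zero_area(self):
        counts = two_type_counts()
        with pytest.raises(ZeroArea):
            area_energy(counts, ("GLY",))


class TestPooling:
    def test_pool_sums_counts_not_energies(self):
        rng = np.random.default_rng(3)
        n = rng.integers(20, 100, size=20)
        b = rng.integers(2, 15, size=20)
        counts = make_counts(n, b, n * rng.uniform(0.2, 0.6, size=20))
        types = CLASSES["hydrophobic"]
        pooled = contact_energy(counts, types)
        member_mean = np.mean([contact_energy(counts, (t,)) for t in types])
        assert pooled != pytest.approx(member_mean, abs=1e-6)  # pooling != averaging

    def test_singleton_class_equals_member(self):
        counts = two_type_counts()
        assert contact_energy(counts, ("ALA",)) == contact_energy(counts, ["ALA"])

    def test_hydrophobic_class_membership(self):
        assert set(CLASSES["hydrophobic"]) == {"ALA", "ILE", "LEU", "MET", "VAL"}
        assert "CYS" not in CLASSES["hydrophobic"]
        assert "GLY" not in CLASSES["hydrophobic"]
        assert set(CLASSES["other"]) == {"CYS", "GLY", "PRO"}

    def test_reference_pool_types(self):
        assert set(REFERENCE_TYPES) == {
            "ARG", "ASP", "GLU", "LYS", "ASN", "GLN", "SER", "THR"
        }


class TestReferenceCorrection:
    def _counts(self):
        rng = np.random.default_rng(11)
        n = rng.integers(30, 200, size=20)
        b = rng.integers(3, 25, size=20)
        return make_counts(n, b, n * rng.uniform(0.2, 0.7, size=20))

    def test_reference_cell_zero(self):
        counts = self._counts()
        corrected = contact_energy(counts, REFERENCE_TYPES) - reference_energy(
            counts, "contact"
        )
        assert corrected == pytest.approx(0.0, abs=1e-14)

    def test_constant_shift_preserves_differences(self):
        counts = self._counts()
        table = compute_potential_table(
            {"b": counts}, {"b": 298.0}, ("ALA", "VAL"), methods=("contact",)
        )
        raw_diff = get_cell(table, "b", "ALA", "contact") - get_cell(
            table, "b", "VAL", "contact"
        )
        cor_diff = get_cell(table, "b", "ALA", "contact", corrected=True) - get_cell(
            table, "b", "VAL", "contact", corrected=True
        )
        assert cor_diff == pytest.approx(raw_diff, abs=1e-12)

    def test_reference_correct_matches_inline(self):
        counts = self._counts()
        raw = compute_potential_table(
            {"b": counts}, {"b": 298.0}, ("ALA", "hydrophobic"),
            methods=("contact", "surface"), include_corrected=False,
        )
        via_fn = reference_correct(raw, {"b": counts})
        inline = compute_potential_table(
            {"b": counts}, {"b": 298.0}, ("ALA", "hydrophobic"),
            methods=("contact", "surface"), include_corrected=True,
        )
        for entity in ("ALA", "hydrophobic"):
            for method in ("contact", "surface"):
                assert get_cell(via_fn, "b", entity, method, corrected=True) == (
                    pytest.approx(
                        get_cell(inline, "b", entity, method, corrected=True),
                        abs=1e-12,
                    )
                )


class TestPotentialTable:
    def test_missing_cells_are_nan(self):
        counts = two_type_counts()  # only ALA and ARG populated
        table = compute_potential_table(
            {"b": counts}, {"b": 298.0}, ("GLY",), methods=("contact",),
            include_corrected=False,
        )
        assert math.isnan(get_cell(table, "b", "GLY", "contact"))
        assert not np.isinf(table["dG_kT"].fillna(0)).any()

    def test_round_trip(self, tmp_path, simple_chain):
        from hydrotemp.potentials import read_potential_table, write_potential_table

        counts = aggregate_bin_counts([simple_chain], bin_id="b")
        table = compute_potential_table(
            {"b": counts}, {"b": 298.0}, ("ALA", "ARG"), methods=("contact", "area")
        )
        path = tmp_path / "pot.tsv"
        write_potential_table(table, path)
        back = read_potential_table(path)
        assert len(back) == len(table)
        assert np.allclose(back["dG_kT"], table["dG_kT"], atol=1e-9)
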