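"""Site-feature registry, windows, LSE, contacts, ASA and assembly."""

import numpy as np
import pytest

from structphos.errors import SchemaError, StructphosError
from structphos.fourbody import train_four_body_table
from structphos.sasa import shrake_rupley
from structphos.site_features import (
    EXTERNAL_NAMES,
    FEATURE_NAMES,
    GROUP_ARITIES,
    NATIVE_NAMES,
    REGISTRY,
    FeatureContext,
    assemble_site_vector,
    contact_counts,
    delta_lse,
    encode_window,
    local_structural_entropy,
    physicochemical,
    read_external_feature_table,
    ss_window_probs,
)
from structphos.structure import Atom, ProteinStructure, Residue
from structphos.synthetic import synth_structure
from tests.conftest import point_structure


class TestRegistry:
    def test_fifty_one_slots_with_printed_group_arities(self):
        assert len(REGISTRY) == 51
        from collections import Counter

        arities = Counter(s.group for s in REGISTRY)
        assert dict(arities) == GROUP_ARITIES

    def test_native_and_external_partition(self):
        assert len(NATIVE_NAMES) == 15
        assert len(EXTERNAL_NAMES) == 36
        assert set(NATIVE_NAMES) | set(EXTERNAL_NAMES) == set(FEATURE_NAMES)


class TestWindow:
    def test_left_truncated_window(self):
        w = encode_window("MKSTYACDEF", 3)
        assert len(w) == 15
        assert w == "_____MKSTYACDEF"
        assert w[7] == "S"

    def test_interior_of_15mer_is_identity(self):
        seq = "ACDEFGHIKLMNPQR"
        assert encode_window(seq, 8) == seq

    def test_single_residue_fully_padded(self):
        assert encode_window("S", 1) == "_______S_______"

    def test_out_of_range_raises(self):
        with pytest.raises(IndexError):
            encode_window("STY", 4)


class TestLSE:
    def test_uniform_windows_give_three_bits(self):
        probs = np.full((6, 8), 1 / 8)
        assert local_structural_entropy(probs, 3) == pytest.approx(3.0)

    def test_concentrated_windows_give_zero(self):
        probs = np.zeros((6, 8))
        probs[:, 2] = 1.0
        assert local_structural_entropy(probs, 3) == pytest.approx(0.0)

    def test_mean_over_windows(self):
        # four rows engineered to entropies 1, 2, 3, 2 bits
        def row(bits):
            k = int(2**bits)
            r = np.zeros(8)
            r[:k] = 1 / k
            return r

        probs = np.array([row(1), row(2), row(3), row(2)])
        assert local_structural_entropy(probs, 3) == pytest.approx(2.0)

    def test_malformed_rows_raise(self):
        with pytest.raises(StructphosError):
            local_structural_entropy(np.full((4, 8), 0.2), 2)

    def test_sequence_probs_are_distributions(self):
        probs = ss_window_probs("ACDEFGHIKLMNPQRSTVWY")
        assert probs.shape == (17, 8)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)

    def test_lse_bounded(self):
        probs = ss_window_probs("MKSTYACDEFGHIKLM")
        for pos in range(16):
            assert 0.0 <= local_structural_entropy(probs, pos) <= 3.0

    def test_delta_lse_antisymmetric(self):
        assert delta_lse(2.0, 2.0) == 0.0
        assert delta_lse(1.5, 2.5) == pytest.approx(1.0)
        assert delta_lse(1.5, 2.5) == -delta_lse(2.5, 1.5)


class TestPhysicochemical:
    def test_lookups(self):
        r, _ = physicochemical("R")
        assert r[1] == pytest.approx(1.0)  # net charge
        f, _ = physicochemical("F")
        assert f[5] == 1.0  # aromatic
        a, _ = physicochemical("A")
        assert a[5] == 0.0

    def test_unknown_type_imputed_with_column_means(self):
        x, imputed = physicochemical("X")
        assert imputed
        from structphos.site_features import PHYSICOCHEMICAL

        means = np.mean(list(PHYSICOCHEMICAL.values()), axis=0)
        np.testing.assert_allclose(x, means)


class TestContacts:
    def test_isolated_residue(self):
        s = point_structure([(0, 0, 0), (50, 0, 0)])
        assert contact_counts(s, s.residues()[0]) == (0, 0)

    def test_two_atoms_four_angstrom_apart(self):
        s = point_structure([(0, 0, 0), (4, 0, 0)])
        for r in s.residues():
            assert contact_counts(s, r) == (1, 1)

    def test_matches_brute_force_enumeration(self):
        s = synth_structure(10, seed=5)
        residues = s.residues()
        for r in residues:
            atoms = 0
            res = 0
            for other in residues:
                if other.key == r.key:
                    continue
                d = np.array(
                    [[np.linalg.norm(a.coord - b.coord) for b in other.heavy_atoms]
                     for a in r.heavy_atoms]
                )
                atoms += int((d <= 5.0).sum())
                res += int(d.min() <= 8.0)
            assert contact_counts(s, r) == (atoms, res)


class TestASA:
    def test_isolated_residue_fully_exposed(self):
        from structphos.sasa import solvent_accessibility

        r = Residue("A", 1, " ", "A", [Atom("CA", "C", (0, 0, 0)),
                                       Atom("CB", "C", (1.5, 0, 0))], 0)
        s = ProteinStructure("ISO", {"A": [r]})
        absolute, relative, imputed = solvent_accessibility(s, r)
        assert relative >= 0.95
        assert not imputed

    def test_caged_atom_buried(self):
        # residue 1 at the origin enclosed by a dense shell of atoms at 3 A
        from structphos.sasa import sphere_points

        shell = 3.0 * sphere_points(200)
        residues = [Residue("A", 1, " ", "A", [Atom("CA", "C", (0, 0, 0))], 0)]
        residues += [
            Residue("A", i + 2, " ", "A", [Atom("CA", "C", c)], i + 1)
            for i, c in enumerate(shell)
        ]
        s = ProteinStructure("CAGE", {"A": residues})
        areas = shrake_rupley(s)
        assert areas[("A", "1")] < 1.0

    def test_deterministic(self):
        s = synth_structure(15, seed=3)
        assert shrake_rupley(s) == shrake_rupley(s)


class TestExternalTables:
    def _table(self, columns, rows=3):
        header = "\t".join(["chain", "seq_num"] + columns)
        lines = [header]
        for i in range(rows):
            lines.append("\t".join(["A", str(i + 1)] + ["0.5"] * len(columns)))
        return "\n".join(lines) + "\n"

    def test_complete_table(self):
        table = read_external_feature_table(self._table(EXTERNAL_NAMES))
        assert len(table) == 3
        assert set(table[("A", "1")]) == set(EXTERNAL_NAMES)

    def test_missing_column_named_in_error(self):
        cols = [c for c in EXTERNAL_NAMES if c != "pssm_07"]
        with pytest.raises(SchemaError, match="pssm_07"):
            read_external_feature_table(self._table(cols))

    def test_extra_column_warned_and_ignored(self):
        with pytest.warns(UserWarning, match="bogus"):
            table = read_external_feature_table(self._table(EXTERNAL_NAMES + ["bogus"]))
        assert "bogus" not in table[("A", "1")]


class TestAssembly:
    @pytest.fixture()
    def context(self):
        s = synth_structure(25, seed=9)
        table = train_four_body_table([s])
        return s, table

    def test_full_providers_no_imputation(self, context):
        s, table = context
        external = {
            r.key: {n: 0.1 for n in EXTERNAL_NAMES} for r in s.residues()
        }
        ctx = FeatureContext.build(s, fourbody_table=table, external=external)
        v = assemble_site_vector(s.residues()[4], ctx)
        assert list(v.values) == FEATURE_NAMES
        assert sum(1 for p in v.provenance.values() if p == "imputed") == 0

    def test_no_external_tables_imputes_36(self, context):
        s, table = context
        ctx = FeatureContext.build(s, fourbody_table=table)
        v = assemble_site_vector(s.residues()[4], ctx)
        counts = {p: 0 for p in ("computed", "supplied", "imputed")}
        for p in v.provenance.values():
            counts[p] += 1
        assert counts["imputed"] == 36
        assert counts["computed"] == 15

    def test_deterministic(self, context):
        s, table = context
        ctx = FeatureContext.build(s, fourbody_table=table)
        v1 = assemble_site_vector(s.residues()[7], ctx)
        v2 = assemble_site_vector(s.residues()[7], ctx)
        assert v1.values == v2.values
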