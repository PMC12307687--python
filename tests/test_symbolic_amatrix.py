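import warnings

import numpy as np
import pytest
import sympy

from strucbif.network_core import Reaction, ReactionNetwork, Species
from strucbif.symbolic_amatrix import (
    SignClass,
    apply_deletion,
    build_A,
    classify_sign,
    sensitivity_solve,
    symbolic_determinant,
)
from strucbif.fixtures import SOCS3_DELETION, KLF4_DELETION

from oracles import numeric_determinant


class TestBuildA:
    def test_example1_determinant_factorization(self, example1):
        A = build_A(example1.network, C=example1.C, D=example1.D)
        det = symbolic_determinant(A.sym)
        r2B = A.symbol("R2", "B")
        r3B = A.symbol("R3", "B")
        r4A = A.symbol("R4", "A")
        assert sympy.expand(det - (r2B - r3B) * r4A) == 0

    def test_macrophage_pattern(self, macrophage_wt):
        A = build_A(macrophage_wt.network, C=macrophage_wt.C,
                    D=macrophage_wt.D)
        assert A.shape == (12, 12)
        # the nine regulation entries plus reactant entries
        expected_symbols = {
            ("R1", "S1"), ("R1", "S3p"), ("R1", "S6p"),
            ("R2", "S1p"),
            ("R3", "S1p"), ("R3", "S3"), ("R3", "S3p"), ("R3", "Np"),
            ("R4", "S3p"),
            ("R5", "S1p"), ("R5", "S6"),
            ("R6", "S6p"),
            ("R7", "S3p"), ("R7", "S6p"), ("R7", "N"), ("R7", "Np"),
            ("R8", "Np"),
        }
        assert set(A.symbols) == expected_symbols

    def test_macrophage_block_layout(self, macrophage_wt):
        A = build_A(macrophage_wt.network, C=macrophage_wt.C,
                    D=macrophage_wt.D)
        pattern = A.pattern()
        # loop columns C sit top right, conserved rows D^T bottom left, 0 corner
        np.testing.assert_array_equal(pattern[:8, 8:], macrophage_wt.C.C != 0)
        np.testing.assert_array_equal(pattern[8:, :8], macrophage_wt.D.D.T != 0)
        assert not pattern[8:, 8:].any()

    def test_degenerate_inflow_only_network(self):
        net = ReactionNetwork([Species("A")],
                              [Reaction("R1", products={"A": 1})])
        A = build_A(net)
        assert A.shape == (1, 1)
        assert A.sym[0, 0] == 0  # structurally singular; flagged downstream

    def test_square_guard(self, conserved_example):
        A = build_A(conserved_example.network, C=conserved_example.C,
                    D=conserved_example.D)
        assert A.shape == (7, 7)


class TestDeletion:
    def test_socs3_deletion_zeroes_three_entries(self, macrophage_wt):
        A = build_A(macrophage_wt.network, C=macrophage_wt.C,
                    D=macrophage_wt.D)
        A2 = apply_deletion(A, SOCS3_DELETION)
        for rid, sid in SOCS3_DELETION:
            i = A.net.reaction_index(rid)
            j = A.net.species_index(sid)
            assert A2.sym[i, j] == 0
        assert len(A.symbols) - len(A2.symbols) == 3

    def test_deleted_pattern_matches_mutant_network(self, macrophage_wt,
                                                    macrophage_socs3d):
        A_del = apply_deletion(
            build_A(macrophage_wt.network, C=macrophage_wt.C,
                    D=macrophage_wt.D), SOCS3_DELETION)
        A_mut = build_A(macrophage_socs3d.network, C=macrophage_socs3d.C,
                        D=macrophage_socs3d.D)
        np.testing.assert_array_equal(A_del.pattern(), A_mut.pattern())

    def test_klf4_extra_deletion(self, macrophage_wt,
                                 macrophage_socs3d_klf4d):
        A_del = apply_deletion(
            build_A(macrophage_wt.network, C=macrophage_wt.C,
                    D=macrophage_wt.D), SOCS3_DELETION | KLF4_DELETION)
        A_mut = build_A(macrophage_socs3d_klf4d.network,
                        C=macrophage_socs3d_klf4d.C,
                        D=macrophage_socs3d_klf4d.D)
        np.testing.assert_array_equal(A_del.pattern(), A_mut.pattern())

    def test_zeroing_zero_entry_is_identity(self, example1):
        A = build_A(example1.network, C=example1.C, D=example1.D)
        A2 = apply_deletion(A, {("R1", "B")})
        assert A2.sym == A.sym

    def test_zeroing_reactant_entry_warns(self, example1):
        A = build_A(example1.network, C=example1.C, D=example1.D)
        with pytest.warns(UserWarning, match="reactant-derivative"):
            apply_deletion(A, {("R4", "A")})

    def test_unknown_ids_raise(self, example1):
        A = build_A(example1.network, C=example1.C, D=example1.D)
        with pytest.raises(KeyError):
            apply_deletion(A, {("R9", "A")})


class TestSymbolicDeterminant:
    def test_numeric_cross_check(self, all_fixtures, rng):
        for fx in all_fixtures:
            A = build_A(fx.network, C=fx.C, D=fx.D)
            det = symbolic_determinant(A.sym)
            for _ in range(3):
                values = {key: rng.uniform(0.1, 2.0) for key in A.symbols}
                num = A.instantiate(values)
                subs = {A.symbols[k].symbol: v for k, v in values.items()}
                sym_val = float(det.subs(subs))
                lu_val = numeric_determinant(num)
                assert abs(sym_val - lu_val) <= 1e-9 * max(1.0, abs(lu_val))

    def test_socs3d_gamma2_polynomial(self, macrophage_socs3d):
        from strucbif.decomposition import block_triangularize
        A = build_A(macrophage_socs3d.network, C=macrophage_socs3d.C,
                    D=macrophage_socs3d.D)
        dec = block_triangularize(A)
        blk = next(s for s in dec.structures if "S1" in s.chemicals)
        s = A.symbol
        expected = (s("R1", "S1") * s("R5", "S6")
                    + s("R1", "S1") * s("R6", "S6p")
                    - s("R1", "S6p") * s("R5", "S1p")
                    + s("R2", "S1p") * s("R5", "S6")
                    + s("R2", "S1p") * s("R6", "S6p"))
        det = blk.determinant
        assert sympy.expand(det - expected) == 0 or \
            sympy.expand(det + expected) == 0

    def test_conserved_example_full_determinant(self, conserved_example):
        A = build_A(conserved_example.network, C=conserved_example.C,
                    D=conserved_example.D)
        s = A.symbol
        expected = s("R2", "A") * s("R4", "C") * (
            s("R3", "B") * s("R5", "D") + s("R3", "B") * s("R5", "E")
            + s("R3", "E") * s("R6", "B"))
        det = symbolic_determinant(A.sym)
        assert sympy.expand(det - expected) == 0 or \
            sympy.expand(det + expected) == 0

    def test_empty_block(self):
        assert symbolic_determinant(sympy.Matrix(0, 0, [])) == 1

    def test_non_square_raises(self):
        with pytest.raises(ValueError):
            symbolic_determinant(sympy.Matrix(1, 2, [1, 2]))


class TestClassifySign:
    def test_gamma1_always_negative(self):
        r7Np, r7N, r8Np = sympy.symbols("r7Np r7N r8Np")
        signs = {r7Np: "-", r7N: "+", r8Np: "+"}
        poly = r7Np - r7N - r8Np
        assert classify_sign(poly, signs) is SignClass.ALWAYS_NEGATIVE

    def test_gamma3_always_positive(self):
        a, b = sympy.symbols("a b")
        assert classify_sign(a + b, {a: "+", b: "+"}) is \
            SignClass.ALWAYS_POSITIVE

    def test_example1_condition_indeterminate(self):
        a, b = sympy.symbols("a b")
        assert classify_sign(a - b, {a: "+", b: "+"}) is \
            SignClass.INDETERMINATE

    def test_unknown_sign_is_indeterminate(self):
        a, b = sympy.symbols("a b")
        assert classify_sign(a * b, {a: "+", b: "?"}) is \
            SignClass.INDETERMINATE

    def test_zero(self):
        assert classify_sign(sympy.Integer(0), {}) is \
            SignClass.IDENTICALLY_ZERO

    def test_even_powers_ignore_sign(self):
        a = sympy.Symbol("a")
        assert classify_sign(a ** 2, {a: "-"}) is SignClass.ALWAYS_POSITIVE

    def test_soundness_on_random_draws(self, macrophage_socs3d, rng):
        from strucbif.decomposition import block_triangularize
        A = build_A(macrophage_socs3d.network, C=macrophage_socs3d.C,
                    D=macrophage_socs3d.D)
        dec = block_triangularize(A)
        signs = A.sign_table()
        for blk in dec.structures:
            verdict = classify_sign(blk.determinant, signs)
            if verdict not in (SignClass.ALWAYS_POSITIVE,
                               SignClass.ALWAYS_NEGATIVE):
                continue
            symbols = sorted(blk.determinant.free_symbols, key=str)
            for _ in range(1000):
                subs = {}
                for symb in symbols:
                    mag = rng.uniform(1e-3, 10.0)
                    subs[symb] = -mag if signs[symb] == "-" else mag
                val = float(blk.determinant.subs(subs))
                if verdict is SignClass.ALWAYS_POSITIVE:
                    assert val > 0
                else:
                    assert val < 0


class TestSensitivity:
    def _example1_values(self, A, rng):
        return {key: rng.uniform(0.5, 2.0) for key in A.symbols}

    def test_source_inside_buffering_structure_localizes(self, example1, rng):
        A = build_A(example1.network, C=example1.C, D=example1.D)
        resp = sensitivity_solve(A, "R2", self._example1_values(A, rng))
        dxA = resp.response[resp.col_labels.index("A")]
        assert abs(dxA) < 1e-10

    def test_source_outside_is_global(self, example1, rng):
        A = build_A(example1.network, C=example1.C, D=example1.D)
        resp = sensitivity_solve(A, "R1", self._example1_values(A, rng))
        assert abs(resp.response[resp.col_labels.index("A")]) > 1e-8
        assert abs(resp.response[resp.col_labels.index("B")]) > 1e-8

    def test_identity_like_matrix(self):
        net = ReactionNetwork(
            [Species("A")],
            [Reaction("R1", reactants={"A": 1})])
        A = build_A(net)
        resp = sensitivity_solve(A, "R1", {("R1", "A"): 1.0})
        np.testing.assert_allclose(resp.response, [-1.0])

    def test_singular_raises(self, example1):
        A = build_A(example1.network, C=example1.C, D=example1.D)
        values = {key: 1.0 for key in A.symbols}  # r2B == r3B: bifurcation
        with pytest.raises(np.linalg.LinAlgError, match="bifurcation"):
            sensitivity_solve(A, "R1", values)

    def test_localization_in_conserved_example(self, conserved_example, rng):
        A = build_A(conserved_example.network, C=conserved_example.C,
                    D=conserved_example.D)
        values = {key: rng.uniform(0.5, 2.0) for key in A.symbols}
        # R4 lies in buffering structure {A, C, R2, R4}
        resp = sensitivity_solve(A, "R4", values)
        for sid in ("B", "D", "E"):
            assert abs(resp.response[resp.col_labels.index(sid)]) < 1e-10
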