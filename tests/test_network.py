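"""Parsing, structural matrices, graph classification and conservation bases."""

import numpy as np
import pytest

from crnt import fixtures as fx
from crnt.network import (
    NetworkSyntaxError,
    conservation_basis,
    is_uniterminal,
    is_weakly_reversible,
    linkage_classes,
    make_semidiffusive,
    parse_network,
    structural_summary,
    terminal_strong_linkage_classes,
    write_network,
)


def rowspace_equal(A, B):
    A, B = np.atleast_2d(A), np.atleast_2d(B)
    r = np.linalg.matrix_rank
    return r(A) == r(B) == r(np.vstack([A, B]))


class TestParser:
    def test_association_example_counts(self, example_open):
        # A+B -> AB, AB -> A+B, AB -> AB*, 0 <-> A, 0 <-> B
        assert (example_open.N, example_open.R, example_open.M) == (4, 7, 6)

    def test_reversible_pair(self):
        net = parse_network("A <-> B")
        assert (net.N, net.R, net.M) == (2, 2, 2)

    def test_dimer_collapse_column(self):
        net = parse_network("2 A -> A")
        assert net.M == 2
        assert net.S[:, 0].tolist() == [-1]

    def test_kinds_inferred_from_zero_complex(self, example_open):
        kinds = [r.kind for r in example_open.reactions]
        assert kinds == ["true", "true", "true", "inflow", "outflow", "inflow", "outflow"]

    @pytest.mark.parametrize(
        "text,fragment",
        [
            ("A -> ", "term"),
            ("A + -> B", "term"),
            ("k1: A -> B\nk1: B -> A", "duplicate rate label"),
            ("0 A -> B", "coefficient"),
            ("A -> A", "coincide"),
        ],
    )
    def test_syntax_errors(self, text, fragment):
        with pytest.raises((NetworkSyntaxError, ValueError)) as exc:
            parse_network(text)
        assert fragment.lower() in str(exc.value).lower()

    def test_error_carries_line_number(self):
        with pytest.raises(NetworkSyntaxError) as exc:
            parse_network("A -> B\nB ->")
        assert exc.value.line == 2

    @pytest.mark.parametrize(
        "name", ["example_open", "motif_closed", "ternary_true", "stat_early_closed"]
    )
    def test_roundtrip(self, name):
        net = fx.fixture(name)
        again = parse_network(write_network(net))
        assert write_network(again) == write_network(net)
        assert (again.N, again.R, again.M) == (net.N, net.R, net.M)


class TestStructure:
    def test_open_example(self, example_open):
        s = structural_summary(example_open)
        assert s.s == 4 and s.lam == 0 and not s.closed

    def test_closed_example_certificate(self, example_closed):
        s = structural_summary(example_closed)
        assert s.lam == 2 and s.closed
        theta = np.asarray(s.theta, dtype=float)
        assert np.all(theta > 0)
        assert np.all(theta @ example_closed.S == 0)
        # the published certificate (1,1,2,2) is one valid choice
        assert np.allclose(theta, [1, 1, 2, 2])

    def test_motif_structure(self, motif):
        s = structural_summary(motif)
        d = s.as_dict()
        assert (d["M"], d["l"], d["lambda"], d["delta"]) == (9, 3, 3, 2)
        assert s.closed and s.uniterminal and not s.weakly_reversible

    def test_motif_lambda_matrix(self, motif):
        _, Lam = linkage_classes(motif)
        printed = np.array(
            [
                [1, 0, 0, 0, 1, 1, 0, 0, 0],
                [0, 1, 0, 0, 0, 0, 1, 1, 0],
                [0, 0, 1, 1, 0, 0, 0, 0, 1],
            ]
        )
        # class ordering is a convention; compare as row sets
        assert sorted(map(tuple, Lam.T)) == sorted(map(tuple, printed))

    def test_open_example_linkage_classes(self, example_open):
        comps, Lam = linkage_classes(example_open)
        assert len(comps) == 2
        assert np.all(Lam.sum(axis=1) == 1)
        names = [
            {example_open.complex_name(j) for j in comp} for comp in comps
        ]
        assert {"A + B", "AB", "AB*"} in names
        assert {"0", "A", "B"} in names

    def test_terminal_classes_biterminal(self):
        net = parse_network("B -> A\nB -> C")
        tslc = terminal_strong_linkage_classes(net)
        assert len(tslc) == 2
        assert not is_uniterminal(net)

    def test_cycle_weakly_reversible(self):
        net = parse_network("A <-> B\nB <-> C")
        assert is_uniterminal(net) and is_weakly_reversible(net)

    def test_ternary_reversible_hence_uniterminal(self):
        net = fx.fixture("ternary_true")
        s = structural_summary(net)
        assert s.weakly_reversible and s.uniterminal
        assert s.delta == 1 and s.lam == 3

    def test_ternary_excess_deficiency(self):
        s = structural_summary(fx.fixture("ternary_excess"))
        assert s.delta == 1 and s.lam == 2

    def test_zero_complex_conventions_differ_only_for_open(self, motif, example_open):
        shared = structural_summary(example_open, zero_complex="shared")
        split = structural_summary(example_open, zero_complex="split")
        assert shared.s == split.s  # stoichiometry untouched
        assert structural_summary(motif, zero_complex="split").delta == 2

    def test_deficiency_nonnegative_on_random_networks(self):
        for seed in range(25):
            net = fx.random_network(seed, N=5, R=8)
            s = structural_summary(net)
            assert s.delta >= 0
            assert s.lam == net.N - s.s
            assert np.all(s.Lambda.sum(axis=1) == 1)


class TestConservation:
    def test_closed_example_rowspace(self, example_closed):
        b = conservation_basis(example_closed)
        printed = np.array([[1, 0, 1, 1], [0, 1, 1, 1]])
        assert rowspace_equal(b.B.T, printed)
        assert np.all(b.B >= 0)
        assert np.all(example_closed.S.T @ b.B == 0)

    def test_motif_rowspace(self, motif):
        b = conservation_basis(motif)
        printed = np.array(
            [
                [0, 1, 0, 0, 1, 0, 0],
                [0, 0, 1, 0, 0, 1, 0],
                [1, 0, 0, 1, 1, 1, 2],
            ]
        )
        assert rowspace_equal(b.B.T, printed)

    def test_trivial_pair(self):
        net = parse_network("A <-> B")
        b = conservation_basis(net)
        assert b.B.T.tolist() == [[1, 1]]

    def test_sigma_from_reference(self, motif):
        c0 = np.arange(1.0, motif.N + 1)
        b = conservation_basis(motif, c0)
        assert np.allclose(b.sigma, b.B.T @ c0)
        assert np.allclose(b.W(c0), 0)

    def test_autocatalytic_network_has_empty_basis(self):
        # net production of mass: no semi-positive conservation relation
        net = parse_network("A -> B\nB -> A + A")
        b = conservation_basis(net)
        assert b.lam == 0

    def test_basis_rank_matches_lambda(self):
        for seed in [3, 7, 11]:
            try:
                net = fx.random_network(seed, N=5, R=6, weakly_reversible=True,
                                        moiety_conserved=True)
            except ValueError:
                continue
            b = conservation_basis(net)
            s = structural_summary(net)
            assert b.B.shape[1] == s.lam
            assert np.linalg.matrix_rank(b.B) == s.lam


class TestSemiDiffusive:
    def test_motif_extension_counts(self, motif_sd):
        assert motif_sd.key_species == ("A", "E1", "E2")
        assert len(motif_sd.true_indices) == 9
        assert len(motif_sd.outflow_indices) == 7
        assert len(motif_sd.inflow_indices) == 3

    def test_extension_has_no_conservation(self, motif_sd):
        assert conservation_basis(motif_sd).lam == 0

    def test_ternary_keys_are_free_forms(self):
        sd = fx.fixture("ternary_semidiffusive")
        assert set(sd.key_species) == {"I", "R1", "R2"}

    def test_no_conservation_no_inflow(self):
        net = parse_network("A -> B\nB -> A + A")
        sd = make_semidiffusive(net)
        assert sd.inflow_indices == []

    def test_sto_structure(self, motif_sd):
        S_to = motif_sd.S_to
        N = motif_sd.N
        assert S_to.shape == (N, len(motif_sd.true_indices) + N)
        assert np.array_equal(S_to[:, -N:], -np.eye(N, dtype=int))

    def test_yr_sources(self, motif_sd):
        Y_r = motif_sd.Y_r
        N = motif_sd.N
        assert np.array_equal(Y_r[:, -N:], np.eye(N, dtype=int))

    def test_rejects_open_input(self, example_open):
        with pytest.raises(ValueError):
            make_semidiffusive(example_open)
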