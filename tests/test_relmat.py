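"""Relationship-matrix construction against hand-derived and dense oracles."""

import numpy as np
import pandas as pd
import pytest

from pigpred.core import DataError, NumericalError, RelationshipMatrix
from pigpred.relmat import (a22, a_inverse, a_matrix, adjust_g, blend,
                            g_matrix, h_inverse, inbreeding)

from conftest import make_pedigree, random_panel, random_pedigree


class TestAMatrix:
    def test_founders_only_identity(self):
        ped = make_pedigree([(str(i), "0", "0") for i in range(1, 6)])
        A = a_matrix(ped)
        assert np.allclose(A.values, np.eye(5))

    def test_parent_offspring_hand_values(self, trio_pedigree):
        A = a_matrix(trio_pedigree)
        assert A.values[0, 2] == pytest.approx(0.5)
        assert A.values[2, 2] == pytest.approx(1.0)
        assert A.values[0, 1] == pytest.approx(0.0)

    def test_fullsib_mating_inbreeding(self, fullsib_mating_pedigree):
        A = a_matrix(fullsib_mating_pedigree)
        i = A.ids.index("5")
        assert A.values[i, i] == pytest.approx(1.25)
        F = inbreeding(fullsib_mating_pedigree)
        assert F[i] == pytest.approx(0.25)

    def test_own_ancestor_rejected(self):
        with pytest.raises(DataError, match="cycle"):
            make_pedigree([("1", "2", "0"), ("2", "1", "0")])


class TestAInverse:
    def test_founders_identity(self):
        ped = make_pedigree([(str(i), "0", "0") for i in range(1, 4)])
        assert np.allclose(a_inverse(ped).toarray(), np.eye(3))

    def test_trio_diagonal_hand_values(self, trio_pedigree):
        Ainv = a_inverse(trio_pedigree).toarray()
        assert np.allclose(np.diag(Ainv), [1.5, 1.5, 2.0])

    @pytest.mark.parametrize("n,seed", [(50, 1), (200, 2), (500, 3)])
    def test_dense_inverse_oracle(self, n, seed):
        """Henderson's rules must invert the tabular A exactly."""
        ped = random_pedigree(n, seed=seed)
        A = a_matrix(ped).values
        Ainv = a_inverse(ped).toarray()
        assert np.max(np.abs(Ainv @ A - np.eye(n))) < 1e-8


class TestGMatrix:
    def test_hand_two_individuals(self):
        panel = random_panel(2, 2)
        panel.dosages = np.array([[0.0, 2.0], [2.0, 0.0]])
        G = g_matrix(panel, freq_source=np.array([0.5, 0.5]))
        assert np.allclose(G.values, [[2.0, -2.0], [-2.0, 2.0]])

    def test_duplicate_individuals(self):
        panel = random_panel(3, 50, seed=4)
        panel.dosages[1] = panel.dosages[0]
        G = g_matrix(panel)
        assert np.allclose(G.values[0], G.values[1])
        assert G.values[0, 1] == pytest.approx(G.values[0, 0])

    def test_mean_diagonal_near_one(self):
        G = g_matrix(random_panel(50, 500, seed=5))
        assert abs(np.mean(np.diag(G.values)) - 1.0) < 0.1

    def test_monomorphic_all_rejected(self):
        panel = random_panel(4, 3)
        panel.dosages[:] = 2.0
        with pytest.raises(DataError):
            g_matrix(panel)

    def test_split_recombination_exact(self):
        """s_f*G_f + s_r*G_r recombines to s*G for any marker split."""
        panel = random_panel(30, 200, seed=6)
        G = g_matrix(panel)
        half = panel.marker_ids[:90]
        rest = panel.marker_ids[90:]
        Gf = g_matrix(panel.subset_markers(half))
        Gr = g_matrix(panel.subset_markers(rest))
        sf, sr = Gf.meta["scale"], Gr.meta["scale"]
        combined = (sf * Gf.values + sr * Gr.values) / (sf + sr)
        assert np.allclose(combined, G.values, atol=1e-12)
        assert sf + sr == pytest.approx(G.meta["scale"])


class TestAdjustG:
    def test_hand_solution(self):
        ids = ["a", "b"]
        G = RelationshipMatrix(ids=ids, values=np.array([[1.0, 0.0], [0.0, 1.0]]))
        A22m = RelationshipMatrix(ids=ids, values=np.array([[1.2, 0.4], [0.4, 1.2]]))
        Ga, fac = adjust_g(G, A22m)
        assert fac.beta == pytest.approx(0.8)
        assert fac.alpha == pytest.approx(0.4)

    def test_identity_when_already_matched(self):
        G = g_matrix(random_panel(10, 100, seed=7))
        Ga, fac = adjust_g(G, G)
        assert fac.beta == pytest.approx(1.0)
        assert fac.alpha == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(Ga.values, G.values)

    @pytest.mark.parametrize("seed", range(10))
    def test_average_matching_postcondition(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        M = rng.normal(size=(n, n))
        G = RelationshipMatrix(ids=[str(i) for i in range(n)],
                               values=M @ M.T / n + np.eye(n))
        M2 = rng.normal(size=(n, n))
        A22m = RelationshipMatrix(ids=G.ids, values=M2 @ M2.T / n + np.eye(n))
        Ga, _ = adjust_g(G, A22m)
        off = ~np.eye(n, dtype=bool)
        assert np.mean(np.diag(Ga.values)) == pytest.approx(
            np.mean(np.diag(A22m.values)), abs=1e-12)
        assert np.mean(Ga.values[off]) == pytest.approx(
            np.mean(A22m.values[off]), abs=1e-12)

    def test_singular_system_rejected(self):
        n = 3
        G = RelationshipMatrix(ids=list("abc"), values=np.ones((n, n)))
        A22m = RelationshipMatrix(ids=list("abc"), values=np.eye(n))
        with pytest.raises(NumericalError):
            adjust_g(G, A22m)


class TestBlend:
    def test_default_weights_and_degenerate_cases(self):
        G = g_matrix(random_panel(8, 60, seed=8))
        Gw = blend(G, G, w=0.95)
        assert np.allclose(Gw.values, G.values)
        Gw1 = blend(G, G, w=1.0)
        assert np.allclose(Gw1.values, G.values)
        with pytest.raises(DataError):
            blend(G, G, w=1.5)

    def test_blend_is_convex_combination(self):
        Ga = g_matrix(random_panel(6, 50, seed=9))
        ids = Ga.ids
        A22m = RelationshipMatrix(ids=ids, values=np.eye(6))
        Gw = blend(Ga, A22m, w=0.95)
        assert np.allclose(Gw.values, 0.95 * Ga.values + 0.05 * np.eye(6))


def _legarra_h(A, Gw, gi, ni):
    """Dense single-step H from the joint-distribution formula (oracle)."""
    A11 = A[np.ix_(ni, ni)]
    A12 = A[np.ix_(ni, gi)]
    A22m = A[np.ix_(gi, gi)]
    A22i = np.linalg.inv(A22m)
    H11 = A11 + A12 @ A22i @ (Gw - A22m) @ A22i @ A12.T
    H12 = A12 @ A22i @ Gw
    n = A.shape[0]
    H = np.empty((n, n))
    H[np.ix_(ni, ni)] = H11
    H[np.ix_(ni, gi)] = H12
    H[np.ix_(gi, ni)] = H12.T
    H[np.ix_(gi, gi)] = Gw
    return H


class TestHInverse:
    def test_all_genotyped_reduces_to_gw_inverse(self):
        ped = random_pedigree(20, seed=10)
        panel = random_panel(20, 150, seed=10)
        panel.ids = ped.ids
        from pigpred.relmat import make_gw

        Gw = make_gw(panel, ped)
        parts = h_inverse(ped, Gw, ped.ids)
        assert np.allclose(parts.assemble(), np.linalg.inv(Gw.values), atol=1e-8)

    def test_none_genotyped_reduces_to_a_inverse(self):
        ped = random_pedigree(15, seed=11)
        parts = h_inverse(ped, RelationshipMatrix(ids=[], values=np.zeros((0, 0))),
                          [])
        assert np.allclose(parts.assemble(), a_inverse(ped).toarray())

    def test_mixed_case_against_legarra_oracle(self):
        ped = random_pedigree(60, seed=12)
        genotyped = ped.ids[30:]
        panel = random_panel(30, 300, seed=12)
        panel.ids = genotyped
        from pigpred.relmat import make_gw

        Gw = make_gw(panel, ped)
        parts = h_inverse(ped, Gw, genotyped)
        H = np.linalg.inv(parts.assemble())
        A = a_matrix(ped).values
        pos = {a: i for i, a in enumerate(ped.ids)}
        gi = [pos[a] for a in genotyped]
        ni = [i for i in range(len(ped)) if i not in set(gi)]
        H_oracle = _legarra_h(A, Gw.values, gi, ni)
        assert np.allclose(H, H_oracle, atol=1e-6)
        eig = np.linalg.eigvalsh(0.5 * (H + H.T))
        assert eig.min() > -1e-8


class TestA22:
    def test_subblock_of_full_tabular_a(self, fullsib_mating_pedigree):
        A = a_matrix(fullsib_mating_pedigree)
        sub = a22(fullsib_mating_pedigree, ["3", "5"])
        i3, i5 = A.ids.index("3"), A.ids.index("5")
        assert sub.values[0, 1] == pytest.approx(A.values[i3, i5])
        assert sub.kind == "A22"
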