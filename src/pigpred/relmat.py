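"""Pedigree and genomic relationship matrices.

Builds the numerator relationship matrix A (tabular method, with
inbreeding), its sparse inverse (Henderson's rules with inbreeding
coefficients from the Meuwissen-Luo recursion), the VanRaden method-1
genomic matrix G, the rescaled Ga (matching A22's average diagonal and
off-diagonal), the blended Gw = w*Ga + (1-w)*A22, and the single-step
H^-1 stored as parts (sparse A^-1 plus a dense correction block on the
genotyped animals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core import DataError, GenotypePanel, NumericalError, Pedigree, RelationshipMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pedigree side


def a_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method."""
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(ids=pedigree.ids, values=A, kind="A")


def inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficients via the Meuwissen-Luo style recursion.

    For each animal with both parents known, F_i is obtained from the
    within-family (Mendelian sampling) variances D_j of its ancestors:
    F_i = D_i + sum_j w_j^2 D_j - 1, where the weights w halve along
    each parent link starting from {sire: 1/2, dam: 1/2}.
    """
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    F = np.zeros(n)
    D = np.zeros(n)

    def mendelian(i: int) -> float:
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            return 0.5 - 0.25 * (F[s] + F[d])
        if s >= 0 or d >= 0:
            return 0.75 - 0.25 * F[max(s, d)]
        return 1.0

    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 or d < 0:
            F[i] = 0.0
        else:
            Di = 0.5 - 0.25 * (F[s] + F[d])
            w: dict[int, float] = {}
            w[s] = w.get(s, 0.0) + 0.5
            w[d] = w.get(d, 0.0) + 0.5
            acc = Di
            while w:
                j = max(w)
                c = w.pop(j)
                acc += c * c * D[j]
                for par in (sire[j], dam[j]):
                    if par >= 0:
                        w[par] = w.get(par, 0.0) + 0.5 * c
            F[i] = acc - 1.0
        D[i] = mendelian(i)
    return F


def a_inverse(pedigree: Pedigree) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding."""
    sire, dam = pedigree.parent_indices()
    F = inbreeding(pedigree)
    n = len(pedigree)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            m = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            m = 0.75 - 0.25 * F[max(s, d)]
        else:
            m = 1.0
        alpha = 1.0 / m
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * alpha)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def a22(pedigree: Pedigree, genotyped_ids: list[str]) -> RelationshipMatrix:
    """Genotyped-animal block of the full tabular A (pedigree depth honoured)."""
    A = a_matrix(pedigree)
    missing = set(genotyped_ids) - set(A.ids)
    if missing:
        raise DataError(f"genotyped ids not in pedigree: {sorted(missing)[:5]}")
    out = A.subset(list(genotyped_ids))
    out.kind = "A22"
    return out


# ---------------------------------------------------------------------------
# genomic side


def g_matrix(panel: GenotypePanel, freq_source: np.ndarray | None = None,
             label_kind: str = "G") -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    G = Z Z' / (2 * sum p(1-p)) with Z = M - 2p.  Allele frequencies
    default to those observed in the genotyped set.  Monomorphic
    markers (p in {0, 1}) are dropped with a logged count.  The scaling
    constant is kept in ``meta["scale"]`` so feature/remainder splits
    recombine exactly.
    """
    M = panel.imputed_dosages()
    p = freq_source if freq_source is not None else M.mean(axis=0) / 2.0
    p = np.asarray(p, dtype=float)
    poly = (p > 0.0) & (p < 1.0)
    n_mono = int((~poly).sum())
    if n_mono:
        log.info("g_matrix: dropping %d monomorphic markers", n_mono)
    if not poly.any():
        raise DataError("all markers monomorphic; cannot build G")
    M = M[:, poly]
    p = p[poly]
    Z = M - 2.0 * p
    scale = 2.0 * float(np.sum(p * (1.0 - p)))
    G = (Z @ Z.T) / scale
    return RelationshipMatrix(ids=list(panel.ids), values=G, kind=label_kind,
                              meta={"scale": scale, "n_markers": int(poly.sum()),
                                    "n_monomorphic_dropped": n_mono})


@dataclass
class AdjustmentFactors:
    """Solution (beta, alpha) of the two average-matching equations."""

    beta: float
    alpha: float


def adjust_g(G: RelationshipMatrix, A22m: RelationshipMatrix):
    """Rescale G so its average diagonal/off-diagonal match A22's.

    Solves ``avg.diag(G)*beta + alpha = avg.diag(A22)`` and
    ``avg.offdiag(G)*beta + alpha = avg.offdiag(A22)``, and returns
    ``Ga = G*beta + alpha`` (alpha added to every element).
    """
    if G.ids != A22m.ids:
        raise DataError("G and A22 must share the same id order")
    n = len(G.ids)
    if n < 2:
        raise DataError("need at least two animals to match off-diagonals")

    def averages(mat):
        d = float(np.mean(np.diag(mat)))
        o = float((mat.sum() - np.trace(mat)) / (n * n - n))
        return d, o

    gd, go = averages(G.values)
    ad, ao = averages(A22m.values)
    denom = gd - go
    if abs(denom) < 1e-14:
        raise NumericalError("avg.diag(G) equals avg.offdiag(G); system singular")
    beta = (ad - ao) / denom
    alpha = ad - gd * beta
    Ga = RelationshipMatrix(ids=list(G.ids), values=G.values * beta + alpha,
                            kind="Ga", meta={"beta": beta, "alpha": alpha})
    return Ga, AdjustmentFactors(beta=beta, alpha=alpha)


def blend(Ga: RelationshipMatrix, A22m: RelationshipMatrix,
          w: float = 0.95) -> RelationshipMatrix:
    """Gw = w*Ga + (1-w)*A22 (default 0.95/0.05, avoids singular G)."""
    if not 0.0 <= w <= 1.0:
        raise DataError(f"blend weight must lie in [0, 1]; got {w}")
    if Ga.ids != A22m.ids:
        raise DataError("Ga and A22 must share the same id order")
    return RelationshipMatrix(ids=list(Ga.ids),
                              values=w * Ga.values + (1.0 - w) * A22m.values,
                              kind="Gw", meta={"w": w})


def make_gw(panel: GenotypePanel, pedigree: Pedigree,
            w: float = 0.95) -> RelationshipMatrix:
    """Convenience: G -> Ga (matched to A22) -> Gw for the panel's animals."""
    G = g_matrix(panel)
    A22m = a22(pedigree, list(panel.ids))
    Ga, _ = adjust_g(G, A22m)
    return blend(Ga, A22m, w)


# ---------------------------------------------------------------------------
# single-step H^-1


@dataclass
class HInverseParts:
    """H^-1 stored as sparse A^-1 plus a dense genotyped-block correction.

    The assembled matrix is ``A^-1`` with ``Gw^-1 - A22^-1`` added on
    the genotyped rows/columns (zeros elsewhere).
    """

    a_inv: sp.csr_matrix
    correction: np.ndarray  # (Gw^-1 - A22^-1) on genotyped ids
    ids: list[str]  # full pedigree order
    genotyped_ids: list[str]

    def assemble(self) -> np.ndarray:
        """Dense H^-1 (for solving and tests; never inverts to dense H)."""
        H = self.a_inv.toarray()
        if self.genotyped_ids:
            pos = {a: i for i, a in enumerate(self.ids)}
            gi = np.array([pos[a] for a in self.genotyped_ids], dtype=int)
            H[np.ix_(gi, gi)] += self.correction
        return H


def h_inverse(pedigree: Pedigree, Gw: RelationshipMatrix,
              genotyped_ids: list[str] | None = None) -> HInverseParts:
    """Single-step H^-1 = A^-1 + [[Gw^-1 - A22^-1, 0], [0, 0]]."""
    genotyped_ids = list(genotyped_ids if genotyped_ids is not None else Gw.ids)
    if genotyped_ids and Gw.ids != genotyped_ids:
        Gw = Gw.subset(genotyped_ids)
    missing = set(genotyped_ids) - set(pedigree.ids)
    if missing:
        raise DataError(f"genotyped ids not in pedigree: {sorted(missing)[:5]}")
    Ainv = a_inverse(pedigree)
    if genotyped_ids:
        A22m = a22(pedigree, genotyped_ids)
        try:
            gw_inv = np.linalg.inv(Gw.values)
        except np.linalg.LinAlgError as exc:
            raise NumericalError("Gw is singular; blend with w < 1") from exc
        a22_inv = np.linalg.inv(A22m.values)
        corr = gw_inv - a22_inv
    else:
        corr = np.zeros((0, 0))
    return HInverseParts(a_inv=Ainv, correction=corr, ids=pedigree.ids,
                         genotyped_ids=genotyped_ids)
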