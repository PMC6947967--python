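"""Pedigree bookkeeping and animal-model BLUP.

EBVs are obtained from Henderson's mixed-model equations for
y = 1*mu + Z*a + e with a ~ N(0, A * sigma_a^2).  A-inverse is assembled
directly from pedigree rules; Mendelian-sampling variances account for
parental inbreeding, with inbreeding coefficients obtained from a
path-coefficient decomposition (A = L D L') evaluated generation by
generation and memoised over full-sib families.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

UNKNOWN = -1

__all__ = ["Pedigree", "EBVSolution", "pedigree_blup", "build_a_inverse",
           "inbreeding_of", "additive_relationship_matrix"]


class Pedigree:
    """Append-only pedigree; animal ids are dense row indices.

    Parents must be added before offspring; sires are male, dams female.
    ``generation`` is a free integer label (-1 = historical founders,
    0 = expanded, 1..G = recent).
    """

    def __init__(self):
        self.sire = np.empty(0, dtype=np.int64)
        self.dam = np.empty(0, dtype=np.int64)
        self.sex = np.empty(0, dtype=np.int8)
        self.generation = np.empty(0, dtype=np.int16)
        self._F: dict[int, float] = {}
        self._pairF: dict[tuple[int, int], float] = {}
        self._D: list[float] = []  # Mendelian-sampling variances, id order

    @property
    def n_animals(self) -> int:
        return len(self.sire)

    def add(self, sire: np.ndarray, dam: np.ndarray, sex: np.ndarray,
            generation: int) -> np.ndarray:
        sire = np.asarray(sire, dtype=np.int64)
        dam = np.asarray(dam, dtype=np.int64)
        sex = np.asarray(sex, dtype=np.int8)
        n0 = self.n_animals
        known_s = sire[sire >= 0]
        known_d = dam[dam >= 0]
        if len(known_s) and (known_s.max() >= n0 or np.any(self.sex[known_s] != 0)):
            raise ValueError("sires must pre-exist and be male")
        if len(known_d) and (known_d.max() >= n0 or np.any(self.sex[known_d] != 1)):
            raise ValueError("dams must pre-exist and be female")
        self.sire = np.concatenate([self.sire, sire])
        self.dam = np.concatenate([self.dam, dam])
        self.sex = np.concatenate([self.sex, sex])
        self.generation = np.concatenate(
            [self.generation, np.full(len(sire), generation, dtype=np.int16)])
        return np.arange(n0, n0 + len(sire))

    # -- inbreeding -------------------------------------------------------

    def _path_coefficients(self, animal: int) -> np.ndarray:
        """Expected genome contribution of every ancestor to ``animal``
        (L-column of the A = L D L' decomposition), via a generation-ordered
        downward sweep."""
        L = np.zeros(animal + 1)
        L[animal] = 1.0
        gens = self.generation[: animal + 1]
        for g in range(int(gens[animal]), int(gens.min()) - 1, -1):
            rows = np.flatnonzero((gens == g) & (L[: animal + 1] != 0))
            if len(rows) == 0:
                continue
            for par in (self.sire, self.dam):
                p = par[rows]
                ok = p >= 0
                np.add.at(L, p[ok], 0.5 * L[rows[ok]])
        return L

    def _mendelian_variance(self, upto: int) -> np.ndarray:
        """D_j for animals 0..upto (uses parental F; cached incrementally).

        Parents always precede offspring, so entries can be filled in id
        order; the recursion through inbreeding() only touches smaller ids.
        """
        for j in range(len(self._D), upto + 1):
            s, d = int(self.sire[j]), int(self.dam[j])
            if s >= 0 and d >= 0:
                v = 0.5 - 0.25 * (self.inbreeding(s) + self.inbreeding(d))
            elif s >= 0:
                v = 0.75 - 0.25 * self.inbreeding(s)
            elif d >= 0:
                v = 0.75 - 0.25 * self.inbreeding(d)
            else:
                v = 1.0
            self._D.append(v)
        return np.asarray(self._D[: upto + 1])

    def relationship(self, a: int, b: int) -> float:
        """Additive relationship a(a, b) via the L-column identity."""
        La = self._path_coefficients(a)
        Lb = self._path_coefficients(b)
        m = min(len(La), len(Lb))
        D = self._mendelian_variance(m - 1)
        return float(np.sum(La[:m] * Lb[:m] * D[:m]))

    def inbreeding(self, animal: int) -> float:
        """F of one animal (memoised; full-sib litters share the value)."""
        if animal in self._F:
            return self._F[animal]
        s, d = int(self.sire[animal]), int(self.dam[animal])
        if s < 0 or d < 0:
            f = 0.0
        else:
            key = (s, d)
            if key not in self._pairF:
                self._pairF[key] = 0.5 * self.relationship(s, d)
            f = self._pairF[key]
        self._F[animal] = f
        return f


def inbreeding_of(ped: Pedigree, animals: np.ndarray) -> np.ndarray:
    return np.array([ped.inbreeding(int(a)) for a in np.asarray(animals)])


def build_a_inverse(ped: Pedigree) -> sp.csr_matrix:
    """Sparse A-inverse by Henderson's rules with inbreeding-adjusted
    Mendelian-sampling variances (only parents' F is required)."""
    n = ped.n_animals
    s, d = ped.sire, ped.dam
    parents = np.unique(np.concatenate([s[s >= 0], d[d >= 0]]))
    F = np.zeros(n)
    F[parents] = inbreeding_of(ped, parents)
    alpha = np.empty(n)
    both = (s >= 0) & (d >= 0)
    alpha[both] = 1.0 / (0.5 - 0.25 * (F[s[both]] + F[d[both]]))
    only_s = (s >= 0) & ~both
    alpha[only_s] = 1.0 / (0.75 - 0.25 * F[s[only_s]])
    only_d = (d >= 0) & ~both
    alpha[only_d] = 1.0 / (0.75 - 0.25 * F[d[only_d]])
    none = (s < 0) & (d < 0)
    alpha[none] = 1.0

    i = np.arange(n)
    rows = [i]
    cols = [i]
    data = [alpha]
    for par, other in ((s, d), (d, s)):
        k = par >= 0
        rows += [i[k], par[k], par[k]]
        cols += [par[k], i[k], par[k]]
        data += [-0.5 * alpha[k], -0.5 * alpha[k], 0.25 * alpha[k]]
        kk = k & (other >= 0)
        rows += [par[kk]]
        cols += [other[kk]]
        data += [0.25 * alpha[kk]]
    A_inv = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n)).tocsr()
    return A_inv


def additive_relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Dense A by the tabular method (oracle-sized pedigrees only)."""
    n = ped.n_animals
    A = np.zeros((n, n))
    for i in range(n):
        s, d = int(ped.sire[i]), int(ped.dam[i])
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * A[j, s]
            if d >= 0:
                v += 0.5 * A[j, d]
            A[i, j] = A[j, i] = v
    return A


@dataclass
class EBVSolution:
    ebv: np.ndarray
    mu: float
    converged: bool
    iterations: int


def pedigree_blup(ped: Pedigree, phenotypes: np.ndarray, h2: float,
                  tol: float = 1e-8, maxiter: int = 5000) -> EBVSolution:
    """Solve the animal-model MME; ``phenotypes`` is NaN for unrecorded
    animals.  The variance ratio is lambda = (1 - h2) / h2."""
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie in (0, 1)")
    y = np.asarray(phenotypes, dtype=np.float64)
    if len(y) != ped.n_animals:
        raise ValueError("phenotype vector length must equal pedigree size")
    obs = np.flatnonzero(np.isfinite(y))
    if len(obs) == 0:
        raise ValueError("no phenotyped animals")
    n = ped.n_animals
    lam = (1.0 - h2) / h2
    A_inv = build_a_inverse(ped)

    Z = sp.csr_matrix((np.ones(len(obs)), (np.arange(len(obs)), obs)),
                      shape=(len(obs), n))
    X = np.ones((len(obs), 1))
    XtX = sp.csr_matrix(np.array([[float(len(obs))]]))
    XtZ = sp.csr_matrix(X.T @ Z)
    ZtZ = Z.T @ Z
    lhs = sp.bmat([[XtX, XtZ], [XtZ.T, ZtZ + lam * A_inv]], format="csr")
    rhs = np.concatenate([[y[obs].sum()], Z.T @ y[obs]])

    diag = lhs.diagonal()
    diag[diag == 0] = 1.0
    M = spla.LinearOperator(lhs.shape, matvec=lambda v: v / diag)
    it = {"n": 0}

    def cb(_):
        it["n"] += 1

    sol, info = spla.cg(lhs, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=M, callback=cb)
    resid = np.linalg.norm(lhs @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
    converged = info == 0 and np.isfinite(sol).all()
    if not np.isfinite(sol).all():
        raise FloatingPointError("mixed-model solve produced non-finite values")
    return EBVSolution(ebv=sol[1:], mu=float(sol[0]), converged=bool(converged),
                       iterations=it["n"])
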