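"""McMurchie-Davidson evaluation of Gaussian one- and two-electron integrals.

Contracted real Cartesian Gaussians; overlap, kinetic, nuclear attraction,
electric-dipole and electron-repulsion integrals.  The Hermite-expansion
recurrences and Hermite Coulomb tensor follow the standard McMurchie-Davidson
scheme (Helgaker/Jorgensen/Olsen conventions).  Written for the small basis
sets this package bundles; clarity over speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import hyp1f1


def boys(n: int, x: float) -> float:
    """Boys function F_n(x) via the confluent hypergeometric function."""
    return hyp1f1(n + 0.5, n + 1.5, -x) / (2.0 * n + 1.0)


def hermite_coefs(i: int, j: int, a: float, b: float, AB: float) -> np.ndarray:
    """1D Hermite expansion coefficients E_t^{ij} for t = 0..i+j."""
    p = a + b
    q = a * b / p
    # E[t, ii, jj]
    E = np.zeros((i + j + 1, i + 1, j + 1))
    E[0, 0, 0] = np.exp(-q * AB * AB)
    for jj in range(j + 1):
        for ii in range(i + 1):
            if ii == 0 and jj == 0:
                continue
            if jj == 0:  # increment ii from ii-1
                for t in range(ii + jj + 1):
                    v = 0.0
                    if t - 1 >= 0:
                        v += E[t - 1, ii - 1, jj] / (2 * p)
                    v -= (q * AB / a) * E[t, ii - 1, jj]
                    if t + 1 <= (ii - 1) + jj:
                        v += (t + 1) * E[t + 1, ii - 1, jj]
                    E[t, ii, jj] = v
            else:  # increment jj from jj-1
                for t in range(ii + jj + 1):
                    v = 0.0
                    if t - 1 >= 0:
                        v += E[t - 1, ii, jj - 1] / (2 * p)
                    v += (q * AB / b) * E[t, ii, jj - 1]
                    if t + 1 <= ii + (jj - 1):
                        v += (t + 1) * E[t + 1, ii, jj - 1]
                    E[t, ii, jj] = v
    return E[:, i, j]


def _E(i, j, a, b, AB):
    return hermite_coefs(i, j, a, b, AB)


def overlap_prim(la, lb, a, b, A, B):
    """Primitive overlap for Cartesian powers la=(l,m,n), lb likewise."""
    p = a + b
    s = (np.pi / p) ** 1.5
    for x in range(3):
        s *= _E(la[x], lb[x], a, b, A[x] - B[x])[0]
    return s


def kinetic_prim(la, lb, a, b, A, B):
    """Primitive kinetic integral via overlap with shifted powers."""
    l, m, n = lb

    def ov(lbx):
        return overlap_prim(la, lbx, a, b, A, B)

    term0 = b * (2 * (l + m + n) + 3) * ov((l, m, n))
    term1 = -2.0 * b * b * (ov((l + 2, m, n)) + ov((l, m + 2, n))
                            + ov((l, m, n + 2)))
    term2 = 0.0
    if l >= 2:
        term2 += -0.5 * l * (l - 1) * ov((l - 2, m, n))
    if m >= 2:
        term2 += -0.5 * m * (m - 1) * ov((l, m - 2, n))
    if n >= 2:
        term2 += -0.5 * n * (n - 1) * ov((l, m, n - 2))
    return term0 + term1 + term2


def dipole_prim(la, lb, a, b, A, B, component: int, origin=(0.0, 0.0, 0.0)):
    """Primitive <a| x_c |b> with x_c relative to ``origin``."""
    p = a + b
    P = (a * np.asarray(A) + b * np.asarray(B)) / p
    s = (np.pi / p) ** 1.5
    val = 1.0
    for x in range(3):
        E = _E(la[x], lb[x], a, b, A[x] - B[x])
        if x == component:
            # x_c = (x - P_x) + (P_x - origin_x); the first term picks E_1
            e1 = E[1] if len(E) > 1 else 0.0
            val *= e1 + (P[x] - origin[x]) * E[0]
        else:
            val *= E[0]
    return val * s


def hermite_coulomb(t, u, v, n, p, PC):
    """Auxiliary Hermite Coulomb tensor R^n_{tuv}(p, PC) (recursive)."""
    if t == u == v == 0:
        x = p * (PC[0] ** 2 + PC[1] ** 2 + PC[2] ** 2)
        return (-2.0 * p) ** n * boys(n, x)
    if t < 0 or u < 0 or v < 0:
        return 0.0
    if t > 0:
        val = PC[0] * hermite_coulomb(t - 1, u, v, n + 1, p, PC)
        if t > 1:
            val += (t - 1) * hermite_coulomb(t - 2, u, v, n + 1, p, PC)
        return val
    if u > 0:
        val = PC[1] * hermite_coulomb(t, u - 1, v, n + 1, p, PC)
        if u > 1:
            val += (u - 1) * hermite_coulomb(t, u - 2, v, n + 1, p, PC)
        return val
    val = PC[2] * hermite_coulomb(t, u, v - 1, n + 1, p, PC)
    if v > 1:
        val += (v - 1) * hermite_coulomb(t, u, v - 2, n + 1, p, PC)
    return val


def nuclear_prim(la, lb, a, b, A, B, C):
    """Primitive nuclear-attraction integral <a| 1/|r-C| |b> (positive)."""
    p = a + b
    P = (a * np.asarray(A) + b * np.asarray(B)) / p
    PC = P - np.asarray(C)
    Ex = _E(la[0], lb[0], a, b, A[0] - B[0])
    Ey = _E(la[1], lb[1], a, b, A[1] - B[1])
    Ez = _E(la[2], lb[2], a, b, A[2] - B[2])
    val = 0.0
    for t in range(la[0] + lb[0] + 1):
        for u in range(la[1] + lb[1] + 1):
            for v in range(la[2] + lb[2] + 1):
                val += Ex[t] * Ey[u] * Ez[v] * hermite_coulomb(t, u, v, 0, p, PC)
    return 2.0 * np.pi / p * val


def eri_prim(la, lb, lc, ld, a, b, c, d, A, B, C, D):
    """Primitive (ab|cd) in chemists' notation."""
    p = a + b
    q = c + d
    alpha = p * q / (p + q)
    P = (a * np.asarray(A) + b * np.asarray(B)) / p
    Q = (c * np.asarray(C) + d * np.asarray(D)) / q
    PQ = P - Q
    E1 = [_E(la[x], lb[x], a, b, A[x] - B[x]) for x in range(3)]
    E2 = [_E(lc[x], ld[x], c, d, C[x] - D[x]) for x in range(3)]
    val = 0.0
    for t in range(la[0] + lb[0] + 1):
        for u in range(la[1] + lb[1] + 1):
            for v in range(la[2] + lb[2] + 1):
                for tt in range(lc[0] + ld[0] + 1):
                    for uu in range(lc[1] + ld[1] + 1):
                        for vv in range(lc[2] + ld[2] + 1):
                            val += (E1[0][t] * E1[1][u] * E1[2][v]
                                    * E2[0][tt] * E2[1][uu] * E2[2][vv]
                                    * (-1.0) ** (tt + uu + vv)
                                    * hermite_coulomb(t + tt, u + uu, v + vv,
                                                      0, alpha, PQ))
    return val * 2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))


def _dfact(n: int) -> int:
    """(2n-1)!! with the convention (-1)!! = 1."""
    out = 1
    k = 2 * n - 1
    while k > 1:
        out *= k
        k -= 2
    return out


@dataclass
class BasisFunction:
    """One contracted Cartesian Gaussian basis function."""

    center: np.ndarray       # (3,) bohr
    powers: tuple            # (l, m, n)
    exps: np.ndarray
    coefs: np.ndarray        # contraction coefficients (for normalized prims)

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        self.exps = np.asarray(self.exps, float)
        self.coefs = np.asarray(self.coefs, float)
        l, m, n = self.powers
        L = l + m + n
        # normalize primitives
        self.pnorms = ((2.0 * self.exps / np.pi) ** 0.75
                       * (4.0 * self.exps) ** (L / 2.0)
                       / np.sqrt(_dfact(l) * _dfact(m) * _dfact(n)))
        # normalize the contraction
        s = 0.0
        for ci, ai, ni in zip(self.coefs, self.exps, self.pnorms):
            for cj, aj, nj in zip(self.coefs, self.exps, self.pnorms):
                s += ci * cj * ni * nj * overlap_prim(
                    self.powers, self.powers, ai, aj, self.center, self.center)
        self.norm = 1.0 / np.sqrt(s)

    def contract(self, other: "BasisFunction", prim_fn) -> float:
        """Contract a primitive-pair integral over both contractions."""
        val = 0.0
        for ci, ai, ni in zip(self.coefs, self.exps, self.pnorms):
            for cj, aj, nj in zip(other.coefs, other.exps, other.pnorms):
                val += ci * cj * ni * nj * prim_fn(
                    self.powers, other.powers, ai, aj, self.center, other.center)
        return val * self.norm * other.norm


def overlap_matrix(bfs):
    n = len(bfs)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            S[i, j] = S[j, i] = bfs[i].contract(bfs[j], overlap_prim)
    return S


def kinetic_matrix(bfs):
    n = len(bfs)
    T = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            T[i, j] = T[j, i] = bfs[i].contract(bfs[j], kinetic_prim)
    return T


def nuclear_matrix(bfs, charges, centers):
    n = len(bfs)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            v = 0.0
            for Z, C in zip(charges, centers):
                v -= Z * bfs[i].contract(
                    bfs[j],
                    lambda la, lb, a, b, A, B: nuclear_prim(la, lb, a, b, A, B, C))
            V[i, j] = V[j, i] = v
    return V


def dipole_matrices(bfs, origin=(0.0, 0.0, 0.0)):
    """Three symmetric matrices <p| x_c |q> about ``origin`` (a.u.)."""
    n = len(bfs)
    R = np.zeros((3, n, n))
    for comp in range(3):
        for i in range(n):
            for j in range(i + 1):
                val = bfs[i].contract(
                    bfs[j],
                    lambda la, lb, a, b, A, B: dipole_prim(
                        la, lb, a, b, A, B, comp, origin))
                R[comp, i, j] = R[comp, j, i] = val
    return R


def eri_tensor(bfs):
    """Full (pq|rs) tensor with 8-fold permutational symmetry."""
    n = len(bfs)
    g = np.zeros((n, n, n, n))
    done = np.zeros((n, n, n, n), bool)
    for p in range(n):
        for q in range(p + 1):
            for r in range(n):
                for s in range(r + 1):
                    if (p, q) < (r, s):
                        continue
                    if done[p, q, r, s]:
                        continue
                    bp, bq, br, bs = bfs[p], bfs[q], bfs[r], bfs[s]
                    val = 0.0
                    for cp, ap, npm in zip(bp.coefs, bp.exps, bp.pnorms):
                        for cq, aq, nq in zip(bq.coefs, bq.exps, bq.pnorms):
                            for cr, ar, nr in zip(br.coefs, br.exps, br.pnorms):
                                for cs, as_, ns in zip(bs.coefs, bs.exps,
                                                       bs.pnorms):
                                    val += (cp * cq * cr * cs
                                            * npm * nq * nr * ns
                                            * eri_prim(bp.powers, bq.powers,
                                                       br.powers, bs.powers,
                                                       ap, aq, ar, as_,
                                                       bp.center, bq.center,
                                                       br.center, bs.center))
                    val *= bp.norm * bq.norm * br.norm * bs.norm
                    for (a, b, c, d) in ((p, q, r, s), (q, p, r, s),
                                         (p, q, s, r), (q, p, s, r),
                                         (r, s, p, q), (s, r, p, q),
                                         (r, s, q, p), (s, r, q, p)):
                        g[a, b, c, d] = val
                        done[a, b, c, d] = True
    return g
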