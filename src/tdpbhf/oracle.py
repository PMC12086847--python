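"""Exact Fock-space oracle for <=5 spatial orbitals.

Dense matrix representations of all second-quantized operators on the full
4^n-dimensional occupation basis (Jordan-Wigner phases, spin-orbital order
p-up before p-down within each orbital).  Everything downstream — energies,
densities, pairing amplitudes, response matrix elements — can be evaluated
here exactly and serves as the certification reference for the closed-form
builders.  Test/debug use only; nothing production-scale runs through it.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla


class FockSpaceRep:
    """Enumerated Fock space with cached elementary operator matrices."""

    def __init__(self, n_orb: int):
        if n_orb > 5:
            raise ValueError("oracle limited to 5 spatial orbitals")
        self.n_orb = n_orb
        self.n_so = 2 * n_orb
        self.dim = 4 ** n_orb
        a1 = np.array([[0.0, 1.0], [0.0, 0.0]])  # a |1> = |0>
        z = np.diag([1.0, -1.0])
        eye = np.eye(2)
        self._a = []
        for j in range(self.n_so):
            ops = [z] * j + [a1] + [eye] * (self.n_so - j - 1)
            m = ops[0]
            for o in ops[1:]:
                m = np.kron(m, o)
            self._a.append(m)

    # spin-orbital index: (p, spin) with spin 0=up, 1=down
    def ann(self, p: int, spin: int) -> np.ndarray:
        if not 0 <= p < self.n_orb:
            raise IndexError(f"orbital index {p} out of range")
        return self._a[2 * p + spin]

    def cre(self, p: int, spin: int) -> np.ndarray:
        return self.ann(p, spin).T

    def E(self, p: int, q: int) -> np.ndarray:
        """Singlet excitation operator E_pq."""
        return (self.cre(p, 0) @ self.ann(q, 0)
                + self.cre(p, 1) @ self.ann(q, 1))

    def Qdag(self, p: int, q: int | None = None) -> np.ndarray:
        """Pair creation a†_p-up a†_q-down (closed-shell pair for q=p)."""
        q = p if q is None else q
        return self.cre(p, 0) @ self.cre(q, 1)

    def Q(self, p: int, q: int | None = None) -> np.ndarray:
        return self.Qdag(p, q).T

    def number_operator(self) -> np.ndarray:
        return sum(self.E(p, p) for p in range(self.n_orb))

    def vacuum(self) -> np.ndarray:
        return self._vacuum_vector()

    def _vacuum_vector(self) -> np.ndarray:
        N = sum(self.cre(p, s) @ self.ann(p, s)
                for p in range(self.n_orb) for s in (0, 1))
        idx = int(np.argmin(np.diag(N)))
        v = np.zeros(self.dim)
        v[idx] = 1.0
        return v

    def determinant(self, n_occ: int) -> np.ndarray:
        """Closed-shell determinant with the first n_occ orbitals doubly
        occupied."""
        v = self._vacuum_vector()
        for p in range(n_occ):
            v = self.cre(p, 0) @ v
            v = self.cre(p, 1) @ v
        nrm = np.linalg.norm(v)
        if nrm == 0:
            raise ValueError("determinant construction annihilated the state")
        return v / nrm

    # ---- composite model operators -------------------------------------
    def hamiltonian(self, mo, coupling: np.ndarray | None = None
                    ) -> np.ndarray:
        """H = H_mol + H_pb (+ V_nn) from MOIntegrals and a pairing field.

        ``coupling`` is the symmetric pairing-strength matrix Λ (diagonal
        Λ = diag(λ_p) for the untransformed model); None means λ = 0.
        """
        n = self.n_orb
        H = np.zeros((self.dim, self.dim))
        Es = [[self.E(p, q) for q in range(n)] for p in range(n)]
        for p in range(n):
            for q in range(n):
                if mo.h[p, q] != 0.0:
                    H += mo.h[p, q] * Es[p][q]
        # ½ Σ g_pqrs (E_pq E_rs − δ_qr E_ps): contract g over (pq) first so
        # only n² dense products are needed
        for r in range(n):
            for s in range(n):
                W = np.zeros((self.dim, self.dim))
                for p in range(n):
                    for q in range(n):
                        gv = mo.g[p, q, r, s]
                        if gv != 0.0:
                            W += gv * Es[p][q]
                H += 0.5 * (W @ Es[r][s])
                for p in range(n):
                    H -= 0.5 * mo.g[p, r, r, s] * Es[p][s]
        if coupling is not None:
            H += self.pairing_hamiltonian(coupling)
        return H + mo.nuclear_repulsion * np.eye(self.dim)

    def pairing_hamiltonian(self, coupling: np.ndarray) -> np.ndarray:
        """H_pb = Σ_pq Λ_pq (a†_p-up a†_q-down + h.c.)."""
        lam = np.atleast_2d(np.asarray(coupling, float))
        if lam.shape == (1, self.n_orb):
            lam = np.diag(lam[0])
        H = np.zeros((self.dim, self.dim))
        for p in range(self.n_orb):
            for q in range(self.n_orb):
                if lam[p, q] != 0.0:
                    P = self.Qdag(p, q)
                    H += lam[p, q] * (P + P.T)
        return H

    def gamma_generator(self, gamma: np.ndarray, n_occ: int) -> np.ndarray:
        """γ̂ = Σ_p γ_p (Q†_pp - Q_pp)."""
        G = np.zeros((self.dim, self.dim))
        for p, gp in enumerate(np.asarray(gamma, float)):
            if gp != 0.0:
                Qd = self.Qdag(p)
                G += gp * (Qd - Qd.T)
        return G

    def kappa_generator(self, kappa: np.ndarray) -> np.ndarray:
        """κ̂ = Σ_{p>q} κ_pq (E_pq - E_qp)."""
        K = np.zeros((self.dim, self.dim))
        kap = np.asarray(kappa, float)
        for p in range(self.n_orb):
            for q in range(p):
                if kap[p, q] != 0.0:
                    K += kap[p, q] * (self.E(p, q) - self.E(q, p))
        return K

    def state(self, gamma, n_occ: int, kappa=None) -> np.ndarray:
        """exp(κ̂) exp(γ̂) |Φ> via exact dense matrix exponentials."""
        v = self.determinant(n_occ)
        v = sla.expm(self.gamma_generator(gamma, n_occ)) @ v
        if kappa is not None and np.any(np.asarray(kappa) != 0):
            v = sla.expm(self.kappa_generator(kappa)) @ v
        return v


def expectation(state: np.ndarray, op: np.ndarray) -> float:
    if op.shape[0] != state.shape[0]:
        raise ValueError("dimension mismatch")
    return float(state @ (op @ state))


def density_matrix(rep: FockSpaceRep, state: np.ndarray) -> np.ndarray:
    n = rep.n_orb
    return np.array([[expectation(state, rep.E(p, q)) for q in range(n)]
                     for p in range(n)])


def pairing_matrix(rep: FockSpaceRep, state: np.ndarray) -> np.ndarray:
    """T_pq = <a†_p-up a†_q-down> (equals <Q_qp...> adjoint for real states)."""
    n = rep.n_orb
    return np.array([[expectation(state, rep.Qdag(p, q)) for q in range(n)]
                     for p in range(n)])


def _comm(A, B):
    return A @ B - B @ A


def sym_double_commutator(state, X, H, Y) -> float:
    """½ <[X,[H,Y]] + [[X,H],Y]> — the symmetrized Hessian element."""
    HY = _comm(H, Y)
    XH = _comm(X, H)
    return 0.5 * (expectation(state, _comm(X, HY))
                  + expectation(state, _comm(XH, Y)))


def response_elements(rep: FockSpaceRep, state: np.ndarray, H: np.ndarray,
                      pairs: list[tuple[int, int]],
                      B: np.ndarray | None = None):
    """Exact paired response blocks over the given (p, q) rotation pairs.

    For pair μ=(p,q) the excitation operator is q†_μ = E_pq.  Returns
    (A, Bm, Sigma, Delta[, gB]) with
      A_μν  = sym<[E_qp, [H, E_rs]]>,  Bm_μν = sym<[E_qp, [E_sr, H]]>,
      Sigma_μν = <[E_qp, E_rs]>,       Delta_μν = <[E_qp, E_sr]>,
    and gB the length-2M property-gradient vector for one-electron B.
    """
    M = len(pairs)
    Eops = {}
    for (p, q) in pairs:
        Eops[(p, q)] = rep.E(p, q)
        Eops[(q, p)] = rep.E(q, p)
    A = np.zeros((M, M))
    Bm = np.zeros((M, M))
    Sig = np.zeros((M, M))
    Del = np.zeros((M, M))
    for i, (p, q) in enumerate(pairs):
        qi = Eops[(q, p)]
        for j, (r, s) in enumerate(pairs):
            A[i, j] = sym_double_commutator(state, qi, H, Eops[(r, s)])
            Bm[i, j] = -sym_double_commutator(state, qi, H, Eops[(s, r)])
            Sig[i, j] = expectation(state, _comm(qi, Eops[(r, s)]))
            Del[i, j] = expectation(state, _comm(qi, Eops[(s, r)]))
    if B is None:
        return A, Bm, Sig, Del
    Bop = np.zeros((rep.dim, rep.dim))
    for p in range(rep.n_orb):
        for q in range(rep.n_orb):
            if B[p, q] != 0.0:
                Bop += B[p, q] * rep.E(p, q)
    g = np.zeros(2 * M)
    for i, (p, q) in enumerate(pairs):
        g[i] = expectation(state, _comm(Eops[(q, p)], Bop))
        g[M + i] = -expectation(state, _comm(Eops[(p, q)], Bop))
    return A, Bm, Sig, Del, g
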