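"""Closed-shell restricted Hartree-Fock reference, MO integrals, active space.

The reference determinant anchors the particle-breaking expansion: the model
mixes determinants of different electron counts around this closed-shell
state, so the SCF is converged tightly (response quality degrades with a
sloppy reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .integrals import AOIntegrals


class SCFConvergenceError(RuntimeError):
    pass


@dataclass
class ReferenceState:
    mo_coefficients: np.ndarray   # (n_ao, n_mo)
    orbital_energies: np.ndarray  # ascending
    n_occ: int
    scf_energy: float             # hartree, including nuclear repulsion
    converged: bool

    @property
    def n_mo(self) -> int:
        return self.mo_coefficients.shape[1]


@dataclass
class MOIntegrals:
    """MO-basis integrals: h_pq, chemists' (pq|rs), dipole matrices, V_nn."""

    h: np.ndarray
    g: np.ndarray
    dipole_mo: np.ndarray      # (3, n, n) electronic <p|r_c|q>
    nuclear_repulsion: float
    nuclear_dipole: np.ndarray = field(
        default_factory=lambda: np.zeros(3))

    @property
    def n_mo(self) -> int:
        return self.h.shape[0]

    def rotated(self, R: np.ndarray) -> "MOIntegrals":
        """Integrals in the orbital basis C' = C R (R orthogonal)."""
        h = R.T @ self.h @ R
        g = np.einsum("pqrs,pa,qb,rc,sd->abcd", self.g, R, R, R, R,
                      optimize=True)
        dip = np.einsum("xpq,pa,qb->xab", self.dipole_mo, R, R, optimize=True)
        return MOIntegrals(h, g, dip, self.nuclear_repulsion,
                           self.nuclear_dipole)


@dataclass
class ActiveSpace:
    """Orbitals carrying environmental coupling and their strengths λ_p."""

    active_indices: tuple
    lambda_by_orbital: dict      # MO index -> λ_p (a.u.); zero if absent
    n_mo: int

    LAMBDA_PHYSICAL = (1e-4, 1e-1)   # noncovalent-interaction guidance range

    def lambda_vector(self) -> np.ndarray:
        lam = np.zeros(self.n_mo)
        for p, v in self.lambda_by_orbital.items():
            lam[p] = v
        return lam

    def coupling_matrix(self) -> np.ndarray:
        return np.diag(self.lambda_vector())


def run_rhf(ints: AOIntegrals, n_electrons: int, max_cycles: int = 200,
            conv: float = 1e-10, diis_size: int = 8) -> ReferenceState:
    """Restricted HF with DIIS; converges the AO orbital gradient ~1e-10.

    The convergence criterion is the max element of the DIIS error
    F D S - S D F (equivalent to the orbital gradient).
    """
    if n_electrons % 2:
        raise ValueError("n_electrons must be even for RHF")
    if n_electrons > 2 * ints.n_ao:
        raise ValueError("more electrons than 2 x n_ao")
    S, h, g = ints.overlap, ints.core_hamiltonian, ints.eri
    n_occ = n_electrons // 2
    X = sla.fractional_matrix_power(S, -0.5).real

    def fock(D):
        J = np.einsum("pqrs,rs->pq", g, D, optimize=True)
        K = np.einsum("psrq,rs->pq", g, D, optimize=True)
        return h + J - 0.5 * K

    def density(F):
        eps, Cp = np.linalg.eigh(X @ F @ X)
        C = X @ Cp
        Cocc = C[:, :n_occ]
        return 2.0 * Cocc @ Cocc.T, eps, C

    D, eps, C = density(h)
    errs, focks = [], []
    err_norm = np.inf
    for _ in range(max_cycles):
        F = fock(D)
        err = F @ D @ S - S @ D @ F
        err_norm = np.abs(err).max()
        if err_norm < conv:
            break
        errs.append(X @ err @ X)
        focks.append(F)
        if len(errs) > diis_size:
            errs.pop(0)
            focks.pop(0)
        if len(errs) > 1:
            m = len(errs)
            Bm = -np.ones((m + 1, m + 1))
            Bm[-1, -1] = 0.0
            for i in range(m):
                for j in range(m):
                    Bm[i, j] = np.vdot(errs[i], errs[j])
            rhs = np.zeros(m + 1)
            rhs[-1] = -1.0
            try:
                c = np.linalg.solve(Bm, rhs)[:m]
                F = sum(ci * Fi for ci, Fi in zip(c, focks))
            except np.linalg.LinAlgError:
                pass
        D, eps, C = density(F)
    else:
        raise SCFConvergenceError(
            f"SCF not converged in {max_cycles} cycles; "
            f"last gradient max-element {err_norm:.3e}")
    F = fock(D)
    e_elec = 0.5 * np.einsum("pq,pq", D, h + F)
    eps, C = np.linalg.eigh(X @ F @ X)[0], X @ np.linalg.eigh(X @ F @ X)[1]
    order = np.argsort(eps)
    eps, C = eps[order], C[:, order]
    # fix orbital sign: largest-magnitude coefficient positive
    for k in range(C.shape[1]):
        j = np.argmax(np.abs(C[:, k]))
        if C[j, k] < 0:
            C[:, k] = -C[:, k]
    return ReferenceState(C, eps, n_occ,
                          float(e_elec + ints.nuclear_repulsion), True)


def transform_to_mo(ints: AOIntegrals, ref: ReferenceState) -> MOIntegrals:
    """Transform AO integrals to the (converged) MO basis."""
    if not ref.converged:
        raise ValueError("reference not converged")
    C = ref.mo_coefficients
    if C.shape[0] != ints.n_ao:
        raise ValueError("dimension mismatch between integrals and reference")
    h = C.T @ ints.core_hamiltonian @ C
    g = np.einsum("pqrs,pa,qb,rc,sd->abcd", ints.eri, C, C, C, C,
                  optimize=True)
    dip = np.einsum("xpq,pa,qb->xab", ints.dipole, C, C, optimize=True)
    return MOIntegrals(h, g, dip, ints.nuclear_repulsion, ints.nuclear_dipole)


def rhf_energy_from_mo(mo: MOIntegrals, n_occ: int) -> float:
    o = slice(0, n_occ)
    e = 2.0 * np.trace(mo.h[o, o])
    e += 2.0 * np.einsum("iijj->", mo.g[o, o, o, o])
    e -= np.einsum("ijji->", mo.g[o, o, o, o])
    return float(e + mo.nuclear_repulsion)


def lambda_schedule(k_max: int = 10, step: float = 0.01) -> np.ndarray:
    """Uniform coupling schedule λ = k*step, k = 1..k_max (a.u.)."""
    return step * np.arange(1, k_max + 1)


def select_active_space(ref: ReferenceState, lambda_max: float,
                        lambda_value, degeneracy_tol: float = 1e-6
                        ) -> ActiveSpace:
    """Energy-window active space [ε_HOMO - λ_max, ε_LUMO + λ_max].

    ``lambda_value`` is either a scalar (uniform coupling of all active
    orbitals) or a mapping {MO index: λ_p}.  Degenerate blocks straddling a
    window edge are included as a whole (tolerance 1e-6 hartree) so the
    selection cannot depend on the basis orientation within the block.
    """
    if lambda_max < 0:
        raise ValueError("lambda_max must be >= 0")
    eps = ref.orbital_energies
    homo, lumo = eps[ref.n_occ - 1], eps[ref.n_occ]
    lo, hi = homo - lambda_max, lumo + lambda_max
    inside = (eps >= lo - degeneracy_tol) & (eps <= hi + degeneracy_tol)
    active = set(np.nonzero(inside)[0].tolist())
    changed = True
    while changed:   # grow over degeneracies at the edges
        changed = False
        for p in list(active):
            for q in range(len(eps)):
                if q not in active and abs(eps[q] - eps[p]) < degeneracy_tol:
                    active.add(q)
                    changed = True
    active = tuple(sorted(active))
    if isinstance(lambda_value, dict):
        lam = {p: float(v) for p, v in lambda_value.items()}
        for p in lam:
            if p not in active:
                raise ValueError(f"λ table names inactive orbital {p}")
    else:
        lam = {p: float(lambda_value) for p in active}
    if any(v < 0 for v in lam.values()):
        raise ValueError("λ_p must be >= 0")
    return ActiveSpace(active, lam, ref.n_mo)
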