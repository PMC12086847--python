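"""Independent textbook TDHF (RPA) reference implementation.

Built directly from the standard closed-shell spatial-orbital formulas

    A_ai,bj = δ_ab δ_ij (ε_a − ε_i) + 2 (ia|jb) − (ij|ab)
    B_ai,bj = 2 (ia|jb) − (ib|ja)

and solved with a dense symplectic eigensolver.  This module shares no code
with the general response builder; it exists as the particle-conserving
limit against which that machinery is validated, and as a plain TDHF/CPHF
engine in its own right.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla

from .scf import MOIntegrals, ReferenceState


def tdhf_matrices(mo: MOIntegrals, ref: ReferenceState):
    """Singlet TDHF A and B matrices over (a, i) pairs, plus the pair list."""
    no = ref.n_occ
    nv = mo.n_mo - no
    eps = ref.orbital_energies
    pairs = [(a + no, i) for a in range(nv) for i in range(no)]
    M = len(pairs)
    A = np.zeros((M, M))
    B = np.zeros((M, M))
    g = mo.g
    for m, (a, i) in enumerate(pairs):
        for k, (b, j) in enumerate(pairs):
            A[m, k] = 2.0 * g[i, a, j, b] - g[i, j, a, b]
            if a == b and i == j:
                A[m, k] += eps[a] - eps[i]
            B[m, k] = 2.0 * g[i, a, b, j] - g[i, b, a, j]
    return A, B, pairs


def tdhf_excitations(mo: MOIntegrals, ref: ReferenceState,
                     n_states: int | None = None):
    """RPA excitation energies (ascending) and normalized (X, Y) amplitudes.

    Solved via the Hermitian (A−B)^{1/2}(A+B)(A−B)^{1/2} form; amplitudes
    satisfy X^T X − Y^T Y = 1.
    """
    A, B, pairs = tdhf_matrices(mo, ref)
    ApB, AmB = A + B, A - B
    wm, um = np.linalg.eigh(AmB)
    if wm.min() <= 0:
        raise np.linalg.LinAlgError("RPA instability: (A−B) not PD")
    half = um @ np.diag(np.sqrt(wm)) @ um.T
    w2, u = np.linalg.eigh(half @ ApB @ half)
    order = np.argsort(w2)
    if n_states is not None:
        order = order[:n_states]
    omegas, Xs, Ys = [], [], []
    for k in order:
        om = np.sqrt(w2[k])
        # (X+Y) = ω^{-1/2} (A−B)^{1/2} u;  (X−Y) = ω^{-1} (A+B)(X+Y)
        xpy = half @ u[:, k] / np.sqrt(om)
        xmy = ApB @ xpy / om
        X = 0.5 * (xpy + xmy)
        Y = 0.5 * (xpy - xmy)
        nrm = X @ X - Y @ Y
        X, Y = X / np.sqrt(nrm), Y / np.sqrt(nrm)
        omegas.append(om)
        Xs.append(X)
        Ys.append(Y)
    return np.array(omegas), np.array(Xs), np.array(Ys), pairs


def tdhf_polarizability(mo: MOIntegrals, ref: ReferenceState,
                        omega: float = 0.0) -> np.ndarray:
    """Frequency-dependent dipole polarizability tensor (a.u.).

    α(ω) from the paired RPA response with dipole gradients
    b_ai = 2 μ_ai; reduces to CPHF at ω = 0.
    """
    A, B, pairs = tdhf_matrices(mo, ref)
    M = len(pairs)
    E2 = np.block([[A, B], [B, A]])
    S2 = np.block([[np.eye(M), np.zeros((M, M))],
                   [np.zeros((M, M)), -np.eye(M)]])
    mu = -mo.dipole_mo            # electronic dipole operator
    alpha = np.zeros((3, 3))
    rhs = []
    for c in range(3):
        b = np.array([2.0 * mu[c, a, i] for (a, i) in pairs])
        rhs.append(np.concatenate([b, b]))
    L = E2 - omega * S2
    for c in range(3):
        x = np.linalg.solve(L, rhs[c])
        for d in range(3):
            # paired doubling: each component of rhs carries the full b,
            # so the contraction counts the response twice
            alpha[c, d] = 0.5 * rhs[d] @ x
    return 0.5 * (alpha + alpha.T)


def tdhf_oscillator_strengths(mo: MOIntegrals, ref: ReferenceState,
                              n_states: int | None = None):
    """(ω_n, f_n) in length gauge from the RPA amplitudes."""
    omegas, Xs, Ys, pairs = tdhf_excitations(mo, ref, n_states)
    mu = -mo.dipole_mo
    f = np.zeros_like(omegas)
    T = np.zeros((omegas.size, 3))
    for k in range(omegas.size):
        for c in range(3):
            # singlet transition dipole <0|mu|n> = sqrt(2) mu^T (X+Y)
            b = np.array([np.sqrt(2.0) * mu[c, a, i] for (a, i) in pairs])
            T[k, c] = b @ (Xs[k] + Ys[k])
        f[k] = 2.0 / 3.0 * omegas[k] * (T[k] @ T[k])
    return omegas, f, T
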