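"""Time-dependent PBHF linear response.

Orbital rotations are the only time-dependent parameters (local excitations;
the occupation angles are frozen), so the response space is spanned by the
non-redundant rotation pairs μ = (p, q) with excitation operator
q†_μ = E_pq.  In the orbital basis where the ground state is the pure angle
product (κ absorbed), the paired electronic Hessian and metric are

    E[2] = [[A, B], [B, A]],       S[2] = [[Σ, 0], [0, −Σ]],

with A_μν / B_μν symmetrized double-commutator expectations
<[q_μ, [H, q†_ν]]> / <[q_μ, [q_ν, H]]> and the diagonal metric
Σ_μμ = D_qq − D_pp.  All element formulas follow from Wick's theorem with
the diagonal normal/pairing densities; they reduce to the textbook TDHF
A/B/unit-metric structure at λ = 0 and are certified against the exact
Fock-space oracle in the tests.

Pairs are oriented so Σ_μμ > 0 and pairs with |Σ_μμ| below a null-space
threshold (redundant rotations, e.g. occupied-occupied at λ = 0) are
projected out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .ground import PBHFState
from .scf import MOIntegrals

METRIC_NULL_TOL = 1e-10


def expectation_e_tensor(occ: np.ndarray, t: np.ndarray) -> np.ndarray:
    """<e_wxyz> for the diagonal product state: dense n^4 tensor.

    occ holds the diagonal of D (occupancies in [0, 2]), t the diagonal of
    the pairing density T.
    """
    n = occ.size
    I = np.eye(n)
    DD = np.einsum("w,y->wy", occ, occ)
    tt = np.einsum("w,z->wz", t, t)
    Ee = np.einsum("wx,yz,wy->wxyz", I, I, DD)
    Ee -= 0.5 * np.einsum("wz,xy,wx->wxyz", I, I, DD)
    Ee += 2.0 * np.einsum("wy,xz,wz->wxyz", I, I, tt)
    return Ee


def double_commutator_tensor(ints: MOIntegrals, coupling: np.ndarray,
                             occ: np.ndarray, t: np.ndarray) -> np.ndarray:
    """W[a,b,c,d] = <[E_ab, [H, E_cd]]> over the diagonal product state."""
    n = occ.size
    h, g = ints.h, ints.g
    Lam = coupling
    # one-electron part: (D_a − D_b)(δ_ad h_bc − δ_bc h_da)
    dD = occ[:, None] - occ[None, :]          # dD[a,b] = D_a − D_b
    W = np.einsum("ab,ad,bc->abcd", dD, np.eye(n), h)
    W -= np.einsum("ab,bc,da->abcd", dD, np.eye(n), h)
    # pairing part
    W -= 2.0 * np.einsum("bc,da,a->abcd", np.eye(n), Lam, t)
    W -= 2.0 * np.einsum("ac,db,a->abcd", np.eye(n), Lam, t)
    W -= 2.0 * np.einsum("ad,cb,b->abcd", np.eye(n), Lam, t)
    W -= 2.0 * np.einsum("bd,ca,b->abcd", np.eye(n), Lam, t)
    # two-electron part via the exact <e> tensor
    Ee = expectation_e_tensor(occ, t)
    W += np.einsum("bcyz,adyz->abcd", g, Ee, optimize=True)
    W -= np.einsum("wcya,wdyb->abcd", g, Ee, optimize=True)
    W += np.einsum("wcbz,wdaz->abcd", g, Ee, optimize=True)
    W += np.einsum("dayz,cbyz->abcd", g, Ee, optimize=True)
    W += np.einsum("dxya,cxyb->abcd", g, Ee, optimize=True)
    W -= np.einsum("dxbz,cxaz->abcd", g, Ee, optimize=True)
    X1 = np.einsum("wcyz,wbyz->cb", g, Ee, optimize=True)
    X6 = np.einsum("dxyz,axyz->da", g, Ee, optimize=True)
    for a in range(n):
        W[a, :, :, a] -= X1.T
        W[:, a, a, :] -= X6.T
    return W


@dataclass
class ResponseMatrices:
    """Paired electronic Hessian and metric over non-redundant rotations."""

    a: np.ndarray                  # (M, M)
    b: np.ndarray                  # (M, M)
    sigma: np.ndarray              # (M,) diagonal of Σ (> 0 by orientation)
    pairs: list                    # ordered (p, q): q†_μ = E_pq, Σ_μμ > 0
    occ: np.ndarray = field(repr=False, default=None)
    t: np.ndarray = field(repr=False, default=None)

    @property
    def m(self) -> int:
        return len(self.pairs)

    @property
    def e2(self) -> np.ndarray:
        return np.block([[self.a, self.b], [self.b, self.a]])

    @property
    def s2(self) -> np.ndarray:
        S = np.diag(self.sigma)
        Z = np.zeros_like(S)
        return np.block([[S, Z], [Z, -S]])


@dataclass
class PropertyGradient:
    g: np.ndarray                  # length 2M
    label: str = ""
    omega: float = 0.0


@dataclass
class ExcitationResult:
    omega: np.ndarray              # ascending, > 0
    Z: np.ndarray                  # (n_states, M) excitation amplitudes
    Y: np.ndarray                  # (n_states, M) deexcitation amplitudes
    pairs: list
    norms: np.ndarray              # X^T S[2] X values before normalization

    @property
    def n_states(self) -> int:
        return self.omega.size

    def amplitude_vectors(self) -> np.ndarray:
        """Stacked (Z, Y) vectors, one row per state."""
        return np.hstack([self.Z, self.Y])


def select_pairs(occ: np.ndarray, null_tol: float = METRIC_NULL_TOL):
    """Oriented non-redundant pairs and their metric entries.

    Pair (p, q) is oriented so that Σ_μμ = D_qq − D_pp > 0 (excitation
    moves density toward the less occupied orbital); pairs with metric
    magnitude below ``null_tol`` are redundant rotations and dropped.
    """
    n = occ.size
    pairs, sig = [], []
    for p in range(n):
        for q in range(p):
            s = occ[q] - occ[p]
            if abs(s) < null_tol:
                continue
            if s > 0:
                pairs.append((p, q))
                sig.append(s)
            else:
                pairs.append((q, p))
                sig.append(-s)
    return pairs, np.asarray(sig)


def build_response_matrices(state: PBHFState) -> ResponseMatrices:
    """E[2]/S[2] blocks for a converged PBHF state (κ absorbed first)."""
    if not state.converged:
        raise ValueError("refusing to build response for unconverged state")
    ints, cpl, angles = state.absorbed()
    occ = 1.0 + angles.signs * np.cos(2.0 * angles.gamma)
    t = -0.5 * angles.signs * np.sin(2.0 * angles.gamma)
    W = double_commutator_tensor(ints, cpl.matrix, occ, t)
    pairs, sigma = select_pairs(occ)
    M = len(pairs)
    A = np.empty((M, M))
    B = np.empty((M, M))
    for i, (p, q) in enumerate(pairs):
        for j, (r, s) in enumerate(pairs):
            A[i, j] = 0.5 * (W[q, p, r, s] + W[s, r, p, q])
            B[i, j] = -0.5 * (W[q, p, s, r] + W[r, s, p, q])
    return ResponseMatrices(a=A, b=B, sigma=sigma, pairs=pairs, occ=occ, t=t)


def build_property_gradient(op_mo: np.ndarray, mats: ResponseMatrices,
                            label: str = "", omega: float = 0.0
                            ) -> PropertyGradient:
    """g^B for a symmetric one-electron operator B̂ = Σ_pq B_pq E_pq.

    Both paired components carry b_μ = (D_qq − D_pp) B_pq; at λ = 0 this is
    the standard TDHF dipole gradient.
    """
    B = np.asarray(op_mo, float)
    if not np.allclose(B, B.T, atol=1e-10):
        raise ValueError("property operator must be symmetric")
    b = np.array([mats.sigma[i] * B[p, q]
                  for i, (p, q) in enumerate(mats.pairs)])
    return PropertyGradient(np.concatenate([b, b]), label, omega)


class ResonanceError(RuntimeError):
    def __init__(self, omega, omega_n):
        super().__init__(
            f"frequency {omega:.6f} a.u. within 1e-4 of excitation "
            f"{omega_n:.6f} a.u.")
        self.omega_n = omega_n


class SubspaceStagnationError(RuntimeError):
    def __init__(self, residuals):
        super().__init__(
            f"iterative response solver stagnated; residual history "
            f"{[f'{r:.2e}' for r in residuals]}")
        self.residuals = residuals


def solve_linear_response(mats: ResponseMatrices, grad: PropertyGradient,
                          omega: float, method: str = "iterative",
                          known_omegas: np.ndarray | None = None,
                          rtol: float = 1e-6, max_space: int = 200
                          ) -> np.ndarray:
    """Solve (E[2] − ω S[2]) X = g.

    ``method`` is 'iterative' (paired-trial-vector subspace expansion with a
    diagonal preconditioner) or 'direct' (dense solve).  Refuses frequencies
    within 1e-4 a.u. of a known excitation energy.
    """
    if known_omegas is not None and known_omegas.size:
        d = np.abs(known_omegas - abs(omega))
        k = int(np.argmin(d))
        if d[k] < 1e-4:
            raise ResonanceError(omega, float(known_omegas[k]))
    E2, S2, g = mats.e2, mats.s2, grad.g
    gn = np.linalg.norm(g)
    if gn == 0.0:
        return np.zeros_like(g)
    L = E2 - omega * S2
    if method == "direct":
        return np.linalg.solve(L, g)
    M = mats.m
    diag = np.diag(L).copy()
    diag[np.abs(diag) < 1e-8] = 1.0

    def precond(r):
        return r / diag

    def paired(v):
        return np.concatenate([v[M:], v[:M]])

    basis = []

    def add_vec(v):
        for u in basis:
            v = v - u * (u @ v)
        nv = np.linalg.norm(v)
        if nv > 1e-10:
            basis.append(v / nv)
            return True
        return False

    add_vec(precond(g))
    if basis:
        add_vec(paired(basis[0]))
    residuals = []
    for _ in range(max_space):
        V = np.array(basis).T
        LV = L @ V
        x_sub = np.linalg.lstsq(V.T @ LV, V.T @ g, rcond=None)[0]
        x = V @ x_sub
        r = g - L @ x
        rn = np.linalg.norm(r)
        residuals.append(rn)
        if rn <= rtol * gn:
            return x
        if len(residuals) > 6 and rn > 0.95 * residuals[-6]:
            raise SubspaceStagnationError(residuals)
        new = precond(r)
        grew = add_vec(new)
        grew |= add_vec(paired(new))
        if not grew:
            # subspace exhausted; fall back to the dense solution
            return np.linalg.solve(L, g)
    raise SubspaceStagnationError(residuals)


class CasidaKernelError(RuntimeError):
    pass


def solve_excitations(mats: ResponseMatrices, n_states: int | None = None,
                      method: str = "casida") -> ExcitationResult:
    """Excitation energies/amplitudes from the paired eigenproblem.

    'casida': the halved-dimension symmetric form built with the diagonal
    metric V = Σ; requires the (A−B) kernel positive definite, otherwise a
    :class:`CasidaKernelError` signals an unstable reference.  'direct':
    dense generalized eigenproblem E[2] X = ω S[2] X.  Amplitudes are
    normalized to X^T S[2] X = 1 with the largest-magnitude component
    positive.
    """
    M = mats.m
    if n_states is None:
        n_states = M
    if n_states > M:
        raise ValueError(f"n_states {n_states} exceeds dimension {M}")
    A, B = mats.a, mats.b
    sig = mats.sigma
    if method == "direct":
        w, vec = sla.eig(mats.e2, mats.s2)
        if np.abs(w.imag).max() > 1e-8:
            raise CasidaKernelError(
                "complex response eigenvalues: unstable PBHF reference")
        w = w.real
        vec = vec.real
        sel = np.where(w > 1e-12)[0]
        order = sel[np.argsort(w[sel])][:n_states]
        omegas, Zs, Ys, norms = [], [], [], []
        S2 = mats.s2
        for k in order:
            x = vec[:, k]
            nrm = float(x @ S2 @ x)
            norms.append(nrm)
            if nrm <= 0:
                continue
            x = x / np.sqrt(nrm)
            x = _fix_sign(x)
            omegas.append(w[k])
            Zs.append(x[:M])
            Ys.append(x[M:])
        return ExcitationResult(np.array(omegas), np.array(Zs), np.array(Ys),
                                mats.pairs, np.array(norms))
    # Casida route: V^{-1/2}(A∓B)V^{-1/2}, ω² eigenproblem
    vs = 1.0 / np.sqrt(sig)
    Mminus = vs[:, None] * (A - B) * vs[None, :]
    Mplus = vs[:, None] * (A + B) * vs[None, :]
    wm, um = np.linalg.eigh(Mminus)
    if wm.min() <= 0:
        raise CasidaKernelError(
            f"(A−B) kernel not positive definite (min eig {wm.min():.3e}): "
            "unstable PBHF reference")
    half = um @ np.diag(np.sqrt(wm)) @ um.T
    C = half @ Mplus @ half
    w2, u = np.linalg.eigh(C)
    if w2.min() <= 0:
        raise CasidaKernelError(
            f"Casida kernel not positive definite (min eig {w2.min():.3e}): "
            "unstable PBHF reference")
    invhalf = um @ np.diag(1.0 / np.sqrt(wm)) @ um.T
    order = np.argsort(w2)[:n_states]
    omegas, Zs, Ys = [], [], []
    for k in order:
        om = np.sqrt(w2[k])
        # back-transform: (Z−Y) ∝ V^{-1/2} (A−B)^{-1/2} u_k in the scaled
        # frame; (Z+Y) follows from the paired first-order equation
        zmy = vs * (invhalf @ u[:, k])
        zpy = (A - B) @ zmy / (om * sig)
        Z = 0.5 * (zpy + zmy)
        Y = 0.5 * (zpy - zmy)
        x = np.concatenate([Z, Y])
        nrm = float(Z @ (sig * Z) - Y @ (sig * Y))
        x = _fix_sign(x / np.sqrt(nrm))
        omegas.append(om)
        Zs.append(x[:mats.m])
        Ys.append(x[mats.m:])
    omegas = np.array(omegas)
    return ExcitationResult(omegas, np.array(Zs), np.array(Ys), mats.pairs,
                            np.ones_like(omegas))


def _fix_sign(x: np.ndarray) -> np.ndarray:
    j = int(np.argmax(np.abs(x)))
    return -x if x[j] < 0 else x
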