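"""Random certification of the closed-form builders against the exact
Fock-space oracle.

Used by the `oracle-check` CLI subcommand and by the acceptance tests: draws
random integrals, coupling fields, occupation angles and orbital rotations
on 2-4 spatial orbitals and compares every quantity the package computes in
closed form (energy, densities, pairing, overlap, fractional charge, all
E[2]/S[2] blocks and property-gradient elements) with the corresponding
exact Fock-space expectation values.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla

from . import oracle as orc
from .ground import (OccupationAngles, CouplingSpec, build_density_matrix,
                     build_pairing_matrix, fractional_charge, hf_overlap,
                     pbhf_energy)
from .response import (build_property_gradient, double_commutator_tensor,
                       ResponseMatrices, select_pairs)
from .scf import MOIntegrals


def random_mo_integrals(n: int, rng: np.random.Generator) -> MOIntegrals:
    """Random symmetric h and 8-fold-symmetric positive-ish g."""
    h = rng.normal(size=(n, n))
    h = 0.5 * (h + h.T)
    g = np.zeros((n, n, n, n))
    for _ in range(3):
        a = rng.normal(size=(n, n))
        a = 0.5 * (a + a.T)
        g += 0.25 * np.einsum("pq,rs->pqrs", a, a)
    dip = rng.normal(size=(3, n, n))
    dip = 0.5 * (dip + dip.transpose(0, 2, 1))
    return MOIntegrals(h, g, dip, float(rng.normal()))


def sample_deviations(n: int, n_occ: int, rng: np.random.Generator,
                      rep: orc.FockSpaceRep | None = None,
                      mo: MOIntegrals | None = None) -> dict:
    """Max |closed form − oracle| for one random (γ, κ, λ) draw."""
    if rep is None:
        rep = orc.FockSpaceRep(n)
    if mo is None:
        mo = random_mo_integrals(n, rng)
    lam_diag = rng.uniform(0.0, 0.1, n) * rng.integers(0, 2, n)
    gamma = rng.uniform(-0.35, 0.35, n)
    kap = np.zeros((n, n))
    for p in range(n):
        for q in range(p):
            kap[p, q] = rng.uniform(-0.25, 0.25)
            kap[q, p] = -kap[p, q]
    angles = OccupationAngles(gamma, n_occ)
    Lam = np.diag(lam_diag)
    cpl = CouplingSpec.__new__(CouplingSpec)
    cpl.matrix = Lam
    dev = {}

    # ground-state quantities with explicit κ against the raw-basis oracle
    psi_full = rep.state(gamma, n_occ, kap)
    H_raw = rep.hamiltonian(mo, Lam)
    dev["energy"] = abs(pbhf_energy(mo, cpl, angles, kap)
                        - orc.expectation(psi_full, H_raw))

    # γ-only state quantities
    psi = rep.state(gamma, n_occ)
    dev["density"] = np.abs(build_density_matrix(angles)
                            - orc.density_matrix(rep, psi)).max()
    dev["pairing"] = np.abs(build_pairing_matrix(angles)
                            - orc.pairing_matrix(rep, psi)).max()
    dev["overlap"] = abs(hf_overlap(angles)
                         - float(rep.determinant(n_occ) @ psi))
    Nop = rep.number_operator()
    dev["delta_n"] = abs(fractional_charge(build_density_matrix(angles),
                                           2 * n_occ)
                         - (orc.expectation(psi, Nop) - 2 * n_occ))

    # response blocks in the κ-absorbed orbital basis
    R = sla.expm(kap)
    mo_rot = mo.rotated(R)
    Lam_rot = R.T @ Lam @ R
    occ = np.diag(build_density_matrix(angles)).copy()
    t = np.diag(build_pairing_matrix(angles)).copy()
    pairs, sigma = select_pairs(occ)
    W = double_commutator_tensor(mo_rot, Lam_rot, occ, t)
    M = len(pairs)
    A = np.empty((M, M))
    B = np.empty((M, M))
    for i, (p, q) in enumerate(pairs):
        for j, (r, s) in enumerate(pairs):
            A[i, j] = 0.5 * (W[q, p, r, s] + W[s, r, p, q])
            B[i, j] = -0.5 * (W[q, p, s, r] + W[r, s, p, q])
    Bop = mo_rot.dipole_mo[0]
    H_rot = rep.hamiltonian(mo_rot, Lam_rot)
    A_or, B_or, Sig_or, Del_or, g_or = orc.response_elements(
        rep, psi, H_rot, pairs, Bop)
    dev["e2_a"] = np.abs(A - A_or).max() if M else 0.0
    dev["e2_b"] = np.abs(B - B_or).max() if M else 0.0
    dev["s2"] = max(np.abs(np.diag(sigma) - Sig_or).max(),
                    np.abs(Del_or).max()) if M else 0.0
    mats = ResponseMatrices(a=A, b=B, sigma=sigma, pairs=pairs, occ=occ, t=t)
    g_my = build_property_gradient(Bop, mats).g
    dev["gradient"] = np.abs(g_my - g_or).max() if M else 0.0
    return dev


def oracle_certification(n_orbitals: int = 3, n_samples: int = 5,
                         seed: int = 0, sizes=None) -> dict:
    """Worst deviation over random draws; keys as in sample_deviations."""
    rng = np.random.default_rng(seed)
    if sizes is None:
        sizes = [n_orbitals] * n_samples
    worst: dict[str, float] = {}
    reps: dict[int, orc.FockSpaceRep] = {}
    for n in sizes:
        rep = reps.setdefault(n, orc.FockSpaceRep(n))
        n_occ = int(rng.integers(1, n))
        dev = sample_deviations(n, n_occ, rng, rep)
        for k, v in dev.items():
            worst[k] = max(worst.get(k, 0.0), float(v))
    return worst
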