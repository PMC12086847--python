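"""Built-in toy systems for tests, examples and the CLI.

Three tiny molecules (H2, LiH, water in a minimal basis) and one synthetic
4-orbital integral set.  The synthetic fixture emulates the electronic
regime in which environmental pair fluctuations redshift the low-lying
excitations: a compact valence-occupied orbital, a diffuse low-lying
virtual carrying the lowest excitation (small self-repulsion, as produced
by augmented basis sets), and a compact higher virtual that carries the
environmental coupling and repels the hole density strongly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .integrals import fetch_ao_integrals
from .molecule import MoleculeSpec, parse_xyz
from .scf import MOIntegrals, run_rhf, select_active_space, transform_to_mo

H2_XYZ = """2
hydrogen molecule, R = 1.4 bohr
H 0.0 0.0 0.0
H 0.0 0.0 0.74084289
"""

LIH_XYZ = """2
lithium hydride, R = 3.015 bohr
Li 0.0 0.0 0.0
H 0.0 0.0 1.59552413
"""

H2O_XYZ = """3
water, experimental-like geometry
O 0.000000 0.000000 0.117300
H 0.000000 0.757200 -0.469200
H 0.000000 -0.757200 -0.469200
"""


@dataclass
class MolecularFixture:
    name: str
    xyz: str
    basis: str
    description: str

    def molecule(self) -> MoleculeSpec:
        return parse_xyz(self.xyz)

    def build(self):
        """(molecule, AO integrals, RHF reference, MO integrals)."""
        mol = self.molecule()
        ints = fetch_ao_integrals(mol, self.basis)
        ref = run_rhf(ints, mol.n_electrons)
        mo = transform_to_mo(ints, ref)
        return mol, ints, ref, mo

    def active_space(self, lam, lambda_max: float = 0.1):
        _, _, ref, _ = self.build()
        return ref, select_active_space(ref, lambda_max, lam)


@dataclass
class SyntheticFixture:
    """Hand-built MO integrals (synthetic; no underlying molecule).

    Orbitals: 0 core (occ), 1 valence (occ), 2 diffuse virtual, 3 compact
    virtual.  The suggested coupling acts on orbital 3 only.
    """

    name: str
    description: str
    n_occ: int = 2
    coupled_orbital: int = 3
    active_indices: tuple = (1, 2, 3)

    def build(self) -> MOIntegrals:
        n = 4
        # Coulomb matrix J[p,q] = (pp|qq): Gram-like, compact orbitals
        # repel strongly, the diffuse virtual (2) weakly
        J = np.array([
            [1.50, 0.55, 0.20, 0.60],
            [0.55, 0.80, 0.25, 0.75],
            [0.20, 0.25, 0.15, 0.20],
            [0.60, 0.75, 0.20, 0.90],
        ])
        K = 0.02
        g = np.zeros((n, n, n, n))
        for p in range(n):
            for q in range(n):
                g[p, p, q, q] = J[p, q]
                if p != q:
                    g[p, q, p, q] = g[q, p, p, q] = K
                    g[p, q, q, p] = g[q, p, q, p] = K
        eps = np.array([-2.0, 0.0, 0.5, 1.2])
        D = np.diag([2.0, 2.0, 0.0, 0.0])
        Jm = np.einsum("pqrs,rs->pq", g, D)
        Km = np.einsum("psrq,rs->pq", g, D)
        h = np.diag(eps) - (Jm - 0.5 * Km)
        rng = np.random.default_rng(5)
        dip = rng.normal(size=(3, n, n))
        dip = 0.5 * (dip + dip.transpose(0, 2, 1))
        return MOIntegrals(h, g, dip, 0.0)

    def lambda_table(self, lam: float) -> dict:
        return {self.coupled_orbital: lam}


REGISTRY = {
    "h2": MolecularFixture(
        "h2", H2_XYZ, "sto-3g",
        "H2 at 1.4 bohr, minimal basis (2 orbitals)"),
    "lih": MolecularFixture(
        "lih", LIH_XYZ, "sto-3g",
        "LiH at 3.015 bohr, minimal basis (6 orbitals)"),
    "h2o_min": MolecularFixture(
        "h2o_min", H2O_XYZ, "sto-3g",
        "water, minimal basis (7 orbitals)"),
    "synthetic_orbitals": SyntheticFixture(
        "synthetic_orbitals",
        "synthetic 4-orbital integrals with a diffuse low virtual"),
}


def make_fixture(name: str):
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; registry: {sorted(REGISTRY)}")
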