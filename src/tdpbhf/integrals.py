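"""AO integral contract: the AOIntegrals container and its builder.

The integral engine behind :func:`fetch_ao_integrals` is an adapter; all
downstream code touches only the AOIntegrals fields (atomic units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import gaussian
from .basis import build_basis
from .molecule import MoleculeSpec


@dataclass
class AOIntegrals:
    """AO-basis integrals in atomic units.

    ``eri`` is (pq|rs) in chemists' notation with 8-fold permutational
    symmetry; ``dipole`` holds the three Cartesian <p|r_c|q> matrices about
    the coordinate origin.
    """

    n_ao: int
    overlap: np.ndarray
    core_hamiltonian: np.ndarray
    eri: np.ndarray
    dipole: np.ndarray        # (3, n_ao, n_ao)
    nuclear_repulsion: float
    nuclear_dipole: np.ndarray

    def validate(self, tol: float = 1e-10) -> None:
        S, h, g = self.overlap, self.core_hamiltonian, self.eri
        assert S.shape == (self.n_ao, self.n_ao)
        assert np.allclose(S, S.T, atol=tol)
        if np.linalg.eigvalsh(S).min() <= 0:
            raise ValueError("overlap matrix is not positive definite")
        assert np.allclose(h, h.T, atol=tol)
        assert np.allclose(g, g.transpose(1, 0, 2, 3), atol=tol)
        assert np.allclose(g, g.transpose(0, 1, 3, 2), atol=tol)
        assert np.allclose(g, g.transpose(2, 3, 0, 1), atol=tol)


class IntegralBackendError(RuntimeError):
    pass


def fetch_ao_integrals(mol: MoleculeSpec, basis) -> AOIntegrals:
    """Evaluate all AO integrals for ``mol`` in the named basis."""
    try:
        bfs = build_basis(mol, basis)
        S = gaussian.overlap_matrix(bfs)
        T = gaussian.kinetic_matrix(bfs)
        V = gaussian.nuclear_matrix(bfs, mol.charges, mol.coords)
        R = gaussian.dipole_matrices(bfs)
        g = gaussian.eri_tensor(bfs)
    except KeyError:
        raise
    except Exception as exc:  # propagate with context per the contract
        raise IntegralBackendError(
            f"integral evaluation failed for basis {basis!r}: {exc}") from exc
    ints = AOIntegrals(
        n_ao=len(bfs), overlap=S, core_hamiltonian=T + V, eri=g, dipole=R,
        nuclear_repulsion=mol.nuclear_repulsion(),
        nuclear_dipole=mol.nuclear_dipole())
    ints.validate()
    return ints
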