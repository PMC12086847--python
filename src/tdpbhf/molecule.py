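"""Molecular input: XYZ parsing and the MoleculeSpec container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_PER_ANGSTROM, ELEMENT_Z


class XYZParseError(ValueError):
    """Raised for malformed XYZ input; the message names the offending line."""


@dataclass(frozen=True)
class MoleculeSpec:
    """A molecule: element symbols, nuclear charges and positions (bohr).

    ``n_electrons`` is fixed by the nuclear charges and the total charge and
    must be even: the model expands around a closed-shell reference
    determinant.
    """

    symbols: tuple[str, ...]
    charges: tuple[int, ...]
    coords: np.ndarray  # (n_atoms, 3), bohr
    total_charge: int = 0
    comment: str = ""
    n_electrons: int = field(init=False)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(self.symbols), 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "coords", coords)
        n_el = int(sum(self.charges)) - self.total_charge
        if n_el <= 0:
            raise ValueError(f"no electrons: sum(Z)={sum(self.charges)}, "
                             f"charge={self.total_charge}")
        if n_el % 2 != 0:
            raise ValueError(
                f"odd electron count {n_el}: a closed-shell reference is "
                "required")
        object.__setattr__(self, "n_electrons", n_el)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def nuclear_repulsion(self) -> float:
        e = 0.0
        for i in range(self.n_atoms):
            for j in range(i):
                r = np.linalg.norm(self.coords[i] - self.coords[j])
                e += self.charges[i] * self.charges[j] / r
        return e

    def nuclear_dipole(self) -> np.ndarray:
        """Sum_K Z_K R_K (a.u.)."""
        return np.einsum("k,kx->x", np.array(self.charges, float), self.coords)

    def translated(self, t) -> "MoleculeSpec":
        return MoleculeSpec(self.symbols, self.charges,
                            self.coords + np.asarray(t, float),
                            self.total_charge, self.comment)


def parse_xyz(text: str, total_charge: int = 0) -> MoleculeSpec:
    """Parse a standard XYZ string (count line, comment line, atoms in A).

    Coordinates are converted to bohr.  Raises :class:`XYZParseError` naming
    the offending line on malformed input.
    """
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise XYZParseError("line 1: missing atom-count line")
    try:
        n_atoms = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(f"line 1: malformed count line {lines[0]!r}")
    if n_atoms <= 0:
        raise XYZParseError(f"line 1: non-positive atom count {n_atoms}")
    if len(lines) < 2 + n_atoms:
        raise XYZParseError(
            f"expected {n_atoms} atom lines, file has {max(len(lines)-2, 0)}")
    comment = lines[1].strip() if len(lines) > 1 else ""
    symbols, charges, coords = [], [], []
    for k in range(n_atoms):
        ln_no = 3 + k
        parts = lines[2 + k].split()
        if len(parts) < 4:
            raise XYZParseError(f"line {ln_no}: expected 'El x y z', got "
                                f"{lines[2 + k]!r}")
        sym = parts[0].capitalize()
        if sym not in ELEMENT_Z:
            raise XYZParseError(f"line {ln_no}: unknown element {parts[0]!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise XYZParseError(
                f"line {ln_no}: non-numeric coordinate in {lines[2 + k]!r}")
        symbols.append(sym)
        charges.append(ELEMENT_Z[sym])
        coords.append(xyz)
    coords = np.asarray(coords) * BOHR_PER_ANGSTROM
    return MoleculeSpec(tuple(symbols), tuple(charges), coords,
                        total_charge, comment)
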