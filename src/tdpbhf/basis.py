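"""Built-in basis-set registry.

STO-3G for H, Li, C, N, O (standard Hehre-Stewart-Pople parametrization;
exponents already include the atomic scale factors).  Each shell is stored as
(angular momentum letter, exponents, coefficients); SP shells are split into
an S and a P entry sharing exponents.
"""

from __future__ import annotations

import numpy as np

from .gaussian import BasisFunction

# Universal STO-3G contraction coefficients
_C_1S = [0.15432897, 0.53532814, 0.44463454]
_C_2S = [-0.09996723, 0.39951283, 0.70011547]
_C_2P = [0.15591627, 0.60768372, 0.39195739]

STO3G = {
    "H": [("S", [3.42525091, 0.62391373, 0.16885540], _C_1S)],
    "Li": [("S", [16.1195750, 2.9362007, 0.7946505], _C_1S),
           ("S", [0.6362897, 0.1478601, 0.0480887], _C_2S),
           ("P", [0.6362897, 0.1478601, 0.0480887], _C_2P)],
    "C": [("S", [71.6168370, 13.0450960, 3.5305122], _C_1S),
          ("S", [2.9412494, 0.6834831, 0.2222899], _C_2S),
          ("P", [2.9412494, 0.6834831, 0.2222899], _C_2P)],
    "N": [("S", [99.1061690, 18.0523120, 4.8856602], _C_1S),
          ("S", [3.7804559, 0.8784966, 0.2857144], _C_2S),
          ("P", [3.7804559, 0.8784966, 0.2857144], _C_2P)],
    "O": [("S", [130.7093200, 23.8088610, 6.4436083], _C_1S),
          ("S", [5.0331513, 1.1695961, 0.3803890], _C_2S),
          ("P", [5.0331513, 1.1695961, 0.3803890], _C_2P)],
}

REGISTRY = {"sto-3g": STO3G}

_P_POWERS = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]


class BasisResolutionError(KeyError):
    """Basis name or element not covered by the built-in registry."""


def build_basis(molecule, basis: str | dict) -> list[BasisFunction]:
    """Expand a basis name (or per-element name mapping) into functions.

    ``basis`` may be a single registry name applied to all elements, or a
    mapping ``{element_symbol: name}`` (heavy/H splits as used for the
    double-zeta protocols).
    """
    bfs: list[BasisFunction] = []
    for sym, center in zip(molecule.symbols, molecule.coords):
        name = basis[sym] if isinstance(basis, dict) else basis
        key = name.lower()
        if key not in REGISTRY:
            raise BasisResolutionError(
                f"unknown basis {name!r}; available: {sorted(REGISTRY)}")
        table = REGISTRY[key]
        if sym not in table:
            raise BasisResolutionError(
                f"basis {name!r} has no parameters for element {sym!r}")
        for (ltr, exps, coefs) in table[sym]:
            if ltr == "S":
                bfs.append(BasisFunction(center, (0, 0, 0),
                                         np.array(exps), np.array(coefs)))
            elif ltr == "P":
                for pw in _P_POWERS:
                    bfs.append(BasisFunction(center, pw,
                                             np.array(exps), np.array(coefs)))
            else:  # pragma: no cover - registry only holds S/P
                raise BasisResolutionError(f"unsupported shell type {ltr}")
    return bfs
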