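"""Spectroscopic observables from the linear response solutions.

Polarizability tensors and dispersion curves, transition moments and
oscillator strengths (length gauge), Gaussian-broadened absorption spectra,
and Cauchy-moment fits of the low-frequency dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import HARTREE_TO_EV
from .response import (ExcitationResult, PropertyGradient, ResponseMatrices,
                       build_property_gradient, solve_linear_response)

OSC_PLOT_THRESHOLD = 0.01    # sticks below this are hidden in plots, kept in data


@dataclass
class PolarizabilityRecord:
    """α tensor (a.u.) at one frequency; isotropic average ᾱ = tr α / 3."""

    omega: float
    alpha: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, float)
        if not np.allclose(self.alpha, self.alpha.T, atol=1e-8):
            raise ValueError("polarizability tensor must be symmetric")

    @property
    def isotropic(self) -> float:
        return float(np.trace(self.alpha) / 3.0)


@dataclass
class SpectrumSticks:
    """Excitation energies (eV), oscillator strengths and transition moments."""

    energies_ev: np.ndarray
    strengths: np.ndarray
    moments: np.ndarray          # (n, 3) Cartesian transition dipoles (a.u.)

    def __post_init__(self):
        if not (len(self.energies_ev) == len(self.strengths)
                == len(self.moments)):
            raise ValueError("stick arrays must have matching lengths")
        if np.any(self.strengths < -1e-12):
            raise ValueError("oscillator strengths must be non-negative")

    @property
    def visible(self) -> np.ndarray:
        """Plot mask: f_osc >= 0.01 (data retains everything)."""
        return self.strengths >= OSC_PLOT_THRESHOLD


@dataclass
class CauchyFit:
    s_minus_2: float
    s_minus_4: float
    r_squared: float
    window: tuple

    def __post_init__(self):
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 out of range")


def dipole_gradients(mats: ResponseMatrices, dipole_mo: np.ndarray
                     ) -> list[PropertyGradient]:
    """Property gradients of the three electronic dipole components −r̂_c."""
    return [build_property_gradient(-dipole_mo[c], mats, label="xyz"[c])
            for c in range(3)]


def polarizability(mats: ResponseMatrices, grads, omega: float,
                   known_omegas: np.ndarray | None = None,
                   method: str = "iterative") -> PolarizabilityRecord:
    """α_γδ(ω) = −<<μ_γ; μ_δ>>_ω by contraction with the response vectors."""
    alpha = np.zeros((3, 3))
    xs = [solve_linear_response(mats, g, omega, method=method,
                                known_omegas=known_omegas) for g in grads]
    for c in range(3):
        for d in range(3):
            alpha[c, d] = grads[d].g @ xs[c]
    return PolarizabilityRecord(omega, 0.5 * (alpha + alpha.T))


def polarizability_sos(exc: ExcitationResult, grads, omega: float
                       ) -> PolarizabilityRecord:
    """Sum-over-states α(ω) = Σ_n 2 ω_n T_n T_nᵀ / (ω_n² − ω²).

    Exact identity against the linear-solve value when ``exc`` spans the
    complete excitation space.
    """
    T = transition_moments(exc, grads)
    alpha = np.zeros((3, 3))
    for k in range(exc.n_states):
        w = exc.omega[k]
        alpha += 2.0 * w * np.outer(T[k], T[k]) / (w * w - omega * omega)
    return PolarizabilityRecord(omega, alpha)


def transition_moments(exc: ExcitationResult, grads) -> np.ndarray:
    """T^{0→n}_γ = g^{μ_γ} · X_n for S[2]-normalized amplitudes."""
    X = exc.amplitude_vectors()
    return np.array([[float(grads[c].g @ X[k]) for c in range(3)]
                     for k in range(exc.n_states)])


def transition_properties(exc: ExcitationResult, grads) -> SpectrumSticks:
    """Oscillator strengths f_n = (2/3) ω_n Σ_γ |T_γ^{0→n}|² (length gauge)."""
    T = transition_moments(exc, grads)
    f = 2.0 / 3.0 * exc.omega * np.einsum("nc,nc->n", T, T)
    return SpectrumSticks(exc.omega * HARTREE_TO_EV, f, T)


def gaussian_broaden(sticks: SpectrumSticks, sigma_ev: float = 0.1,
                     grid: np.ndarray | None = None):
    """Broadened absorption curve: each stick becomes a unit-area Gaussian
    scaled by its oscillator strength.

    Returns (grid_ev, curve).  Default grid 0–15 eV in 0.005 eV steps.
    """
    if sigma_ev <= 0:
        raise ValueError("sigma_ev must be positive")
    if grid is None:
        grid = np.arange(0.0, 15.0 + 1e-12, 0.005)
    grid = np.asarray(grid, float)
    curve = np.zeros_like(grid)
    pref = 1.0 / (sigma_ev * np.sqrt(2.0 * np.pi))
    for e, f in zip(sticks.energies_ev, sticks.strengths):
        curve += f * pref * np.exp(-0.5 * ((grid - e) / sigma_ev) ** 2)
    return grid, curve


def frequency_grid(omega_res: float, step: float = 0.01) -> np.ndarray:
    """ω = k·step for k = 0..k_max with k_max the greatest integer such that
    ω ≤ ω_res (the first resonance)."""
    k_max = int(np.floor(omega_res / step + 1e-12))
    return step * np.arange(0, k_max + 1)


def dispersion_scan(mats: ResponseMatrices, grads,
                    exc: ExcitationResult, step: float = 0.01,
                    method: str = "iterative") -> list[PolarizabilityRecord]:
    """ᾱ(ω) on the uniform grid up to the first resonance."""
    omega_res = float(exc.omega[0])
    records = []
    for w in frequency_grid(omega_res, step):
        try:
            records.append(polarizability(mats, grads, w,
                                          known_omegas=exc.omega,
                                          method=method))
        except Exception:
            if w == 0.0:
                raise
            break   # grid point collided with the resonance; stop the scan
    return records


def finite_field_polarizability(ints, coupling, active, n_occ,
                                gamma: np.ndarray | None = None,
                                field: float = 1e-3) -> np.ndarray:
    """Static α by central-difference dipole derivative of the optimized
    state.

    The occupation angles are held at ``gamma`` (the zero-field optimum;
    zeros if omitted) while the orbitals relax in the field, consistent
    with the frozen-angle response treatment.  Independent of the response
    machinery: uses only the ground-state optimizer.
    """
    from .ground import optimize_pbhf
    from .scf import MOIntegrals

    n = ints.n_mo
    if gamma is None:
        gamma = np.zeros(n)
    alpha = np.zeros((3, 3))
    for d in range(3):
        mus = []
        for sgn in (+1.0, -1.0):
            # H(F) = H - F·μ̂ with μ̂ = -r̂, i.e. h -> h + F r_d
            hp = ints.h + sgn * field * ints.dipole_mo[d]
            pert = MOIntegrals(hp, ints.g, ints.dipole_mo,
                               ints.nuclear_repulsion, ints.nuclear_dipole)
            st = optimize_pbhf(pert, coupling, active, n_occ,
                               fixed_gamma=gamma, warn_overlap=False)
            mus.append(np.array([-np.einsum("pq,pq", st.density,
                                            ints.dipole_mo[c])
                                 for c in range(3)]))
        alpha[:, d] = (mus[0] - mus[1]) / (2.0 * field)
    return 0.5 * (alpha + alpha.T)


def fit_cauchy_moments(records: list[PolarizabilityRecord],
                       omega_res: float | None = None,
                       window: tuple | None = None) -> CauchyFit:
    """Two-term even-power fit ᾱ(ω) ≈ S(−2) + ω² S(−4).

    The fit window defaults to the lower half of the first transition
    region, ω ∈ [0, ω_res/2].  Requires at least three points.
    """
    if window is None:
        if omega_res is None:
            raise ValueError("either omega_res or an explicit window needed")
        window = (0.0, omega_res / 2.0)
    pts = [(r.omega, r.isotropic) for r in records
           if window[0] - 1e-12 <= r.omega <= window[1] + 1e-12]
    if len(pts) < 3:
        raise ValueError(
            f"need >= 3 dispersion points in window {window}, got {len(pts)}")
    w = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    X = np.vstack([np.ones_like(w), w * w]).T
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CauchyFit(float(coef[0]), float(coef[1]),
                     float(min(max(r2, 0.0), 1.0)), window)
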