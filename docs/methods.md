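# Methods

## Model

A molecule in weak noncovalent contact with an electron reservoir is
described by an effective Hamiltonian Ĥ = Ĥ_mol + Ĥ_pb, where Ĥ_mol is the
standard molecular electronic Hamiltonian in second quantization (real
orbitals, singlet excitation operators E_pq, chemists'-notation
two-electron integrals) and

    Ĥ_pb = Σ_p λ_p (Q̂†_pp + Q̂_pp),   Q̂†_pp = a†_p↑ a†_p↓

creates/annihilates closed-shell pairs in molecular orbital p.  Ĥ_pb does
not commute with N̂ = Σ_p E_pp, so the variational state must mix particle
numbers.  The ansatz is

    |Ψ(γ, κ)⟩ = exp(κ̂) exp(γ̂) |Φ⟩,
    γ̂ = Σ_p γ_p (Q̂†_pp − Q̂_pp),   κ̂ = Σ_{p>q} κ_pq (E_pq − E_qp),

expanded around the closed-shell RHF determinant |Φ⟩, the dominant
configuration for physical couplings (λ ~ 1e-4–1e-1 a.u.).

### Conventions fixed by the limits

The generator γ̂ rotates each spatial orbital in the two-dimensional space
spanned by its empty and doubly-occupied configurations.  With
s_p = +1 for reference-occupied and −1 for reference-virtual orbitals the
angle state is the orbital product with

    D_pp = 1 + s_p cos 2γ_p   (so D_ii = 2cos²γ_i, D_aa = 2sin²γ_a),
    T_pp = ⟨a†_p↑ a†_p↓⟩ = −½ s_p sin 2γ_p,
    ⟨Φ|Ψ⟩ = Π_p cos γ_p,      δN = tr D − N₀.

These conventions are pinned by three exact limits, each verified in the
oracle: the HF state at γ = 0, the quasi-particle (HFB-type) vacuum when
every occupied angle is shifted by π/2 (the transformed annihilators kill
that state — the killer condition), and the cos²/sin² occupancy rule.
The sign of T is a convention; only λ·T products are observable and the
optimizer picks the energy-lowering branch.

### Energy functional

The angle state is a Gaussian (HFB-type) state, so Wick's theorem gives a
closed-form energy in the normal density D and pairing density T:

    E[D, T] = Σ h_pq D_pq + ½ Σ g_pqrs [D_pq D_rs − ½ D_ps D_rq]
              + Σ g_pqrs T_pr T_sq + 2 tr(Λ T) + V_nn,

with Λ the pairing-field matrix (diag(λ_p) in the reference basis; a
general symmetric matrix after orbital rotation).  The generalized Fock
matrix F = ∂E/∂D (not diagonal away from the canonical density) and the
pairing-exchange matrix K_pq = Σ (pr|qs) T_rs drive the gradients.
Orbital rotation is handled exactly through R = exp(κ), with analytic
κ-gradients via the adjoint Fréchet derivative of the matrix exponential
(`scipy.linalg.expm_frechet`).

### Ground-state optimization

BFGS on the concatenated (γ_active, κ_nonredundant) vector from the HF
point (γ = κ = 0), followed by a Newton polish using a finite-difference
Hessian of the analytic gradient (step 1e-6).  Convergence demands a
parameter-gradient max-norm ≤ 1e-8 (typically 1e-13 is reached);
non-convergence raises with the iterate trajectory attached.  The
occupancy bounds 0 ≤ D_pp ≤ 2 hold at every iterate by construction of the
cos²/sin² parametrization.  Non-redundant κ pairs are selected statically:
occupied–virtual always, plus occupied–occupied/virtual–virtual pairs with
at least one active member; inactive-block rotations have identically zero
gradient and curvature and are excluded.  An analytic-vs-central-difference
gradient check (step 1e-5) runs in the test suite.

## Linear response

Only the orbitals carry time dependence (local excitations; the angles are
frozen).  In the optimized-orbital basis — the rotation κ* absorbed into
the integrals so the state is the pure angle product — the response space
is the set of rotation pairs μ = (p, q) with excitation operator
q†_μ = E_pq.  The paired Hessian/metric blocks are symmetrized
(double-)commutator expectations over |Ψ⟩:

    A_μν = ½⟨[q_μ,[Ĥ,q†_ν]] + [[q_μ,Ĥ],q†_ν]⟩,
    B_μν = −½⟨[q_μ,[Ĥ,q_ν]] + [[q_μ,Ĥ],q_ν]⟩,
    Σ_μν = ⟨[q_μ, q†_ν]⟩ = δ_μν (D_qq − D_pp),   Δ_μν = ⟨[q_μ, q_ν]⟩ = 0.

The B-block sign follows the quasi-energy Hessian convention; it is fixed
operationally by requiring the static limit to reproduce finite-field
(CPHF) polarizabilities.  Evaluation uses Wick's theorem with the diagonal
D, T: every element reduces to contractions of the two-electron integrals
with the exact ⟨e_pqrs⟩ tensor of the product state plus one-electron and
pairing-field terms.  No element formula is trusted on paper: the
acceptance suite compares each A/B/Σ/Δ/property-gradient element against
the exact Fock-space commutator expectation on hundreds of random
(γ, κ, λ) draws at 1e-10.

Pairs are oriented so Σ_μμ > 0; metric-null directions (|Σ| < 1e-10, e.g.
occupied–occupied rotations at λ = 0, or degenerate fractional occupancies)
are redundant and projected out.  At λ = 0 this leaves exactly the
occupied–virtual TDHF space, with A/B equal to the textbook singlet TDHF
matrices (times the metric normalization 2).

Two eigenvalue routes are implemented and must agree to 1e-9: the dense
generalized eigenproblem on the full paired matrices, and the
halved-dimension symmetric form
V^{-1/2}(A−B)^{1/2}(A+B)(A−B)^{1/2}V^{-1/2}-style product with the
diagonal metric V = Σ, which requires the (A−B) kernel positive definite
(violation raises a reference-instability diagnostic).  Near-degenerate
occupancy pairs (Σ ~ 1e-7) can make the scaled kernel numerically
indefinite; such systems are solved with the direct route.

The standard response equation (E[2] − ω S[2])X = g is solved either
densely or with a paired-trial-vector subspace iteration (diagonal
preconditioner diag(E[2]) − ω diag(S[2]), residual tolerance 1e-6·‖g‖,
stagnation guard).  Frequencies within 1e-4 a.u. of an excitation energy
are refused with a resonance error naming the offending pole.

## Properties

Property gradients for a one-electron operator B̂ carry
b_μ = (D_qq − D_pp) B_pq in both paired components.  Then

  * α_γδ(ω) = −⟨⟨μ_γ; μ_δ⟩⟩_ω = g_γᵀ X_δ(ω); tensor symmetrized, isotropic
    average tr α/3; α(ω) = α(−ω) by construction.
  * Transition dipoles T^{0→n} = gᵀX_n for S[2]-normalized amplitudes;
    residue analysis makes the sum-over-states rebuild
    α = Σ 2ω_n T_nT_nᵀ/(ω_n²−ω²) an exact identity in a complete
    excitation space (asserted to 1e-8).
  * Oscillator strengths in length gauge only: f = ⅔ ω Σ_γ |T_γ|².
  * Spectra: each stick broadened by a unit-area Gaussian (σ = 0.1 eV
    default) scaled by f; default grid 0–15 eV at 0.005 eV.  Sticks with
    f < 0.01 are flagged invisible for plotting but kept in the data.
  * Dispersion: ω = k·0.01 a.u. up to the greatest multiple ≤ ω_res.
  * Cauchy moments: two-term even-power least squares
    ᾱ(ω) ≈ S(−2) + ω²S(−4) in the lower half of the first transition
    region, implemented as ω ∈ [0, ω_res/2]; R² is reported.
  * The finite-field cross-check of the static α freezes the occupation
    angles at their zero-field optimum and relaxes only the orbitals
    (field 1e-3 a.u., central differences) — the derivative consistent
    with the frozen-angle response; letting the angles relax would probe a
    different susceptibility.

## The Fock-space oracle

`tdpbhf.oracle` enumerates the full 4ⁿ-dimensional Fock space for n ≤ 5
spatial orbitals with Jordan–Wigner phases (spin-orbital order: up before
down within each orbital).  Creation/annihilation matrices satisfy the
anticommutation relations exactly; model states are built with dense
matrix exponentials of the generator matrices.  Every closed-form quantity
in the package — energies, densities, pairing amplitudes, overlaps,
response elements, transition moments — has a corresponding exact
evaluation here, and `tdpbhf.verify` drives randomized certification over
2–4-orbital systems (mixed system sizes keep the run under a minute).

## Fixtures and what they show

Bundled systems: H2 (1.4 bohr), LiH (3.015 bohr), water — all STO-3G via
the built-in McMurchie–Davidson engine (validated against the classic
printed H2 integral and energy values, and water/LiH total energies) — and
a synthetic 4-orbital integral set.  The synthetic system is designed to
emulate the regime where environmental pair fluctuations redshift low
excitations: a compact valence-occupied orbital, a *diffuse* low virtual
that hosts the lowest transition (small self-repulsion, as augmented basis
sets produce), and a compact higher virtual carrying the coupling, whose
Coulomb repulsion with the hole orbital exceeds that with the diffuse
virtual.  Pair fluctuations into the coupled virtual then stabilize the
excited state more than the ground state and the lowest transition moves
down monotonically along the λ schedule, while δN > 0 (the environment
donates density).  On compact minimal-basis toys (H2, LiH, water with
uniform coupling) the same physics produces a *blueshift* — the shift
direction is system-dependent, set by the balance of the coupled orbital's
self-repulsion against its repulsion with the hole density; exact
diagonalization on 2-orbital models confirms the blueshift there is real,
not an artifact.  Passing the qualitative redshift test on the synthetic
fixture therefore demonstrates the mechanism, not a universal direction.

The fixtures are tiny and noiseless; they probe exactness of the
implementation (oracle equivalence, route agreement, identities), not
basis-set or correlation effects in real chromophores.

## Known limitations

  * Restricted (closed-shell) reference only; no unrestricted variant.
  * Particle-conserving environment couplings (embedding/fluctuating
    charge) are out of scope.
  * No damped (complex) response; frequencies at resonance are refused
    rather than broadened.
  * The integral engine covers s/p shells (STO-3G registry for H, Li, C,
    N, O); heavier elements or d-functions need a different backend behind
    the same adapter.
  * The oracle scales as 4ⁿ and is capped at five spatial orbitals.
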