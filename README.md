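# tdpbhf

Mean-field electronic structure for **electronically open molecules**:
molecules that exchange electrons with their surroundings through weak,
noncovalent contact (solvent shells, physisorbing surfaces).  The package
implements the particle-breaking Hartree–Fock (PBHF) ground state and its
frequency-domain linear response (TDPBHF), giving excitation energies,
oscillator strengths, Gaussian-broadened absorption spectra and
frequency-dependent electric dipole polarizabilities, together with an
exact Fock-space oracle used to certify every working equation.

## The model

The environment enters through an effective pairing Hamiltonian

    Ĥ = Ĥ_mol + Σ_p λ_p (Q̂†_pp + Q̂_pp),     Q̂†_pp = a†_p↑ a†_p↓,

which creates and annihilates closed-shell electron pairs in molecular
orbital p with empirical strength λ_p ≥ 0 (physically ~1e-4–1e-1 a.u. for
noncovalent contact).  Because Ĥ does not commute with the number operator
N̂, the ground state mixes determinants with different electron counts:

    |Ψ⟩ = exp(κ̂) exp(γ̂) |Φ⟩,     γ̂ = Σ_p γ_p (Q̂†_pp − Q̂_pp),

where |Φ⟩ is the closed-shell N₀-electron RHF determinant, γ_p are
occupation angles and κ̂ is a real orbital rotation.  The angle unitary is
a Bogoliubov transformation: orbital occupancies become 2cos²γ_i
(occupied) and 2sin²γ_a (virtual), the pairing density
T_pp = ⟨a†_p↑a†_p↓⟩ = ∓½ sin 2γ_p turns on, and the HF character
⟨Φ|Ψ⟩ = Π_p cos γ_p decreases as the molecule opens.  Two diagnostics
summarize the openness: the HF overlap and the fractional charge
δN = tr D − N₀.

Linear response keeps the angles frozen (local excitations only) and lets
the orbitals carry the time dependence.  Over the non-redundant rotation
pairs the paired eigenproblem

    E[2] X_n = ω_n S[2] X_n,   E[2] = [[A, B], [B, A]],  S[2] = diag(Σ, −Σ)

delivers transition frequencies and amplitudes; the metric Σ is diagonal
(Σ_μμ = D_qq − D_pp), so the Casida-style halved-dimension reformulation
applies.  Transition dipoles follow from the property gradients, oscillator
strengths in length gauge as f = ⅔ ω |T|², and the dipole polarizability as
α_γδ(ω) = −⟨⟨μ_γ; μ_δ⟩⟩_ω.  At λ = 0 everything reduces to restricted HF
and textbook TDHF/RPA.

All matrix elements are derived with Wick's theorem over the angle-product
state and certified against an exact 4ⁿ-dimensional Fock-space
representation (`tdpbhf.oracle`) to 1e-10 on randomly sampled states.

## Worked example

Ground-state scan of LiH over a coupling schedule (energy in hartree):

    $ tdpbhf ground --fixture lih --lambdas 0,0.02,0.05,0.1 -o out
    0 -7.862007562742 1.000000000000 0.000000000000 8.654e-14
    0.02 -7.864159770029 0.998474888346 0.004907675570 1.837e-14
    0.05 -7.875352431557 0.990773694162 0.029324451263 5.293e-10
    0.1 -7.914081981926 0.966462517357 0.102209418853 2.206e-10

Columns: λ (a.u.), PBHF energy, HF overlap, fractional charge δN, final
gradient norm.  The energy drops quadratically in λ (the pairing field has
no first-order expectation), the HF character decays monotonically, and
δN > 0 here: the environment donates electron density into the active
virtual orbitals.

Absorption sticks for water (minimal basis):

    $ tdpbhf spectrum --fixture h2o_min --lambdas 0,0.1 --n-states 5 -o out
    lambda=0: 5 states, lowest 13.1459 eV
    lambda=0.1: 5 states, lowest 13.4472 eV

Dispersion and Cauchy moments of the bundled synthetic 4-orbital system
(S(−2) approximates the static isotropic polarizability; S(−4) grows with
the coupling):

    $ tdpbhf dispersion --fixture synthetic_orbitals --lambdas 0,0.05,0.1 -o out
    lambda=0: S(-2)=5.0276 S(-4)=50.2344 R2=0.995717
    lambda=0.05: S(-2)=5.0269 S(-4)=50.3292 R2=0.995696
    lambda=0.1: S(-2)=5.0250 S(-4)=50.6171 R2=0.995631

`tdpbhf oracle-check` certifies the closed-form builders against the exact
Fock-space oracle on random systems and prints the worst deviations.

## Layout

    src/tdpbhf/
      molecule.py     XYZ parsing, MoleculeSpec
      gaussian.py     McMurchie-Davidson integrals
      basis.py        STO-3G registry
      integrals.py    AOIntegrals adapter
      scf.py          RHF reference, MO integrals, active-space window
      ground.py       PBHF densities, energy, optimizer
      oracle.py       exact Fock-space representation (certification)
      verify.py       random oracle-certification driver
      response.py     E[2]/S[2]/property gradients, eigen + linear solvers
      tdhf.py         independent textbook TDHF/RPA + CPHF reference
      properties.py   polarizabilities, spectra, Cauchy fits
      fixtures.py     bundled toy systems
      cli.py          command-line front end

See `docs/methods.md` for the derivation conventions, parameter choices
and known limitations.
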