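# Methods

This note records the model implemented by `nonaffine`, the numerical
and design choices behind it, what the synthetic generators do and do
not emulate, and the known limitations.

## Model

All analysis is relative to a fixed reference {**R**ᵢ} (by default the
first model of the input PDB, i.e. a crystal/native structure; a
time-averaged reference can be supplied by writing it to a PDB first —
the choice is recorded in the structure metadata). For each analysed
atom *i*, a neighborhood Ωᵢ collects the heavy atoms strictly within a
radius of *i* in the reference, excluding *i* itself. Displacements are
taken relative to the center, Δᵢⱼ = uⱼ − uᵢ, which makes every result
exactly invariant under global translations; global rotations are
affine maps and are removed by the projection, so no superposition of
frames is needed or performed.

The non-affine parameter is the residual of the best single linear
deformation D of the neighborhood,

χᵢ = min_D Σⱼ [Δᵢⱼ − D(Rⱼ−Rᵢ)]² = ΔᵀPΔ,  P = I − R(RᵀR)⁻¹Rᵀ,

with D an unconstrained real 3×3 matrix (strains, shears and rotations
alike; in the Δ convention the fitted D equals the deformation minus the
identity). χ carries units of Å² and is reported as the unnormalized
neighborhood sum by default; a `per_atom` flag divides by n_Ω, which is
the right scale whenever sites with different neighborhood sizes are
compared against each other (hotspot ranking, gap–susceptibility
correlation).

Ensemble observables: the local correlator C = ⟨ΔΔᵀ⟩ over frames,
spectra of PCP (eigenvalues λ_μ, Σλ_μ = ⟨χ⟩ exactly when C is built
about the reference without mean subtraction), the normalized gap
Γ = 1 − λ₂/λ₁, the per-site susceptibility ⟨(χ−⟨χ⟩)²⟩ with the
population (1/T) convention, residue-level χ as the mean over a
residue's heavy-atom χ series, and the residue–residue same-time
covariance map.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| neighborhood radius | calibrated | Å; smallest 0.1 Å-grid radius whose median heavy-atom neighborhood size lands in `target_n` |
| `target_n` | (50, 100) | heavy atoms per neighborhood: small enough to stay local, large enough to average single-atom noise |
| `min_size` | 10 | below this the affine fit is meaningless; the site is excluded and reported, never silently dropped |
| `max_condition` | 1e8 | condition-number cut on RᵀR; worse geometry raises a collinearity error and excludes the site |
| `threshold_fraction` | 0.04 | correlation-map cut as a fraction of the **off-diagonal** maximum (the diagonal susceptibilities would otherwise dominate the scale; using the full-matrix maximum is the flagged alternative) |
| `min_seq_sep` | 10 residues | "spatially far" filter: sequence-adjacent residues are trivially correlated through bonding |
| `min_distance` | 12 Å | same filter in space, on reference Cα positions (heavy-atom centroid where no Cα exists) |
| `mean_subtract` | off | subtracting the mean Δ breaks the exact trace identity; enable only for drifted ensembles |

## Numerical choices

- P is built from a reduced QR factorization of R (orthonormal affine
  basis Q, P = I − QQᵀ) and symmetrized; rank deficiency of R raises an
  error rather than falling back to a pseudo-inverse silently.
- Per-frame χ over long ensembles uses χ = ‖Δ‖² − ‖QᵀΔ‖², algebraically
  identical to ΔᵀPΔ at O(n_Ω·d²) per frame instead of O((n_Ω·d)²); the
  equality is tested to relative 1e-10.
- `chi_direct` solves the normal equations (RᵀR)vec(D) = RᵀΔ explicitly
  and is kept as the independent oracle for the projection route.
- Eigen-decompositions sort descending and fix each eigenvector's sign
  so its largest-magnitude component is positive; a top pair closer than
  1e-6 relative is flagged degenerate (the dominant mode is then only
  defined up to a rotation in the degenerate plane).
- Tiny negative χ or eigenvalues from round-off are clamped to zero;
  significantly negative values raise.
- The Marchenko–Pastur fit is moment-matched (σ² = mean eigenvalue of
  the non-affine block, q = (n_Ω·d − d²)/T), not maximum-likelihood:
  deterministic and parameter-free, which suffices for a null
  comparison. With q ≥ 1 the point mass at zero is included and a
  warning recorded. The KS distance integrates the MP density on a
  4096-point grid (renormalized, so discretization error is nulled at
  the support edges).
- The gap of an all-zero spectrum is defined as 0, of a rank-1 spectrum
  as 1; an all-equal susceptibility vector maps to hotspot scale 0.

## Synthetic generators

The `synthetic` module is the package's test bed and defines its study
conditions; every generator is bit-reproducible from its seed.

- **Geometries.** `lattice` (closed-form neighbor counts), `cloud`
  (uniform at ~0.1 heavy atoms/Å³, protein-like density), and `helix` —
  a helical chain of 8-atom pseudo-residues (2.3 Å radius, 1.5 Å rise,
  100° twist, 1.2 Å side-chain jitter) whose local density is
  protein-like and whose sequence order tracks spatial order, which is
  what residue-level correlation and allostery analyses need.
- **Planted modes** are random vectors projected into a site's
  non-affine subspace and normalized (optionally supported on one
  residue's atoms to localize them). Amplitudes are specified as the
  per-atom RMS displacement of the mode, so "10:1 over noise" means
  each member atom moves ten times as far along the mode as the noise
  moves it, independent of neighborhood size. With the shared-center
  convention Δᵢⱼ = uⱼ − uᵢ, isotropic noise creates three
  quasi-translation modes of eigenvalue ≈ n_Ω σ², which this
  convention's planted eigenvalue (ratio² · n_Ω σ²) cleanly dominates.
- **Graded softness** plants one mode per site with geometrically
  (log-uniform) graded amplitudes, rms 1.5–15 × noise over 22 sites,
  T = 400. Log-uniform grading reflects the multiplicative scale on
  which local compliance varies and keeps adjacent sites equally
  separated in both the gap and the susceptibility ranking; linear
  grading crowds the soft end where Γ ≈ 1 − 1/r² saturates.
- **Conjugate-field ensembles** sample Δ from the Gaussian with energy
  ½σ⁻²‖Δ‖² − hΔᵀPΔ: variance σ² in the affine block and σ²/(1−2hσ²)
  along each of the n_Ω·d − 9 non-affine directions, hence
  ⟨χ⟩(h) = (n_Ω·d−9)·σ²/(1−2hσ²) in closed form and a stability bound
  h < 1/(2σ²). The fluctuation–response check uses a central finite
  difference at h = ±0.02 with common random numbers across field
  strengths: the one-sided difference carries an O(h) bias (the exact
  slope is Var₀/(1−2hσ²)) that a central difference reduces to O(h²),
  and shared draws cancel most of the Monte-Carlo error in the
  difference.

What the generators do **not** emulate: bonded connectivity and
excluded volume, solvent, anisotropic thermal motion, realistic
force-field energetics, or the slow conformational kinetics of real
proteins. Passing tests therefore demonstrate the correctness and
sensitivity of the estimator — exact affine annihilation, spectral
identities, recovery of planted structure above noise — not that any
particular real protein's hotspots will be found at a given simulation
length.

## Problem sizes

The bundled checks run on helical chains of 40–230 pseudo-residues
(320–1840 atoms), 120–500 frames for spectral quantities, 4000 frames
for the fluctuation–response estimate, and a 150-dimensional Wishart
ensemble of 600 frames for the Marchenko–Pastur null; together they
complete in a few seconds on one CPU.

## Known limitations

- Neighborhoods are reference-fixed; atoms that exchange neighbors
  during very large rearrangements are still compared against the
  original Ωᵢ (by design — χ measures departure from the reference).
- No periodic-boundary handling: the input must be a whole molecule.
- The correlation-map threshold is the fixed-fraction rule (4% of the
  off-diagonal maximum); no statistical significance is attached to
  pairs.
- mmCIF input and trajectory formats beyond multi-model PDB and
  XTC/TRR/DCD are not supported.
- Constrained deformations (e.g. symmetric, rotation-free D) and
  distance-weighted neighbors are out of scope.
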