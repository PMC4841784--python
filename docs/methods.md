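# Methods

## Scope and model

`premelt` implements the analysis machinery for pre-melting effects at the
solid-ordered / liquid-disordered transition of a lipid bilayer: local
bond-orientational order, coarse-grained order-density fields, level-set
interfaces, capillary-wave spectra and stiffness fits, radial order
profiles, and interfacial energetics.  Molecular dynamics is out of scope;
the synthetic generators reproduce the *statistical* structure the
analysis consumes, with exact ground truth.

## Bond-orientational order

`compute_phi` evaluates phi_l = |(1/6) Σ_{j∈nn(l)} e^{6iθ_lj}|² over the
six nearest neighbors by minimum-image distance.  The paperless details we
had to fix ourselves:

- **Tie-break.** Neighbor sets use (distance, particle index) ordering, so
  exact distance ties resolve deterministically by ascending index.
- **Reference axis.** Angles are measured from the box x-axis; phi is
  rotationally invariant, so the choice is immaterial (verified to 1e-12
  by property test).
- phi requires N ≥ 7; mixed periodic/open boxes are not supported.

## Coarse-graining

The order density φ(r) = Σ_l phi_l δ(r−r_l) (and the number density with
unit weights) is smoothed with the Gaussian kernel of width ξ, truncated
and shifted to zero at 3ξ:

    K(r) = (1/2πξ²)[e^{−r²/2ξ²} − e^{−9/2}],  r < 3ξ.

The kernel is **not** renormalized by default: its mass is
1 − (11/2)e^{−9/2} ≈ 0.93890, so the box integral of the density field is
0.93890·N.  A `renormalize=True` flag divides by that factor.  Fields live
on a uniform periodic grid; the requested spacing (default Δ = 0.25 nm) is
rounded to divide the box exactly, Δ > ξ/2 is an error and Δ > ξ/4 warns.
Values between nodes use bilinear interpolation.

`estimate_xi` implements the width criterion: the distance at which the
normalized spatial covariance of phi in an ordered-phase sample decays to
1/10, found by linear interpolation between distance bins (bin width
0.2 nm by default; the binning/interpolation rule is our choice).  A
single frame's covariance estimate is noisy when the correlation length is
not far below the box size, so the estimator accepts a stack of phi
realizations sharing one configuration and averages the covariance — the
frame-averaged form one would use on a trajectory.  The package default is
ξ = 1.5 nm; the extracted interface is insensitive to ξ across 1–2 nm
(verified: the slab interface position moves by < 0.03 nm across
ξ ∈ {1, 1.5, 2} nm, well under one grid spacing).

## Bulk levels and the interface level set

The interface is the marching-squares contour of φ̄ at (φ_d + φ_o)/2 with
linear edge interpolation (scikit-image, `fully_connected='low'`; this
fixed saddle-cell convention is deterministic, which is what matters for
reproducibility).  The grid is padded by one wrapped row/column and the
resulting open segments are stitched across the periodic seam by matching
endpoints modulo the box; stitched curves are classified closed (zero net
image shift) or spanning (one box image along an axis).  Curves shorter
than 6 vertices are discarded as short-lived bubbles of disorder
(configurable).

Bulk levels φ_d, φ_o default to the values of the coarse-grained DPPC
membrane at 294 K (0.4 and 2.15 nm⁻²) but are model-dependent; synthetic
pipelines calibrate them from one pure sample of each phase, using the
identity that the box-mean of the coarse-grained field is the kernel mass
times the summed weight per area.

**Known bias.** On the synthetic slab the extracted boundary sits about
half a lattice spacing (~0.25 nm) inside the ordered strip: lattice
particles at a sharp construction boundary have disrupted neighbor shells
and hence depressed phi.  The offset is uniform along the boundary, so it
cancels in fluctuation spectra; absolute positions are accurate to one
lattice spacing.

## Height and radius reduction

`height_function` bins a spanning curve's vertices by the coordinate along
the spanning axis and averages the transverse coordinate per bin;
overhangs are thereby folded to a single-valued h(x), with the vertex
count of repeat bin visits recorded (`n_overhang_points`) so the effect is
auditable.  Transverse coordinates are unwrapped to the branch nearest
their circular mean before averaging.  Empty bins are filled by periodic
linear interpolation and counted.  `radius_function` does the same in
polar angle about a supplied center — by default the inclusion center, not
the curve centroid — after checking that the winding number about the
center is ±1.

## Spectra and stiffness

The DFT convention is δh(x) = Σ_k δh_k e^{ikx} (forward transform divided
by the grid size); the per-frame mean is subtracted, ±m modes are pooled
and m = 0 excluded.  Standard errors are frame-to-frame; frames are
independent for all generators here, so no block averaging is applied by
default.  `fit_stiffness` fits A_k·k² — constant under capillary theory —
by weighted least squares over modes with k < k_max and inverts the
constant to γ with a propagated standard error.  The default
k_max = 0.8 nm⁻¹ reflects where interface fluctuations in the membrane
system deviate from the small-k law.  Anisotropy of γ with respect to the
lattice orientation is ignored.

**Coarse-graining deconvolution.** Heights extracted from a ξ-smoothed
field are low-pass filtered: mode amplitudes are attenuated by ≈e^{−k²ξ²}.
Passing `xi` to `fit_stiffness` multiplies amplitudes by e^{+k²ξ²} before
fitting.  The point-cloud pipelines enable this by default; spectra of raw
height samples (no field in the loop) must not use it.

## Synthetic generators

All generators take a mandatory seed and use private `numpy` Generator
streams; identical inputs give bit-identical outputs.

- **Hexagonal** (`gen_hexagonal`): triangular lattice with iid Gaussian
  jitter; the box is adjusted to the nearest commensurate size and both
  sizes recorded.  Defaults a = 0.52 nm (two tail beads per lipid at the
  ordered-phase area per lipid) and jitter σ = 0.05a.
- **Disordered** (`gen_disordered`): random sequential addition with hard
  minimum distance r_min = 0.4 nm at ρ₀ = 3.3 nm⁻² (the disordered-phase
  tail-end density is not a published number; it is exposed as a free
  preset).  RSA is *not* equilibrium liquid sampling: it reproduces
  packing disorder, which is what phi statistics depend on, but its pair
  correlations are slightly weaker than a liquid's; the r_min exclusion
  raises mean phi above 1/6 (≈0.19 at the presets), as short-range order
  should.
- **Slab** (`gen_slab`): a centered hexagonal strip between two vertical
  boundaries, disordered elsewhere; boundaries are sharp in construction
  (interfacial smoothness arises only from coarse-graining) and recorded
  as ground truth, optionally displaced by periodic height profiles.
- **Inclusion** (`gen_inclusion`): excluded disk of radius R, disordered
  annulus to the halo radius R₀ (optionally perturbed per angle),
  hexagonal beyond.
- **Capillary samples** (`gen_capillary_flat`, `gen_capillary_circle`):
  Fourier modes drawn as complex Gaussians with the theoretical variances,
  Hermitian symmetry enforced, m = 0 (and the flat Nyquist mode) empty.
- **Bilayer** (`gen_bilayer3d`): two leaflets with first-tail beads at
  ±D/2 plus optional vertical jitter, one head/first-tail/tail-end bead
  per lipid.

What the generators do **not** emulate: molecular interactions, chain
internal structure, equilibrium liquid correlations, interface intrinsic
width, curvature/undulation of the bilayer, and correlated frame-to-frame
dynamics.  Passing tests therefore demonstrate the correctness of the
analysis chain under capillary statistics with sharp microscopic
boundaries — not the physics of any particular force field.

## Problem sizes and validation choices

The point-cloud stiffness recovery uses slabs of 24 × 80 nm (≈9,000
particles per frame), 100 frames per stiffness, two boundaries pooled
(200 interface samples), fitting modes with k < 0.35 nm⁻¹ with
deconvolution enabled.  These sizes put the per-mode standard error near
3%, small enough to resolve a 10% bias while keeping a three-stiffness
sweep (5, 11.5, 30 pN) in a few minutes.  The circular round trip uses
R₀ = 6 nm halos in a 26 nm box, 150 frames, modes k < 0.8 nm⁻¹.  Spectrum
self-tests use 500–1000 generated frames, where 3-standard-error bands
are a few percent.

## Degenerate inputs and numerical conventions

Boxes are half-open [0, L); wrapping maps exact-L artifacts of floating
`mod` back to 0 and is idempotent.  RSA refuses densities with
ρ₀·π·r_min² > 1.9 (close to the ~2.19 jamming coverage) and errors if the
attempt budget leaves it short of 99% of the target count, reporting the
achieved density.  A field entirely on one side of the level yields an
empty curve list (not an error).  Stiffness fits require ≥ 3 modes and a
positive fitted constant; an all-zero spectrum is flagged as
non-capillary input.  Circular ensembles whose mean radius drifts by
more than 20% are rejected as non-stationary.

## Known limitations

- No 3D (surface) interface construction; the analysis is strictly 2D.
- No director field, per-lipid tilt, hexatic/crystal discrimination, or
  ripple/tilt subphases.
- Leaflet assignment is by head-bead height against the median midplane —
  valid for flat bilayers only.
- GRO support covers fixed-column coordinate files; trajectories (XTC/TRR)
  and topologies are not parsed.
- The overhang-folding rule for multivalued h(x) is a pragmatic choice;
  heavily overhung interfaces (near-critical, very soft) would need a
  different parameterization.
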