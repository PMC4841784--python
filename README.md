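# premelt

Analysis of pre-melting ("orderphobic") effects in lipid bilayers:
bond-orientational order fields, instantaneous order–disorder interfaces,
capillary-wave spectra with interfacial-stiffness estimation, radial order
profiles around membrane inclusions, and interfacial free energies of
assembly.

## Who this is for

Researchers studying the first-order transition between the solid-ordered
and liquid-disordered phases of model membranes (e.g. coarse-grained DPPC
bilayers), and in particular the microscopic disordered layer that a
hydrophobically mismatched transmembrane inclusion nucleates in an
otherwise ordered bilayer.  The package analyzes 2D point configurations
of lipid tail-end particles (projected leaflet coordinates, from delimited
text or GRO coordinate files) and ships synthetic-configuration generators
with exact ground truth, so every stage of the chain can be validated
without molecular dynamics.

## The quantities at the core

For tail-end particle *l* with six nearest neighbors nn(*l*), the local
hexagonal bond-orientational invariant is

    phi_l = | (1/6) Σ_{j ∈ nn(l)} exp(6 i θ_lj) |²,

where θ_lj is the bond angle to a fixed axis.  phi_l = 1 for perfect
hexagonal packing and 1/6 in expectation for uncorrelated bond angles.
The orientational-order density φ(r) = Σ_l phi_l δ(r − r_l) is
coarse-grained with a Gaussian of width ξ = 1.5 nm (truncated and shifted
to zero at 3ξ), and the **instantaneous order–disorder interface** is the
level set φ̄(s) = (φ_d + φ_o)/2, the midpoint of the bulk disordered and
ordered levels.

Interface fluctuations follow capillary-wave statistics,

    ⟨|δh_k|²⟩ = k_B T / (L γ k²)          (flat interface, k = 2πm/L)
    ⟨|δR_k|²⟩ = k_B T / (2π γ k² R₀)      (circular halo, k = m/R₀),

so the small-k spectrum inverts to the interfacial stiffness γ (pN).  The
free-energy change when two inclusion halos of perimeters P₁, P₂ merge
into one of perimeter P_f is ΔF = γ(P_f − P₁ − P₂).

Units: nm, K, pN throughout; k_B = 0.01380649 pN·nm/K.

## Worked example

`examples/flat_interface_stiffness.py` draws 500 height profiles of a
100 nm interface from the capillary distribution at γ = 11.5 pN and
T = 294 K and inverts the spectrum:

```
generated at gamma = 11.5 pN, T = 294.0 K, L = 100.0 nm
fitted    gamma = 11.811 +- 0.150 pN (12 modes, k < 0.8 1/nm)
mode m   k (1/nm)   measured <|dh_k|^2>   theory (nm^2)
     1     0.0628                0.9146          0.8941
     2     0.1257                0.2095          0.2235
     4     0.2513                0.0571          0.0559
     8     0.5027                0.0145          0.0140
```

The measured mode amplitudes track the 1/k² capillary law and the fitted
stiffness recovers the generator's value to ~2%.  The other examples
exercise the full particle-level chain:

- `order_parameter.py` — phi statistics, area per lipid and hydrophobic
  thickness of the two phases,
- `slab_point_cloud_recovery.py` — stiffness recovered from slab *point
  clouds* (order field → level set → spectrum → fit),
- `inclusion_halo.py` — radial order ratio around an inclusion, halo
  contour and perimeter, assembly free energy,
- `pipeline_run.py` — a reproducible run directory with artifacts and a
  plotted report.

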