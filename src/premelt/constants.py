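"""Physical constants and package-wide defaults.

Unit conventions: lengths in nm, temperature in K, interfacial stiffness in
pN, energies in pN·nm (1 pN·nm = 1e-21 J = 1 zJ).
"""

import math

#: Boltzmann constant in pN·nm/K.
KB = 0.01380649

#: Default Gaussian coarse-graining width xi (nm).  Chosen so that the
#: normalized covariance of the per-particle order parameter in the ordered
#: phase decays to 1/10 at this separation; the coarse-grained field is
#: insensitive to the exact value in the 1-2 nm range.
XI_DEFAULT = 1.5

#: Default grid spacing for coarse-grained fields (nm); kernel sampling
#: requires spacing <= xi/4.
GRID_SPACING_DEFAULT = 0.25

#: Truncation radius of the coarse-graining kernel, in units of xi.
KERNEL_CUTOFF_XI = 3.0

#: Mass of the truncated-and-shifted Gaussian kernel:
#: integral of (1/2πξ²)[exp(-r²/2ξ²) - exp(-9/2)] over r < 3ξ,
#: = 1 - e^{-9/2} - (9/2) e^{-9/2} ≈ 0.93890.  Independent of xi.
KERNEL_MASS = 1.0 - 5.5 * math.exp(-4.5)

#: Bulk levels of the orientational-order density field phi_bar (nm^-2) in
#: the disordered and ordered phases of the coarse-grained DPPC membrane at
#: zero lateral tension and 294 K.  Used as fallbacks when no calibration
#: frames are supplied; synthetic pipelines calibrate their own levels.
PHI_DISORDERED = 0.4
PHI_ORDERED = 2.15

#: Bulk levels of the density-normalized order ratio <phi(r)>/<rho(r)> in
#: the disordered and ordered phases of the same membrane model.
RATIO_DISORDERED = 0.15
RATIO_ORDERED = 0.45

#: Wavevector (nm^-1) above which interface fluctuations deviate from the
#: small-k capillary-wave law; stiffness fits exclude k >= K_MAX_DEFAULT.
K_MAX_DEFAULT = 0.8

#: Hydrophobic thickness of the ordered and disordered phases (nm),
#: measured between the first tail beads of the two leaflets.
THICKNESS_ORDERED = 3.1
THICKNESS_DISORDERED = 2.6

#: Stiffness of the free order-disorder interface at coexistence (pN),
#: from the capillary-spectrum analysis of the flat interface.
STIFFNESS_COEXISTENCE = 11.5
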