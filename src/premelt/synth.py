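"""Synthetic configurations and interface samples with known ground truth.

The generators emulate the statistical structure of coarse-grained bilayer
leaflets so every analysis stage can be validated without molecular
dynamics: hexagonally packed ordered phases with thermal jitter, disordered
random packings, two-phase slabs, a circular inclusion with a disordered
halo, and flat/circular interfaces fluctuating according to capillary-wave
statistics at user-set stiffness and temperature.

Boundaries in slab/inclusion constructions are sharp; interfacial smoothness
arises only from downstream coarse-graining, so the geometric ground truth
stays exact.  All randomness flows through explicitly seeded per-generator
``numpy.random.Generator`` streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .configuration import BilayerConfiguration3D, PointConfiguration2D
from .constants import KB

__all__ = [
    "SynthSpec", "HeightSample",
    "gen_hexagonal", "gen_disordered", "gen_slab", "gen_inclusion",
    "gen_capillary_flat", "gen_capillary_circle", "gen_bilayer3d",
    "generate",
    "HEX_SPACING", "HEX_JITTER_FRACTION", "RHO_DISORDERED", "RMIN_DISORDERED",
]

# --- presets emulating the coarse-grained DPPC leaflet -----------------
# Tail-end surface density of the ordered phase ~ 2 beads per lipid at
# ~0.47 nm^2 area per lipid -> hexagonal spacing ~0.52 nm.  The disordered
# phase has a larger area per lipid, hence a lower density; the exact
# disordered density is a free preset, not an asserted value.
HEX_SPACING = 0.52          # nm
HEX_JITTER_FRACTION = 0.05  # jitter sigma as a fraction of the spacing
RHO_DISORDERED = 3.3        # nm^-2
RMIN_DISORDERED = 0.4       # nm hard minimum pair distance


@dataclass
class SynthSpec:
    """Declarative description of one synthetic sample (seed mandatory)."""

    kind: str                       # hexagonal | disordered | slab |
                                    # inclusion | capillary_flat |
                                    # capillary_circle | bilayer3d
    seed: int
    params: dict = field(default_factory=dict)

    KINDS = ("hexagonal", "disordered", "slab", "inclusion",
             "capillary_flat", "capillary_circle", "bilayer3d")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; one of {self.KINDS}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)


def generate(spec: SynthSpec):
    """Dispatch a SynthSpec to the matching generator."""
    fn = {
        "hexagonal": gen_hexagonal, "disordered": gen_disordered,
        "slab": gen_slab, "inclusion": gen_inclusion,
        "capillary_flat": gen_capillary_flat,
        "capillary_circle": gen_capillary_circle,
        "bilayer3d": gen_bilayer3d,
    }[spec.kind]
    return fn(seed=spec.seed, **spec.params)


@dataclass
class HeightSample:
    """Interface sample on a uniform grid: h(x) over [0, L) for a flat
    interface, or R(theta) over [0, 2pi) for a circular one.

    For generated samples the fluctuation (h - mean h, or R - R0) has zero
    mean by construction.
    """

    values: np.ndarray
    length: float               # L (flat, nm) or R0 (circular, nm)
    kind: str                   # 'flat' | 'circle'
    temperature: float | None = None
    gamma_true: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("flat", "circle"):
            raise ValueError("kind must be 'flat' or 'circle'")
        if self.length <= 0:
            raise ValueError("length must be positive")

    @property
    def n_grid(self) -> int:
        return self.values.size

    @property
    def grid(self) -> np.ndarray:
        """x positions (flat) or angles (circle) of the grid points."""
        span = self.length if self.kind == "flat" else 2 * np.pi
        return np.arange(self.n_grid) * span / self.n_grid


# ----------------------------------------------------------------------
# lattice and packing generators
# ----------------------------------------------------------------------

def _hex_counts(box: Sequence[float], a: float) -> tuple[int, int]:
    """Commensurate column/row counts for a triangular lattice."""
    row = math.sqrt(3.0) / 2.0 * a
    nx = int(round(box[0] / a))
    ny = int(round(box[1] / row))
    ny -= ny % 2  # row offset pattern must close under the y-wrap
    return nx, ny


def _hex_sites(nx: int, ny: int, a: float) -> np.ndarray:
    row = math.sqrt(3.0) / 2.0 * a
    i, j = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    x = i * a + (j % 2) * (a / 2.0)
    y = j * row
    return np.column_stack([x.ravel(), y.ravel()])


def gen_hexagonal(a: float = HEX_SPACING, sigma: float | None = None,
                  box: Sequence[float] = (20.0, 20.0), *,
                  seed: int) -> PointConfiguration2D:
    """Triangular lattice with iid Gaussian positional jitter.

    The box is adjusted to the nearest lattice-commensurate size (reported
    in ``metadata['box_requested']``).  ``sigma`` defaults to 5% of the
    lattice spacing; sigma=0 gives the perfect lattice (order parameter 1).
    """
    if sigma is None:
        sigma = HEX_JITTER_FRACTION * a
    if sigma < 0:
        raise ValueError("jitter sigma must be >= 0")
    if a <= 0:
        raise ValueError("lattice spacing must be positive")
    row = math.sqrt(3.0) / 2.0 * a
    if box[0] < a or box[1] < 2 * row:
        raise ValueError(f"box {tuple(box)} too small for one unit cell "
                         f"(needs at least {a:.3f} x {2 * row:.3f} nm)")
    nx, ny = _hex_counts(box, a)
    adj_box = (nx * a, ny * row)
    rng = np.random.default_rng(seed)
    pos = _hex_sites(nx, ny, a)
    if sigma > 0:
        pos = pos + rng.normal(0.0, sigma, size=pos.shape)
    return PointConfiguration2D(pos, adj_box, metadata={
        "kind": "hexagonal", "a": a, "sigma": sigma, "seed": seed,
        "box_requested": tuple(float(b) for b in box)})


def _rsa_points(n_target: int, box: Sequence[float], r_min: float,
                rng: np.random.Generator,
                mask: Callable[[np.ndarray], np.ndarray] | None = None,
                max_batches: int = 400,
                batch: int = 4096) -> np.ndarray:
    """Random sequential addition with a hard minimum pair distance under
    periodic boundaries, optionally restricted to a region mask."""
    box = (float(box[0]), float(box[1]))
    accepted: list[np.ndarray] = []
    if r_min > 0:
        ncx = max(1, int(box[0] // r_min))
        ncy = max(1, int(box[1] // r_min))
    cells: dict[tuple[int, int], list[int]] = {}
    pts = np.empty((0, 2))
    for _ in range(max_batches):
        if len(accepted) >= n_target:
            break
        prop = rng.random((batch, 2)) * np.array(box)
        if mask is not None:
            prop = prop[mask(prop)]
        if prop.size == 0:
            continue
        if r_min <= 0:
            take = prop[: n_target - len(accepted)]
            accepted.extend(take)
            continue
        # vectorized pre-filter against already-accepted points
        if accepted:
            tree = cKDTree(pts, boxsize=box)
            d, _ = tree.query(prop, k=1)
            prop = prop[d >= r_min]
        # sequential within-batch acceptance via a periodic cell list
        for p in prop:
            if len(accepted) >= n_target:
                break
            ci = int(p[0] / box[0] * ncx) % ncx
            cj = int(p[1] / box[1] * ncy) % ncy
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for idx in cells.get(((ci + di) % ncx, (cj + dj) % ncy), ()):
                        d = accepted[idx] - p
                        d -= np.array(box) * np.round(d / np.array(box))
                        if d[0] * d[0] + d[1] * d[1] < r_min * r_min:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                cells.setdefault((ci, cj), []).append(len(accepted))
                accepted.append(np.asarray(p, dtype=float))
        pts = np.array(accepted) if accepted else np.empty((0, 2))
    return np.array(accepted) if accepted else np.empty((0, 2))


def gen_disordered(rho0: float = RHO_DISORDERED,
                   r_min: float = RMIN_DISORDERED,
                   box: Sequence[float] = (20.0, 20.0), *,
                   seed: int) -> PointConfiguration2D:
    """Random packing at density rho0 with hard minimum distance r_min.

    Random sequential addition (RSA), not equilibrium liquid sampling: only
    packing disorder matters for bond-orientational statistics.  Errors out
    if the requested density is infeasibly close to RSA jamming or the
    attempt budget is exhausted before reaching 99% of the target count.
    """
    if rho0 <= 0:
        raise ValueError("density must be positive")
    if r_min < 0:
        raise ValueError("r_min must be >= 0")
    # RSA saturation coverage for hard disks is ~0.547, i.e.
    # rho * pi * r_min^2 ~ 2.19; refuse anything close to it.
    if r_min > 0 and rho0 * math.pi * r_min ** 2 > 1.9:
        raise ValueError(
            f"infeasible packing: rho0*pi*r_min^2 = "
            f"{rho0 * math.pi * r_min ** 2:.3f} exceeds the jamming guard 1.9")
    area = float(box[0]) * float(box[1])
    n_target = max(1, int(round(rho0 * area)))
    rng = np.random.default_rng(seed)
    pos = _rsa_points(n_target, box, r_min, rng)
    achieved = pos.shape[0] / area
    if pos.shape[0] < 0.99 * n_target:
        raise RuntimeError(
            f"RSA attempt budget exhausted: achieved density "
            f"{achieved:.3f} nm^-2 of requested {rho0:.3f} nm^-2")
    return PointConfiguration2D(pos, (float(box[0]), float(box[1])), metadata={
        "kind": "disordered", "rho0": rho0, "r_min": r_min, "seed": seed,
        "achieved_density": achieved})


def _interp_periodic(grid_values: np.ndarray, span: float,
                     query: np.ndarray) -> np.ndarray:
    """Linear interpolation of a periodic uniform-grid profile."""
    n = grid_values.size
    t = np.mod(query, span) / span * n
    i0 = np.floor(t).astype(int) % n
    frac = t - np.floor(t)
    return grid_values[i0] * (1 - frac) + grid_values[(i0 + 1) % n] * frac


def gen_slab(a: float = HEX_SPACING, sigma: float | None = None,
             rho0: float = RHO_DISORDERED, fraction_ordered: float = 0.5,
             box: Sequence[float] = (24.0, 40.0), *, seed: int,
             r_min: float = RMIN_DISORDERED,
             boundary_profiles: tuple[np.ndarray, np.ndarray] | None = None,
             ) -> PointConfiguration2D:
    """Two-phase slab: a centered hexagonal (ordered) strip flanked by
    disordered packing, with two flat vertical boundaries under PBC.

    The ordered strip spans Lx(1-f)/2 <= x < Lx(1+f)/2 after box
    commensuration; the ground-truth boundary x positions are recorded in
    ``metadata['boundaries']``.  ``boundary_profiles`` optionally displaces
    each boundary by a periodic height profile h(y) (uniform y-grid over
    [0, Ly)), e.g. from :func:`gen_capillary_flat`, recorded as ground
    truth for end-to-end interface recovery.
    """
    f = float(fraction_ordered)
    if not 0.0 < f < 1.0:
        raise ValueError("fraction_ordered must be in (0, 1)")
    if sigma is None:
        sigma = HEX_JITTER_FRACTION * a
    nx, ny = _hex_counts(box, a)
    row = math.sqrt(3.0) / 2.0 * a
    if nx < 1 or ny < 2:
        raise ValueError("box too small for the hexagonal strip")
    Lx, Ly = float(box[0]), ny * row  # y must close the lattice rows
    x_lo, x_hi = Lx * (1 - f) / 2.0, Lx * (1 + f) / 2.0
    if min(f, 1 - f) * Lx < 3 * a:
        raise ValueError(
            f"strip width {min(f, 1 - f) * Lx:.2f} nm narrower than 3a "
            f"= {3 * a:.2f} nm")
    rng = np.random.default_rng(seed)

    def b1(y):
        if boundary_profiles is None:
            return np.full_like(np.asarray(y, float), x_lo)
        return x_lo + _interp_periodic(np.asarray(boundary_profiles[0], float),
                                       Ly, y)

    def b2(y):
        if boundary_profiles is None:
            return np.full_like(np.asarray(y, float), x_hi)
        return x_hi + _interp_periodic(np.asarray(boundary_profiles[1], float),
                                       Ly, y)

    sites = _hex_sites(nx, ny, a)
    ordered = (sites[:, 0] >= b1(sites[:, 1])) & (sites[:, 0] < b2(sites[:, 1]))
    hex_pts = sites[ordered]
    if sigma > 0:
        hex_pts = hex_pts + rng.normal(0.0, sigma, size=hex_pts.shape)

    def in_disordered(p):
        return ~((p[:, 0] >= b1(p[:, 1])) & (p[:, 0] < b2(p[:, 1])))

    area_dis = (1 - f) * Lx * Ly
    n_dis = max(1, int(round(rho0 * area_dis)))
    dis_pts = _rsa_points(n_dis, (Lx, Ly), r_min, rng, mask=in_disordered)
    pos = np.vstack([hex_pts, dis_pts])
    return PointConfiguration2D(pos, (Lx, Ly), metadata={
        "kind": "slab", "a": a, "sigma": sigma, "rho0": rho0,
        "fraction_ordered": f, "seed": seed, "boundaries": (x_lo, x_hi),
        "boundary_profiles": boundary_profiles,
        "box_requested": tuple(float(b) for b in box)})


def gen_inclusion(R: float = 1.5, R0: float = 4.0, a: float = HEX_SPACING,
                  sigma: float | None = None, rho0: float = RHO_DISORDERED,
                  box: Sequence[float] = (24.0, 24.0), *, seed: int,
                  r_min: float = RMIN_DISORDERED,
                  radius_profile: np.ndarray | None = None,
                  center: Sequence[float] | None = None,
                  ) -> PointConfiguration2D:
    """Circular inclusion of radius R (excluded footprint) surrounded by a
    disordered annulus out to the halo radius R0, hexagonal beyond.

    ``radius_profile`` optionally perturbs the halo boundary,
    R0 + dR(theta) on a uniform theta-grid.  R = R0 produces no halo.
    Requires R <= R0 < min(box)/4.
    """
    if sigma is None:
        sigma = HEX_JITTER_FRACTION * a
    if not (0 < R <= R0):
        raise ValueError("need 0 < R <= halo radius R0")
    if R0 >= min(box) / 4.0:
        raise ValueError("halo radius must be < min(box)/4")
    nx, ny = _hex_counts(box, a)
    row = math.sqrt(3.0) / 2.0 * a
    Lx, Ly = nx * a, ny * row
    c = (np.array([Lx, Ly]) / 2.0 if center is None
         else np.asarray(center, dtype=float))
    rng = np.random.default_rng(seed)

    def halo_radius(theta):
        if radius_profile is None:
            return np.full_like(np.asarray(theta, float), R0)
        return R0 + _interp_periodic(np.asarray(radius_profile, float),
                                     2 * np.pi, theta)

    sites = _hex_sites(nx, ny, a)
    rel = sites - c
    rel -= np.array([Lx, Ly]) * np.round(rel / np.array([Lx, Ly]))
    r = np.hypot(rel[:, 0], rel[:, 1])
    th = np.arctan2(rel[:, 1], rel[:, 0])
    hex_pts = sites[r >= halo_radius(th)]
    if sigma > 0:
        hex_pts = hex_pts + rng.normal(0.0, sigma, size=hex_pts.shape)

    def in_annulus(p):
        d = p - c
        d -= np.array([Lx, Ly]) * np.round(d / np.array([Lx, Ly]))
        rr = np.hypot(d[:, 0], d[:, 1])
        tt = np.arctan2(d[:, 1], d[:, 0])
        return (rr >= R) & (rr < halo_radius(tt))

    area_annulus = max(0.0, math.pi * (R0 ** 2 - R ** 2))
    pos_list = [hex_pts]
    if area_annulus > 0:
        n_dis = int(round(rho0 * area_annulus))
        if n_dis > 0:
            pos_list.append(_rsa_points(n_dis, (Lx, Ly), r_min, rng,
                                        mask=in_annulus))
    pos = np.vstack([p for p in pos_list if p.size])
    return PointConfiguration2D(pos, (Lx, Ly), metadata={
        "kind": "inclusion", "R": R, "R0": R0, "a": a, "sigma": sigma,
        "rho0": rho0, "seed": seed, "center": tuple(c),
        "radius_profile": radius_profile,
        "box_requested": tuple(float(b) for b in box)})


# ----------------------------------------------------------------------
# capillary-wave interface generators
# ----------------------------------------------------------------------

def gen_capillary_flat(L: float = 100.0, gamma: float = 11.5,
                       T: float = 294.0, n_grid: int = 512,
                       n_frames: int = 500, *, seed: int,
                       ) -> list[HeightSample]:
    """Independent flat-interface height samples drawn from the capillary
    distribution <|dh_k|^2> = kB T / (L gamma k^2), k = 2 pi m / L.

    Fourier coefficients for m != 0 are complex Gaussians with the stated
    variance; Hermitian symmetry makes h(x) real and the mean height zero.
    The Nyquist mode (m = n_grid/2) is left empty.
    """
    if gamma <= 0 or T <= 0 or L <= 0:
        raise ValueError("L, gamma and T must be positive")
    if n_grid < 4:
        raise ValueError("n_grid must be >= 4")
    rng = np.random.default_rng(seed)
    m_max = (n_grid - 1) // 2
    m = np.arange(1, m_max + 1)
    k = 2 * np.pi * m / L
    var = KB * T / (L * gamma * k ** 2)   # <|dh_k|^2> per signed mode
    samples = []
    for _ in range(n_frames):
        re = rng.normal(0.0, np.sqrt(var / 2.0))
        im = rng.normal(0.0, np.sqrt(var / 2.0))
        coeff = np.zeros(n_grid, dtype=complex)
        coeff[1:m_max + 1] = re + 1j * im
        coeff[-m_max:] = np.conj(coeff[1:m_max + 1])[::-1]
        h = np.fft.ifft(coeff * n_grid).real
        samples.append(HeightSample(h, L, "flat", T, gamma))
    return samples


def gen_capillary_circle(R0: float = 6.0, gamma: float = 11.5,
                         T: float = 294.0, n_modes: int = 8,
                         n_frames: int = 500, n_grid: int = 256, *,
                         seed: int) -> list[HeightSample]:
    """Independent circular-interface samples R(theta) = R0 + dR(theta)
    with <|dR_m|^2> = kB T R0 / (2 pi gamma m^2)  (k = m/R0), m=1..n_modes.
    """
    if gamma <= 0 or T <= 0 or R0 <= 0:
        raise ValueError("R0, gamma and T must be positive")
    if n_modes < 2:
        raise ValueError("n_modes must be >= 2")
    if n_grid < 2 * (n_modes + 1):
        raise ValueError("n_grid too small to resolve n_modes")
    rng = np.random.default_rng(seed)
    m = np.arange(1, n_modes + 1)
    var = KB * T * R0 / (2 * np.pi * gamma * m ** 2)
    samples = []
    for _ in range(n_frames):
        re = rng.normal(0.0, np.sqrt(var / 2.0))
        im = rng.normal(0.0, np.sqrt(var / 2.0))
        coeff = np.zeros(n_grid, dtype=complex)
        coeff[1:n_modes + 1] = re + 1j * im
        coeff[-n_modes:] = np.conj(coeff[1:n_modes + 1])[::-1]
        dR = np.fft.ifft(coeff * n_grid).real
        samples.append(HeightSample(R0 + dR, R0, "circle", T, gamma))
    return samples


def gen_bilayer3d(D: float = 3.1, a: float = HEX_SPACING,
                  sigma_z: float = 0.0, box: Sequence[float] = (15.0, 15.0),
                  *, seed: int) -> BilayerConfiguration3D:
    """Flat two-leaflet bilayer with first-tail beads at z = +-D/2.

    Each lipid contributes one head, one first_tail and one tail_end bead;
    D is the hydrophobic thickness (first-tail to first-tail).  sigma_z adds
    iid vertical jitter to every bead.
    """
    if D <= 0:
        raise ValueError("thickness D must be positive")
    if sigma_z < 0:
        raise ValueError("sigma_z must be >= 0")
    nx, ny = _hex_counts(box, a)
    row = math.sqrt(3.0) / 2.0 * a
    Lx, Ly = nx * a, ny * row
    xy = _hex_sites(nx, ny, a)
    n_lip = xy.shape[0]
    rng = np.random.default_rng(seed)
    Lz = D + 4.0
    mid = Lz / 2.0
    positions, roles, leaflets, lipid_ids = [], [], [], []
    lid = 0
    for sign in (+1, -1):
        for i in range(n_lip):
            lid += 1
            x, y = xy[i]
            for role, dz in (("head", sign * (D / 2.0 + 1.0)),
                             ("first_tail", sign * D / 2.0),
                             ("tail_end", sign * 0.35)):
                z = mid + dz
                if sigma_z > 0:
                    z += rng.normal(0.0, sigma_z)
                positions.append((x, y, z))
                roles.append(role)
                leaflets.append("upper" if sign > 0 else "lower")
                lipid_ids.append(lid)
    return BilayerConfiguration3D(
        np.array(positions), np.array(roles), np.array(leaflets),
        np.array(lipid_ids), box=(Lx, Ly, Lz),
        metadata={"kind": "bilayer3d", "D": D, "a": a, "sigma_z": sigma_z,
                  "seed": seed})
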