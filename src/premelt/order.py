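"""Bond-orientational order: the per-particle hexagonal invariant, the
Gaussian coarse-grained order/density fields, the coarse-graining width
criterion, radial profiles, and scalar membrane observables.

The per-particle order parameter is the local rotational invariant

    phi_l = | (1/6) sum_{j in nn(l)} exp(6 i theta_lj) |^2

where theta_lj is the angle between a fixed reference axis (the box x-axis)
and the minimum-image vector from particle l to neighbor j, and nn(l) are
the six nearest neighbors.  phi_l is 1 for a perfect hexagonal packing and
1/6 in expectation for uncorrelated bond angles.

The orientational-order density phi(r) = sum_l phi_l delta(r - r_l) is
coarse-grained by replacing the delta function with a Gaussian of width xi,
truncated and shifted to zero at 3 xi (not renormalized by default; the
kernel mass is 0.93890).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .configuration import Ensemble, PointConfiguration2D, minimum_image
from .constants import (GRID_SPACING_DEFAULT, KERNEL_CUTOFF_XI, KERNEL_MASS,
                        XI_DEFAULT)

__all__ = [
    "OrderValues", "ScalarField2D", "RadialProfile",
    "phi_from_angles", "compute_phi", "estimate_xi", "coarse_grain",
    "order_density_field", "number_density_field", "bulk_levels",
    "radial_profile", "hydrophobic_thickness", "area_per_lipid",
]

log = logging.getLogger("premelt")

N_NEIGHBORS = 6


@dataclass
class OrderValues:
    """Per-particle order parameters and the neighbor sets behind them."""

    phi: np.ndarray                  # (N,) in [0, 1]
    neighbors: np.ndarray            # (N, 6) int indices
    reference_axis: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.neighbors = np.asarray(self.neighbors, dtype=int)
        if self.neighbors.shape != (self.phi.size, N_NEIGHBORS):
            raise ValueError("neighbors must have shape (N, 6)")


def phi_from_angles(theta: np.ndarray) -> np.ndarray:
    """Hexagonal invariant |mean exp(6 i theta)|^2 over the last axis."""
    z = np.exp(6j * np.asarray(theta, dtype=float)).mean(axis=-1)
    return np.abs(z) ** 2


def _neighbor_table(config: PointConfiguration2D,
                    k: int = N_NEIGHBORS) -> tuple[np.ndarray, np.ndarray]:
    """Indices and minimum-image displacement vectors of the k nearest
    neighbors of every particle, ties broken by ascending particle index."""
    n = config.n
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} particles, got {n}")
    pos = config.positions
    if all(config.periodic):
        tree = cKDTree(pos, boxsize=config.box)
    elif not any(config.periodic):
        tree = cKDTree(pos)
    else:
        raise NotImplementedError("mixed periodicity is not supported")
    kq = min(n, k + 7)  # headroom so distance ties can be re-sorted
    dist, idx = tree.query(pos, k=kq)
    # deterministic (distance, index) ordering: stable sort by index, then
    # stable sort by distance
    order = np.argsort(idx, axis=1, kind="stable")
    dist = np.take_along_axis(dist, order, axis=1)
    idx = np.take_along_axis(idx, order, axis=1)
    order = np.argsort(dist, axis=1, kind="stable")
    dist = np.take_along_axis(dist, order, axis=1)
    idx = np.take_along_axis(idx, order, axis=1)
    # drop self (distance 0 at own index), keep first k of the rest
    self_col = idx == np.arange(n)[:, None]
    keep = np.empty((n, k), dtype=int)
    for i in range(n):
        row = idx[i][~self_col[i]]
        keep[i] = row[:k]
    disp = minimum_image(pos[keep] - pos[:, None, :], config.box,
                         config.periodic)
    return keep, disp


def compute_phi(config: PointConfiguration2D,
                reference_axis: Sequence[float] = (1.0, 0.0)) -> OrderValues:
    """Per-particle hexagonal bond-orientational invariant.

    Neighbors are the six smallest minimum-image distances (ties broken by
    ascending particle index); angles are measured from ``reference_axis``.
    """
    axis = np.asarray(reference_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    neighbors, disp = _neighbor_table(config)
    # rotate displacements into the reference frame; theta = atan2 there
    dx = disp[..., 0] * axis[0] + disp[..., 1] * axis[1]
    dy = -disp[..., 0] * axis[1] + disp[..., 1] * axis[0]
    theta = np.arctan2(dy, dx)
    return OrderValues(phi_from_angles(theta), neighbors, axis)


def estimate_xi(config: PointConfiguration2D, phi: np.ndarray,
                bin_width: float = 0.2, r_max: float | None = None,
                threshold: float = 0.1) -> float:
    """Coarse-graining width from the decay of the normalized spatial
    covariance of phi in a (near-)ordered sample.

    Computes C(d) = <dphi_l dphi_j>_{|r_l - r_j| ~ d} / <dphi^2> in distance
    bins and returns the linearly interpolated distance where C(d) first
    crosses ``threshold`` (1/10) from above.  ``phi`` may be (N,) for one
    frame or (F, N) to average the equilibrium covariance over F frames
    sharing the particle positions.  If the first populated bin is
    already below threshold the bin center is returned with a warning; if
    C never crosses, a ValueError suggests a larger box.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    if r_max is None:
        r_max = min(config.box) / 2.0
    dphi = phi - phi.mean(axis=1, keepdims=True)
    var = float(np.mean(dphi ** 2))
    if var <= 0:
        raise ValueError("phi values are constant; covariance undefined")
    tree = (cKDTree(config.positions, boxsize=config.box)
            if all(config.periodic) else cKDTree(config.positions))
    pairs = tree.query_pairs(r_max, output_type="ndarray")
    if pairs.size == 0:
        raise ValueError("no particle pairs within r_max")
    d = np.linalg.norm(minimum_image(
        config.positions[pairs[:, 0]] - config.positions[pairs[:, 1]],
        config.box, config.periodic), axis=1)
    nbins = max(1, int(np.ceil(r_max / bin_width)))
    which = np.minimum((d / bin_width).astype(int), nbins - 1)
    prod = np.mean(dphi[:, pairs[:, 0]] * dphi[:, pairs[:, 1]], axis=0)
    sums = np.bincount(which, weights=prod, minlength=nbins)
    counts = np.bincount(which, minlength=nbins)
    filled = counts > 0
    centers = (np.arange(nbins) + 0.5) * bin_width
    corr = np.full(nbins, np.nan)
    corr[filled] = sums[filled] / counts[filled] / var
    centers, corr = centers[filled], corr[filled]
    if corr[0] < threshold:
        warnings.warn(
            "phi covariance already below threshold in the first populated "
            "distance bin; returning that bin center", stacklevel=2)
        return float(centers[0])
    below = np.nonzero(corr < threshold)[0]
    if below.size == 0:
        raise ValueError(
            "phi covariance never crosses the threshold within r_max; "
            "use a larger box or r_max")
    j = below[0]
    c0, c1 = corr[j - 1], corr[j]
    x0, x1 = centers[j - 1], centers[j]
    return float(x0 + (c0 - threshold) / (c0 - c1) * (x1 - x0))


@dataclass
class ScalarField2D:
    """Coarse-grained scalar field on a uniform periodic grid.

    ``values[i, j]`` sits at (i*dx, j*dy); units nm^-2 for both the number
    density rho_bar and the order density phi_bar.
    """

    values: np.ndarray
    box: tuple[float, float]
    xi: float
    periodic: tuple[bool, bool] = (True, True)
    kind: str = "phi_bar"         # phi_bar | rho_bar | ratio

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D")
        self.box = (float(self.box[0]), float(self.box[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def spacing(self) -> tuple[float, float]:
        return (self.box[0] / self.shape[0], self.box[1] / self.shape[1])

    def grid_axes(self) -> tuple[np.ndarray, np.ndarray]:
        dx, dy = self.spacing
        return (np.arange(self.shape[0]) * dx, np.arange(self.shape[1]) * dy)

    def integral(self) -> float:
        """Box integral of the field (rectangle rule on the periodic grid)."""
        dx, dy = self.spacing
        return float(self.values.sum() * dx * dy)

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Bilinear interpolation at arbitrary points (periodic wrap)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        nx, ny = self.shape
        dx, dy = self.spacing
        tx = np.mod(pts[:, 0], self.box[0]) / dx
        ty = np.mod(pts[:, 1], self.box[1]) / dy
        i0 = np.floor(tx).astype(int) % nx
        j0 = np.floor(ty).astype(int) % ny
        fx = tx - np.floor(tx)
        fy = ty - np.floor(ty)
        i1, j1 = (i0 + 1) % nx, (j0 + 1) % ny
        v = self.values
        return (v[i0, j0] * (1 - fx) * (1 - fy) + v[i1, j0] * fx * (1 - fy)
                + v[i0, j1] * (1 - fx) * fy + v[i1, j1] * fx * fy)


def _kernel(r2: np.ndarray, xi: float) -> np.ndarray:
    """Truncated-and-shifted Gaussian kernel evaluated at squared radii."""
    cutoff2 = (KERNEL_CUTOFF_XI * xi) ** 2
    shift = np.exp(-KERNEL_CUTOFF_XI ** 2 / 2.0)
    out = np.exp(-r2 / (2.0 * xi * xi)) - shift
    out[r2 >= cutoff2] = 0.0
    return out / (2.0 * np.pi * xi * xi)


def coarse_grain(config: PointConfiguration2D, weights: np.ndarray,
                 xi: float = XI_DEFAULT,
                 delta: float = GRID_SPACING_DEFAULT,
                 kind: str = "phi_bar",
                 renormalize: bool = False) -> ScalarField2D:
    """Gaussian coarse-graining of a weighted point density onto a grid.

    field(g) = sum_l w_l K(|g - r_l|) with the truncated-shifted kernel
    K(r) = (1/2 pi xi^2)[exp(-r^2/2 xi^2) - exp(-9/2)] for r < 3 xi,
    minimum-image distances.  The kernel is NOT renormalized by default
    (box integral of rho_bar = 0.93890 N); ``renormalize=True`` divides by
    the kernel mass so the integral equals N.
    """
    if delta > xi / 2.0:
        raise ValueError(f"grid spacing {delta} undersamples the kernel "
                         f"(must be <= xi/2 = {xi / 2.0})")
    if delta > xi / 4.0:
        warnings.warn(f"grid spacing {delta} coarser than the recommended "
                      f"xi/4 = {xi / 4.0}", stacklevel=2)
    w = np.asarray(weights, dtype=float)
    if w.shape != (config.n,):
        raise ValueError("weights must be one value per particle")
    Lx, Ly = config.box
    nx = max(1, int(round(Lx / delta)))
    ny = max(1, int(round(Ly / delta)))
    dx, dy = Lx / nx, Ly / ny
    cutoff = KERNEL_CUTOFF_XI * xi
    mx, my = int(np.ceil(cutoff / dx)) + 1, int(np.ceil(cutoff / dy)) + 1
    pos = config.positions
    base_i = np.floor(pos[:, 0] / dx).astype(int)
    base_j = np.floor(pos[:, 1] / dy).astype(int)
    field_flat = np.zeros(nx * ny)
    per_x, per_y = config.periodic
    for di in range(-mx, mx + 1):
        gi = base_i + di
        gx = gi * dx
        if per_x:
            gi = gi % nx
        else:
            ok_x = (gi >= 0) & (gi < nx)
        rx = gx - pos[:, 0]
        for dj in range(-my, my + 1):
            gj = base_j + dj
            gy = gj * dy
            if per_y:
                gj = gj % ny
            ry = gy - pos[:, 1]
            r2 = rx * rx + ry * ry
            contrib = _kernel(r2, xi) * w
            idx = gi * ny + gj
            if not per_x or not per_y:
                ok = np.ones(config.n, dtype=bool)
                if not per_x:
                    ok &= ok_x
                if not per_y:
                    ok &= (gj >= 0) & (gj < ny)
                idx, contrib = idx[ok], contrib[ok]
            field_flat += np.bincount(idx, weights=contrib,
                                      minlength=nx * ny)
    values = field_flat.reshape(nx, ny)
    if renormalize:
        values = values / KERNEL_MASS
    return ScalarField2D(values, config.box, xi, config.periodic, kind)


def order_density_field(config: PointConfiguration2D,
                        phi: np.ndarray | None = None,
                        xi: float = XI_DEFAULT,
                        delta: float = GRID_SPACING_DEFAULT,
                        **kw) -> ScalarField2D:
    """Coarse-grained orientational-order density phi_bar(r)."""
    if phi is None:
        phi = compute_phi(config).phi
    return coarse_grain(config, phi, xi, delta, kind="phi_bar", **kw)


def number_density_field(config: PointConfiguration2D,
                         xi: float = XI_DEFAULT,
                         delta: float = GRID_SPACING_DEFAULT,
                         **kw) -> ScalarField2D:
    """Coarse-grained number density rho_bar(r)."""
    return coarse_grain(config, np.ones(config.n), xi, delta,
                        kind="rho_bar", **kw)


def bulk_levels(config: PointConfiguration2D,
                phi: np.ndarray | None = None) -> tuple[float, float]:
    """Box-mean levels (phi_bar, rho_bar) of a homogeneous bulk sample.

    The box mean of the coarse-grained field is the kernel mass times the
    summed weight per area, so no gridding is needed.
    """
    if phi is None:
        phi = compute_phi(config).phi
    return (KERNEL_MASS * float(np.sum(phi)) / config.area,
            KERNEL_MASS * config.n / config.area)


@dataclass
class RadialProfile:
    """Angle-averaged profiles around a center.

    ``mean_phi``/``mean_rho`` average the coarse-grained fields over grid
    points per annulus; ``ratio`` divides the accumulated phi_bar by the
    accumulated rho_bar (numerator and denominator averaged separately).
    ``particle_phi`` is the raw particle-based mean of phi per annulus,
    which retains the granularity oscillations the ratio removes.
    """

    r: np.ndarray
    mean_phi: np.ndarray
    mean_rho: np.ndarray
    ratio: np.ndarray
    counts: np.ndarray          # grid points per bin summed over frames
    particle_phi: np.ndarray
    particle_counts: np.ndarray
    center: tuple[float, float]


def radial_profile(frames, center: Sequence[float],
                   bin_width: float = 0.25, r_max: float | None = None,
                   phi_values: Sequence[np.ndarray] | None = None,
                   xi: float = XI_DEFAULT,
                   delta: float = GRID_SPACING_DEFAULT) -> RadialProfile:
    """Radial order profiles <phi_bar(r)>, <rho_bar(r)>, their ratio, and
    the particle-based <phi(r)> around a fixed center.

    ``frames`` is an Ensemble, list of configurations, or one configuration.
    r_max must not exceed min(box)/2 (annuli would self-overlap under PBC).
    """
    if isinstance(frames, PointConfiguration2D):
        frames = [frames]
    elif isinstance(frames, Ensemble):
        frames = list(frames)
    box = frames[0].box
    if r_max is None:
        r_max = min(box) / 2.0
    if r_max > min(box) / 2.0:
        raise ValueError("r_max must be <= min(box)/2 under PBC")
    nbins = int(np.ceil(r_max / bin_width))
    c = np.asarray(center, dtype=float)
    sum_phi = np.zeros(nbins)
    sum_rho = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=int)
    p_sum = np.zeros(nbins)
    p_cnt = np.zeros(nbins, dtype=int)
    for fi, cfg in enumerate(frames):
        phi = (np.asarray(phi_values[fi], dtype=float) if phi_values
               is not None else compute_phi(cfg).phi)
        fphi = coarse_grain(cfg, phi, xi, delta, kind="phi_bar")
        frho = coarse_grain(cfg, np.ones(cfg.n), xi, delta, kind="rho_bar")
        ax, ay = fphi.grid_axes()
        gx, gy = np.meshgrid(ax, ay, indexing="ij")
        rel = minimum_image(
            np.stack([gx - c[0], gy - c[1]], axis=-1), box, cfg.periodic)
        r = np.hypot(rel[..., 0], rel[..., 1]).ravel()
        sel = r < r_max
        which = (r[sel] / bin_width).astype(int)
        sum_phi += np.bincount(which, weights=fphi.values.ravel()[sel],
                               minlength=nbins)
        sum_rho += np.bincount(which, weights=frho.values.ravel()[sel],
                               minlength=nbins)
        counts += np.bincount(which, minlength=nbins)
        relp = minimum_image(cfg.positions - c, box, cfg.periodic)
        rp = np.hypot(relp[:, 0], relp[:, 1])
        selp = rp < r_max
        whichp = (rp[selp] / bin_width).astype(int)
        p_sum += np.bincount(whichp, weights=phi[selp], minlength=nbins)
        p_cnt += np.bincount(whichp, minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_phi = np.where(counts > 0, sum_phi / np.maximum(counts, 1),
                            np.nan)
        mean_rho = np.where(counts > 0, sum_rho / np.maximum(counts, 1),
                            np.nan)
        ratio = np.where((counts > 0) & (sum_rho > 0),
                         sum_phi / np.where(sum_rho > 0, sum_rho, 1.0),
                         np.nan)
        particle_phi = np.where(p_cnt > 0, p_sum / np.maximum(p_cnt, 1),
                                np.nan)
    centers = (np.arange(nbins) + 0.5) * bin_width
    return RadialProfile(centers, mean_phi, mean_rho, ratio, counts,
                         particle_phi, p_cnt, (float(c[0]), float(c[1])))


def hydrophobic_thickness(config3d) -> float:
    """Hydrophobic thickness: mean z of upper first-tail beads minus mean z
    of lower first-tail beads (nm)."""
    up = config3d.select(leaflet="upper", role="first_tail")
    lo = config3d.select(leaflet="lower", role="first_tail")
    if not up.any() or not lo.any():
        raise ValueError("both leaflets must contain first_tail beads")
    return float(config3d.positions[up, 2].mean()
                 - config3d.positions[lo, 2].mean())


def area_per_lipid(config, leaflet: str | None = None) -> float:
    """Leaflet box area divided by the number of lipids in the leaflet.

    For a 2D configuration every particle counts as one lipid of the
    projected leaflet; for a 3D bilayer, ``leaflet`` selects which side
    (lipids counted via head beads, falling back to distinct lipid ids).
    """
    if isinstance(config, PointConfiguration2D):
        return config.area / config.n
    if leaflet is None:
        raise ValueError("leaflet required for a 3D configuration")
    mask = config.select(leaflet=leaflet)
    n_lip = np.unique(config.lipid_ids[mask]).size
    if n_lip == 0:
        raise ValueError(f"no lipids in leaflet {leaflet!r}")
    return config.box[0] * config.box[1] / n_lip
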