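"""Instantaneous order-disorder interface: level-set extraction from the
coarse-grained order density, and conversion to height h(x) or radius
R(theta) functions.

The interface is the iso-contour phi_bar(s) = (phi_d + phi_o)/2, the
midpoint of the bulk disordered and ordered levels.  Contours come from
marching squares (scikit-image) on a wrap-padded grid and are stitched
across the periodic boundaries; each stitched curve is classified as
closed (a loop) or spanning (connects to its own periodic image along one
axis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import measure

from .configuration import minimum_image
from .constants import PHI_DISORDERED, PHI_ORDERED
from .order import ScalarField2D

__all__ = [
    "InterfaceCurve", "HeightFunction", "RadiusFunction",
    "extract_interface", "height_function", "radius_function", "perimeter",
]

log = logging.getLogger("premelt")

#: Curves with fewer vertices are dropped as short-lived bubbles of
#: disorder, which a too-small coarse-graining width would proliferate.
MIN_VERTICES_DEFAULT = 6


@dataclass
class InterfaceCurve:
    """One extracted iso-contour.

    Vertices are an ordered polyline in continuous (unwrapped) coordinates;
    a spanning curve's last vertex sits one box image away from its first
    along ``spanning_axis``.
    """

    vertices: np.ndarray           # (n, 2) nm, unwrapped
    closed: bool
    level: float
    box: tuple[float, float]
    spanning_axis: int | None = None     # 0=x, 1=y for open curves
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be (n, 2)")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]


@dataclass
class HeightFunction:
    """Single-valued interface height on a uniform grid along one box axis."""

    x: np.ndarray                 # bin centers along the spanning axis (nm)
    h: np.ndarray                 # mean transverse coordinate per bin (nm)
    length: float                 # box length along the spanning axis
    n_overhang_points: int = 0    # vertices folded from repeat passes
    n_empty_bins: int = 0


@dataclass
class RadiusFunction:
    """Interface radius R(theta) about a center on a uniform angle grid."""

    theta: np.ndarray
    R: np.ndarray
    center: tuple[float, float]
    R0: float                     # mean radius over bins
    n_empty_bins: int = 0


def _match(p: np.ndarray, q: np.ndarray, box, tol: float):
    """Image shift making q coincide with p, or None."""
    d = p - q
    shift = np.round(d / np.asarray(box)) * np.asarray(box)
    if np.max(np.abs(d - shift)) < tol:
        return shift
    return None


def _stitch(segments: list[np.ndarray], box, tol: float):
    """Join open polylines whose endpoints coincide modulo the box."""
    curves = []
    pool = [np.asarray(s, dtype=float) for s in segments]
    while pool:
        cur = pool.pop()
        grown = True
        while grown:
            grown = False
            for i, seg in enumerate(pool):
                for rev in (False, True):
                    s = seg[::-1] if rev else seg
                    shift = _match(cur[-1], s[0], box, tol)
                    if shift is not None:
                        cur = np.vstack([cur, s[1:] + shift])
                        pool.pop(i)
                        grown = True
                        break
                    shift = _match(cur[0], s[-1], box, tol)
                    if shift is not None:
                        cur = np.vstack([s[:-1] + shift, cur])
                        pool.pop(i)
                        grown = True
                        break
                if grown:
                    break
        curves.append(cur)
    return curves


def extract_interface(field: ScalarField2D,
                      phi_d: float = PHI_DISORDERED,
                      phi_o: float = PHI_ORDERED,
                      min_vertices: int = MIN_VERTICES_DEFAULT,
                      frame_id: int = 0) -> list[InterfaceCurve]:
    """Extract the instantaneous interface as the level set
    phi_bar = (phi_d + phi_o)/2.

    Marching-squares contours with linear edge interpolation on the
    wrap-padded grid, stitched across periodic boundaries.  A field
    entirely above or below the level yields an empty list.  Curves
    shorter than ``min_vertices`` are discarded (logged).
    """
    if not phi_d < phi_o:
        raise ValueError("need phi_d < phi_o")
    level = 0.5 * (phi_d + phi_o)
    dx, dy = field.spacing
    padded = np.pad(field.values, ((0, 1), (0, 1)), mode="wrap")
    raw = measure.find_contours(padded, level, fully_connected="low")
    closed_curves: list[np.ndarray] = []
    open_segments: list[np.ndarray] = []
    scale = np.array([dx, dy])
    for contour in raw:
        pts = contour * scale        # rows -> x, cols -> y
        if np.allclose(pts[0], pts[-1]):
            closed_curves.append(pts[:-1])
        else:
            open_segments.append(pts)
    tol = 1e-6 * max(field.box)
    stitched = _stitch(open_segments, field.box, tol)
    curves: list[InterfaceCurve] = []
    n_short = 0
    for pts in closed_curves:
        if pts.shape[0] < max(min_vertices, 3):
            n_short += 1
            continue
        curves.append(InterfaceCurve(pts, True, level, field.box,
                                     frame_id=frame_id))
    for pts in stitched:
        shift = _match(pts[-1], pts[0], field.box, tol)
        if shift is None:
            # dangling fragment (should not occur on a periodic field)
            log.warning("unstitched interface fragment with %d vertices",
                        pts.shape[0])
            continue
        if pts.shape[0] < min_vertices:
            n_short += 1
            continue
        if np.allclose(shift, 0.0):
            curves.append(InterfaceCurve(pts[:-1], True, level, field.box,
                                         frame_id=frame_id))
        else:
            axis = int(np.argmax(np.abs(shift)))
            curves.append(InterfaceCurve(pts[:-1], False, level, field.box,
                                         spanning_axis=axis,
                                         frame_id=frame_id))
    if n_short:
        log.info("discarded %d short-lived bubble contour(s)", n_short)
    return curves


def _fill_empty_bins(values: np.ndarray, filled: np.ndarray) -> int:
    """Fill empty bins in place by periodic linear interpolation; returns
    the number of bins filled."""
    n_empty = int((~filled).sum())
    if n_empty == 0:
        return 0
    if not filled.any():
        raise ValueError("no populated bins")
    n = values.size
    idx = np.arange(n)
    src = idx[filled]
    # periodic linear interpolation via extended sample points
    src_ext = np.concatenate([src - n, src, src + n])
    val_ext = np.tile(values[filled], 3)
    values[~filled] = np.interp(idx[~filled], src_ext, val_ext)
    return n_empty


def height_function(curve: InterfaceCurve, axis: int = 1,
                    n_bins: int = 128) -> HeightFunction:
    """Reduce a spanning curve to a single-valued height profile.

    Vertices are binned by their coordinate along the spanning ``axis``;
    the height per bin is the mean transverse coordinate (overhang loops
    are folded by this averaging and the folded vertex count recorded).
    Empty bins are filled by periodic linear interpolation.
    """
    if curve.closed or curve.spanning_axis != axis:
        raise ValueError(
            "curve does not span the requested axis; closed curves should "
            "use radius_function")
    L = curve.box[axis]
    Lt = curve.box[1 - axis]
    s = np.mod(curve.vertices[:, axis], L)
    t = curve.vertices[:, 1 - axis]
    # fold transverse coordinates to the branch nearest the circular mean
    ang = 2 * np.pi * t / Lt
    mean_t = np.angle(np.exp(1j * ang).mean()) * Lt / (2 * np.pi)
    t = mean_t + minimum_image((t - mean_t)[:, None], (Lt,), (True,))[:, 0]
    which = np.minimum((s / L * n_bins).astype(int), n_bins - 1)
    sums = np.bincount(which, weights=t, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    # count overhang vertices: entries in repeat visits of a bin along the
    # curve (contiguous runs of vertex indices, circular adjacency)
    n_over = 0
    runs_per_bin: dict[int, int] = {}
    prev_bin = None
    first_bin = None
    for b in which:
        if b != prev_bin:
            runs_per_bin[b] = runs_per_bin.get(b, 0) + 1
            prev_bin = b
            if first_bin is None:
                first_bin = b
    if first_bin is not None and prev_bin == first_bin and \
            runs_per_bin.get(first_bin, 0) > 1:
        runs_per_bin[first_bin] -= 1  # curve wraps through its start bin
    for b, nruns in runs_per_bin.items():
        if nruns > 1:
            n_over += int(counts[b] * (nruns - 1) / nruns)
    h = np.full(n_bins, np.nan)
    filled = counts > 0
    h[filled] = sums[filled] / counts[filled]
    n_empty = _fill_empty_bins(h, filled)
    if n_empty:
        log.info("height_function: %d of %d bins interpolated",
                 n_empty, n_bins)
    x = (np.arange(n_bins) + 0.5) * L / n_bins
    return HeightFunction(x, h, L, n_over, n_empty)


def radius_function(curve: InterfaceCurve, center: Sequence[float],
                    n_bins: int = 128) -> RadiusFunction:
    """Reduce a closed curve to R(theta) about a center strictly inside.

    Vertices are binned by polar angle; R per bin is the mean radial
    distance and R0 the mean over bins.  Errors if the center lies outside
    the curve or the winding number about the center is not +-1.
    """
    if not curve.closed:
        raise ValueError("radius_function requires a closed curve")
    c = np.asarray(center, dtype=float)
    rel = minimum_image(curve.vertices - c, curve.box, (True, True))
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    r = np.hypot(rel[:, 0], rel[:, 1])
    if np.any(r <= 0):
        raise ValueError("center coincides with a contour vertex")
    dtheta = np.diff(np.concatenate([theta, theta[:1]]))
    dtheta = (dtheta + np.pi) % (2 * np.pi) - np.pi
    winding = int(np.round(dtheta.sum() / (2 * np.pi)))
    if winding == 0:
        raise ValueError("center lies outside the curve (winding number 0)")
    if abs(winding) != 1:
        raise ValueError(f"winding number {winding} about center; expected "
                         "a simple loop")
    which = np.minimum((np.mod(theta, 2 * np.pi) / (2 * np.pi)
                        * n_bins).astype(int), n_bins - 1)
    sums = np.bincount(which, weights=r, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    R = np.full(n_bins, np.nan)
    filled = counts > 0
    R[filled] = sums[filled] / counts[filled]
    n_empty = _fill_empty_bins(R, filled)
    grid = (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
    return RadiusFunction(grid, R, (float(c[0]), float(c[1])),
                          float(R.mean()), n_empty)


def perimeter(curve: InterfaceCurve) -> float:
    """Curve length: sum of minimum-image segment lengths (closing segment
    included for closed curves)."""
    if curve.n_vertices < 2:
        raise ValueError("perimeter needs at least 2 vertices")
    v = curve.vertices
    seg = np.diff(v, axis=0)
    total = float(np.linalg.norm(
        minimum_image(seg, curve.box, (True, True)), axis=1).sum())
    if curve.closed:
        total += float(np.linalg.norm(
            minimum_image(v[0] - v[-1], curve.box, (True, True))))
    return total
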