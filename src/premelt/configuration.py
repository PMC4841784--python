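"""Core configuration containers: 2D leaflet projections, 3D bilayers,
and frame ensembles, with periodic-boundary helpers.

Conventions: coordinates are 0-based, boxes half-open [0, L); distances use
the minimum-image convention on periodic axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "PointConfiguration2D",
    "BilayerConfiguration3D",
    "Ensemble",
    "minimum_image",
    "wrap_positions",
]

BEAD_ROLES = ("head", "first_tail", "tail_end", "other")
LEAFLETS = ("upper", "lower")


def wrap_positions(positions: np.ndarray, box: Sequence[float],
                   periodic: Sequence[bool]) -> np.ndarray:
    """Wrap coordinates into [0, L) on each periodic axis."""
    out = np.array(positions, dtype=float, copy=True)
    for ax, (L, per) in enumerate(zip(box, periodic)):
        if per:
            w = np.mod(out[:, ax], L)
            # np.mod can return exactly L for tiny negative inputs
            out[:, ax] = np.where(w >= L, 0.0, w)
    return out


def minimum_image(delta: np.ndarray, box: Sequence[float],
                  periodic: Sequence[bool] = (True, True)) -> np.ndarray:
    """Minimum-image displacement vectors for a periodic box."""
    out = np.array(delta, dtype=float, copy=True)
    for ax, (L, per) in enumerate(zip(box, periodic)):
        if per:
            out[..., ax] -= L * np.round(out[..., ax] / L)
    return out


@dataclass
class PointConfiguration2D:
    """One frame of projected tail-end particle positions in a periodic box.

    Parameters
    ----------
    positions : (N, 2) array, nm
        Particle coordinates; wrapped into [0, Lx) x [0, Ly) on periodic
        axes at construction.
    box : (Lx, Ly)
        Box edge lengths in nm, both > 0.
    periodic : (bool, bool)
        Periodicity flags per axis.
    frame_id : int
        Frame index within a trajectory or ensemble.
    metadata : dict
        Free-form provenance (generator ground truth, source file, ...).
    """

    positions: np.ndarray
    box: tuple[float, float]
    periodic: tuple[bool, bool] = (True, True)
    frame_id: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError(f"positions must be (N, 2); got {pos.shape}")
        if pos.shape[0] < 1:
            raise ValueError("configuration must contain at least one particle")
        box = (float(self.box[0]), float(self.box[1]))
        if box[0] <= 0 or box[1] <= 0:
            raise ValueError(f"box lengths must be positive; got {box}")
        self.box = box
        self.periodic = (bool(self.periodic[0]), bool(self.periodic[1]))
        self.positions = wrap_positions(pos, box, self.periodic)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def area(self) -> float:
        return self.box[0] * self.box[1]

    def displacement(self, other_positions: np.ndarray,
                     reference: np.ndarray) -> np.ndarray:
        """Minimum-image displacements other_positions - reference."""
        return minimum_image(np.asarray(other_positions) - np.asarray(reference),
                             self.box, self.periodic)

    def shifted(self, delta: Sequence[float]) -> "PointConfiguration2D":
        """Rigidly translated copy (re-wrapped)."""
        return PointConfiguration2D(self.positions + np.asarray(delta, float),
                                    self.box, self.periodic, self.frame_id,
                                    dict(self.metadata))


@dataclass
class BilayerConfiguration3D:
    """Coarse-grained bilayer frame with per-bead role and leaflet labels.

    Each lipid is expected to contribute exactly one bead per assigned role
    (head / first_tail / tail_end); beads outside the role mapping carry the
    role 'other'.
    """

    positions: np.ndarray          # (N, 3) nm
    roles: np.ndarray              # (N,) str from BEAD_ROLES
    leaflets: np.ndarray           # (N,) str from LEAFLETS
    lipid_ids: np.ndarray          # (N,) int, groups beads into lipids
    box: tuple[float, float, float]
    frame_id: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError(f"positions must be (N, 3); got {pos.shape}")
        self.positions = pos
        self.roles = np.asarray(self.roles)
        self.leaflets = np.asarray(self.leaflets)
        self.lipid_ids = np.asarray(self.lipid_ids)
        n = pos.shape[0]
        for name, arr in (("roles", self.roles), ("leaflets", self.leaflets),
                          ("lipid_ids", self.lipid_ids)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        bad = set(np.unique(self.roles)) - set(BEAD_ROLES)
        if bad:
            raise ValueError(f"unknown bead roles: {sorted(bad)}")
        bad = set(np.unique(self.leaflets)) - set(LEAFLETS)
        if bad:
            raise ValueError(f"unknown leaflet labels: {sorted(bad)}")
        self.box = tuple(float(b) for b in self.box)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def select(self, leaflet: str | None = None,
               role: str | None = None) -> np.ndarray:
        """Boolean mask of beads matching the given leaflet and/or role."""
        mask = np.ones(self.n, dtype=bool)
        if leaflet is not None:
            if leaflet not in LEAFLETS:
                raise ValueError(f"leaflet must be one of {LEAFLETS}")
            mask &= self.leaflets == leaflet
        if role is not None:
            if role not in BEAD_ROLES:
                raise ValueError(f"role must be one of {BEAD_ROLES}")
            mask &= self.roles == role
        return mask


@dataclass
class Ensemble:
    """Ordered sequence of frames sharing box dimensions and periodicity."""

    frames: list
    temperature: float | None = None   # K
    source: str = ""

    def __post_init__(self) -> None:
        self.frames = list(self.frames)
        if not self.frames:
            raise ValueError("ensemble must contain at least one frame")
        first = self.frames[0]
        for fr in self.frames[1:]:
            if tuple(fr.box) != tuple(first.box):
                raise ValueError("all frames must share box dimensions")
            if getattr(fr, "periodic", None) != getattr(first, "periodic", None):
                raise ValueError("all frames must share periodicity")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator:
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]
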