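"""Readers and writers: delimited point files, GRO coordinate files, and
leaflet projection.

The GRO reader/writer implements the fixed-column GROMACS coordinate layout
(positions in nm, 3 decimals) and assigns bead roles from a bead-name
mapping and leaflets from head-bead height relative to the bilayer
midplane (median head z).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .configuration import (BilayerConfiguration3D, PointConfiguration2D)

__all__ = [
    "read_points", "write_points", "read_gro", "write_gro",
    "project_leaflet", "MARTINI_DPPC_ROLES", "SYNTHETIC_ROLES",
]

log = logging.getLogger("premelt")

#: Bead-name -> role mapping for coarse-grained DPPC (one chain tracked so
#: each lipid contributes exactly one bead per role).
MARTINI_DPPC_ROLES: dict[str, str] = {
    "NC3": "head", "C1A": "first_tail", "C4A": "tail_end",
}

#: Mapping used by the package's own synthetic bilayer writer.
SYNTHETIC_ROLES: dict[str, str] = {
    "HEAD": "head", "TAIL1": "first_tail", "TAILE": "tail_end",
}


class PointsParseError(ValueError):
    """Malformed delimited points file."""


class GroFormatError(ValueError):
    """Malformed GRO file."""


def read_points(path, box: Sequence[float],
                periodic: Sequence[bool] = (True, True),
                skip_header: bool = False,
                frame_id: int = 0) -> PointConfiguration2D:
    """Read one particle per row (x y [extra...]) from delimited text.

    Whitespace- or comma-separated; lines starting with '#' are comments.
    Columns beyond the first two are ignored (with a logged notice).
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    extra_cols = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if skip_header and not rows and lineno == 1:
                continue
            fields = line.replace(",", " ").split()
            if len(fields) < 2:
                raise PointsParseError(
                    f"{path}:{lineno}: expected at least 2 numeric columns")
            try:
                x, y = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise PointsParseError(
                    f"{path}:{lineno}: non-numeric value in row: {line!r}"
                ) from exc
            extra_cols = max(extra_cols, len(fields) - 2)
            rows.append((x, y))
    if not rows:
        raise PointsParseError(f"{path}: no particle rows found")
    if extra_cols:
        log.info("read_points(%s): ignored %d extra column(s) per row",
                 path, extra_cols)
    return PointConfiguration2D(np.array(rows), tuple(box),
                                tuple(periodic), frame_id)


def write_points(config: PointConfiguration2D, path,
                 header: bool = True) -> None:
    """Write a configuration as whitespace-delimited x y rows."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# x y  box {config.box[0]:.6f} {config.box[1]:.6f}\n")
        for x, y in config.positions:
            fh.write(f"{x:.6f} {y:.6f}\n")


def _assign_leaflets(positions: np.ndarray, roles: np.ndarray,
                     lipid_ids: np.ndarray) -> np.ndarray:
    """Leaflet labels from each lipid's head-bead z vs the median head z."""
    head = roles == "head"
    if not head.any():
        raise GroFormatError("no head beads found; cannot assign leaflets")
    midplane = float(np.median(positions[head, 2]))
    leaflets = np.empty(positions.shape[0], dtype=object)
    head_z = {}
    for lid, z in zip(lipid_ids[head], positions[head, 2]):
        head_z[int(lid)] = float(z)
    for i, lid in enumerate(lipid_ids):
        z = head_z.get(int(lid))
        if z is None:
            # lipid without a mapped head bead: fall back to the bead's own z
            z = positions[i, 2]
        leaflets[i] = "upper" if z > midplane else "lower"
    return leaflets.astype(str)


def read_gro(path, role_map: Mapping[str, str] | None = None,
             frame_id: int = 0) -> BilayerConfiguration3D:
    """Read a GRO coordinate file into a bilayer configuration.

    ``role_map`` maps bead (atom) names to roles head/first_tail/tail_end;
    unmapped names get role 'other' and are reported once in a warning.
    Leaflets are assigned by comparing each lipid's head-bead z to the
    bilayer midplane (median of all head-bead z).
    """
    path = Path(path)
    if role_map is None:
        role_map = {**SYNTHETIC_ROLES, **MARTINI_DPPC_ROLES}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise GroFormatError(f"{path}: file too short for GRO format")
    try:
        natoms = int(lines[1].strip())
    except ValueError as exc:
        raise GroFormatError(f"{path}:2: atom count is not an integer") from exc
    if len(lines) < 2 + natoms + 1:
        raise GroFormatError(
            f"{path}: truncated: expected {natoms} atom records plus a box "
            f"line, file ends at line {len(lines)}")
    positions = np.empty((natoms, 3))
    names: list[str] = []
    resids = np.empty(natoms, dtype=int)
    for i in range(natoms):
        lineno = 3 + i
        line = lines[2 + i]
        if len(line) < 44:
            raise GroFormatError(
                f"{path}:{lineno}: atom record shorter than fixed-column "
                f"width (44 chars)")
        try:
            resids[i] = int(line[0:5])
            names.append(line[10:15].strip())
            positions[i] = [float(line[20:28]), float(line[28:36]),
                            float(line[36:44])]
        except ValueError as exc:
            raise GroFormatError(
                f"{path}:{lineno}: malformed fixed columns: {line!r}") from exc
    box_fields = lines[2 + natoms].split()
    if len(box_fields) < 3:
        raise GroFormatError(f"{path}:{3 + natoms}: malformed box line")
    box = tuple(float(v) for v in box_fields[:3])

    roles = np.array([role_map.get(nm, "other") for nm in names])
    unknown = sorted({nm for nm in names if nm not in role_map})
    if unknown:
        warnings.warn(
            f"read_gro({path.name}): bead names absent from role mapping "
            f"treated as 'other': {unknown}", stacklevel=2)
    return BilayerConfiguration3D(positions, roles, leaflets=_assign_leaflets(
        positions, roles, resids), lipid_ids=resids, box=box,
        frame_id=frame_id)


def write_gro(config: BilayerConfiguration3D, path,
              title: str = "premelt bilayer",
              name_map: Mapping[str, str] | None = None) -> None:
    """Write a bilayer configuration in GRO fixed-column format."""
    if name_map is None:
        name_map = {v: k for k, v in SYNTHETIC_ROLES.items()}
        name_map.setdefault("other", "OTHER")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{title}\n{config.n:5d}\n")
        for i in range(config.n):
            resid = int(config.lipid_ids[i]) % 100000
            name = name_map.get(str(config.roles[i]), "OTHER")[:5]
            x, y, z = config.positions[i]
            fh.write(f"{resid:5d}{'LIP':<5s}{name:>5s}{(i + 1) % 100000:5d}"
                     f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
        fh.write(f"{config.box[0]:10.5f}{config.box[1]:10.5f}"
                 f"{config.box[2]:10.5f}\n")


def project_leaflet(config: BilayerConfiguration3D, leaflet: str,
                    role: str = "tail_end") -> PointConfiguration2D:
    """Project the selected beads of one leaflet onto the box xy-plane."""
    if role not in ("first_tail", "tail_end"):
        raise ValueError("role must be 'first_tail' or 'tail_end'")
    mask = config.select(leaflet=leaflet, role=role)
    if not mask.any():
        raise ValueError(f"no beads with role {role!r} in leaflet {leaflet!r}")
    return PointConfiguration2D(config.positions[mask, :2],
                                box=config.box[:2], periodic=(True, True),
                                frame_id=config.frame_id,
                                metadata={"leaflet": leaflet, "role": role})
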