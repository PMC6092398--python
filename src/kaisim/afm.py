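"""Simulated AFM images from atomic coordinates.

The sample surface is a hard-sphere height map: each atom contributes a
spherical cap, and the surface is the pointwise maximum over atoms above a
flat substrate at height zero.  The imaging probe is a sphere-capped cone
(default apex radius 0.5 nm, half-angle 10 degrees); the simulated image is
the grayscale morphological dilation of the surface by the inverted tip,
image(x) = max_u [surface(u) - tip(x - u)], which reproduces the geometric
tip-convolution broadening of AFM topographs.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import grey_dilation

__all__ = [
    "AtomSet",
    "TipModel",
    "HeightMap",
    "sample_surface",
    "dilate_with_tip",
    "read_structure",
    "write_heightmap",
    "read_heightmap",
]

#: van der Waals radii (nm) for common protein elements.
VDW_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "SE": 0.190,
    "FE": 0.194,
    "ZN": 0.139,
    "MG": 0.173,
}
DEFAULT_RADIUS_NM = 0.170


@dataclass
class AtomSet:
    """Hard-sphere atoms: positions in nm and per-atom radii in nm."""

    positions: np.ndarray  # (n, 3)
    radii: np.ndarray  # (n,)
    labels: np.ndarray | None = None  # optional residue/chain labels

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        if self.radii.shape[0] != self.positions.shape[0]:
            raise ValueError("positions and radii length mismatch")
        if self.positions.shape[0] and not (self.radii > 0).all():
            raise ValueError("atom radii must be positive")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def translated(self, dx: float = 0.0, dy: float = 0.0, dz: float = 0.0) -> "AtomSet":
        return AtomSet(self.positions + np.array([dx, dy, dz]), self.radii, self.labels)


@dataclass(frozen=True)
class TipModel:
    """Sphere-capped conical probe.

    ``cone_half_angle_deg`` is measured from the probe axis; when
    ``angle_is_full`` the stated angle is interpreted as the full opening
    angle and halved.  The spherical apex continues tangentially into the
    cone at lateral distance R*cos(theta).
    """

    apex_radius: float = 0.5  # nm
    cone_half_angle_deg: float = 10.0
    angle_is_full: bool = False

    def __post_init__(self):
        if not self.apex_radius > 0:
            raise ValueError("apex_radius must be positive")
        half = self.half_angle_rad
        if not 0 < half < math.pi / 2:
            raise ValueError("cone half-angle must be in (0, 90) degrees")

    @property
    def half_angle_rad(self) -> float:
        angle = self.cone_half_angle_deg
        if self.angle_is_full:
            angle /= 2.0
        return math.radians(angle)

    def profile(self, d) -> np.ndarray:
        """Tip height above its apex at lateral distance ``d`` (nm).

        Spherical cap for d <= R*cos(theta); tangent cone beyond, with slope
        cot(theta).
        """
        d = np.abs(np.asarray(d, dtype=float))
        r = self.apex_radius
        theta = self.half_angle_rad
        d_t = r * math.cos(theta)
        sphere = r - np.sqrt(np.clip(r * r - d * d, 0.0, None))
        y_t = r * (1.0 - math.sin(theta))
        cone = y_t + (d - d_t) / math.tan(theta)
        return np.where(d <= d_t, sphere, cone)


@dataclass
class HeightMap:
    """Raster of surface heights (nm) on a square-pixel grid."""

    origin: tuple[float, float]  # (x0, y0) of pixel (0, 0) center, nm
    pixel_size: float  # nm
    heights: np.ndarray  # (ny, nx)

    def __post_init__(self):
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        self.heights = np.asarray(self.heights, dtype=float)
        if (self.heights < 0).any():
            raise ValueError("heights must not go below the substrate (0)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape


def sample_surface(
    atoms: AtomSet,
    pixel_size: float = 0.1,
    padding: float = 1.0,
    grid_origin: tuple[float, float] | None = None,
    grid_shape: tuple[int, int] | None = None,
) -> HeightMap:
    """Hard-sphere height map of an atom set.

    h(x, y) = max over atoms with lateral distance d <= r of
    z + sqrt(r^2 - d^2), clipped at the substrate plane z = 0.  The grid spans
    the atoms' lateral extent plus ``padding`` nm unless an explicit origin
    and shape are given.
    """
    if len(atoms) == 0:
        raise ValueError("empty atom set")
    pos, rad = atoms.positions, atoms.radii
    if grid_origin is None or grid_shape is None:
        x0 = pos[:, 0].min() - rad.max() - padding
        y0 = pos[:, 1].min() - rad.max() - padding
        x1 = pos[:, 0].max() + rad.max() + padding
        y1 = pos[:, 1].max() + rad.max() + padding
        nx = int(np.ceil((x1 - x0) / pixel_size)) + 1
        ny = int(np.ceil((y1 - y0) / pixel_size)) + 1
    else:
        x0, y0 = grid_origin
        ny, nx = grid_shape
    heights = np.zeros((ny, nx))
    for (ax, ay, az), r in zip(pos, rad):
        # local patch of pixels the sphere can touch
        i_lo = max(0, int(np.floor((ay - r - y0) / pixel_size)))
        i_hi = min(ny - 1, int(np.ceil((ay + r - y0) / pixel_size)))
        j_lo = max(0, int(np.floor((ax - r - x0) / pixel_size)))
        j_hi = min(nx - 1, int(np.ceil((ax + r - x0) / pixel_size)))
        if i_lo > i_hi or j_lo > j_hi:
            continue
        ys = y0 + np.arange(i_lo, i_hi + 1) * pixel_size
        xs = x0 + np.arange(j_lo, j_hi + 1) * pixel_size
        d2 = (xs[None, :] - ax) ** 2 + (ys[:, None] - ay) ** 2
        cap = az + np.sqrt(np.clip(r * r - d2, 0.0, None))
        cap = np.where(d2 <= r * r, cap, -np.inf)
        patch = heights[i_lo : i_hi + 1, j_lo : j_hi + 1]
        np.maximum(patch, cap, out=patch)
    heights = np.clip(heights, 0.0, None)
    return HeightMap(origin=(x0, y0), pixel_size=pixel_size, heights=heights)


def dilate_with_tip(surface: HeightMap, tip: TipModel) -> HeightMap:
    """Grayscale dilation of the surface by the inverted tip shape.

    image(x) = max_u [surface(u) - tipshape(x - u)] >= surface(x) pointwise
    (the tip profile is zero at its apex).  The tip footprint is truncated
    where its height exceeds the surface relief; if the footprint exceeds the
    grid, the image near the borders uses substrate padding and a warning is
    emitted.
    """
    h = surface.heights
    relief = float(h.max() - h.min())
    px = surface.pixel_size
    theta = tip.half_angle_rad
    # lateral reach where tip profile first exceeds the relief
    reach = tip.apex_radius * math.cos(theta) + relief * math.tan(theta)
    half = max(1, int(np.ceil(reach / px)))
    if 2 * half + 1 > max(h.shape):
        warnings.warn(
            "tip footprint exceeds the grid; borders assume substrate padding",
            stacklevel=2,
        )
    offsets = np.arange(-half, half + 1) * px
    d = np.hypot(offsets[None, :], offsets[:, None])
    structure = -tip.profile(d)
    dilated = grey_dilation(h, structure=structure, mode="constant", cval=0.0)
    dilated = np.maximum(dilated, h)  # guard round-off at truncation edge
    return HeightMap(origin=surface.origin, pixel_size=px, heights=dilated)


def read_structure(
    path: str | Path,
    chains: list[str] | None = None,
    exclude_residues: tuple[int, int] | None = None,
    per_residue: bool = False,
) -> AtomSet:
    """Read a PDB-format file into an AtomSet (coordinates in nm).

    Coordinates are converted Angstrom -> nm; radii default to element van
    der Waals values.  ``chains`` keeps only the named chains;
    ``exclude_residues=(lo, hi)`` drops that residue-number range inclusive
    (e.g. to truncate the C-terminal tentacles).  ``per_residue`` collapses
    each residue to a single coarse sphere at its centroid.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse structure file {path}: {exc}") from exc
    positions, radii, labels = [], [], []
    model = structure[0]
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for residue in chain:
            seqid = residue.seqid.num
            if exclude_residues is not None:
                lo, hi = exclude_residues
                if lo <= seqid <= hi:
                    continue
            res_pos = []
            for atom in residue:
                p = atom.pos
                res_pos.append((p.x / 10.0, p.y / 10.0, p.z / 10.0))
                if not per_residue:
                    elem = atom.element.name.upper()
                    radii.append(VDW_RADII_NM.get(elem, DEFAULT_RADIUS_NM))
                    labels.append(f"{chain.name}:{seqid}")
            if per_residue and res_pos:
                positions.append(np.mean(res_pos, axis=0))
                radii.append(0.33)  # coarse residue sphere
                labels.append(f"{chain.name}:{seqid}")
            elif not per_residue:
                positions.extend(res_pos)
    if not positions:
        raise ValueError(f"no atoms read from {path}")
    return AtomSet(
        positions=np.array(positions),
        radii=np.array(radii),
        labels=np.array(labels),
    )


def write_heightmap(hm: HeightMap, path: str | Path) -> None:
    """Plain-text raster: header lines then the height matrix."""
    with open(path, "w") as fh:
        fh.write(f"# origin_x_nm\t{hm.origin[0]:.6g}\n")
        fh.write(f"# origin_y_nm\t{hm.origin[1]:.6g}\n")
        fh.write(f"# pixel_nm\t{hm.pixel_size:.6g}\n")
        np.savetxt(fh, hm.heights, fmt="%.6g", delimiter="\t")


def read_heightmap(path: str | Path) -> HeightMap:
    meta = {}
    with open(path) as fh:
        for _ in range(3):
            key, val = fh.readline().lstrip("# ").split("\t")
            meta[key.strip()] = float(val)
        heights = np.loadtxt(fh, delimiter="\t")
    return HeightMap(
        origin=(meta["origin_x_nm"], meta["origin_y_nm"]),
        pixel_size=meta["pixel_nm"],
        heights=np.atleast_2d(heights),
    )
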