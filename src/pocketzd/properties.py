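"""Physicochemical property channels on surface points and their encoding
as rotation-invariant descriptors.

Channels: binary shape, screened-Coulomb electrostatic potential,
nearest-residue hydropathy, and ray-visibility concaveness. Signed channels
(electrostatics, hydrophobicity) are split into positive and negative parts
before encoding, giving two concatenated descriptors (144 components at
order 15); unsigned channels give one (72).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .structure import ComplexStructure, SurfacePatch
from .zernike import (
    compute_descriptor,
    descriptor_length,
    voxelize_channels,
)

__all__ = [
    "CHANNELS",
    "SIGNED_CHANNELS",
    "KYTE_DOOLITTLE",
    "PARTIAL_CHARGES",
    "channel_length",
    "electrostatic_potential",
    "hydrophobicity",
    "occupancy_grid",
    "concaveness",
    "encode_channel",
    "encode_patch_channel",
    "compute_patch_descriptors",
    "import_point_values",
]

CHANNELS = ("shape", "ele", "hyd", "conc")
SIGNED_CHANNELS = frozenset({"ele", "hyd"})

# Kyte-Doolittle hydropathy index per residue
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

# simplified per-atom partial charges (elementary charge units):
# ionizable side-chain termini carry the formal charge, backbone N/O a dipole
PARTIAL_CHARGES = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
    ("HIS", "ND1"): 0.25, ("HIS", "NE2"): 0.25,
    ("*", "N"): 0.25, ("*", "O"): -0.25,
}


def channel_length(channel: str, order: int = 15) -> int:
    """Descriptor length contract per channel (72/144 at order 15)."""
    base = descriptor_length(order)
    return 2 * base if channel in SIGNED_CHANNELS else base


def _atom_charge(atom) -> float:
    key = (atom.resname, atom.name)
    if key in PARTIAL_CHARGES:
        return PARTIAL_CHARGES[key]
    return PARTIAL_CHARGES.get(("*", atom.name), 0.0)


def electrostatic_potential(
    structure: ComplexStructure, points: np.ndarray
) -> np.ndarray:
    """Screened Coulomb potential with distance-dependent dielectric 4r.

    phi(p) = sum_i q_i / (4 r_i^2), r_i in angstrom; atoms with no entry in
    the bundled charge table contribute zero (warned once per structure).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    charges = np.array([_atom_charge(a) for a in structure.protein_atoms])
    unknown = {a.resname for a in structure.protein_atoms} - set(KYTE_DOOLITTLE)
    if unknown:
        warnings.warn(f"residues with no charge assignment treated as neutral: "
                      f"{sorted(unknown)}", stacklevel=2)
    coords = structure.protein_coords()
    sel = charges != 0.0
    if not sel.any():
        return np.zeros(len(points))
    d = np.linalg.norm(points[:, None, :] - coords[None, sel, :], axis=2)
    d = np.maximum(d, 1e-6)
    return (charges[sel][None, :] / (4.0 * d * d)).sum(axis=1)


def hydrophobicity(structure: ComplexStructure, points: np.ndarray) -> np.ndarray:
    """Kyte-Doolittle index of the residue owning the nearest protein atom."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    coords = structure.protein_coords()
    scale = np.array(
        [KYTE_DOOLITTLE.get(a.resname, 0.0) for a in structure.protein_atoms]
    )
    if any(a.resname not in KYTE_DOOLITTLE for a in structure.protein_atoms):
        warnings.warn("nonstandard residues assigned hydropathy 0", stacklevel=2)
    _, nearest = cKDTree(coords).query(points, k=1)
    return scale[nearest]


def occupancy_grid(structure: ComplexStructure, spacing: float = 1.0):
    """Boolean occupancy of protein atom spheres, for visibility ray casting.

    Returns (occupied bool array, origin, spacing).
    """
    coords = structure.protein_coords()
    radii = np.array([a.radius() for a in structure.protein_atoms])
    margin = radii.max() + 2 * spacing
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    occ = np.zeros(shape, dtype=bool)
    for c, r in zip(coords, radii):
        imin = np.maximum(np.floor((c - r - lo) / spacing).astype(int), 0)
        imax = np.minimum(np.ceil((c + r - lo) / spacing).astype(int) + 1, shape)
        ax = [lo[d] + spacing * np.arange(imin[d], imax[d]) for d in range(3)]
        d2 = (
            (ax[0][:, None, None] - c[0]) ** 2
            + (ax[1][None, :, None] - c[1]) ** 2
            + (ax[2][None, None, :] - c[2]) ** 2
        )
        occ[imin[0]:imax[0], imin[1]:imax[1], imin[2]:imax[2]] |= d2 <= r * r
    return occ, lo, spacing


def _sphere_directions(n: int) -> np.ndarray:
    """Deterministic near-uniform directions (Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z * z)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def concaveness(
    points: np.ndarray,
    normals: np.ndarray,
    occupancy,
    n_rays: int = 128,
    offset: float = 1.0,
    step: float = 0.5,
) -> np.ndarray:
    """Visibility fraction: rays escaping the occupancy grid unblocked.

    Each point is offset slightly along its outward normal, then ``n_rays``
    uniformly distributed rays are marched until they leave the grid
    (escape) or enter an occupied voxel (blocked). Deep cavity points see
    few escaping directions.
    """
    if n_rays < 32:
        raise ValueError("n_rays must be >= 32")
    occ, lo, spacing = occupancy
    shape = np.array(occ.shape)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    normals = np.atleast_2d(np.asarray(normals, dtype=float))
    start = points + offset * normals

    sidx = np.floor((start - lo) / spacing).astype(int)
    if np.any(sidx < 0) or np.any(sidx >= shape):
        raise ValueError("point outside occupancy grid")

    dirs = _sphere_directions(n_rays)
    extent = float(np.linalg.norm(shape * spacing))
    n_steps = int(np.ceil(extent / step))
    ts = step * (np.arange(n_steps) + 1.0)

    out = np.empty(len(points))
    for i, p in enumerate(start):
        pos = p[None, None, :] + dirs[:, None, :] * ts[None, :, None]
        idx = np.floor((pos - lo) / spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < shape), axis=2)
        hit = np.zeros(idx.shape[:2], dtype=bool)
        ii = np.clip(idx, 0, shape - 1)
        hit[inside] = occ[ii[..., 0], ii[..., 1], ii[..., 2]][inside]
        # a ray escapes if it exits the grid before its first hit
        first_hit = np.where(hit.any(axis=1), hit.argmax(axis=1), n_steps)
        first_exit = np.where((~inside).any(axis=1), (~inside).argmax(axis=1), n_steps)
        out[i] = np.mean(first_exit < first_hit)
    return out


def encode_channel(
    points: np.ndarray,
    values: np.ndarray,
    signed: bool,
    order: int = 15,
    dim: int = 64,
    ball_fill: float = 0.7,
) -> np.ndarray:
    """Voxelize one per-point channel and return its invariant vector.

    Unsigned channels give ``descriptor_length(order)`` components; signed
    channels are split into positive/negative parts encoded separately and
    concatenated.
    """
    values = np.asarray(values, dtype=float)
    if signed:
        parts = np.stack([np.maximum(values, 0.0), np.maximum(-values, 0.0)])
        grids = voxelize_channels(points, parts, dim=dim, ball_fill=ball_fill)
        return np.concatenate(
            [compute_descriptor(g, order).values for g in grids]
        )
    grid = voxelize_channels(points, values[None, :], dim=dim, ball_fill=ball_fill)[0]
    return compute_descriptor(grid, order).values


def encode_patch_channel(
    patch: SurfacePatch, channel: str, order: int = 15, dim: int = 64,
    ball_fill: float = 0.7,
) -> np.ndarray:
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    if channel == "shape":
        values = np.ones(patch.n_points)
    else:
        values = np.asarray(patch.property_values[channel], dtype=float)
    if len(values) != patch.n_points:
        raise ValueError("channel values must cover every patch point")
    return encode_channel(
        patch.points, values, signed=channel in SIGNED_CHANNELS,
        order=order, dim=dim, ball_fill=ball_fill,
    )


def compute_patch_descriptors(
    patch: SurfacePatch, order: int = 15, dim: int = 64, ball_fill: float = 0.7
) -> None:
    """Fill ``patch.descriptors`` for all four channels in place."""
    for ch in CHANNELS:
        patch.descriptors[ch] = encode_patch_channel(
            patch, ch, order=order, dim=dim, ball_fill=ball_fill
        )


def import_point_values(
    path, surface_points: np.ndarray, tolerance: float = 0.5
) -> np.ndarray:
    """Read whitespace-delimited (x, y, z, value) rows and map them onto
    surface points by nearest neighbor within ``tolerance`` angstrom."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] != 4:
        raise ValueError("expected four columns: x y z value")
    d, nearest = cKDTree(data[:, :3]).query(surface_points, k=1)
    if np.any(d > tolerance):
        raise ValueError(
            f"{int((d > tolerance).sum())} surface points have no imported value "
            f"within {tolerance} A"
        )
    return data[nearest, 3]
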