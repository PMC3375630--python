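"""Deterministic synthetic inputs: voxel test objects, artificial
protein-ligand complexes with hemispherical binding cavities, and a small
retrieval benchmark with truth labels.

Everything is generated from integer seeds through ``numpy.random
.default_rng``; identical parameters give bit-identical output on any
platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Atom, ComplexStructure, LigandRecord, write_pdb
from .zernike import VoxelGrid

__all__ = [
    "FixtureSpec",
    "make_voxel_object",
    "blob_descriptor_pair_fields",
    "make_synthetic_complex",
    "make_benchmark",
]

VOXEL_KINDS = ("ball", "blob", "two-lobe")

# pseudo-residues of four atoms each; charged residue types expose their
# ionizable atom so the charge table applies, without any claim to real
# chemistry
_RESIDUES = ("ALA", "ASP", "LYS", "ILE", "GLY", "SER", "PHE", "GLU",
             "ARG", "VAL")
_RESIDUE_ATOMS = {
    "ASP": (("N", "N"), ("CA", "C"), ("OD1", "O"), ("O", "O")),
    "GLU": (("N", "N"), ("CA", "C"), ("OE1", "O"), ("O", "O")),
    "LYS": (("N", "N"), ("CA", "C"), ("NZ", "N"), ("O", "O")),
    "ARG": (("N", "N"), ("CA", "C"), ("NH1", "N"), ("O", "O")),
}
_DEFAULT_ATOMS = (("N", "N"), ("CA", "C"), ("CB", "C"), ("O", "O"))
_ATOMS_PER_RESIDUE = 4


@dataclass
class FixtureSpec:
    seed: int = 42
    family_count: int = 5
    pockets_per_family: int = 6
    noise_sigma: float = 0.3
    ligand_size: int = 8
    cavity_radius: float = 6.0
    cavity_radius_step: float = 0.45  # per-family increment
    wall_spacing: float = 1.8


# ---------------------------------------------------------------------------
# voxel objects


def _blob_params(rng: np.random.Generator):
    centers = rng.uniform(-0.45, 0.45, size=(12, 3))
    sigmas = rng.uniform(0.05, 0.09, size=12)
    weights = rng.uniform(0.5, 1.5, size=12)
    return centers, sigmas, weights


def _object_field(kind: str, seed: int):
    """Analytic scalar field for a voxel object; rotating the evaluation
    points rotates the object exactly (no resampling error)."""
    if kind not in VOXEL_KINDS:
        raise ValueError(
            f"unknown voxel object kind {kind!r}; choose from {VOXEL_KINDS}")
    rng = np.random.default_rng([seed, VOXEL_KINDS.index(kind)])
    if kind == "ball":
        return lambda pts: (np.linalg.norm(pts, axis=1) <= 0.7).astype(float)
    if kind == "two-lobe":
        c = np.array([[0.0, 0.0, 0.35], [0.0, 0.0, -0.35]])
        w = rng.uniform(0.8, 1.2, size=2)
        def field(pts):
            out = np.zeros(len(pts))
            for ci, wi in zip(c, w):
                d2 = ((pts - ci) ** 2).sum(axis=1)
                out += wi * np.exp(-d2 / (2 * 0.18**2))
            return out
        return field
    if kind == "blob":
        centers, sigmas, weights = _blob_params(rng)
        def field(pts):
            out = np.zeros(len(pts))
            for ci, si, wi in zip(centers, sigmas, weights):
                d2 = ((pts - ci) ** 2).sum(axis=1)
                out += wi * np.exp(-d2 / (2 * si * si))
            return out
        return field
    raise ValueError(f"unknown voxel object kind {kind!r}; choose from {VOXEL_KINDS}")


def make_voxel_object(
    kind: str, dim: int = 64, seed: int = 0, rotation: np.ndarray = None
) -> VoxelGrid:
    """Deterministic unit-ball voxel object; optional exact rotation.

    ``rotation`` is a 3x3 matrix applied to the object (the field is
    evaluated at rotated sample positions, so no interpolation error is
    introduced).
    """
    if dim < 16:
        raise ValueError(f"dim must be >= 16, got {dim}")
    field = _object_field(kind, seed)
    c = (np.arange(dim) + 0.5 - dim / 2.0) * (2.0 / dim)
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    pts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    if rotation is not None:
        pts = pts @ np.asarray(rotation)
    vals = field(pts).reshape(dim, dim, dim)
    r2 = x * x + y * y + z * z
    vals = vals * (r2 <= 0.9**2)
    return VoxelGrid(dim=dim, spacing=2.0 / dim, origin=np.full(3, -1.0),
                     values=vals)


def blob_descriptor_pair_fields(seed: int):
    """Two independently seeded blob fields (for difference tests)."""
    return _object_field("blob", seed), _object_field("blob", seed + 1)


# ---------------------------------------------------------------------------
# synthetic complexes


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def _wall_bump_field(rng: np.random.Generator, n_bumps: int = 10):
    """Smooth family-specific radial deformation of the cavity wall."""
    dirs = _fibonacci_sphere(64)
    dirs = dirs[dirs[:, 2] < 0.2]
    picks = rng.choice(len(dirs), size=n_bumps, replace=False)
    centers = dirs[picks]
    amps = rng.uniform(-1.0, 1.0, size=n_bumps)
    widths = rng.uniform(0.25, 0.5, size=n_bumps)

    def offset(unit_dirs: np.ndarray) -> np.ndarray:
        out = np.zeros(len(unit_dirs))
        for c, a, w in zip(centers, amps, widths):
            ang2 = np.arccos(np.clip(unit_dirs @ c, -1.0, 1.0)) ** 2
            out += a * np.exp(-ang2 / (2 * w * w))
        return out

    return offset


def _cavity_protein_coords(
    radius: float, wall_spacing: float, bump_offset=None
) -> np.ndarray:
    """Cup geometry: two concentric hemispherical shells (cavity opens
    toward +z, optionally deformed by a radial bump field) plus a flat
    two-layer rim slab around the opening."""
    coords = []
    for shell_r in (radius, radius + 2.8):
        n = int(np.ceil(4.0 * np.pi * shell_r**2 / wall_spacing**2))
        pts = _fibonacci_sphere(n)
        pts = pts[pts[:, 2] <= 0.15]
        rr = shell_r
        if bump_offset is not None:
            rr = shell_r + bump_offset(pts)
            coords.append(pts * rr[:, None])
        else:
            coords.append(pts * rr)
    half = radius + 5.0
    ax = np.arange(-half, half + 1e-9, 2.0)
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    flat = np.stack([gx.ravel(), gy.ravel()], axis=1)
    hole = np.linalg.norm(flat, axis=1) > radius + 0.8
    flat = flat[hole]
    for zlev in (1.0, 3.0):
        coords.append(np.column_stack([flat, np.full(len(flat), zlev)]))
    return np.vstack(coords)


def _ligand_coords(
    rng: np.random.Generator,
    ligand_size: int,
    radius: float,
    wall_coords: np.ndarray,
    target_gap: float = 2.5,
) -> np.ndarray:
    """Ligand atom cloud seated in the cavity, scaled so its minimum
    heavy-atom distance to the wall is exactly ``target_gap`` angstrom
    (inside the 1.4/3.5 A contact window)."""
    reach = radius - target_gap
    if reach < 0.8:
        raise ValueError(f"cavity radius {radius} too small for a seated ligand")
    pts = rng.uniform(-1.0, 1.0, size=(ligand_size, 3))
    pts[:, 2] = -np.abs(pts[:, 2])  # keep inside the lower (cavity) half
    pts = pts / np.linalg.norm(pts, axis=1).max()

    def min_gap(scale: float) -> float:
        p = pts * scale
        d = np.linalg.norm(p[:, None, :] - wall_coords[None, :, :], axis=2)
        return float(d.min())

    lo, hi = 0.3, radius  # min_gap decreases as the ligand grows
    if min_gap(lo) <= target_gap:
        raise ValueError(f"cavity radius {radius} too small for a seated ligand")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_gap(mid) > target_gap:
            lo = mid
        else:
            hi = mid
    return pts * (0.5 * (lo + hi))


def make_synthetic_complex(
    spec: FixtureSpec, family_id: int, member_id: int
) -> ComplexStructure:
    """One pseudo-complex: family sets the cavity and ligand geometry,
    member adds coordinate noise of ``spec.noise_sigma`` angstrom."""
    radius = spec.cavity_radius + spec.cavity_radius_step * family_id
    fam_rng = np.random.default_rng([spec.seed, family_id])
    bumps = _wall_bump_field(fam_rng)
    prot = _cavity_protein_coords(radius, spec.wall_spacing, bump_offset=bumps)
    lig = _ligand_coords(fam_rng, spec.ligand_size, radius, wall_coords=prot)

    # family-specific, spatially coherent residue layout: pre-noise atom
    # directions are bucketed into angular sectors, each sector carrying one
    # family-chosen residue type -> smooth charge/hydropathy texture
    sectors = _fibonacci_sphere(16)
    sector_res = fam_rng.integers(0, len(_RESIDUES), size=len(sectors))
    n_res = (len(prot) + _ATOMS_PER_RESIDUE - 1) // _ATOMS_PER_RESIDUE
    res_names = []
    for ri in range(n_res):
        lead = prot[ri * _ATOMS_PER_RESIDUE]
        u = lead / (np.linalg.norm(lead) or 1.0)
        res_names.append(_RESIDUES[sector_res[int(np.argmax(sectors @ u))]])

    mem_rng = np.random.default_rng([spec.seed, family_id, member_id, 7])
    if spec.noise_sigma > 0:
        prot = prot + mem_rng.normal(0.0, spec.noise_sigma, size=prot.shape)
        lig = lig + mem_rng.normal(0.0, spec.noise_sigma, size=lig.shape)

    protein_atoms = []
    for i, c in enumerate(prot):
        ri = i // _ATOMS_PER_RESIDUE
        resname = res_names[ri]
        name, element = _RESIDUE_ATOMS.get(resname, _DEFAULT_ATOMS)[
            i % _ATOMS_PER_RESIDUE]
        protein_atoms.append(Atom(
            name=name, element=element, resname=resname,
            resseq=ri + 1, icode="", chain="A",
            coord=np.round(c, 3),
        ))
    het = f"L{family_id:02d}"
    ligand = LigandRecord(
        het_code=het, chain="L", resseq=900,
        atoms=[
            Atom(name=f"C{j + 1}", element="C", resname=het, resseq=900,
                 icode="", chain="L", coord=np.round(c, 3))
            for j, c in enumerate(lig)
        ],
    )
    return ComplexStructure(
        source_id=f"fam{family_id:02d}_m{member_id:03d}",
        protein_atoms=protein_atoms,
        ligands=[ligand],
    )


def make_benchmark(spec: FixtureSpec):
    """Database structures, held-out noisy queries, and truth labels.

    Returns (db_structures, query_structures, truth) where truth maps each
    query source_id to its family's het code.
    """
    if spec.family_count < 2:
        raise ValueError("at least two families are required")
    db_structures = [
        make_synthetic_complex(spec, fam, member)
        for fam in range(spec.family_count)
        for member in range(spec.pockets_per_family)
    ]
    queries = []
    truth = {}
    for fam in range(spec.family_count):
        q = make_synthetic_complex(spec, fam, 1000 + fam)
        queries.append(q)
        truth[q.source_id] = f"L{fam:02d}"
    return db_structures, queries, truth


def write_benchmark(spec: FixtureSpec, out_dir) -> None:
    """Emit the benchmark as PDB files plus a tab-separated truth table."""
    from pathlib import Path

    out = Path(out_dir)
    (out / "db").mkdir(parents=True, exist_ok=True)
    (out / "queries").mkdir(parents=True, exist_ok=True)
    db_structures, queries, truth = make_benchmark(spec)
    for s in db_structures:
        (out / "db" / f"{s.source_id}.pdb").write_text(write_pdb(s))
    for s in queries:
        (out / "queries" / f"{s.source_id}.pdb").write_text(write_pdb(s))
    with open(out / "truth.tsv", "w") as fh:
        fh.write("query\tligand_code\n")
        for qid, code in sorted(truth.items()):
            fh.write(f"{qid}\t{code}\n")
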