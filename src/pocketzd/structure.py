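"""PDB parsing, molecular surface generation, pocket extraction and
patch segmentation.

Parsing is a fixed-width PDB v3.3 reader: ATOM records become protein
atoms, non-water HETATM groups become ligand records, alternate locations
are resolved to the highest occupancy, and models after the first are
ignored. The surface is a deterministic point cloud sampled from the
solvent-excluded isosurface of a signed-distance grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

__all__ = [
    "Atom",
    "LigandRecord",
    "ComplexStructure",
    "Surface",
    "SurfacePatch",
    "Pocket",
    "VDW_RADII",
    "parse_structure",
    "write_pdb",
    "compute_surface",
    "extract_pocket",
    "segment_patches",
    "LigandNotInContactError",
]

# fixed van der Waals radii (angstrom), bundled for reproducibility
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "FE": 1.80, "ZN": 1.39, "MG": 1.73, "CA": 1.97, "MN": 1.73,
    "NA": 2.27, "K": 2.75, "CU": 1.40, "SE": 1.90, "B": 1.92,
}
DEFAULT_RADIUS = 1.70

WATER_CODES = {"HOH", "WAT", "DOD", "H2O"}


class LigandNotInContactError(ValueError):
    """Raised when no surface point lies within the pocket cutoff of a ligand."""


@dataclass
class Atom:
    name: str
    element: str
    resname: str
    resseq: int
    icode: str
    chain: str
    coord: np.ndarray
    occupancy: float = 1.0

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")

    def radius(self) -> float:
        return VDW_RADII.get(self.element, DEFAULT_RADIUS)


@dataclass
class LigandRecord:
    het_code: str
    chain: str
    resseq: int
    atoms: list

    @property
    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if a.is_heavy]

    @property
    def heavy_atom_count(self) -> int:
        return len(self.heavy_atoms)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.heavy_atoms])

    @property
    def site_id(self) -> str:
        return f"{self.het_code}:{self.chain}:{self.resseq}"


@dataclass
class ComplexStructure:
    source_id: str
    protein_atoms: list
    ligands: list

    def protein_coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = self.protein_atoms
        if heavy_only:
            atoms = [a for a in atoms if a.is_heavy]
        return np.array([a.coord for a in atoms])


@dataclass
class Surface:
    points: np.ndarray
    normals: np.ndarray
    point_area: np.ndarray

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SurfacePatch:
    """Surface-point subset anchored to one ligand heavy atom."""

    anchor_atom: int
    anchor_name: str
    point_indices: np.ndarray
    points: np.ndarray
    normals: np.ndarray
    property_values: dict = field(default_factory=dict)
    descriptors: dict = field(default_factory=dict)
    weights: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class Pocket:
    source_id: str
    ligand_code: str
    patches: list

    def __post_init__(self) -> None:
        anchors = [p.anchor_atom for p in self.patches]
        if len(set(anchors)) != len(anchors):
            raise ValueError("patch anchor atoms must be distinct")

    @property
    def n_patches(self) -> int:
        return len(self.patches)


# ---------------------------------------------------------------------------
# PDB parsing


def _parse_element(line: str) -> str:
    el = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not el:
        # deduce from atom name columns 13-16; col 13 blank => 1-letter element
        name = line[12:16]
        el = name[:2].strip().upper()
        if el and el[0].isdigit():
            el = el[1:]
        if len(el) == 2 and el not in VDW_RADII:
            el = el[0]
    return el


def _coord_fields(line: str, lineno: int) -> np.ndarray:
    try:
        return np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed coordinate fields at line {lineno}") from exc


def parse_structure(pdb_text: str, source_id: str = "struct") -> ComplexStructure:
    """Parse fixed-width PDB text into protein atoms and ligand records.

    Waters are excluded from ligands; alternate locations are resolved to
    the highest-occupancy copy; only the first MODEL is read.
    """
    protein: dict = {}   # altloc resolution keyed by atom site
    het: dict = {}
    het_order: list = []
    model = 0
    saw_atom = False

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            model += 1
            if model > 1:
                break
            continue
        if rec == "ENDMDL":
            if model >= 1:
                break
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        coord = _coord_fields(line, lineno)
        if not np.all(np.isfinite(coord)):
            raise ValueError(f"non-finite coordinates at line {lineno}")
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21:22]
        try:
            resseq = int(line[22:26])
        except ValueError as exc:
            raise ValueError(f"malformed residue number at line {lineno}") from exc
        icode = line[26:27].strip()
        try:
            occ = float(line[54:60]) if line[54:60].strip() else 1.0
        except ValueError:
            occ = 1.0
        atom = Atom(
            name=name, element=_parse_element(line), resname=resname,
            resseq=resseq, icode=icode, chain=chain, coord=coord, occupancy=occ,
        )
        site = (chain, resseq, icode, resname, name)
        if rec == "ATOM  ":
            saw_atom = True
            if site not in protein or occ > protein[site].occupancy:
                protein[site] = atom
        else:
            if resname in WATER_CODES:
                continue
            group = (resname, chain, resseq, icode)
            if group not in het:
                het[group] = {}
                het_order.append(group)
            if site not in het[group] or occ > het[group][site].occupancy:
                het[group][site] = atom

    if not saw_atom:
        raise ValueError("no ATOM records found")

    ligands = [
        LigandRecord(het_code=g[0], chain=g[1], resseq=g[2],
                     atoms=list(het[g].values()))
        for g in het_order
    ]
    return ComplexStructure(
        source_id=source_id, protein_atoms=list(protein.values()), ligands=ligands
    )


def write_pdb(structure: ComplexStructure) -> str:
    """Emit fixed-width PDB text (coordinates to 3 decimals)."""
    lines = []
    serial = 1
    for a in structure.protein_atoms:
        lines.append(_pdb_line("ATOM", serial, a))
        serial += 1
    for lig in structure.ligands:
        for a in lig.atoms:
            lines.append(_pdb_line("HETATM", serial, a))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _pdb_line(rec: str, serial: int, a: Atom) -> str:
    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
    return (
        f"{rec:<6s}{serial:>5d} {name:<4s}{'':1s}{a.resname:>3s} {a.chain:1s}"
        f"{a.resseq:>4d}{a.icode or ' ':1s}   "
        f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
        f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
    )


# ---------------------------------------------------------------------------
# molecular surface


def compute_surface(
    structure: ComplexStructure,
    probe_radius: float = 1.4,
    spacing: float = 0.8,
) -> Surface:
    """Solvent-excluded surface point cloud via a signed-distance grid.

    Atom spheres inflated by the probe radius define the solvent-accessible
    region; the Euclidean distance transform back from that region gives a
    field whose ``probe_radius`` isosurface is the solvent-excluded surface.
    Points and outward normals come from marching cubes on that field.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be > 0")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    coords = structure.protein_coords()
    if len(coords) == 0:
        raise ValueError("structure has no protein atoms")
    radii = np.array([a.radius() for a in structure.protein_atoms])

    margin = radii.max() + probe_radius + 3 * spacing
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1

    blocked = np.zeros(shape, dtype=bool)
    for c, r in zip(coords, radii):
        rr = r + probe_radius
        imin = np.maximum(np.floor((c - rr - lo) / spacing).astype(int), 0)
        imax = np.minimum(np.ceil((c + rr - lo) / spacing).astype(int) + 1, shape)
        ax = [lo[d] + spacing * np.arange(imin[d], imax[d]) for d in range(3)]
        d2 = (
            (ax[0][:, None, None] - c[0]) ** 2
            + (ax[1][None, :, None] - c[1]) ** 2
            + (ax[2][None, None, :] - c[2]) ** 2
        )
        blocked[imin[0]:imax[0], imin[1]:imax[1], imin[2]:imax[2]] |= d2 <= rr * rr

    # distance from each blocked voxel back to the solvent-accessible region
    h = ndimage.distance_transform_edt(blocked, sampling=spacing)
    verts, faces, normals, _ = measure.marching_cubes(
        h, level=probe_radius, spacing=(spacing, spacing, spacing)
    )
    points = verts + lo
    # marching_cubes normals follow descending field values = outward here
    norms = normals / np.linalg.norm(normals, axis=1, keepdims=True)

    area = np.zeros(len(points))
    tri = points[faces]
    tri_area = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    for i in range(3):
        np.add.at(area, faces[:, i], tri_area / 3.0)

    return Surface(points=points, normals=norms, point_area=area)


# ---------------------------------------------------------------------------
# pocket extraction and patch segmentation


def extract_pocket(
    surface: Surface, ligand: LigandRecord, cutoff: float = 4.5
) -> np.ndarray:
    """Indices of surface points within ``cutoff`` of any ligand heavy atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    lig = ligand.heavy_coords()
    if len(lig) == 0:
        raise ValueError("ligand has no heavy atoms")
    tree = cKDTree(lig)
    dist, _ = tree.query(surface.points, k=1, distance_upper_bound=cutoff)
    idx = np.nonzero(np.isfinite(dist) & (dist <= cutoff))[0]
    if len(idx) == 0:
        raise LigandNotInContactError(
            f"ligand {ligand.site_id} not in contact with surface at {cutoff} A"
        )
    return idx


def segment_patches(
    surface: Surface, pocket_indices: np.ndarray, ligand: LigandRecord
) -> list:
    """Partition pocket points by nearest ligand heavy atom.

    Ties go to the lowest ligand-atom index; each nonempty group becomes
    one patch skeleton.
    """
    if len(pocket_indices) == 0:
        raise ValueError("pocket has no points")
    heavy = ligand.heavy_atoms
    lig = ligand.heavy_coords()
    pts = surface.points[pocket_indices]
    d = np.linalg.norm(pts[:, None, :] - lig[None, :, :], axis=2)
    assign = np.argmin(d, axis=1)  # argmin returns first minimum: tie rule

    patches = []
    for atom_idx in range(len(heavy)):
        mask = assign == atom_idx
        if not mask.any():
            continue
        sel = pocket_indices[mask]
        patches.append(
            SurfacePatch(
                anchor_atom=atom_idx,
                anchor_name=heavy[atom_idx].name,
                point_indices=sel,
                points=surface.points[sel],
                normals=surface.normals[sel],
            )
        )
    return patches
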