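"""Pocket-database construction: ligand filters, binding-site grouping, the
full structure-to-pocket pipeline, and on-disk persistence.

Filtering rules: ligands under 7 heavy atoms are dropped; ligands of the
same structure are pooled into one binding site when any inter-ligand atom
pair is closer than 4.0 A; sites covalently fused to the protein (minimum
heavy-atom distance < 1.4 A) or out of contact (> 3.5 A) are dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import (
    Atom,
    ComplexStructure,
    LigandNotInContactError,
    LigandRecord,
    Pocket,
    SurfacePatch,
    compute_surface,
    extract_pocket,
    segment_patches,
)
from .properties import (
    CHANNELS,
    compute_patch_descriptors,
    concaveness,
    electrostatic_potential,
    hydrophobicity,
    occupancy_grid,
)
from .matching import compute_weights

__all__ = [
    "BuildConfig",
    "DropRecord",
    "PocketDatabase",
    "filter_small_ligands",
    "group_ligands",
    "filter_contacts",
    "pocket_from_site",
    "build_database",
    "save_database",
    "load_database",
]


@dataclass
class BuildConfig:
    order: int = 15
    grid_dim: int = 64
    ball_fill: float = 0.7
    probe_radius: float = 1.4
    surface_spacing: float = 0.8
    pocket_cutoff: float = 4.5
    min_heavy: int = 7
    group_cutoff: float = 4.0
    covalent_cutoff: float = 1.4
    contact_cutoff: float = 3.5
    n_rays: int = 128

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class DropRecord:
    structure_id: str
    site_id: str
    reason: str  # one of {"small", "covalent", "no-contact", "no-pocket"}


@dataclass
class PocketDatabase:
    entries: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    drops: list = field(default_factory=list)

    @property
    def index(self) -> dict:
        """ligand code -> entry indices (rebuilt on access, always consistent)."""
        idx: dict = {}
        for i, e in enumerate(self.entries):
            idx.setdefault(e.ligand_code, []).append(i)
        return idx

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# filters


def filter_small_ligands(ligands: list, min_heavy: int = 7) -> list:
    """Keep ligands with at least ``min_heavy`` non-hydrogen atoms."""
    return [lig for lig in ligands if lig.heavy_atom_count >= min_heavy]


def _min_pair_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    d = np.linalg.norm(coords_a[:, None, :] - coords_b[None, :, :], axis=2)
    return float(d.min())


def group_ligands(ligands: list, link_cutoff: float = 4.0) -> list:
    """Single-linkage grouping: ligands with any atom pair closer than
    ``link_cutoff`` share a binding site. Returns a list of ligand lists."""
    if not ligands:
        return []
    n = len(ligands)
    coords = [lig.heavy_coords() for lig in ligands]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _min_pair_distance(coords[i], coords[j]) < link_cutoff:
                parent[find(i)] = find(j)

    groups: dict = {}
    first_member: dict = {}
    for i in range(n):
        root = find(i)
        groups.setdefault(root, []).append(ligands[i])
        first_member.setdefault(root, i)
    return [groups[r] for r in sorted(groups, key=first_member.get)]


def filter_contacts(
    ligand_group: list,
    protein_atoms: list,
    covalent_cutoff: float = 1.4,
    contact_cutoff: float = 3.5,
):
    """(keep, reason) for one binding site, from heavy-atom distances only.

    Closer than ``covalent_cutoff`` -> covalently bound, dropped; farther
    than ``contact_cutoff`` from every protein heavy atom -> not
    interacting, dropped.
    """
    lig = np.vstack([l.heavy_coords() for l in ligand_group])
    prot = np.array([a.coord for a in protein_atoms if a.is_heavy])
    if len(lig) == 0 or len(prot) == 0:
        raise ValueError("both atom sets must be nonempty")
    dmin = _min_pair_distance(lig, prot)
    if dmin < covalent_cutoff:
        return False, "covalent"
    if dmin > contact_cutoff:
        return False, "no-contact"
    return True, "kept"


# ---------------------------------------------------------------------------
# structure -> pocket pipeline


def _pooled_ligand(group: list) -> LigandRecord:
    """Merge a ligand group into one record; atom names are qualified with
    the het code so equivalent positions align across pockets."""
    if len(group) == 1:
        return group[0]
    atoms = []
    for lig in group:
        for a in lig.atoms:
            atoms.append(Atom(
                name=f"{lig.het_code}.{a.name}", element=a.element,
                resname=a.resname, resseq=a.resseq, icode=a.icode,
                chain=a.chain, coord=a.coord, occupancy=a.occupancy,
            ))
    codes = "+".join(sorted(l.het_code for l in group))
    first = group[0]
    return LigandRecord(het_code=codes, chain=first.chain,
                        resseq=first.resseq, atoms=atoms)


def pocket_from_site(
    structure: ComplexStructure,
    ligand: LigandRecord,
    config: BuildConfig = None,
    surface=None,
    occupancy=None,
) -> Pocket:
    """Surface -> pocket -> patches -> property channels -> descriptors."""
    cfg = config or BuildConfig()
    if surface is None:
        surface = compute_surface(structure, cfg.probe_radius, cfg.surface_spacing)
    if occupancy is None:
        occupancy = occupancy_grid(structure, spacing=1.0)
    idx = extract_pocket(surface, ligand, cutoff=cfg.pocket_cutoff)
    patches = segment_patches(surface, idx, ligand)

    pocket_pts = surface.points[idx]
    ele = electrostatic_potential(structure, pocket_pts)
    hyd = hydrophobicity(structure, pocket_pts)
    conc = concaveness(pocket_pts, surface.normals[idx], occupancy,
                       n_rays=cfg.n_rays)
    pos = {int(g): i for i, g in enumerate(idx)}
    for patch in patches:
        local = np.array([pos[int(g)] for g in patch.point_indices])
        patch.property_values = {
            "ele": ele[local], "hyd": hyd[local], "conc": conc[local],
        }
        compute_patch_descriptors(patch, order=cfg.order, dim=cfg.grid_dim,
                                  ball_fill=cfg.ball_fill)
    return Pocket(
        source_id=f"{structure.source_id}|{ligand.site_id}",
        ligand_code=ligand.het_code,
        patches=patches,
    )


def build_database(structures: list, config: BuildConfig = None) -> PocketDatabase:
    """Apply the filters to every structure, extract surviving pockets,
    compute descriptors, then derive per-patch channel weights from patches
    at equivalent positions across same-ligand pockets."""
    if not structures:
        raise ValueError("at least one structure is required")
    cfg = config or BuildConfig()
    db = PocketDatabase(metadata=cfg.to_dict())

    for structure in structures:
        survivors = filter_small_ligands(structure.ligands, cfg.min_heavy)
        for lig in structure.ligands:
            if lig.heavy_atom_count < cfg.min_heavy:
                db.drops.append(DropRecord(structure.source_id, lig.site_id, "small"))
        if not survivors:
            continue
        groups = group_ligands(survivors, cfg.group_cutoff)
        surface = None
        occupancy = None
        for group in groups:
            site = _pooled_ligand(group)
            keep, reason = filter_contacts(
                group, structure.protein_atoms,
                cfg.covalent_cutoff, cfg.contact_cutoff,
            )
            if not keep:
                db.drops.append(DropRecord(structure.source_id, site.site_id, reason))
                continue
            if surface is None:
                surface = compute_surface(structure, cfg.probe_radius,
                                          cfg.surface_spacing)
                occupancy = occupancy_grid(structure, spacing=1.0)
            try:
                pocket = pocket_from_site(structure, site, cfg,
                                          surface=surface, occupancy=occupancy)
            except LigandNotInContactError:
                db.drops.append(
                    DropRecord(structure.source_id, site.site_id, "no-pocket"))
                continue
            db.entries.append(pocket)

    _assign_weights(db)
    return db


def _assign_weights(db: PocketDatabase) -> None:
    """Group patches by (ligand code, anchor atom name) and set weights."""
    groups: dict = {}
    for pocket in db.entries:
        for patch in pocket.patches:
            groups.setdefault((pocket.ligand_code, patch.anchor_name), []).append(patch)
    for patches in groups.values():
        w = compute_weights(patches)
        for p in patches:
            p.weights = w.values.copy()


# ---------------------------------------------------------------------------
# persistence: directory with JSON metadata, TSV index, per-entry JSON


def save_database(db: PocketDatabase, path) -> None:
    path = Path(path)
    (path / "entries").mkdir(parents=True, exist_ok=True)
    with open(path / "metadata.json", "w") as fh:
        json.dump(db.metadata, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(path / "index.tsv", "w") as fh:
        fh.write("entry\tsource_id\tligand_code\tn_patches\n")
        for i, e in enumerate(db.entries):
            fh.write(f"{i:06d}\t{e.source_id}\t{e.ligand_code}\t{e.n_patches}\n")
    with open(path / "drops.tsv", "w") as fh:
        fh.write("structure_id\tsite_id\treason\n")
        for d in db.drops:
            fh.write(f"{d.structure_id}\t{d.site_id}\t{d.reason}\n")
    for i, e in enumerate(db.entries):
        with open(path / "entries" / f"{i:06d}.json", "w") as fh:
            json.dump(_pocket_to_json(e), fh, sort_keys=True)
            fh.write("\n")


def load_database(path) -> PocketDatabase:
    path = Path(path)
    with open(path / "metadata.json") as fh:
        metadata = json.load(fh)
    entries = []
    with open(path / "index.tsv") as fh:
        next(fh)
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    for entry_id, _, _, _ in rows:
        with open(path / "entries" / f"{entry_id}.json") as fh:
            entries.append(_pocket_from_json(json.load(fh)))
    drops = []
    drops_path = path / "drops.tsv"
    if drops_path.exists():
        with open(drops_path) as fh:
            next(fh)
            for line in fh:
                if line.strip():
                    sid, site, reason = line.rstrip("\n").split("\t")
                    drops.append(DropRecord(sid, site, reason))
    return PocketDatabase(entries=entries, metadata=metadata, drops=drops)


def _pocket_to_json(pocket: Pocket) -> dict:
    return {
        "source_id": pocket.source_id,
        "ligand_code": pocket.ligand_code,
        "patches": [
            {
                "anchor_atom": int(p.anchor_atom),
                "anchor_name": p.anchor_name,
                "n_points": int(p.n_points),
                "weights": [float(w) for w in p.weights],
                "descriptors": {
                    ch: [float(v) for v in p.descriptors[ch]] for ch in CHANNELS
                },
            }
            for p in pocket.patches
        ],
    }


def _pocket_from_json(obj: dict) -> Pocket:
    patches = []
    for pj in obj["patches"]:
        patch = SurfacePatch(
            anchor_atom=pj["anchor_atom"],
            anchor_name=pj["anchor_name"],
            point_indices=np.zeros(pj["n_points"], dtype=int),
            points=np.zeros((pj["n_points"], 3)),
            normals=np.zeros((pj["n_points"], 3)),
        )
        patch.descriptors = {ch: np.array(v) for ch, v in pj["descriptors"].items()}
        patch.weights = np.array(pj["weights"])
        patches.append(patch)
    return Pocket(source_id=obj["source_id"], ligand_code=obj["ligand_code"],
                  patches=patches)
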