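import numpy as np
import pytest

from pocketzd import database, fixtures
from pocketzd.structure import Atom, ComplexStructure, LigandRecord


def make_atom(coord, name="CA", element="C", resname="GLY", resseq=1,
              chain="A", occupancy=1.0):
    return Atom(name=name, element=element, resname=resname, resseq=resseq,
                icode="", chain=chain, coord=np.asarray(coord, float),
                occupancy=occupancy)


def make_ligand(coords, het="LIG", elements=None, chain="L", resseq=900):
    coords = np.asarray(coords, float)
    elements = elements or ["C"] * len(coords)
    atoms = [
        make_atom(c, name=f"{el}{i + 1}", element=el, resname=het,
                  resseq=resseq, chain=chain)
        for i, (c, el) in enumerate(zip(coords, elements))
    ]
    return LigandRecord(het_code=het, chain=chain, resseq=resseq, atoms=atoms)


def slab_structure(extent=20.0, spacing=1.5, layers=(0.0, -1.5, -3.0),
                   source_id="slab"):
    atoms = []
    i = 0
    ax = np.arange(-extent, extent + 1e-9, spacing)
    for x in ax:
        for y in ax:
            for z in layers:
                i += 1
                atoms.append(make_atom([x, y, z], resseq=i))
    return ComplexStructure(source_id, atoms, [])


@pytest.fixture(scope="session")
def bench():
    """Full synthetic benchmark: database + query pockets + truth labels.

    Session-scoped: built once (the dominant cost of the suite).
    """
    spec = fixtures.FixtureSpec(seed=42, family_count=5, pockets_per_family=6,
                                noise_sigma=0.3)
    cfg = database.BuildConfig()
    db_structs, queries, truth = fixtures.make_benchmark(spec)
    db = database.build_database(db_structs, cfg)
    query_pockets = [
        database.pocket_from_site(q, q.ligands[0], cfg) for q in queries
    ]
    return db, query_pockets, truth


@pytest.fixture(scope="session")
def small_complex():
    """One noiseless synthetic complex plus its computed pocket."""
    spec = fixtures.FixtureSpec(seed=3, noise_sigma=0.0)
    s = fixtures.make_synthetic_complex(spec, 0, 0)
    cfg = database.BuildConfig()
    pocket = database.pocket_from_site(s, s.ligands[0], cfg)
    return s, pocket, cfg
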