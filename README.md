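# pocketzd

Ligand-binding pocket comparison with rotation-invariant 3D Zernike
surface-patch descriptors.

A protein–ligand binding pocket is represented as a set of surface patches,
one per ligand heavy atom. Each patch carries four property channels —
geometric shape, electrostatic potential, hydrophobicity and concaveness
(ray visibility) — encoded as 3D Zernike descriptors (order 15: 72
invariants per unsigned channel, 144 for signed channels via a
positive/negative split). Pockets are compared by thresholded optimal
bipartite matching of patches under per-patch channel weights learned from
the descriptor spread at equivalent positions, and retrieval is evaluated
with the enrichment factor.

## Library overview

| module | contents |
| --- | --- |
| `pocketzd.zernike` | voxel grids, 3D Zernike moments/invariants, descriptor I/O |
| `pocketzd.structure` | PDB parsing, solvent-excluded surface, pocket extraction, patch segmentation |
| `pocketzd.properties` | electrostatics, hydropathy, visibility, channel encoding |
| `pocketzd.database` | ligand filters (≥7 heavy atoms, 4.0 Å grouping, 1.4/3.5 Å contact window), database build and persistence |
| `pocketzd.matching` | patch weights, weighted patch distance, bipartite matching, search, ligand prediction |
| `pocketzd.evaluation` | enrichment factor and EF curves |
| `pocketzd.fixtures` | deterministic synthetic complexes, voxel objects and benchmarks |

```python
from pocketzd import (FixtureSpec, make_benchmark, build_database,
                      pocket_from_site, search_database, predict_ligand)

db_structs, queries, truth = make_benchmark(FixtureSpec(seed=42))
db = build_database(db_structs)
q = queries[0]
result = search_database(pocket_from_site(q, q.ligands[0]), db, threshold=0.3)
print(predict_ligand(result, k=5))
```

## Command line

```sh
# synthetic benchmark: 5 pocket families x 6 members + held-out queries
pocketzd simulate --families 5 --members 6 --noise 0.3 --seed 42 --out bench/

# build the pocket-descriptor database from a directory of PDB complexes
pocketzd build-db --pdb-dir bench/db --out pocketdb/

# search / predict against the database
pocketzd search  --db pocketdb/ --query bench/queries/fam00_m1000.pdb --threshold 0.2
pocketzd predict --db pocketdb/ --query bench/queries/fam00_m1000.pdb --k 10

# enrichment-factor table over a query directory
pocketzd evaluate --db pocketdb/ --queries bench/queries --x 1,5,10,20
```

## Notes

- Surfaces are deterministic point clouds from a signed-distance grid
  (probe 1.4 Å, spacing 0.8 Å); identical inputs give bit-identical output.
- Electrostatics use a bundled screened-Coulomb model (dielectric 4r) and a
  simplified partial-charge table; precomputed per-point potentials can be
  imported via `properties.import_point_values`.
- The database directory layout is plain text: `metadata.json`,
  `index.tsv`, `drops.tsv` and one JSON file per pocket entry.
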