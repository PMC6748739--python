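# contactsurf

Direct calculation of interatomic **contact surface areas (CSA)** for
molecular structures, together with solvent accessible surface area (SASA)
and buried surface area (BSA), for proteins, nucleic acids and small
molecules in PDB or Tripos Mol2 format.

## Why direct contact surfaces

Interface areas are routinely *approximated* by differential SASA: compute
the SASA of each binding partner in isolation and in the complex, and call
the difference the buried interface. That approximation ignores shielding
by neighboring atoms — a surface patch of atom B that is occluded both by
its binding partner A and by B's own neighbor C is invisible to ΔSASA (it
is buried either way) yet it is real contact surface. On crowded
interfaces the ΔSASA estimate is systematically too small.

`contactsurf` instead extends Shrake-Rupley point sampling. Each atom's
*expanded sphere* (radius `r + r_probe`, probe 1.4 Å for water) carries a
deterministic lattice of `n` near-equidistant points, each representing
solid angle `4π/n`. Instead of discarding points buried inside neighboring
expanded spheres, the engine records for every buried point its **occluder
group** — the full set of atoms whose spheres contain it. A patch buried by
group *G* is attributed fractionally:

```
CSA(A, B) = Σ_{G ∋ B}  area(G) / |G|          (area on A's sphere)
SASA(A)   = n_accessible · (4π/n) · (r_A + r_probe)²
```

so that for every atom, exactly,

```
SASA(A) + Σ_B CSA(A, B) = 4π (r_A + r_probe)²
```

BSA is a column sum of the contact matrix. Five operating modes cover
SASA-only runs (0), intermolecular atom/residue contact matrices with BSA
(1), intramolecular residue and atom contact maps (2, 3), and
intermolecular contacts computed against the partner object only (4), which
preserves the full contact area of deeply buried ligands.

## Worked example

```python
import contactsurf as cs
from contactsurf.engine import build_group_tables
from contactsurf.fixtures import make_two_sphere, make_fig1_triple

lattice = cs.generate_sphere_points(2000)

# two atoms, r = 1.6 Å each, centers 3.0 Å apart, probe 1.4 Å:
# the analytic contact area is the spherical cap 2πRh = 9π ≈ 28.274 Å²
pair = cs.compute_contacts(make_two_sphere().atoms, lattice)
print(round(pair.values[0, 1], 4))        # 28.3309  (0.2% from 9π)

# three atoms: A occluded by overlapping B and C; the patch shared by
# B and C is split half-and-half
triple = make_fig1_triple()
tables = build_group_tables(triple.atoms, lattice)
print(tables[0].groups)                   # {(3,): 187, (2,): 187, (2, 3): 322}
m = cs.compute_contacts(triple.atoms, lattice)
print(round(m.values[0, 1], 4))           # 19.6789 = area({B}) + area({B,C})/2
print(m.values[0, 1] == m.values[0, 2])   # True (mirror-symmetric geometry)
```

The group table says 187 of A's 2000 points are buried by B alone, 187 by C
alone, and 322 by both; the contact area of A with B is the {B}-only patch
plus half the shared patch.

From the shell:

```sh
contactsurf --input complex.pdb --mode 1 --chains A --chains B,C \
            --output-prefix out/complex
# -> out/complex.atom_matrix.tsv  out/complex.res_matrix.tsv
#    out/complex.bsa.pdb (BSA in the B-factor column)  out/complex.log
```

Contact maps are rendered from any matrix TSV with
`contactsurf.contactmap.render_contact_map("out/complex.res_matrix.tsv",
"map.png")`.

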