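# xlinkforge

Tools for turning quantum-chemistry Hessians of covalent protein cross-links
into usable molecular-mechanics artifacts, and for analysing the trajectories
of the cross-linked proteins afterwards. The pipeline covers:

1. **`qm_io`** — parse formatted-checkpoint geometry/Hessian files
   (lower-triangular force constants, Hartree/Bohr²), plain wavenumber
   lists, and bonded atom-pair / angle-triplet request files; normalize
   everything to nm / kJ mol⁻¹.
2. **`bonded_params`** — derive harmonic bond and angle force constants and
   equilibrium values from the Cartesian Hessian by eigen-projection of the
   3×3 interatomic sub-blocks (Seminario-style), with bond-model deflation
   and iterative angle decoupling for clean recovery on coupled systems.
3. **`topology_emit`** — split a cross-link into two residue templates along
   a declared boundary, enforce the zero-net-charge invariant, and emit
   residue-template (.rtp-style), special-bond (specbond.dat-style) and
   bonded-parameter (.itp-style) files with paired readers.
4. **`normal_modes`** — assemble the bonded MM Hessian analytically,
   diagonalize the mass-weighted form, and compare the resulting wavenumber
   spectrum against QM frequencies (rank-order, zero modes removed).
5. **`traj_analysis`** — hydrogen bonds (distance + angle criteria,
   triclinic minimum image), Shrake–Rupley SASA on a deterministic
   golden-spiral lattice (960 points / 0.14 nm probe defaults), Kabsch
   RMSD and all-pairs net-RMSD matrices, backbone PCA, centroid-frame
   extraction via similarity scores, and the Shapiro–Wilk /
   Fligner–Killeen statistical layer.
6. **`synthetic_data`** — deterministic fixtures with known ground truth:
   toy molecules with analytic Hessians, cross-link-shaped molecules with
   the standard atom naming and a declared residue boundary, and
   multi-chain helical trajectories with planted hydrogen-bond geometries.

Energy convention throughout: V = ½k(x − x₀)² (harmonic, GROMACS-style
function type 1). Internal units: nm, kJ/mol, amu; angles in degrees at I/O
boundaries.

## CLI

```bash
# parse QM outputs
xlinkforge ingest --fchk molecule.fchk --pairs pairs.txt --triplets triplets.txt --out parsed.json

# derive bonded parameters (optional CSV table)
xlinkforge derive --parsed parsed.json --out params.json --csv table.csv

# split the cross-link and emit force-field files
xlinkforge topology --parsed parsed.json --params params.json \
    --charges charges.csv --split boundary.yaml --out-dir ff/

# MM normal modes vs QM wavenumbers
xlinkforge nma --parsed parsed.json --ff params.json --qm-freqs freqs.txt --n 40 --out cmp.csv

# trajectory analyses (hbonds | sasa | rmsd | netrmsd | pca | centroid)
xlinkforge analyze hbonds --top traj.pdb --config cfg.yaml --out results/

# generate a synthetic trajectory fixture (PDB + truth.json)
xlinkforge simulate-fixtures --recipe recipe.yaml --seed 1234 --out fixture/
```

`boundary.yaml` holds the residue split (`boundary`, `caps`, optional
explicit `bonds`, `residue_names`); `charges.csv` maps atom name → partial
charge (e). Analysis configs may set `d_max`, `angle_min`, `donors`,
`acceptors`, `distance_mode`, `probe`, `n_points`, `uniform_radius`,
`selection`, `stride`, `beta`, and `discard_fraction` (default 0.25 of the
leading frames are dropped as equilibration).

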