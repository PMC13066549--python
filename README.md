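# eetnet

Pigment census and excitation-energy-transfer (EET) network analysis for
pigment–protein complexes (photosystem supercomplexes and their
light-harvesting antennae).

From an atomic model (mmCIF or PDB), the pipeline:

1. **reads and classifies cofactors** (`eetnet.structure_io`) against a
   configurable chemical-component table (chlorophylls, carotenoids,
   quinones, Fe–S clusters, lipids);
2. **builds geometric pigment sites** (`eetnet.pigment_model`): central Mg,
   NB→ND Qy dipole axis, ring-plane normals, macrocycle atoms for
   transition-charge evaluation;
3. **runs the structural census** (`eetnet.census`): stoichiometry ratios
   normalized to 100 Chl a, Mg–Mg distances, minimum residue–residue gaps,
   axial-ligand calls, chlorophyll pairs and parallel stacking clusters,
   per-domain binding-site counts;
4. **computes excitonic couplings** (`eetnet.coupling`): screened
   point-dipole and transition-charge (TrEsp-style) routes, assembled into a
   site-basis Hamiltonian in cm⁻¹;
5. **computes EET rates** (`eetnet.rates`): pairwise Förster rates with
   Gaussian lineshapes and Stokes shift, and domain-level generalized-Förster
   rates (intra-domain exciton states, Boltzmann-weighted donors);
6. **derives network products** (`eetnet.pathways`): time-constant-binned
   edge maps, antenna group partitions by thresholded connectivity, and
   composite (series-sum) pathway time constants with best-route search;
7. **generates synthetic fixtures** (`eetnet.synth`): dimers with prescribed
   orientation factors, stacks, rings, two-domain clusters and census scenes
   with analytic ground truth, emitted as valid mmCIF.

Spectral parameters (site energies, dipole strengths, lineshape widths,
Stokes shift, temperature, screening) are explicit config stand-ins — see
`src/eetnet/data/site_params.yaml` — not fitted values; every number can be
overridden per run.

## CLI

```sh
eetnet census  --input model.cif --out out/            # inventory, ratios, ligands, pairs
eetnet couplings --input model.cif --method tresp --out out/
eetnet rates   --input model.cif --method tresp --out out/   # pairwise Förster + binned map
eetnet gf      --input model.cif --domains chains.tsv --out out/  # domain rates, groups, routes
eetnet pathways --rates out/gf_rates.csv --out out/
eetnet synth   --kind dimer --param R=10 --param kappa_target=collinear --out fixture/
```

`chains.tsv` is a 2-column chain→domain-label file (e.g. `A core`,
`B LHC-1`). Exit codes: 0 success, 2 usage/config error, 3 parse error,
4 computation error. Every run writes a `manifest.json` with the resolved
configuration.

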