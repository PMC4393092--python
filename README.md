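# porescope

Trajectory analysis of ion and metabolite permeation through membrane pores.
Given a structure and a trajectory, porescope computes:

- **Geometric contacts** — electrostatic (phosphate O to Lys/Arg side-chain N,
  ≤ 4 Å), cation pairing (< 4 Å), π–π stacking (< 6 Å, inter-plane angle
  < 30°), cation–π (< 6 Å, NH-vector/plane angle > 60°), guanidinium stacking
  (< 6 Å, < 30°), and hydrogen bonds (< 3.5 Å heavy-atom distance, D–H–A angle
  > 120°), plus contact timelines and long-lived (> 5 ns contiguous)
  classification.
- **Axial profiles** along the pore reaction coordinate z (signed projection
  onto the pore axis relative to the geometric center of reference residues):
  occupancy histograms, per-residue interaction fractions (N_int), cation
  pairing numbers, and concentration profiles in a cylindrical sampling
  region.
- **Free-energy profiles** by Boltzmann inversion,
  ΔG(z) = −RT ln(C(z)/C_bulk), with block-averaged standard errors.
- **Translocation events** — full crossings of the ±15 Å pore slab with
  hysteresis, counted per particle and direction.
- **Selectivity** — the ratio of time-averaged anion vs cation pore
  occupancies.
- **MSA conservation** — per-position identity and %-substituted-to-K/R
  relative to a reference sequence.
- **Conductance** — OLS slope of an I/V curve in a ±20 mV window (pA/mV = nS)
  and normalized conductance changes.

A first-class synthetic-data module generates ground-truth-known inputs: toy
cylindrical pores decorated with tagged interaction partners, and seeded
overdamped Brownian-dynamics trajectories in Gaussian axial potentials whose
stationary law is exactly the Boltzmann distribution — so the free-energy
machinery can be validated by parameter recovery without an MD engine.

## CLI

Single entry point `porescope` with subcommands:

```bash
# generate a synthetic system (text trajectory dialect + PDB + ground truth)
porescope synth --spec spec.yaml --out traj.txt --structure-out pore.pdb

# tag-derived electrostatic + cation-pairing contacts
porescope contacts --structure pore.pdb --traj traj.txt --out contacts.tsv

# axial profiles
porescope profile --kind occupancy --structure pore.pdb --traj traj.txt --out occ.tsv
porescope profile --kind pmf --species cl --structure pore.pdb --traj traj.txt --out pmf.tsv

# translocation events, conservation, conductance
porescope events --structure pore.pdb --traj traj.txt --out events.tsv
porescope conserve --msa msa.fasta --ref mVDAC1 --positions 12,15,20
porescope conductance --iv before.csv --iv-test after.csv

# everything for a synthetic spec in one bundle (TSVs + effective config)
porescope report --spec spec.yaml --out bundle/
```

A synthetic spec is YAML mirroring `SyntheticSpec`:

```yaml
seed: 11
n_frames: 2000
timestep_ns: 0.005
box_A: [40, 40, 80]
pore_radius_A: 12.0
potential:
  - {amplitude_kcal: -2.0, center_z_A: -5.0, width_A: 2.5}
  - {amplitude_kcal: -1.0, center_z_A: 6.0, width_A: 2.5}
species:
  - {name: cl, charge: -1, count: 100, diffusion_A2_per_ns: 100.0}
  - {name: na, charge: 1, count: 50, diffusion_A2_per_ns: 100.0}
```

## File formats

PDB structures (ATOM/HETATM), CHARMM/NAMD DCD, a plain-text trajectory
dialect (`natoms N dt_ns X`, then per frame `frame I time_ns T [box a b c]`
followed by one `x y z` line per atom), aligned FASTA for MSAs, CSV
(`voltage_mV,current_pA`) for I/V data, and TSV
(`z_center value se n_samples`) for profiles.

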