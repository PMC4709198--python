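# amphitraj

Trajectory analysis of amphipathic ligand–membrane-protein interactions.

Free fatty acids partition into lipid bilayers and modulate membrane
proteins — most prominently voltage-gated ion channels, where
polyunsaturated fatty acids (PUFAs) such as docosahexaenoic acid shift
voltage dependence while their fully saturated counterparts (SFAs) do not.
Characterising *how* an amphipathic ligand engages a tetrameric channel in a
molecular-dynamics trajectory requires a battery of measurements that are
scattered across ad-hoc scripts in most labs:

* **chain flexibility** — per-carbon deuterium order parameters
  S_CD(i) = ⟨(3 cos²θᵢ − 1)/2⟩ (θᵢ: angle of the C–H bond to the membrane
  normal), tail radius of gyration, and the head-oxygen-to-terminal-carbon
  (O–C22) distance;
* **contact fingerprints** — residues whose minimum distance to the ligand's
  carboxyl head group or carbon tail stays within a cutoff (default 3.5 Å)
  for more than a persistence threshold (default 300 ns, strict), with
  contact frequencies, helix-region attribution (S1–S4, S3–S4 linker, pore)
  and hydrophobic/polar/charged classing;
* **segment-wise minimum distances** — HEAD and tail quarters TAIL-A (C2–6)
  … TAIL-D (C17–22), or head vs C12–22, with standard errors across the
  four channel subunits;
* **residency** — continuous intervals a whole molecule spends within a
  cutoff (default 2 Å) of the protein, optionally near a named residue set;
* **occupancy density maps** — fraction-of-frames voxel grids with
  iso-surface export (OpenDX + OBJ) for "X % occupancy" renderings;
* **lateral diffusion** — unwrapped xy tracks, time/ensemble-averaged MSD,
  and D = slope/4 from the 2-D Einstein relation;
* **structural stability** — backbone RMSD against the trajectory-average
  structure after least-squares superposition.

`amphitraj` implements the full battery over a small topology/trajectory
data model (PDB/GRO structures; XTC/DCD/TRR or a plain-text dialect for
trajectories), plus a **synthetic system generator** that plants known
ground truth — tail disorder, contact intervals, residence times, a lateral
diffusion constant — so that every analysis stage is verifiable without
running MD. See `docs/methods.md` for the model details and design choices.

## Worked example

Generate a toy tetramer system with two planted contacts (a head contact on
the S3–S4 linker of subunit A and a tail contact on helix S4 of subunit B),
then fingerprint it:

```python
from amphitraj.synthetic import GeneratorConfig, PlantedContact, generate_system
from amphitraj.schema import default_fatty_acid_schema
from amphitraj.contacts import ContactCriterion, detect_contacts, contact_table
from amphitraj.density import lateral_diffusion

schema = default_fatty_acid_schema(22)
cfg = GeneratorConfig(
    n_frames=500, dt_ns=1.0, n_ligands=8,
    planted_contacts=[
        PlantedContact("A", 323, 0, "head", [(0.0, 400.0)]),
        PlantedContact("B", 329, 1, "tail", [(50.0, 420.0)]),
    ],
    seed=11,
)
topology, trajectory, truth = generate_system(cfg)

criterion = ContactCriterion(distance_cutoff=3.5, persistence_threshold=300.0)
events = detect_contacts(trajectory, criterion, "role:protein", schema)
print(contact_table(events, trajectory).filtered.to_string(index=False))

fit = lateral_diffusion(trajectory, "role:ligand", fit_window=(0.01, 0.1),
                        exclude_molecules={("L", 1), ("L", 2)})
print(f"lateral D = {fit.D_cm2_per_s:.2e} cm^2/s")
```

Output:

```
chain_id  residue_id residue_name ligand_part  cumulative_ns  longest_continuous_ns  frequency       region  extracellular residue_class
       A         323          ASN        head          401.0                  401.0      0.802 S3-S4_linker           True         polar
       B         329          ALA        tail          371.0                  371.0      0.742           S4           True   hydrophobic
lateral D = 3.82e-09 cm^2/s
```

The filtered table recovers exactly the two planted contacts: cumulative
times match the planted 400/370 ns intervals to one frame, the frequency
column is cumulative time over the 500 ns trajectory, and region/class
annotations come from the generated region map.  The diffusion constant
fitted from the six freely diffusing ligands (the two contact-planted
molecules are excluded) recovers the generator's planted
4 × 10⁻⁹ cm²/s within a few percent.

The same battery is available from the shell:

```sh
amphitraj generate -c examples/gen.yaml --out-prefix scratch/sys
amphitraj contacts -s scratch/sys.pdb -t scratch/sys.txt --cutoff 3.5 --min-time 300
amphitraj report -c examples/demo.yaml      # full pipeline + JSON manifest
```

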