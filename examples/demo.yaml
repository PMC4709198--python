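# Synthetic demo: tetrameric channel in a bilayer with 8 fatty-acid ligands,
# two planted head contacts on the S3-S4 linker and one tail contact on S3.
output_dir: scratch/demo_report
generate:
  n_frames: 120
  dt_ns: 1.0
  n_ligands: 8
  n_lipids: 32
  flexibility: 0.8
  planted_contacts:
    - {chain_id: A, residue_id: 322, ligand_id: 0, part: head, intervals: [[0.0, 80.0]]}
    - {chain_id: B, residue_id: 325, ligand_id: 1, part: head, intervals: [[10.0, 100.0]]}
    - {chain_id: C, residue_id: 318, ligand_id: 2, part: tail, intervals: [[0.0, 70.0]]}
schema: fatty_acid_22
contact_cutoff: 3.5
persistence_threshold_ns: 50.0
residency_cutoff: 3.5
density_voxel: 2.0
iso_threshold: 0.27
diffusion_fit_window: [0.1, 0.5]
seed: 11
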