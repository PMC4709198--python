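# Generator config for a standalone synthetic system (CLI `amphitraj generate`).
n_frames: 200
dt_ns: 1.0
n_ligands: 8
n_lipids: 32
flexibility: 0.8
planted_contacts:
  - {chain_id: A, residue_id: 323, ligand_id: 0, part: head, intervals: [[0.0, 150.0]]}
seed: 11
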