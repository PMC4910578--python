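# Reference run configuration.  All defaults are explicit here: copy this
# file, adjust paths, and run `plgicmap run --config my_config.yaml`.
#
# Structure files are local PDB/mmCIF paths; `plgicmap fetch 4COF 3RIF ...`
# downloads them when network access is available.  Every other command
# works offline.
#
# Anchor resolution per structure comes either from the master alignment
# (`alignment:` plus per-structure `rows:` mapping chain id -> alignment
# row) or from a ground-truth JSON sidecar (`anchors_json`, as written by
# `plgicmap make-fixtures` for synthetic receptors).

seed: 1
output: out
verbosity: 1

alignment:
  path: master_alignment.sto   # Stockholm with a '#=GC anchors' track
  format: stockholm

structures:
  - label: 4COF
    path: structures/4cof.pdb
    format: pdb
    assembly_note: deposited biological pentamer
    rows: {A: GABAA_b3, B: GABAA_b3, C: GABAA_b3, D: GABAA_b3, E: GABAA_b3}
  - label: 3RIF
    path: structures/3rif.pdb
    format: pdb
    assembly_note: deposited biological pentamer
    rows: {A: GluCl, B: GluCl, C: GluCl, D: GluCl, E: GluCl}

analyses:
  atlas:
    # heavy-atom contact cutoff in Angstrom (use 6.5 on Calpha-only fixtures)
    contact_cutoff: 4.0
    vestibule_radius: 8.0
    clash_distance: 2.8
    occlusion_threshold: 0.25
    merge_overlap: 0.5
  rmsd:
    subset: pentamer        # ECD | TMD | subunit | pentamer
    mode: structural        # structural | alignment | positional
  group:
    threshold: 2.5          # single-linkage cut, Angstrom
  geometry:
    definitions: ecd_interface   # or intrasubunit, or an inline list
    interfaces:
      4COF: [A, B]
      3RIF: [A, B]
  transfer:
    source: 3RIF
    ligand: null            # null = every ligand in the source
    targets: [4COF]
    mode: structural
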