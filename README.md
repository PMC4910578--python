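# plgicmap

Structure-based mapping of small-molecule binding sites in pentameric
ligand-gated ion channels (pLGICs / cys-loop receptors), and quantitative
analysis of how conformational motion reshapes those sites.

## The problem

GABA_A receptors, glycine receptors, GluCl, the 5-HT3 receptor and the
bacterial channels GLIC and ELIC share one architecture: five subunits
around a central pore, each subunit an extracellular β-sandwich (ECD)
stacked on a four-helix trans-membrane bundle (TMD, helices M1–M4).
Dozens of deposited structures of these homologs carry co-crystallized
ligands — agonists, anesthetics, cations, lipids — in ten recurring
locations per subunit or subunit pair:

| class | location |
|---|---|
| 1–3 | ECD interface subsites (loops B/C/D/E; loop C distal + strand 7 / loops G/F; loop-F cation site) |
| 4 | ECD vestibule (pore-facing, intra-subunit) |
| 5 | ECD packing core between the inner and outer β-sheets |
| 6 | N-terminal helix-1 pocket |
| 7 | TMD inter-subunit interface |
| 8 | TMD intra-subunit (M1/M2/M3) |
| 9 | M1/M4 groove on the subunit minus face |
| 10 | M3/M4 pocket near the intracellular end |

For receptors with only one (or no) ligand-bound structure, the way to
locate these sites is *annotation transfer*: superpose a ligand-bound
homolog, map its pocket-forming residues through a residue-level
correspondence, and check whether the mapped pocket still has room for
the ligand.  `plgicmap` implements that workflow as a tested library:

- **Residue correspondences** either from a curated master alignment
  (gapped rows plus an anchor track naming loops A–G, strands 5/5′/7/8′/9,
  helix 1, pre-M1, M1–M4, MX, MA) or sequence-independently by
  secondary-structure matching: Cα-only SSE assignment, segment matching,
  Kabsch seeding, then iterated nearest-neighbour refinement under a
  strict one-to-one monotonic constraint.
- **Alignment validation** with the conserved strand-8′ motif
  (hydrophobic / any / hydrophobic-or-small, e.g. V-T-G), which pins the
  otherwise ambiguous loop-F region.
- **Site detection and classification**: heavy-atom ligand contacts at a
  4.0 Å cutoff, then a decision cascade over anchor membership, interface
  tests and pore geometry assigns each bound ligand to one of the ten
  classes (pore-blocking ligands are flagged and excluded).
- **Transfer with steric-occlusion scoring**: a transferred ligand is
  placed by a pocket-local superposition and rejected when more than 25%
  of its atoms clash (< 2.8 Å) with the target — this is how a vestibule
  site is ruled out in receptors whose longer strand 5–5′ insertion fills
  that pocket.
- **Conformational analysis**: Cα RMSD at domain/subunit/pentamer
  granularity (with cyclic chain-assignment minimization for pentamers),
  swing–twist decomposition of inter-domain motion about the pore axis,
  internal Cα–Cα pocket distance tables, and single-linkage grouping of
  conformational states.
- **A synthetic-receptor generator** that builds C5-symmetric two-domain
  pentamers with planted secondary structure, anchors, ligands, domain
  motions and pocket-occluding insertions — so the whole pipeline is
  testable offline with exact ground truth.

## Worked example

```python
from plgicmap import (SyntheticSpec, make_pentamer, plant_ligand, ligand_contacts,
                      classify_site, transfer_site, structural_correspondence,
                      pore_axis)
from plgicmap.pockets import PocketConfig
from plgicmap.synthetic import FIXTURE_CONTACT_CUTOFF

open_form, gt = make_pentamer(SyntheticSpec(seed=1))
occluded, _ = make_pentamer(SyntheticSpec(seed=1, occluding_insertion=True))
cfg = PocketConfig(contact_cutoff=FIXTURE_CONTACT_CUTOFF)  # 6.5 A on Calpha fixtures
pore = pore_axis(open_form, gt.m2_keys())
anchor_maps = gt.anchor_maps()

planted, _ = plant_ligand(open_form, gt, site_class=4)   # vestibule ligand
lig = planted.ligands[-1]
contacts = ligand_contacts(planted, lig, cfg.contact_cutoff)
cls = classify_site(contacts, planted, anchor_maps, pore, cfg)
print(f"site class {cls.site_class} ({cls.domain}, interface={cls.interface})")
print(f"contacts: { {c: len(k) for c, k in contacts.contacts.items()} }")

corrs = [structural_correspondence(planted, c, occluded, c) for c in contacts.contacts]
result = transfer_site(contacts, corrs, planted, occluded, cfg)
print(f"transfer onto occluded variant: occlusion={result.occlusion:.2f} -> {result.verdict}")
```

prints

```
site class 4 (ECD, interface=False)
contacts: {'A': 12}
transfer onto occluded variant: occlusion=1.00 -> occluded
```

The planted vestibule ligand touches 12 inner-sheet residues of one
chain and is classified as the intra-subunit vestibule site (class 4).
Transferred onto the variant whose strand 5–5′ linker detours through
that pocket, every ligand atom clashes with the insertion, so the site
is rejected as occluded — the same verdict the analysis returns for the
vestibule site when mapped onto anion-selective receptors.

## Command line

```sh
plgicmap make-fixtures --out fixtures --seed 7   # synthetic test suite + config
plgicmap run --config fixtures/config.yaml      # atlas, RMSD, grouping, geometry, transfer
plgicmap fetch 4COF 3RIF 2YOE                   # optional, needs network
```

`run` executes the analysis blocks of a YAML configuration (see
`src/plgicmap/data/reference_config.yaml` for a fully documented
example, and `src/plgicmap/data/table1_sites.tsv` for the curated
ligand-bound template manifest) and writes TSV/JSON tables plus a
manifest recording every threshold, file checksum and the configuration
hash.  Single blocks are exposed as `atlas`, `superpose`, `geometry`,
`group` and `transfer`.

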