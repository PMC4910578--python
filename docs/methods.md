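# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `plgicmap`.

## Coordinate model

Structures are chains of residues of atoms, addressed by author numbering
(integer plus insertion code).  Parsing and writing go through gemmi; only
the first model of a multi-model file is read.  Alternate locations are
collapsed to the highest-occupancy conformer, ties broken by altloc label
order — a deterministic policy chosen because downstream measurements are
backbone-driven and must not depend on file ordering.  Hetero groups are
split into ligands and solvent/buffer; the exclusion list (HOH, DOD, NA,
CL, K, SO4, PO4, GOL, EDO, PEG, ACT) deliberately keeps divalent cations
(Ba²⁺, Zn²⁺, Ca²⁺, Sr²⁺): in this receptor family they occupy genuine
interface and vestibule sites and must be classified, not discarded.
An optional per-subunit offset table maps author numbering to
mature-protein numbering; author numbering is canonical throughout.
mmCIF is read-only; PDB is the write format.  Whether a given deposited
entry should be used as its asymmetric unit or biological assembly is
recorded per structure in the run configuration (`assembly_note`); the
library itself never generates symmetry copies.

## Secondary structure from Cα geometry

Deposited cryo-EM and crystal structures vary in side-chain quality, so
SSE assignment uses Cα distances only (P-SEA-style):

- helix: d(i,i+3) ∈ [4.4, 6.4] Å and d(i,i+4) ∈ [5.7, 7.7] Å,
- strand: d(i,i+2) ∈ [6.0, 7.4] Å with a Cα(i),Cα(i+1),Cα(i+2) angle
  > 115°,

with minimum segment lengths of 5 (helix) and 3 (strand).  A segment is
accepted only when several consecutive windows agree (three for helices),
which suppresses spurious hits at sharp coil corners; isolated windows
that satisfy the distance tests are common at turns and would otherwise
seed false five-residue helices.  Residues without a Cα, and flanks of
chain breaks, are coil.

## Structural correspondence

The sequence-independent pairing mirrors secondary-structure-matching
superposition at Cα resolution:

1. assign SSE strings to both chains and extract segments;
2. match segments order-preservingly by type, requiring length
   compatibility within a factor of two (LCS-style dynamic program scored
   by overlap length);
3. seed a Kabsch fit from the matched segments' residues, paired from
   segment centres;
4. refine: superpose, pair each source Cα with its nearest target Cα
   within 3.5 Å, reduce the candidates to the largest strictly monotonic
   one-to-one subset (dynamic program maximizing pair count, ties broken
   toward smaller summed distance), refit, and repeat until the pair set
   is stable or 50 iterations.

Monotonicity is enforced even though generic structure matching permits
crossings: subunit topology in this family is strictly sequential, and
the constraint makes results deterministic and symmetric.  Fewer than
three seed pairs is a hard error.

Alignment-derived correspondences pair residues sharing a column of the
master alignment.  A row must match its chain's sequence; up to 2% of
positions may disagree (engineered constructs — linker replacements for
the intracellular domain, crystallization mutations), and such pairs are
kept but flagged.  Beyond 2% the mapping errors out listing the
mismatches.

## Master alignment and anchors

The master alignment is an input, not a product: this package does not
build multiple alignments.  Its per-column anchor track names the binding
site-forming elements (loops A–G, strands 5/5′/7/8′/9, helix 1, pre-M1,
M1–M4, MX, MA); each label occupies one contiguous column block.
Serialization is Stockholm with a `#=GC anchors` line (one code character
per column) or aligned FASTA plus a tab-separated sidecar of
label/start/end blocks.  The strand-8′ validator enforces the conserved
3-residue pattern — position 1 hydrophobic {A,V,L,I,M,F,W,C}, position 3
hydrophobic or small {G,A,S} — on every row's anchor window; these
standard residue classes cover the V and G of the V-T-G exemplar.  The
shipped anchor layout for synthetic receptors is exact by construction;
for real receptor families the loop boundaries are editable configuration
and should be reviewed against a curated alignment before residue-level
claims are made.

## Superposition and RMSD

All superpositions are Cα-only least-squares (Kabsch via SVD, reflections
excluded), with no outlier trimming: every matched pair contributes, so
reported RMSDs stay comparable across correspondence choices.  Domain
subsets derive from the anchor track — ECD is the chain start through the
last pre-M1 residue, TMD the first M1 through the last M4 residue — and
are configurable, since deposited entries differ in where domains are
truncated.  Pentamer RMSDs take the minimum over the five cyclic
chain-order assignments only; mirror assignments would invert the ring's
handedness and are forbidden.  The counter-clockwise subunit order (as
viewed from the extracellular side) is assumed for all pentamers.

The pore axis is the principal axis of the pooled M2-helix Cα cloud,
oriented positive toward the extracellular side.  Inter-domain motion is
decomposed by superposing the TMDs, fitting the residual ECD-onto-ECD
rotation, and splitting that rotation (swing–twist on quaternions) into a
twist about the pore axis and a tilt of the axis.  Rotations below 0.1°
are reported as zero with a degeneracy flag, since the axis of a
near-identity rotation is numerically meaningless.

## Site detection, classification, transfer

Contacts are heavy-atom/heavy-atom within 4.0 Å (the convention of
ligand-interaction diagrams); on Cα-only synthetic fixtures the cutoff is
6.5 Å, compensating for the missing side chains.  Classification is a
cascade: ligands inside an 8 Å cylinder around the pore axis at TMD
heights are flagged as channel blockers and left unclassified (pore
pharmacology is out of scope); the contact majority fixes the domain
(junction contacts follow the TMD rules); an interface requires two
chains with at least two contacts each; anchor-overlap fractions then
separate the subsites.  At the ECD interface, a plurality in loops
B/C/D/E gives subsite 1 and in loops G/F + strand 7 subsite 2; a
monatomic cation touching the loop-F/strand-7 region is the class-3
cation site.  Non-interface ECD ligands are vestibule (class 4) when
their centroid falls inside the pore cylinder above the TMD, helix-1
(class 6) on a helix-1 plurality, and packing-core (class 5) when
contacts span both the inner (strands 5/5′) and outer (strands 7/9)
sheets.  TMD interface ligands are class 7 with the principal chain
chosen by M2/M3 contribution; intra-subunit TMD ligands score class 8
(M1+M2+M3), 9 (M1+M4) and 10 (M3+M4, gated to the lower third of the TMD
along the pore axis) and take the argmax.  The 8 Å vestibule radius
separates vestibule-facing from core ligands; like every threshold here
it is configurable and recorded in the run manifest.

Transfer maps each contact residue through a correspondence, places the
source ligand by a Kabsch fit of the mapped pocket Cαs (at least three
required), and scores occlusion as the fraction of ligand atoms within
2.8 Å of any target heavy atom outside the mapped pocket.  Occlusion
above 0.25 rejects the transfer.  The qualitative criterion being
quantified is "the insertion completely fills the space the ligand would
occupy"; 2.8 Å is a conservative heavy-atom clash distance and 0.25
tolerates grazing contacts from imperfect pocket superposition while
rejecting any substantially filled pocket.  Multiple copies of one het
group merge into a single site occurrence when their contact sets share
at least half their residues (several halogenated-anesthetic structures
carry two or three copies in one pocket).

## Pocket geometry and conformational grouping

Pocket geometry across states is measured as internal Cα–Cα distances —
no superposition enters, so the tables are exactly rigid-transform
invariant.  The default ECD-interface set holds 10 distances between the
plus and minus subunits (loop B↔E ×2, loop C tip↔D ×2, loop C tip↔E,
loop A↔G ×2, loop A↔F, strand 7↔F, loop C↔F), anchored at block midpoints
and tips, with the loop-C "tip" defined as the middle residue of the
loop-C block; a companion intra-subunit set covers the packing core and
the three TMD intra-subunit pockets.  These endpoint choices are a
declared default, editable via configuration; per-pocket variability is
the maximum absolute pairwise distance difference across states.
Conformational grouping is single-linkage agglomeration of the pairwise
RMSD matrix cut at 2.5 Å — between the observed within-group (≤ 2.0 Å)
and cross-group (> 3 Å) separations for pentamer ensembles of this
family — with deterministic output ordering.

## Synthetic receptors

The generator builds what the analysis assumes and nothing more: a
C5-symmetric pentamer of two-domain subunits at Cα resolution.  Each
subunit carries an N-terminal helix (helix 1), two β-sheet-like strand
bundles with ideal strand geometry (3.8 Å consecutive Cα, zigzag
amplitude 0.85 Å), explicit loop paths for loops A–G and the strand-8′
triplet, a pre-M1 connector, and four ideal TMD helices (1.5 Å rise,
100°/residue, radius 2.3 Å) in the canonical arrangement — M2 pore-lining,
M3 on the plus face, M1/M4 on the minus face.  Default dimensions: ring
radius 14 Å, 20-residue TMD helices, 7-residue strands (~180 residues per
subunit), noise-free.  Sequences are random with the V-T-G motif planted
at strand 8′.  Controlled states rotate every ECD rigidly about the pore
axis (twist) and about a radial axis (tilt); note a common rotation of
all five ECDs is itself rigid, so interface distances respond to the
local `displace_anchor` motion (e.g. a 2 Å loop-C displacement away from
loop D), not to global twist.  Planted pseudo-ligands are small
tetrahedral clusters (or single cations) at the centroid of each class's
anchor signature, balanced between chains at interfaces; expected
contacts come from a plain double-loop distance scan, independent of the
KD-tree implementation under test.  The occluding variant routes the
strand 5–5′ linker through the vestibule pocket, placing its residues
exactly where the class-4 ligand atoms sit.

What the fixtures do not emulate: side chains, real loop conformations,
sequence–structure coupling, experimental noise statistics, or the
structural diversity of real receptor families.  Passing the planted
tests therefore demonstrates algorithmic correctness (detection,
classification logic, transfer and occlusion arithmetic, motion
decomposition), not biological accuracy of any particular anchor
configuration on real structures.  Analyses of deposited coordinate
files additionally depend on the curated master alignment supplied as
input.

Problem sizes used by the test suite and acceptance script — pentamers of
5 × ~180 residues, ensembles of five states, 10-point clouds for the
superposition oracle, 200 randomized motif windows — keep a full run in
the low seconds while exercising every code path; the planted two-state
ensembles use a 25° twist with 0.15 Å coordinate noise, which puts the
between-state pentamer RMSD (~3.2 Å) and within-state RMSD (~0.36 Å) on
opposite sides of the 2.5 Å grouping threshold.

## Known limitations

- No bond inference, hydrogen handling, assembly generation or flexible
  fitting; files are taken as deposited.
- The classification cascade resolves ambiguous ligands (those spanning
  two subsites) by the larger anchor fraction and reports the overlap
  fractions as evidence rather than attempting probabilistic assignment.
- Occlusion scoring uses a fixed clash distance, not element-specific
  van der Waals radii; for backbone-driven questions the difference is
  immaterial, but borderline occlusion fractions near the 0.25 threshold
  deserve visual inspection.
- The TMD zinc-site evidence (histidine/glutamate pairs at the interface)
  is reported as class-7 evidence, not as a separate class.
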