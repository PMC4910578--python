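"""Secondary-structure assignment, structural matching and the master alignment."""

import math

import numpy as np
import pytest

from plgicmap import (
    alignment_correspondence,
    assign_sse,
    correspondence_agreement,
    structural_correspondence,
    validate_strand8,
)
from plgicmap.alignment import (
    HYDROPHOBIC,
    SMALL,
    AlignmentError,
    MappingError,
    MasterAlignment,
)
from plgicmap.matching import MatchingError, positional_correspondence
from plgicmap.structure import Atom, Chain, Residue, Structure
from tests.conftest import random_rotation


def _ca_chain(points, chain_id="A") -> Chain:
    chain = Chain(id=chain_id)
    for i, p in enumerate(points):
        chain.residues.append(Residue(
            chain_id=chain_id, number=i + 1, icode="", name="ALA",
            atoms=[Atom(name="CA", element="C", position=np.asarray(p, float))]))
    return chain


def ideal_helix(n, rise=1.5, turn=100.0, radius=2.3):
    return [
        (radius * math.cos(math.radians(turn * i)),
         radius * math.sin(math.radians(turn * i)),
         rise * i)
        for i in range(n)
    ]


def ideal_strand(n, rise=3.4, zig=0.85):
    return [((zig if i % 2 else -zig), 0.0, rise * i) for i in range(n)]


def test_ideal_helix_labelled_h():
    sse = assign_sse(_ca_chain(ideal_helix(12)))
    assert sse.count("H") >= 10


def test_ideal_strand_labelled_e():
    sse = assign_sse(_ca_chain(ideal_strand(8)))
    assert sse.count("E") >= 6


def test_too_short_chain_rejected():
    with pytest.raises(MatchingError):
        assign_sse(_ca_chain(ideal_helix(4)))


def test_synthetic_chain_sse_agreement(pentamer):
    s, gt = pentamer
    sse = assign_sse(s.chains[0])
    assert len(sse) == len(s.chains[0])
    agreement = np.mean([a == b for a, b in zip(sse, gt.sse)])
    assert agreement >= 0.90


# ---------------------------------------------------------------------------
# structural correspondence


def test_rigid_copy_gives_identity_pairing(pentamer, rng):
    s, _ = pentamer
    moved = s.transformed(random_rotation(rng), rng.normal(size=3) * 8)
    corr = structural_correspondence(s, "A", moved, "A")
    ident = positional_correspondence(s, "A", moved, "A")
    assert corr.pairs == ident.pairs
    # post-fit RMSD over the matched pairs is numerically zero
    from plgicmap import kabsch_fit

    pa = np.array([s.residue(ka).calpha.position for ka, _ in corr.pairs])
    pb = np.array([moved.residue(kb).calpha.position for _, kb in corr.pairs])
    assert kabsch_fit(pa, pb).rmsd < 1e-6


def test_noisy_copy_mostly_identity(pentamer, rng):
    s, _ = pentamer
    noisy = s.copy()
    for r in noisy.chains[0].residues:
        r.atoms[0].position = r.atoms[0].position + rng.normal(0, 0.3, 3)
    corr = structural_correspondence(s, "A", noisy, "A")
    ident = set(positional_correspondence(s, "A", noisy, "A").pairs)
    frac = sum(p in ident for p in corr.pairs) / len(ident)
    assert frac >= 0.95


def test_matching_symmetric_on_rigid_copies(pentamer, rng):
    s, _ = pentamer
    moved = s.transformed(random_rotation(rng), rng.normal(size=3))
    ab = structural_correspondence(s, "A", moved, "A")
    ba = structural_correspondence(moved, "A", s, "A")
    assert ab.pairs == ba.reversed().pairs


def test_correspondence_invariant_under_rigid_transform(pentamer, rng):
    s, _ = pentamer
    other = s.copy()
    base = structural_correspondence(s, "A", other, "B")
    moved = other.transformed(random_rotation(rng), rng.normal(size=3) * 20)
    again = structural_correspondence(s, "A", moved, "B")
    assert base.pairs == again.pairs


def test_pairs_are_one_to_one_and_monotonic(pentamer):
    s, _ = pentamer
    corr = structural_correspondence(s, "A", s, "B")
    src = [k[1] for k, _ in corr.pairs]
    tgt = [k[1] for _, k in corr.pairs]
    assert src == sorted(src) and len(set(src)) == len(src)
    assert tgt == sorted(tgt) and len(set(tgt)) == len(tgt)


# ---------------------------------------------------------------------------
# alignment correspondence


def _single_chain_structure(seq, label="s"):
    coords = ideal_strand(len(seq))
    chain = _ca_chain(coords)
    for r, aa in zip(chain.residues, seq):
        from plgicmap.structure import one_to_three

        r.name = one_to_three(aa)
    return Structure(label=label, chains=[chain])


def test_identical_rows_full_identity():
    seq = "AVLIMFWCAVLIMFWC"
    sa = _single_chain_structure(seq, "a")
    sb = _single_chain_structure(seq, "b")
    aln = MasterAlignment(rows={"ra": seq, "rb": seq}, anchors=["none"] * len(seq))
    corr = alignment_correspondence(aln, "ra", "rb", sa, "A", sb, "A")
    assert len(corr.pairs) == len(seq)
    assert all(ka == kb for ka, kb in corr.pairs)


def test_gap_block_reduces_pairs_by_gap_length():
    seq = "AVLIMFWCAVLIMFWC"
    gapped = seq[:5] + "-----" + seq[10:]
    sa = _single_chain_structure(seq, "a")
    sb = _single_chain_structure(seq[:5] + seq[10:], "b")
    aln = MasterAlignment(rows={"ra": seq, "rb": gapped}, anchors=["none"] * len(seq))
    corr = alignment_correspondence(aln, "ra", "rb", sa, "A", sb, "A")
    assert len(corr.pairs) == len(seq) - 5


def test_alignment_pairs_match_brute_force_column_scan(homologs):
    sa, sb, aln, _ = homologs
    corr = alignment_correspondence(aln, "homologA", "homologB", sa, "A", sb, "A")
    # brute force: walk columns counting ungapped positions in each row
    expected = []
    ia = ib = 0
    ra, rb = aln.rows["homologA"], aln.rows["homologB"]
    for col in range(aln.length):
        ga, gb = ra[col] in "-.", rb[col] in "-."
        if not ga and not gb:
            expected.append((("A", ia + 1, ""), ("A", ib + 1, "")))
        if not ga:
            ia += 1
        if not gb:
            ib += 1
    assert corr.pairs == expected


def test_sequence_mismatch_beyond_tolerance_errors(homologs):
    sa, _, aln, _ = homologs
    bad = sa.copy()
    for r in bad.chains[0].residues[:40]:
        r.name = "GLY" if r.name != "GLY" else "ALA"
    with pytest.raises(MappingError):
        alignment_correspondence(aln, "homologA", "homologA", sa, "A", bad, "A")


def test_alignment_vs_structural_agreement_on_homologs(homologs):
    sa, sb, aln, _ = homologs
    ac = alignment_correspondence(aln, "homologA", "homologB", sa, "A", sb, "A")
    stc = structural_correspondence(sa, "A", sb, "A")
    assert correspondence_agreement(ac, stc) >= 0.90


# ---------------------------------------------------------------------------
# strand-8' motif


def _motif_alignment(windows: dict[str, str]) -> MasterAlignment:
    rows = {rid: f"AAAA{win}AAAA" for rid, win in windows.items()}
    anchors = ["none"] * 4 + ["strand8p"] * 3 + ["none"] * 4
    return MasterAlignment(rows=rows, anchors=anchors)


def test_vtg_window_passes():
    report = validate_strand8(_motif_alignment({"b3": "VTG"}))
    assert report.passed["b3"]
    assert report.n_violations == 0


def test_charged_first_position_flagged():
    report = validate_strand8(_motif_alignment({"bad": "DTG"}))
    assert not report.passed["bad"]
    assert ("bad", 1, "D") in report.violations


def test_missing_anchor_errors():
    aln = MasterAlignment(rows={"r": "AAAA"}, anchors=["none"] * 4)
    with pytest.raises(AlignmentError):
        validate_strand8(aln)


def test_random_windows_match_brute_force(rng):
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    windows = {f"r{i}": "".join(rng.choice(letters, 3)) for i in range(50)}
    report = validate_strand8(_motif_alignment(windows))
    expected = 0
    for win in windows.values():
        if win[0] not in HYDROPHOBIC:
            expected += 1
        if win[2] not in (HYDROPHOBIC | SMALL):
            expected += 1
    assert report.n_violations == expected


# ---------------------------------------------------------------------------
# master alignment serialization


def test_stockholm_round_trip(homologs):
    _, _, aln, _ = homologs
    again = MasterAlignment.from_stockholm(aln.to_stockholm())
    assert again.rows == aln.rows
    assert again.anchors == aln.anchors


def test_fasta_sidecar_round_trip(homologs):
    _, _, aln, _ = homologs
    fasta, sidecar = aln.to_fasta_sidecar()
    again = MasterAlignment.from_fasta_sidecar(fasta, sidecar)
    assert again.rows == aln.rows
    assert again.anchors == aln.anchors


def test_non_contiguous_anchor_rejected():
    with pytest.raises(AlignmentError, match="non-contiguous"):
        MasterAlignment(rows={"r": "AAAAA"},
                        anchors=["loopA", "none", "loopA", "none", "none"])
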