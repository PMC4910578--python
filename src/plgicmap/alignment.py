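"""The annotated master alignment and alignment-derived residue pairing.

The master alignment is a gapped multiple alignment of receptor-subunit
and template sequences carrying a per-column *anchor* track that names
the conserved binding-site-forming elements: loops A-G, strands 5/5'/7/8'/9,
the N-terminal helix 1, the pre-M1 stretch, the trans-membrane helices
M1-M4 and the intracellular helices MX and MA.  Anchors drive domain
definitions, site classification and the pocket-geometry distance tables.

Serialization: a small Stockholm dialect with the anchor track as a
``#=GC anchors`` line (one code character per column), or aligned FASTA
plus a tab-separated sidecar of ``label<TAB>start<TAB>end`` column blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ANCHOR_LABELS",
    "MasterAlignment",
    "MotifReport",
    "Correspondence",
    "alignment_correspondence",
    "validate_strand8",
    "HYDROPHOBIC",
    "SMALL",
]

#: anchor label -> single-character code used in the Stockholm GC track
ANCHOR_CODES = {
    "loopA": "A", "loopB": "B", "loopC": "C", "loopD": "D", "loopE": "E",
    "loopF": "F", "loopG": "G",
    "strand5": "5", "strand5p": "f", "strand7": "7", "strand8p": "8",
    "strand9": "9",
    "helix1": "h", "preM1": "p",
    "M1": "1", "M2": "2", "M3": "3", "M4": "4", "MX": "x", "MA": "a",
    "none": ".",
}
CODE_TO_ANCHOR = {v: k for k, v in ANCHOR_CODES.items()}
ANCHOR_LABELS = tuple(k for k in ANCHOR_CODES if k != "none")

#: residue classes for the strand-8' motif test (V-x-G exemplar)
HYDROPHOBIC = frozenset("AVLIMFWC")
SMALL = frozenset("GAS")

GAP_CHARS = frozenset("-.")


class AlignmentError(ValueError):
    pass


@dataclass
class MasterAlignment:
    rows: dict[str, str]  # id -> gapped sequence, all equal length
    anchors: list[str]  # per-column labels from ANCHOR_CODES

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise AlignmentError(f"rows have unequal lengths: {sorted(lengths)}")
        self.length = lengths.pop() if lengths else 0
        if len(self.anchors) != self.length:
            raise AlignmentError(
                f"anchor track length {len(self.anchors)} != alignment length {self.length}"
            )
        for lab in self.anchors:
            if lab not in ANCHOR_CODES:
                raise AlignmentError(f"unknown anchor label {lab!r}")
        self._check_contiguous()

    def _check_contiguous(self) -> None:
        seen_done = set()
        prev = None
        for lab in self.anchors:
            if lab != prev:
                if lab in seen_done and lab != "none":
                    raise AlignmentError(f"anchor {lab!r} occupies non-contiguous columns")
                if prev is not None and prev != "none":
                    seen_done.add(prev)
                prev = lab

    # -- column bookkeeping -------------------------------------------------

    def ungapped(self, row_id: str) -> str:
        return "".join(c for c in self.rows[row_id] if c not in GAP_CHARS)

    def column_to_index(self, row_id: str) -> dict[int, int]:
        """Column -> 0-based ungapped residue index, for non-gap columns."""
        out: dict[int, int] = {}
        i = 0
        for col, c in enumerate(self.rows[row_id]):
            if c not in GAP_CHARS:
                out[col] = i
                i += 1
        return out

    def anchor_block(self, label: str) -> tuple[int, int]:
        """(start, end) inclusive column span of an anchor label."""
        cols = [i for i, lab in enumerate(self.anchors) if lab == label]
        if not cols:
            raise AlignmentError(f"anchor {label!r} not present in alignment")
        return cols[0], cols[-1]

    # -- serialization ------------------------------------------------------

    def to_stockholm(self) -> str:
        width = max(max(len(rid) for rid in self.rows), len("#=GC anchors")) + 2
        lines = ["# STOCKHOLM 1.0"]
        for rid, seq in self.rows.items():
            lines.append(f"{rid:<{width}}{seq}")
        track = "".join(ANCHOR_CODES[lab] for lab in self.anchors)
        lines.append(f"{'#=GC anchors':<{width}}{track}")
        lines.append("//")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_stockholm(cls, text: str) -> "MasterAlignment":
        rows: dict[str, str] = {}
        track = ""
        for line in text.splitlines():
            line = line.rstrip()
            if not line or line == "//" or line.startswith("# "):
                continue
            if line.startswith("#=GC"):
                parts = line.split()
                if len(parts) >= 3 and parts[1] == "anchors":
                    track += parts[2]
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                rows[parts[0]] = rows.get(parts[0], "") + parts[1]
        if not rows:
            raise AlignmentError("no sequence rows found in Stockholm input")
        anchors = [CODE_TO_ANCHOR.get(c, "none") for c in track] if track else \
            ["none"] * len(next(iter(rows.values())))
        return cls(rows=rows, anchors=anchors)

    def to_fasta_sidecar(self) -> tuple[str, str]:
        fasta = "".join(f">{rid}\n{seq}\n" for rid, seq in self.rows.items())
        blocks = []
        prev, start = None, 0
        for col, lab in enumerate(list(self.anchors) + ["none"]):
            if lab != prev:
                if prev not in (None, "none"):
                    blocks.append((prev, start, col - 1))
                prev, start = lab, col
        sidecar = "".join(f"{lab}\t{s}\t{e}\n" for lab, s, e in blocks)
        return fasta, sidecar

    @classmethod
    def from_fasta_sidecar(cls, fasta: str, sidecar: str) -> "MasterAlignment":
        rows: dict[str, str] = {}
        rid = None
        for line in fasta.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                rid = line[1:].split()[0]
                rows[rid] = ""
            elif rid is not None:
                rows[rid] += line
        if not rows:
            raise AlignmentError("no sequences in FASTA input")
        length = len(next(iter(rows.values())))
        anchors = ["none"] * length
        for line in sidecar.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            lab, s, e = line.split("\t")
            for col in range(int(s), int(e) + 1):
                anchors[col] = lab
        return cls(rows=rows, anchors=anchors)


# ---------------------------------------------------------------------------
# correspondences


@dataclass
class Correspondence:
    """One-to-one, order-monotonic residue pairing between two chains."""

    source: tuple[str, str]  # (structure label, chain id)
    target: tuple[str, str]
    pairs: list[tuple]  # [(source ResidueKey, target ResidueKey), ...]
    mode: str = "alignment"  # or "structural"
    flagged: list[tuple] = field(default_factory=list)  # mismatched-but-paired

    def __len__(self) -> int:
        return len(self.pairs)

    def mapping(self) -> dict:
        return dict(self.pairs)

    def reversed(self) -> "Correspondence":
        return Correspondence(
            source=self.target,
            target=self.source,
            pairs=[(kb, ka) for ka, kb in self.pairs],
            mode=self.mode,
            flagged=[(kb, ka) for ka, kb in self.flagged],
        )

    def to_tsv(self) -> str:
        lines = ["source_chain\tsource_number\tsource_icode\t"
                 "target_chain\ttarget_number\ttarget_icode\tmode"]
        for (ca, na, ia), (cb, nb, ib) in self.pairs:
            lines.append(f"{ca}\t{na}\t{ia}\t{cb}\t{nb}\t{ib}\t{self.mode}")
        return "\n".join(lines) + "\n"


class MappingError(ValueError):
    pass


def _row_residue_map(aln: MasterAlignment, row_id: str, chain, mismatch_tol: float):
    """0-based ungapped row index -> Residue, verifying sequence agreement."""
    seq_row = aln.ungapped(row_id).upper()
    seq_chain = chain.sequence().upper()
    if len(seq_row) != len(seq_chain):
        raise MappingError(
            f"row {row_id!r} has {len(seq_row)} residues but chain "
            f"{chain.id!r} has {len(seq_chain)}"
        )
    mismatches = [i for i, (a, b) in enumerate(zip(seq_row, seq_chain))
                  if a != b and a != "X" and b != "X"]
    if len(mismatches) > mismatch_tol * max(len(seq_row), 1):
        raise MappingError(
            f"row {row_id!r} vs chain {chain.id!r}: {len(mismatches)} mismatched "
            f"positions (tolerance {mismatch_tol:.0%}): {mismatches[:10]}"
        )
    return {i: r for i, r in enumerate(chain.residues)}, set(mismatches)


def alignment_correspondence(
    aln: MasterAlignment,
    row_a: str,
    row_b: str,
    a, chain_a: str,
    b, chain_b: str,
    mismatch_tol: float = 0.02,
) -> Correspondence:
    """Pair residues of two chains through shared alignment columns.

    Residues occupying the same non-gap column are paired; gap columns
    produce no pair.  Each row's ungapped sequence must match its chain
    (at most ``mismatch_tol`` mismatched positions, which are paired but
    flagged).  Pairs lacking a Cα on either side are dropped.
    """
    for rid in (row_a, row_b):
        if rid not in aln.rows:
            raise MappingError(f"alignment has no row {rid!r}")
    ch_a = a.chain(chain_a)
    ch_b = b.chain(chain_b)
    map_a, mis_a = _row_residue_map(aln, row_a, ch_a, mismatch_tol)
    map_b, mis_b = _row_residue_map(aln, row_b, ch_b, mismatch_tol)
    col_a = aln.column_to_index(row_a)
    col_b = aln.column_to_index(row_b)

    pairs, flagged = [], []
    for col in range(aln.length):
        ia = col_a.get(col)
        ib = col_b.get(col)
        if ia is None or ib is None:
            continue
        ra, rb = map_a[ia], map_b[ib]
        if ra.calpha is None or rb.calpha is None:
            continue
        pair = (ra.key, rb.key)
        pairs.append(pair)
        if ia in mis_a or ib in mis_b:
            flagged.append(pair)
    return Correspondence(
        source=(a.label, chain_a),
        target=(b.label, chain_b),
        pairs=pairs,
        mode="alignment",
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# strand-8' motif


@dataclass
class MotifReport:
    """Per-row check of the strand-8' pattern: hydrophobic / any / hydrophobic-or-small."""

    windows: dict[str, str]  # row id -> 3-character window (may contain gaps)
    passed: dict[str, bool]
    violations: list[tuple[str, int, str]]  # (row id, position 1..3, residue)

    @property
    def n_violations(self) -> int:
        return len(self.violations)


def validate_strand8(aln: MasterAlignment) -> MotifReport:
    """Check every row against the conserved strand-8' 3-residue motif.

    Position 1 must be hydrophobic, position 3 hydrophobic or small
    (position 2 is unconstrained).  Gapped positions are skipped: the
    motif is only enforced where the row actually has residues.
    """
    try:
        start, end = aln.anchor_block("strand8p")
    except AlignmentError as exc:
        raise AlignmentError("strand8p anchor missing: cannot validate motif") from exc
    if end - start + 1 != 3:
        raise AlignmentError(
            f"strand8p anchor block has width {end - start + 1}, expected 3"
        )
    windows: dict[str, str] = {}
    passed: dict[str, bool] = {}
    violations: list[tuple[str, int, str]] = []
    for rid, seq in aln.rows.items():
        win = seq[start : end + 1].upper()
        windows[rid] = win
        ok = True
        if win[0] not in GAP_CHARS and win[0] not in HYDROPHOBIC:
            violations.append((rid, 1, win[0]))
            ok = False
        if win[2] not in GAP_CHARS and win[2] not in (HYDROPHOBIC | SMALL):
            violations.append((rid, 3, win[2]))
            ok = False
        passed[rid] = ok
    return MotifReport(windows=windows, passed=passed, violations=violations)
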