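"""Sequence-independent residue correspondence by secondary-structure matching.

The pipeline mirrors the classic SSM idea at Cα resolution: assign
helix/strand/coil labels from Cα geometry alone (P-SEA-style distance
windows), match secondary-structure segments between the two chains by
type and length, seed a Kabsch fit from the matched segments, then refine
by iterated nearest-Cα pairing under a distance cutoff with a strictly
monotonic one-to-one constraint (longest increasing subsequence), refit
and repeat to convergence.

The monotonicity constraint is stronger than generic SSM (which permits
crossings); receptor-subunit topology is sequential, and the constraint
makes results deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .alignment import Correspondence
from .structure import Chain, Structure
from .superpose import FitError, kabsch_fit

__all__ = [
    "assign_sse",
    "sse_segments",
    "structural_correspondence",
    "correspondence_agreement",
    "MatchingError",
]

# P-SEA-style Calpha-only thresholds (Angstrom / degrees)
HELIX_D13 = (4.4, 6.4)
HELIX_D14 = (5.7, 7.7)
STRAND_D13 = (6.0, 7.4)
STRAND_MIN_ANGLE = 115.0
PAIRING_CUTOFF = 3.5
MAX_ITER = 50


class MatchingError(ValueError):
    """Structural matching failed (too few seeds or no convergence basis)."""


def assign_sse(chain: Chain) -> str:
    """Helix/strand/coil labels (H/E/C) for every residue of a chain.

    Assignment uses Cα geometry only: a residue window is helical when
    d(i,i+3) and d(i,i+4) fall in the canonical helix ranges over a run
    of at least five residues, and extended when d(i,i+2) is in the
    strand range with a near-collinear Cα(i),Cα(i+1),Cα(i+2) angle over
    at least three residues.  Residues without a Cα (or flanking chain
    breaks) are labelled coil.
    """
    coords: list[np.ndarray | None] = [
        (r.calpha.position if r.calpha is not None else None) for r in chain.residues
    ]
    n = len(coords)
    if sum(c is not None for c in coords) < 5:
        raise MatchingError(f"chain {chain.id!r}: fewer than 5 Calpha atoms")

    def dist(i: int, j: int) -> float | None:
        if i < 0 or j >= n or coords[i] is None or coords[j] is None:
            return None
        return float(np.linalg.norm(coords[i] - coords[j]))

    labels = ["C"] * n

    # a window is helical/extended when its distance criteria hold; a
    # segment is only accepted when several consecutive windows agree,
    # which suppresses spurious hits at sharp coil corners
    hflag = [False] * n
    for i in range(n - 4):
        d13 = dist(i, i + 3)
        d14 = dist(i, i + 4)
        if d13 is None or d14 is None:
            continue
        hflag[i] = (HELIX_D13[0] <= d13 <= HELIX_D13[1]
                    and HELIX_D14[0] <= d14 <= HELIX_D14[1])
    for start, length in _runs(hflag):
        if length >= 3:  # covered span >= 7 residues
            for k in range(start, min(start + length + 4, n)):
                labels[k] = "H"

    eflag = [False] * n
    for i in range(n - 2):
        d13 = dist(i, i + 2)
        if d13 is None or not (STRAND_D13[0] <= d13 <= STRAND_D13[1]):
            continue
        a, b, c = coords[i], coords[i + 1], coords[i + 2]
        if a is None or b is None or c is None:
            continue
        v1 = a - b
        v2 = c - b
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        eflag[i] = angle > STRAND_MIN_ANGLE
    for start, length in _runs(eflag):
        if length >= 1 and length + 2 >= 3:
            span = range(start, min(start + length + 2, n))
            if all(labels[k] != "H" for k in span):
                for k in span:
                    labels[k] = "E"
    _drop_short_runs(labels, "H", 5)
    _drop_short_runs(labels, "E", 3)
    return "".join(labels)


def _runs(flags: list[bool]) -> list[tuple[int, int]]:
    out = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


def _drop_short_runs(labels: list[str], kind: str, minimum: int) -> None:
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] == kind:
            j = i
            while j < n and labels[j] == kind:
                j += 1
            if j - i < minimum:
                for k in range(i, j):
                    labels[k] = "C"
            i = j
        else:
            i += 1


def sse_segments(sse: str) -> list[tuple[str, int, int]]:
    """Maximal non-coil runs as (type, start index, length)."""
    segs = []
    i = 0
    while i < len(sse):
        if sse[i] in "HE":
            j = i
            while j < len(sse) and sse[j] == sse[i]:
                j += 1
            segs.append((sse[i], i, j - i))
            i = j
        else:
            i += 1
    return segs


def _match_segments(segs_a, segs_b) -> list[tuple[int, int]]:
    """Order-preserving pairing of compatible segments (DP, LCS-style).

    Two segments are compatible when they share a type and their lengths
    differ by at most a factor of two; the score of a match is the length
    overlap, so long well-conserved elements dominate the seeding.
    """
    na, nb = len(segs_a), len(segs_b)
    score = np.zeros((na + 1, nb + 1))
    back = np.zeros((na + 1, nb + 1), dtype=int)  # 0 diag, 1 up, 2 left
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            ta, _, la = segs_a[i - 1]
            tb, _, lb = segs_b[j - 1]
            diag = -np.inf
            if ta == tb and min(la, lb) * 2 >= max(la, lb):
                diag = score[i - 1, j - 1] + min(la, lb)
            options = (diag, score[i - 1, j], score[i, j - 1])
            k = int(np.argmax(options))
            score[i, j] = options[k]
            back[i, j] = k
    out = []
    i, j = na, nb
    while i > 0 and j > 0:
        k = back[i, j]
        if k == 0:
            out.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif k == 1:
            i -= 1
        else:
            j -= 1
    return out[::-1]


def _monotone_pairs(candidates: list[tuple[int, int, float]]) -> list[tuple[int, int]]:
    """Largest strictly-monotone one-to-one subset of candidate (i, j, d) pairs.

    Dynamic programming over candidates sorted by (i, j): maximizes pair
    count, breaking ties toward smaller total distance, which favors
    pairings consistent with the current superposition.
    """
    cand = sorted(candidates, key=lambda t: (t[0], t[1]))
    n = len(cand)
    if n == 0:
        return []
    best_len = [1] * n
    best_cost = [c[2] for c in cand]
    prev = [-1] * n
    for k in range(n):
        ik, jk, dk = cand[k]
        for m in range(k):
            im, jm, _ = cand[m]
            if im < ik and jm < jk:
                cand_len = best_len[m] + 1
                cand_cost = best_cost[m] + dk
                if cand_len > best_len[k] or (
                    cand_len == best_len[k] and cand_cost < best_cost[k]
                ):
                    best_len[k] = cand_len
                    best_cost[k] = cand_cost
                    prev[k] = m
    end = max(range(n), key=lambda k: (best_len[k], -best_cost[k]))
    out = []
    while end != -1:
        out.append((cand[end][0], cand[end][1]))
        end = prev[end]
    return out[::-1]


def structural_correspondence(
    a: Structure,
    chain_a: str,
    b: Structure,
    chain_b: str,
    cutoff: float = PAIRING_CUTOFF,
    max_iter: int = MAX_ITER,
) -> Correspondence:
    """SSM-style residue correspondence between two chains.

    Returns a one-to-one, order-monotonic pairing of residues (all with
    Cα) together with provenance.  Raises :class:`MatchingError` when
    fewer than three seed pairs can be found.
    """
    ch_a = a.chain(chain_a)
    ch_b = b.chain(chain_b)
    res_a = [r for r in ch_a.residues if r.calpha is not None]
    res_b = [r for r in ch_b.residues if r.calpha is not None]
    xyz_a = np.array([r.calpha.position for r in res_a])
    xyz_b = np.array([r.calpha.position for r in res_b])

    sse_a = assign_sse(ch_a)
    sse_b = assign_sse(ch_b)
    # indices into res_* (Calpha-bearing residues only)
    idx_a = [i for i, r in enumerate(ch_a.residues) if r.calpha is not None]
    sse_ca_a = "".join(sse_a[i] for i in idx_a)
    idx_b = [i for i, r in enumerate(ch_b.residues) if r.calpha is not None]
    sse_ca_b = "".join(sse_b[i] for i in idx_b)

    segs_a = sse_segments(sse_ca_a)
    segs_b = sse_segments(sse_ca_b)
    seeds: list[tuple[int, int]] = []
    for ia, ib in _match_segments(segs_a, segs_b):
        _, sa, la = segs_a[ia]
        _, sb, lb = segs_b[ib]
        n = min(la, lb)
        offa = sa + (la - n) // 2
        offb = sb + (lb - n) // 2
        seeds.extend((offa + k, offb + k) for k in range(n))
    if len(seeds) < 3:
        raise MatchingError(
            f"{a.label}:{chain_a} vs {b.label}:{chain_b}: only {len(seeds)} "
            f"seed pairs from segment matching (need >=3)"
        )

    pairs = sorted(set(seeds))
    fit = kabsch_fit(xyz_a[[p[0] for p in pairs]], xyz_b[[p[1] for p in pairs]])
    tree = cKDTree(xyz_b)
    for _ in range(max_iter):
        moved = fit.transform(xyz_a)
        dist, nearest = tree.query(moved, distance_upper_bound=cutoff)
        candidates = [
            (i, int(j), float(d))
            for i, (d, j) in enumerate(zip(dist, nearest))
            if np.isfinite(d)
        ]
        new_pairs = _monotone_pairs(candidates)
        if len(new_pairs) < 3:
            break
        if new_pairs == pairs:
            break
        pairs = new_pairs
        fit = kabsch_fit(xyz_a[[p[0] for p in pairs]], xyz_b[[p[1] for p in pairs]])

    return Correspondence(
        source=(a.label, chain_a),
        target=(b.label, chain_b),
        pairs=[(res_a[i].key, res_b[j].key) for i, j in pairs],
        mode="structural",
    )


def positional_correspondence(
    a: Structure, chain_a: str, b: Structure, chain_b: str
) -> Correspondence:
    """Pair residues of two equal-length chains by position.

    For structures that share a construction (renumbered copies,
    conformational states of one model) the k-th residue of one chain
    corresponds to the k-th of the other; this is the degenerate
    alignment correspondence with no gaps.
    """
    res_a = [r for r in a.chain(chain_a).residues if r.calpha is not None]
    res_b = [r for r in b.chain(chain_b).residues if r.calpha is not None]
    if len(res_a) != len(res_b):
        raise MatchingError(
            f"positional pairing needs equal chain lengths: "
            f"{len(res_a)} vs {len(res_b)}")
    return Correspondence(
        source=(a.label, chain_a),
        target=(b.label, chain_b),
        pairs=[(ra.key, rb.key) for ra, rb in zip(res_a, res_b)],
        mode="alignment",
    )


def correspondence_agreement(c1: Correspondence, c2: Correspondence) -> float:
    """Fraction of c1's pairs present in c2 (identical source and target keys)."""
    if not c1.pairs:
        return 0.0
    s2 = set(c2.pairs)
    return sum(p in s2 for p in c1.pairs) / len(c1.pairs)
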