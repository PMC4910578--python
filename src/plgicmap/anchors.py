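"""Resolving alignment anchors onto structure residues.

An *anchor map* for one chain is ``{anchor label: [residue keys]}``; a
per-structure collection is ``{chain id: anchor map}``.  Anchor maps come
either from the master alignment (positional mapping of the chain's row)
or straight from a synthetic generator's ground truth, and they feed the
domain definitions used for superposition subsets and site classification:
ECD runs from the chain start to the end of the pre-M1 stretch, TMD from
the start of M1 to the end of M4.
"""

from __future__ import annotations

from .alignment import MasterAlignment
from .structure import Chain, ResidueKey, Structure

__all__ = [
    "ECD_ANCHORS",
    "TMD_ANCHORS",
    "anchors_from_alignment",
    "structure_anchor_maps",
    "reverse_lookup",
    "domain_keys",
    "tmd_z_range",
]

ECD_ANCHORS = frozenset(
    {"loopA", "loopB", "loopC", "loopD", "loopE", "loopF", "loopG",
     "strand5", "strand5p", "strand7", "strand8p", "strand9",
     "helix1", "preM1"}
)
TMD_ANCHORS = frozenset({"M1", "M2", "M3", "M4", "MX", "MA"})

INNER_SHEET = frozenset({"strand5", "strand5p"})
OUTER_SHEET = frozenset({"strand7", "strand9"})


def anchors_from_alignment(
    aln: MasterAlignment, row_id: str, chain: Chain
) -> dict[str, list[ResidueKey]]:
    """Anchor label -> residue keys of one chain, via its alignment row.

    The k-th ungapped residue of the row corresponds to the k-th residue
    of the chain; the chain must have the row's ungapped length.
    """
    seq = aln.ungapped(row_id)
    if len(seq) != len(chain.residues):
        raise ValueError(
            f"row {row_id!r} has {len(seq)} residues, chain {chain.id!r} "
            f"has {len(chain.residues)}"
        )
    col_to_idx = aln.column_to_index(row_id)
    out: dict[str, list[ResidueKey]] = {}
    for col, label in enumerate(aln.anchors):
        if label == "none":
            continue
        idx = col_to_idx.get(col)
        if idx is None:
            continue
        out.setdefault(label, []).append(chain.residues[idx].key)
    return out


def structure_anchor_maps(
    aln: MasterAlignment, s: Structure, row_by_chain: dict[str, str]
) -> dict[str, dict[str, list[ResidueKey]]]:
    """Anchor maps for every chain of a structure (chain id -> row id given)."""
    return {
        cid: anchors_from_alignment(aln, row_id, s.chain(cid))
        for cid, row_id in row_by_chain.items()
    }


def reverse_lookup(anchor_map: dict[str, list[ResidueKey]]) -> dict[ResidueKey, str]:
    out: dict[ResidueKey, str] = {}
    for label, keys in anchor_map.items():
        for key in keys:
            out[key] = label
    return out


def _order_index(chain: Chain) -> dict[ResidueKey, int]:
    return {r.key: i for i, r in enumerate(chain.residues)}


def domain_keys(
    s: Structure,
    anchor_maps: dict[str, dict[str, list[ResidueKey]]],
    domain: str,
) -> set[ResidueKey]:
    """Residue keys of the ECD or TMD across all mapped chains.

    ECD = chain start up to the last pre-M1 residue (or the residue before
    M1 when no pre-M1 anchor is mapped); TMD = first M1 residue through
    the last M4 residue.
    """
    if domain not in ("ECD", "TMD"):
        raise ValueError(f"domain must be 'ECD' or 'TMD', got {domain!r}")
    out: set[ResidueKey] = set()
    for cid, amap in anchor_maps.items():
        chain = s.chain(cid)
        order = _order_index(chain)
        m1 = amap.get("M1", [])
        m4 = amap.get("M4", [])
        prem1 = amap.get("preM1", [])
        if domain == "ECD":
            if prem1:
                end = max(order[k] for k in prem1 if k in order)
            elif m1:
                end = min(order[k] for k in m1 if k in order) - 1
            else:
                end = len(chain.residues) - 1
            out.update(r.key for r in chain.residues[: end + 1])
        else:
            if not m1 or not m4:
                continue
            start = min(order[k] for k in m1 if k in order)
            end = max(order[k] for k in m4 if k in order)
            out.update(r.key for r in chain.residues[start : end + 1])
    return out


def tmd_z_range(
    s: Structure,
    anchor_maps: dict[str, dict[str, list[ResidueKey]]],
    origin,
    axis,
) -> tuple[float, float]:
    """Extent of the TMD along the pore axis (coordinates of projections)."""
    import numpy as np

    zs = []
    for key in domain_keys(s, anchor_maps, "TMD"):
        r = s.residue(key)
        if r is not None and r.calpha is not None:
            zs.append(float(np.dot(r.calpha.position - origin, axis)))
    if not zs:
        raise ValueError("no TMD Calpha atoms to project")
    return min(zs), max(zs)
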