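"""Pocket distance geometry and conformational grouping across states.

Internal Cα-Cα distances between anchor-defined endpoints quantify how a
pocket's geometry differs between conformational states without any
superposition; single-linkage clustering of a pairwise-RMSD matrix splits
an ensemble of pentamer structures into conformational groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .anchors import reverse_lookup  # noqa: F401  (re-export convenience)
from .structure import Structure
from .superpose import RMSDMatrix

__all__ = [
    "DistanceDefinition",
    "PocketGeometryTable",
    "ConformationalGrouping",
    "distance_table",
    "pocket_variability",
    "group_conformations",
    "DEFAULT_ECD_INTERFACE_DISTANCES",
    "DEFAULT_INTRASUBUNIT_DISTANCES",
    "DEFAULT_POCKET_GROUPS",
]


@dataclass(frozen=True)
class DistanceDefinition:
    """A named Cα-Cα distance between two anchor-defined endpoints.

    Each endpoint is (chain role, anchor label, offset): role selects the
    principal ("plus"), complementary ("minus") or same chain at the
    interface under study; the offset indexes into that anchor's residue
    block, with negative offsets counting from the end and the string
    "mid" meaning the block middle (a loop tip).
    """

    label: str
    a: tuple[str, str, int | str]  # (role, anchor, offset)
    b: tuple[str, str, int | str]


#: Default 10-distance description of the ECD interface pocket geometry:
#: loop B <-> loop E (2), loop C tip <-> loop D (2), loop C tip <-> loop E (1),
#: loop A <-> loop G (2), loop A <-> loop F (1), strand 7 <-> loop F (1),
#: loop C <-> loop F (1).
DEFAULT_ECD_INTERFACE_DISTANCES: tuple[DistanceDefinition, ...] = (
    DistanceDefinition("loopB_loopE_1", ("plus", "loopB", 0), ("minus", "loopE", "mid")),
    DistanceDefinition("loopB_loopE_2", ("plus", "loopB", -1), ("minus", "loopE", 0)),
    DistanceDefinition("loopCtip_loopD_1", ("plus", "loopC", "mid"), ("minus", "loopD", "mid")),
    DistanceDefinition("loopCtip_loopD_2", ("plus", "loopC", "mid"), ("minus", "loopD", 0)),
    DistanceDefinition("loopCtip_loopE", ("plus", "loopC", "mid"), ("minus", "loopE", "mid")),
    DistanceDefinition("loopA_loopG_1", ("plus", "loopA", 0), ("minus", "loopG", "mid")),
    DistanceDefinition("loopA_loopG_2", ("plus", "loopA", -1), ("minus", "loopG", 0)),
    DistanceDefinition("loopA_loopF", ("plus", "loopA", "mid"), ("minus", "loopF", "mid")),
    DistanceDefinition("strand7_loopF", ("plus", "strand7", "mid"), ("minus", "loopF", 0)),
    DistanceDefinition("loopC_loopF", ("plus", "loopC", 0), ("minus", "loopF", "mid")),
)

#: Intra-subunit pocket distances (all on the principal chain): the ECD
#: packing core (site 5), the TMD intra-subunit pocket (site 8), the
#: M1/M4 groove (site 9) and the M3/M4 near-ICD site (10).
DEFAULT_INTRASUBUNIT_DISTANCES: tuple[DistanceDefinition, ...] = (
    DistanceDefinition("strand5_strand7", ("same", "strand5", "mid"), ("same", "strand7", "mid")),
    DistanceDefinition("strand5p_strand9", ("same", "strand5p", "mid"), ("same", "strand9", "mid")),
    DistanceDefinition("M1_M2_upper", ("same", "M1", 3), ("same", "M2", -4)),
    DistanceDefinition("M1_M3_upper", ("same", "M1", 3), ("same", "M3", 3)),
    DistanceDefinition("M1_M4_mid", ("same", "M1", "mid"), ("same", "M4", "mid")),
    DistanceDefinition("M3_M4_low", ("same", "M3", -3), ("same", "M4", 2)),
)

#: Which distance columns describe which pocket (for variability summaries).
DEFAULT_POCKET_GROUPS: dict[str, tuple[str, ...]] = {
    "subsite1": ("loopB_loopE_1", "loopB_loopE_2", "loopCtip_loopD_1",
                 "loopCtip_loopD_2", "loopCtip_loopE"),
    "subsite2": ("loopA_loopG_1", "loopA_loopG_2", "loopA_loopF",
                 "strand7_loopF", "loopC_loopF"),
    "site5": ("strand5_strand7", "strand5p_strand9"),
    "site8": ("M1_M2_upper", "M1_M3_upper"),
    "site9": ("M1_M4_mid",),
    "site10": ("M3_M4_low",),
}


@dataclass
class PocketGeometryTable:
    frame: pd.DataFrame  # rows = state labels, columns = definition labels; NaN = missing

    def to_tsv(self) -> str:
        return self.frame.to_csv(sep="\t", na_rep=".", float_format="%.3f")


@dataclass
class ConformationalGrouping:
    groups: list[list[str]]  # partition of structure labels
    threshold: float
    method: str = "single-linkage"

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self, label: str) -> int:
        for i, g in enumerate(self.groups):
            if label in g:
                return i
        raise KeyError(label)


def _resolve_endpoint(
    s: Structure,
    anchor_map: dict,
    chain_id: str,
    anchor: str,
    offset,
):
    keys = anchor_map.get(chain_id, {}).get(anchor)
    if not keys:
        return None
    if offset == "mid":
        idx = len(keys) // 2
    else:
        idx = int(offset)
    try:
        key = keys[idx]
    except IndexError:
        return None
    r = s.residue(key)
    if r is None or r.calpha is None:
        return None
    return r.calpha.position


def distance_table(
    states: list[Structure],
    defs,
    anchor_maps_by_label: dict[str, dict],
    interface_by_label: dict[str, tuple[str, str]],
) -> PocketGeometryTable:
    """One Cα-Cα distance per (state, definition), in each state's own frame.

    ``interface_by_label`` names the (plus chain, minus chain) pair to
    evaluate for each state; "same"-role endpoints resolve on the plus
    chain.  Unresolvable endpoints yield NaN cells (flagged, not dropped).
    """
    defs = list(defs)
    data = {}
    for s in states:
        plus, minus = interface_by_label[s.label]
        amap = anchor_maps_by_label[s.label]
        row = []
        for d in defs:
            pa = _resolve_endpoint(s, amap, _role_chain(d.a[0], plus, minus), d.a[1], d.a[2])
            pb = _resolve_endpoint(s, amap, _role_chain(d.b[0], plus, minus), d.b[1], d.b[2])
            row.append(np.nan if pa is None or pb is None
                       else float(np.linalg.norm(pa - pb)))
        data[s.label] = row
    frame = pd.DataFrame.from_dict(data, orient="index", columns=[d.label for d in defs])
    return PocketGeometryTable(frame=frame)


def _role_chain(role: str, plus: str, minus: str) -> str:
    if role in ("plus", "same"):
        return plus
    if role == "minus":
        return minus
    raise ValueError(f"unknown chain role {role!r}")


def pocket_variability(
    table: PocketGeometryTable,
    pocket_groups: dict[str, tuple[str, ...]] | None = None,
) -> pd.Series:
    """Per-pocket maximum |Δdistance| across all states and definitions.

    For each pocket (a named group of distance columns), the largest
    absolute pairwise difference of any of its distances between any two
    states.  Requires at least two states.
    """
    frame = table.frame
    if len(frame) < 2:
        raise ValueError("pocket variability needs at least two states")
    pocket_groups = pocket_groups or DEFAULT_POCKET_GROUPS
    out = {}
    for pocket, cols in pocket_groups.items():
        cols = [c for c in cols if c in frame.columns]
        if not cols:
            out[pocket] = np.nan
            continue
        sub = frame[cols].to_numpy(float)
        diffs = np.abs(sub[:, None, :] - sub[None, :, :])
        out[pocket] = float(np.nanmax(diffs)) if np.isfinite(diffs).any() else np.nan
    return pd.Series(out, name="max_abs_delta")


def group_conformations(m: RMSDMatrix, threshold: float = 2.5) -> ConformationalGrouping:
    """Single-linkage agglomeration of an RMSD matrix, cut at ``threshold`` Å.

    Deterministic: groups are ordered by their first member's position in
    the matrix label order, members within a group keep label order.
    """
    vals = np.asarray(m.values, float)
    if np.isnan(vals).any():
        bad = [(m.labels[i], m.labels[j]) for i, j in zip(*np.where(np.isnan(vals)))
               if i < j]
        raise ValueError(f"RMSD matrix has missing entries: {bad}")
    n = len(m.labels)
    if n == 1:
        return ConformationalGrouping(groups=[list(m.labels)], threshold=threshold)
    condensed = squareform(vals, checks=False)
    link = linkage(condensed, method="single")
    flat = fcluster(link, t=threshold, criterion="distance")
    by_cluster: dict[int, list[str]] = {}
    for label, cid in zip(m.labels, flat):
        by_cluster.setdefault(int(cid), []).append(label)
    groups = sorted(by_cluster.values(), key=lambda g: m.labels.index(g[0]))
    return ConformationalGrouping(groups=groups, threshold=threshold)
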