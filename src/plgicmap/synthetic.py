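"""Download-free pentameric test fixtures with known ground truth.

The generator builds an idealized C5-symmetric pentamer of two-domain
subunits: an extracellular β-sandwich-like domain (two strand bundles
plus an N-terminal helix, carrying the loop A-G / strand / helix-1
anchors) stacked on a four-helix trans-membrane bundle (M1-M4), all at
Cα resolution.  Subunit domains are internally rigid, so controlled
twist/tilt states, planted pseudo-ligands for every placeable site class
and a vestibule-occluding strand 5-5' insertion all come with exact
ground truth.

Fixtures are Cα plus pseudo-ligand heavy atoms only — contact detection
on synthetic data therefore uses Cα as the "heavy atom" set, with a
6.5 Å cutoff standing in for the 4.0 Å heavy-atom cutoff used on real
structures.  No claim of biophysical realism is made beyond the
geometric structure the analysis pipeline assumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .pockets import ContactSet
from .structure import Atom, Chain, LigandInstance, Residue, ResidueKey, Structure, one_to_three

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_pentamer",
    "make_homolog_pair",
    "perturb_state",
    "plant_ligand",
    "FIXTURE_CONTACT_CUTOFF",
    "PLANTABLE_CLASSES",
]

#: contact cutoff to use on Cα-only fixtures (vs 4.0 Å heavy-atom on real files)
FIXTURE_CONTACT_CUTOFF = 6.5

#: site classes the synthetic geometry can host (all ten)
PLANTABLE_CLASSES = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10)

_CHAIN_IDS = "ABCDE"
_AA = "ACDEFGHIKLMNPQRSTVWY"

# ideal-geometry constants (Angstrom / degrees)
_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_HELIX_TURN = 100.0
_STRAND_RISE = 3.4
_STRAND_ZIG = 0.85
_COIL_SPACING = 2.5

_TETRA = np.array([
    [0.0, 0.0, 0.0],
    [1.5, 0.0, -0.6],
    [-0.75, 1.3, -0.6],
    [-0.75, -1.3, -0.6],
    [0.0, 0.0, 1.6],
])


@dataclass
class SyntheticSpec:
    seed: int = 0
    n_chains: int = 5
    ecd_residues: int = 78  # size target; the realized count is in GroundTruth
    tmd_residues: int = 88
    ring_radius: float = 14.0
    noise_sd: float = 0.0
    occluding_insertion: bool = False

    def __post_init__(self) -> None:
        if self.n_chains != 5:
            raise ValueError("synthetic receptors are pentamers: n_chains must be 5")
        if self.ecd_residues < 30 or self.tmd_residues < 30:
            raise ValueError("need at least 30 residues per domain")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    seed: int
    sse: str  # per-residue template labels (identical across chains)
    anchors: dict[str, list[int]]  # anchor label -> residue numbers (template)
    sequence: str
    ecd_count: int
    tmd_count: int
    geometry: dict
    chain_ids: tuple[str, ...] = tuple(_CHAIN_IDS)
    insertion_numbers: list[int] = field(default_factory=list)
    planted: list[dict] = field(default_factory=list)

    def anchor_maps(self) -> dict[str, dict[str, list[ResidueKey]]]:
        return {
            cid: {lab: [(cid, n, "") for n in nums] for lab, nums in self.anchors.items()}
            for cid in self.chain_ids
        }

    def m2_keys(self) -> list[ResidueKey]:
        return [(cid, n, "") for cid in self.chain_ids for n in self.anchors["M2"]]

    def domain_numbers(self, domain: str) -> list[int]:
        if domain == "ECD":
            end = max(self.anchors["preM1"])
            return [n for n in range(1, end + 1)]
        start = min(self.anchors["M1"])
        end = max(self.anchors["M4"])
        return list(range(start, end + 1))

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "sse": self.sse,
            "anchors": self.anchors,
            "sequence": self.sequence,
            "ecd_count": self.ecd_count,
            "tmd_count": self.tmd_count,
            "geometry": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                         for k, v in self.geometry.items()},
            "chain_ids": list(self.chain_ids),
            "insertion_numbers": self.insertion_numbers,
            "planted": self.planted,
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# geometric primitives


def _unit(v) -> np.ndarray:
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def _perp_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(u, ref))
    e2 = np.cross(u, e1)
    return e1, e2


def _helix_pts(n: int, axis_start, direction, phase: float = 0.0) -> np.ndarray:
    u = _unit(direction)
    e1, e2 = _perp_frame(u)
    start = np.asarray(axis_start, float)
    pts = []
    for i in range(n):
        ang = math.radians(phase + _HELIX_TURN * i)
        pts.append(start + _HELIX_RISE * i * u
                   + _HELIX_RADIUS * (math.cos(ang) * e1 + math.sin(ang) * e2))
    return np.array(pts)


def _strand_pts(n: int, start, direction, zig) -> np.ndarray:
    u = _unit(direction)
    z = _unit(zig)
    start = np.asarray(start, float)
    return np.array([
        start + _STRAND_RISE * i * u + (_STRAND_ZIG if i % 2 else -_STRAND_ZIG) * z
        for i in range(n)
    ])


def _connector(p_from: np.ndarray, p_to: np.ndarray) -> np.ndarray:
    d = float(np.linalg.norm(p_to - p_from))
    k = max(int(round(d / _COIL_SPACING)) - 1, 0)
    if k == 0:
        return np.empty((0, 3))
    ts = np.linspace(0, 1, k + 2)[1:-1]
    return p_from + ts[:, None] * (p_to - p_from)


class _ChainBuilder:
    def __init__(self) -> None:
        self.points: list[np.ndarray] = []
        self.sse: list[str] = []
        self.anchor: list[str | None] = []

    def add(self, pts: np.ndarray, sse: str, anchor: str | None) -> None:
        pts = np.atleast_2d(pts)
        if self.points:
            for p in _connector(self.points[-1], pts[0]):
                self.points.append(p)
                self.sse.append("C")
                self.anchor.append(None)
        for p in pts:
            self.points.append(p)
            self.sse.append(sse)
            self.anchor.append(anchor)


def _subunit_template(spec: SyntheticSpec) -> tuple[np.ndarray, str, list, dict]:
    """One subunit in the local frame: x radially outward, y toward the
    plus-side neighbour, z along the pore axis (extracellular up)."""
    strand_n = max(5, round((spec.ecd_residues - 50) / 4))
    helix_n = max(10, round((spec.tmd_residues - 8) / 4))
    tmd_top = _HELIX_RISE * (helix_n - 1)
    e_lo = tmd_top + 11.0
    e_hi = e_lo + _STRAND_RISE * (strand_n - 1)
    m = 0.5 * (e_lo + e_hi)
    h1z = e_hi + 6.0

    b = _ChainBuilder()
    b.add(_helix_pts(12, (0, -8, h1z), (0, 1, 0)), "H", "helix1")
    b.add(_strand_pts(strand_n, (-4, -2, e_hi), (0, 0, -1), (1, 0, 0)), "E", "strand5")

    # strand 5-5' linker; the occluding variant detours through the
    # vestibule pocket where site-4 ligands sit in open homologs
    s5_atoms = _site4_atoms(spec.ring_radius, e_lo)
    if spec.occluding_insertion:
        b.add(np.array(s5_atoms[1:]), "C", None)
    b.add(np.array([(-3.0, -4.5, e_lo - 1.0), (-2.0, -5.5, e_lo - 1.5),
                    (-1.0, -6.5, e_lo - 1.0), (0.0, -7.0, e_lo - 0.5)]), "C", "loopG")
    b.add(_strand_pts(strand_n, (3.5, 2, e_lo + 1.0), (0, 0, 1), (1, 0, 0)), "E", "strand7")
    b.add(np.array([(2.5, 3.5, e_hi - 3.0), (2.0, 4.5, e_hi - 5.0),
                    (1.5, 5.5, e_hi - 7.0), (1.0, 6.5, e_hi - 9.0)]), "C", "loopB")
    b.add(np.array([(0.5, 7.5, m + 0.5), (0.0, 8.5, m), (-0.2, 9.5, m - 0.3),
                    (0.0, 8.5, m - 0.8), (0.5, 7.5, m - 1.2)]), "C", "loopC")
    b.add(np.array([(1.0, 5.9, m + 2.0), (1.4, 5.4, m + 4.5),
                    (1.8, 4.9, m + 7.0), (2.2, 4.4, m + 9.5)]), "C", "loopA")
    b.add(_strand_pts(strand_n, (3.5, -2, e_hi), (0, 0, -1), (1, 0, 0)), "E", "strand9")
    b.add(np.array([(2.5, -3.5, e_lo - 2.0), (1.5, -5.0, e_lo - 3.0),
                    (0.5, -6.5, e_lo - 3.5), (-0.5, -8.0, e_lo - 3.0),
                    (-1.0, -9.0, e_lo - 2.5)]), "C", "loopF")
    b.add(_strand_pts(3, (-2, -7.5, e_lo - 1.5), (-0.1, 1, 0.15), (1, 0, 0)), "E", "strand8p")
    b.add(np.array([(-3.0, -5.2, m - 3.5), (-3.1, -5.8, m - 1.0),
                    (-3.0, -6.0, m + 1.5)]), "C", "loopE")
    b.add(np.array([(-2.6, -5.6, m + 4.0), (-2.2, -5.8, m + 6.5),
                    (-1.8, -5.4, m + 9.0)]), "C", "loopD")
    b.add(_strand_pts(strand_n, (-4, 1, e_hi - 2.0), (0, 0, -1), (1, 0, 0)), "E", "strand5p")
    b.add(np.array([(-3.0, -0.5, tmd_top + 6.0), (-2.0, -1.5, tmd_top + 4.5),
                    (-1.0, -2.8, tmd_top + 3.0), (0.0, -4.0, tmd_top + 1.8)]), "C", "preM1")
    b.add(_helix_pts(helix_n, (0, -4, tmd_top), (0, 0, -1)), "H", "M1")
    b.add(np.array([(-1.7, -2.7, 0.8), (-3.4, -1.3, 0.3)]), "C", None)
    b.add(_helix_pts(helix_n, (-5, 0, 0), (0, 0, 1)), "H", "M2")
    b.add(np.array([(-3.2, 1.5, tmd_top + 1.2), (-1.2, 3.0, tmd_top + 1.5)]), "C", None)
    b.add(_helix_pts(helix_n, (0.5, 4, tmd_top), (0, 0, -1)), "H", "M3")
    b.add(np.array([(2.0, 3.0, 0.6), (3.5, 1.2, 0.2), (4.5, -0.3, 0.1)]), "C", None)
    b.add(_helix_pts(helix_n, (5, -1.5, 0), (0, 0, 1)), "H", "M4")

    geometry = {
        "ring_radius": spec.ring_radius,
        "strand_n": strand_n,
        "helix_n": helix_n,
        "tmd_top": tmd_top,
        "e_lo": e_lo,
        "e_hi": e_hi,
        "e_mid": m,
        "site4_local_atoms": s5_atoms,
    }
    return np.array(b.points), "".join(b.sse), list(b.anchor), geometry


def _site4_atoms(ring_radius: float, e_lo: float) -> np.ndarray:
    """Local-frame atom sites of a vestibule (site 4) ligand: a small
    cluster pulled inside the pore cylinder beside the inner sheet."""
    center = np.array([-(ring_radius - 7.0), 0.0, e_lo + 4.0])
    return center + _TETRA


def _chain_rotation(k: int) -> np.ndarray:
    ang = math.radians(72.0 * k)
    c, s = math.cos(ang), math.sin(ang)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _to_global(local_pts: np.ndarray, k: int, ring_radius: float) -> np.ndarray:
    shifted = np.asarray(local_pts, float) + np.array([ring_radius, 0.0, 0.0])
    return shifted @ _chain_rotation(k).T


# ---------------------------------------------------------------------------
# generators


def _template_sequence(rng: np.random.Generator, n: int, anchor: list) -> str:
    letters = [str(c) for c in rng.choice(list(_AA), size=n)]
    idx8 = [i for i, a in enumerate(anchor) if a == "strand8p"]
    for i, aa in zip(idx8, "VTG"):
        letters[i] = aa
    return "".join(letters)


def make_pentamer(spec: SyntheticSpec | None = None) -> tuple[Structure, GroundTruth]:
    """Build a C5-symmetric Cα pentamer with exact ground truth.

    Deterministic for a fixed spec/seed: the five chains are identical up
    to rotation by multiples of 72° about the pore (z) axis, before any
    optional coordinate noise.
    """
    spec = spec or SyntheticSpec()
    pts, sse, anchor, geometry = _subunit_template(spec)
    rng = np.random.default_rng(spec.seed)
    seq = _template_sequence(rng, len(pts), anchor)

    anchors: dict[str, list[int]] = {}
    for i, lab in enumerate(anchor):
        if lab is not None:
            anchors.setdefault(lab, []).append(i + 1)
    insertion_numbers: list[int] = []
    if spec.occluding_insertion:
        site4 = np.asarray(geometry["site4_local_atoms"])[1:]
        for i, p in enumerate(pts):
            if any(np.allclose(p, q) for q in site4):
                insertion_numbers.append(i + 1)

    s = Structure(label=f"synthetic_seed{spec.seed}"
                  + ("_occluded" if spec.occluding_insertion else ""))
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_chains, len(pts), 3)) \
        if spec.noise_sd > 0 else None
    for k in range(spec.n_chains):
        cid = _CHAIN_IDS[k]
        gpts = _to_global(pts, k, spec.ring_radius)
        if noise is not None:
            gpts = gpts + noise[k]
        chain = Chain(id=cid)
        for i, p in enumerate(gpts):
            chain.residues.append(Residue(
                chain_id=cid, number=i + 1, icode="", name=one_to_three(seq[i]),
                atoms=[Atom(name="CA", element="C", position=p)],
            ))
        s.chains.append(chain)

    ecd_end = max(anchors["preM1"])
    tmd = list(range(min(anchors["M1"]), max(anchors["M4"]) + 1))
    gt = GroundTruth(
        seed=spec.seed,
        sse=sse,
        anchors=anchors,
        sequence=seq,
        ecd_count=ecd_end,
        tmd_count=len(tmd),
        geometry=geometry,
        insertion_numbers=insertion_numbers,
    )
    return s, gt


def perturb_state(
    base: Structure,
    gt: GroundTruth,
    twist: float = 0.0,
    tilt: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str | None = None,
) -> Structure:
    """A new conformational state: every ECD rotated rigidly about the
    pore axis by ``twist`` degrees and tilted by ``tilt`` degrees about a
    radial (x) axis through the domain junction; the TMD untouched;
    optional Gaussian coordinate noise on every atom."""
    out = base.copy()
    out.label = label or f"{base.label}_tw{twist:g}_ti{tilt:g}"
    ecd_max = max(gt.anchors["preM1"])
    pivot = np.array([0.0, 0.0, gt.geometry["tmd_top"] + 5.5])
    rz = _rot_z(twist)
    rx = _rot_x(tilt)
    for chain in out.chains:
        for r in chain.residues:
            if r.number <= ecd_max:
                for a in r.atoms:
                    p = rz @ a.position
                    a.position = pivot + rx @ (p - pivot)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for chain in out.chains:
            for r in chain.residues:
                for a in r.atoms:
                    a.position = a.position + rng.normal(0.0, noise_sd, 3)
        for lig in out.ligands:
            for a in lig.atoms:
                a.position = a.position + rng.normal(0.0, noise_sd, 3)
    return out


def _rot_z(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def displace_anchor(
    s: Structure,
    gt: GroundTruth,
    label: str = "loopC",
    delta: float = 2.0,
    towards: str = "loopD",
    label_suffix: str | None = None,
) -> Structure:
    """Displace one anchor's residues rigidly by ``delta`` Å per chain.

    The displacement direction is along the line from the neighbouring
    chain's ``towards`` anchor centroid to the displaced anchor's own
    centroid — i.e. a loop-C displacement away from loop D emulates the
    classic "uncapping" motion, increasing the loop C tip to loop D
    distance by ``delta``.
    """
    out = s.copy()
    out.label = s.label + (label_suffix or f"_{label}{delta:+g}")
    cids = list(gt.chain_ids)
    nums = gt.anchors[label]
    other = gt.anchors[towards]
    for k, cid in enumerate(cids):
        minus_cid = cids[(k + 1) % len(cids)]
        own = _positions(out, [(cid, n, "") for n in nums]).mean(axis=0)
        ref = _positions(out, [(minus_cid, n, "") for n in other]).mean(axis=0)
        u = _unit(own - ref)
        for n in nums:
            r = out.residue((cid, n, ""))
            for a in r.atoms:
                a.position = a.position + delta * u
    return out


# ---------------------------------------------------------------------------
# ligand planting


def _keys_near_z(s: Structure, cid: str, numbers: list[int], z0: float, k: int):
    """The k residues of an anchor closest to height z0 (global frame)."""
    cands = []
    for n in numbers:
        r = s.residue((cid, n, ""))
        if r is not None and r.calpha is not None:
            cands.append((abs(r.calpha.position[2] - z0), n))
    cands.sort()
    return [(cid, n, "") for n in sorted(n for _, n in cands[:k])]


def _positions(s: Structure, keys) -> np.ndarray:
    return np.array([s.residue(k).calpha.position for k in keys])


def plant_ligand(
    s: Structure,
    gt: GroundTruth,
    site_class: int,
    chain: str = "A",
) -> tuple[Structure, ContactSet]:
    """Plant a rigid pseudo-ligand whose contact signature matches a site class.

    Interface classes (1, 2, 3, 7) straddle ``chain`` (principal) and its
    counter-clockwise neighbour; the rest sit on ``chain`` alone.  Returns
    the modified structure and the expected contact set computed by an
    exhaustive distance scan at the fixture cutoff (6.5 Å, Cα-only).
    """
    if site_class not in PLANTABLE_CLASSES:
        raise ValueError(f"site class {site_class!r} is not placeable on the synthetic geometry")
    geo = gt.geometry
    cids = list(gt.chain_ids)
    k = cids.index(chain)
    neighbour = cids[(k + 1) % len(cids)]
    a = gt.anchors
    tmd_top = geo["tmd_top"]
    m = geo["e_mid"]
    e_lo = geo["e_lo"]
    e_hi = geo["e_hi"]

    def near(cid, label, z0, count):
        return _keys_near_z(s, cid, a[label], z0, count)

    shift = np.zeros(3)
    n_atoms = 5
    het = "LIG"
    if site_class == 1:
        targets = (near(chain, "loopC", m, 3) + near(chain, "loopB", m + 4, 2)
                   + near(neighbour, "loopD", m + 5, 2) + near(neighbour, "loopE", m, 2))
    elif site_class == 2:
        targets = near(chain, "strand7", e_lo + 3, 3) + near(neighbour, "loopF", e_lo - 3, 3)
    elif site_class == 3:
        targets = near(chain, "strand7", e_lo + 3, 2) + near(neighbour, "loopF", e_lo - 3, 3)
        n_atoms = 1
        het = "BA"
    elif site_class == 4:
        center = _to_global(np.asarray(geo["site4_local_atoms"])[0], k, geo["ring_radius"])
        return _finish_plant(s, gt, center, 5, het, chain, site_class)
    elif site_class == 5:
        targets = (near(chain, "strand5", m, 2) + near(chain, "strand5p", m, 2)
                   + near(chain, "strand7", m, 2) + near(chain, "strand9", m, 2))
    elif site_class == 6:
        targets = [(chain, n, "") for n in a["helix1"][4:8]]
        shift = np.array([0.0, 0.0, -3.5])
    elif site_class == 7:
        targets = near(chain, "M3", tmd_top - 5, 4) + near(neighbour, "M1", tmd_top - 5, 4)
    elif site_class == 8:
        targets = (near(chain, "M1", tmd_top - 7, 3) + near(chain, "M2", tmd_top - 7, 3)
                   + near(chain, "M3", tmd_top - 7, 3))
    elif site_class == 9:
        targets = near(chain, "M1", tmd_top / 2, 4) + near(chain, "M4", tmd_top / 2, 4)
        shift = _chain_rotation(k) @ np.array([0.0, -1.5, 0.0])
    else:  # site 10
        targets = near(chain, "M3", 4.0, 4) + near(chain, "M4", 4.0, 4)
        shift = _chain_rotation(k) @ np.array([1.0, 0.5, 0.0])
    # balance interface ligands between the two chains' contributions:
    # average the per-chain centroids, not the raw residue positions
    by_chain: dict[str, list] = {}
    for key in targets:
        by_chain.setdefault(key[0], []).append(key)
    sides = {cid: _positions(s, keys).mean(axis=0) for cid, keys in by_chain.items()}
    if site_class == 3 and len(sides) == 2:
        # a single cation has short reach: sit it closer to the strand-7 wall
        center = 0.62 * sides[chain] + 0.38 * sides[neighbour] + shift
    else:
        center = np.mean(list(sides.values()), axis=0) + shift
    return _finish_plant(s, gt, center, n_atoms, het, chain, site_class)


def _finish_plant(s, gt, center, n_atoms, het, chain, site_class):
    atoms_xyz = (center + _TETRA[:n_atoms]) if n_atoms > 1 else np.atleast_2d(center)
    element = "BA" if het == "BA" else "C"
    lig = LigandInstance(
        het_name=het, chain_id=chain, number=900 + site_class,
        atoms=[Atom(name=f"C{i+1}" if element == "C" else "BA",
                    element=element, position=p, is_hetero=True)
               for i, p in enumerate(atoms_xyz)],
    )
    out = s.copy()
    out.ligands.append(lig)
    expected = _brute_force_contacts(out, lig, FIXTURE_CONTACT_CUTOFF)
    gt_entry = {"site_class": site_class, "chain": chain, "het": het,
                "contacts": {cid: [list(k) for k in keys]
                             for cid, keys in expected.contacts.items()}}
    gt.planted.append(gt_entry)
    return out, expected


def _brute_force_contacts(s: Structure, lig: LigandInstance, cutoff: float) -> ContactSet:
    # deliberately plain double loop: the generator's own oracle
    lig_xyz = lig.coords()
    contacts: dict[str, list] = {}
    for chain in s.chains:
        hits = []
        for r in chain.residues:
            close = False
            for atom in r.atoms:
                for q in lig_xyz:
                    if np.linalg.norm(atom.position - q) <= cutoff:
                        close = True
                        break
                if close:
                    break
            if close:
                hits.append(r.key)
        if hits:
            contacts[chain.id] = hits
    return ContactSet(ligand=lig, structure_label=s.label, contacts=contacts, cutoff=cutoff)


# ---------------------------------------------------------------------------
# homolog pair + master alignment


def make_homolog_pair(
    seed: int = 0,
    noise_sd: float = 0.0,
    n_mutations: int = 3,
):
    """Two single-chain homolog structures built from the same template,
    plus the master alignment relating them.

    The variant lacks the last two loop-E residues (a small INDEL) and
    carries a few point mutations at unanchored coil positions; geometry
    elsewhere is identical up to optional jitter.  Returns
    ``(struct_a, struct_b, alignment, ground_truth_a)``.
    """
    from .alignment import MasterAlignment

    spec = SyntheticSpec(seed=seed)
    pts, sse, anchor, geometry = _subunit_template(spec)
    rng = np.random.default_rng(seed)
    seq = _template_sequence(rng, len(pts), anchor)

    loop_e = [i for i, lab in enumerate(anchor) if lab == "loopE"]
    removed = set(loop_e[-2:])

    def build(label, keep_all: bool, jitter: float, sequence: str) -> Structure:
        chain = Chain(id="A")
        num = 0
        for i, p in enumerate(pts):
            if not keep_all and i in removed:
                continue
            num += 1
            pos = np.asarray(p, float)
            if jitter > 0:
                pos = pos + rng.normal(0.0, jitter, 3)
            chain.residues.append(Residue(
                chain_id="A", number=num, icode="", name=one_to_three(sequence[i]),
                atoms=[Atom(name="CA", element="C", position=pos)],
            ))
        return Structure(label=label, chains=[chain])

    seq_b = list(seq)
    coil_pos = [i for i, (lab, ss) in enumerate(zip(anchor, sse))
                if lab is None and ss == "C" and i not in removed]
    for i in rng.choice(coil_pos, size=min(n_mutations, len(coil_pos)), replace=False):
        choices = [c for c in _AA if c != seq_b[i]]
        seq_b[i] = str(rng.choice(choices))
    seq_b = "".join(seq_b)

    sa = build("homologA", True, 0.0, seq)
    sb = build("homologB", False, noise_sd, seq_b)

    row_a = seq
    row_b = "".join("-" if i in removed else seq_b[i] for i in range(len(seq)))
    anchors_track = [lab if lab is not None else "none" for lab in anchor]
    aln = MasterAlignment(rows={"homologA": row_a, "homologB": row_b},
                          anchors=anchors_track)

    anchors: dict[str, list[int]] = {}
    for i, lab in enumerate(anchor):
        if lab is not None:
            anchors.setdefault(lab, []).append(i + 1)
    gt = GroundTruth(
        seed=seed, sse=sse, anchors=anchors, sequence=seq,
        ecd_count=max(anchors["preM1"]),
        tmd_count=max(anchors["M4"]) - min(anchors["M1"]) + 1,
        geometry=geometry, chain_ids=("A",),
    )
    return sa, sb, aln, gt
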