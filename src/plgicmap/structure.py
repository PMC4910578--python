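"""Coordinate-file I/O and the in-memory structure model.

A :class:`Structure` is a thin, deterministic view of a coordinate file:
ordered chains of residues of atoms, addressed by *author* numbering
(residue number plus insertion code), with non-solvent hetero groups
isolated as :class:`LigandInstance` objects.  Parsing and writing go
through gemmi; this module owns selection, transformation and the
solvent/buffer policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "LigandInstance",
    "Structure",
    "ResidueKey",
    "DEFAULT_EXCLUDE",
    "apply_numbering_offset",
    "parse_structure",
    "extract_ligands",
    "select_calpha",
    "write_structure",
]

#: Residue key: (chain id, author residue number, insertion code).
ResidueKey = tuple[str, int, str]

#: Hetero groups treated as solvent/buffer, never as ligands.  Divalent
#: cations (BA, ZN, CA, SR) are deliberately *not* listed: they occupy
#: real sites at subunit interfaces and in the vestibule.
DEFAULT_EXCLUDE = frozenset(
    {"HOH", "DOD", "NA", "CL", "K", "SO4", "PO4", "GOL", "EDO", "PEG", "ACT"}
)


class ParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


class SelectionError(KeyError):
    """Raised when a selection names chains or residues that do not exist."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def calpha(self) -> Atom | None:
        return self.atom("CA")


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self):
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None

    def calpha_coords(self) -> np.ndarray:
        """(n, 3) array of Cα positions for residues that have one."""
        return np.array([r.calpha.position for r in self.residues if r.calpha is not None])

    def sequence(self) -> str:
        """One-letter sequence (X for non-standard residues)."""
        return "".join(_three_to_one(r.name) for r in self.residues)


@dataclass
class LigandInstance:
    het_name: str
    chain_id: str
    number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.number, self.icode)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)


@dataclass
class Structure:
    label: str
    chains: list[Chain] = field(default_factory=list)
    ligands: list[LigandInstance] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise SelectionError(f"{self.label}: no chain {chain_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def residue(self, key: ResidueKey) -> Residue | None:
        try:
            chain = self.chain(key[0])
        except SelectionError:
            return None
        return chain.residue(key[1], key[2])

    def protein_coords(self) -> np.ndarray:
        """All protein heavy-atom positions, chains in order."""
        pts = [a.position for c in self.chains for r in c.residues for a in r.atoms
               if not a.element.upper().startswith("H")]
        return np.array(pts) if pts else np.empty((0, 3))

    def copy(self) -> "Structure":
        import copy as _copy

        return _copy.deepcopy(self)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigid-transformed deep copy (x -> R x + t)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        out = self.copy()
        for c in out.chains:
            for r in c.residues:
                for a in r.atoms:
                    a.position = rotation @ a.position + translation
        for lig in out.ligands:
            for a in lig.atoms:
                a.position = rotation @ a.position + translation
        return out


_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M",
}

_AA1TO3 = {v: k for k, v in _AA3TO1.items() if k != "MSE"}


def _three_to_one(name: str) -> str:
    return _AA3TO1.get(name.upper(), "X")


def one_to_three(letter: str) -> str:
    return _AA1TO3.get(letter.upper(), "UNK")


# ---------------------------------------------------------------------------
# parsing

def parse_structure(
    text: str,
    fmt: str = "pdb",
    label: str = "",
    exclude: frozenset[str] | set[str] = DEFAULT_EXCLUDE,
) -> Structure:
    """Parse PDB or mmCIF text into a :class:`Structure`.

    Alternate locations are collapsed to the highest-occupancy conformer
    (ties broken by altloc label order); waters and buffer components are
    dropped from the ligand list; author numbering and insertion codes are
    preserved.  Only the first model of a multi-model file is read.
    """
    fmt = fmt.lower()
    if fmt == "pdb":
        try:
            st = gemmi.read_pdb_string(text)
        except (RuntimeError, ValueError) as exc:
            raise ParseError(f"malformed PDB input: {exc}") from exc
    elif fmt in ("mmcif", "cif"):
        try:
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        except (RuntimeError, ValueError) as exc:
            raise ParseError(f"malformed mmCIF input: {exc}") from exc
    else:
        raise ValueError(f"unknown format {fmt!r}: expected 'pdb' or 'mmcif'")

    st.setup_entities()
    if len(st) == 0:
        raise ParseError("file contains no models")
    model = st[0]

    out = Structure(label=label or st.name or "structure")
    out.metadata["format"] = fmt
    exclude = frozenset(n.upper() for n in exclude)

    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            is_het = gres.het_flag == "H"
            resname = gres.name.upper()
            atoms = _collapse_altlocs(gres, is_het)
            if not atoms:
                continue
            if is_het and resname not in _AA3TO1:
                if resname in exclude:
                    continue
                heavy = [a for a in atoms if not a.element.upper().startswith("H")]
                if heavy:
                    out.ligands.append(
                        LigandInstance(
                            het_name=resname,
                            chain_id=gchain.name,
                            number=gres.seqid.num,
                            icode=(gres.seqid.icode or "").strip(),
                            atoms=heavy,
                        )
                    )
                continue
            chain.residues.append(
                Residue(
                    chain_id=gchain.name,
                    number=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    name=resname,
                    atoms=atoms,
                )
            )
        if chain.residues:
            out.chains.append(chain)
    return out


def _collapse_altlocs(gres, is_het: bool) -> list[Atom]:
    """Highest-occupancy conformer per atom name; ties by altloc order."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for ga in gres:
        atom = Atom(
            name=ga.name,
            element=ga.element.name,
            position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
            occupancy=min(max(ga.occ, 0.0), 1.0),
            altloc=(ga.altloc or "").strip(),
            is_hetero=is_het,
        )
        prev = best.get(ga.name)
        if prev is None:
            best[ga.name] = atom
            order.append(ga.name)
        elif (atom.occupancy, _neg_ord(atom.altloc)) > (prev.occupancy, _neg_ord(prev.altloc)):
            best[ga.name] = atom
    for a in best.values():
        a.altloc = ""
    return [best[n] for n in order]


def _neg_ord(altloc: str) -> int:
    # earlier altloc labels win ties -> larger score
    return -ord(altloc) if altloc else 0


def extract_ligands(
    s: Structure, include: list[str] | None = None
) -> list[LigandInstance]:
    """Ligand instances of ``s``, optionally restricted to het names in ``include``."""
    if include is None:
        return list(s.ligands)
    wanted = {n.upper() for n in include}
    return [lig for lig in s.ligands if lig.het_name in wanted]


def apply_numbering_offset(s: Structure, offsets: dict[str, int]) -> Structure:
    """Renumber chains by per-chain offsets (author -> mature-protein numbering).

    Receptor literature mixes construct and mature numbering (e.g. a
    residue quoted as T255 in the construct is T230 of the mature chain);
    author numbering stays canonical in this package and this helper
    produces an explicitly renumbered copy when mature numbering is
    needed.  Ligand instances on renumbered chains keep their numbers.
    """
    out = s.copy()
    for chain in out.chains:
        delta = offsets.get(chain.id, 0)
        for r in chain.residues:
            r.number += delta
    return out


# ---------------------------------------------------------------------------
# selection

def select_calpha(s: Structure, selection=None) -> list[tuple[ResidueKey, np.ndarray]]:
    """Ordered ``(residue key, Cα position)`` list for a selection.

    ``selection`` may be None (everything), a chain id, a comma-separated
    expression like ``"A:10-30,B"``, or a mapping chain id -> (start, end)
    residue-number range (inclusive).  Residues without a Cα are skipped.
    """
    ranges = _parse_selection(s, selection)
    out: list[tuple[ResidueKey, np.ndarray]] = []
    for chain in s.chains:
        if chain.id not in ranges:
            continue
        lo, hi = ranges[chain.id]
        for r in chain.residues:
            if lo is not None and not (lo <= r.number <= hi):
                continue
            ca = r.calpha
            if ca is not None:
                out.append((r.key, ca.position))
    return out


def _parse_selection(s: Structure, selection) -> dict[str, tuple]:
    all_ids = set(s.chain_ids)
    if selection is None:
        return {cid: (None, None) for cid in all_ids}
    if isinstance(selection, dict):
        missing = set(selection) - all_ids
        if missing:
            raise SelectionError(f"{s.label}: no such chain(s) {sorted(missing)}")
        return {cid: tuple(rng) for cid, rng in selection.items()}
    ranges: dict[str, tuple] = {}
    for token in str(selection).split(","):
        token = token.strip()
        if not token:
            continue
        if ":" in token:
            cid, span = token.split(":", 1)
            lo, hi = span.split("-", 1)
            ranges[cid] = (int(lo), int(hi))
        else:
            ranges[token] = (None, None)
    missing = set(ranges) - all_ids
    if missing:
        raise SelectionError(f"{s.label}: no such chain(s) {sorted(missing)}")
    return ranges


# ---------------------------------------------------------------------------
# writing

def write_structure(
    s: Structure,
    fmt: str = "pdb",
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> str:
    """Serialize to PDB text, optionally applying a rigid transform first."""
    if fmt.lower() != "pdb":
        raise ValueError(f"unsupported write format {fmt!r} (PDB only)")
    if not s.chains and not s.ligands:
        raise ValueError("refusing to write an empty structure")
    src = s
    if rotation is not None or translation is not None:
        rotation = np.eye(3) if rotation is None else np.asarray(rotation, float)
        translation = np.zeros(3) if translation is None else np.asarray(translation, float)
        src = s.transformed(rotation, translation)

    st = gemmi.Structure()
    st.name = src.label
    model = gemmi.Model("1")
    for chain in src.chains:
        gchain = gemmi.Chain(chain.id)
        for r in chain.residues:
            gchain.add_residue(_to_gemmi_residue(r.name, r.number, r.icode, r.atoms, False))
        for lig in src.ligands:
            if lig.chain_id == chain.id:
                gchain.add_residue(
                    _to_gemmi_residue(lig.het_name, lig.number, lig.icode, lig.atoms, True)
                )
        model.add_chain(gchain)
    # ligands on chains that carry no protein
    protein_ids = set(src.chain_ids)
    orphan = {}
    for lig in src.ligands:
        if lig.chain_id not in protein_ids:
            orphan.setdefault(lig.chain_id, []).append(lig)
    for cid, ligs in orphan.items():
        gchain = gemmi.Chain(cid)
        for lig in ligs:
            gchain.add_residue(
                _to_gemmi_residue(lig.het_name, lig.number, lig.icode, lig.atoms, True)
            )
        model.add_chain(gchain)
    st.add_model(model)
    limit = 9999.999
    for c in src.chains:
        for r in c.residues:
            for a in r.atoms:
                if np.any(np.abs(a.position) > limit):
                    raise ValueError("coordinate overflows fixed-width PDB field")
    return st.make_pdb_string()


def _to_gemmi_residue(name, number, icode, atoms, het) -> gemmi.Residue:
    gres = gemmi.Residue()
    gres.name = name
    gres.seqid = gemmi.SeqId(number, icode or " ")
    gres.het_flag = "H" if het else "A"
    for a in atoms:
        ga = gemmi.Atom()
        ga.name = a.name
        ga.element = gemmi.Element(a.element or a.name[0])
        ga.pos = gemmi.Position(*a.position)
        ga.occ = a.occupancy
        ga.b_iso = 0.0
        gres.add_atom(ga)
    return gres
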