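"""End-to-end orchestration: run configured analysis blocks over a
structure manifest and write a reproducible report bundle.

A run configuration is one YAML document naming the structures, the
master alignment (or per-structure ground-truth anchor sidecars), and
the analysis blocks to execute (atlas, rmsd, group, geometry, transfer).
Outputs are TSV/JSON files plus a run manifest recording the tool
version, configuration hash, per-structure checksums and every
geometric threshold in force — enough to re-run bit-identically up to
floating-point determinism.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alignment import MasterAlignment, alignment_correspondence
from .anchors import structure_anchor_maps
from .conformation import (
    DEFAULT_ECD_INTERFACE_DISTANCES,
    DEFAULT_INTRASUBUNIT_DISTANCES,
    DistanceDefinition,
    distance_table,
    group_conformations,
)
from .matching import positional_correspondence, structural_correspondence
from .pockets import PocketConfig, build_site_atlas, ligand_contacts, transfer_site
from .structure import Structure, parse_structure
from .superpose import pairwise_rmsd, pore_axis
from .anchors import domain_keys

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "ConfigError"]

_DISTANCE_SETS = {
    "ecd_interface": DEFAULT_ECD_INTERFACE_DISTANCES,
    "intrasubunit": DEFAULT_INTRASUBUNIT_DISTANCES,
}

KNOWN_BLOCKS = ("atlas", "rmsd", "group", "geometry", "transfer")


class ConfigError(ValueError):
    """Configuration fails schema validation before any computation."""


@dataclass
class StructureEntry:
    label: str
    path: str
    format: str = "pdb"
    rows: dict[str, str] = field(default_factory=dict)  # chain id -> alignment row
    anchors_json: str = ""  # ground-truth sidecar alternative to alignment rows
    assembly_note: str = ""


@dataclass
class RunConfig:
    seed: int
    output: str
    structures: list[StructureEntry]
    analyses: dict[str, dict]
    alignment_path: str = ""
    alignment_format: str = "stockholm"
    verbosity: int = 1
    config_hash: str = ""

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        missing = {"structures", "analyses"} - raw.keys()
        if missing:
            raise ConfigError(f"{path}: missing required keys {sorted(missing)}")
        entries = []
        for i, item in enumerate(raw["structures"]):
            if "label" not in item or "path" not in item:
                raise ConfigError(f"structure #{i}: needs 'label' and 'path'")
            entries.append(StructureEntry(
                label=str(item["label"]),
                path=str(item["path"]),
                format=str(item.get("format", "pdb")),
                rows={str(k): str(v) for k, v in (item.get("rows") or {}).items()},
                anchors_json=str(item.get("anchors_json", "")),
                assembly_note=str(item.get("assembly_note", "")),
            ))
        labels = [e.label for e in entries]
        if len(set(labels)) != len(labels):
            raise ConfigError("structure labels must be unique")
        analyses = raw["analyses"] or {}
        unknown = set(analyses) - set(KNOWN_BLOCKS)
        if unknown:
            raise ConfigError(f"unknown analysis blocks: {sorted(unknown)}")
        for block, params in analyses.items():
            for lab in _referenced_labels(block, params or {}):
                if lab not in labels:
                    raise ConfigError(f"block {block!r} references unknown label {lab!r}")
        aln = raw.get("alignment") or {}
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            output=str(raw.get("output", "out")),
            structures=entries,
            analyses={k: (v or {}) for k, v in analyses.items()},
            alignment_path=str(aln.get("path", "")),
            alignment_format=str(aln.get("format", "stockholm")),
            verbosity=int(raw.get("verbosity", 1)),
            config_hash=hashlib.sha256(text.encode()).hexdigest()[:16],
        )
        base = path.parent
        for e in cfg.structures:
            p = (base / e.path) if not Path(e.path).is_absolute() else Path(e.path)
            if not p.exists():
                raise ConfigError(f"structure file not found: {p}")
            e.path = str(p)
            if e.anchors_json:
                q = (base / e.anchors_json) if not Path(e.anchors_json).is_absolute() \
                    else Path(e.anchors_json)
                if not q.exists():
                    raise ConfigError(f"anchor sidecar not found: {q}")
                e.anchors_json = str(q)
        if cfg.alignment_path:
            p = (base / cfg.alignment_path) if not Path(cfg.alignment_path).is_absolute() \
                else Path(cfg.alignment_path)
            if not p.exists():
                raise ConfigError(f"alignment file not found: {p}")
            cfg.alignment_path = str(p)
        return cfg


def _referenced_labels(block: str, params: dict):
    if block == "geometry":
        yield from (params.get("interfaces") or {})
    elif block == "transfer":
        if params.get("source"):
            yield params["source"]
        yield from (params.get("targets") or [])
    elif block == "rmsd":
        yield from (params.get("labels") or [])


@dataclass
class ReportBundle:
    output_dir: Path
    manifest: dict
    tables: dict[str, object] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


class _Runner:
    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.out = Path(cfg.output)
        self.out.mkdir(parents=True, exist_ok=True)
        self.tables_cache: dict = {}
        params = dict(cfg.analyses.get("atlas", {}) or {})
        if "cutoff" in params:  # CLI-flag spelling
            params["contact_cutoff"] = params.pop("cutoff")
        known = set(PocketConfig.__dataclass_fields__)
        unknown = set(params) - known
        if unknown:
            raise ConfigError(f"atlas block: unknown parameters {sorted(unknown)}")
        self.pocket_config = PocketConfig(**params)
        self.structures: dict[str, Structure] = {}
        self.anchor_maps: dict[str, dict] = {}
        self.alignment: MasterAlignment | None = None

    def log(self, level: int, msg: str) -> None:
        if self.cfg.verbosity >= level:
            print(msg, file=sys.stderr)

    # -- loading ------------------------------------------------------------

    def load(self) -> None:
        if self.cfg.alignment_path:
            text = Path(self.cfg.alignment_path).read_text()
            if self.cfg.alignment_format == "stockholm":
                self.alignment = MasterAlignment.from_stockholm(text)
            else:
                raise ConfigError(
                    f"unsupported alignment format {self.cfg.alignment_format!r}")
        for entry in self.cfg.structures:
            s = parse_structure(Path(entry.path).read_text(), entry.format,
                                label=entry.label)
            self.structures[entry.label] = s
            if entry.anchors_json:
                gt = json.loads(Path(entry.anchors_json).read_text())
                anchors = gt["anchors"] if "anchors" in gt else gt
                self.anchor_maps[entry.label] = {
                    c.id: {lab: [(c.id, n, "") for n in nums]
                           for lab, nums in anchors.items()}
                    for c in s.chains
                }
            elif entry.rows and self.alignment is not None:
                self.anchor_maps[entry.label] = structure_anchor_maps(
                    self.alignment, s, entry.rows)
            self.log(2, f"loaded {entry.label}: {len(s.chains)} chains, "
                        f"{len(s.ligands)} ligands")

    def pore(self, label: str):
        amap = self.anchor_maps[label]
        m2 = [k for cmap in amap.values() for k in cmap.get("M2", [])]
        return pore_axis(self.structures[label], m2)

    def corr_provider(self, mode: str):
        if mode == "structural":
            return structural_correspondence
        if mode == "positional":
            return positional_correspondence
        if mode == "alignment":
            aln = self.alignment
            rows = {e.label: e.rows for e in self.cfg.structures}
            if aln is None:
                raise ConfigError("alignment mode requires an alignment")

            def provider(a, ca, b, cb):
                return alignment_correspondence(
                    aln, rows[a.label][ca], rows[b.label][cb], a, ca, b, cb)

            return provider
        raise ConfigError(f"unknown correspondence mode {mode!r}")

    # -- blocks -------------------------------------------------------------

    def run_atlas(self, params: dict):
        labeled = [self.structures[e.label] for e in self.cfg.structures
                   if e.label in self.anchor_maps]
        pores = {s.label: self.pore(s.label) for s in labeled}
        df = build_site_atlas(labeled, self.anchor_maps, pores, self.pocket_config)
        path = self.out / "atlas.tsv"
        df.to_csv(path, sep="\t", index=False, na_rep=".")
        (self.out / "atlas.json").write_text(df.to_json(orient="records", indent=2))
        return df

    def run_rmsd(self, params: dict):
        subset = params.get("subset", "pentamer")
        mode = params.get("mode", "structural")
        provider = self.corr_provider(mode)
        labels = params.get("labels") or [e.label for e in self.cfg.structures]
        structures = [self.structures[lab] for lab in labels]
        subset_keys = None
        if subset in ("ECD", "TMD"):
            def subset_keys(s):  # noqa: E306
                return domain_keys(s, self.anchor_maps[s.label], subset)
        m = pairwise_rmsd(structures, provider, subset_label=subset,
                          subset_keys=subset_keys,
                          pentamer_mode=subset == "pentamer")
        m.mode = mode
        m.to_frame().to_csv(self.out / f"rmsd_{subset}.tsv", sep="\t", na_rep=".")
        return m

    def run_group(self, params: dict):
        m = self.tables_cache.get("rmsd")
        if m is None:
            m = self.run_rmsd(self.cfg.analyses.get("rmsd", {}))
        g = group_conformations(m, float(params.get("threshold", 2.5)))
        lines = ["group\tstructure"]
        for i, grp in enumerate(g.groups):
            lines.extend(f"{i}\t{lab}" for lab in grp)
        (self.out / "groups.tsv").write_text("\n".join(lines) + "\n")
        return g

    def run_geometry(self, params: dict):
        name = params.get("definitions", "ecd_interface")
        if isinstance(name, str):
            defs = _DISTANCE_SETS.get(name)
            if defs is None:
                raise ConfigError(f"unknown distance-definition set {name!r}")
        else:
            defs = [DistanceDefinition(d["label"], tuple(d["a"]), tuple(d["b"]))
                    for d in name]
        interfaces = {lab: tuple(pair) for lab, pair
                      in (params.get("interfaces") or {}).items()}
        states = [self.structures[lab] for lab in interfaces]
        tbl = distance_table(states, defs, self.anchor_maps, interfaces)
        (self.out / "geometry.tsv").write_text(tbl.to_tsv())
        return tbl

    def run_transfer(self, params: dict):
        src_label = params["source"]
        het = params.get("ligand")
        src = self.structures[src_label]
        ligs = [l for l in src.ligands if het is None or l.het_name == het]
        if not ligs:
            raise ValueError(f"{src_label}: no ligand {het!r} to transfer")
        mode = params.get("mode", "structural")
        provider = self.corr_provider(mode)
        cutoff = float(params.get("cutoff", self.pocket_config.contact_cutoff))
        rows = ["source\tligand\ttarget\tmapped\tunmapped\tocclusion\tverdict"]
        results = []
        for lig in ligs:
            cs = ligand_contacts(src, lig, cutoff)
            for tgt_label in params.get("targets", []):
                tgt = self.structures[tgt_label]
                corrs = [provider(src, cid, tgt, cid) for cid in cs.contacts]
                ts = transfer_site(cs, corrs, src, tgt, self.pocket_config)
                n_mapped = sum(len(v) for v in ts.mapped.values())
                rows.append(f"{src_label}\t{lig.het_name}\t{tgt_label}\t"
                            f"{n_mapped}\t{ts.unmapped_count}\t"
                            f"{ts.occlusion:.3f}\t{ts.verdict}")
                results.append(ts)
        (self.out / "transfer.tsv").write_text("\n".join(rows) + "\n")
        return results


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute the configured blocks in dependency order.

    Block failures are isolated: a failing block is recorded in the
    bundle and the remaining blocks still run.  The manifest records the
    tool version, configuration hash, structure checksums and all
    thresholds in force.
    """
    runner = _Runner(cfg)
    runner.load()
    bundle = ReportBundle(output_dir=runner.out, manifest={})

    order = [b for b in KNOWN_BLOCKS if b in cfg.analyses]
    for block in order:
        params = cfg.analyses[block]
        try:
            result = getattr(runner, f"run_{block}")(params)
            bundle.tables[block] = result
            if block == "rmsd":
                runner.tables_cache["rmsd"] = result
            runner.log(1, f"[{block}] done")
        except Exception as exc:  # isolate per block
            bundle.failures[block] = f"{type(exc).__name__}: {exc}"
            runner.log(1, f"[{block}] FAILED: {exc}")

    manifest = {
        "tool": "plgicmap",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash,
        "structures": {
            e.label: {
                "path": e.path,
                "sha256": hashlib.sha256(Path(e.path).read_bytes()).hexdigest()[:16],
                "assembly_note": e.assembly_note,
            }
            for e in cfg.structures
        },
        "thresholds": {
            "contact_cutoff": runner.pocket_config.contact_cutoff,
            "vestibule_radius": runner.pocket_config.vestibule_radius,
            "clash_distance": runner.pocket_config.clash_distance,
            "occlusion_threshold": runner.pocket_config.occlusion_threshold,
            "merge_overlap": runner.pocket_config.merge_overlap,
            "group_threshold": cfg.analyses.get("group", {}).get("threshold", 2.5),
        },
        "blocks_run": order,
        "failures": bundle.failures,
    }
    bundle.manifest = manifest
    (runner.out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle
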