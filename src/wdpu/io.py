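"""File formats, run configuration and the generate → analyze → report pipeline.

Structures are written as PDB (via MDAnalysis) or extended-XYZ, always
accompanied by a ``<name>.labels.json`` sidecar holding every per-particle
label and the bonded topology exactly.  In the PDB mapping the residue name
carries the segment type, the chain field the chain id, and the occupancy
column the hydrogen-bond role code (0 none, 1 donor, 2 donor-H, 3 acceptor);
the extended-XYZ writer emits one labeled column per field.  Round-tripping
preserves labels exactly and coordinates to PDB precision (1e-3 Å) or full
precision for extended-XYZ.

``run_pipeline`` executes the three-stage workflow over R seeded replicates
(generate, analyze, aggregate mean ± sd) and writes deterministic JSON/CSV
outputs stamped with a configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .builder import CompositionPreset, get_preset
from .descriptors import DescriptorReport, summarize
from .generator import (DecoyHBonds, DensityProfile, GeneratorConfig,
                        PlantedHBonds, pack_assembly)
from .system import ParticleSystem

__all__ = ["RunConfig", "read_structure", "write_structure", "run_pipeline",
           "config_hash"]

logger = logging.getLogger("wdpu")

_CHAIN_CHARS = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                "abcdefghijklmnopqrstuvwxyz0123456789")
_RESNAME = {"HARD": "HRD", "PCL": "PCL", "PLA": "PLA"}
_RESNAME_BACK = {v: k for k, v in _RESNAME.items()}
_ROLE_CODE = {"none": 0, "donor_heavy": 1, "donor_hydrogen": 2, "acceptor": 3}
_ROLE_BACK = {v: k for k, v in _ROLE_CODE.items()}

_LABEL_FIELDS = ("masses", "radii", "charges", "tag", "chain_id", "unit_index",
                 "segment_type", "block_type", "segment_index", "hbond_role")
_TOPO_FIELDS = ("bonds", "angles", "torsions", "out_of_plane", "chain_ends",
                "segment_ends", "segment_ends_type", "segment_ends_chain")


# ------------------------------------------------------------------- sidecar
def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels.json")


def _write_sidecar(system: ParticleSystem, path: Path) -> None:
    data = {"n_particles": system.n_particles, "version": __version__}
    for name in _LABEL_FIELDS + _TOPO_FIELDS:
        data[name] = np.asarray(getattr(system, name)).tolist()
    data["backbones"] = [b.tolist() for b in system.backbones]
    if system.side_parent is not None:
        data["side_parent"] = system.side_parent.tolist()
    if system.box is not None:
        data["box"] = system.box.tolist()
    _sidecar_path(path).write_text(json.dumps(data))


def _apply_sidecar(positions: np.ndarray, path: Path) -> ParticleSystem:
    data = json.loads(_sidecar_path(path).read_text())
    if data["n_particles"] != len(positions):
        raise ValueError(
            f"sidecar lists {data['n_particles']} particles but structure "
            f"file holds {len(positions)}")
    kwargs = {name: np.asarray(data[name]) for name in _LABEL_FIELDS + _TOPO_FIELDS}
    return ParticleSystem(
        positions=positions,
        backbones=[np.asarray(b, dtype=np.intp) for b in data.get("backbones", [])],
        side_parent=(np.asarray(data["side_parent"], dtype=np.intp)
                     if "side_parent" in data else None),
        box=np.asarray(data["box"]) if "box" in data else None,
        **kwargs)


# ----------------------------------------------------------------------- PDB
def _write_pdb(system: ParticleSystem, path: Path) -> None:
    import MDAnalysis as mda

    if system.n_chains > len(_CHAIN_CHARS):
        raise ValueError(
            f"PDB chain field supports at most {len(_CHAIN_CHARS)} chains; "
            "use extended-XYZ for replicated systems")
    n = system.n_particles
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                               trajectory=True)
        u.add_TopologyAttr("names", [t[:4] for t in system.tag])
        u.add_TopologyAttr("resnames",
                           [_RESNAME.get(s, s[:3]) for s in system.segment_type])
        u.add_TopologyAttr("resids", (system.unit_index + 1).tolist())
        u.add_TopologyAttr("chainIDs",
                           [_CHAIN_CHARS[c] for c in system.chain_id])
        u.add_TopologyAttr("occupancies",
                           [float(_ROLE_CODE[r]) for r in system.hbond_role])
        u.add_TopologyAttr("tempfactors",
                           [float({"PCL": 0, "PLA": 1}.get(b, -1))
                            for b in system.block_type])
        u.add_TopologyAttr("elements", [t[0] for t in system.tag])
        u.atoms.positions = system.positions.astype(np.float32)
        u.atoms.write(str(path))


def _read_pdb_positions(path: Path) -> tuple[np.ndarray, np.ndarray]:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        pos = u.atoms.positions.astype(float)
        try:
            chains = np.asarray(u.atoms.chainIDs)
        except (mda.exceptions.NoDataError, AttributeError):
            chains = np.array([""] * len(pos))
    return pos, chains


# -------------------------------------------------------------- extended XYZ
def _write_extxyz(system: ParticleSystem, path: Path, append: bool = False) -> None:
    cols = ("Properties=species:S:1:pos:R:3:mass:R:1:radius:R:1:charge:R:1:"
            "chain:I:1:unit:I:1:segment:S:1:block:S:1:role:S:1:segidx:I:1")
    lines = [str(system.n_particles), cols]
    for i in range(system.n_particles):
        x, y, z = system.positions[i]
        lines.append(
            f"{system.tag[i]} {x:.10g} {y:.10g} {z:.10g} "
            f"{system.masses[i]:.10g} {system.radii[i]:.10g} "
            f"{system.charges[i]:.10g} {system.chain_id[i]} "
            f"{system.unit_index[i]} {system.segment_type[i]} "
            f"{system.block_type[i]} {system.hbond_role[i]} "
            f"{system.segment_index[i]}")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


def _read_extxyz(path: Path) -> list[dict]:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        n = int(lines[k])
        body = lines[k + 2: k + 2 + n]
        rows = [ln.split() for ln in body]
        frames.append({
            "tag": np.array([r[0] for r in rows], dtype="U6"),
            "positions": np.array([[float(r[1]), float(r[2]), float(r[3])]
                                   for r in rows]),
            "masses": np.array([float(r[4]) for r in rows]),
            "radii": np.array([float(r[5]) for r in rows]),
            "charges": np.array([float(r[6]) for r in rows]),
            "chain_id": np.array([int(r[7]) for r in rows]),
            "unit_index": np.array([int(r[8]) for r in rows]),
            "segment_type": np.array([r[9] for r in rows], dtype="U6"),
            "block_type": np.array([r[10] for r in rows], dtype="U6"),
            "hbond_role": np.array([r[11] for r in rows], dtype="U16"),
            "segment_index": np.array([int(r[12]) for r in rows]),
        })
        k += 2 + n
    return frames


# ------------------------------------------------------------------ public IO
def write_structure(system: ParticleSystem, path, fmt: str | None = None) -> Path:
    """Write a labeled structure plus its JSON label sidecar."""
    path = Path(path)
    fmt = fmt or ("pdb" if path.suffix.lower() == ".pdb" else "extxyz")
    if fmt == "pdb":
        _write_pdb(system, path)
    elif fmt == "extxyz":
        _write_extxyz(system, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'pdb' or 'extxyz'")
    _write_sidecar(system, path)
    return path


def read_structure(path, fmt: str | None = None,
                   require_labels: bool = True) -> ParticleSystem:
    """Read a structure; labels come from the sidecar (authoritative) or the
    embedded extended-XYZ columns.  Unlabeled input is rejected in analysis
    mode (``require_labels``)."""
    path = Path(path)
    fmt = fmt or ("pdb" if path.suffix.lower() == ".pdb" else "extxyz")
    if fmt == "pdb":
        pos, chains = _read_pdb_positions(path)
        blank = [i for i, c in enumerate(chains) if not str(c).strip()]
        if blank:
            shown = blank[:10]
            raise ValueError(f"PDB atoms without chain ids: {shown}"
                             + (" …" if len(blank) > 10 else ""))
        if _sidecar_path(path).exists():
            return _apply_sidecar(pos, path)
        if require_labels:
            raise ValueError(
                f"missing label sidecar {_sidecar_path(path).name}: "
                "PDB alone cannot carry full segment/role labels")
        raise ValueError("label-free PDB reading is not supported")
    frames = _read_extxyz(path)
    if not frames:
        raise ValueError(f"no frames in {path}")
    fr = frames[0]
    if _sidecar_path(path).exists():
        return _apply_sidecar(fr["positions"], path)
    if require_labels:
        # embedded columns carry per-particle labels; topology is empty
        n = len(fr["positions"])
        empty2 = np.empty((0, 2), np.intp)
        return ParticleSystem(
            positions=fr["positions"], masses=fr["masses"], radii=fr["radii"],
            charges=fr["charges"], tag=fr["tag"], chain_id=fr["chain_id"],
            unit_index=fr["unit_index"], segment_type=fr["segment_type"],
            block_type=fr["block_type"], segment_index=fr["segment_index"],
            hbond_role=fr["hbond_role"], bonds=empty2,
            angles=np.empty((0, 3), np.intp), torsions=np.empty((0, 4), np.intp),
            out_of_plane=np.empty((0, 4), np.intp), chain_ends=empty2,
            segment_ends=empty2, segment_ends_type=np.empty(0, "U6"),
            segment_ends_chain=np.empty(0, np.intp))
    raise ValueError("unreachable")


# ------------------------------------------------------------------ RunConfig
@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    replicates: int = 5
    seeds: list | None = None          # defaults to generator.seed + i
    output_dir: str = "wdpu_run"
    include_sasa: bool = False
    sasa_points: int = 384
    hbond_d_cut: float = 3.0
    hbond_angle_cut: float = 30.0
    profile_bin: float = 5.0
    rdf_bin: float = 0.5
    write_structures: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if self.seeds is None:
            self.seeds = [int(self.generator.seed) + i for i in range(self.replicates)]
        if len(self.seeds) != self.replicates:
            raise ValueError("seed list length must equal the replicate count")

    # ---------------------------------------------------------------- yaml
    def to_dict(self) -> dict:
        gen = dataclasses.asdict(self.generator)
        gen["preset"] = dataclasses.asdict(self.generator.preset)
        gen["density_profile"] = dataclasses.asdict(self.generator.density_profile)
        for opt in ("planted_hbonds", "decoy_hbonds"):
            v = getattr(self.generator, opt)
            gen[opt] = dataclasses.asdict(v) if v is not None else None
        d = dataclasses.asdict(self)
        d["generator"] = gen
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        g = dict(d.pop("generator", {}))
        if "preset" in g and g["preset"] is not None:
            p = g["preset"]
            g["preset"] = (get_preset(p) if isinstance(p, str)
                           else CompositionPreset(**p))
        if g.get("density_profile") is not None and not isinstance(
                g.get("density_profile"), DensityProfile):
            g["density_profile"] = DensityProfile(**g["density_profile"])
        if g.get("planted_hbonds") is not None and not isinstance(
                g.get("planted_hbonds"), PlantedHBonds):
            g["planted_hbonds"] = PlantedHBonds(**g["planted_hbonds"])
        if g.get("decoy_hbonds") is not None and not isinstance(
                g.get("decoy_hbonds"), DecoyHBonds):
            g["decoy_hbonds"] = DecoyHBonds(**g["decoy_hbonds"])
        if "anisotropy" in g and g["anisotropy"] is not None:
            g["anisotropy"] = tuple(g["anisotropy"])
        return cls(generator=GeneratorConfig(**g), **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Hash of the scientific run content (paths and log level excluded)."""
    d = config.to_dict()
    d.pop("output_dir", None)
    d.pop("log_level", None)
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ------------------------------------------------------------------- pipeline
def run_pipeline(config: RunConfig) -> DescriptorReport:
    """Generate → analyze → aggregate over replicates; write JSON/CSV files."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    chash = config_hash(config)
    logger.info("pipeline start: hash=%s seeds=%s", chash, config.seeds)
    try:
        systems = []
        for rep, seed in enumerate(config.seeds):
            cfg = config.generator.replace(seed=int(seed))
            assembly = pack_assembly(None, cfg)
            systems.append(assembly.system)
            if config.write_structures:
                write_structure(assembly.system, out / f"replicate_{rep}.xyz")
            logger.info("replicate %d generated (seed %d, %d particles)",
                        rep, seed, assembly.system.n_particles)
        report = summarize(
            systems, include_sasa=config.include_sasa,
            sasa_points=config.sasa_points, hbond_d_cut=config.hbond_d_cut,
            hbond_angle_cut=config.hbond_angle_cut,
            profile_bin=config.profile_bin, rdf_bin=config.rdf_bin)
        report.metadata["config_hash"] = chash
        report.metadata["code_version"] = __version__
        report.metadata["seeds"] = list(config.seeds)
        _write_report(report, out)
        config.to_yaml(out / "config.yaml")
        logger.info("pipeline done")
        return report
    except Exception:
        logger.exception("pipeline stage failed; partial outputs retained in %s", out)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_report(report: DescriptorReport, out: Path) -> None:
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), sort_keys=True, indent=1))
    rows = [{"descriptor": k, "mean": v[0], "sd": v[1],
             **{f"rep{i}": x for i, x in enumerate(v[2])}}
            for k, v in sorted(report.scalars.items())]
    pd.DataFrame(rows).to_csv(out / "scalars.csv", index=False)
    for name, prof in report.profiles.items():
        pd.DataFrame({k: np.asarray(v).ravel() for k, v in prof.items()
                      if len(np.asarray(v).ravel()) > 0 and k != "bin_edges"}
                     | ({"r_lo": np.asarray(prof["bin_edges"])[:-1],
                         "r_hi": np.asarray(prof["bin_edges"])[1:]}
                        if "bin_edges" in prof else {})).to_csv(
            out / f"{name}.csv", index=False)
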