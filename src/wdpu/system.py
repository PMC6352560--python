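"""Labeled particle-system container shared by the builder, generator and descriptors.

A :class:`ParticleSystem` holds one coordinate frame for one or more polymer
chains together with every per-particle label the structural descriptors
consume: masses, van der Waals radii, partial charges, chain / repeating-unit
membership, segment type (hard block vs. PCL vs. PLA soft block), the soft-block
type each particle is attributed to for hydrogen-bond classification, and
donor / hydrogen / acceptor roles.  Bonded topology (bonds, angles, torsions,
out-of-plane tuples) and the junction-nitrogen end markers used for end-to-end
distances ride along as index arrays.

Units: coordinates in Å, masses in Da, charges in units of the elementary
charge.  Ensembles are represented as plain lists of systems (one per
replicate or frame).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

SEGMENT_TYPES = ("HARD", "PCL", "PLA")
BLOCK_TYPES = ("PCL", "PLA")
HBOND_ROLES = ("none", "donor_heavy", "donor_hydrogen", "acceptor")


def _as_int2(a, width: int) -> np.ndarray:
    arr = np.asarray(a, dtype=np.intp)
    if arr.size == 0:
        return arr.reshape(0, width)
    if arr.ndim != 2 or arr.shape[1] != width:
        raise ValueError(f"expected index tuples of width {width}, got shape {arr.shape}")
    return arr


@dataclass
class ParticleSystem:
    """One frame of coordinates plus labels and bonded topology."""

    positions: np.ndarray            # (N, 3) Å
    masses: np.ndarray               # (N,) Da
    radii: np.ndarray                # (N,) Å, van der Waals
    charges: np.ndarray              # (N,) e
    tag: np.ndarray                  # (N,) bead/element tag, e.g. "N", "CH2"
    chain_id: np.ndarray             # (N,) contiguous ints starting at 0
    unit_index: np.ndarray           # (N,) repeating-unit index within the chain
    segment_type: np.ndarray         # (N,) one of SEGMENT_TYPES
    block_type: np.ndarray           # (N,) one of BLOCK_TYPES (classification label)
    segment_index: np.ndarray        # (N,) soft-segment instance id, -1 for hard blocks
    hbond_role: np.ndarray           # (N,) one of HBOND_ROLES
    bonds: np.ndarray                # (B, 2)
    angles: np.ndarray               # (A, 3) central atom second
    torsions: np.ndarray             # (T, 4)
    out_of_plane: np.ndarray         # (O, 4) central atom first, oop atom last
    chain_ends: np.ndarray           # (C, 2) junction-N marker pair per chain
    segment_ends: np.ndarray         # (S, 2) junction-N marker pair per soft segment
    segment_ends_type: np.ndarray    # (S,) PCL / PLA
    segment_ends_chain: np.ndarray   # (S,) chain id
    backbones: list = field(default_factory=list)   # per-chain backbone index arrays
    side_parent: np.ndarray | None = None           # (N,) parent index of side beads, -1 on backbone
    box: np.ndarray | None = None    # (3,) bounding box lengths, Å

    # ------------------------------------------------------------------ basics
    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        for name in ("masses", "radii", "charges"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(n))
        for name in ("chain_id", "unit_index", "segment_index"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.intp).reshape(n))
        for name, dt in (("tag", "U6"), ("segment_type", "U6"),
                         ("block_type", "U6"), ("hbond_role", "U16")):
            setattr(self, name, np.asarray(getattr(self, name), dtype=dt).reshape(n))
        self.bonds = _as_int2(self.bonds, 2)
        self.angles = _as_int2(self.angles, 3)
        self.torsions = _as_int2(self.torsions, 4)
        self.out_of_plane = _as_int2(self.out_of_plane, 4)
        self.chain_ends = _as_int2(self.chain_ends, 2)
        self.segment_ends = _as_int2(self.segment_ends, 2)
        self.segment_ends_type = np.asarray(self.segment_ends_type, dtype="U6").reshape(-1)
        self.segment_ends_chain = np.asarray(self.segment_ends_chain, dtype=np.intp).reshape(-1)
        if self.side_parent is not None:
            self.side_parent = np.asarray(self.side_parent, dtype=np.intp).reshape(n)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1 if self.n_particles else 0

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def copy(self) -> "ParticleSystem":
        new = dataclasses.replace(self)
        for f in dataclasses.fields(self):
            v = getattr(new, f.name)
            if isinstance(v, np.ndarray):
                setattr(new, f.name, v.copy())
        new.backbones = [b.copy() for b in self.backbones]
        return new

    # -------------------------------------------------------------- transforms
    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "ParticleSystem":
        """Return a copy with coordinates rigidly rotated then translated."""
        new = self.copy()
        if rotation is not None:
            new.positions = new.positions @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            new.positions = new.positions + np.asarray(translation, dtype=float)
        return new

    def scaled(self, factor) -> "ParticleSystem":
        """Return a copy with coordinates scaled (scalar or per-axis factors)."""
        new = self.copy()
        new.positions = new.positions * np.asarray(factor, dtype=float)
        if new.box is not None:
            new.box = new.box * np.asarray(factor, dtype=float)
        return new

    def center_of_mass(self) -> np.ndarray:
        m = self.total_mass
        if m <= 0:
            raise ValueError("center of mass undefined for zero total mass")
        return (self.masses[:, None] * self.positions).sum(axis=0) / m

    # ------------------------------------------------------------------ concat
    @classmethod
    def concatenate(cls, systems: list["ParticleSystem"],
                    renumber_chains: bool = True) -> "ParticleSystem":
        """Stack systems, offsetting topology indices (and chain ids if asked)."""
        if not systems:
            raise ValueError("cannot concatenate an empty list of systems")
        off = 0
        chain_off = 0
        seg_off = 0
        parts: dict[str, list] = {f.name: [] for f in dataclasses.fields(cls)
                                  if f.name not in ("backbones", "side_parent", "box")}
        backbones: list[np.ndarray] = []
        side_parent: list[np.ndarray] = []
        for s in systems:
            for name in ("positions", "masses", "radii", "charges", "tag",
                         "unit_index", "segment_type", "block_type",
                         "hbond_role", "segment_ends_type"):
                parts[name].append(getattr(s, name))
            parts["segment_index"].append(
                np.where(s.segment_index >= 0, s.segment_index + seg_off, -1))
            if s.segment_index.size and s.segment_index.max() >= 0:
                seg_off += int(s.segment_index.max()) + 1
            cid = s.chain_id + (chain_off if renumber_chains else 0)
            parts["chain_id"].append(cid)
            parts["segment_ends_chain"].append(
                s.segment_ends_chain + (chain_off if renumber_chains else 0))
            for name in ("bonds", "angles", "torsions", "out_of_plane",
                         "chain_ends", "segment_ends"):
                parts[name].append(getattr(s, name) + off)
            backbones.extend(b + off for b in s.backbones)
            sp = s.side_parent if s.side_parent is not None else np.full(s.n_particles, -1)
            side_parent.append(np.where(sp >= 0, sp + off, -1))
            off += s.n_particles
            chain_off += s.n_chains
        kwargs = {k: np.concatenate(v) if v else v for k, v in parts.items()}
        return cls(backbones=backbones, side_parent=np.concatenate(side_parent),
                   box=None, **kwargs)
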