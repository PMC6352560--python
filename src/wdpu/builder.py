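"""Construction of labeled WDPU-like block-copolymer chain topologies.

A waterborne biodegradable polyurethane (WDPU) chain is modelled as an
alternating sequence of rigid urethane-bearing junction blocks ("hard
segments") and flexible polyester blocks ("soft segments").  Each chain
carries ``repeating_units_per_chain × soft_segments_per_unit`` soft-segment
slots (4 × 2 = 8 by default) which are filled with poly(ε-caprolactone)
(PCL) or polylactide (PLA) blocks in the molar ratio of the composition
preset — 3:1 PCL:PLA for the two shipped presets, i.e. exactly 6 PCL + 2 PLA
slots, with the PLA slot positions drawn from a seeded stream.

Resolution is united-heavy-atom beads plus explicit polar hydrogens on the
urethane nitrogens, which preserves everything the structural descriptors
consume: masses, van der Waals radii, chain/segment labels and
donor–hydrogen–acceptor geometry.  The junction chemistry between the two
marker nitrogens is not modelled explicitly; each junction is padded with
generic backbone beads so a chain meets an exact per-chain particle-count
target (3,070 by default).  Every soft segment is therefore flanked by two
nitrogen marker particles (the N of the N-C…C-N junction motif), which the
end-to-end descriptors use as segment delimiters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .system import ParticleSystem

__all__ = [
    "ELEMENT_MASSES", "BEAD_MASSES", "BEAD_RADII",
    "MonomerSpec", "CompositionPreset", "ChainTopology",
    "build_chain_topology", "single_repeat_chain", "count_particles",
    "assemble_unit_cell", "replicate_cell",
]

ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}

# united-atom bead masses (Da); CP is a generic hard-segment pad bead
BEAD_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "CH": 13.019, "CH2": 14.027, "CH3": 15.035, "CP": 14.027,
}
BEAD_RADII = {
    "H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52,
    "CH": 1.85, "CH2": 1.85, "CH3": 1.95, "CP": 1.85,
}


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class MonomerSpec:
    """Per-repeat composition bookkeeping for one monomer type."""

    name: str
    heavy_atom_count: int
    hydrogen_count: int
    mass: float                      # Da
    donor_sites: int = 0
    acceptor_sites: int = 0
    formula: dict | None = None      # element -> count, optional

    def __post_init__(self):
        if min(self.heavy_atom_count, self.hydrogen_count,
               self.donor_sites, self.acceptor_sites) < 0:
            raise ValueError("monomer site counts must be non-negative")
        if self.mass <= 0:
            raise ValueError("monomer mass must be positive")
        if self.formula is not None:
            m = sum(ELEMENT_MASSES[el] * n for el, n in self.formula.items())
            if abs(m - self.mass) > 0.01 * self.mass:
                raise ValueError(
                    f"monomer mass {self.mass} inconsistent with formula mass {m:.3f}")
            heavy = sum(n for el, n in self.formula.items() if el != "H")
            if heavy != self.heavy_atom_count or self.formula.get("H", 0) != self.hydrogen_count:
                raise ValueError("monomer formula inconsistent with atom counts")

    @classmethod
    def pcl_repeat(cls) -> "MonomerSpec":
        """Open ε-caprolactone repeat −O(CH2)5CO−, C6H10O2."""
        f = {"C": 6, "H": 10, "O": 2}
        mass = sum(ELEMENT_MASSES[e] * n for e, n in f.items())
        return cls("PCL", 8, 10, mass, donor_sites=0, acceptor_sites=2, formula=f)

    @classmethod
    def pla_repeat(cls) -> "MonomerSpec":
        """Lactide half-repeat −OCH(CH3)CO−, C3H4O2."""
        f = {"C": 3, "H": 4, "O": 2}
        mass = sum(ELEMENT_MASSES[e] * n for e, n in f.items())
        return cls("PLA", 5, 4, mass, donor_sites=0, acceptor_sites=2, formula=f)


@dataclass(frozen=True)
class CompositionPreset:
    """Soft-segment composition of a WDPU chain.

    ``pla_form_tag`` records whether the lactide blocks are the L- or the
    racemic D,L-form.  Stereochemistry itself is not modelled; the tag selects
    downstream generator parameters (stiffness, packing) only.
    """

    preset_name: str
    pcl_fraction: float = 0.75
    pla_fraction: float = 0.25
    pla_form_tag: str = "DL"
    repeating_units_per_chain: int = 4
    soft_segments_per_unit: int = 2
    particle_target: int = 3070           # per-chain particle count to pad to
    pcl_repeats_per_segment: int = 18     # ~2054 Da, matching Mn ~ 2000 Da diols
    pla_repeats_per_segment: int = 28     # ~2018 Da

    def __post_init__(self):
        if abs(self.pcl_fraction + self.pla_fraction - 1.0) > 1e-9:
            raise ValueError("pcl_fraction + pla_fraction must equal 1")
        if not (0.0 <= self.pcl_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.pla_form_tag not in ("L", "DL"):
            raise ValueError("pla_form_tag must be 'L' or 'DL'")
        if self.repeating_units_per_chain < 1 or self.soft_segments_per_unit < 1:
            raise ValueError("chain must contain at least one soft-segment slot")

    @property
    def n_slots(self) -> int:
        return self.repeating_units_per_chain * self.soft_segments_per_unit

    @classmethod
    def PCL75DL25(cls, **kw) -> "CompositionPreset":
        return cls("PCL75DL25", pla_form_tag="DL", **kw)

    @classmethod
    def PCL75LL25(cls, **kw) -> "CompositionPreset":
        return cls("PCL75LL25", pla_form_tag="L", **kw)


def get_preset(name: str, **kw) -> CompositionPreset:
    try:
        return {"PCL75DL25": CompositionPreset.PCL75DL25,
                "PCL75LL25": CompositionPreset.PCL75LL25}[name](**kw)
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; use PCL75DL25 or PCL75LL25") from None


@dataclass
class ChainTopology:
    """One polymer chain: particles, labels, bonded terms and end markers.

    ``backbone`` lists particle indices along the covalent backbone path;
    ``side_parent[i]`` is the backbone particle a side bead hangs from
    (−1 for backbone particles).  ``chain_ends`` and ``segment_ends`` hold
    the junction-nitrogen marker pairs delimiting the chain and each soft
    segment.
    """

    tag: np.ndarray
    masses: np.ndarray
    radii: np.ndarray
    charges: np.ndarray
    unit_index: np.ndarray
    segment_type: np.ndarray
    block_type: np.ndarray
    segment_index: np.ndarray
    hbond_role: np.ndarray
    bonds: np.ndarray
    angles: np.ndarray
    torsions: np.ndarray
    out_of_plane: np.ndarray
    backbone: np.ndarray
    side_parent: np.ndarray
    chain_ends: np.ndarray                 # (2,) or empty
    segment_ends: np.ndarray               # (S, 2)
    segment_ends_type: np.ndarray          # (S,)
    slot_types: np.ndarray = field(default_factory=lambda: np.empty(0, "U6"))

    @property
    def n_particles(self) -> int:
        return len(self.tag)

    @property
    def total_mass(self) -> float:
        return float(np.sum(self.masses))

    @property
    def n_backbone_bonds(self) -> int:
        return max(len(self.backbone) - 1, 0)

    @classmethod
    def empty(cls) -> "ChainTopology":
        z = np.empty(0)
        zi = np.empty(0, dtype=np.intp)
        return cls(tag=np.empty(0, "U6"), masses=z, radii=z.copy(), charges=z.copy(),
                   unit_index=zi, segment_type=np.empty(0, "U6"),
                   block_type=np.empty(0, "U6"), segment_index=zi.copy(),
                   hbond_role=np.empty(0, "U16"),
                   bonds=np.empty((0, 2), np.intp), angles=np.empty((0, 3), np.intp),
                   torsions=np.empty((0, 4), np.intp),
                   out_of_plane=np.empty((0, 4), np.intp),
                   backbone=zi.copy(), side_parent=zi.copy(),
                   chain_ends=np.empty((0, 2), np.intp),
                   segment_ends=np.empty((0, 2), np.intp),
                   segment_ends_type=np.empty(0, "U6"))

    def to_system(self, positions: np.ndarray | None = None,
                  box=None) -> ParticleSystem:
        n = self.n_particles
        if positions is None:
            positions = np.zeros((n, 3))
        ends = self.chain_ends.reshape(-1, 2)
        return ParticleSystem(
            positions=positions, masses=self.masses, radii=self.radii,
            charges=self.charges, tag=self.tag,
            chain_id=np.zeros(n, dtype=np.intp), unit_index=self.unit_index,
            segment_type=self.segment_type, block_type=self.block_type,
            segment_index=self.segment_index, hbond_role=self.hbond_role,
            bonds=self.bonds, angles=self.angles, torsions=self.torsions,
            out_of_plane=self.out_of_plane, chain_ends=ends,
            segment_ends=self.segment_ends,
            segment_ends_type=self.segment_ends_type,
            segment_ends_chain=np.zeros(len(self.segment_ends), dtype=np.intp),
            backbones=[self.backbone], side_parent=self.side_parent, box=box)


# ---------------------------------------------------------------- construction
class _ChainBuilder:
    def __init__(self):
        self.tag, self.mass, self.radius = [], [], []
        self.unit, self.seg_type, self.block, self.seg_idx, self.role = [], [], [], [], []
        self.backbone: list[int] = []
        self.side_parent: list[int] = []
        self.side_bonds: list[tuple[int, int]] = []
        self.oop: list[tuple[int, int, int, int]] = []

    def add(self, tag, unit, seg_type, block, seg_idx, role, parent=None) -> int:
        i = len(self.tag)
        self.tag.append(tag)
        self.mass.append(BEAD_MASSES[tag])
        self.radius.append(BEAD_RADII[tag])
        self.unit.append(unit)
        self.seg_type.append(seg_type)
        self.block.append(block)
        self.seg_idx.append(seg_idx)
        self.role.append(role)
        if parent is None:
            self.backbone.append(i)
            self.side_parent.append(-1)
        else:
            self.side_parent.append(parent)
            self.side_bonds.append((parent, i))
        return i

    def finish(self, chain_ends, segment_ends, segment_ends_type, slot_types) -> ChainTopology:
        bb = np.asarray(self.backbone, dtype=np.intp)
        bonds = [(bb[k], bb[k + 1]) for k in range(len(bb) - 1)] + self.side_bonds
        angles = [(bb[k], bb[k + 1], bb[k + 2]) for k in range(len(bb) - 2)]
        torsions = [(bb[k], bb[k + 1], bb[k + 2], bb[k + 3]) for k in range(len(bb) - 3)]
        return ChainTopology(
            tag=np.asarray(self.tag, dtype="U6"),
            masses=np.asarray(self.mass, dtype=float),
            radii=np.asarray(self.radius, dtype=float),
            charges=np.zeros(len(self.tag)),
            unit_index=np.asarray(self.unit, dtype=np.intp),
            segment_type=np.asarray(self.seg_type, dtype="U6"),
            block_type=np.asarray(self.block, dtype="U6"),
            segment_index=np.asarray(self.seg_idx, dtype=np.intp),
            hbond_role=np.asarray(self.role, dtype="U16"),
            bonds=np.asarray(bonds, dtype=np.intp).reshape(-1, 2),
            angles=np.asarray(angles, dtype=np.intp).reshape(-1, 3),
            torsions=np.asarray(torsions, dtype=np.intp).reshape(-1, 4),
            out_of_plane=np.asarray(self.oop, dtype=np.intp).reshape(-1, 4),
            backbone=bb,
            side_parent=np.asarray(self.side_parent, dtype=np.intp),
            chain_ends=np.asarray(chain_ends, dtype=np.intp),
            segment_ends=np.asarray(segment_ends, dtype=np.intp).reshape(-1, 2),
            segment_ends_type=np.asarray(segment_ends_type, dtype="U6"),
            slot_types=np.asarray(slot_types, dtype="U6"))


def _junction_sizes(preset: CompositionPreset) -> tuple[int, int, np.ndarray]:
    """Particles per junction before padding, and pad counts per junction."""
    n_slots = preset.n_slots
    n_junctions = n_slots + 1
    junction_base = 8                                   # N,C,C,N + 2 H + 2 O
    pcl_particles = preset.pcl_repeats_per_segment * 8  # 7 backbone + 1 side O
    pla_particles = preset.pla_repeats_per_segment * 5  # 3 backbone + 2 sides
    n_pcl, _ = _slot_counts(preset)
    base = (n_junctions * junction_base + n_pcl * pcl_particles
            + (n_slots - n_pcl) * pla_particles)
    pad_total = preset.particle_target - base
    if pad_total < 0:
        raise ValueError(
            f"particle_target {preset.particle_target} smaller than the "
            f"{base} chemically explicit particles of this preset")
    pads = np.full(n_junctions, pad_total // n_junctions, dtype=np.intp)
    pads[: pad_total % n_junctions] += 1
    return junction_base, base, pads


def _slot_counts(preset: CompositionPreset) -> tuple[int, int]:
    n_slots = preset.n_slots
    n_pcl_f = preset.pcl_fraction * n_slots
    n_pcl = round(n_pcl_f)
    if abs(n_pcl_f - n_pcl) > 1e-9:
        raise ValueError(
            f"pcl_fraction {preset.pcl_fraction} is not representable with "
            f"{n_slots} soft-segment slots ({n_pcl_f} PCL slots is not integral)")
    return n_pcl, n_slots - n_pcl


def build_chain_topology(preset: CompositionPreset, seed: int) -> ChainTopology:
    """Build one labeled chain; PLA slot positions are drawn from ``seed``.

    The returned topology is bit-reproducible for a fixed (preset, seed)
    pair.  Raises ``ValueError`` when the preset's molar fraction cannot be
    realized exactly in the available soft-segment slots.
    """
    n_pcl, n_pla = _slot_counts(preset)
    n_slots = preset.n_slots
    rng = np.random.default_rng(seed)
    slot_types = np.array(["PCL"] * n_slots, dtype="U6")
    pla_slots = rng.choice(n_slots, size=n_pla, replace=False)
    slot_types[np.sort(pla_slots)] = "PLA"

    _, _, pads = _junction_sizes(preset)
    b = _ChainBuilder()
    segment_ends, segment_ends_type = [], []
    per_unit = preset.soft_segments_per_unit

    def junction(j: int, block: str, unit: int) -> tuple[int, int]:
        """[N, C, pads…, C, N] backbone with H donors on N, carbonyl O on C."""
        n1 = b.add("N", unit, "HARD", block, -1, "donor_heavy")
        b.add("H", unit, "HARD", block, -1, "donor_hydrogen", parent=n1)
        c1 = b.add("C", unit, "HARD", block, -1, "none")
        o1 = b.add("O", unit, "HARD", block, -1, "acceptor", parent=c1)
        for _ in range(int(pads[j])):
            b.add("CP", unit, "HARD", block, -1, "none")
        c2 = b.add("C", unit, "HARD", block, -1, "none")
        o2 = b.add("O", unit, "HARD", block, -1, "acceptor", parent=c2)
        n2 = b.add("N", unit, "HARD", block, -1, "donor_heavy")
        b.add("H", unit, "HARD", block, -1, "donor_hydrogen", parent=n2)
        b.oop.append((c1, n1, b.backbone[b.backbone.index(c1) + 1], o1))
        b.oop.append((c2, b.backbone[b.backbone.index(c2) - 1], n2, o2))
        return n1, n2

    def soft_segment(slot: int, unit: int) -> None:
        st = str(slot_types[slot])
        if st == "PCL":
            for _ in range(preset.pcl_repeats_per_segment):
                for _ in range(5):
                    b.add("CH2", unit, st, st, slot, "none")
                c = b.add("C", unit, st, st, slot, "none")
                b.add("O", unit, st, st, slot, "acceptor", parent=c)   # carbonyl
                b.add("O", unit, st, st, slot, "acceptor")             # ester, backbone
        else:
            for _ in range(preset.pla_repeats_per_segment):
                ch = b.add("CH", unit, st, st, slot, "none")
                b.add("CH3", unit, st, st, slot, "none", parent=ch)
                c = b.add("C", unit, st, st, slot, "none")
                b.add("O", unit, st, st, slot, "acceptor", parent=c)   # carbonyl
                b.add("O", unit, st, st, slot, "acceptor")             # ester, backbone

    # junction j precedes soft slot j and inherits its type; the final junction
    # inherits the type of the last soft segment it follows.
    first_marker = last_marker = None
    open_marker = None
    for slot in range(n_slots):
        unit = slot // per_unit
        n1, n2 = junction(slot, str(slot_types[slot]), unit)
        if first_marker is None:
            first_marker = n1
        if open_marker is not None:
            segment_ends[-1][1] = n1
        soft_segment(slot, unit)
        segment_ends.append([n2, -1])
        segment_ends_type.append(str(slot_types[slot]))
        open_marker = n2
    unit = preset.repeating_units_per_chain - 1
    n1, n2 = junction(n_slots, str(slot_types[-1]), unit)
    segment_ends[-1][1] = n1
    last_marker = n2

    return b.finish([first_marker, last_marker], segment_ends,
                    segment_ends_type, slot_types)


def single_repeat_chain(monomer: MonomerSpec) -> ChainTopology:
    """All-atom chain of one monomer repeat (explicit hydrogens), for bookkeeping."""
    if monomer.formula is None:
        raise ValueError("single_repeat_chain needs a monomer with an element formula")
    b = _ChainBuilder()
    heavy: list[int] = []
    for el in ("C", "O", "N"):
        for _ in range(monomer.formula.get(el, 0)):
            heavy.append(b.add(el, 0, monomer.name, monomer.name, 0, "none"))
    for h in range(monomer.formula.get("H", 0)):
        b.add("H", 0, monomer.name, monomer.name, 0, "none",
              parent=heavy[h % len(heavy)])
    return b.finish([heavy[0], heavy[-1]] if heavy else [], [], [], [monomer.name])


# ----------------------------------------------------------------- operations
def count_particles(chain: ChainTopology) -> int:
    """Exact particle count of one chain (total mass via ``chain.total_mass``)."""
    return chain.n_particles


def assemble_unit_cell(chains: list[ChainTopology], n_chains: int,
                       target_density: float = 0.6022) -> ParticleSystem:
    """Assemble ``n_chains`` chains into one labeled system (a "unit cell").

    The provided topologies are cycled if fewer than ``n_chains`` are given.
    Coordinates are initialized to zero — geometry is the job of the
    configuration generator — but a bounding box is attached, sized so the
    cell has ``target_density`` (Da/Å³; default ≈ 1 g/cm³), which the
    replication bookkeeping needs.
    """
    if n_chains < 1:
        raise ValueError("a unit cell needs at least one chain")
    if not chains:
        raise ValueError("no chain topologies given")
    systems = [chains[i % len(chains)].to_system() for i in range(n_chains)]
    cell = ParticleSystem.concatenate(systems)
    edge = (cell.total_mass / target_density) ** (1.0 / 3.0) if cell.total_mass > 0 else 1.0
    cell.box = np.array([edge, edge, edge])
    return cell


def replicate_cell(system: ParticleSystem, nx: int, ny: int, nz: int) -> ParticleSystem:
    """Tile a boxed cell nx × ny × nz, remapping chain ids uniquely."""
    if min(nx, ny, nz) < 1:
        raise ValueError("replication factors must be >= 1")
    if system.box is None:
        raise ValueError("replicate_cell requires a system with a bounding box")
    images = []
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                img = system.copy()
                img.positions = img.positions + system.box * np.array([ix, iy, iz], float)
                images.append(img)
    out = ParticleSystem.concatenate(images)
    out.box = system.box * np.array([nx, ny, nz], float)
    return out
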