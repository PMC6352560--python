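"""Seeded generator of WDPU-like nanoparticle configurations.

The generator emulates the statistical structure of an amorphous
block-copolymer nanoparticle — a radial mass-density plateau that decays to
zero at the particle surface, chains whose end-to-end statistics are set by
a stiffness (persistence) parameter, optional shape anisotropy, and planted
donor–H–acceptor geometries with controlled decoys — without running
molecular dynamics.  Everything is driven by a single integer seed and is
bit-reproducible.

Chain conformations come from a correlated random walk along the bonded
backbone.  Two modes exist:

* *free*: a pure correlated walk, ``d' ∝ κ·d + u`` with ``u`` an isotropic
  unit vector.  At κ = 0 this is a freely-jointed chain (mean-square
  end-to-end = N·b²); κ → ∞ is the rigid-rod limit.
* *bridged* (default when packing assemblies): the walk is given a small
  linear drift so the end-to-end vector matches a per-chain target drawn
  around the analytic correlated-walk RMS value.  This reproduces the very
  narrow chain-to-chain end-to-end spreads seen in equilibrated nanoparticle
  ensembles, which a free walk (≈42 % relative spread per chain) cannot.

The analytic RMS end-to-end of the correlated walk with per-step mean cosine
``c`` and ``N`` bonds of length ``b`` is the exact finite-chain expression

    <R²> = N b² [ (1+c)/(1−c) − 2c(1−c^N) / (N(1−c)²) ],

which interpolates between N·b² (c = 0) and the contour length squared
(c → 1).  ``calibrate_preset`` inverts it by bisection.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .builder import ChainTopology, CompositionPreset, build_chain_topology
from .system import ParticleSystem

__all__ = [
    "DensityProfile", "PlantedHBonds", "DecoyHBonds", "GeneratorConfig",
    "GroundTruth", "Assembly",
    "mean_square_end_to_end", "persistence_to_cosine", "cosine_to_persistence",
    "sample_chain_conformation", "end_to_end_ensemble",
    "pack_assembly", "plant_hbond_geometries", "calibrate_preset",
    "fcc_lattice",
]

_SIDE_BOND = {"H": 1.0, "O": 1.23, "CH3": 1.53}
_CLOSE_PACKING = 0.74


def fcc_lattice(nearest_neighbor: float, radius: float) -> np.ndarray:
    """Face-centered-cubic point lattice with the given nearest-neighbor
    spacing (Å), clipped to a ball of the given radius about the origin.
    Used to plant centroid arrangements with a known RDF peak position."""
    from itertools import product as _product
    a = nearest_neighbor * np.sqrt(2.0)
    n = int(np.ceil(radius / a)) + 1
    pts = []
    for i, j, k in _product(range(-n, n + 1), repeat=3):
        for b in ((0.0, 0.0, 0.0), (0.0, .5, .5), (.5, 0.0, .5), (.5, .5, 0.0)):
            p = (np.array((i, j, k), dtype=float) + b) * a
            if p @ p <= radius * radius:
                pts.append(p)
    return np.array(pts)


# --------------------------------------------------------------------- config
@dataclass(frozen=True)
class DensityProfile:
    """Target radial mass-density shape: plateau to ``core_radius`` (Å), then a
    linear decay reaching zero at ``decay_radius`` (Å).  ``core_density`` is in
    Da/Å³ (0.6022 Da/Å³ = 1 g/cm³) and is used for feasibility checks; the
    realized plateau level is set by the total assembly mass and the shape."""

    core_density: float = 0.60
    core_radius: float = 50.0
    decay_radius: float = 115.0

    def __post_init__(self):
        if not (0.0 < self.core_radius < self.decay_radius):
            raise ValueError("need 0 < core_radius < decay_radius")
        if self.core_density <= 0:
            raise ValueError("core_density must be positive")

    def shape(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        w = (self.decay_radius - r) / (self.decay_radius - self.core_radius)
        return np.clip(np.where(r <= self.core_radius, 1.0, w), 0.0, 1.0)

    def analytic_rg(self) -> float:
        """Rg of the target mass profile itself (no chain-extent smearing)."""
        r = np.linspace(0.0, self.decay_radius, 4001)
        s = self.shape(r)
        return float(np.sqrt(np.trapezoid(s * r**4, r) / np.trapezoid(s * r**2, r)))

    def sample_radii(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Stratified draw of n radii from the pdf ∝ shape(r)·r²."""
        r = np.linspace(0.0, self.decay_radius, 4001)
        pdf = self.shape(r) * r**2
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * np.diff(r) / 2)])
        cdf /= cdf[-1]
        q = (np.arange(n) + rng.uniform(size=n)) / n
        return np.interp(q, cdf, r)


@dataclass(frozen=True)
class PlantedHBonds:
    count: int = 0
    d_da: float = 2.9        # donor–acceptor distance, Å
    angle: float = 10.0      # max deviation of D–H…A from linearity, degrees

    def __post_init__(self):
        if self.count < 0 or self.d_da <= 0 or self.angle < 0:
            raise ValueError("invalid planted H-bond specification")


@dataclass(frozen=True)
class DecoyHBonds:
    count: int = 0
    violation: str = "distance"   # "distance" or "angle"

    def __post_init__(self):
        if self.violation not in ("distance", "angle"):
            raise ValueError("decoy violation must be 'distance' or 'angle'")


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to regenerate an assembly bit-for-bit."""

    seed: int = 0
    n_chains: int = 10
    preset: CompositionPreset = field(default_factory=CompositionPreset.PCL75DL25)
    bond_length: float = 1.5                      # backbone bond length, Å
    persistence: float = 0.0                      # walk stiffness κ; mean cosine = κ/√(1+κ²)
    end_to_end_relative_sd: float = 0.02          # chain-to-chain spread in bridged mode
    bridged: bool = True
    density_profile: DensityProfile = field(default_factory=DensityProfile)
    anisotropy: tuple = (1.0, 1.0, 1.0)           # per-axis coordinate scale factors
    planted_hbonds: PlantedHBonds | None = None
    decoy_hbonds: DecoyHBonds | None = None
    min_center_separation: float = 2.0            # Å between chain centers
    excluded_volume: bool = False                 # intra-chain bead overlap rejection

    def __post_init__(self):
        if min(self.anisotropy) <= 0:
            raise ValueError("anisotropy scale factors must be positive")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Exact generator bookkeeping (not re-measured quantities)."""

    end_to_end: np.ndarray                      # per-chain imposed/realized marker e2e
    profile_rg: float                           # analytic Rg of the target profile
    planted: list = field(default_factory=list)  # (donor, hydrogen, acceptor) triples
    decoys: list = field(default_factory=list)   # (donor, hydrogen, acceptor, mode)


@dataclass
class Assembly:
    system: ParticleSystem
    provenance: GeneratorConfig
    ground_truth: GroundTruth


# ----------------------------------------------------------- chain statistics
def persistence_to_cosine(kappa: float) -> float:
    return float(kappa / np.sqrt(1.0 + kappa * kappa))


def cosine_to_persistence(c: float) -> float:
    c = float(np.clip(c, -1 + 1e-12, 1 - 1e-12))
    return float(c / np.sqrt(1.0 - c * c))


def mean_square_end_to_end(n_bonds: int, bond_length: float, cosine: float) -> float:
    """Exact <R²> of a correlated walk with per-step mean cosine ``cosine``."""
    n, b, c = int(n_bonds), float(bond_length), float(cosine)
    if n < 1:
        return 0.0
    if abs(1.0 - c) < 1e-12:
        return (n * b) ** 2
    term = (1.0 + c) / (1.0 - c) - 2.0 * c * (1.0 - c**n) / (n * (1.0 - c) ** 2)
    return n * b * b * term


def _rms_end_to_end(n_bonds: int, bond_length: float, kappa: float) -> float:
    return float(np.sqrt(mean_square_end_to_end(
        n_bonds, bond_length, persistence_to_cosine(kappa))))


# --------------------------------------------------------------- conformation
def _random_units(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _walk(n_bonds: int, bond_length: float, kappa: float,
          rng: np.random.Generator) -> np.ndarray:
    """Correlated random walk; returns (n_bonds + 1, 3) backbone positions."""
    u = _random_units(rng, n_bonds)
    steps = np.empty((n_bonds, 3))
    d = u[0]
    steps[0] = d
    for k in range(1, n_bonds):
        v = kappa * d + u[k]
        norm = np.linalg.norm(v)
        if norm < 1e-12:               # exact back-fold; keep the random direction
            v, norm = u[k], 1.0
        d = v / norm
        steps[k] = d
    pos = np.empty((n_bonds + 1, 3))
    pos[0] = 0.0
    np.cumsum(steps * bond_length, axis=0, out=pos[1:])
    return pos


def _bridge(pos: np.ndarray, target: float, rng: np.random.Generator) -> np.ndarray:
    """Add a linear drift so |pos[-1] − pos[0]| equals ``target`` exactly."""
    n = len(pos)
    r = pos[-1] - pos[0]
    norm = np.linalg.norm(r)
    direction = r / norm if norm > 1e-9 else _random_units(rng, 1)[0]
    shift = direction * target - r
    return pos + np.linspace(0.0, 1.0, n)[:, None] * shift


def sample_chain_conformation(chain: ChainTopology, persistence: float, seed,
                              bond_length: float = 1.5,
                              target_end_to_end: float | None = None,
                              excluded_volume: bool = False,
                              max_retries: int = 20) -> np.ndarray:
    """Sample coordinates for one chain topology; returns an (N, 3) array.

    The backbone follows a correlated random walk (optionally end-to-end
    bridged to ``target_end_to_end``); side beads are placed at their bonded
    distance in a seeded direction roughly perpendicular to the backbone.
    With ``excluded_volume`` the walk is re-drawn (bounded retries) until no
    two non-adjacent backbone beads overlap at 0.8× their summed radii.
    """
    rng = np.random.default_rng(seed)
    nb = chain.n_backbone_bonds
    if nb < 1:
        raise ValueError("chain has no backbone bonds to sample")
    if target_end_to_end is not None and target_end_to_end > nb * bond_length:
        raise ValueError("target end-to-end exceeds the contour length")
    for attempt in range(max_retries):
        bb_pos = _walk(nb, bond_length, persistence, rng)
        if target_end_to_end is not None:
            bb_pos = _bridge(bb_pos, float(target_end_to_end), rng)
        if not excluded_volume or _self_clear(bb_pos, chain):
            break
    else:
        raise RuntimeError(
            f"could not place a self-clearing conformation in {max_retries} "
            f"attempts (persistence {persistence}, {nb} bonds): walk too congested")

    pos = np.empty((chain.n_particles, 3))
    pos[chain.backbone] = bb_pos
    side = np.flatnonzero(chain.side_parent >= 0)
    if side.size:
        parents = chain.side_parent[side]
        order = {int(p): k for k, p in enumerate(chain.backbone)}
        pk = np.array([order[int(p)] for p in parents])
        tangents = bb_pos[np.minimum(pk + 1, nb)] - bb_pos[np.maximum(pk - 1, 0)]
        tangents /= np.maximum(np.linalg.norm(tangents, axis=1, keepdims=True), 1e-12)
        raw = _random_units(rng, side.size)
        perp = raw - (raw * tangents).sum(axis=1, keepdims=True) * tangents
        nrm = np.linalg.norm(perp, axis=1, keepdims=True)
        bad = nrm[:, 0] < 1e-9
        if bad.any():
            perp[bad] = _random_units(rng, int(bad.sum()))
            nrm = np.linalg.norm(perp, axis=1, keepdims=True)
        lengths = np.array([_SIDE_BOND.get(t, 1.2) for t in chain.tag[side]])
        pos[side] = pos[parents] + perp / nrm * lengths[:, None]
    return pos


def _self_clear(bb_pos: np.ndarray, chain: ChainTopology) -> bool:
    radii = chain.radii[chain.backbone]
    cutoff = 0.8 * 2.0 * radii.max()
    pairs = cKDTree(bb_pos).query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return True
    nonadjacent = np.abs(pairs[:, 0] - pairs[:, 1]) > 1
    pairs = pairs[nonadjacent]
    if pairs.size == 0:
        return True
    limit = 0.8 * (radii[pairs[:, 0]] + radii[pairs[:, 1]])
    d = np.linalg.norm(bb_pos[pairs[:, 0]] - bb_pos[pairs[:, 1]], axis=1)
    return bool(np.all(d >= limit))


def end_to_end_ensemble(n_bonds: int, bond_length: float, persistence: float,
                        n_samples: int, seed) -> np.ndarray:
    """Vectorized free-walk end-to-end distances over ``n_samples`` chains."""
    rng = np.random.default_rng(seed)
    d = _random_units(rng, n_samples)
    r = bond_length * d.copy()
    for _ in range(n_bonds - 1):
        u = _random_units(rng, n_samples)
        v = persistence * d + u
        d = v / np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-12)
        r += bond_length * d
    return np.linalg.norm(r, axis=1)


# -------------------------------------------------------------------- packing
def pack_assembly(chains: list[ChainTopology] | None,
                  config: GeneratorConfig) -> Assembly:
    """Generate a full nanoparticle configuration from ``config``.

    Chain topologies are built per chain from the preset (or cycled from
    ``chains`` if given); conformations are sampled, centered, and the chain
    centers placed at stratified radii drawn from the target density profile
    in random directions, subject to a minimum center separation.  Anisotropy
    scale factors are applied to all coordinates at the end.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_chains + 2)
    rng = np.random.default_rng(children[-1])

    topologies = []
    for i in range(config.n_chains):
        if chains:
            topologies.append(chains[i % len(chains)])
        else:
            topo_seed = int(np.random.default_rng(children[i]).integers(2**31 - 1))
            topologies.append(build_chain_topology(config.preset, topo_seed))

    _check_feasible(topologies, config)

    kappa = config.persistence
    systems, e2e = [], []
    radii = config.density_profile.sample_radii(config.n_chains, rng)
    rng.shuffle(radii)
    centers = _place_centers(radii, config.min_center_separation, rng)
    chain_masses = np.array([t.total_mass for t in topologies])
    centers = _condition_centers(centers, chain_masses,
                                 config.density_profile.analytic_rg())
    for i, topo in enumerate(topologies):
        target = None
        if config.bridged:
            rms = _rms_end_to_end(topo.n_backbone_bonds, config.bond_length, kappa)
            xi = 1.0 + config.end_to_end_relative_sd * rng.standard_normal()
            target = float(np.clip(rms * max(xi, 0.05), config.bond_length,
                                   0.995 * topo.n_backbone_bonds * config.bond_length))
        pos = sample_chain_conformation(
            topo, kappa, children[i], bond_length=config.bond_length,
            target_end_to_end=target, excluded_volume=config.excluded_volume)
        sys_i = topo.to_system(pos)
        com = sys_i.center_of_mass()
        sys_i.positions = pos - com + centers[i]
        systems.append(sys_i)
        ends = sys_i.chain_ends[0]
        e2e.append(float(np.linalg.norm(
            sys_i.positions[ends[1]] - sys_i.positions[ends[0]])))

    system = ParticleSystem.concatenate(systems)
    aniso = np.asarray(config.anisotropy, dtype=float)
    if not np.allclose(aniso, 1.0):
        system.positions = system.positions * aniso
        ce = system.chain_ends
        e2e = list(np.linalg.norm(system.positions[ce[:, 1]]
                                  - system.positions[ce[:, 0]], axis=1))
    extent = system.positions.max(axis=0) - system.positions.min(axis=0)
    system.box = np.maximum(extent, 1.0)

    gt = GroundTruth(end_to_end=np.asarray(e2e),
                     profile_rg=config.density_profile.analytic_rg())
    assembly = Assembly(system=system, provenance=config, ground_truth=gt)
    if config.planted_hbonds is not None or config.decoy_hbonds is not None:
        planted_seed = int(rng.integers(2**31 - 1))
        assembly = plant_hbond_geometries(
            assembly, config.planted_hbonds or PlantedHBonds(0),
            config.decoy_hbonds, planted_seed)
    return assembly


def _condition_centers(centers: np.ndarray, masses: np.ndarray,
                       target_rms: float) -> np.ndarray:
    """Zero the mass-weighted mean of the chain centers and rescale so their
    mass-weighted RMS radius equals the analytic RMS radius of the density
    profile exactly.  This reproduces the near-deterministic ensemble spreads
    of an equilibrated nanoparticle (assembly-level Rg error bars are orders
    of magnitude below the chain-level ones) while keeping the angular and
    stratified-radial randomness of the placement."""
    if len(centers) < 2:
        return centers
    m = masses / masses.sum()
    centered = centers - (m[:, None] * centers).sum(axis=0)
    rms = np.sqrt(np.sum(m * np.sum(centered**2, axis=1)))
    if rms < 1e-9:
        return centered
    return centered * (target_rms / rms)


def _place_centers(radii: np.ndarray, min_sep: float,
                   rng: np.random.Generator) -> np.ndarray:
    centers = np.zeros((len(radii), 3))
    for i, r in enumerate(radii):
        for _ in range(200):
            c = r * _random_units(rng, 1)[0]
            if i == 0 or min_sep <= 0:
                centers[i] = c
                break
            if np.min(np.linalg.norm(centers[:i] - c, axis=1)) >= min_sep:
                centers[i] = c
                break
        else:
            raise RuntimeError(
                "could not place chain centers at the requested minimum "
                "separation: density profile too narrow for the chain count")
    return centers


def _check_feasible(topologies: list[ChainTopology], config: GeneratorConfig) -> None:
    total_mass = sum(t.total_mass for t in topologies)
    prof = config.density_profile
    r = np.linspace(0.0, prof.decay_radius, 2001)
    volume_integral = float(np.trapezoid(prof.shape(r) * 4 * np.pi * r**2, r))
    implied_plateau = total_mass / volume_integral
    all_radii = np.concatenate([t.radii for t in topologies])
    all_masses = np.concatenate([t.masses for t in topologies])
    bead_density = all_masses.sum() / np.sum(4.0 / 3.0 * np.pi * all_radii**3)
    if implied_plateau > _CLOSE_PACKING * bead_density:
        raise ValueError(
            f"infeasible density profile: implied plateau {implied_plateau:.3g} "
            f"Da/Å³ exceeds close packing of the beads "
            f"({_CLOSE_PACKING * bead_density:.3g} Da/Å³)")


# ------------------------------------------------------------------- planting
def _donor_triples(system: ParticleSystem):
    """(donor, hydrogen) pairs from roles + bonds."""
    role = system.hbond_role
    donors = np.flatnonzero(role == "donor_heavy")
    hydro = set(np.flatnonzero(role == "donor_hydrogen").tolist())
    pairs = []
    bonded: dict[int, list[int]] = {}
    for a, b in system.bonds:
        bonded.setdefault(int(a), []).append(int(b))
        bonded.setdefault(int(b), []).append(int(a))
    for d in donors:
        for nb in bonded.get(int(d), []):
            if nb in hydro:
                pairs.append((int(d), nb))
    return pairs, bonded


def plant_hbond_geometries(assembly: Assembly, planted: PlantedHBonds | int,
                           decoys, seed) -> Assembly:
    """Reposition donor–H–acceptor triads so exactly ``planted.count`` satisfy
    the geometric hydrogen-bond criterion, plus decoys violating exactly one
    criterion each; all remaining donor–acceptor pairs are swept apart so the
    planted list is the complete ground truth.  ``decoys`` may be a single
    :class:`DecoyHBonds` or a list mixing violation modes.
    """
    if isinstance(planted, int):
        planted = PlantedHBonds(count=planted)
    if decoys is None:
        decoys = []
    elif isinstance(decoys, DecoyHBonds):
        decoys = [decoys]
    decoy_modes = [d.violation for d in decoys for _ in range(d.count)]
    rng = np.random.default_rng(seed)
    system = assembly.system.copy()
    d_cut = 3.0

    dh_pairs, bonded = _donor_triples(system)
    acceptors = np.flatnonzero(system.hbond_role == "acceptor")
    n_need = planted.count + len(decoy_modes)
    if len(dh_pairs) < n_need or len(acceptors) < n_need:
        raise ValueError(
            f"not enough labeled sites to plant {n_need} triads "
            f"({len(dh_pairs)} donor-H pairs, {len(acceptors)} acceptors)")

    pick_dh = [dh_pairs[i] for i in rng.permutation(len(dh_pairs))[:n_need]]
    # assign each triad an acceptor at least 3 covalent bonds from its donor
    # (closer pairs are excluded by the detector's bonded-pair rule)
    acc_pool = list(rng.permutation(acceptors))
    pick_acc = []
    for d, _h in pick_dh:
        near = {d} | set(bonded.get(d, []))
        near |= {m for n in list(near) for m in bonded.get(n, [])}
        for idx, a in enumerate(acc_pool):
            if int(a) not in near:
                pick_acc.append(int(acc_pool.pop(idx)))
                break
        else:
            raise ValueError("not enough non-bonded acceptors to plant the "
                             "requested triads")

    planted_list, decoy_list = [], []
    planted_pairs: set[tuple[int, int]] = set()
    exempt_pairs: set[tuple[int, int]] = set()
    for k in range(n_need):
        d, h = pick_dh[k]
        a = int(pick_acc[k])
        w = _random_units(rng, 1)[0]
        p = _random_units(rng, 1)[0]
        p -= (p @ w) * w
        p /= max(np.linalg.norm(p), 1e-12)
        if k < planted.count:
            dist = min(planted.d_da, d_cut)
            system.positions[a] = system.positions[d] + dist * w
            # hydrogen close to the donor–acceptor axis: small deviation
            tilt = np.deg2rad(min(planted.angle, 30.0) * 0.3)
            hdir = np.cos(tilt) * w + np.sin(tilt) * p
            system.positions[h] = system.positions[d] + 1.0 * hdir
            planted_list.append((d, h, a))
            planted_pairs.add((d, a))
        elif decoy_modes[k - planted.count] == "distance":
            system.positions[a] = system.positions[d] + (d_cut + 0.1) * w
            system.positions[h] = system.positions[d] + 1.0 * w
            decoy_list.append((d, h, a, "distance"))
            exempt_pairs.add((d, a))
        else:
            system.positions[a] = system.positions[d] + 2.9 * w
            # hydrogen 60° off-axis: D–H…A deviates from linearity by ~80°
            hdir = 0.5 * w + np.sqrt(3.0) / 2.0 * p
            system.positions[h] = system.positions[d] + 1.0 * hdir
            decoy_list.append((d, h, a, "angle"))
            exempt_pairs.add((d, a))

    triad_of_donor = {d: (h, a) for d, h, a in planted_list}
    _sweep_apart(system, bonded, planted_pairs, exempt_pairs,
                 triad_of_donor, {a for _, _, a in planted_list}, d_cut, rng)

    gt = dataclasses.replace(assembly.ground_truth,
                             planted=planted_list, decoys=decoy_list)
    return Assembly(system=system, provenance=assembly.provenance, ground_truth=gt)


def _sweep_apart(system, bonded, planted_pairs, exempt_pairs,
                 triad_of_donor, planted_acceptors, d_cut, rng,
                 margin: float = 0.3, max_sweeps: int = 60) -> None:
    """Push all unplanned donor–acceptor pairs beyond the distance cutoff.

    Unplanted acceptors are moved away from the offending donor; when the
    acceptor belongs to a planted triad, the donor side moves instead — and
    if that donor is itself planted, its whole (D, H, A) triad is translated
    rigidly so the planted geometry survives.
    """
    donors = np.flatnonzero(system.hbond_role == "donor_heavy")
    acceptors = np.flatnonzero(system.hbond_role == "acceptor")
    near_bonded = {int(d): {int(d)} | {n for n in bonded.get(int(d), [])}
                   | {m for n in bonded.get(int(d), []) for m in bonded.get(n, [])}
                   for d in donors}
    for _ in range(max_sweeps):
        tree = cKDTree(system.positions[acceptors])
        moved = 0
        for d in donors:
            d = int(d)
            hits = tree.query_ball_point(system.positions[d], d_cut + margin)
            for j in np.atleast_1d(hits):
                a = int(acceptors[int(j)])
                if (d, a) in planted_pairs or (d, a) in exempt_pairs:
                    continue
                if a in near_bonded[d]:
                    continue
                if a in planted_acceptors:
                    # move the donor side away from the planted acceptor
                    delta = system.positions[d] - system.positions[a]
                    norm = np.linalg.norm(delta)
                    direction = delta / norm if norm > 1e-9 else _random_units(rng, 1)[0]
                    new = system.positions[a] + direction * (
                        d_cut + margin + 0.2 + 0.3 * rng.uniform())
                    shift = new - system.positions[d]
                    group = [d] + [n for n in bonded.get(d, [])
                                   if system.hbond_role[n] == "donor_hydrogen"]
                    if d in triad_of_donor:          # carry its own triad rigidly
                        h_p, a_p = triad_of_donor[d]
                        group += [h_p, a_p]
                    for g in set(group):
                        system.positions[g] = system.positions[g] + shift
                else:
                    delta = system.positions[a] - system.positions[d]
                    norm = np.linalg.norm(delta)
                    direction = delta / norm if norm > 1e-9 else _random_units(rng, 1)[0]
                    system.positions[a] = system.positions[d] + direction * (
                        d_cut + margin + 0.2 + 0.3 * rng.uniform())
                moved += 1
        if moved == 0:
            return
    raise RuntimeError("could not separate unplanned donor–acceptor pairs; "
                       "system too congested for the requested planting")


# ---------------------------------------------------------------- calibration
def calibrate_preset(target_stat: str, target_value: float,
                     config: GeneratorConfig, tolerance: float = 0.02,
                     max_iter: int = 40, n_verify_seeds: int = 5) -> GeneratorConfig:
    """Tune the generator so an ensemble statistic hits ``target_value``.

    ``target_stat`` is ``"mean_end_to_end"`` (control: the persistence
    parameter, inverted through the analytic correlated-walk law and then
    verified on generated ensembles) or ``"rg"`` (control: a radial scale
    factor on the density profile, bisected against 5-seed ensemble means).
    Raises ``ValueError`` with the achievable range when the target cannot
    be bracketed.
    """
    from . import descriptors as desc

    if target_stat == "mean_end_to_end":
        topo = build_chain_topology(config.preset, 0)
        nb, b = topo.n_backbone_bonds, config.bond_length
        lo_c, hi_c = -1.0 + 1e-9, 1.0 - 1e-12
        floor = np.sqrt(mean_square_end_to_end(nb, b, lo_c))
        ceil = 0.995 * nb * b
        if not (floor < target_value < ceil):
            raise ValueError(
                f"target {target_value} Å outside the achievable mean "
                f"end-to-end range ({floor:.2f}, {ceil:.2f}) Å for this preset")
        for _ in range(200):
            mid = 0.5 * (lo_c + hi_c)
            if np.sqrt(mean_square_end_to_end(nb, b, mid)) < target_value:
                lo_c = mid
            else:
                hi_c = mid
            if hi_c - lo_c < 1e-14:
                break
        out = config.replace(persistence=cosine_to_persistence(0.5 * (lo_c + hi_c)),
                             bridged=True)
        measured = _ensemble_mean(out, n_verify_seeds,
                                  lambda s: float(np.mean(desc.end_to_end_distances(s).per_chain)))
        if abs(measured - target_value) > tolerance * target_value:
            raise RuntimeError(
                f"calibration verification failed: measured {measured:.3f} Å "
                f"vs target {target_value} Å")
        return out

    if target_stat == "rg":
        base = config.density_profile

        def measure(scale: float) -> float:
            prof = DensityProfile(core_density=base.core_density,
                                  core_radius=base.core_radius * scale,
                                  decay_radius=base.decay_radius * scale)
            cfg = config.replace(density_profile=prof)
            return _ensemble_mean(cfg, n_verify_seeds,
                                  lambda s: desc.radius_of_gyration(s))

        topologies = [build_chain_topology(config.preset, i)
                      for i in range(config.n_chains)]
        total_mass = sum(t.total_mass for t in topologies)
        r = np.linspace(0.0, base.decay_radius, 2001)
        vol_int = float(np.trapezoid(base.shape(r) * 4 * np.pi * r**2, r))
        all_radii = np.concatenate([t.radii for t in topologies])
        bead_density = (np.concatenate([t.masses for t in topologies]).sum()
                        / np.sum(4.0 / 3.0 * np.pi * all_radii**3))
        s_min = (total_mass / (vol_int * _CLOSE_PACKING * bead_density)) ** (1 / 3)
        lo, hi = 1.02 * s_min, max(1.0, 1.1 * s_min)
        f_lo, f_hi = measure(lo), measure(hi)
        while f_hi < target_value and hi < 64:
            lo, f_lo = hi, f_hi
            hi *= 2.0
            f_hi = measure(hi)
        if not (f_lo <= target_value <= f_hi):
            raise ValueError(
                f"target Rg {target_value} Å outside the achievable range "
                f"({f_lo:.2f}, {f_hi:.2f}) Å: chain extent sets the floor")
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            f_mid = measure(mid)
            if abs(f_mid - target_value) <= tolerance * target_value * 0.5:
                lo = hi = mid
                break
            if f_mid < target_value:
                lo = mid
            else:
                hi = mid
        scale = 0.5 * (lo + hi)
        prof = DensityProfile(core_density=base.core_density,
                              core_radius=base.core_radius * scale,
                              decay_radius=base.decay_radius * scale)
        return config.replace(density_profile=prof)

    raise ValueError("target_stat must be 'mean_end_to_end' or 'rg'")


def _ensemble_mean(config: GeneratorConfig, n_seeds: int, stat) -> float:
    seeds = np.random.SeedSequence(config.seed).spawn(1)[0].generate_state(n_seeds)
    vals = [stat(pack_assembly(None, config.replace(seed=int(s % (2**31 - 1)))).system)
            for s in seeds]
    return float(np.mean(vals))
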