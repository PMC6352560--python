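"""Consistent-valence force field (CVFF) energy evaluation.

The potential is evaluated term by term:

* Morse bond stretch            D_b (1 − e^{−α(b−b0)})²
* harmonic angle bend           H_θ (θ − θ0)²
* cosine torsion                H_φ (1 + s·cos nφ)
* out-of-plane (Wilson angle)   H_χ χ²
* five cross-coupling terms: bond–bond′ and bond–angle within each angle,
  angle–angle′ and torsion–angle–angle′ within each torsion, and
  out-of-plane pairs sharing a central atom
* 12-6 Lennard-Jones            ε ((r*/r)¹² − 2 (r*/r)⁶)
* Coulomb                       C q_i q_j / (ε_r r_ij), C = 332.0637 kcal·Å/(mol·e²)

Non-bonded pairs exclude 1–2 and 1–3 neighbours; 1–4 pairs are included at
full weight (the CVFF-era convention).  Energies are in kcal/mol, lengths in
Å, angles internally in radians.  Parameter values are the user's
responsibility — none are shipped beyond a clearly non-physical toy set used
by the test suite — and every bonded tuple must resolve to an entry (type
keys are matched forward or reversed, with an optional ``"*"`` wildcard).

``evaluate_forces`` returns the exact analytic gradient of
``evaluate_energy``; ``relax`` runs line-searched steepest descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .system import ParticleSystem

__all__ = ["FFParams", "EnergyBreakdown", "toy_params",
           "evaluate_energy", "evaluate_forces", "relax"]

COULOMB_CONSTANT = 332.0637   # kcal·Å/(mol·e²)


# -------------------------------------------------------------------- params
@dataclass(frozen=True)
class BondParam:
    d: float        # well depth D_b, kcal/mol
    alpha: float    # 1/Å
    b0: float       # Å


@dataclass(frozen=True)
class AngleParam:
    h: float        # kcal/mol/rad²
    theta0: float   # rad


@dataclass(frozen=True)
class TorsionParam:
    h: float        # kcal/mol
    n: int
    s: int          # ±1


@dataclass(frozen=True)
class OopParam:
    h: float        # kcal/mol/rad²


@dataclass(frozen=True)
class NonbondedParam:
    epsilon: float  # kcal/mol
    rstar: float    # Å


@dataclass
class FFParams:
    """Parameter tables keyed by bead-type tuples (``"*"`` = wildcard)."""

    bonds: dict = field(default_factory=dict)            # (t1,t2) or "*"
    angles: dict = field(default_factory=dict)           # (t1,t2,t3) or "*"
    torsions: dict = field(default_factory=dict)
    out_of_plane: dict = field(default_factory=dict)
    nonbonded: dict = field(default_factory=dict)        # type or "*"
    cross_bond_bond: dict = field(default_factory=dict)      # keyed like angles
    cross_angle_angle: dict = field(default_factory=dict)    # keyed like torsions
    cross_bond_angle: dict = field(default_factory=dict)     # keyed like angles
    cross_torsion_angle_angle: dict = field(default_factory=dict)
    cross_oop_oop: dict = field(default_factory=dict)        # keyed by central type
    dielectric: float = 1.0

    def __post_init__(self):
        for key, p in self.bonds.items():
            if p.d < 0:
                raise ValueError(f"bond well depth must be >= 0 for {key}")
            if p.alpha <= 0 or p.b0 <= 0:
                raise ValueError(f"bond alpha and b0 must be positive for {key}")
        for key, p in self.angles.items():
            if p.h < 0:
                raise ValueError(f"angle force constant must be >= 0 for {key}")
        for key, p in self.torsions.items():
            if p.h < 0:
                raise ValueError(f"torsion force constant must be >= 0 for {key}")
        for key, p in self.nonbonded.items():
            if p.rstar <= 0:
                raise ValueError(f"nonbonded r* must be positive for {key}")

    def _lookup(self, table: dict, key: tuple, what: str):
        if key in table:
            return table[key]
        if key[::-1] in table:
            return table[key[::-1]]
        if "*" in table:
            return table["*"]
        raise KeyError(f"no {what} parameters for type tuple {key}")

    def bond(self, t1, t2) -> BondParam:
        return self._lookup(self.bonds, (t1, t2), "bond")

    def angle(self, t1, t2, t3) -> AngleParam:
        return self._lookup(self.angles, (t1, t2, t3), "angle")

    def torsion(self, *t) -> TorsionParam:
        return self._lookup(self.torsions, tuple(t), "torsion")

    def oop(self, *t) -> OopParam:
        return self._lookup(self.out_of_plane, tuple(t), "out-of-plane")

    def pair(self, t1, t2) -> NonbondedParam:
        p1 = self.nonbonded.get(t1, self.nonbonded.get("*"))
        p2 = self.nonbonded.get(t2, self.nonbonded.get("*"))
        if p1 is None or p2 is None:
            raise KeyError(f"no nonbonded parameters for {t1!r}/{t2!r}")
        return NonbondedParam(epsilon=float(np.sqrt(p1.epsilon * p2.epsilon)),
                              rstar=0.5 * (p1.rstar + p2.rstar))

    def cross(self, table_name: str, key: tuple) -> float:
        table = getattr(self, table_name)
        if key in table:
            return float(table[key])
        if key[::-1] in table:
            return float(table[key[::-1]])
        return float(table.get("*", 0.0))


def toy_params(dielectric: float = 1.0, with_cross: bool = True) -> FFParams:
    """A small self-consistent TOY parameter set for tests and demos.

    The values are NOT physical CVFF parameters (none are published in a
    transcribable form); they only exercise every term of the functional form.
    """
    cross = 2.0 if with_cross else 0.0
    return FFParams(
        bonds={"*": BondParam(d=100.0, alpha=2.0, b0=1.5)},
        angles={"*": AngleParam(h=50.0, theta0=np.deg2rad(109.5))},
        torsions={"*": TorsionParam(h=1.2, n=3, s=1)},
        out_of_plane={"*": OopParam(h=5.0)},
        nonbonded={"*": NonbondedParam(epsilon=0.1, rstar=3.5)},
        cross_bond_bond={"*": cross},
        cross_angle_angle={"*": 0.5 * cross},
        cross_bond_angle={"*": cross},
        cross_torsion_angle_angle={"*": 0.25 * cross},
        cross_oop_oop={"*": 0.1 * cross},
        dielectric=dielectric)


# ------------------------------------------------------- internal coordinates
def _bond_geom(p, i, j):
    v = p[j] - p[i]
    b = float(np.linalg.norm(v))
    u = v / b
    return b, {i: -u, j: u}


def _angle_geom(p, i, j, k):
    """Angle at j between bonds j→i and j→k, with analytic gradients."""
    u = p[i] - p[j]
    v = p[k] - p[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    c = float(np.clip(uh @ vh, -1.0, 1.0))
    s = np.sqrt(max(1.0 - c * c, 1e-14))
    theta = float(np.arccos(c))
    gi = (c * uh - vh) / (nu * s)
    gk = (c * vh - uh) / (nv * s)
    return theta, {i: gi, j: -(gi + gk), k: gk}


def _dihedral_geom(p, i, j, k, l):
    """Torsion angle about j–k with analytic gradients."""
    b1 = p[j] - p[i]
    b2 = p[k] - p[j]
    b3 = p[l] - p[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = float(np.linalg.norm(b2))
    m1 = np.cross(n1, b2 / nb2)
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    phi = float(np.arctan2(y, x))
    sq1 = float(n1 @ n1)
    sq2 = float(n2 @ n2)
    gi = nb2 / sq1 * n1
    gl = -nb2 / sq2 * n2
    f1 = float(b1 @ b2) / (nb2 * nb2)
    f3 = float(b3 @ b2) / (nb2 * nb2)
    gj = -(1.0 + f1) * gi + f3 * gl
    gk = f1 * gi - (1.0 + f3) * gl
    return phi, {i: gi, j: gj, k: gk, l: gl}


def _oop_geom(p, c, j, k, l):
    """Wilson out-of-plane angle: bond c→l vs. the plane of (c→j, c→k)."""
    u = p[j] - p[c]
    v = p[k] - p[c]
    w = p[l] - p[c]
    n = np.cross(u, v)
    nn = float(np.linalg.norm(n))
    nw = float(np.linalg.norm(w))
    s = float(n @ w) / (nn * nw)
    s = float(np.clip(s, -1.0, 1.0))
    chi = float(np.arcsin(s))
    dchi_ds = 1.0 / np.sqrt(max(1.0 - s * s, 1e-12))
    ds_dn = w / (nn * nw) - s * n / (nn * nn)
    ds_dw = n / (nn * nw) - s * w / (nw * nw)
    gu = np.cross(v, ds_dn)
    gv = np.cross(ds_dn, u)
    gj = dchi_ds * gu
    gk = dchi_ds * gv
    gl = dchi_ds * ds_dw
    return chi, {j: gj, k: gk, l: gl, c: -(gj + gk + gl)}


# ----------------------------------------------------------------- evaluation
@dataclass
class EnergyBreakdown:
    bond: float = 0.0
    angle: float = 0.0
    torsion: float = 0.0
    out_of_plane: float = 0.0
    cross_bond_bond: float = 0.0
    cross_angle_angle: float = 0.0
    cross_bond_angle: float = 0.0
    cross_torsion_angle_angle: float = 0.0
    cross_oop_oop: float = 0.0
    lj: float = 0.0
    coulomb: float = 0.0

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.torsion + self.out_of_plane
                + self.cross_bond_bond + self.cross_angle_angle
                + self.cross_bond_angle + self.cross_torsion_angle_angle
                + self.cross_oop_oop + self.lj + self.coulomb)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "bond", "angle", "torsion", "out_of_plane", "cross_bond_bond",
            "cross_angle_angle", "cross_bond_angle",
            "cross_torsion_angle_angle", "cross_oop_oop", "lj", "coulomb")}
        d["total"] = self.total
        return d


def _excluded_pairs(system: ParticleSystem) -> set:
    """1–2 and 1–3 pairs as a set of sorted index tuples."""
    adj: dict[int, set] = {}
    excl: set = set()
    for i, j in system.bonds:
        i, j = int(i), int(j)
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
        excl.add((min(i, j), max(i, j)))
    for center, neigh in adj.items():
        neigh = sorted(neigh)
        for a in range(len(neigh)):
            for b in range(a + 1, len(neigh)):
                excl.add((neigh[a], neigh[b]))
    return excl


def _accumulate(system: ParticleSystem, params: FFParams, want_forces: bool):
    p = system.positions
    t = system.tag
    n = system.n_particles
    grad = np.zeros((n, 3)) if want_forces else None
    e = EnergyBreakdown()

    def addg(grads, scale):
        if want_forces:
            for idx, g in grads.items():
                grad[idx] += scale * g

    # bonds
    bond_vals = {}
    for i, j in system.bonds:
        i, j = int(i), int(j)
        bp = params.bond(t[i], t[j])
        b, gb = _bond_geom(p, i, j)
        bond_vals[(min(i, j), max(i, j))] = (b, bp.b0, gb)
        ex = np.exp(-bp.alpha * (b - bp.b0))
        e.bond += bp.d * (1.0 - ex) ** 2
        addg(gb, 2.0 * bp.d * (1.0 - ex) * bp.alpha * ex)

    def bond_of(i, j):
        key = (min(int(i), int(j)), max(int(i), int(j)))
        if key not in bond_vals:
            raise KeyError(f"angle/torsion references missing bond {key}")
        return bond_vals[key]

    # angles + bond-bond and bond-angle cross terms (within each angle)
    angle_vals = {}
    for i, j, k in system.angles:
        i, j, k = int(i), int(j), int(k)
        ap = params.angle(t[i], t[j], t[k])
        theta, gt = _angle_geom(p, i, j, k)
        angle_vals[(i, j, k)] = (theta, ap.theta0, gt)
        dth = theta - ap.theta0
        e.angle += ap.h * dth * dth
        addg(gt, 2.0 * ap.h * dth)

        b1, b01, gb1 = bond_of(i, j)
        b2, b02, gb2 = bond_of(j, k)
        fbb = params.cross("cross_bond_bond", (t[i], t[j], t[k]))
        if fbb != 0.0:
            e.cross_bond_bond += fbb * (b1 - b01) * (b2 - b02)
            addg(gb1, fbb * (b2 - b02))
            addg(gb2, fbb * (b1 - b01))
        fbt = params.cross("cross_bond_angle", (t[i], t[j], t[k]))
        if fbt != 0.0:
            e.cross_bond_angle += fbt * ((b1 - b01) + (b2 - b02)) * dth
            addg(gb1, fbt * dth)
            addg(gb2, fbt * dth)
            addg(gt, fbt * ((b1 - b01) + (b2 - b02)))

    def angle_of(i, j, k):
        i, j, k = int(i), int(j), int(k)
        if (i, j, k) in angle_vals:
            return angle_vals[(i, j, k)]
        if (k, j, i) in angle_vals:
            return angle_vals[(k, j, i)]
        raise KeyError(f"torsion references missing angle {(i, j, k)}")

    # torsions + angle-angle and torsion-angle-angle cross terms
    for i, j, k, l in system.torsions:
        i, j, k, l = int(i), int(j), int(k), int(l)
        tp = params.torsion(t[i], t[j], t[k], t[l])
        phi, gp = _dihedral_geom(p, i, j, k, l)
        e.torsion += tp.h * (1.0 + tp.s * np.cos(tp.n * phi))
        addg(gp, -tp.h * tp.s * tp.n * np.sin(tp.n * phi))

        th1, th01, gt1 = angle_of(i, j, k)
        th2, th02, gt2 = angle_of(j, k, l)
        d1, d2 = th1 - th01, th2 - th02
        ftt = params.cross("cross_angle_angle", (t[i], t[j], t[k], t[l]))
        if ftt != 0.0:
            e.cross_angle_angle += ftt * d1 * d2
            addg(gt1, ftt * d2)
            addg(gt2, ftt * d1)
        fpt = params.cross("cross_torsion_angle_angle", (t[i], t[j], t[k], t[l]))
        if fpt != 0.0:
            cphi = np.cos(phi)
            e.cross_torsion_angle_angle += fpt * cphi * d1 * d2
            addg(gp, -fpt * np.sin(phi) * d1 * d2)
            addg(gt1, fpt * cphi * d2)
            addg(gt2, fpt * cphi * d1)

    # out-of-plane + oop-oop cross pairs sharing a central atom
    oop_vals: dict[int, list] = {}
    for c, j, k, l in system.out_of_plane:
        c, j, k, l = int(c), int(j), int(k), int(l)
        op = params.oop(t[c], t[j], t[k], t[l])
        chi, gc = _oop_geom(p, c, j, k, l)
        oop_vals.setdefault(c, []).append((chi, gc))
        e.out_of_plane += op.h * chi * chi
        addg(gc, 2.0 * op.h * chi)
    for c, terms in oop_vals.items():
        fxx = params.cross("cross_oop_oop", (t[c],))
        if fxx == 0.0:
            continue
        for a in range(len(terms)):
            for b in range(a + 1, len(terms)):
                chi1, g1 = terms[a]
                chi2, g2 = terms[b]
                e.cross_oop_oop += fxx * chi1 * chi2
                addg(g1, fxx * chi2)
                addg(g2, fxx * chi1)

    # nonbonded
    excl = _excluded_pairs(system)
    q = system.charges
    kc = COULOMB_CONSTANT / params.dielectric
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            v = p[j] - p[i]
            r = float(np.linalg.norm(v))
            if r < 1e-9:
                raise ValueError(f"particles {i} and {j} coincide")
            np_pair = params.pair(t[i], t[j])
            sr = np_pair.rstar / r
            e.lj += np_pair.epsilon * (sr**12 - 2.0 * sr**6)
            dedr = np_pair.epsilon * (-12.0 * sr**12 + 12.0 * sr**6) / r
            if q[i] != 0.0 and q[j] != 0.0:
                e.coulomb += kc * q[i] * q[j] / r
                dedr += -kc * q[i] * q[j] / (r * r)
            if want_forces:
                u = v / r
                grad[i] += -dedr * u
                grad[j] += dedr * u
    return e, grad


def evaluate_energy(system: ParticleSystem, params: FFParams) -> EnergyBreakdown:
    """Potential energy, term by term (kcal/mol)."""
    e, _ = _accumulate(system, params, want_forces=False)
    return e


def evaluate_forces(system: ParticleSystem, params: FFParams) -> np.ndarray:
    """Analytic forces, −∂E/∂r, shape (N, 3), kcal/mol/Å."""
    _, grad = _accumulate(system, params, want_forces=True)
    return -grad


def relax(system: ParticleSystem, params: FFParams, max_steps: int = 200,
          tol: float = 1e-4) -> tuple[ParticleSystem, list[float]]:
    """Line-searched steepest descent; energy is monotone non-increasing.

    Returns the relaxed system and the energy sequence.  Stops when the
    gradient RMS falls below ``tol`` or after ``max_steps``.
    """
    sys = system.copy()
    energies = []
    e, grad = _accumulate(sys, params, want_forces=True)
    e0 = e.total
    if not np.isfinite(e0):
        raise ValueError("starting energy is not finite")
    energies.append(e0)
    step = 0.05
    for _ in range(max_steps):
        gnorm = float(np.sqrt(np.mean(grad**2)))
        if gnorm <= tol:
            break
        direction = -grad / max(np.abs(grad).max(), 1e-30)
        trial = step
        accepted = False
        for _ls in range(40):
            cand = sys.copy()
            cand.positions = sys.positions + trial * direction
            e_new = evaluate_energy(cand, params).total
            if np.isfinite(e_new) and e_new <= e0:
                sys = cand
                e0 = e_new
                accepted = True
                step = min(trial * 1.6, 0.5)
                break
            trial *= 0.5
        if not accepted:
            break
        energies.append(e0)
        _, grad = _accumulate(sys, params, want_forces=True)
        if not np.isfinite(e0):
            raise ValueError("energy diverged during relaxation")
    return sys, energies
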