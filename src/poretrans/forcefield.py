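"""Force field: WCA pair repulsion, FENE bonds, harmonic tethers, pulling force.

Interactions (reduced LJ units, epsilon = 1 unless configured otherwise):

* every bead pair repels through the truncated-and-shifted 12-6 potential
  U = 4 eps [(sigma/r)^12 - (sigma/r)^6] + eps for r <= 2^(1/6) sigma and 0
  beyond (the WCA construction: energy and force both vanish continuously at
  the cutoff).  Pair diameters follow sigma_ij = (sigma_i + sigma_j)/2 within
  the polymer; membrane-membrane pairs use sigma = a/3 and membrane-polymer
  pairs sigma = a, which keeps the polymer from sneaking between membrane
  beads.  Membrane-membrane repulsion is only evaluated in the kinetic
  (tethered, mobile) membrane mode.
* bonded S-P and S-B pairs additionally feel the attractive finitely
  extensible term U = -1/2 K R^2 ln(1 - (r/R)^2) with R = 1.5 sigma_ij and
  K = 30 eps/sigma_ij^2; together with the WCA repulsion this is the FENE
  bond.  Bonded pairs are *not* excluded from the pair term.
* in the kinetic mode every membrane bead is tethered to its lattice site by
  U = k/2 |r - r_o|^2; the immobile membrane (k = inf) is realised by
  freezing the beads, never by arithmetic on infinities.
* a constant force F = 1.5 f  e_z acts on the first P bead while the pull is
  active (f = F a / k_B T_p with T_p = 3/2 is the dimensionless control
  parameter).

The x-y plane is periodic (minimum image); z is open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .errors import BondBreakError, NonFiniteError
from .geometry import MembraneLattice, Topology, POLYMER_RADII

WCA_CUT = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ForceFieldParams:
    """All interaction constants, in reduced LJ units."""

    epsilon: float = 1.0
    fene_k: float = 30.0            # FENE stiffness, units eps/sigma_ij^2
    fene_extension: float = 1.5     # R_ij = fene_extension * sigma_ij
    sigma_membrane: float = 1.0 / 3.0   # membrane-membrane pair diameter
    sigma_cross: float = 1.0        # membrane-polymer pair diameter
    pull_f: float = 0.0             # dimensionless force f = F a/(k_B T_p)
    T_p: float = 1.5                # polymer temperature entering f

    def __post_init__(self):
        if self.epsilon <= 0 or self.sigma_membrane <= 0 or self.sigma_cross <= 0:
            raise ValueError("energy and length scales must be positive")

    @property
    def pull_force(self) -> float:
        """Pulling force in LJ force units: F = f k_B T_p / a (= 1.5 f)."""
        return self.pull_f * self.T_p

    def sigma_table(self) -> np.ndarray:
        """Pair diameters sigma_ij indexed by (kind_i, kind_j)."""
        s = np.empty((4, 4))
        for i in range(3):
            for j in range(3):
                s[i, j] = 0.5 * (POLYMER_RADII[i] + POLYMER_RADII[j])
        s[3, :3] = s[:3, 3] = self.sigma_cross
        s[3, 3] = self.sigma_membrane
        return s

    def cutoff_table(self) -> np.ndarray:
        return WCA_CUT * self.sigma_table()


# --- scalar reference forms -------------------------------------------------

def pair_energy_force(r: float, sigma: float, epsilon: float = 1.0) -> tuple:
    """WCA energy and scalar force (positive = repulsive) at separation r."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if r > WCA_CUT * sigma:
        return 0.0, 0.0
    sr6 = (sigma / r) ** 6
    energy = 4.0 * epsilon * (sr6 * sr6 - sr6) + epsilon
    force = 24.0 * epsilon * (2.0 * sr6 * sr6 - sr6) / r
    return energy, force


def bond_energy_force(r: float, sigma: float, fene_k: float = 30.0,
                      fene_extension: float = 1.5, epsilon: float = 1.0) -> tuple:
    """Attractive FENE term at separation r; raises on r >= R_ij (broken bond)."""
    R = fene_extension * sigma
    if r <= 0:
        raise ValueError("bond distance must be positive")
    if r >= R:
        raise BondBreakError(
            f"bond stretched to r = {r:.4f} >= R = {R:.4f}; "
            "reduce the time step or the driving force")
    K = fene_k * epsilon / sigma**2
    x = (r / R) ** 2
    energy = -0.5 * K * R * R * math.log1p(-x)
    force = -K * r / (1.0 - x)     # negative: pulls the pair together
    return energy, force


def tether_energy_force(r, r_o, k: float) -> tuple:
    """Harmonic tether k/2 |r - r_o|^2: energy and force vector on the bead."""
    if k < 0:
        raise ValueError("tether stiffness must be non-negative")
    d = np.asarray(r, dtype=float) - np.asarray(r_o, dtype=float)
    return 0.5 * k * float(d @ d), -k * d


# --- compiled kernels -------------------------------------------------------

@njit(cache=True)
def _forces_kernel(pos, frc, kinds, sig2, cut2, eps,
                   pairs, bonds, bond_r2max, bond_k,
                   teth_i, teth_anchor, teth_k,
                   pull_i, pull_f, Lx, Ly):
    """Accumulate all forces into ``frc``; returns (potential, bad_pair_index).

    ``bad_pair_index`` is -1 on success, otherwise the row of ``bonds`` whose
    length reached its FENE maximum.  The pulling force contributes no
    potential-energy bookkeeping.
    """
    n = pos.shape[0]
    for i in range(n):
        frc[i, 0] = 0.0
        frc[i, 1] = 0.0
        frc[i, 2] = 0.0
    pe = 0.0
    periodic = Lx > 0.0
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if periodic:
            dx -= Lx * np.rint(dx / Lx)
            dy -= Ly * np.rint(dy / Ly)
        r2 = dx * dx + dy * dy + dz * dz
        ki = kinds[i]
        kj = kinds[j]
        if r2 < cut2[ki, kj]:
            s2 = sig2[ki, kj] / r2
            s6 = s2 * s2 * s2
            pe += 4.0 * eps * (s6 * s6 - s6) + eps
            fr = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
            frc[i, 0] += fr * dx
            frc[i, 1] += fr * dy
            frc[i, 2] += fr * dz
            frc[j, 0] -= fr * dx
            frc[j, 1] -= fr * dy
            frc[j, 2] -= fr * dz
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if periodic:
            dx -= Lx * np.rint(dx / Lx)
            dy -= Ly * np.rint(dy / Ly)
        r2 = dx * dx + dy * dy + dz * dz
        R2 = bond_r2max[b]
        if r2 >= R2:
            return np.nan, b
        x = r2 / R2
        pe += -0.5 * bond_k[b] * R2 * np.log(1.0 - x)
        fr = -bond_k[b] / (1.0 - x)
        frc[i, 0] += fr * dx
        frc[i, 1] += fr * dy
        frc[i, 2] += fr * dz
        frc[j, 0] -= fr * dx
        frc[j, 1] -= fr * dy
        frc[j, 2] -= fr * dz
    for t in range(teth_i.shape[0]):
        i = teth_i[t]
        dx = pos[i, 0] - teth_anchor[t, 0]
        dy = pos[i, 1] - teth_anchor[t, 1]
        dz = pos[i, 2] - teth_anchor[t, 2]
        pe += 0.5 * teth_k[t] * (dx * dx + dy * dy + dz * dz)
        frc[i, 0] -= teth_k[t] * dx
        frc[i, 1] -= teth_k[t] * dy
        frc[i, 2] -= teth_k[t] * dz
    if pull_i >= 0:
        frc[pull_i, 2] += pull_f
    return pe, -1


# --- system assembly --------------------------------------------------------

_EMPTY_PAIRS = np.empty((0, 2), dtype=np.int64)
_EMPTY_F = np.empty(0)
_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_V = np.empty((0, 3))


class System:
    """Topology + membrane + parameters flattened into kernel-ready arrays.

    Beads are ordered polymer first, then membrane; the membrane anchor
    positions double as the initial membrane coordinates.
    """

    def __init__(self, topology: Topology, membrane: MembraneLattice | None,
                 params: ForceFieldParams = ForceFieldParams()):
        topology.validate()
        if membrane is not None and membrane.n_sites != topology.n_membrane:
            raise ValueError("membrane site count disagrees with topology")
        self.top = topology
        self.membrane = membrane
        self.params = params
        self.kinds = np.ascontiguousarray(topology.kinds, dtype=np.int64)
        sig = params.sigma_table()
        self.sig2 = sig * sig
        cut = params.cutoff_table()
        self.cut2 = cut * cut
        self.bonds = np.ascontiguousarray(topology.bonds, dtype=np.int64)
        if len(self.bonds):
            bs = sig[topology.kinds[self.bonds[:, 0]],
                     topology.kinds[self.bonds[:, 1]]]
            self.bond_r2max = (params.fene_extension * bs) ** 2
            self.bond_k = params.fene_k * params.epsilon / bs**2
        else:
            self.bond_r2max = _EMPTY_F
            self.bond_k = _EMPTY_F
        self.kinetic = (topology.n_membrane > 0
                        and not topology.immobile_membrane)
        if self.kinetic:
            self.teth_i = np.arange(topology.n_polymer, topology.n_total,
                                    dtype=np.int64)
            self.teth_anchor = membrane.anchors
            self.teth_k = np.full(topology.n_membrane, topology.tether_k)
        else:
            self.teth_i = _EMPTY_I
            self.teth_anchor = _EMPTY_V
            self.teth_k = _EMPTY_F
        if membrane is not None:
            self.box = membrane.box
            # anchor tree is built once: candidate searches query anchors, with
            # margins covering the bounded tether displacements
            if self.box[0] > 0:
                wrapped = np.mod(membrane.xy, self.box)
                self._anchor_tree = cKDTree(wrapped, boxsize=self.box)
            else:
                self._anchor_tree = cKDTree(membrane.xy)
        else:
            self.box = (0.0, 0.0)
            self._anchor_tree = None
        self.n_polymer = topology.n_polymer
        self.n_total = topology.n_total
        i, j = np.triu_indices(self.n_polymer, k=1)
        self._pp_pairs = np.column_stack([i, j]).astype(np.int64)

    # cutoffs used by the neighbour machinery
    @property
    def cutoff_cross(self) -> float:
        return WCA_CUT * self.params.sigma_cross

    @property
    def cutoff_membrane(self) -> float:
        return WCA_CUT * self.params.sigma_membrane

    def initial_positions(self, polymer_positions: np.ndarray) -> np.ndarray:
        if self.top.n_membrane:
            return np.vstack([polymer_positions, self.membrane.anchors])
        return np.array(polymer_positions, dtype=float)

    def all_pairs(self) -> np.ndarray:
        """Brute-force candidate list: every pair that can ever interact."""
        blocks = [self._pp_pairs]
        npol, ntot = self.n_polymer, self.n_total
        if self.top.n_membrane:
            i, j = np.meshgrid(np.arange(npol), np.arange(npol, ntot),
                               indexing="ij")
            blocks.append(np.column_stack([i.ravel(), j.ravel()]))
            if self.kinetic:
                mi, mj = np.triu_indices(self.top.n_membrane, k=1)
                blocks.append(np.column_stack([mi + npol, mj + npol]))
        return np.ascontiguousarray(np.vstack(blocks), dtype=np.int64)


class NeighborList:
    """Candidate pair list: polymer-polymer (exhaustive), polymer-membrane and
    membrane-membrane (anchor-tree searches with a skin).

    Membrane beads are tethered, so their displacement from the anchors is
    bounded; ``disp_budget`` is that bound.  Candidate searches query the
    static anchor tree with radius cutoff + skin + budget (cross pairs) and
    cutoff + 2 budget (membrane pairs), which keeps the list a superset of
    all interacting pairs as long as (a) no polymer bead has moved more than
    skin/2 since the last build and (b) no membrane bead strays beyond the
    budget.  Both conditions are monitored during integration; violating (b)
    escalates the budget and rebuilds.
    """

    def __init__(self, system: System, skin: float = 0.75,
                 disp_budget: float = 0.35):
        self.system = system
        self.skin = skin
        self.disp_budget = disp_budget if system.kinetic else 0.0
        self.pairs = system._pp_pairs
        self.ref_pos: np.ndarray | None = None
        self._mm_pairs = _EMPTY_PAIRS
        self._mm_budget_used = -1.0

    def build(self, pos: np.ndarray) -> np.ndarray:
        sys_ = self.system
        blocks = [sys_._pp_pairs]
        if sys_.top.n_membrane:
            tree = sys_._anchor_tree
            r_cross = sys_.cutoff_cross + self.skin + self.disp_budget
            q = pos[:sys_.n_polymer, :2]
            if sys_.box[0] > 0:
                q = np.mod(q, sys_.box)
            hits = tree.query_ball_point(q, r_cross)
            pm = [(i, sys_.n_polymer + j) for i, js in enumerate(hits) for j in js]
            if pm:
                blocks.append(np.array(pm, dtype=np.int64))
            if sys_.kinetic:
                if self._mm_budget_used != self.disp_budget:
                    r_mm = sys_.cutoff_membrane + 2.0 * self.disp_budget
                    mm = tree.query_pairs(r_mm, output_type="ndarray")
                    self._mm_pairs = np.ascontiguousarray(
                        mm.astype(np.int64) + sys_.n_polymer)
                    self._mm_budget_used = self.disp_budget
                if len(self._mm_pairs):
                    blocks.append(self._mm_pairs)
        self.pairs = np.ascontiguousarray(np.vstack(blocks), dtype=np.int64)
        self.ref_pos = pos.copy()
        return self.pairs

    def escalate(self, pos: np.ndarray) -> None:
        """Grow the membrane displacement budget and rebuild."""
        self.disp_budget *= 1.5
        self.build(pos)


def total_forces(pos: np.ndarray, system: System,
                 pairs: np.ndarray | None = None,
                 pull_on: bool = False) -> tuple:
    """Forces on every bead and the total potential energy.

    ``pairs = None`` evaluates all pairs brute force (the O(N^2) reference
    path); otherwise the supplied candidate list is used.  Raises
    :class:`BondBreakError` on an over-stretched bond and
    :class:`NonFiniteError` if any force component is non-finite.
    """
    pos = np.ascontiguousarray(pos, dtype=float)
    frc = np.empty_like(pos)
    if pairs is None:
        pairs = system.all_pairs()
    pull_i = system.top.pulled_bead if pull_on else -1
    pe, bad = _forces_kernel(
        pos, frc, system.kinds, system.sig2, system.cut2,
        system.params.epsilon, pairs, system.bonds, system.bond_r2max,
        system.bond_k, system.teth_i, system.teth_anchor, system.teth_k,
        pull_i, system.params.pull_force, system.box[0], system.box[1])
    if bad >= 0:
        i, j = system.bonds[bad]
        raise BondBreakError(f"bond ({i}, {j}) reached its FENE maximum")
    if not np.isfinite(frc).all():
        culprit = np.argwhere(~np.isfinite(frc))[0, 0]
        raise NonFiniteError(f"non-finite force on bead {culprit}")
    return frc, pe
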