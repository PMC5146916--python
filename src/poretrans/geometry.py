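"""Construction of the structured polymer and the honeycomb membrane.

All geometry lives in reduced LJ units with the backbone bead diameter
``a = sigma_P = 1`` as the length unit.  The membrane is a graphene-like
honeycomb sheet in the z = 0 plane, periodic in x-y, with a circular
nano-pore carved around the (0, 0, 0) reference point.  The polymer is a
coarse-grained single-stranded-DNA chain built from three bead types:
phosphate-like P and sugar-like S units alternating along the backbone and
one base-like B unit grafted to every S.  One extra P bead sits at the head
of the chain and is the bead the pulling force acts on, so a chain with
``n`` repeat units has N = 3n + 1 beads.

Lattice convention
------------------
The stated hexagonal lattice constant is ``b = a/2``.  That number alone
does not fix the sheet: the nearest-neighbour spacing and the placement of
the pore center relative to the lattice are both conventions.  We treat
them as a calibrated pair.  Carving a pore of radius 1.25a must remove 24
sites and one of radius 1.75a must remove 54 — these are the coronene and
circumcoronene motifs, which pins the pore center to a *hexagon center* and
restricts the nearest-neighbour spacing to d in [0.347a, 0.401a].  The
default d = 3a/8 = 0.75 b lies in that window and, in addition, makes the
default periodic patch for the N = 49 chain (49 x 28 four-site cells) hold
exactly 5488 sites in a 31.83a x 31.5a box — large enough that the chain at
its rest contour length (~31a) cannot reach its own periodic image.  The
literal "b = bond length" reading and the site / bond-midpoint origins are
also implemented and selectable; the chosen convention is recorded in the
lattice metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .errors import CommensurabilityError, GrowthError

logger = logging.getLogger(__name__)

# --- bead kinds -------------------------------------------------------------

P, S, B, C = 0, 1, 2, 3
KIND_LABELS = "PSBC"

#: steric radii sigma_i of the polymer bead types (P, S, B) in units of a
POLYMER_RADII = np.array([1.0, 1.0, 1.5])


@dataclass(frozen=True)
class BeadKind:
    """Static description of one bead species."""

    label: str
    sigma: float   # own-pair diameter; pair values follow the mixing rules
    mass: float

    def __post_init__(self):
        if self.label not in KIND_LABELS:
            raise ValueError(f"bead label must be one of {KIND_LABELS!r}")
        if self.sigma <= 0:
            raise ValueError("bead radius must be strictly positive")


# --- membrane lattice -------------------------------------------------------

LATTICE_B = 0.5           # stated hexagonal lattice constant b = a/2
BOND_CALIBRATED = 0.375   # nearest-neighbour spacing d = 0.75 b (see module docstring)
R_SMALL = 1.25            # small pore radius R_s
R_LARGE = 1.75            # large pore radius R_l

_ORIGIN_OFFSETS = {
    # offset of the reference point (pore center) within the lattice, in units
    # of the nearest-neighbour spacing d
    "hex_center": (0.0, 1.0),
    "site": (0.0, 0.0),
    "bond_midpoint": (math.sqrt(3.0) / 4.0, 0.25),
}


@dataclass(eq=False)
class MembraneLattice:
    """Honeycomb sheet in the z = 0 plane, centered on the pore reference point.

    ``xy`` holds the in-plane site coordinates (the anchors of the tethers in
    the kinetic-membrane mode); the sheet is periodic over ``box`` in x-y, or
    a free-standing fragment when ``box == (0, 0)``.
    """

    xy: np.ndarray
    box: tuple
    bond: float
    origin: str
    pore_radius: float | None = None
    n_removed: int = 0
    rim: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.xy)

    @property
    def anchors(self) -> np.ndarray:
        """Site positions as (n, 3) coordinates with z = 0."""
        return np.column_stack([self.xy, np.zeros(len(self.xy))])

    def metadata(self) -> dict:
        return {
            "lattice_constant_b": LATTICE_B,
            "bond_length": self.bond,
            "origin_convention": self.origin,
            "box": list(self.box),
            "n_sites": self.n_sites,
            "pore_radius": self.pore_radius,
            "n_removed": self.n_removed,
        }


def honeycomb_lattice(nx: int, ny: int, bond: float = BOND_CALIBRATED,
                      origin: str = "hex_center") -> MembraneLattice:
    """Periodic honeycomb sheet of ``nx`` x ``ny`` rectangular four-site cells.

    The rectangular cell has extent (sqrt(3) d, 3 d); the sheet is shifted so
    the chosen origin convention places the pore reference point at (0, 0),
    and wrapped into the centered box (-L/2, L/2].
    """
    if nx < 1 or ny < 1:
        raise ValueError("cell counts must be positive")
    if origin not in _ORIGIN_OFFSETS:
        raise ValueError(f"origin must be one of {sorted(_ORIGIN_OFFSETS)}")
    d = float(bond)
    w, h = math.sqrt(3.0) * d, 3.0 * d
    basis = np.array([[0.0, 0.0],
                      [math.sqrt(3.0) / 2.0 * d, 0.5 * d],
                      [math.sqrt(3.0) / 2.0 * d, 1.5 * d],
                      [0.0, 2.0 * d]])
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    shifts = np.column_stack([ii.ravel() * w, jj.ravel() * h])
    xy = (shifts[:, None, :] + basis[None, :, :]).reshape(-1, 2)
    off = np.array(_ORIGIN_OFFSETS[origin]) * d
    xy = xy - off
    Lx, Ly = w * nx, h * ny
    # wrap into the centered box so planar distances from the pore center are
    # directly the minimum-image ones
    xy[:, 0] -= Lx * np.round(xy[:, 0] / Lx)
    xy[:, 1] -= Ly * np.round(xy[:, 1] / Ly)
    return MembraneLattice(xy=xy, box=(Lx, Ly), bond=d, origin=origin)


def single_hexagon(bond: float = BOND_CALIBRATED) -> MembraneLattice:
    """The smallest closed ring: one hexagon of 6 sites around the origin."""
    d = float(bond)
    ang = np.pi / 2 + np.arange(6) * np.pi / 3
    xy = d * np.column_stack([np.cos(ang), np.sin(ang)])
    return MembraneLattice(xy=xy, box=(0.0, 0.0), bond=d, origin="hex_center")


def default_cells(n: int, bond: float = BOND_CALIBRATED) -> tuple:
    """Cell counts for the default membrane extent at repeat count ``n``.

    Sized from the rest-length contour of the chain, (2n + 1) r*, so that a
    stretched chain cannot reach its own periodic image; calibrated so that
    n = 16 (N = 49) gives the 49 x 28 patch with 5488 sites.
    """
    target = (2 * n + 1) * fene_rest_length(1.0)
    d = float(bond)
    nx = max(2, round(target / (math.sqrt(3.0) * d)))
    ny = max(2, round(target / (3.0 * d)))
    return (nx, ny)


def build_membrane(n: int | None = None, cells: tuple | None = None,
                   box_extent: tuple | None = None,
                   bond: float = BOND_CALIBRATED,
                   origin: str = "hex_center") -> MembraneLattice:
    """Build the periodic membrane sheet.

    Exactly one of ``cells`` (nx, ny), ``box_extent`` (Lx, Ly) or the chain
    repeat count ``n`` (default sizing rule) selects the extent.  A
    ``box_extent`` that is not commensurate with the lattice period raises
    :class:`CommensurabilityError` listing the nearest valid sizes.
    """
    if cells is not None:
        nx, ny = cells
    elif box_extent is not None:
        d = float(bond)
        periods = (math.sqrt(3.0) * d, 3.0 * d)
        counts = []
        for L, per, name in zip(box_extent, periods, "xy"):
            m = L / per
            if abs(m - round(m)) > 1e-8 * max(1.0, m) or round(m) < 1:
                lo, hi = math.floor(m) * per, math.ceil(m) * per
                raise CommensurabilityError(
                    f"L{name} = {L} is not commensurate with the lattice period "
                    f"{per:.6f}; nearest valid sizes are {lo:.6f} and {hi:.6f}")
            counts.append(round(m))
        nx, ny = counts
    else:
        nx, ny = default_cells(16 if n is None else n, bond=bond)
    return honeycomb_lattice(nx, ny, bond=bond, origin=origin)


def carve_pore(membrane: MembraneLattice, radius: float) -> MembraneLattice:
    """Remove every site at planar distance strictly less than ``radius``.

    Returns a new lattice with the removed count and the pore-rim site set
    (sites initially within one lattice spacing outside the pore).  Carving is
    idempotent: re-carving with the same radius removes nothing further.
    """
    if radius < 0:
        raise ValueError("pore radius must be non-negative")
    Lx, Ly = membrane.box
    if Lx > 0 and radius > min(Lx, Ly) / 2:
        raise ValueError(
            f"pore radius {radius} exceeds half the box {min(Lx, Ly) / 2:.3f}: "
            "the pore would touch its own periodic image")
    r = np.hypot(membrane.xy[:, 0], membrane.xy[:, 1])
    keep = r >= radius
    xy = membrane.xy[keep]
    rkept = r[keep]
    rim = np.flatnonzero(rkept < radius + membrane.bond)
    return replace(membrane, xy=xy, pore_radius=radius,
                   n_removed=int((~keep).sum()), rim=rim)


def check_membrane_extent(membrane: MembraneLattice, n: int) -> bool:
    """Warn when the box violates the stretched-chain sizing rule.

    The largest in-plane span the chain can present is the rest end-to-end
    length of the backbone, 2n bonds at the FENE rest distance.
    """
    needed = 2 * n * fene_rest_length(1.0)
    Lx, Ly = membrane.box
    ok = Lx <= 0 or min(Lx, Ly) >= needed
    if not ok:
        logger.warning(
            "membrane box %.1f x %.1f is smaller than the rest contour %.1f of "
            "the n = %d chain; the chain can reach its own periodic image",
            Lx, Ly, needed, n)
    return ok


# --- structured polymer -----------------------------------------------------

@lru_cache(maxsize=None)
def fene_rest_length(sigma: float, fene_k: float = 30.0,
                     fene_extension: float = 1.5) -> float:
    """Rest distance of a FENE bond: minimum of WCA repulsion + FENE attraction.

    ``fene_k`` is in units of epsilon/sigma_ij^2, ``fene_extension`` gives the
    maximum elongation R_ij = fene_extension * sigma_ij.
    """
    Rf = fene_extension

    def balance(x):
        # d/dx of U_WCA + U_FENE in units of sigma (repulsive positive)
        rep = 24.0 * (2.0 * x**-13 - x**-7) if x < 2 ** (1 / 6) else 0.0
        att = fene_k * x / (1.0 - (x / Rf) ** 2)
        return rep - att

    x = brentq(balance, 0.7, 2 ** (1 / 6) - 1e-12)
    return float(x * sigma)


@dataclass(eq=False)
class Topology:
    """Static description of the full system (polymer first, then membrane).

    The polymer beads occupy indices ``0 .. n_polymer - 1`` in the order
    P, (S, B, P) x n, so bead ``3k`` is a P unit, ``3k+1`` an S and ``3k+2``
    a B.  Membrane beads, if present, follow and carry one tether each to
    their lattice anchor; ``tether_k = inf`` marks the immobile membrane
    (beads frozen rather than tethered).
    """

    kinds: np.ndarray
    groups: np.ndarray            # 0 = polymer, 1 = membrane
    masses: np.ndarray
    bonds: np.ndarray             # (M, 2) index pairs, S-P and S-B only
    pulled_bead: int
    n: int
    n_polymer: int
    n_membrane: int = 0
    tether_k: float = math.inf

    @property
    def n_total(self) -> int:
        return self.n_polymer + self.n_membrane

    @property
    def n_P(self) -> int:
        return self.n + 1

    @property
    def n_S(self) -> int:
        return self.n

    @property
    def n_B(self) -> int:
        return self.n

    @property
    def immobile_membrane(self) -> bool:
        return math.isinf(self.tether_k)

    def validate(self) -> None:
        kinds, groups = self.kinds, self.groups
        assert self.n_polymer == 3 * self.n + 1
        assert (groups[:self.n_polymer] == 0).all()
        assert (groups[self.n_polymer:] == 1).all()
        assert (kinds[self.n_polymer:] == C).all()
        if len(self.bonds):
            assert self.bonds.max() < self.n_polymer, "membrane beads carry no bonds"
            s_mask = kinds[self.bonds[:, 0]] == S
            assert s_mask.all(), "every bond is anchored on an S bead"
        assert kinds[self.pulled_bead] == P
        if self.tether_k < 0:
            raise ValueError("tether stiffness must be non-negative")


def _polymer_kinds(n: int) -> np.ndarray:
    kinds = np.empty(3 * n + 1, dtype=np.int64)
    kinds[0::3] = P
    if n > 0:
        kinds[1::3] = S
        kinds[2::3] = B
    return kinds


def polymer_bonds(n: int) -> np.ndarray:
    """Bond list of the chain: each S bonded to its flanking P beads and its B."""
    bonds = []
    for k in range(n):
        s = 3 * k + 1
        bonds += [(s, s - 1), (s, s + 1), (s, s + 2)]  # S-P_prev, S-B, S-P_next
    return np.array(bonds, dtype=np.int64).reshape(-1, 2)


def build_polymer(n: int, seed: int) -> tuple:
    """Grow the structured chain into the cis half-space z < 0.

    Returns ``(topology, positions)``.  The first (pulled) P bead is pinned at
    the origin, every other bead lies strictly below the membrane plane, all
    bonds start at their FENE rest length and no bead pair is closer than
    0.85 of its WCA cutoff.  Growth is retried a bounded number of times and
    raises :class:`GrowthError` if self-avoidance cannot be satisfied.
    """
    if n < 0:
        raise ValueError("repeat count must be non-negative")
    kinds = _polymer_kinds(n)
    bonds = polymer_bonds(n)
    top = Topology(kinds=kinds, groups=np.zeros(3 * n + 1, dtype=np.int64),
                   masses=np.ones(3 * n + 1), bonds=bonds, pulled_bead=0,
                   n=n, n_polymer=3 * n + 1)
    rng = np.random.default_rng(seed)
    radii = POLYMER_RADII[kinds]
    min2 = (0.85 * 2 ** (1 / 6) * 0.5 * (radii[:, None] + radii[None, :])) ** 2
    r_ps = fene_rest_length(1.0)
    r_sb = fene_rest_length(1.25)

    def draw_dir(z_cap):
        while True:
            u = rng.standard_normal(3)
            nu = np.linalg.norm(u)
            if nu < 1e-12:
                continue
            u /= nu
            if u[2] <= z_cap:
                return u

    for _restart in range(40):
        pos = np.zeros((3 * n + 1, 3))
        if n == 0:
            return top, pos
        pos[1] = (0.0, 0.0, -r_ps)  # first S hangs below the pinned bead
        ok = True
        placed = 2
        for k in range(n):
            s = 3 * k + 1
            steps = [(s + 1, s, r_sb, -0.25),      # B off the sugar
                     (s + 2, s, r_ps, -0.45)]      # next backbone P
            if k < n - 1:
                steps.append((s + 3, s + 2, r_ps, -0.45))  # next backbone S
            for idx, prev, length, cap in steps:
                for _try in range(200):
                    cand = pos[prev] + length * draw_dir(cap)
                    if cand[2] > -1.2:
                        continue
                    d2 = np.sum((pos[:placed] - cand) ** 2, axis=1)
                    if (d2 >= min2[idx, :placed]).all():
                        pos[idx] = cand
                        placed += 1
                        break
                else:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return top, pos
    raise GrowthError(
        f"could not grow a self-avoiding n = {n} chain after 40 restarts")


def combine(polymer: Topology, membrane: MembraneLattice,
            tether_k: float = math.inf, membrane_mass: float = 1.0) -> Topology:
    """Append the membrane beads to a polymer topology.

    ``tether_k = inf`` selects the immobile membrane; finite values tether
    every C bead harmonically to its lattice site.
    """
    if tether_k < 0:
        raise ValueError("tether stiffness must be non-negative")
    nc = membrane.n_sites
    npol = polymer.n_polymer
    return Topology(
        kinds=np.concatenate([polymer.kinds, np.full(nc, C, dtype=np.int64)]),
        groups=np.concatenate([polymer.groups, np.ones(nc, dtype=np.int64)]),
        masses=np.concatenate([polymer.masses, np.full(nc, float(membrane_mass))]),
        bonds=polymer.bonds, pulled_bead=polymer.pulled_bead, n=polymer.n,
        n_polymer=npol, n_membrane=nc, tether_k=float(tether_k))
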