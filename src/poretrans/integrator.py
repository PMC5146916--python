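"""Underdamped Langevin dynamics with per-group thermostats.

One BAOAB splitting step advances positions and velocities through
B (half kick) - A (half drift) - O (exact Ornstein-Uhlenbeck velocity
refresh) - A - B.  The O sub-step uses the exact damping factor
exp(-xi dt / m), so the integrator is well behaved for any xi dt and reduces
to velocity Verlet when the friction vanishes.  Polymer and membrane beads
carry separate temperatures (T_p and T_m); a zero temperature keeps the
friction but switches the noise off, and frozen beads (the immobile
membrane, the pinned head bead) are excluded from integration entirely while
still acting as force sources.

The inner loop is a compiled kernel that also performs the cheap per-step
bookkeeping the translocation protocol needs (termination test, failed-slide
detection, per-bead pore waiting times, effective-pore-radius series) and
returns control to Python only to rebuild neighbour candidate lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import BondBreakError, NonFiniteError
from .forcefield import NeighborList, System, _forces_kernel, total_forces

DEFAULT_DT = 5.0e-3

# kernel exit statuses
_DONE, _REBUILD, _TRANSLOCATED, _FAILED, _BONDBREAK, _NONFINITE, _BUDGET = range(7)


@dataclass(frozen=True)
class ThermostatSpec:
    """Per-group Langevin thermostat: polymer at T_p, membrane at T_m.

    The noise obeys <eta_i(t) eta_j(t')> = 2 xi k_B T delta_ij delta(t - t')
    for the group temperature T; friction xi is common to all beads.
    """

    T_polymer: float = 1.5
    T_membrane: float = 0.0
    friction: float = 1.0

    def __post_init__(self):
        if self.T_polymer < 0 or self.T_membrane < 0:
            raise ValueError("temperatures must be non-negative")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")

    def bead_temperatures(self, groups: np.ndarray) -> np.ndarray:
        return np.where(groups == 0, self.T_polymer, self.T_membrane)


@dataclass(eq=False)
class SimulationState:
    """Dynamic state: coordinates, velocities, counters, RNG, frozen flags."""

    pos: np.ndarray
    vel: np.ndarray
    frozen: np.ndarray
    step: int = 0
    time: float = 0.0
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0))


@njit(cache=True)
def _run_kernel(pos, vel, frc, mass, imass, movable, c1, c2,
                dt, nsteps, step_offset, seed,
                kinds, sig2, cut2, eps, pairs,
                bonds, bond_r2max, bond_k,
                teth_i, teth_anchor, teth_k, pull_i, pull_f, Lx, Ly,
                ref_pos, skin_half2, budget2, check_stride,
                n_poly, do_term, head, fail_r2, fail_needed, fail_counter,
                wait_half, wait_acc, cross_step,
                rim_idx, rim_off, reff_stride, reff_out, reff_n,
                out):
    n = pos.shape[0]
    np.random.seed(seed)
    pe, bad = _forces_kernel(pos, frc, kinds, sig2, cut2, eps, pairs,
                             bonds, bond_r2max, bond_k,
                             teth_i, teth_anchor, teth_k,
                             pull_i, pull_f, Lx, Ly)
    if bad >= 0:
        out[0] = _BONDBREAK
        out[1] = bad
        return 0
    for s in range(nsteps):
        for i in range(n):
            if movable[i]:
                h = 0.5 * dt * imass[i]
                vel[i, 0] += h * frc[i, 0]
                vel[i, 1] += h * frc[i, 1]
                vel[i, 2] += h * frc[i, 2]
                g = 0.5 * dt
                pos[i, 0] += g * vel[i, 0]
                pos[i, 1] += g * vel[i, 1]
                pos[i, 2] += g * vel[i, 2]
                if c2[i] > 0.0:
                    vel[i, 0] = c1[i] * vel[i, 0] + c2[i] * np.random.standard_normal()
                    vel[i, 1] = c1[i] * vel[i, 1] + c2[i] * np.random.standard_normal()
                    vel[i, 2] = c1[i] * vel[i, 2] + c2[i] * np.random.standard_normal()
                else:
                    vel[i, 0] = c1[i] * vel[i, 0]
                    vel[i, 1] = c1[i] * vel[i, 1]
                    vel[i, 2] = c1[i] * vel[i, 2]
                pos[i, 0] += g * vel[i, 0]
                pos[i, 1] += g * vel[i, 1]
                pos[i, 2] += g * vel[i, 2]
        pe, bad = _forces_kernel(pos, frc, kinds, sig2, cut2, eps, pairs,
                                 bonds, bond_r2max, bond_k,
                                 teth_i, teth_anchor, teth_k,
                                 pull_i, pull_f, Lx, Ly)
        if bad >= 0:
            out[0] = _BONDBREAK
            out[1] = bad
            return s
        for i in range(n):
            if movable[i]:
                h = 0.5 * dt * imass[i]
                vel[i, 0] += h * frc[i, 0]
                vel[i, 1] += h * frc[i, 1]
                vel[i, 2] += h * frc[i, 2]
        gstep = step_offset + s + 1
        if wait_half > 0.0:
            for i in range(n_poly):
                z = pos[i, 2]
                if -wait_half < z < wait_half:
                    wait_acc[i] += dt
        if reff_stride > 0 and gstep % reff_stride == 0:
            best = 1.0e30
            for t in range(rim_idx.shape[0]):
                i = rim_idx[t]
                d = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2) - rim_off
                if d < best:
                    best = d
            if reff_n[0] < reff_out.shape[0]:
                reff_out[reff_n[0]] = best
                reff_n[0] += 1
        if gstep % check_stride == 0:
            finite = True
            for i in range(n):
                if movable[i]:
                    if not (np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1])
                            and np.isfinite(pos[i, 2])):
                        finite = False
                        break
            if not finite:
                out[0] = _NONFINITE
                out[1] = gstep
                return s + 1
            if do_term:
                done = True
                for i in range(n_poly):
                    if pos[i, 2] <= 0.0:
                        done = False
                    elif cross_step.shape[0] > 0 and cross_step[i] < 0:
                        cross_step[i] = gstep
                if done:
                    out[0] = _TRANSLOCATED
                    out[1] = 0
                    return s + 1
            if fail_needed > 0:
                lat2 = pos[head, 0] ** 2 + pos[head, 1] ** 2
                if pos[head, 2] < 0.0 and lat2 > fail_r2:
                    fail_counter[0] += 1
                    if fail_counter[0] >= fail_needed:
                        out[0] = _FAILED
                        out[1] = 0
                        return s + 1
                else:
                    fail_counter[0] = 0
            if budget2 < 1.0e30:
                for t in range(teth_i.shape[0]):
                    i = teth_i[t]
                    dx = pos[i, 0] - teth_anchor[t, 0]
                    dy = pos[i, 1] - teth_anchor[t, 1]
                    dz = pos[i, 2] - teth_anchor[t, 2]
                    if dx * dx + dy * dy + dz * dz > budget2:
                        out[0] = _BUDGET
                        out[1] = 0
                        return s + 1
            if skin_half2 < 1.0e30:
                for i in range(n_poly):
                    dx = pos[i, 0] - ref_pos[i, 0]
                    dy = pos[i, 1] - ref_pos[i, 1]
                    dz = pos[i, 2] - ref_pos[i, 2]
                    if dx * dx + dy * dy + dz * dz > skin_half2:
                        out[0] = _REBUILD
                        out[1] = 0
                        return s + 1
    out[0] = _DONE
    out[1] = 0
    return nsteps


_NO_FAIL = np.zeros(1, dtype=np.int64)
_NO_WAIT = np.empty(0)
_NO_RIM = np.empty(0, dtype=np.int64)
_NO_CROSS = np.empty(0, dtype=np.int64)
_NO_REFF = np.empty(0)
_NO_REFFN = np.zeros(1, dtype=np.int64)


class Simulation:
    """A system plus its dynamic state, stepped by the Langevin kernel."""

    def __init__(self, system: System, state: SimulationState,
                 thermostat: ThermostatSpec = ThermostatSpec(),
                 dt: float = DEFAULT_DT, check_stride: int = 10,
                 skin: float = 0.75, disp_budget: float = 0.35):
        if dt <= 0:
            raise ValueError("time step must be positive")
        self.system = system
        self.state = state
        self.thermostat = thermostat
        self.dt = float(dt)
        self.check_stride = int(check_stride)
        self.pull_on = False
        self.nlist = NeighborList(system, skin=skin, disp_budget=disp_budget)
        self.nlist.build(state.pos)
        self._frc = np.empty_like(state.pos)

    # -- construction --------------------------------------------------------

    @classmethod
    def create(cls, system: System, polymer_positions: np.ndarray,
               thermostat: ThermostatSpec = ThermostatSpec(),
               dt: float = DEFAULT_DT, seed: int | np.random.SeedSequence = 0,
               **kw) -> "Simulation":
        """Assemble a state with Maxwell velocities at the group temperatures.

        Membrane beads start exactly on their anchors; the immobile membrane
        is frozen.  Frozen beads and zero-temperature groups get zero
        velocity.
        """
        rng = np.random.default_rng(seed)
        pos = system.initial_positions(polymer_positions)
        n = system.n_total
        T = thermostat.bead_temperatures(system.top.groups)
        scale = np.sqrt(T / system.top.masses)
        vel = rng.standard_normal((n, 3)) * scale[:, None]
        frozen = np.zeros(n, dtype=bool)
        if system.top.n_membrane and system.top.immobile_membrane:
            frozen[system.n_polymer:] = True
        vel[frozen] = 0.0
        state = SimulationState(pos=pos, vel=vel, frozen=frozen, rng=rng)
        return cls(system, state, thermostat, dt=dt, **kw)

    # -- frozen-bead control --------------------------------------------------

    def freeze_bead(self, i: int) -> None:
        self.state.frozen[i] = True
        self.state.vel[i] = 0.0

    def release_bead(self, i: int, thermal: bool = True) -> None:
        """Unfreeze bead ``i``, optionally drawing a Maxwell velocity."""
        self.state.frozen[i] = False
        if thermal:
            T = self.thermostat.bead_temperatures(self.system.top.groups)[i]
            s = math.sqrt(T / self.system.top.masses[i])
            self.state.vel[i] = self.state.rng.standard_normal(3) * s

    # -- energetics -----------------------------------------------------------

    def forces(self) -> tuple:
        return total_forces(self.state.pos, self.system,
                            pairs=self.nlist.pairs, pull_on=self.pull_on)

    def kinetic_energy(self, selection: slice | np.ndarray = slice(None)) -> float:
        v = self.state.vel[selection]
        m = self.system.top.masses[selection]
        return float(0.5 * np.sum(m[:, None] * v * v))

    # -- stepping -------------------------------------------------------------

    def _coefficients(self) -> tuple:
        xi = self.thermostat.friction
        m = self.system.top.masses
        T = self.thermostat.bead_temperatures(self.system.top.groups)
        c1 = np.exp(-xi * self.dt / m)
        c2 = np.sqrt(np.maximum(0.0, T / m * (1.0 - c1 * c1)))
        return c1, c2

    def _advance(self, n_steps: int, terminate: bool = False,
                 fail_r2: float = 0.0, fail_needed: int = 0,
                 fail_counter: np.ndarray = _NO_FAIL,
                 wait_half: float = 0.0, wait_acc: np.ndarray = _NO_WAIT,
                 cross_step: np.ndarray = _NO_CROSS,
                 rim_idx: np.ndarray = _NO_RIM, rim_off: float = 0.0,
                 reff_stride: int = 0, reff_out: np.ndarray = _NO_REFF,
                 reff_n: np.ndarray = _NO_REFFN) -> int:
        """Run up to ``n_steps``; returns a terminal status (0, 2 or 3)."""
        sys_, st = self.system, self.state
        c1, c2 = self._coefficients()
        movable = ~st.frozen
        imass = 1.0 / sys_.top.masses
        pull_i = sys_.top.pulled_bead if self.pull_on else -1
        has_membrane = sys_.top.n_membrane > 0
        skin_half2 = (0.5 * self.nlist.skin) ** 2 if has_membrane else np.inf
        remaining = int(n_steps)
        out = np.zeros(2, dtype=np.int64)
        while remaining > 0:
            budget2 = (self.nlist.disp_budget ** 2
                       if sys_.kinetic else np.inf)
            seed = int(st.rng.integers(1, 2**31 - 1))
            done = _run_kernel(
                st.pos, st.vel, self._frc, sys_.top.masses, imass, movable,
                c1, c2, self.dt, remaining, st.step, seed,
                sys_.kinds, sys_.sig2, sys_.cut2, sys_.params.epsilon,
                self.nlist.pairs, sys_.bonds, sys_.bond_r2max, sys_.bond_k,
                sys_.teth_i, sys_.teth_anchor, sys_.teth_k,
                pull_i, sys_.params.pull_force, sys_.box[0], sys_.box[1],
                self.nlist.ref_pos, skin_half2, budget2, self.check_stride,
                sys_.n_polymer, terminate, sys_.top.pulled_bead,
                fail_r2, fail_needed, fail_counter,
                wait_half, wait_acc, cross_step,
                rim_idx, rim_off, reff_stride, reff_out, reff_n,
                out)
            st.step += done
            st.time += done * self.dt
            remaining -= done
            status = int(out[0])
            if status == _REBUILD:
                self.nlist.build(st.pos)
            elif status == _BUDGET:
                self.nlist.escalate(st.pos)
            elif status == _BONDBREAK:
                i, j = sys_.bonds[out[1]]
                raise BondBreakError(
                    f"bond ({i}, {j}) reached its FENE maximum at step {st.step}")
            elif status == _NONFINITE:
                raise NonFiniteError(f"non-finite coordinates at step {st.step}")
            elif status in (_TRANSLOCATED, _FAILED):
                return status
        return _DONE

    def step(self, n: int = 1) -> SimulationState:
        """Advance ``n`` plain Langevin steps."""
        if n < 0:
            raise ValueError("step count must be non-negative")
        if n:
            self._advance(n)
        return self.state

    def run(self, n_steps: int, observer=None, observer_stride: int = 1000
            ) -> SimulationState:
        """Advance ``n_steps``, calling ``observer(sim)`` every stride steps.

        Observer exceptions abort the run with context.
        """
        if n_steps < 0:
            raise ValueError("step count must be non-negative")
        left = int(n_steps)
        while left > 0:
            chunk = min(left, observer_stride if observer else left)
            self._advance(chunk)
            left -= chunk
            if observer is not None:
                try:
                    observer(self)
                except Exception as exc:
                    raise RuntimeError(
                        f"observer failed at step {self.state.step}") from exc
        return self.state
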