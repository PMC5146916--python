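"""The translocation experiment: pin, thermalize, pull, repeat over an ensemble.

One trajectory runs as in the underlying experiment: the chain is grown on
the cis side (z < 0) with its head P bead pinned at the pore center
(0, 0, 0), thermalized at T_p with the membrane restricting the
conformation space, and at t = 0 the head is released (with a thermal
velocity) while the constant pulling force along +z switches on.  The run
terminates when every polymer bead sits on the trans side (z > 0); the step
count at termination is the translocation time.  Trajectories in which the
chain abandons the pore and slides along the membrane are detected and
recorded as failures; exhausting the step budget records a timeout.  Both
are kept in the ensemble bookkeeping but excluded from the time statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PoreTransError
from .forcefield import ForceFieldParams, System
from .geometry import MembraneLattice, R_SMALL, build_membrane, build_polymer, \
    carve_pore, check_membrane_extent, combine
from .integrator import DEFAULT_DT, Simulation, ThermostatSpec

logger = logging.getLogger(__name__)

#: half-thickness of the pore slab used for per-bead waiting times; the
#: membrane is one bead thick and sigma_B is the largest bead diameter.
PORE_SLAB_HALF = 1.5

#: steric radius assigned to a rim bead when converting rim positions into an
#: effective pore clearance: half the membrane-polymer pair diameter a.
RIM_STERIC_RADIUS = 0.5


@dataclass(frozen=True)
class ProtocolConfig:
    """Complete declarative description of one translocation state point."""

    n: int = 16                       # repeat count; N = 3n + 1 beads
    force: float = 10.0               # dimensionless pulling force f
    pore_radius: float = R_SMALL
    tether_k: float = math.inf        # inf = immobile membrane
    T_m: float = 0.0
    T_p: float = 1.5
    friction: float = 1.0
    dt: float = DEFAULT_DT
    thermalization_steps: int = 200_000
    max_steps: int = 100_000_000
    check_stride: int = 10
    ensemble_size: int = 1000
    seed: int = 0
    membrane_cells: tuple | None = None   # default: sizing rule for n
    membrane_mass: float = 1.0
    fail_lateral: float = 4.0         # slide threshold, units of a
    fail_steps: int = 10_000          # how long the slide must persist
    record_waiting_times: bool = True
    record_reff: bool = False
    reff_stride: int = 100

    def __post_init__(self):
        if self.force <= 0:
            raise ValueError("pulling force must be positive")
        if self.ensemble_size < 1:
            raise ValueError("ensemble size must be at least 1")
        if self.max_steps <= self.thermalization_steps:
            raise ValueError("step budget must exceed the thermalization length")

    @property
    def kinetic(self) -> bool:
        return not math.isinf(self.tether_k)

    def thermostat(self) -> ThermostatSpec:
        return ThermostatSpec(T_polymer=self.T_p, T_membrane=self.T_m,
                              friction=self.friction)

    def forcefield(self) -> ForceFieldParams:
        return ForceFieldParams(pull_f=self.force, T_p=self.T_p)


@dataclass(eq=False)
class TranslocationRecord:
    """Outcome of one trajectory."""

    status: str                       # translocated | failed_slide | timeout
    seed: int
    steps: int | None = None          # translocation time in steps
    time: float | None = None         # and in LJ time units
    waiting_times: np.ndarray | None = None
    crossing_steps: np.ndarray | None = None   # first step each bead reached z > 0
    reff: np.ndarray | None = None    # effective-pore-radius series (kinetic)

    def __post_init__(self):
        if (self.status == "translocated") != (self.steps is not None):
            raise ValueError("translocation time present iff translocated")


@dataclass(eq=False)
class EnsembleResult:
    """All records of one state point plus the configuration that made them."""

    config: ProtocolConfig
    records: list

    @property
    def tally(self) -> dict:
        out = {"translocated": 0, "failed_slide": 0, "timeout": 0}
        for r in self.records:
            out[r.status] += 1
        return out

    @property
    def times(self) -> np.ndarray:
        """Translocation times (LJ units) of the successful records only."""
        return np.array([r.time for r in self.records
                         if r.status == "translocated"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"seed": [r.seed for r in self.records],
             "status": [r.status for r in self.records],
             "tau_steps": [-1 if r.steps is None else r.steps
                           for r in self.records],
             "tau_lj": [np.nan if r.time is None else r.time
                        for r in self.records]})


def trajectory_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Derived per-trajectory seed: SeedSequence(master) spawned at ``index``.

    Workers sharing only (master seed, index) reproduce identical streams, so
    ensemble results are independent of how trajectories are distributed.
    """
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def pore_membrane(config: ProtocolConfig) -> MembraneLattice:
    """Build and carve the membrane for a state point."""
    membrane = build_membrane(n=config.n, cells=config.membrane_cells)
    membrane = carve_pore(membrane, config.pore_radius)
    check_membrane_extent(membrane, config.n)
    return membrane


def initialize(config: ProtocolConfig,
               seed: int | np.random.SeedSequence | None = None,
               membrane: MembraneLattice | None = None) -> Simulation:
    """Build one trajectory: chain pinned at the pore center on the cis side.

    Membrane beads start on their anchors with Maxwell velocities at T_m
    (exactly zero when T_m = 0, or frozen in the immobile mode); the head
    bead is frozen at the origin and the pull is off.
    """
    if membrane is None:
        membrane = pore_membrane(config)
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    grow_seed = int(rng.integers(2**31))
    poly, pos = build_polymer(config.n, seed=grow_seed)
    top = combine(poly, membrane, tether_k=config.tether_k,
                  membrane_mass=config.membrane_mass)
    system = System(top, membrane, config.forcefield())
    sim = Simulation.create(system, pos, thermostat=config.thermostat(),
                            dt=config.dt, seed=rng,
                            check_stride=config.check_stride)
    sim.freeze_bead(top.pulled_bead)
    sim.pull_on = False
    return sim


def thermalize(sim: Simulation, duration: int) -> Simulation:
    """Equilibrate with the head pinned and the pull off; reset the clock."""
    if not sim.state.frozen[sim.system.top.pulled_bead]:
        raise PoreTransError("the pulled bead must be pinned during thermalization")
    sim.pull_on = False
    n = sim.system.top.n
    rouse_steps = (sim.thermostat.friction * (2 * n + 1) ** 2
                   / (3 * math.pi**2 * max(sim.thermostat.T_polymer, 1e-9))
                   / sim.dt)
    if 0 < duration < 2 * rouse_steps:
        logger.warning(
            "thermalization of %d steps is short against the chain relaxation "
            "(~%.0f steps); equilibration may be incomplete", duration, rouse_steps)
    if duration:
        sim.step(duration)
    sim.state.step = 0
    sim.state.time = 0.0
    return sim


def detect_failure(head_position, lateral_threshold: float = 4.0) -> bool:
    """Instantaneous slide condition: head off-axis beyond the threshold while
    still on the cis side.  The protocol requires the condition to persist for
    ``fail_steps`` before a trajectory is abandoned."""
    x, y, z = head_position
    if not np.isfinite(lateral_threshold):
        return False
    return bool(z < 0 and x * x + y * y > lateral_threshold**2)


def effective_pore_radius(positions: np.ndarray, membrane: MembraneLattice,
                          offset: int = 0,
                          steric_radius: float = RIM_STERIC_RADIUS) -> float:
    """Instantaneous pore clearance from the displaced rim beads.

    Minimum over the rim set (fixed at carve time: sites initially within one
    lattice spacing outside the pore) of planar distance from the pore axis
    minus the bead steric radius.  ``offset`` maps membrane site indices into
    rows of ``positions`` (the polymer bead count for a full system).
    """
    if membrane.rim is None or len(membrane.rim) == 0:
        raise PoreTransError("pore rim set is empty; carve a pore first")
    rim = positions[membrane.rim + offset]
    return float(np.min(np.hypot(rim[:, 0], rim[:, 1])) - steric_radius)


def run_translocation(sim: Simulation, config: ProtocolConfig,
                      seed: int = -1) -> TranslocationRecord:
    """Release the head, switch the pull on and run to completion or failure."""
    top = sim.system.top
    sim.release_bead(top.pulled_bead, thermal=True)
    sim.pull_on = True
    wait_half = PORE_SLAB_HALF if config.record_waiting_times else 0.0
    wait_acc = np.zeros(top.n_polymer) if config.record_waiting_times \
        else np.empty(0)
    fail_needed = 0
    if np.isfinite(config.fail_lateral):
        fail_needed = max(1, int(round(config.fail_steps / config.check_stride)))
    do_reff = (config.record_reff and sim.system.kinetic
               and sim.system.membrane.rim is not None)
    if do_reff:
        rim_idx = np.ascontiguousarray(sim.system.membrane.rim
                                       + top.n_polymer, dtype=np.int64)
        cap = config.max_steps // config.reff_stride + 2
        reff_out = np.empty(cap)
        reff_n = np.zeros(1, dtype=np.int64)
        reff_kw = dict(rim_idx=rim_idx, rim_off=RIM_STERIC_RADIUS,
                       reff_stride=config.reff_stride, reff_out=reff_out,
                       reff_n=reff_n)
    else:
        reff_kw = {}
    budget = config.max_steps - config.thermalization_steps
    cross = np.full(top.n_polymer, -1, dtype=np.int64)
    status = sim._advance(
        budget, terminate=True,
        fail_r2=config.fail_lateral**2 if fail_needed else 0.0,
        fail_needed=fail_needed, fail_counter=np.zeros(1, dtype=np.int64),
        wait_half=wait_half, wait_acc=wait_acc, cross_step=cross, **reff_kw)
    wt = wait_acc if config.record_waiting_times else None
    reff = reff_out[:int(reff_n[0])].copy() if do_reff else None
    if status == 2:
        return TranslocationRecord(
            status="translocated", seed=seed, steps=sim.state.step,
            time=sim.state.time, waiting_times=wt, crossing_steps=cross,
            reff=reff)
    name = "failed_slide" if status == 3 else "timeout"
    return TranslocationRecord(status=name, seed=seed,
                               waiting_times=wt, crossing_steps=cross,
                               reff=reff)


def run_trajectory(config: ProtocolConfig, index: int,
                   membrane: MembraneLattice | None = None
                   ) -> TranslocationRecord:
    """One full pin-thermalize-pull trajectory with its derived seed."""
    seq = trajectory_seed(config.seed, index)
    sim = initialize(config, seed=seq, membrane=membrane)
    thermalize(sim, config.thermalization_steps)
    return run_translocation(sim, config, seed=index)


def run_ensemble(config: ProtocolConfig,
                 membrane: MembraneLattice | None = None,
                 progress: bool = False) -> EnsembleResult:
    """N_t independent trajectories at one state point.

    Individual slide failures and timeouts are recorded, never fatal; only
    translocated records enter the time statistics downstream.
    """
    if membrane is None:
        membrane = pore_membrane(config)
    records = []
    for i in range(config.ensemble_size):
        records.append(run_trajectory(config, i, membrane=membrane))
        if progress:
            logger.info("trajectory %d/%d: %s", i + 1, config.ensemble_size,
                        records[-1].status)
    result = EnsembleResult(config=config, records=records)
    logger.info("ensemble f=%g k=%g T_m=%g: %s", config.force,
                config.tether_k, config.T_m, result.tally)
    return result
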