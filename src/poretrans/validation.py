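"""Desk-scale reproduction studies and the fast invariant suite.

These are the package's own scaled-down versions of the headline
measurements: the free-chain diffusion and gyration-radius scaling checks,
and the high-force translocation-time power law through the large pore with
the immobile membrane.  Problem sizes (ensemble sizes, trajectory lengths)
are chosen so each study completes in minutes on one core while keeping the
statistical error well inside the quoted acceptance bands; docs/methods.md
records the sizes.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import analysis, geometry, units
from .forcefield import ForceFieldParams, System, total_forces
from .geometry import R_LARGE, build_polymer
from .integrator import Simulation, ThermostatSpec
from .protocol import ProtocolConfig, run_ensemble, pore_membrane


def free_chain_simulation(n: int, seed, thermostat=ThermostatSpec(),
                          dt: float = 5.0e-3) -> Simulation:
    """A chain with no membrane, no pull and no pinned bead."""
    grow_rng = np.random.default_rng(seed)
    top, pos = build_polymer(n, seed=int(grow_rng.integers(2**31)))
    system = System(top, None, ForceFieldParams())
    return Simulation.create(system, pos, thermostat=thermostat, dt=dt,
                             seed=grow_rng)


# --- free-chain diffusion ----------------------------------------------------

def measure_diffusion(n: int, seed, replicates: int = 40,
                      steps: int = 30_000, sample_stride: int = 20) -> tuple:
    """Center-of-mass diffusion constant of the free chain: mean and SE over
    independent replicates.

    The COM of this chain is an exact Ornstein-Uhlenbeck particle with
    friction N xi (forces are internal), so no equilibration is needed.
    """
    seq = np.random.SeedSequence(entropy=seed, spawn_key=(n,))
    ds = []
    for rep, child in enumerate(seq.spawn(replicates)):
        sim = free_chain_simulation(n, child)
        masses = sim.system.top.masses
        com = []

        def grab(s):
            com.append(np.average(s.state.pos, axis=0, weights=masses))

        grab(sim)
        sim.run(steps, observer=grab, observer_stride=sample_stride)
        ds.append(analysis.diffusion_constant(
            np.array(com), dt=sample_stride * sim.dt, fit_window=(0.03, 0.12)))
    ds = np.array(ds)
    return float(ds.mean()), float(ds.std(ddof=1) / math.sqrt(len(ds)))


def diffusion_scaling_study(seed: int, n_values=(4, 8, 16),
                            replicates: int = 40, steps: int = 30_000) -> dict:
    """D(N) across chain lengths and the fitted scaling exponent."""
    rows = []
    for n in n_values:
        N = 3 * n + 1
        d, err = measure_diffusion(n, seed, replicates=replicates, steps=steps)
        rows.append({"n": n, "N": N, "D": d, "D_err": err})
    fit = analysis.diffusion_scaling([r["N"] for r in rows],
                                     [r["D"] for r in rows],
                                     [r["D_err"] for r in rows])
    return {"table": rows, "fit": fit}


# --- free-chain gyration radius ----------------------------------------------

def measure_gyration(n: int, seed, samples: int = 80) -> tuple:
    """Root-mean-square gyration radius over decorrelated free-chain
    conformations (the standard sqrt(<Rg^2>) estimator).

    The ideal-chain Rouse time underestimates the relaxation of this
    self-avoiding, side-chain-decorated chain, so the burn-in is ten Rouse
    times (the grown starting conformation is artificially elongated) and
    samples are spaced three Rouse times apart; the quoted error treats
    successive samples as weakly correlated.
    """
    sim = free_chain_simulation(n, np.random.SeedSequence(entropy=seed,
                                                          spawn_key=(n, 1)))
    N_back = 2 * n + 1
    rouse_steps = max(2000, int(N_back**2 / (3 * math.pi**2 * 1.5) / sim.dt))
    sim.step(10 * rouse_steps)
    masses = sim.system.top.masses
    rgs = []
    for _ in range(samples):
        sim.step(3 * rouse_steps)
        rgs.append(analysis.gyration_radius(sim.state.pos, masses))
    rgs = np.array(rgs)
    rms = math.sqrt(float(np.mean(rgs**2)))
    return rms, float(rgs.std(ddof=1) / math.sqrt(len(rgs) / 2))


def flory_study(seed: int, n_values=(4, 8, 16, 32), samples: int = 80) -> dict:
    """R_g(n) across chain lengths and the apparent Flory exponent.

    The n = 32 point costs most of the runtime but lengthens the lever arm
    of the fit and damps the small-n noise in the exponent.
    """
    rows = []
    for n in n_values:
        rg, err = measure_gyration(n, seed, samples=samples)
        rows.append({"n": n, "Rg": rg, "Rg_err": err})
    fit = analysis.flory_fit([r["n"] for r in rows], [r["Rg"] for r in rows],
                             [r["Rg_err"] for r in rows])
    return {"table": rows, "fit": fit}


# --- high-force translocation scaling ----------------------------------------

def force_scaling_study(seed: int, forces=(10.0, 20.0, 40.0),
                        n_traj: int = 30, n: int = 16,
                        pore_radius: float = R_LARGE,
                        thermalization_steps: int = 30_000,
                        pull_step_budget: int = 2_000_000) -> dict:
    """tau(f) through the large pore with the immobile membrane, and gamma.

    Runs ``n_traj`` seeded translocations of the N = 3n+1 chain at each
    force and fits log tau against log f by weighted least squares.
    """
    rows, ensembles = [], []
    base = ProtocolConfig(
        n=n, pore_radius=pore_radius, tether_k=math.inf,
        thermalization_steps=thermalization_steps,
        max_steps=thermalization_steps + pull_step_budget,
        ensemble_size=n_traj, record_waiting_times=False)
    membrane = pore_membrane(base)
    for i, f in enumerate(forces):
        cfg = dataclasses.replace(base, force=float(f),
                                  seed=int(seed) + 1000 * i)
        ens = run_ensemble(cfg, membrane=membrane)
        tau, err = analysis.mean_translocation_time(ens)
        rows.append({"f": float(f), "tau": tau, "tau_err": err,
                     "n_success": int(ens.tally["translocated"])})
        ensembles.append(ens)
    fit = analysis.fit_power_law([r["f"] for r in rows],
                                 [r["tau"] for r in rows],
                                 [r["tau_err"] for r in rows])
    return {"table": rows, "fit": fit, "ensembles": ensembles}


# --- fast invariant suite (cli validate) --------------------------------------

def _random_small_system(rng) -> tuple:
    """A randomized <=30-bead polymer+membrane fragment for force oracles."""
    n = int(rng.integers(1, 4))
    top, pos = build_polymer(n, seed=int(rng.integers(2**31)))
    mem = geometry.honeycomb_lattice(3, 2)
    mem = geometry.carve_pore(mem, 0.4)
    full = geometry.combine(top, mem, tether_k=float(rng.uniform(75, 500)))
    system = System(full, mem, ForceFieldParams(pull_f=float(rng.uniform(1, 10))))
    allpos = system.initial_positions(pos)
    allpos += rng.normal(scale=0.04, size=allpos.shape)
    return system, allpos


def quick_validate(seed: int = 0) -> dict:
    """Fast geometry, unit and force checks; all should pass in seconds."""
    checks = {}
    mem = geometry.build_membrane(n=16)
    checks["membrane_sites_5488"] = mem.n_sites == 5488
    checks["pore_small_removes_24"] = geometry.carve_pore(mem, 1.25).n_removed == 24
    checks["pore_large_removes_54"] = geometry.carve_pore(mem, 1.75).n_removed == 54
    checks["force_unit_9.1_pN"] = abs(units.lj_to_si(1.0, "force") * 1e12 - 9.1) < 0.05
    checks["time_unit_2.3_ps"] = abs(units.lj_to_si(1.0, "time") * 1e12 - 2.3) < 0.05
    rng = np.random.default_rng(seed)
    ok = True
    for _ in range(20):
        system, pos = _random_small_system(rng)
        from .forcefield import NeighborList
        nl = NeighborList(system, skin=0.75)
        f_nl, u_nl = total_forces(pos, system, pairs=nl.build(pos), pull_on=True)
        f_bf, u_bf = total_forces(pos, system, pairs=None, pull_on=True)
        scale = max(1.0, float(np.abs(f_bf).max()))
        if np.abs(f_nl - f_bf).max() / scale > 1e-10 or \
                abs(u_nl - u_bf) / max(1.0, abs(u_bf)) > 1e-10:
            ok = False
            break
    checks["neighbor_list_matches_brute_force"] = ok
    checks["all_passed"] = all(checks.values())
    return checks
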