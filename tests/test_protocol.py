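import dataclasses
import math

import numpy as np
import pytest

from poretrans import geometry
from poretrans.analysis import crossing_intervals, mean_translocation_time
from poretrans.errors import NoSuccessfulTranslocations, PoreTransError
from poretrans.protocol import (ProtocolConfig, TranslocationRecord,
                                detect_failure, effective_pore_radius,
                                initialize, pore_membrane, run_ensemble,
                                run_translocation, thermalize,
                                trajectory_seed)

# one fast, fully-translocating state point used across this module:
# n = 6 chain through the large pore with the immobile membrane
FAST = ProtocolConfig(n=6, force=40.0, pore_radius=1.75,
                      thermalization_steps=5000, max_steps=505_000,
                      ensemble_size=3, seed=77)


@pytest.fixture(scope="module")
def fast_membrane():
    return pore_membrane(FAST)


def test_initialize_contracts(fast_membrane):
    sim = initialize(FAST, membrane=fast_membrane)
    top = sim.system.top
    # head pinned exactly at the pore center
    assert (sim.state.pos[0] == 0.0).all()
    assert sim.state.frozen[0]
    # remaining polymer strictly cis-side
    assert (sim.state.pos[1:top.n_polymer, 2] < 0).all()
    # immobile membrane: frozen on the anchors with zero velocity
    assert sim.state.frozen[top.n_polymer:].all()
    assert (sim.state.vel[top.n_polymer:] == 0.0).all()


def test_kinetic_membrane_velocities_zero_at_cold_start(fast_membrane):
    cfg = dataclasses.replace(FAST, tether_k=300.0, T_m=0.0)
    sim = initialize(cfg, membrane=fast_membrane)
    npol = sim.system.top.n_polymer
    assert not sim.state.frozen[npol:].any()
    assert (sim.state.vel[npol:] == 0.0).all()
    cfg_hot = dataclasses.replace(FAST, tether_k=300.0, T_m=1.5)
    hot = initialize(cfg_hot, membrane=fast_membrane)
    assert hot.state.vel[npol:].std() > 0


def test_thermalize_resets_clock_and_equilibrates(fast_membrane):
    sim = initialize(FAST, membrane=fast_membrane)
    p0 = sim.state.pos.copy()
    thermalize(sim, 0)
    assert sim.state.step == 0 and (sim.state.pos == p0).all()
    thermalize(sim, 6000)
    assert sim.state.step == 0 and sim.state.time == 0.0
    npol = sim.system.top.n_polymer
    # polymer kinetic energy per dof near T_p/2 (head frozen: exclude)
    v = sim.state.vel[1:npol]
    ke_dof = 0.5 * np.mean(v * v)
    assert abs(ke_dof - 0.75) < 0.25
    # the chain points into the cis half-space
    assert sim.state.pos[1:npol, 2].mean() < 0


def test_thermalize_requires_pinned_head(fast_membrane):
    sim = initialize(FAST, membrane=fast_membrane)
    sim.release_bead(0)
    with pytest.raises(PoreTransError, match="pinned"):
        thermalize(sim, 10)


def test_detect_failure_conditions():
    assert not detect_failure((0.0, 0.0, 1.0))
    assert detect_failure((10.0, 0.0, -0.5))
    assert not detect_failure((10.0, 0.0, -0.5), lateral_threshold=math.inf)
    assert not detect_failure((1.0, 1.0, -0.5))   # within threshold


def test_record_invariant():
    with pytest.raises(ValueError):
        TranslocationRecord(status="translocated", seed=0, steps=None)
    with pytest.raises(ValueError):
        TranslocationRecord(status="timeout", seed=0, steps=100)


def test_single_bead_drift_oracle():
    """A lone released bead under strong pull crosses in the drift time z/(F/xi)."""
    cfg = ProtocolConfig(n=0, force=60.0, pore_radius=1.75,
                         membrane_cells=(10, 6), thermalization_steps=0,
                         max_steps=100_000, ensemble_size=1, seed=5,
                         check_stride=1, record_waiting_times=False)
    mem = pore_membrane(cfg)
    sim = initialize(cfg, seed=trajectory_seed(5, 0), membrane=mem)
    thermalize(sim, 0)
    start = 2.0
    sim.state.pos[0] = (0.0, 0.0, -start)
    rec = run_translocation(sim, cfg, seed=0)
    assert rec.status == "translocated"
    # deterministic crossing time of m dv = F - xi v from rest:
    # z(t) = (F/xi) (t - (m/xi)(1 - exp(-xi t / m)))
    from scipy.optimize import brentq
    F = cfg.force * 1.5
    t_det = brentq(lambda t: F * (t - (1 - math.exp(-t))) - start, 1e-6, 10.0)
    assert 0.5 * t_det < rec.time < 2.0 * t_det


def test_translocation_completes_with_all_beads_trans(fast_membrane):
    sim = initialize(FAST, seed=trajectory_seed(77, 0), membrane=fast_membrane)
    thermalize(sim, FAST.thermalization_steps)
    rec = run_translocation(sim, FAST, seed=0)
    npol = sim.system.top.n_polymer
    assert rec.status == "translocated"
    assert (sim.state.pos[:npol, 2] > 0).all()        # monotone completion
    assert rec.steps == sim.state.step
    assert rec.time == pytest.approx(rec.steps * FAST.dt)
    # every bead crossed, in a causally ordered record
    assert (rec.crossing_steps >= 0).all()
    assert rec.crossing_steps.max() <= rec.steps
    # waiting times: non-negative, each below the total run time
    assert (rec.waiting_times >= 0).all()
    assert (rec.waiting_times <= rec.time + 1e-9).all()


def test_ensemble_reproducible_and_tallied(fast_membrane):
    a = run_ensemble(FAST, membrane=fast_membrane)
    b = run_ensemble(FAST, membrane=fast_membrane)
    assert [r.steps for r in a.records] == [r.steps for r in b.records]
    assert [r.status for r in a.records] == [r.status for r in b.records]
    assert sum(a.tally.values()) == FAST.ensemble_size
    assert len(a.times) == a.tally["translocated"]
    df = a.to_frame()
    assert list(df.columns) == ["seed", "status", "tau_steps", "tau_lj"]
    assert len(df) == FAST.ensemble_size


def test_all_timeout_ensemble_flags_undefined(fast_membrane):
    cfg = dataclasses.replace(FAST, force=0.5, thermalization_steps=10,
                              max_steps=200, ensemble_size=2,
                              fail_lateral=math.inf)
    ens = run_ensemble(cfg, membrane=fast_membrane)
    assert ens.tally["timeout"] == 2
    with pytest.raises(NoSuccessfulTranslocations):
        mean_translocation_time(ens)


def test_mean_tau_decreases_with_force(fast_membrane):
    taus = {}
    for f in (20.0, 60.0):
        cfg = dataclasses.replace(FAST, force=f, ensemble_size=4)
        taus[f] = mean_translocation_time(
            run_ensemble(cfg, membrane=fast_membrane))[0]
    assert taus[20.0] > taus[60.0]


def test_base_beads_cause_the_stalls():
    """Through the tight pore the grafted B beads wait longest: passage
    intervals attributed to B beads exceed the backbone ones."""
    cfg = ProtocolConfig(n=6, force=40.0, pore_radius=1.25,
                         thermalization_steps=5000, max_steps=2_005_000,
                         ensemble_size=4, seed=3)
    mem = pore_membrane(cfg)
    ens = run_ensemble(cfg, membrane=mem)
    kinds = geometry._polymer_kinds(cfg.n)
    b_iv, bb_iv = [], []
    for rec in ens.records:
        if rec.status != "translocated":
            continue
        who, iv = crossing_intervals(rec.crossing_steps)
        sel = kinds[who] == geometry.B
        b_iv.extend(iv[sel])
        bb_iv.extend(iv[~sel])
    assert np.mean(b_iv) > np.mean(bb_iv)


def test_effective_pore_radius_geometry(small_pore_membrane):
    mem = small_pore_membrane
    static = effective_pore_radius(mem.anchors, mem)
    rim_r = np.hypot(mem.xy[mem.rim, 0], mem.xy[mem.rim, 1])
    assert static == pytest.approx(rim_r.min() - 0.5)
    # displacing every rim bead radially outward by d raises R_eff by exactly d
    d = 0.3
    pos = mem.anchors.copy()
    unit = mem.xy[mem.rim] / rim_r[:, None]
    pos[mem.rim, :2] += d * unit
    assert effective_pore_radius(pos, mem) == pytest.approx(static + d)
    # an uncarved sheet has no rim
    with pytest.raises(PoreTransError, match="rim"):
        effective_pore_radius(mem.anchors, geometry.build_membrane(cells=(3, 2)))


def test_effective_pore_radius_fluctuates_under_translocation():
    cfg = ProtocolConfig(n=6, force=40.0, pore_radius=1.25, tether_k=75.0,
                         thermalization_steps=5000, max_steps=2_005_000,
                         ensemble_size=1, seed=3, record_reff=True,
                         reff_stride=50)
    mem = pore_membrane(cfg)
    sim = initialize(cfg, seed=trajectory_seed(3, 0), membrane=mem)
    thermalize(sim, cfg.thermalization_steps)
    rec = run_translocation(sim, cfg, seed=0)
    assert rec.status == "translocated"
    static = effective_pore_radius(mem.anchors, mem)
    # the soft pore deforms measurably while the chain squeezes through; the
    # incoherent displacements narrow the clearance on average
    assert rec.reff.std() > 0.01
    assert rec.reff.mean() < static
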