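"""Simulation backend: point models, cable solver, synapses, events."""

import copy
import math

import numpy as np
import pytest

import netsim
from netsim.build import build_network
from netsim.diagnostics import SimulationError
from netsim.engine import (Engine, replay_single_cell, spikes_by_gid,
                           step_izhikevich, step_lif)
from netsim.specs import canonical_json

from conftest import hh_soma_spec, minimal_spec, soma_dend_spec, \
    two_pop_spec

RS = {"a": 0.02, "b": 0.2, "c": -65.0, "d": 8.0}


# --- Izhikevich point model ------------------------------------------

def test_izhikevich_rest_is_stable():
    # the RS parameter set has its stable fixed point at v = -70 mV
    # (0.04 v^2 + 5 v + 140 - b v = 0); no input, no spikes
    state = {"v": -65.0, "u": 0.2 * -65.0}
    spikes = sum(step_izhikevich(state, 0.0, 0.1, RS)
                 for _ in range(10000))
    assert spikes == 0
    assert state["v"] == pytest.approx(-70.0, abs=0.1)


def test_izhikevich_tonic_firing_rate_band():
    state = {"v": -65.0, "u": 0.2 * -65.0}
    spikes = sum(step_izhikevich(state, 10.0, 0.1, RS)
                 for _ in range(10000))
    assert 10 <= spikes <= 80  # regular-spiking band over 1 s


def test_izhikevich_threshold_boundary_resets_this_step():
    state = {"v": 30.0, "u": 0.0}
    assert step_izhikevich(state, 0.0, 0.1, RS) is True
    assert state["v"] == RS["c"]
    assert state["u"] == RS["d"]


def test_lif_fires_and_resets():
    params = {"tau_m": 10.0, "v_rest": -65.0, "v_reset": -65.0,
              "v_thresh": -50.0, "r_m": 10.0, "t_ref": 2.0}
    state = {"v": -65.0}
    spikes = sum(step_lif(state, 2.0, 0.1, params) for _ in range(10000))
    # analytic steady state -65 + 20 = -45 > threshold, so it must fire
    assert spikes > 10
    assert state["v"] <= params["v_thresh"]


def test_lif_subthreshold_matches_exponential_relaxation():
    params = {"tau_m": 10.0, "v_rest": -65.0, "v_reset": -65.0,
              "v_thresh": 0.0, "r_m": 10.0, "t_ref": 0.0}
    state = {"v": -65.0}
    dt = 0.001
    for _ in range(int(20.0 / dt)):
        step_lif(state, 1.0, dt, params)
    # v_inf = -65 + 10 = -55; after 2 tau: within e^-2
    expected = -55.0 - 10.0 * math.exp(-2.0)
    assert state["v"] == pytest.approx(expected, abs=0.01)


# --- compartmental solver --------------------------------------------

def test_passive_equilibrium_is_preserved():
    spec = soma_dend_spec()
    spec["simConfig"]["duration"] = 10.0
    net = build_network(spec)
    eng = Engine(net)
    out = eng.run()
    v = np.array(out["traces"]["V"]["0"])
    assert np.max(np.abs(v + 65.0)) < 1e-9


def test_cable_steady_state_matches_cosh_profile():
    """Sealed-end passive cable, current injected at x=0: the voltage
    profile matches cosh((L-x)/lambda)/cosh(L/lambda) within 2%."""
    lam, L, nseg = 500.0, 1000.0, 41
    spec = {
        "netParams": {
            "popParams": {"P": {"cellType": "C", "numCells": 1,
                                "cellModel": "compartmental"}},
            "cellParams": {"r": {"conds": {}, "secs": {
                "soma": {"geom": {"L": L, "diam": 1.0, "Ra": 100.0,
                                  "cm": 0.01, "nseg": nseg},
                         # g = d/(4 Ra lambda^2) = 1e-4 S/cm^2
                         "mechs": {"pas": {"g": 1e-4, "e": -65.0}}}}}},
            "stimSourceParams": {"ic": {"type": "IClamp", "del": 0.0,
                                        "dur": 1e9, "amp": 0.05}},
            "stimTargetParams": {"t": {"source": "ic", "conds": {},
                                       "sec": "soma", "loc": 0.0}},
        },
        "simConfig": {"duration": 50.0, "dt": 0.05, "recordStep": 1.0},
    }
    net = build_network(spec)
    eng = Engine(net)
    eng.run()
    v = eng.forest.v + 65.0
    x = (np.arange(nseg) + 0.5) / nseg * L
    pred = np.cosh((L - x) / lam) / np.cosh(L / lam)
    ratio = v / v[0]
    assert np.max(np.abs(ratio - pred / pred[0])
                  / (pred / pred[0])) < 0.02


def test_hh_soma_fires_repetitively_with_tall_spikes():
    out = netsim.run(build_network(hh_soma_spec(amp=0.1,
                                                duration=200.0)))
    v = np.array(out["traces"]["V"]["0"])
    assert len(out["spkt"]) >= 5
    assert v.max() > 20.0
    isi = np.diff(out["spkt"])
    assert np.std(isi[1:]) < 0.5  # settled into tonic firing


def test_hh_matches_independent_ode_integration():
    """Cross-check against an independently written hh ODE solved by
    scipy's adaptive integrator: same spike count, peaks aligned."""
    from scipy.integrate import solve_ivp

    area_cm2 = math.pi * 18.8 * 18.8 * 1e-8
    c_nf = 1.0 * area_cm2 * 1e3
    gna, gk, gl = (0.12 * area_cm2 * 1e6, 0.036 * area_cm2 * 1e6,
                   0.0003 * area_cm2 * 1e6)

    def rates(v):
        am = 0.1 * (v + 40) / -math.expm1(-(v + 40) / 10.0)
        bm = 4.0 * math.exp(-(v + 65) / 18.0)
        ah = 0.07 * math.exp(-(v + 65) / 20.0)
        bh = 1.0 / (1.0 + math.exp(-(v + 35) / 10.0))
        an = 0.01 * (v + 55) / -math.expm1(-(v + 55) / 10.0)
        bn = 0.125 * math.exp(-(v + 65) / 80.0)
        return am, bm, ah, bh, an, bn

    def f(t, y):
        v, m, h, n = y
        am, bm, ah, bh, an, bn = rates(v)
        i_ion = (gna * m ** 3 * h * (v - 50.0)
                 + gk * n ** 4 * (v + 77.0) + gl * (v + 54.3))
        i_stim = 0.1 if 20.0 <= t <= 220.0 else 0.0
        return [(-i_ion + i_stim) / c_nf,
                am * (1 - m) - bm * m,
                ah * (1 - h) - bh * h,
                an * (1 - n) - bn * n]

    am, bm, ah, bh, an, bn = rates(-65.0)
    y0 = [-65.0, am / (am + bm), ah / (ah + bh), an / (an + bn)]
    sol = solve_ivp(f, (0.0, 230.0), y0, max_step=0.05, rtol=1e-8,
                    atol=1e-8, dense_output=False)
    v_ref = sol.y[0]
    up = np.nonzero((v_ref[1:] >= 0.0) & (v_ref[:-1] < 0.0))[0]
    ref_times = sol.t[up]
    ref_times = ref_times[np.concatenate(
        [[True], np.diff(ref_times) > 2.0])]

    spec = hh_soma_spec(amp=0.1, duration=200.0, dt=0.005)
    spec["simConfig"]["duration"] = 230.0
    out = netsim.run(build_network(spec))
    assert len(out["spkt"]) == len(ref_times)
    assert np.max(np.abs(np.array(out["spkt"]) - ref_times)) < 1.0


def test_dt_refinement_converges():
    """Halving dt moves hh spike times by < 0.2 ms."""
    spec = hh_soma_spec(amp=0.1, duration=150.0, dt=0.005)
    a = netsim.run(build_network(spec))["spkt"]
    spec["simConfig"]["dt"] = 0.0025
    b = netsim.run(build_network(spec))["spkt"]
    assert len(a) == len(b)
    assert np.max(np.abs(np.array(a) - np.array(b))) < 0.2


# --- synapses and events ---------------------------------------------

def _chain_spec(weight_ab=0.5, delay_ab=5.0):
    spec = two_pop_spec(1, 1, {"connFunc": "fullConn",
                               "weight": weight_ab,
                               "delay": delay_ab})
    spec["netParams"]["stimSourceParams"] = {
        "ns": {"type": "NetStim", "rate": 20.0, "noise": 0.0,
               "start": 10.0, "number": 10 ** 9}}
    spec["netParams"]["stimTargetParams"] = {
        "t": {"source": "ns", "conds": {"pop": "A"}, "synMech": "exc",
              "weight": 0.8, "delay": 1.0}}
    spec["simConfig"]["duration"] = 300.0
    spec["simConfig"]["recordTraces"] = {"V": {"conds": {}, "var": "v"}}
    return spec


def test_two_cell_chain_causality():
    out = netsim.run(build_network(_chain_spec(delay_ab=5.0)))
    spikes = spikes_by_gid(out)
    assert spikes.get(0) and spikes.get(1)
    assert spikes[1][0] >= spikes[0][0] + 5.0


def test_zero_weight_event_is_null():
    base = netsim.run(build_network(_chain_spec(weight_ab=0.0)))
    silent = copy.deepcopy(_chain_spec(weight_ab=0.0))
    del silent["netParams"]["connParams"]["c"]
    alone = netsim.run(build_network(silent))
    assert base["traces"]["V"]["1"] == alone["traces"]["V"]["1"]


def test_exp_synapse_analytic_decay():
    """After its last event the exp conductance decays exactly as
    w·exp(-Δt/tau) per step."""
    spec = _chain_spec()
    spec["netParams"]["stimSourceParams"]["ns"].update(number=1,
                                                       start=10.0)
    del spec["netParams"]["connParams"]["c"]
    spec["simConfig"]["duration"] = 110.0
    net = build_network(spec)
    eng = Engine(net)
    eng.run()
    dt = 0.1
    # one event, weight 0.8, delivered at start+delay = 11 ms
    steps_since = int(round((110.0 - 11.0) / dt))
    expected = 0.8 * math.exp(-steps_since * dt / 5.0)
    assert eng.syn_g[0] == pytest.approx(expected, rel=1e-10)


def test_simultaneous_events_superpose_linearly():
    """Two simultaneous events of weight w equal one event of 2w."""
    spec = two_pop_spec(2, 1, {"connFunc": "fullConn",
                               "weight": 0.001, "delay": 1.0})
    spec["netParams"]["popParams"]["B"]["cellModel"] = "compartmental"
    spec["netParams"]["popParams"]["B"]["cellType"] = "C"
    spec["netParams"]["cellParams"] = {
        "pt": {"conds": {"cellType": "RS"}, "pointParams": {}},
        "comp": {"conds": {"cellType": "C"}, "secs": {
            "soma": {"geom": {"L": 20.0, "diam": 20.0, "Ra": 120.0,
                              "cm": 1.0, "nseg": 1},
                     "mechs": {"pas": {"g": 0.0002, "e": -65.0}}}}},
    }
    spec["netParams"]["stimSourceParams"] = {
        "ic": {"type": "IClamp", "del": 5.0, "dur": 1.0, "amp": 10.0}}
    spec["netParams"]["stimTargetParams"] = {
        "t": {"source": "ic", "conds": {"pop": "A"}}}
    spec["simConfig"]["duration"] = 100.0
    spec["simConfig"]["recordTraces"] = {"V": {"conds": {"pop": "B"},
                                               "var": "v"}}
    out2 = netsim.run(build_network(spec))
    spec["netParams"]["popParams"]["A"]["numCells"] = 1
    spec["netParams"]["connParams"]["c"]["weight"] = 0.002
    out1 = netsim.run(build_network(spec))
    v2 = np.array(out2["traces"]["V"]["2"])
    v1 = np.array(out1["traces"]["V"]["1"])
    assert np.max(np.abs(v2 - v1)) < 1e-9


def test_silent_network_stays_flat():
    spec = minimal_spec()
    # LIF cells initialized at v_rest are exactly at equilibrium
    spec["netParams"]["popParams"]["P"]["cellModel"] = "lif"
    spec["simConfig"]["recordTraces"] = {"V": {"conds": {}, "var": "v"}}
    out = netsim.run(build_network(spec))
    assert out["spkt"] == []
    for trace in out["traces"]["V"].values():
        assert np.ptp(trace) == 0.0


def test_same_spec_runs_identically():
    spec = _chain_spec()
    a = netsim.run(build_network(spec))
    b = netsim.run(build_network(spec))
    assert canonical_json(a) == canonical_json(b)


def test_nonfinite_state_aborts_with_context():
    # corrupt one compartment's state; the solver guard must abort
    # with the gid and time of the failure instead of propagating NaNs
    net = build_network(soma_dend_spec())
    eng = Engine(net)
    eng.forest.v[0] = float("nan")
    with pytest.raises(SimulationError) as exc:
        eng.run()
    assert "gid" in str(exc.value) and "t=" in str(exc.value)


# --- charge bookkeeping ----------------------------------------------

def _driven_comp_spec():
    spec = soma_dend_spec(n_cells=2, mechs={"pas": {"g": 0.0002,
                                                    "e": -65.0}})
    spec["netParams"]["cellParams"]["r"]["secs"]["soma"]["mechs"] = {
        "hh": {}}
    spec["netParams"]["synMechParams"] = {
        "exc": {"mode": "exp2", "tau1": 0.5, "tau2": 5.0, "e": 0.0}}
    spec["netParams"]["connParams"] = {
        "c": {"preConds": {}, "postConds": {}, "connFunc": "probConn",
              "probability": 1.0, "synMech": "exc", "weight": 0.01,
              "delay": 2.0, "sec": "dend", "loc": 0.5}}
    spec["netParams"]["stimSourceParams"] = {
        "ns": {"type": "NetStim", "rate": 50.0, "noise": 1.0,
               "start": 0.0, "number": 10 ** 9}}
    spec["netParams"]["stimTargetParams"] = {
        "t": {"source": "ns", "conds": {}, "sec": "dend", "loc": 0.3,
              "synMech": "exc", "weight": 0.01, "delay": 1.0}}
    spec["simConfig"].update(duration=100.0, recordLFP=[[50, 50, 50]])
    return spec


def test_membrane_currents_sum_to_zero_without_injection():
    net = build_network(_driven_comp_spec())
    eng = Engine(net)
    eng.run()
    gids = np.array(eng.forest.gid)
    for g in (0, 1):
        total = eng._imem[gids == g, :].sum(axis=0)
        assert np.abs(total).max() < 1e-9


def test_membrane_currents_sum_to_injected_current():
    spec = _driven_comp_spec()
    spec["netParams"]["stimSourceParams"]["ic"] = {
        "type": "IClamp", "del": 10.0, "dur": 50.0, "amp": 0.2}
    spec["netParams"]["stimTargetParams"]["ti"] = {
        "source": "ic", "conds": {"gid": [0]}, "sec": "soma",
        "loc": 0.5}
    net = build_network(spec)
    eng = Engine(net)
    out = eng.run()
    gids = np.array(eng.forest.gid)
    total = eng._imem[gids == 0, :].sum(axis=0)
    t = np.array(out["t"])
    window = (t > 10.5) & (t < 59.5)
    assert np.allclose(total[window], 0.2, atol=1e-9)


# --- single-cell replay ----------------------------------------------

def test_replay_reproduces_full_network_trace():
    spec = _driven_comp_spec()
    net = build_network(spec)
    out = netsim.run(net)
    rep = replay_single_cell(out, build_network(spec), 1)
    v_full = np.array(out["traces"]["V"]["1"])
    v_rep = np.array(rep["traces"]["V"]["1"])
    assert np.max(np.abs(v_full - v_rep)) <= 1e-6


def test_replay_with_silent_presyn_rests():
    spec = soma_dend_spec()
    spec["netParams"]["synMechParams"] = {
        "exc": {"mode": "exp", "tau": 5.0, "e": 0.0}}
    net = build_network(spec)
    rep = replay_single_cell({0: []}, net, 0)
    assert rep["spkt"] == []
    v = np.array(rep["traces"]["V"]["0"])
    assert np.max(np.abs(v + 65.0)) < 1e-9


def test_replay_is_sensitive_to_afferent_spikes():
    spec = _driven_comp_spec()
    net = build_network(spec)
    out = netsim.run(net)
    by_gid = spikes_by_gid(out)
    by_gid.setdefault(0, [])
    by_gid[0] = []  # silence the recurrent afferent
    rep = replay_single_cell(by_gid, build_network(spec), 1)
    v_full = np.array(out["traces"]["V"]["1"])
    v_rep = np.array(rep["traces"]["V"]["1"])
    assert np.max(np.abs(v_full - v_rep)) > 1e-3


def test_replay_missing_presyn_is_diagnosed():
    spec = _driven_comp_spec()
    net = build_network(spec)
    with pytest.raises(netsim.BuildError) as exc:
        replay_single_cell({1: [5.0]}, net, 1)  # gid 0 missing
    assert "missing" in str(exc.value)
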