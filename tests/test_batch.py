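"""Parameter exploration: grid search and evolutionary optimization."""

import itertools

import numpy as np
import pytest

import netsim
from netsim.batch import (eval_fitness, run_evol, run_grid, set_by_path,
                          summarize_output, emit_queue_script)
from netsim.diagnostics import BuildError

from conftest import two_pop_spec


def _fast_spec():
    spec = two_pop_spec(2, 2, {"connFunc": "fullConn", "weight": 0.2,
                               "delay": 1.0})
    spec["netParams"]["stimSourceParams"] = {
        "ns": {"type": "NetStim", "rate": 50.0, "noise": 1.0,
               "start": 0.0, "number": 10 ** 9}}
    spec["netParams"]["stimTargetParams"] = {
        "t": {"source": "ns", "conds": {}, "synMech": "exc",
              "weight": 0.3, "delay": 1.0}}
    spec["simConfig"]["duration"] = 200.0
    return spec


# --- fitness ---------------------------------------------------------

def test_fitness_zero_at_target():
    assert eval_fitness({"rate_E": 20.0},
                        {"targetRate": {"E": 20.0}}) == 0.0


def test_fitness_absolute_difference():
    assert eval_fitness({"rate_E": 15.0},
                        {"targetRate": {"E": 20.0}}) == 5.0


def test_fitness_sums_over_populations():
    assert eval_fitness({"rate_E": 18.0, "rate_I": 7.0},
                        {"targetRate": {"E": 20.0, "I": 10.0}}) == 5.0


def test_fitness_expression_over_summary():
    assert eval_fitness({"rate_E": 10.0, "rate_I": 5.0},
                        {"expr": "abs(rate_E - 2*rate_I)"}) == 0.0


def test_fitness_missing_field_raises():
    with pytest.raises(KeyError):
        eval_fitness({}, {"targetRate": {"E": 20.0}})


def test_set_by_path_nested():
    doc = {"a": {"b": {"c": 1}}}
    set_by_path(doc, "a.b.c", 5)
    assert doc["a"]["b"]["c"] == 5
    set_by_path(doc, "a.x.y", 2)
    assert doc["a"]["x"]["y"] == 2


# --- grid search -----------------------------------------------------

def test_grid_enumerates_full_cartesian_product():
    batch = {"params": [
        {"path": "netParams.connParams.c.weight",
         "values": [0.1, 0.2, 0.3]},
        {"path": "simConfig.duration", "values": [100.0, 150.0, 200.0,
                                                  250.0]}]}
    res = run_grid(_fast_spec(), batch)
    assert res["nTrials"] == 12
    got = [(t["params"]["netParams.connParams.c.weight"],
            t["params"]["simConfig.duration"]) for t in res["trials"]]
    expected = list(itertools.product([0.1, 0.2, 0.3],
                                      [100.0, 150.0, 200.0, 250.0]))
    assert got == expected  # odometer order over declaration order


def test_single_value_grid_equals_plain_run():
    spec = _fast_spec()
    batch = {"params": [{"path": "netParams.connParams.c.weight",
                         "values": [0.2]}],
             "fitness": {"targetRate": {"B": 10.0}}}
    res = run_grid(spec, batch)
    assert res["nTrials"] == 1
    direct = netsim.run(netsim.build_network(spec))
    assert res["trials"][0]["summary"] == summarize_output(direct)


def test_grid_parallel_worker_invariance():
    batch = {"params": [{"path": "netParams.connParams.c.weight",
                         "values": [0.1, 0.2, 0.3, 0.4]}],
             "fitness": {"targetRate": {"B": 10.0}}}
    seq = run_grid(_fast_spec(), dict(batch, run={"workers": 1}))
    par = run_grid(_fast_spec(), dict(batch, run={"workers": 4}))
    for a, b in zip(seq["trials"], par["trials"]):
        assert a["params"] == b["params"]
        assert a["summary"] == b["summary"]
        assert a["fitness"] == b["fitness"]


def test_failed_trial_recorded_batch_continues():
    batch = {"params": [{"path": "simConfig.duration",
                         "values": [-50.0, 100.0]}],
             "fitness": {"targetRate": {"B": 10.0}}}
    res = run_grid(_fast_spec(), batch)
    assert res["nTrials"] == 2
    assert res["trials"][0]["failed"] is True
    assert "error" in res["trials"][0]
    assert res["trials"][1]["failed"] is False


def test_empty_grid_is_diagnosed():
    with pytest.raises(BuildError):
        run_grid(_fast_spec(), {"params": [{"path": "x", "values": []}]})


def test_grid_results_saved(tmp_path):
    out = tmp_path / "batch"
    batch = {"params": [{"path": "netParams.connParams.c.weight",
                         "values": [0.1, 0.2]}],
             "fitness": {"targetRate": {"B": 10.0}},
             "run": {"outDir": str(out)}}
    run_grid(_fast_spec(), batch)
    assert (out / "batch_results.csv").exists()
    assert (out / "batch_summary.json").exists()
    assert len(list(out.glob("trial_*.json"))) == 2


# --- evolutionary search ---------------------------------------------

def _sphere_batch(seed, generations=30):
    return {
        "params": [{"path": f"simConfig.s{i}", "bounds": [0.0, 1.0]}
                   for i in range(3)],
        "fitness": {"paramExpr":
                    "(p0-0.3)^2 + (p1-0.3)^2 + (p2-0.3)^2",
                    "simulate": False},
        "evolConfig": {"popSize": 20, "generations": generations},
        "run": {"seed": seed},
    }


def test_evol_recovers_sphere_optimum():
    res = run_evol({}, _sphere_batch(seed=1))
    best = list(res["best"]["params"].values())
    assert all(abs(b - 0.3) <= 0.05 for b in best)


def test_evol_trajectory_nonincreasing():
    res = run_evol({}, _sphere_batch(seed=2, generations=15))
    traj = res["trajectory"]
    assert all(b <= a for a, b in zip(traj, traj[1:]))
    assert res["nTrials"] == 20 * 15


def test_evol_repeats_mostly_succeed():
    """>= 9/10 seeded repeats land within 0.05 per coordinate."""
    hits = 0
    for seed in range(10):
        res = run_evol({}, _sphere_batch(seed=seed))
        best = list(res["best"]["params"].values())
        hits += all(abs(b - 0.3) <= 0.05 for b in best)
    assert hits >= 9


def test_evol_beats_coarse_grid():
    """On one parameter the EA's optimum is at least as good as a
    10-point grid spanning the same bounds."""
    grid_vals = list(np.linspace(0.0, 1.0, 10))
    gbatch = {"params": [{"path": "simConfig.s0",
                          "values": grid_vals}],
              "fitness": {"paramExpr": "(p0-0.237)^2",
                          "simulate": False}}
    ebatch = {"params": [{"path": "simConfig.s0",
                          "bounds": [0.0, 1.0]}],
              "fitness": {"paramExpr": "(p0-0.237)^2",
                          "simulate": False},
              "evolConfig": {"popSize": 20, "generations": 20},
              "run": {"seed": 5}}
    gres = run_grid({}, gbatch)
    eres = run_evol({}, ebatch)
    assert eres["best"]["fitness"] <= gres["best"]["fitness"]


def test_evol_requires_bounds_and_fitness():
    with pytest.raises(BuildError):
        run_evol({}, {"params": [{"path": "x", "bounds": [1.0, 0.0]}],
                      "fitness": {"paramExpr": "p0", "simulate": False}})
    with pytest.raises(BuildError):
        run_evol({}, {"params": [{"path": "x", "bounds": [0.0, 1.0]}]})


def test_evol_is_reproducible_from_seed():
    a = run_evol({}, _sphere_batch(seed=9, generations=5))
    b = run_evol({}, _sphere_batch(seed=9, generations=5))
    assert a["trajectory"] == b["trajectory"]
    assert a["best"]["params"] == b["best"]["params"]


def test_recorded_trial_reproduces_fitness():
    """Any recorded trial re-runs to exactly the same fitness."""
    batch = {"params": [{"path": "netParams.connParams.c.weight",
                         "values": [0.15, 0.3]}],
             "fitness": {"targetRate": {"B": 10.0}},
             "run": {"seed": 11}}
    res = run_grid(_fast_spec(), batch)
    trial = res["trials"][1]
    from netsim.batch import _run_trial
    redo = _run_trial((_fast_spec(), trial["params"],
                       {"targetRate": {"B": 10.0}}, trial["index"],
                       trial["seed"]))
    assert redo["fitness"] == trial["fitness"]
    assert redo["summary"] == trial["summary"]


def test_queue_script_emitted_not_executed(tmp_path):
    path = tmp_path / "submit.sh"
    text = emit_queue_script({"run": {"workers": 8}}, scheduler="slurm",
                             path=str(path))
    assert path.read_text() == text
    assert "#SBATCH" in text and "netsim batch" in text
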