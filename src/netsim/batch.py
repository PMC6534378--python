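"""Automated parameter exploration and optimization.

Grid search enumerates the Cartesian product of declared value lists in
odometer order (last declared parameter varies fastest); the
evolutionary search is a generational GA with tournament selection,
uniform crossover, Gaussian mutation clipped to bounds and elitism,
minimizing the fitness.  Trials run in local worker processes; results
are deterministic and independent of the worker count because every
trial's parameters and seeds are fixed up front.
"""

from __future__ import annotations

import copy
import itertools
import json
import os
from concurrent.futures import ProcessPoolExecutor

import numpy as np

from .build import build_network
from .diagnostics import BuildError, Diagnostic
from .engine import run as run_engine
from .funcstring import parse_func_string
from .streams import _mix

__all__ = ["run_grid", "run_evol", "eval_fitness", "set_by_path",
           "summarize_output"]

EVOL_DEFAULTS = {
    "popSize": 20,
    "generations": 20,
    "mutationRate": 0.2,      # per-gene mutation probability
    "mutationSd": 0.1,        # sd as fraction of the parameter range
    "elitism": 1,
    "tournament": 3,
}


def set_by_path(doc, path, value):
    """Set a dotted path inside a spec document (in place)."""
    keys = path.split(".")
    node = doc
    for k in keys[:-1]:
        if k not in node or not isinstance(node[k], dict):
            node[k] = {}
        node = node[k]
    node[keys[-1]] = value


def get_by_path(doc, path):
    node = doc
    for k in path.split("."):
        node = node[k]
    return node


def summarize_output(output):
    """Flatten a SimOutput into scalar summary fields for fitness."""
    summary = {"totalSpikes": float(len(output["spkt"]))}
    for pop, rate in output.get("popRates", {}).items():
        summary[f"rate_{pop}"] = float(rate)
    return summary


def eval_fitness(summary, fitness_spec, params=None):
    """Scalar fitness (lower is better) from a summary.

    Built-in ``targetRate``: sum over populations of |rate - target|.
    ``expr`` mode evaluates an expression over the summary scalars;
    ``paramExpr`` evaluates one over the trial's parameter values,
    named p0, p1, ... in declaration order (useful for benchmarking
    the optimizer itself; combine with ``"simulate": false`` to skip
    the simulation entirely).
    """
    if "paramExpr" in fitness_spec:
        env = {f"p{i}": float(v)
               for i, v in enumerate((params or {}).values())}
        fs = parse_func_string(fitness_spec["paramExpr"],
                               frozenset(env))
        return float(fs.eval(env))
    if "targetRate" in fitness_spec:
        total = 0.0
        for pop, target in fitness_spec["targetRate"].items():
            key = f"rate_{pop}"
            if key not in summary:
                raise KeyError(f"summary has no field {key}")
            total += abs(summary[key] - float(target))
        return total
    if "expr" in fitness_spec:
        fs = parse_func_string(fitness_spec["expr"],
                               frozenset(summary))
        return float(fs.eval(summary))
    raise ValueError("fitness spec needs targetRate or expr")


def _run_trial(args):
    """Worker: run one parameterized simulation; never raises."""
    base_spec, params, fitness_spec, trial_index, seed = args
    spec = copy.deepcopy(base_spec)
    for path, value in params.items():
        set_by_path(spec, path, value)
    if seed is not None:
        set_by_path(spec, "simConfig.seeds.global", int(seed))
    try:
        if fitness_spec and fitness_spec.get("simulate") is False:
            summary = {}
        else:
            net = build_network(spec)
            output = run_engine(net)
            summary = summarize_output(output)
        fitness = eval_fitness(summary, fitness_spec, params) \
            if fitness_spec else None
        return {"index": trial_index, "params": params, "seed": seed,
                "summary": summary, "fitness": fitness, "failed": False}
    except Exception as err:  # recorded, batch continues
        return {"index": trial_index, "params": params, "seed": seed,
                "summary": None, "fitness": float("inf"), "failed": True,
                "error": f"{type(err).__name__}: {err}"}


def _run_trials(trials, workers):
    if workers <= 1:
        return [_run_trial(t) for t in trials]
    with ProcessPoolExecutor(max_workers=workers) as pool:
        results = list(pool.map(_run_trial, trials))
    return sorted(results, key=lambda r: r["index"])


def _save_results(result, out_dir):
    if not out_dir:
        return
    os.makedirs(out_dir, exist_ok=True)
    import pandas as pd
    rows = []
    for trial in result["trials"]:
        with open(os.path.join(out_dir,
                               f"trial_{trial['index']:05d}.json"),
                  "w") as fh:
            json.dump(trial, fh, indent=1, sort_keys=True)
        row = dict(trial["params"])
        row["fitness"] = trial["fitness"]
        row["failed"] = trial["failed"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "batch_results.csv"),
                              index=False)
    with open(os.path.join(out_dir, "batch_summary.json"), "w") as fh:
        json.dump({k: v for k, v in result.items() if k != "trials"},
                  fh, indent=1, sort_keys=True, default=str)


def run_grid(base_spec, batch_spec):
    """Evaluate the full Cartesian product of parameter value lists.

    Trial order is the odometer over declaration order; results are
    identical for any worker count.
    """
    params = batch_spec.get("params", [])
    if not params or any(not p.get("values") for p in params):
        raise BuildError(Diagnostic("batch.params",
                                    "grid search needs non-empty value "
                                    "lists"))
    fitness_spec = batch_spec.get("fitness")
    run_cfg = batch_spec.get("run", {})
    seed = int(run_cfg.get("seed", 1))
    paths = [p["path"] for p in params]
    combos = list(itertools.product(*[p["values"] for p in params]))
    trials = [(base_spec, dict(zip(paths, combo)), fitness_spec, i, seed)
              for i, combo in enumerate(combos)]
    results = _run_trials(trials, int(run_cfg.get("workers", 1)))
    best = None
    if fitness_spec:
        ok = [r for r in results if not r["failed"]]
        best = min(ok, key=lambda r: r["fitness"]) if ok else None
    out = {"method": "grid", "trials": results, "best": best,
           "nTrials": len(results)}
    _save_results(out, run_cfg.get("outDir"))
    return out


def run_evol(base_spec, batch_spec):
    """Evolutionary (GA) minimization of the fitness over bounded
    parameters; returns the best-ever individual and the per-generation
    best-fitness trajectory (nonincreasing thanks to elitism)."""
    params = batch_spec.get("params", [])
    fitness_spec = batch_spec.get("fitness")
    if not fitness_spec:
        raise BuildError(Diagnostic("batch.fitness",
                                    "evolutionary search needs a fitness"))
    for p in params:
        lo, hi = p.get("bounds", (None, None))
        if lo is None or hi is None or not lo < hi:
            raise BuildError(Diagnostic(
                f"batch.params.{p.get('path')}",
                "evolutionary search needs bounds [lo, hi] with lo < hi"))
    cfg = dict(EVOL_DEFAULTS)
    cfg.update(batch_spec.get("evolConfig", {}))
    run_cfg = batch_spec.get("run", {})
    workers = int(run_cfg.get("workers", 1))
    seed = int(run_cfg.get("seed", 1))
    rng = np.random.Generator(np.random.Philox(key=_mix((0xE0, seed))))

    paths = [p["path"] for p in params]
    lo = np.array([p["bounds"][0] for p in params], dtype=float)
    hi = np.array([p["bounds"][1] for p in params], dtype=float)
    span = hi - lo
    pop_size = int(cfg["popSize"])
    n_gen = int(cfg["generations"])
    sd = float(cfg["mutationSd"]) * span

    pop = lo + rng.uniform(size=(pop_size, len(params))) * span
    trial_index = 0
    all_trials = []
    best_ever = None
    trajectory = []
    fitness = np.full(pop_size, np.inf)
    for gen in range(n_gen):
        trials = []
        for i in range(pop_size):
            pvals = {path: float(v) for path, v in zip(paths, pop[i])}
            trials.append((base_spec, pvals, fitness_spec,
                           trial_index, seed))
            trial_index += 1
        results = _run_trials(trials, workers)
        all_trials.extend(results)
        fitness = np.array([r["fitness"] for r in results], dtype=float)
        if not np.any(np.isfinite(fitness)):
            raise BuildError(Diagnostic(
                "batch.evol", f"every trial failed in generation {gen}"))
        gi = int(np.argmin(fitness))
        if best_ever is None or fitness[gi] < best_ever["fitness"]:
            best_ever = results[gi]
        trajectory.append(float(best_ever["fitness"]))

        if gen == n_gen - 1:
            break
        # next generation: elitism + tournament/crossover/mutation
        order = np.argsort(fitness, kind="stable")
        next_pop = [pop[i].copy() for i in order[:int(cfg["elitism"])]]
        while len(next_pop) < pop_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(pop_size,
                                          size=int(cfg["tournament"]))
                parents.append(pop[min(contenders,
                                       key=lambda i: fitness[i])])
            mask = rng.uniform(size=len(params)) < 0.5
            child = np.where(mask, parents[0], parents[1])
            mutate = rng.uniform(size=len(params)) < cfg["mutationRate"]
            child = child + mutate * rng.normal(size=len(params)) * sd
            next_pop.append(np.clip(child, lo, hi))
        pop = np.array(next_pop)

    out = {"method": "evol", "trials": all_trials, "best": best_ever,
           "trajectory": trajectory, "nTrials": len(all_trials)}
    _save_results(out, run_cfg.get("outDir"))
    return out


def emit_queue_script(batch_spec, scheduler="slurm", path=None):
    """Generate (but never submit) a queue-system submission script."""
    run_cfg = batch_spec.get("run", {})
    lines = ["#!/bin/bash"]
    if scheduler == "slurm":
        lines += [f"#SBATCH --ntasks={run_cfg.get('workers', 1)}",
                  f"#SBATCH --time={run_cfg.get('timeout', 3600) // 60}"]
    else:  # pbs
        lines += [f"#PBS -l nodes=1:ppn={run_cfg.get('workers', 1)}"]
    lines.append("netsim batch batch.json")
    text = "\n".join(lines) + "\n"
    if path:
        with open(path, "w") as fh:
            fh.write(text)
    return text
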