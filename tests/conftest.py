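"""Shared spec-document builders for the test suite."""

from __future__ import annotations

import copy

import pytest


def minimal_spec(num_cells=2):
    """Smallest valid model: one population of Izhikevich cells."""
    return {
        "netParams": {
            "popParams": {"P": {"cellType": "RS", "numCells": num_cells,
                                "cellModel": "izhi"}},
            "cellParams": {"r": {"conds": {"cellType": "RS"},
                                 "pointParams": {}}},
        },
        "simConfig": {"duration": 100.0, "dt": 0.1},
    }


def two_pop_spec(n_pre=3, n_post=2, conn=None, seed=1):
    """Two point-cell populations with one connectivity rule."""
    spec = {
        "netParams": {
            "popParams": {
                "A": {"cellType": "RS", "numCells": n_pre,
                      "cellModel": "izhi"},
                "B": {"cellType": "RS", "numCells": n_post,
                      "cellModel": "izhi"},
            },
            "cellParams": {"r": {"conds": {}, "pointParams": {}}},
            "synMechParams": {"exc": {"mode": "exp", "tau": 5.0,
                                      "e": 0.0}},
            "connParams": {},
        },
        "simConfig": {"duration": 100.0, "dt": 0.1,
                      "seeds": {"global": seed}},
    }
    if conn is not None:
        rule = {"preConds": {"pop": "A"}, "postConds": {"pop": "B"},
                "synMech": "exc", "weight": 0.1, "delay": 1.0}
        rule.update(conn)
        spec["netParams"]["connParams"]["c"] = rule
    return spec


def soma_dend_spec(n_cells=1, soma_L=100.0, dend_L=300.0, nseg=5,
                   mechs=None):
    """Compartmental cell: soma plus one dendrite along +y."""
    mechs = mechs or {"pas": {"g": 0.0002, "e": -65.0}}
    return {
        "netParams": {
            "popParams": {"P": {"cellType": "C", "numCells": n_cells,
                                "cellModel": "compartmental"}},
            "cellParams": {"r": {"conds": {}, "secs": {
                "soma": {"geom": {"L": soma_L, "diam": 10.0, "Ra": 120.0,
                                  "cm": 1.0, "nseg": nseg},
                         "mechs": copy.deepcopy(mechs)},
                "dend": {"geom": {"L": dend_L, "diam": 2.0, "Ra": 120.0,
                                  "cm": 1.0, "nseg": nseg},
                         "topol": {"parentSec": "soma",
                                   "parentLoc": 1.0, "childLoc": 0.0},
                         "mechs": copy.deepcopy(mechs)},
            }}},
        },
        "simConfig": {"duration": 100.0, "dt": 0.025,
                      "recordStep": 0.1,
                      "recordTraces": {"V": {"conds": {}, "var": "v"}}},
    }


def hh_soma_spec(amp=0.1, duration=200.0, dt=0.025, delay=20.0):
    """Single Hodgkin-Huxley soma driven by a current clamp."""
    return {
        "netParams": {
            "popParams": {"P": {"cellType": "C", "numCells": 1,
                                "cellModel": "compartmental"}},
            "cellParams": {"r": {"conds": {}, "secs": {
                "soma": {"geom": {"L": 18.8, "diam": 18.8, "Ra": 123.0,
                                  "cm": 1.0, "nseg": 1},
                         "mechs": {"hh": {}}}}}},
            "stimSourceParams": {"ic": {"type": "IClamp", "del": delay,
                                        "dur": duration, "amp": amp}},
            "stimTargetParams": {"t": {"source": "ic", "conds": {},
                                       "sec": "soma", "loc": 0.5}},
        },
        "simConfig": {"duration": duration + delay + 10.0, "dt": dt,
                      "recordStep": max(dt, 0.1),
                      "recordTraces": {"V": {"conds": {}, "var": "v"}}},
    }


@pytest.fixture
def tmp_json(tmp_path):
    """Write a document as JSON and return its path."""
    import json

    def write(doc, name="spec.json"):
        path = tmp_path / name
        path.write_text(json.dumps(doc))
        return str(path)

    return write
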