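"""Built-in demonstration models.

Each fixture returns a complete, valid spec document (netParams +
simConfig) exercising a slice of the toolkit:

* ``two_cell``     -- artificial spike source driving a two-neuron chain.
* ``three_layer``  -- three excitatory layers plus an inhibitory
  population with probabilistic, distance-dependent connectivity.
* ``lfp_demo``     -- 120 five-compartment neurons across cortical
  depth with four extracellular depth electrodes.
* ``buffering``    -- one Hodgkin-Huxley cell with calcium buffering
  (2Ca + Buf <-> CaBuf) and first-order buffer degradation.  The rate
  constants are illustrative, chosen to relax within the simulated
  window, not measured values.
"""

from __future__ import annotations

import copy

__all__ = ["fixture", "FIXTURES"]

_RS = {"a": 0.02, "b": 0.2, "c": -65.0, "d": 8.0}     # regular spiking
_FS = {"a": 0.1, "b": 0.2, "c": -65.0, "d": 2.0}      # fast spiking


def two_cell():
    return {
        "netParams": {
            "popParams": {
                "A": {"cellType": "RS", "numCells": 1,
                      "cellModel": "izhi", "yRange": [40.0, 60.0]},
                "B": {"cellType": "RS", "numCells": 1,
                      "cellModel": "izhi", "yRange": [40.0, 60.0]},
            },
            "cellParams": {
                "RSrule": {"conds": {"cellType": "RS"},
                           "pointParams": dict(_RS)},
            },
            "synMechParams": {
                "exc": {"mode": "exp", "tau": 5.0, "e": 0.0},
            },
            "connParams": {
                "A->B": {"preConds": {"pop": "A"},
                         "postConds": {"pop": "B"},
                         "connFunc": "fullConn", "synMech": "exc",
                         "weight": 0.5, "delay": 5.0},
            },
            "stimSourceParams": {
                "drive": {"type": "NetStim", "rate": 20.0, "noise": 0.0,
                          "start": 10.0, "number": 1000000000},
            },
            "stimTargetParams": {
                "drive->A": {"source": "drive", "conds": {"pop": "A"},
                             "synMech": "exc", "weight": 0.8,
                             "delay": 1.0},
            },
        },
        "simConfig": {
            "duration": 500.0, "dt": 0.1, "recordStep": 0.1,
            "recordTraces": {"V": {"conds": {}, "var": "v"}},
        },
    }


def three_layer():
    """Three excitatory layers and one inhibitory population with
    probabilistic distance-dependent wiring and background drive."""
    pops = {
        "E2": [0.1, 0.3],
        "E4": [0.35, 0.55],
        "E5": [0.6, 0.85],
    }
    net = {
        "popParams": {},
        "cellParams": {
            "RSrule": {"conds": {"cellType": "RS"},
                       "pointParams": dict(_RS)},
            "FSrule": {"conds": {"cellType": "FS"},
                       "pointParams": dict(_FS)},
        },
        "synMechParams": {
            "AMPA": {"mode": "exp", "tau": 5.0, "e": 0.0},
            "GABA": {"mode": "exp", "tau": 10.0, "e": -80.0},
        },
        "connParams": {},
        "stimSourceParams": {
            "bkg": {"type": "NetStim", "rate": 40.0, "noise": 1.0,
                    "start": 0.0, "number": 1000000000},
        },
        "stimTargetParams": {
            "bkg->E": {"source": "bkg", "conds": {"cellType": "RS"},
                       "synMech": "AMPA", "weight": 0.45,
                       "delay": 1.0},
            "bkg->I": {"source": "bkg", "conds": {"pop": "I"},
                       "synMech": "AMPA", "weight": 0.15,
                       "delay": 1.0},
        },
    }
    for pname, yr in pops.items():
        net["popParams"][pname] = {
            "cellType": "RS", "numCells": 20, "cellModel": "izhi",
            "ynormRange": yr}
    net["popParams"]["I"] = {"cellType": "FS", "numCells": 20,
                             "cellModel": "izhi",
                             "ynormRange": [0.1, 0.85]}
    feed = [("E4", "E2"), ("E2", "E5"), ("E5", "E4")]
    for pre, post in feed:
        net["connParams"][f"{pre}->{post}"] = {
            "preConds": {"pop": pre}, "postConds": {"pop": post},
            "connFunc": "probConn",
            "probability": "0.4*exp(-dist_3D/200)",
            "synMech": "AMPA", "weight": 0.25,
            "delay": "max(1, dist_3D/100)"}
    net["connParams"]["E->I"] = {
        "preConds": {"cellType": "RS"}, "postConds": {"pop": "I"},
        "connFunc": "probConn", "probability": 0.2,
        "synMech": "AMPA", "weight": 0.1, "delay": 1.0}
    net["connParams"]["I->E"] = {
        "preConds": {"pop": "I"}, "postConds": {"cellType": "RS"},
        "connFunc": "probConn", "probability": 0.3,
        "synMech": "GABA", "weight": 0.3, "delay": 1.0}
    return {
        "netParams": net,
        "simConfig": {
            "duration": 1000.0, "dt": 0.1, "recordStep": 1.0,
            "sizeX": 300.0, "sizeY": 1000.0, "sizeZ": 300.0,
            "recordTraces": {"V": {"conds": {"gid": [0, 25, 45]},
                                   "var": "v"}},
        },
    }


def _five_compartment_rule():
    """Soma plus a four-section apical-like chain extending in +y."""
    secs = {
        "soma": {"geom": {"L": 20.0, "diam": 20.0, "Ra": 120.0,
                          "cm": 1.0, "nseg": 1},
                 "mechs": {"hh": {"gnabar": 0.12, "gkbar": 0.036,
                                  "gl": 0.0003, "el": -54.3}}},
    }
    parent = "soma"
    for i in range(1, 5):
        secs[f"dend{i}"] = {
            "geom": {"L": 150.0, "diam": 2.0, "Ra": 120.0, "cm": 1.0,
                     "nseg": 1},
            "topol": {"parentSec": parent, "parentLoc": 1.0,
                      "childLoc": 0.0},
            "mechs": {"pas": {"g": 0.0002, "e": -65.0}},
        }
        parent = f"dend{i}"
    return {"conds": {"cellType": "PYR5"}, "secs": secs,
            "secLists": {"apical": ["dend1", "dend2", "dend3", "dend4"],
                         "proximal": ["dend1", "dend2"]}}


def lfp_demo():
    """120 five-compartment neurons with four depth electrodes."""
    return {
        "netParams": {
            "popParams": {
                "PYR": {"cellType": "PYR5", "numCells": 120,
                        "cellModel": "compartmental",
                        "xnormRange": [0.35, 0.65],
                        "ynormRange": [0.25, 0.4],
                        "znormRange": [0.35, 0.65]},
            },
            "cellParams": {"PYRrule": _five_compartment_rule()},
            "synMechParams": {
                "AMPA": {"mode": "exp2", "tau1": 0.5, "tau2": 5.0,
                         "e": 0.0},
                "GABA": {"mode": "exp", "tau": 10.0, "e": -80.0},
            },
            "connParams": {
                "PYR->PYR": {"preConds": {"pop": "PYR"},
                             "postConds": {"pop": "PYR"},
                             "connFunc": "probConn",
                             "probability": 0.05,
                             "synMech": "AMPA", "weight": 0.002,
                             "delay": "max(1, dist_3D/200)",
                             "sec": "dend1", "loc": 0.5},
            },
            "subConnParams": {
                "drive-map": {"preConds": {"pop": "PYR"},
                              "postConds": {"pop": "PYR"},
                              "density": {"sectionGroups":
                                          {"proximal": 1.0}}},
            },
            "stimSourceParams": {
                "thal": {"type": "NetStim", "rate": 25.0, "noise": 1.0,
                         "start": 0.0, "number": 1000000000},
            },
            "stimTargetParams": {
                "thal->PYR": {"source": "thal", "conds": {"pop": "PYR"},
                              "sec": "dend2", "loc": 0.5,
                              "synMech": "AMPA", "weight": 0.004,
                              "delay": 1.0},
            },
        },
        "simConfig": {
            "duration": 500.0, "dt": 0.05, "recordStep": 0.5,
            "sizeX": 400.0, "sizeY": 1000.0, "sizeZ": 400.0,
            "recordLFP": [[200.0, 250.0, 200.0], [200.0, 450.0, 200.0],
                          [200.0, 650.0, 200.0], [200.0, 850.0, 200.0]],
            "recordTraces": {"V": {"conds": {"gid": [0]}, "var": "v"}},
        },
    }


def buffering():
    """One Hodgkin-Huxley cell with cytosolic calcium buffering and
    buffer degradation: 2Ca + Buf <-> CaBuf, Buf -> (degraded)."""
    return {
        "netParams": {
            "popParams": {
                "CELL": {"cellType": "PYR", "numCells": 1,
                         "cellModel": "compartmental"},
            },
            "cellParams": {
                "PYRrule": {
                    "conds": {"cellType": "PYR"},
                    "secs": {"soma": {
                        "geom": {"L": 18.8, "diam": 18.8, "Ra": 123.0,
                                 "cm": 1.0, "nseg": 1},
                        "mechs": {"hh": {}}}},
                },
            },
            "rxdParams": {
                "regions": {"cyt": {"cells": "all", "secs": ["soma"],
                                    "volume_fraction": 1.0}},
                "species": {
                    "ca": {"regions": ["cyt"], "initial": 1.0,
                           "charge": 2},
                    "buf": {"regions": ["cyt"], "initial": 1.0,
                            "charge": 0},
                    "cabuf": {"regions": ["cyt"], "initial": 0.0,
                              "charge": 2},
                },
                "reactions": {
                    "buffering": {"reactants": "2 ca + buf",
                                  "products": "cabuf",
                                  "rate_f": 1.0, "rate_b": 0.1},
                },
                "rates": {
                    "degradation": {"species": "buf",
                                    "rate": "-0.001*buf"},
                },
            },
        },
        "simConfig": {
            "duration": 200.0, "dt": 0.025, "recordStep": 0.1,
            "recordTraces": {
                "V": {"conds": {}, "var": "v"},
                "cai": {"conds": {}, "var": "ca"},
                "bufi": {"conds": {}, "var": "buf"},
            },
        },
    }


FIXTURES = {
    "two_cell": two_cell,
    "three_layer": three_layer,
    "lfp_demo": lfp_demo,
    "buffering": buffering,
}


def fixture(name):
    """Return a deep copy of the named fixture spec."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: "
            + ", ".join(sorted(FIXTURES)))
    return copy.deepcopy(FIXTURES[name]())
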