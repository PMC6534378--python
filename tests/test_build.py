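"""Network instantiation: populations, cell rules, connectivity,
subcellular synapse distribution, stimulation."""

import math
from collections import Counter

import numpy as np
import pytest

import netsim
from netsim.build import build_network, netstim_train
from netsim.diagnostics import BuildError
from netsim.specs import canonical_json
from netsim.streams import stream

from conftest import minimal_spec, soma_dend_spec, two_pop_spec


# --- populations -----------------------------------------------------

def test_positions_within_declared_range():
    spec = minimal_spec(5)
    spec["netParams"]["popParams"]["P"]["yRange"] = [100.0, 300.0]
    spec["simConfig"].update(sizeY=500.0)
    net = build_network(spec)
    assert len(net.cells) == 5
    assert all(100.0 <= c.tags.y <= 300.0 for c in net.cells)


def test_density_to_count_arithmetic():
    spec = minimal_spec()
    spec["netParams"]["popParams"]["P"] = {
        "cellType": "RS", "density": 100000.0, "cellModel": "izhi"}
    spec["simConfig"].update(sizeX=100.0, sizeY=100.0, sizeZ=100.0)
    net = build_network(spec)
    # 1e5 cells/mm^3 x 1e-3 mm^3 = 100 cells
    assert len(net.cells) == 100


def test_density_scales_with_range_fraction():
    spec = minimal_spec()
    spec["netParams"]["popParams"]["P"] = {
        "cellType": "RS", "density": 100000.0, "cellModel": "izhi",
        "ynormRange": [0.0, 0.5]}
    net = build_network(spec)
    assert len(net.cells) == 50


def test_gids_follow_declaration_order():
    spec = two_pop_spec(n_pre=3, n_post=2)
    net = build_network(spec)
    assert [c.gid for c in net.cells] == [0, 1, 2, 3, 4]
    assert net.pops["A"]["cellGids"] == [0, 1, 2]
    assert net.pops["B"]["cellGids"] == [3, 4]


def test_zero_volume_density_region_is_diagnosed():
    spec = minimal_spec()
    spec["netParams"]["popParams"]["P"] = {
        "cellType": "RS", "density": 1000.0, "cellModel": "izhi",
        "ynormRange": [0.5, 0.5]}
    with pytest.raises(BuildError):
        build_network(spec)


def test_positions_keyed_by_gid_not_build_order():
    spec = two_pop_spec(n_pre=5, n_post=5, seed=7)
    a = build_network(spec)
    b = build_network(spec)
    assert canonical_json(a.cells) == canonical_json(b.cells)


# --- cell rules ------------------------------------------------------

def test_conds_match_cell_type():
    spec = two_pop_spec()
    spec["netParams"]["popParams"]["B"]["cellType"] = "FS"
    spec["netParams"]["cellParams"] = {
        "rs": {"conds": {"cellType": "RS"},
               "pointParams": {"a": 0.02}},
        "fs": {"conds": {"cellType": "FS"},
               "pointParams": {"a": 0.1}},
    }
    net = build_network(spec)
    assert all(c.params.a == 0.02 for c in net.cells if c.pop == "A")
    assert all(c.params.a == 0.1 for c in net.cells if c.pop == "B")


def test_first_declared_rule_wins():
    spec = minimal_spec()
    spec["netParams"]["cellParams"] = {
        "first": {"conds": {}, "pointParams": {"d": 4.0}},
        "second": {"conds": {}, "pointParams": {"d": 9.0}},
    }
    net = build_network(spec)
    assert all(c.params.d == 4.0 for c in net.cells)


def test_unmatched_cell_is_diagnosed_with_tags():
    spec = minimal_spec()
    spec["netParams"]["cellParams"]["r"]["conds"] = {"cellType": "FS"}
    with pytest.raises(BuildError) as exc:
        build_network(spec, validate=False)
    assert "RS" in str(exc.value)


def test_cylinder_lateral_area():
    spec = soma_dend_spec(soma_L=18.8, nseg=1)
    spec["netParams"]["cellParams"]["r"]["secs"]["soma"]["geom"][
        "diam"] = 18.8
    net = build_network(spec)
    area = sum(s.area for s in net.cells[0].secs.soma.segments)
    assert area == pytest.approx(math.pi * 18.8 * 18.8, rel=1e-12)
    assert area == pytest.approx(1110.4, abs=0.5)


def test_network_addressable_by_path():
    spec = soma_dend_spec(mechs={"hh": {"gnabar": 0.1}})
    net = build_network(spec)
    assert net.cells[0].secs.soma.mechs.hh.gnabar == 0.1
    seg = net.cells[0].secs.soma.segments[0]
    assert seg.loc == pytest.approx(0.1)  # (0+0.5)/5


def test_segment_lengths_sum_to_section_length():
    spec = soma_dend_spec(dend_L=300.0, nseg=7)
    spec["netParams"]["cellParams"]["r"]["secs"]["dend"]["geom"][
        "nseg"] = 7
    net = build_network(spec)
    dend = net.cells[0].secs.dend
    assert sum(s.L for s in dend.segments) == pytest.approx(300.0)
    assert all(s.area > 0 for s in dend.segments)


# --- connectivity ----------------------------------------------------

def test_fullconn_cartesian_product():
    net = build_network(two_pop_spec(3, 2, {"connFunc": "fullConn"}))
    assert len(net.conns) == 6
    pairs = {(c.preGid, c.postGid) for c in net.conns}
    assert pairs == {(i, j) for i in range(3) for j in range(3, 5)}


@pytest.mark.parametrize("p, expected", [(0.0, 0), (1.0, 50 * 50)])
def test_probconn_degenerate_probabilities(p, expected):
    net = build_network(two_pop_spec(
        50, 50, {"connFunc": "probConn", "probability": p}))
    assert len(net.conns) == expected


def test_convconn_exact_in_degree():
    net = build_network(two_pop_spec(
        20, 10, {"connFunc": "convConn", "convergence": 5}))
    assert len(net.conns) == 50
    indeg = Counter(c.postGid for c in net.conns)
    assert set(indeg.values()) == {5}
    for post in set(c.postGid for c in net.conns):
        pres = [c.preGid for c in net.conns if c.postGid == post]
        assert len(set(pres)) == 5  # sampled without replacement


def test_divconn_exact_out_degree():
    net = build_network(two_pop_spec(
        10, 20, {"connFunc": "divConn", "divergence": 4}))
    assert len(net.conns) == 40
    outdeg = Counter(c.preGid for c in net.conns)
    assert set(outdeg.values()) == {4}


def test_convergence_exceeding_pool_is_diagnosed():
    with pytest.raises(BuildError) as exc:
        build_network(two_pop_spec(
            3, 2, {"connFunc": "convConn", "convergence": 5}))
    assert "exceeds" in str(exc.value)


def test_connmatrix_explicit_pairs():
    net = build_network(two_pop_spec(3, 2, {
        "connMatrix": [[1, 0], [0, 1], [1, 1]]}))
    pairs = {(c.preGid, c.postGid) for c in net.conns}
    assert pairs == {(0, 3), (1, 4), (2, 3), (2, 4)}


def test_self_connections_excluded_by_default():
    spec = two_pop_spec(0, 0)
    spec["netParams"]["connParams"]["c"] = {
        "preConds": {"pop": "A"}, "postConds": {"pop": "A"},
        "connFunc": "fullConn", "synMech": "exc", "weight": 0.1,
        "delay": 1.0}
    spec["netParams"]["popParams"]["A"]["numCells"] = 4
    spec["netParams"]["popParams"]["B"]["numCells"] = 0
    net = build_network(spec)
    assert len(net.conns) == 12
    assert all(c.preGid != c.postGid for c in net.conns)
    spec["simConfig"]["allowSelfConns"] = True
    assert len(build_network(spec).conns) == 16


def test_connection_list_sorted_and_rules_cumulative():
    spec = two_pop_spec(3, 2, {"connFunc": "fullConn"})
    spec["netParams"]["connParams"]["c2"] = dict(
        spec["netParams"]["connParams"]["c"])
    net = build_network(spec)
    assert len(net.conns) == 12  # parallel connections add up
    keys = [(c.postGid, c.preGid, c.ruleIndex) for c in net.conns]
    assert keys == sorted(keys)


def test_funcstring_weight_and_delay_resolved_per_pair():
    spec = two_pop_spec(4, 4, {
        "connFunc": "fullConn",
        "weight": "0.001*dist_3D",
        "delay": "max(1, dist_3D/100)"})
    net = build_network(spec)
    cells = {c.gid: c for c in net.cells}
    for conn in net.conns:
        p, q = cells[conn.preGid].tags, cells[conn.postGid].tags
        d = math.dist((p.x, p.y, p.z), (q.x, q.y, q.z))
        assert conn.weight == pytest.approx(0.001 * d)
        assert conn.delay == pytest.approx(max(1.0, d / 100.0))


def test_partition_and_order_invariance():
    """Round-robin partitioning across simulated workers and reversed
    processing order leave the connection list byte-identical."""
    spec = two_pop_spec(20, 20, {"connFunc": "probConn",
                                 "probability": 0.3})
    ref = build_network(spec)
    ref_json = canonical_json(ref.conns)

    def round_robin(k):
        def order(post):
            return [c for i in range(k) for c in post[i::k]]
        return order

    for k in (1, 2, 4, 8):
        net = build_network(spec, post_order=round_robin(k))
        assert canonical_json(net.conns) == ref_json
    net = build_network(spec, post_order=lambda p: list(reversed(p)))
    assert canonical_json(net.conns) == ref_json


def test_conn_seed_changes_wiring_but_not_locations():
    spec = two_pop_spec(10, 10, {"connFunc": "probConn",
                                 "probability": 0.5})
    spec["simConfig"]["seeds"] = {"global": 1, "conn": 1}
    a = build_network(spec)
    spec["simConfig"]["seeds"] = {"global": 1, "conn": 2}
    b = build_network(spec)
    assert canonical_json(a.cells) == canonical_json(b.cells)
    assert canonical_json(a.conns) != canonical_json(b.conns)


# --- subcellular synapse distribution --------------------------------

def _subconn_spec(density, n_pre=200):
    spec = soma_dend_spec()
    spec["netParams"]["popParams"]["SRC"] = {
        "cellType": "RS", "numCells": n_pre, "cellModel": "izhi"}
    spec["netParams"]["cellParams"] = {
        "comp": {"conds": {"cellType": "C"},
                 "secs": spec["netParams"]["cellParams"]["r"]["secs"]},
        "pt": {"conds": {"cellType": "RS"}, "pointParams": {}},
    }
    spec["netParams"]["synMechParams"] = {
        "exc": {"mode": "exp", "tau": 5.0, "e": 0.0}}
    spec["netParams"]["connParams"] = {
        "c": {"preConds": {"pop": "SRC"}, "postConds": {"pop": "P"},
              "connFunc": "fullConn", "synMech": "exc", "weight": 0.001,
              "delay": 1.0, "sec": "soma", "loc": 0.5}}
    spec["netParams"]["subConnParams"] = {
        "d": {"preConds": {"pop": "SRC"}, "postConds": {"pop": "P"},
              "density": density}}
    return spec


def test_single_support_map_restricts_all_synapses():
    # soma spans y in [y0, y0+100], dend [y0+100, y0+400]; a map whose
    # only nonzero bin covers the dendrite forces every synapse there
    spec = _subconn_spec({"map1D": {"gridY": [0.0, 50.0, 250.0, 450.0],
                                    "gridValues": [0.0, 0.0, 1.0, 1.0],
                                    "norm": False}})
    spec["netParams"]["popParams"]["P"]["yRange"] = [0.0, 0.0]
    net = build_network(spec)
    assert len(net.conns) == 200
    assert all(c.sec == "dend" for c in net.conns)


def test_section_groups_fraction_one():
    spec = _subconn_spec({"sectionGroups": {"dend": 1.0}})
    net = build_network(spec)
    assert all(c.sec == "dend" for c in net.conns)


def test_length_weighted_sampling_proportions():
    """Uniform density over a 100 µm and a 300 µm section: synapse
    counts split 1:3 within multinomial 3 sigma at n = 4000."""
    spec = _subconn_spec({"distance": {"expr": "1"}}, n_pre=4000)
    net = build_network(spec)
    n = len(net.conns)
    assert n == 4000
    frac_soma = sum(1 for c in net.conns if c.sec == "soma") / n
    sigma = math.sqrt(0.25 * 0.75 / n)
    assert abs(frac_soma - 0.25) <= 3 * sigma


def test_all_zero_density_is_diagnosed():
    spec = _subconn_spec({"map1D": {"gridY": [10000.0, 20000.0],
                                    "gridValues": [1.0, 1.0],
                                    "norm": False}}, n_pre=2)
    with pytest.raises(BuildError) as exc:
        build_network(spec)
    assert "zero" in str(exc.value)


def test_connection_count_preserved_by_redistribution():
    spec = _subconn_spec({"distance": {"expr": "exp(-path_dist/100)"}},
                         n_pre=50)
    net = build_network(spec)
    assert len(net.conns) == 50


# --- stimulation -----------------------------------------------------

def test_netstim_periodic_train():
    rng = stream(1, "stim", 1, 0, 0)
    train = netstim_train(10.0, 0.0, 0.0, 1000.0, 10 ** 9, rng)
    assert train == pytest.approx(list(range(0, 1000, 100)))


def test_netstim_zero_rate_gives_empty_train():
    rng = stream(1, "stim", 1, 0, 0)
    assert netstim_train(0.0, 1.0, 0.0, 1000.0, 5, rng) == []


def test_netstim_number_caps_train():
    rng = stream(1, "stim", 1, 0, 0)
    assert len(netstim_train(100.0, 0.0, 0.0, 1000.0, 7, rng)) == 7


def test_netstim_poisson_statistics():
    """noise=1: Poisson process: mean count = rate x duration and
    ISI CV near 1 (200 independent streams)."""
    counts, cvs = [], []
    for i in range(200):
        rng = stream(i, "stim", 1, 0, 0)
        train = np.array(netstim_train(10.0, 1.0, 0.0, 10000.0,
                                       10 ** 9, rng))
        counts.append(len(train))
        isi = np.diff(train)
        cvs.append(isi.std() / isi.mean())
    mean_count = np.mean(counts)
    # 3 sigma of the mean of 200 Poisson(100) counts
    assert abs(mean_count - 100.0) <= 3 * math.sqrt(100.0 / 200)
    assert abs(np.mean(cvs) - 1.0) <= 3 * np.std(cvs) / math.sqrt(200)


def test_netstim_trains_deterministic_across_builds():
    spec = two_pop_spec(2, 2)
    spec["netParams"]["stimSourceParams"] = {
        "ns": {"type": "NetStim", "rate": 20.0, "noise": 1.0,
               "start": 0.0, "number": 10 ** 9}}
    spec["netParams"]["stimTargetParams"] = {
        "t": {"source": "ns", "conds": {}, "synMech": "exc",
              "weight": 0.1, "delay": 1.0}}
    a = build_network(spec)
    b = build_network(spec)
    assert canonical_json(a.stims) == canonical_json(b.stims)
    assert len(a.stims) == 4
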