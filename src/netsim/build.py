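"""Network instantiation from declarative parameters.

The build sequence mirrors the standard order: (1) create populations
and cells with positions, (2) apply cell rules (morphology/biophysics
or point-model parameters), (3) create connections from connectivity
rules, (4) redistribute synapses from subcellular rules, (5) attach
stimulation.  Every random decision draws from a stream keyed by the
gids involved (see :mod:`netsim.streams`), so the instantiated network
is independent of the order in which cells are processed and of any
partitioning of the work across workers.

The instantiated network is a plain hierarchical structure of dicts
with attribute access, addressable by path, e.g.::

    net.cells[5].secs.soma.mechs.hh.gnabar
"""

from __future__ import annotations

import math

import numpy as np

from .diagnostics import BuildError, Diagnostic
from .funcstring import FuncString, parse_func_string
from .specs import (_conds_match_tags, complete_simconfig, validate_netparams)
from .streams import StreamSet

__all__ = [
    "DotDict", "Network", "build_network", "create_populations",
    "apply_cell_rules", "connect", "distribute_synapses", "add_stims",
]

IZHI_DEFAULTS = {"a": 0.02, "b": 0.2, "c": -65.0, "d": 8.0}
LIF_DEFAULTS = {"tau_m": 10.0, "v_rest": -65.0, "v_reset": -65.0,
                "v_thresh": -50.0, "r_m": 10.0, "t_ref": 0.0}


class DotDict(dict):
    """Dictionary with attribute access; the instantiated network is
    built from these so every parameter resolves by dotted path."""

    def __getattr__(self, name):
        try:
            return self[name]
        except KeyError as err:
            raise AttributeError(name) from err

    def __setattr__(self, name, value):
        self[name] = value

    @classmethod
    def wrap(cls, obj):
        if isinstance(obj, dict):
            return cls({k: cls.wrap(v) for k, v in obj.items()})
        if isinstance(obj, list):
            return [cls.wrap(v) for v in obj]
        return obj


class Network:
    """An instantiated network: cells, connections, stimulators."""

    def __init__(self, net_params, sim_config):
        self.netParams = net_params
        self.simConfig = sim_config
        self.cells = []
        self.conns = []
        self.stims = []
        self.pops = DotDict()

    # -- serialization ------------------------------------------------
    def todict(self):
        return {
            "netParams": self.netParams,
            "simConfig": self.simConfig,
            "cells": self.cells,
            "conns": self.conns,
            "stims": self.stims,
            "pops": self.pops,
        }

    @classmethod
    def fromdict(cls, doc):
        net = cls(doc.get("netParams", {}),
                  complete_simconfig(doc.get("simConfig", {})))
        net.cells = DotDict.wrap(doc.get("cells", []))
        net.conns = DotDict.wrap(doc.get("conns", []))
        net.stims = DotDict.wrap(doc.get("stims", []))
        net.pops = DotDict.wrap(doc.get("pops", {}))
        return net

    def cell(self, gid):
        return self.cells[gid]


# ---------------------------------------------------------------------------
# step 1: populations and positions

def _pop_axis_range(pop, axis, size):
    """Absolute [lo, hi] µm for one axis of a population's region."""
    if f"{axis}Range" in pop:
        lo, hi = pop[f"{axis}Range"]
        return float(lo), float(hi)
    if f"{axis}normRange" in pop:
        lo, hi = pop[f"{axis}normRange"]
        return float(lo) * size, float(hi) * size
    return 0.0, size


def create_populations(net_params, sim_config, streams=None):
    """Create cells with gids, positions and tags (no models yet).

    Gids are contiguous from 0 in population declaration order.  Each
    cell's position is drawn (x, then y, then z) from its private
    ``loc`` stream, uniformly within the population's region.
    """
    streams = streams or StreamSet(sim_config["seeds"])
    sizes = {ax: float(sim_config[f"size{ax.upper()}"]) for ax in "xyz"}
    cells = []
    pops = DotDict()
    gid = 0
    for pname, pop in net_params.get("popParams", {}).items():
        ranges = {ax: _pop_axis_range(pop, ax, sizes[ax]) for ax in "xyz"}
        if "numCells" in pop:
            n = int(pop["numCells"])
        else:
            frac = 1.0
            for ax in "xyz":
                lo, hi = ranges[ax]
                frac *= (hi - lo) / sizes[ax]
            if frac <= 0.0:
                raise BuildError(Diagnostic(
                    f"popParams.{pname}",
                    "density given but the population region has zero "
                    "volume"))
            vol_mm3 = sizes["x"] * sizes["y"] * sizes["z"] * 1e-9
            # round half to even for cross-platform reproducibility
            n = int(round(pop["density"] * vol_mm3 * frac))
        pop_gids = []
        for _ in range(n):
            rng = streams("loc", gid, 0)
            xyz = {}
            for ax in "xyz":
                lo, hi = ranges[ax]
                xyz[ax] = float(rng.uniform(lo, hi)) if hi > lo else lo
            tags = DotDict(
                cellType=pop.get("cellType"),
                x=xyz["x"], y=xyz["y"], z=xyz["z"],
                xnorm=xyz["x"] / sizes["x"],
                ynorm=xyz["y"] / sizes["y"],
                znorm=xyz["z"] / sizes["z"],
            )
            cells.append(DotDict(gid=gid, pop=pname, tags=tags,
                                 model=pop.get("cellModel", "compartmental"),
                                 params=DotDict(), secs=DotDict()))
            pop_gids.append(gid)
            gid += 1
        pops[pname] = DotDict(cellGids=pop_gids,
                              cellType=pop.get("cellType"),
                              cellModel=pop.get("cellModel",
                                                "compartmental"))
    return cells, pops


# ---------------------------------------------------------------------------
# step 2: cell rules (morphology and biophysics)

def _cell_tags(cell):
    tags = dict(cell["tags"])
    tags["pop"] = cell["pop"]
    tags["gid"] = cell["gid"]
    return tags


def _polyline_point(pts, arc):
    """Point at arc-length fraction ``arc`` along a 3D polyline."""
    pts = np.asarray(pts, dtype=float)
    seg_len = np.linalg.norm(np.diff(pts[:, :3], axis=0), axis=1)
    total = seg_len.sum()
    if total == 0:
        return pts[0, :3]
    target = arc * total
    acc = 0.0
    for i, sl in enumerate(seg_len):
        if acc + sl >= target or i == len(seg_len) - 1:
            f = 0.0 if sl == 0 else (target - acc) / sl
            return pts[i, :3] + f * (pts[i + 1, :3] - pts[i, :3])
        acc += sl
    return pts[-1, :3]


def _build_sections(cell, secs_spec):
    """Construct the compartment tree: 3D points, segments, areas.

    Sections without explicit ``pt3d`` get a stylized straight line
    along +y starting at the parent attachment point (the root starts
    at the cell position).  Explicit pt3d points are interpreted
    relative to the cell position.
    """
    origin = np.array([cell.tags.x, cell.tags.y, cell.tags.z])
    # topological order: parents before children
    order, seen = [], set()

    def visit(name):
        if name in seen:
            return
        parent = (secs_spec[name].get("topol") or {}).get("parentSec")
        if parent and parent not in seen:
            visit(parent)
        seen.add(name)
        order.append(name)

    for name in secs_spec:
        visit(name)

    secs = DotDict()
    path0 = {}  # path distance from tree root to each section's 0 end
    for name in order:
        spec = secs_spec[name]
        geom = spec.get("geom", {})
        L = float(geom["L"])
        diam = float(geom["diam"])
        nseg = int(geom.get("nseg", 1))
        topol = DotDict(spec.get("topol") or {})
        parent = topol.get("parentSec")
        if spec.get("pt3d"):
            pts = [(origin[0] + p[0], origin[1] + p[1], origin[2] + p[2],
                    p[3]) for p in spec["pt3d"]]
        else:
            if parent:
                ploc = float(topol.get("parentLoc", 1.0))
                ppts = [(p[0], p[1], p[2]) for p in secs[parent].pt3d]
                start = _polyline_point(np.array(
                    [list(p) + [diam] for p in ppts]), ploc)
            else:
                start = origin
            pts = [(start[0], start[1], start[2], diam),
                   (start[0], start[1] + L, start[2], diam)]
        if parent:
            path0[name] = path0[parent] + float(
                topol.get("parentLoc", 1.0)) * float(
                secs_spec[parent]["geom"]["L"])
        else:
            path0[name] = 0.0
        pts_arr = np.array([list(p) for p in pts])
        seg_list = []
        seg_L = L / nseg
        for i in range(nseg):
            p0 = _polyline_point(pts_arr, i / nseg)
            p1 = _polyline_point(pts_arr, (i + 1) / nseg)
            seg_list.append(DotDict(
                sec=name, index=i, loc=(i + 0.5) / nseg,
                p0=[float(v) for v in p0], p1=[float(v) for v in p1],
                L=seg_L, diam=diam,
                area=math.pi * diam * seg_L,           # µm², lateral
                pathDist=path0[name] + (i + 0.5) / nseg * L,
            ))
        secs[name] = DotDict(
            geom=DotDict(L=L, diam=diam, Ra=float(geom["Ra"]),
                         cm=float(geom["cm"]), nseg=nseg),
            topol=topol,
            mechs=DotDict.wrap(spec.get("mechs", {})),
            pt3d=[list(p) for p in pts],
            segments=seg_list,
        )
    return secs


def apply_cell_rules(cells, cell_params):
    """Attach model parameters to each cell; first-declared matching
    rule wins."""
    rules = list(cell_params.items())
    for cell in cells:
        tags = _cell_tags(cell)
        matched = None
        for rname, rule in rules:
            if _conds_match_tags(rule.get("conds", {}), tags):
                matched = (rname, rule)
                break
        if matched is None:
            raise BuildError(Diagnostic(
                f"cells[{cell.gid}]",
                f"no cell rule matches tags {tags}"))
        rname, rule = matched
        cell.ruleName = rname
        if cell.model == "compartmental":
            if "secs" not in rule:
                raise BuildError(Diagnostic(
                    f"cellParams.{rname}",
                    f"cell {cell.gid} is compartmental but the rule has "
                    "no sections"))
            cell.secs = _build_sections(cell, rule["secs"])
            cell.secLists = DotDict.wrap(rule.get("secLists", {}))
        else:
            defaults = IZHI_DEFAULTS if cell.model == "izhi" else LIF_DEFAULTS
            params = dict(defaults)
            params.update(rule.get("pointParams", {}))
            cell.params = DotDict(params)
    return cells


# ---------------------------------------------------------------------------
# step 3: connections

def _pair_env(pre, post):
    pt, qt = pre["tags"], post["tags"]
    dx, dy, dz = (qt["x"] - pt["x"], qt["y"] - pt["y"], qt["z"] - pt["z"])
    return {
        "pre_x": pt["x"], "pre_y": pt["y"], "pre_z": pt["z"],
        "post_x": qt["x"], "post_y": qt["y"], "post_z": qt["z"],
        "pre_xnorm": pt["xnorm"], "pre_ynorm": pt["ynorm"],
        "pre_znorm": pt["znorm"],
        "post_xnorm": qt["xnorm"], "post_ynorm": qt["ynorm"],
        "post_znorm": qt["znorm"],
        "dist_3D": math.sqrt(dx * dx + dy * dy + dz * dz),
        "dist_2D": math.sqrt(dx * dx + dz * dz),
        "dist_y": abs(dy),
    }


def _resolve(value, env, rng, default=None):
    if value is None:
        return default
    if isinstance(value, str):
        value = parse_func_string(value)
    if isinstance(value, FuncString):
        return value.eval(env, rng)
    return float(value)


def _select(cells, conds):
    return [c for c in cells if _conds_match_tags(conds, _cell_tags(c))]


def _fisher_yates_sample(pool, k, rng):
    """k distinct items, partial Fisher-Yates driven by ``rng``."""
    pool = list(pool)
    n = len(pool)
    for m in range(k):
        j = m + int(rng.integers(n - m))
        pool[m], pool[j] = pool[j], pool[m]
    return pool[:k]


def _make_conns(rule_name, rule_idx, rule, pre, post, pairs, dt, streams,
                pair_rngs=None):
    """Materialize Connection records for the given (pre, post) pairs."""
    conns = []
    mechs = rule.get("synMech")
    mechs = mechs if isinstance(mechs, list) else [mechs]
    secs = rule.get("sec", "soma")
    secs = secs if isinstance(secs, list) else [secs]
    locs = rule.get("loc", 0.5)
    locs = locs if isinstance(locs, list) else [locs]
    for pre_cell, post_cell in pairs:
        env = _pair_env(pre_cell, post_cell)
        key = (pre_cell.gid, post_cell.gid)
        rng = None
        if pair_rngs is not None and key in pair_rngs:
            rng = pair_rngs[key]

        def _rng():
            nonlocal rng
            if rng is None:
                rng = streams("conn", key[0], key[1])
            return rng

        needs_rng = any(isinstance(v, str)
                        and parse_func_string(v).is_stochastic
                        for v in (rule.get("weight"), rule.get("delay"),
                                  rule.get("loc")) if v is not None)
        use = _rng() if needs_rng else rng
        weight = _resolve(rule.get("weight"), env, use, default=1.0)
        delay = _resolve(rule.get("delay"), env, use, default=1.0)
        if delay < dt:
            raise BuildError(Diagnostic(
                f"connParams.{rule_name}.delay",
                f"resolved delay {delay} ms < dt {dt} ms for pair "
                f"{key}"))
        for mi, mech in enumerate(mechs):
            sec = secs[min(mi, len(secs) - 1)]
            loc = locs[min(mi, len(locs) - 1)]
            loc = _resolve(loc, env, use, default=0.5)
            conns.append(DotDict(
                preGid=pre_cell.gid, postGid=post_cell.gid,
                synMech=mech, sec=sec, loc=loc,
                weight=weight, delay=delay,
                rule=rule_name, ruleIndex=rule_idx))
    return conns


def connect(net_params, cells, sim_config, streams=None, post_order=None):
    """Create connections from all connectivity rules.

    ``post_order`` optionally permutes the iteration order over
    postsynaptic cells (used to verify partition/order invariance); the
    result is independent of it because every decision draws from a
    pair- or cell-keyed stream, and the final list is sorted by
    (postGid, preGid, ruleIndex).
    """
    streams = streams or StreamSet(sim_config["seeds"])
    dt = float(sim_config["dt"])
    allow_self = bool(sim_config.get("allowSelfConns", False))
    conns = []
    for rule_idx, (rule_name, rule) in enumerate(
            net_params.get("connParams", {}).items()):
        pre = _select(cells, rule.get("preConds", {}))
        post = _select(cells, rule.get("postConds", {}))
        if post_order is not None:
            post = post_order(post)
        pairs = []
        pair_rngs = {}
        func = rule.get("connFunc")
        if "connMatrix" in rule:
            mat = rule["connMatrix"]
            for i, pre_cell in enumerate(pre):
                for j, post_cell in enumerate(post):
                    if mat[i][j]:
                        pairs.append((pre_cell, post_cell))
        elif func == "fullConn":
            pairs = [(p, q) for q in post for p in pre
                     if allow_self or p.gid != q.gid]
        elif func == "probConn":
            for post_cell in post:
                for pre_cell in pre:
                    if not allow_self and pre_cell.gid == post_cell.gid:
                        continue
                    rng = streams("conn", pre_cell.gid, post_cell.gid)
                    u = rng.uniform()
                    p = _resolve(rule["probability"],
                                 _pair_env(pre_cell, post_cell), rng)
                    if u < p:
                        pairs.append((pre_cell, post_cell))
                        pair_rngs[(pre_cell.gid, post_cell.gid)] = rng
        elif func in ("convConn", "divConn"):
            anchor, pool = (post, pre) if func == "convConn" else (pre, post)
            for cell in anchor:
                rng = streams("conn", cell.gid, 0)
                tags = _cell_tags(cell)
                env = {f"post_{k}" if func == "convConn" else f"pre_{k}": v
                       for k, v in tags.items()
                       if k in ("x", "y", "z", "xnorm", "ynorm", "znorm")}
                env.update({v: 0.0 for v in
                            ("dist_3D", "dist_2D", "dist_y")})
                k = int(round(_resolve(
                    rule["convergence" if func == "convConn"
                         else "divergence"], env, rng)))
                avail = [c for c in pool
                         if allow_self or c.gid != cell.gid]
                if k > len(avail):
                    raise BuildError(Diagnostic(
                        f"connParams.{rule_name}",
                        f"{func} degree {k} exceeds the {len(avail)} "
                        f"available partners of gid {cell.gid}"))
                chosen = _fisher_yates_sample(avail, k, rng)
                for other in chosen:
                    pairs.append((other, cell) if func == "convConn"
                                 else (cell, other))
        else:
            raise BuildError(Diagnostic(
                f"connParams.{rule_name}.connFunc",
                f"unknown connectivity function {func!r}"))
        conns.extend(_make_conns(rule_name, rule_idx, rule, pre, post,
                                 pairs, dt, streams, pair_rngs))
    conns.sort(key=lambda c: (c.postGid, c.preGid, c.ruleIndex))
    return conns


# ---------------------------------------------------------------------------
# step 4: subcellular synapse distribution

def _segment_density(rule, cell, sim_config):
    """Per-segment sampling weight = density(segment) x segment length."""
    density = rule["density"]
    segs = [seg for sec in cell.secs.values() for seg in sec.segments]
    weights = np.zeros(len(segs))
    if "map1D" in density:
        spec = density["map1D"]
        grid = np.asarray(spec["gridY"], dtype=float)
        vals = np.asarray(spec["gridValues"], dtype=float)
        norm = spec.get("norm")
        if norm is None:
            norm = bool(np.all(grid <= 1.0) and np.all(grid >= 0.0))
        for i, seg in enumerate(segs):
            y = (seg.p0[1] + seg.p1[1]) / 2.0
            if norm:
                y = y / float(sim_config["sizeY"])
            weights[i] = _grid_lookup(grid, vals, y) * seg.L
    elif "map2D" in density:
        spec = density["map2D"]
        gx = np.asarray(spec["gridX"], dtype=float)
        gy = np.asarray(spec["gridY"], dtype=float)
        vals = np.asarray(spec["gridValues"], dtype=float)
        for i, seg in enumerate(segs):
            x = (seg.p0[0] + seg.p1[0]) / 2.0
            y = (seg.p0[1] + seg.p1[1]) / 2.0
            xi = _grid_index(gx, x)
            yi = _grid_index(gy, y)
            v = vals[xi, yi] if xi is not None and yi is not None else 0.0
            weights[i] = v * seg.L
    elif "distance" in density:
        expr = parse_func_string(density["distance"]["expr"],
                                 frozenset({"path_dist"}))
        for i, seg in enumerate(segs):
            weights[i] = max(0.0, expr.eval({"path_dist": seg.pathDist})) \
                * seg.L
    else:  # sectionGroups
        groups = density["sectionGroups"]
        total = sum(groups.values())
        sec_of_group = {}
        for gname in groups:
            named = (cell.get("secLists") or {}).get(gname)
            members = list(named) if named else \
                [s for s in cell.secs if s.startswith(gname)]
            sec_of_group[gname] = members
        for gname, members in sec_of_group.items():
            frac = groups[gname] / total
            glen = sum(cell.secs[s].geom.L for s in members)
            if glen == 0:
                continue
            for i, seg in enumerate(segs):
                if seg.sec in members:
                    weights[i] += frac * seg.L / glen
    return segs, weights


def _grid_lookup(grid, vals, x):
    i = _grid_index(grid, x)
    return 0.0 if i is None else vals[i]


def _grid_index(grid, x):
    """Nearest-bin index; bins are centred on the grid points with
    edges at midpoints; positions beyond the outer half-bin get None
    (zero density).  A single-point grid covers everything."""
    if len(grid) == 1:
        return 0
    half_lo = (grid[1] - grid[0]) / 2.0
    half_hi = (grid[-1] - grid[-2]) / 2.0
    if x < grid[0] - half_lo or x > grid[-1] + half_hi:
        return None
    return int(np.argmin(np.abs(grid - x)))


def distribute_synapses(conns, sub_rules, cells, sim_config, streams=None):
    """Reassign (sec, loc) of matched connections from density rules.

    Connection count is preserved; each reassignment draws from the
    pair's ``synloc`` stream with probability proportional to
    density x segment length, so zero-density segments never receive
    synapses.
    """
    streams = streams or StreamSet(sim_config["seeds"])
    by_gid = {c.gid: c for c in cells}
    for rule_name, rule in (sub_rules or {}).items():
        pre_gids = {c.gid for c in _select(cells, rule.get("preConds", {}))}
        post_sel = [c for c in _select(cells, rule.get("postConds", {}))
                    if c.model == "compartmental"]
        post_gids = {c.gid for c in post_sel}
        cache = {}
        matched = [c for c in conns
                   if c.postGid in post_gids and c.preGid in pre_gids]
        # group by pair: one stream per (pre, post) pair, consumed in
        # deterministic order across all of the pair's connections
        matched.sort(key=lambda c: (c.preGid, c.postGid, c.ruleIndex))
        pair_rng = {}
        for conn in matched:
            cell = by_gid[conn.postGid]
            if conn.postGid not in cache:
                cache[conn.postGid] = _segment_density(rule, cell,
                                                       sim_config)
            segs, weights = cache[conn.postGid]
            total = weights.sum()
            if total <= 0:
                raise BuildError(Diagnostic(
                    f"subConnParams.{rule_name}",
                    f"density is zero over the entire arbor of gid "
                    f"{conn.postGid}"))
            key = (conn.preGid, conn.postGid)
            if key not in pair_rng:
                pair_rng[key] = streams("synloc", *key)
            rng = pair_rng[key]
            idx = int(rng.choice(len(segs), p=weights / total))
            seg = segs[idx]
            nseg = cell.secs[seg.sec].geom.nseg
            conn.sec = seg.sec
            conn.loc = (seg.index + float(rng.uniform())) / nseg
    return conns


# ---------------------------------------------------------------------------
# step 5: stimulation

def netstim_train(rate, noise, start, duration, number, rng):
    """Spike times for an artificial generator.

    noise=0: strictly periodic at ``rate`` starting at ``start``;
    noise=1: Poisson with the same mean rate; in between each interval
    is (1-noise)/rate plus an exponential with mean noise/rate.
    """
    times = []
    if rate <= 0:
        return times
    period = 1000.0 / rate  # ms
    if noise == 0:
        t = start
        while t < duration and len(times) < number:
            times.append(t)
            t += period
        return times
    t = start
    while len(times) < number:
        t += (1.0 - noise) * period + float(rng.exponential(noise * period))
        if t >= duration:
            break
        times.append(t)
    return times


def add_stims(net_params, cells, sim_config, streams=None):
    """Bind stimulation sources to their target cells.

    NetStim spike trains are precomputed from the (stim, gid,
    sourceIndex) stream; IClamp and band-limited noise sources are
    recorded for the engine to realize as currents.
    """
    streams = streams or StreamSet(sim_config["seeds"])
    duration = float(sim_config["duration"])
    sources = net_params.get("stimSourceParams", {})
    src_index = {name: i for i, name in enumerate(sources)}
    stims = []
    for tname, tgt in net_params.get("stimTargetParams", {}).items():
        src_name = tgt.get("source")
        if src_name not in sources:
            raise BuildError(Diagnostic(
                f"stimTargetParams.{tname}.source",
                f"unresolved stim source {src_name!r}"))
        src = sources[src_name]
        targets = _select(cells, tgt.get("conds", {}))
        for cell in targets:
            stype = src["type"]
            if stype == "NetStim":
                rng = streams("stim", cell.gid, src_index[src_name])
                train = netstim_train(
                    float(src.get("rate", 0.0)),
                    float(src.get("noise", 0.0)),
                    float(src.get("start", 0.0)),
                    duration,
                    int(src.get("number", 10 ** 9)),
                    rng)
                stims.append(DotDict(
                    type="NetStim", gid=cell.gid, source=src_name,
                    target=tname, train=train,
                    sec=tgt.get("sec", "soma"), loc=tgt.get("loc", 0.5),
                    synMech=tgt.get("synMech"),
                    weight=float(tgt.get("weight", 1.0)),
                    delay=float(tgt.get("delay", 1.0))))
            elif stype == "IClamp":
                stims.append(DotDict(
                    type="IClamp", gid=cell.gid, source=src_name,
                    target=tname,
                    sec=tgt.get("sec", "soma"), loc=tgt.get("loc", 0.5),
                    **{"del": float(src.get("del", 0.0))},
                    dur=float(src.get("dur", duration)),
                    amp=float(src.get("amp", 0.0))))
            else:  # BandNoise
                stims.append(DotDict(
                    type="BandNoise", gid=cell.gid, source=src_name,
                    target=tname,
                    sec=tgt.get("sec", "soma"), loc=tgt.get("loc", 0.5),
                    fLow=float(src["fLow"]), fHigh=float(src["fHigh"]),
                    amp=float(src.get("amp", 0.0)),
                    seedIndex=src_index[src_name]))
    stims.sort(key=lambda s: (s.gid, s.source, s.target))
    return stims


# ---------------------------------------------------------------------------
# full build

def build_network(spec, validate=True, post_order=None):
    """Instantiate a :class:`Network` from a spec document.

    Runs validation first (raising :class:`BuildError` with the full
    diagnostic list on failure), then the five build steps in order.
    """
    if validate:
        diags = validate_netparams(spec)
        if diags:
            raise BuildError(diags)
    net_params = spec.get("netParams", {})
    sim_config = complete_simconfig(spec.get("simConfig"))
    streams = StreamSet(sim_config["seeds"])
    net = Network(net_params, sim_config)
    net.cells, net.pops = create_populations(net_params, sim_config, streams)
    apply_cell_rules(net.cells, net_params.get("cellParams", {}))
    net.conns = connect(net_params, net.cells, sim_config, streams,
                        post_order=post_order)
    distribute_synapses(net.conns, net_params.get("subConnParams", {}),
                        net.cells, sim_config, streams)
    net.stims = add_stims(net_params, net.cells, sim_config, streams)
    return net
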