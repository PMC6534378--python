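"""Fixed-step simulation backend.

Integrates networks of point neurons (Izhikevich, leaky
integrate-and-fire) and branched multicompartment conductance-based
neurons with exponential synapses, an event queue with per-connection
delays, artificial spike generators, current clamps and band-limited
noise currents.

Numerical scheme
----------------
* Point models: forward Euler (v updated before u for Izhikevich).
* Compartmental cells: backward (implicit) Euler on the branched cable
  equation.  The tree system is solved exactly each step by Hines-style
  elimination, vectorized over tree depth levels so whole populations
  advance with a handful of array operations per level.  Hodgkin-Huxley
  gating variables advance by the Rush-Larsen exact exponential update
  evaluated at the start-of-step voltage.
* Reaction kinetics (if declared) are operator-split: membrane step
  first, then an RK4 reaction step per timestep.

Units: mV, ms, nA, µS, nF (so C·dV/dt, g·V and injected currents are
all in nA).  Synaptic events scheduled by a spike are delivered at
spike time + delay, with delay >= dt enforced at build time.
"""

from __future__ import annotations

import math

import numpy as np

from .diagnostics import BuildError, Diagnostic, SimulationError
from .specs import _conds_match_tags
from .streams import StreamSet

__all__ = ["run", "replay_single_cell", "step_izhikevich", "step_lif",
           "Engine", "spikes_by_gid"]

HH_DEFAULTS = {"gnabar": 0.12, "gkbar": 0.036, "gl": 0.0003,
               "el": -54.3, "ena": 50.0, "ek": -77.0}
PAS_DEFAULTS = {"g": 0.001, "e": -70.0}
KCA_DEFAULTS = {"gmax": 0.01, "kd": 0.001, "e": -77.0, "species": "ca",
                "region": None}

REFRACTORY_DETECT = 2.0  # ms, min interval between compartmental spikes


# ---------------------------------------------------------------------------
# point-model single steps (also used standalone in tests)

def step_izhikevich(state, I, dt, params):
    """One forward-Euler step of the Izhikevich model; returns True on
    a spike (v crossed 30 mV; reset applied)."""
    v, u = state["v"], state["u"]
    if v >= 30.0:
        state["v"] = params["c"]
        state["u"] = u + params["d"]
        return True
    state["v"] = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
    # v is updated first; the recovery variable sees the new v
    state["u"] = u + dt * params["a"] * (params["b"] * state["v"] - u)
    if not math.isfinite(state["v"]):
        raise SimulationError("non-finite Izhikevich state")
    return False


def step_lif(state, I, dt, params):
    """One forward-Euler step of the leaky integrate-and-fire model."""
    if state.get("ref", 0.0) > 0:
        state["ref"] -= dt
        return False
    v = state["v"]
    v += dt / params["tau_m"] * (-(v - params["v_rest"])
                                 + params["r_m"] * I)
    if v >= params["v_thresh"]:
        state["v"] = params["v_reset"]
        state["ref"] = params.get("t_ref", 0.0)
        return True
    state["v"] = v
    return False


# ---------------------------------------------------------------------------
# Hodgkin-Huxley kinetics (classic squid parameters, 6.3 °C)

def _exprel(z):
    """z / (1 - exp(-z)), stable near z = 0."""
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < 1e-6
    safe = np.where(small, 1.0, z)
    return np.where(small, 1.0 + z / 2.0, safe / (-np.expm1(-safe)))


def hh_rates(v):
    v = np.asarray(v, dtype=float)
    am = _exprel((v + 40.0) / 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.1 * _exprel((v + 55.0) / 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


def hh_steady(v):
    am, bm, ah, bh, an, bn = hh_rates(v)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


# ---------------------------------------------------------------------------
# engine

class _CompForest:
    """Flattened compartment arrays for all compartmental cells."""

    def __init__(self):
        self.n = 0
        self.gid = []        # owning cell gid per segment
        self.sec = []        # section name per segment
        self.seg_index = []  # index within section
        self.parent = []     # global parent segment index, -1 for roots
        self.c = []          # nF
        self.area_cm2 = []
        self.p0 = []
        self.p1 = []
        self.diam = []
        self.v = None
        self.seg_of = {}     # (gid, sec, index) -> global index
        self.soma_seg = {}   # gid -> global index of soma segment 0

    def finalize(self, v_init):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.c = np.asarray(self.c)
        self.area_cm2 = np.asarray(self.area_cm2)
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        self.diam = np.asarray(self.diam, dtype=float)
        self.g_ax = np.asarray(self.g_ax)
        self.v = np.full(self.n, v_init)
        # depth levels for vectorized Hines elimination
        depth = np.zeros(self.n, dtype=np.int64)
        for i in range(self.n):
            p = self.parent[i]
            depth[i] = 0 if p < 0 else depth[p] + 1
        self.levels = [np.nonzero(depth == d)[0]
                       for d in range(depth.max() + 1 if self.n else 0)]
        # total axial conductance attached to each segment (self term)
        g_self = np.zeros(self.n)
        idx = np.nonzero(self.parent >= 0)[0]
        np.add.at(g_self, idx, self.g_ax[idx])
        np.add.at(g_self, self.parent[idx], self.g_ax[idx])
        self.g_ax_self = g_self


def _segment_loc_index(cell, sec, loc):
    nseg = cell.secs[sec].geom.nseg
    return min(int(loc * nseg), nseg - 1)


def _topological_sections(secs):
    """Section names, parents before children, in a canonical order
    that does not depend on declaration or serialization order."""
    order, seen = [], set()

    def visit(name):
        if name in seen:
            return
        parent = (secs[name].get("topol") or {}).get("parentSec")
        if parent and parent in secs and parent not in seen:
            visit(parent)
        seen.add(name)
        order.append(name)

    for name in sorted(secs):
        visit(name)
    return order


class Engine:
    def __init__(self, network, external_spikes=None, restrict_gid=None):
        self.net = network
        self.cfg = network.simConfig
        self.dt = float(self.cfg["dt"])
        self.duration = float(self.cfg["duration"])
        self.nsteps = int(round(self.duration / self.dt))
        self.record_every = max(1, int(round(self.cfg["recordStep"]
                                             / self.dt)))
        self.streams = StreamSet(self.cfg["seeds"])
        self.external_spikes = external_spikes
        self.restrict_gid = restrict_gid
        self._compile()

    # -- compilation --------------------------------------------------
    def _compile(self):
        cfg = self.cfg
        cells = self.net.cells
        if self.restrict_gid is not None:
            cells = [c for c in cells if c.gid == self.restrict_gid]
            if not cells:
                raise BuildError(Diagnostic(
                    "replay", f"gid {self.restrict_gid} not in network"))
        self.cells = cells
        local_gids = {c.gid for c in cells}

        # ---- point cells
        self.izhi = [c for c in cells if c.model == "izhi"]
        self.lif = [c for c in cells if c.model == "lif"]
        self.point_index = {}
        for arr, group in (("izhi", self.izhi), ("lif", self.lif)):
            for i, c in enumerate(group):
                self.point_index[c.gid] = (arr, i)
        v0 = float(cfg["vInit"])
        self.izhi_v = np.full(len(self.izhi), v0)
        self.izhi_u = np.array([c.params.b * v0 for c in self.izhi]) \
            if self.izhi else np.zeros(0)
        for name in ("a", "b", "c", "d"):
            setattr(self, f"izhi_{name}_arr",
                    np.array([c.params[name] for c in self.izhi]))
        self.lif_v = np.array([c.params.v_rest for c in self.lif]) \
            if self.lif else np.zeros(0)
        self.lif_ref = np.zeros(len(self.lif))
        for name in ("tau_m", "v_rest", "v_reset", "v_thresh", "r_m",
                     "t_ref"):
            setattr(self, f"lif_{name}",
                    np.array([c.params[name] for c in self.lif]))

        # ---- compartmental forest
        forest = _CompForest()
        forest.g_ax = []
        comp_cells = [c for c in cells if c.model == "compartmental"]
        for cell in comp_cells:
            sec_root_seg = {}
            for sname in _topological_sections(cell.secs):
                sec = cell.secs[sname]
                geom = sec.geom
                nseg = geom.nseg
                seg_L_cm = geom.L / nseg * 1e-4
                cross_cm2 = math.pi * (geom.diam * 1e-4 / 2.0) ** 2
                r_half = geom.Ra * (seg_L_cm / 2.0) / cross_cm2  # ohm
                for seg in sec.segments:
                    gi = forest.n
                    forest.n += 1
                    forest.gid.append(cell.gid)
                    forest.sec.append(sname)
                    forest.seg_index.append(seg.index)
                    area_cm2 = seg.area * 1e-8
                    forest.area_cm2.append(area_cm2)
                    forest.c.append(geom.cm * area_cm2 * 1e3)  # nF
                    forest.p0.append(seg.p0)
                    forest.p1.append(seg.p1)
                    forest.diam.append(seg.diam)
                    forest.seg_of[(cell.gid, sname, seg.index)] = gi
                    if seg.index == 0:
                        sec_root_seg[sname] = gi
                        parent_sec = (sec.topol or {}).get("parentSec")
                        if parent_sec:
                            ploc = float((sec.topol or {}).get(
                                "parentLoc", 1.0))
                            pseg_local = _segment_loc_index(
                                cell, parent_sec, min(ploc, 0.999999))
                            pgi = forest.seg_of[(cell.gid, parent_sec,
                                                 pseg_local)]
                            pgeom = cell.secs[parent_sec].geom
                            pl_cm = pgeom.L / pgeom.nseg * 1e-4
                            pcross = math.pi * (pgeom.diam * 1e-4 / 2) ** 2
                            r = r_half + pgeom.Ra * (pl_cm / 2) / pcross
                            forest.parent.append(pgi)
                            forest.g_ax.append(1e6 / r)  # µS
                        else:
                            forest.parent.append(-1)
                            forest.g_ax.append(0.0)
                    else:
                        forest.parent.append(gi - 1)
                        forest.g_ax.append(1e6 / (2 * r_half))
            forest.soma_seg[cell.gid] = forest.seg_of.get(
                (cell.gid, "soma", 0))
        forest.finalize(v0)
        self.forest = forest

        # ---- membrane mechanisms
        hh_idx, hh_par = [], {k: [] for k in HH_DEFAULTS}
        pas_idx, pas_g, pas_e = [], [], []
        kca_idx, kca_g, kca_kd, kca_e = [], [], [], []
        for cell in comp_cells:
            for sname, sec in cell.secs.items():
                for mech, mpars in sec.mechs.items():
                    for seg in sec.segments:
                        gi = forest.seg_of[(cell.gid, sname, seg.index)]
                        area = forest.area_cm2[gi]
                        if mech == "hh":
                            hh_idx.append(gi)
                            for k in HH_DEFAULTS:
                                v = float(mpars.get(k, HH_DEFAULTS[k]))
                                hh_par[k].append(
                                    v * area * 1e6 if k.startswith("g")
                                    else v)
                        elif mech == "pas":
                            pas_idx.append(gi)
                            pas_g.append(float(mpars.get(
                                "g", PAS_DEFAULTS["g"])) * area * 1e6)
                            pas_e.append(float(mpars.get(
                                "e", PAS_DEFAULTS["e"])))
                        elif mech == "kca":
                            kca_idx.append(gi)
                            kca_g.append(float(mpars.get(
                                "gmax", KCA_DEFAULTS["gmax"])) * area * 1e6)
                            kca_kd.append(float(mpars.get(
                                "kd", KCA_DEFAULTS["kd"])))
                            kca_e.append(float(mpars.get(
                                "e", KCA_DEFAULTS["e"])))
        self.hh_idx = np.asarray(hh_idx, dtype=np.int64)
        self.hh = {k: np.asarray(v) for k, v in hh_par.items()}
        vh = forest.v[self.hh_idx] if len(hh_idx) else np.zeros(0)
        self.hh_m, self.hh_h, self.hh_n = hh_steady(vh)
        self.pas_idx = np.asarray(pas_idx, dtype=np.int64)
        self.pas_g = np.asarray(pas_g)
        self.pas_e = np.asarray(pas_e)
        self.kca_idx = np.asarray(kca_idx, dtype=np.int64)
        self.kca_g = np.asarray(kca_g)
        self.kca_kd = np.asarray(kca_kd)
        self.kca_e = np.asarray(kca_e)

        # ---- reaction kinetics
        self.rxd = None
        rxd_params = self.net.netParams.get("rxdParams") or {}
        if rxd_params:
            from .rxd import build_reaction_system
            self.rxd = build_reaction_system(rxd_params, self.net,
                                             cells=comp_cells,
                                             forest=forest)

        # ---- synapses
        syn_mechs = self.net.netParams.get("synMechParams", {})
        self._syn_mode = []
        self._syn_kind = []
        self._syn_target = []
        self._syn_e = []
        self._syn_d1 = []
        self._syn_d2 = []
        self._syn_factor = []
        self.schedule = {}
        self.efferent = {}

        def add_synapse(gid, sec, loc, mech_name):
            mech = syn_mechs[mech_name]
            cell = self._cell_by_gid[gid]
            if cell.model == "compartmental":
                kind, target = 0, self.forest.seg_of[
                    (gid, sec, _segment_loc_index(cell, sec, loc))]
            else:
                arr, i = self.point_index[gid]
                kind, target = (1, i) if arr == "izhi" else (2, i)
            mode = mech.get("mode", "exp")
            self._syn_mode.append(0 if mode == "exp" else 1)
            self._syn_kind.append(kind)
            self._syn_target.append(target)
            self._syn_e.append(float(mech.get("e", 0.0)))
            if mode == "exp":
                self._syn_d1.append(math.exp(-self.dt / mech["tau"]))
                self._syn_d2.append(1.0)
                self._syn_factor.append(1.0)
            else:
                t1, t2 = mech["tau1"], mech["tau2"]
                tp = t1 * t2 / (t2 - t1) * math.log(t2 / t1)
                factor = 1.0 / (-math.exp(-tp / t1) + math.exp(-tp / t2))
                self._syn_d1.append(math.exp(-self.dt / t1))
                self._syn_d2.append(math.exp(-self.dt / t2))
                self._syn_factor.append(factor)
            return len(self._syn_mode) - 1

        self._cell_by_gid = {c.gid: c for c in cells}

        for conn in self.net.conns:
            if conn.postGid not in local_gids:
                continue
            delay_steps = int(round(conn.delay / self.dt))
            if delay_steps < 1:
                raise BuildError(Diagnostic(
                    f"conns[{conn.preGid}->{conn.postGid}]",
                    f"delay {conn.delay} ms < dt {self.dt} ms"))
            si = add_synapse(conn.postGid, conn.sec, conn.loc, conn.synMech)
            if conn.preGid in local_gids:
                self.efferent.setdefault(conn.preGid, []).append(
                    (si, float(conn.weight), delay_steps))
            else:
                times = self._external_times(conn.preGid)
                for ts in times:
                    step = int(round(ts / self.dt)) + delay_steps
                    if 0 <= step < self.nsteps:
                        self.schedule.setdefault(step, []).append(
                            (si, float(conn.weight)))

        # ---- stimulation
        self.iclamps = []     # (kind, index, start_step, end_step, amp)
        self.noise_wavs = []  # (kind, index, waveform)
        for stim in self.net.stims:
            if stim.gid not in local_gids:
                continue
            cell = self._cell_by_gid[stim.gid]
            if stim.type == "NetStim":
                if stim.synMech is None:
                    raise BuildError(Diagnostic(
                        f"stims[{stim.target}]",
                        "NetStim targets need a synMech"))
                si = add_synapse(stim.gid, stim.sec, stim.loc, stim.synMech)
                delay_steps = max(1, int(round(stim.delay / self.dt)))
                for ts in stim.train:
                    step = int(round(ts / self.dt)) + delay_steps
                    if 0 <= step < self.nsteps:
                        self.schedule.setdefault(step, []).append(
                            (si, float(stim.weight)))
            else:
                if cell.model == "compartmental":
                    kind = 0
                    target = self.forest.seg_of[
                        (stim.gid, stim.sec,
                         _segment_loc_index(cell, stim.sec, stim.loc))]
                else:
                    arr, i = self.point_index[stim.gid]
                    kind, target = (1, i) if arr == "izhi" else (2, i)
                if stim.type == "IClamp":
                    start = int(round(stim["del"] / self.dt))
                    end = int(round((stim["del"] + stim.dur) / self.dt))
                    self.iclamps.append((kind, target, start, end,
                                         stim.amp))
                else:  # BandNoise
                    rng = self.streams("stim", stim.gid, stim.seedIndex)
                    wav = band_noise(self.nsteps, self.dt, stim.fLow,
                                     stim.fHigh, stim.amp, rng)
                    self.noise_wavs.append((kind, target, wav))

        for name in ("_syn_mode", "_syn_kind", "_syn_target"):
            setattr(self, name, np.asarray(getattr(self, name),
                                           dtype=np.int64))
        for name in ("_syn_e", "_syn_d1", "_syn_d2", "_syn_factor"):
            setattr(self, name, np.asarray(getattr(self, name),
                                           dtype=float))
        nsyn = len(self._syn_mode)
        self.syn_g = np.zeros(nsyn)   # exp state
        self.syn_A = np.zeros(nsyn)   # exp2 rising state
        self.syn_B = np.zeros(nsyn)   # exp2 decaying state
        self._is_exp = self._syn_mode == 0

        # ---- recording plan
        self.trace_plan = []
        for label, tr in (self.cfg.get("recordTraces") or {}).items():
            conds = tr.get("conds", {})
            var = tr.get("var", "v")
            for cell in cells:
                tags = dict(cell.tags)
                tags["pop"] = cell["pop"]
                tags["gid"] = cell.gid
                if "gid" in conds:
                    want = conds["gid"]
                    if cell.gid not in (want if isinstance(want, list)
                                        else [want]):
                        continue
                    rest = {k: v for k, v in conds.items() if k != "gid"}
                else:
                    rest = conds
                if not _conds_match_tags(rest, tags):
                    continue
                self.trace_plan.append(
                    (label, cell.gid, var,
                     tr.get("sec", "soma"), float(tr.get("loc", 0.5))))
        self.lfp_on = bool(self.cfg.get("recordLFP"))

    def _external_times(self, pre_gid):
        ext = self.external_spikes
        if ext is None:
            return []
        if isinstance(ext, dict) and "spkt" in ext:
            return [t for t, g in zip(ext["spkt"], ext["spkid"])
                    if g == pre_gid]
        if pre_gid not in ext:
            raise BuildError(Diagnostic(
                "replay",
                f"saved spikes missing presynaptic gid {pre_gid}"))
        return list(ext[pre_gid])

    # -- main loop ----------------------------------------------------
    def run(self):
        dt = self.dt
        forest = self.forest
        nseg = forest.n
        rec_steps = list(range(0, self.nsteps + 1, self.record_every))
        rec_times = [s * dt for s in rec_steps]
        n_rec = len(rec_steps)

        spkt, spkid = [], []
        traces = {label: {} for label, *_ in self.trace_plan}
        trace_bufs = []
        for label, gid, var, sec, loc in self.trace_plan:
            buf = np.zeros(n_rec)
            traces[label][str(gid)] = buf
            trace_bufs.append((label, gid, var, sec, loc, buf))
        imem = np.zeros((nseg, n_rec)) if (self.lfp_on and nseg) else None
        ipoint = None
        if self.lfp_on and (len(self.izhi) + len(self.lif)):
            ipoint = np.zeros((len(self.izhi) + len(self.lif), n_rec))

        comp_last_spike = {g: -1e9 for g in forest.soma_seg}
        prev_above = {g: False for g in forest.soma_seg}

        c_over_dt = forest.c / dt if nseg else np.zeros(0)
        rec_ptr = 0

        def sample(step, i_mem_vec, i_pt_vec):
            nonlocal rec_ptr
            for label, gid, var, sec, loc, buf in trace_bufs:
                buf[rec_ptr] = self._read_var(gid, var, sec, loc)
            if imem is not None and i_mem_vec is not None:
                imem[:, rec_ptr] = i_mem_vec
            if ipoint is not None and i_pt_vec is not None:
                ipoint[:, rec_ptr] = i_pt_vec
            rec_ptr += 1

        sample(0, np.zeros(nseg) if imem is not None else None,
               np.zeros(len(self.izhi) + len(self.lif))
               if ipoint is not None else None)

        for step in range(self.nsteps):
            t_next = (step + 1) * dt
            # 1. deliver due events
            events = self.schedule.pop(step, None)
            if events:
                idx = np.fromiter((e[0] for e in events), dtype=np.int64,
                                  count=len(events))
                w = np.fromiter((e[1] for e in events), dtype=float,
                                count=len(events))
                exp_mask = self._is_exp[idx]
                np.add.at(self.syn_g, idx[exp_mask], w[exp_mask])
                nm = ~exp_mask
                wf = w[nm] * self._syn_factor[idx[nm]]
                np.add.at(self.syn_A, idx[nm], wf)
                np.add.at(self.syn_B, idx[nm], wf)

            # 2. synaptic conductances onto targets
            g_now = np.where(self._is_exp, self.syn_g,
                             self.syn_B - self.syn_A)
            gsum_seg = np.zeros(nseg)
            ge_seg = np.zeros(nseg)
            i_syn_izhi = np.zeros(len(self.izhi))
            i_syn_lif = np.zeros(len(self.lif))
            if len(g_now):
                comp_m = self._syn_kind == 0
                np.add.at(gsum_seg, self._syn_target[comp_m], g_now[comp_m])
                np.add.at(ge_seg, self._syn_target[comp_m],
                          g_now[comp_m] * self._syn_e[comp_m])
                izhi_m = self._syn_kind == 1
                if izhi_m.any():
                    np.add.at(i_syn_izhi, self._syn_target[izhi_m],
                              g_now[izhi_m] * (self._syn_e[izhi_m]
                                               - self.izhi_v[
                                                   self._syn_target[izhi_m]]))
                lif_m = self._syn_kind == 2
                if lif_m.any():
                    np.add.at(i_syn_lif, self._syn_target[lif_m],
                              g_now[lif_m] * (self._syn_e[lif_m]
                                              - self.lif_v[
                                                  self._syn_target[lif_m]]))

            # 3. injected currents
            istim_seg = np.zeros(nseg)
            istim_izhi = np.zeros(len(self.izhi))
            istim_lif = np.zeros(len(self.lif))
            for kind, target, start, end, amp in self.iclamps:
                if start <= step < end:
                    (istim_seg, istim_izhi, istim_lif)[kind][target] += amp
            for kind, target, wav in self.noise_wavs:
                (istim_seg, istim_izhi, istim_lif)[kind][target] += \
                    wav[step]

            # 4. compartmental implicit step
            i_mem_vec = None
            if nseg:
                v_old = forest.v
                g_mem = np.zeros(nseg)
                ge_mem = np.zeros(nseg)
                if len(self.hh_idx):
                    vh = v_old[self.hh_idx]
                    am, bm, ah, bh, an, bn = hh_rates(vh)
                    self.hh_m = self._rl(self.hh_m, am, bm, dt)
                    self.hh_h = self._rl(self.hh_h, ah, bh, dt)
                    self.hh_n = self._rl(self.hh_n, an, bn, dt)
                    gna = self.hh["gnabar"] * self.hh_m ** 3 * self.hh_h
                    gk = self.hh["gkbar"] * self.hh_n ** 4
                    gl = self.hh["gl"]
                    np.add.at(g_mem, self.hh_idx, gna + gk + gl)
                    np.add.at(ge_mem, self.hh_idx,
                              gna * self.hh["ena"] + gk * self.hh["ek"]
                              + gl * self.hh["el"])
                if len(self.pas_idx):
                    np.add.at(g_mem, self.pas_idx, self.pas_g)
                    np.add.at(ge_mem, self.pas_idx,
                              self.pas_g * self.pas_e)
                if len(self.kca_idx) and self.rxd is not None:
                    ca = self.rxd.concentration_at(self.kca_idx, "ca")
                    gk = self.kca_g * ca / (ca + self.kca_kd)
                    np.add.at(g_mem, self.kca_idx, gk)
                    np.add.at(ge_mem, self.kca_idx, gk * self.kca_e)

                diag = c_over_dt + g_mem + gsum_seg + forest.g_ax_self
                rhs = c_over_dt * v_old + ge_mem + ge_seg + istim_seg
                v_new = self._hines_solve(diag.copy(), rhs.copy())
                if not np.all(np.isfinite(v_new)):
                    bad = int(np.nonzero(~np.isfinite(v_new))[0][0])
                    raise SimulationError(
                        "non-finite membrane potential",
                        t=t_next, gid=forest.gid[bad])
                if imem is not None:
                    i_mem_vec = (c_over_dt * (v_new - v_old)
                                 + g_mem * v_new - ge_mem
                                 + gsum_seg * v_new - ge_seg)
                forest.v = v_new

            # 5. point-model steps
            new_spikes = []
            if len(self.izhi):
                v, u = self.izhi_v, self.izhi_u
                I = i_syn_izhi + istim_izhi
                fired = v >= 30.0
                if fired.any():
                    for i in np.nonzero(fired)[0]:
                        new_spikes.append(self.izhi[i].gid)
                    v[fired] = self.izhi_c_arr[fired]
                    u[fired] += self.izhi_d_arr[fired]
                nf = ~fired
                vn = v[nf]
                v[nf] = vn + dt * (0.04 * vn * vn + 5.0 * vn + 140.0
                                   - u[nf] + I[nf])
                # v is updated first; the recovery variable sees new v
                u[nf] += dt * self.izhi_a_arr[nf] * (
                    self.izhi_b_arr[nf] * v[nf] - u[nf])
                if not np.all(np.isfinite(v)):
                    bad = int(np.nonzero(~np.isfinite(v))[0][0])
                    raise SimulationError("non-finite Izhikevich state",
                                          t=t_next,
                                          gid=self.izhi[bad].gid)
            if len(self.lif):
                v = self.lif_v
                I = i_syn_lif + istim_lif
                active = self.lif_ref <= 0
                self.lif_ref[~active] -= dt
                vn = v[active] + dt / self.lif_tau_m[active] * (
                    -(v[active] - self.lif_v_rest[active])
                    + self.lif_r_m[active] * I[active])
                v[active] = vn
                fired = active.copy()
                fired[active] = vn >= self.lif_v_thresh[active]
                if fired.any():
                    for i in np.nonzero(fired)[0]:
                        new_spikes.append(self.lif[i].gid)
                    v[fired] = self.lif_v_reset[fired]
                    self.lif_ref[fired] = self.lif_t_ref[fired]

            # 6. compartmental spike detection (somatic crossing)
            thresh = float(self.cfg["spikeThreshold"])
            for gid, seg in forest.soma_seg.items():
                if seg is None:
                    continue
                above = forest.v[seg] >= thresh
                if above and not prev_above[gid] \
                        and t_next - comp_last_spike[gid] \
                        >= REFRACTORY_DETECT:
                    comp_last_spike[gid] = t_next
                    new_spikes.append(gid)
                prev_above[gid] = above

            # 7. route spikes
            for gid in new_spikes:
                spkt.append(t_next)
                spkid.append(gid)
                for si, w, dsteps in self.efferent.get(gid, ()):
                    target_step = step + 1 + dsteps
                    if target_step < self.nsteps:
                        self.schedule.setdefault(target_step, []).append(
                            (si, w))

            # 8. reaction kinetics (operator split)
            if self.rxd is not None:
                self.rxd.step(dt, engine=self)

            # 9. synaptic state decay
            self.syn_g *= self._syn_d1 * self._is_exp \
                + (1.0 - self._is_exp)
            self.syn_A *= self._syn_d1
            self.syn_B *= self._syn_d2

            # 10. recording
            if (step + 1) % self.record_every == 0:
                ipt = None
                if ipoint is not None:
                    ipt = np.concatenate([i_syn_izhi + istim_izhi,
                                          i_syn_lif + istim_lif])
                sample(step + 1, i_mem_vec, ipt)

        order = np.lexsort((np.asarray(spkid, dtype=float),
                            np.asarray(spkt, dtype=float)))
        spkt = [float(spkt[i]) for i in order]
        spkid = [int(spkid[i]) for i in order]

        out = {
            "t": rec_times,
            "spkt": spkt,
            "spkid": spkid,
            "traces": {label: {g: [float(x) for x in buf]
                               for g, buf in d.items()}
                       for label, d in traces.items()},
            "popRates": self._pop_rates(spkid),
        }
        if self.lfp_on:
            out["lfp"] = self._compute_lfp(imem, ipoint)
        self._imem = imem  # exposed for diagnostics/tests
        return out

    # -- helpers ------------------------------------------------------
    @staticmethod
    def _rl(x, a, b, dt):
        """Rush-Larsen exact exponential gate update."""
        tau = 1.0 / (a + b)
        inf = a * tau
        return inf + (x - inf) * np.exp(-dt / tau)

    def _hines_solve(self, diag, rhs):
        forest = self.forest
        off = forest.g_ax  # coupling conductance to parent (negative off-diag)
        for level in reversed(forest.levels[1:]):
            p = forest.parent[level]
            f = off[level] / diag[level]
            np.add.at(diag, p, -f * off[level])
            np.add.at(rhs, p, f * rhs[level])
        v = np.zeros(forest.n)
        root = forest.levels[0] if forest.levels else []
        v[root] = rhs[root] / diag[root]
        for level in forest.levels[1:]:
            p = forest.parent[level]
            v[level] = (rhs[level] + off[level] * v[p]) / diag[level]
        return v

    def _read_var(self, gid, var, sec, loc):
        cell = self._cell_by_gid[gid]
        if cell.model == "compartmental":
            if var == "v":
                si = self.forest.seg_of[
                    (gid, sec, _segment_loc_index(cell, sec, loc))]
                return float(self.forest.v[si])
            if self.rxd is not None and var in self.rxd.species_names:
                si = self.forest.seg_of[
                    (gid, sec, _segment_loc_index(cell, sec, loc))]
                return float(self.rxd.concentration_at(
                    np.array([si]), var)[0])
            return 0.0
        arr, i = self.point_index[gid]
        if arr == "izhi":
            return float(self.izhi_v[i] if var == "v" else self.izhi_u[i])
        return float(self.lif_v[i])

    def _pop_rates(self, spkid):
        counts = {}
        for g in spkid:
            counts[g] = counts.get(g, 0) + 1
        rates = {}
        for pname, pop in self.net.pops.items():
            gids = [g for g in pop.cellGids
                    if self.restrict_gid is None
                    or g == self.restrict_gid]
            if not gids:
                continue
            total = sum(counts.get(g, 0) for g in gids)
            rates[pname] = total / len(gids) / (self.duration / 1000.0)
        return rates

    def _compute_lfp(self, imem, ipoint):
        from .lfp import ElectrodeArray
        electrodes = self.cfg["recordLFP"]
        sigma = float(self.cfg.get("sigma", 0.3))
        array = ElectrodeArray(electrodes, sigma=sigma)
        n_rec = len(range(0, self.nsteps + 1, self.record_every))
        total = np.zeros((len(electrodes), n_rec))
        if imem is not None and self.forest.n:
            tr = array.transfer_segments(self.forest.p0, self.forest.p1,
                                         self.forest.diam)
            total += 1000.0 * (tr @ imem)  # MΩ x nA -> mV; report µV
        if ipoint is not None and self.cfg.get("lfpIncludePoint"):
            pos = np.array([[c.tags.x, c.tags.y, c.tags.z]
                            for c in self.izhi + self.lif])
            tr = array.transfer_points(pos)
            total += 1000.0 * (tr @ ipoint)
        return [[float(x) for x in row] for row in total]


def band_noise(nsteps, dt, f_low, f_high, amp, rng):
    """Gaussian white noise spectrally masked to [f_low, f_high] Hz and
    scaled to RMS = amp (nA)."""
    white = rng.standard_normal(nsteps)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(nsteps, dt * 1e-3)
    spec[(freqs < f_low) | (freqs > f_high)] = 0.0
    wav = np.fft.irfft(spec, n=nsteps)
    rms = np.sqrt(np.mean(wav ** 2))
    return wav * (amp / rms) if rms > 0 else wav


def run(network):
    """Simulate an instantiated network; returns the SimOutput dict."""
    return Engine(network).run()


def spikes_by_gid(output):
    """Regroup a SimOutput's spike lists into {gid: [times]}."""
    spikes = {}
    for t, g in zip(output["spkt"], output["spkid"]):
        spikes.setdefault(int(g), []).append(float(t))
    return spikes


def replay_single_cell(saved_spikes, network, gid, sim_config=None):
    """Re-simulate one cell, replaying its recorded afferent spikes.

    ``saved_spikes`` is either a SimOutput dict (with spkt/spkid) or a
    {gid: [times]} mapping that must cover every presynaptic gid of the
    replayed cell.  The somatic trajectory matches the full-network run
    to solver tolerance because the cell's arithmetic is identical.
    """
    if sim_config is not None:
        import copy as _copy
        network = _copy.deepcopy(network)
        network.simConfig = sim_config
    eng = Engine(network, external_spikes=saved_spikes, restrict_gid=gid)
    return eng.run()
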