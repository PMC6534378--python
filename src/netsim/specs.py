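"""Declarative model specification: schema defaults and validation.

A model is one JSON-compatible document::

    {"netParams": {...}, "simConfig": {...}}

``netParams`` holds the biological description (populations, cell
rules, synaptic mechanisms, connectivity rules, subcellular synapse
distribution rules, stimulation, reaction kinetics); ``simConfig``
holds per-run options, every one of which has a default.  Documents are
order-free: a rule may reference a label declared later; references are
resolved only here, at validation time.

Units: µm (space), ms (time), mV (voltage), nA (point currents), µS
(synaptic peak conductance), S/cm² (density conductances), Ω·cm (axial
resistivity), µF/cm² (specific capacitance), mM (concentrations),
cells/mm³ (density).  The network bounding box is ``sizeX × sizeY ×
sizeZ`` µm with y the cortical-depth axis: ynorm 0 at the pia, 1 at
the white matter.
"""

from __future__ import annotations

import copy
import json
import math

from .diagnostics import Diagnostic
from .funcstring import (DEFAULT_VARIABLES, FuncString, FuncStringError,
                         parse_func_string)

__all__ = [
    "SIM_DEFAULTS",
    "complete_simconfig",
    "validate_netparams",
    "spec_roundtrip",
    "canonical_json",
]

CELL_MODELS = ("izhi", "lif", "compartmental")
CONN_FUNCS = ("fullConn", "probConn", "convConn", "divConn")
MECHANISMS = ("hh", "pas", "kca")
STIM_TYPES = ("IClamp", "NetStim", "BandNoise")

SIM_DEFAULTS = {
    "duration": 1000.0,          # ms
    "dt": 0.025,                 # ms
    "sizeX": 100.0,              # µm
    "sizeY": 100.0,
    "sizeZ": 100.0,
    "seeds": {"global": 1, "conn": 1, "loc": 1, "stim": 1},
    "recordTraces": {},
    "recordLFP": [],             # list of [x, y, z] electrode positions, µm
    "recordStep": 0.1,           # ms
    "saveJson": None,
    "verbose": False,
    "vInit": -65.0,              # mV
    "spikeThreshold": 0.0,       # mV, somatic crossing for compartmental cells
    "sigma": 0.3,                # S/m, extracellular conductivity
    "lfpIncludePoint": False,    # include point-cell contributions to LFP
    "allowSelfConns": False,
}

_PRE_POST_VARS = DEFAULT_VARIABLES
_DIST_VARS = frozenset({"path_dist"})


def complete_simconfig(cfg=None):
    """Return a fully-defaulted copy of a (possibly partial) simConfig."""
    out = copy.deepcopy(SIM_DEFAULTS)
    for key, val in (cfg or {}).items():
        if key == "seeds":
            out["seeds"].update(val)
        else:
            out[key] = copy.deepcopy(val)
    return out


# ---------------------------------------------------------------------------
# validation helpers

def _is_num(x):
    return isinstance(x, (int, float)) and not isinstance(x, bool) \
        and math.isfinite(x)


def _check_range(diags, path, rng, lo_bound=None, hi_bound=None):
    if (not isinstance(rng, (list, tuple)) or len(rng) != 2
            or not all(_is_num(v) for v in rng)):
        diags.append(Diagnostic(path, "range must be [lo, hi] numbers"))
        return
    lo, hi = rng
    if lo > hi:
        diags.append(Diagnostic(path, f"range lo {lo} > hi {hi}"))
    if lo_bound is not None and (lo < lo_bound or hi > hi_bound):
        diags.append(Diagnostic(
            path, f"range must lie within [{lo_bound}, {hi_bound}]"))


def _check_funcstring(diags, path, value, variables=_PRE_POST_VARS):
    if isinstance(value, str):
        try:
            parse_func_string(value, variables)
        except FuncStringError as err:
            diags.append(Diagnostic(path, f"bad expression: {err}"))
        return True
    return False


def _num_or_funcstring(diags, path, value, minimum=None,
                       variables=_PRE_POST_VARS):
    if value is None:
        return
    if _check_funcstring(diags, path, value, variables):
        return
    if not _is_num(value):
        diags.append(Diagnostic(path, "must be a number or expression string"))
    elif minimum is not None and value < minimum:
        diags.append(Diagnostic(path, f"must be >= {minimum}"))


def _check_conds(diags, path, conds):
    if not isinstance(conds, dict):
        diags.append(Diagnostic(path, "conds must be a mapping"))
        return
    for attr, val in conds.items():
        if attr not in ("pop", "cellType", "x", "y", "z",
                        "xnorm", "ynorm", "znorm", "gid"):
            diags.append(Diagnostic(f"{path}.{attr}",
                                    f"unknown cell attribute {attr!r}"))


# ---------------------------------------------------------------------------
# per-section validation

def _validate_sections(diags, path, secs):
    if not isinstance(secs, dict) or not secs:
        diags.append(Diagnostic(path, "secs must be a non-empty mapping"))
        return
    for sname, sec in secs.items():
        spath = f"{path}.{sname}"
        if not isinstance(sec, dict):
            diags.append(Diagnostic(spath, "section must be a mapping"))
            continue
        geom = sec.get("geom", {})
        for par in ("L", "diam", "Ra", "cm"):
            val = geom.get(par)
            if val is None or not _is_num(val) or val <= 0:
                diags.append(Diagnostic(f"{spath}.geom.{par}",
                                        "must be a positive number"))
        nseg = geom.get("nseg", 1)
        if not isinstance(nseg, int) or isinstance(nseg, bool) or nseg < 1:
            diags.append(Diagnostic(f"{spath}.geom.nseg",
                                    "must be a positive integer"))
        topol = sec.get("topol", {})
        parent = topol.get("parentSec")
        if parent is not None:
            if parent not in secs:
                diags.append(Diagnostic(f"{spath}.topol.parentSec",
                                        f"unknown parent section {parent!r}"))
            for par in ("parentLoc", "childLoc"):
                val = topol.get(par, 0.0 if par == "childLoc" else 1.0)
                if not _is_num(val) or not 0.0 <= val <= 1.0:
                    diags.append(Diagnostic(f"{spath}.topol.{par}",
                                            "must be in [0, 1]"))
        for mname, mpars in sec.get("mechs", {}).items():
            if mname not in MECHANISMS:
                diags.append(Diagnostic(
                    f"{spath}.mechs.{mname}",
                    f"unknown mechanism (supported: {', '.join(MECHANISMS)})"))
            elif not isinstance(mpars, dict):
                diags.append(Diagnostic(f"{spath}.mechs.{mname}",
                                        "parameters must be a mapping"))
        pt3d = sec.get("pt3d")
        if pt3d is not None:
            if (not isinstance(pt3d, list) or len(pt3d) < 2 or not all(
                    isinstance(p, (list, tuple)) and len(p) == 4
                    and all(_is_num(v) for v in p) for p in pt3d)):
                diags.append(Diagnostic(
                    f"{spath}.pt3d",
                    "must be a list of >= 2 (x, y, z, diam) points"))
    # topology must form a tree with a single root
    roots = [s for s, sec in secs.items()
             if isinstance(sec, dict)
             and not (sec.get("topol") or {}).get("parentSec")]
    if len(roots) != 1:
        diags.append(Diagnostic(path,
                                f"topology must have exactly one root "
                                f"section, found {len(roots)}"))
    # cycle check by walking parents
    for sname in secs:
        seen, cur = set(), sname
        while cur is not None:
            if cur in seen:
                diags.append(Diagnostic(f"{path}.{sname}",
                                        "cycle in section topology"))
                break
            seen.add(cur)
            sec = secs.get(cur)
            cur = (sec.get("topol") or {}).get("parentSec") \
                if isinstance(sec, dict) else None


def _validate_density(diags, path, density):
    if not isinstance(density, dict):
        diags.append(Diagnostic(path, "density must be a mapping"))
        return
    kinds = [k for k in ("map1D", "map2D", "distance", "sectionGroups")
             if k in density]
    if len(kinds) != 1:
        diags.append(Diagnostic(
            path, "density must give exactly one of map1D / map2D / "
                  "distance / sectionGroups"))
        return
    kind = kinds[0]
    spec = density[kind]
    if kind == "map1D":
        gy, gv = spec.get("gridY"), spec.get("gridValues")
        if not (isinstance(gy, list) and isinstance(gv, list)
                and len(gy) == len(gv) and len(gy) > 0):
            diags.append(Diagnostic(f"{path}.map1D",
                                    "gridY and gridValues must be equal-"
                                    "length non-empty lists"))
            return
        if any(not _is_num(v) or v < 0 for v in gv):
            diags.append(Diagnostic(f"{path}.map1D.gridValues",
                                    "densities must be >= 0"))
        elif not any(v > 0 for v in gv):
            diags.append(Diagnostic(f"{path}.map1D.gridValues",
                                    "densities must not all be zero"))
    elif kind == "map2D":
        gx, gy, gv = spec.get("gridX"), spec.get("gridY"), spec.get("gridValues")
        ok = (isinstance(gx, list) and isinstance(gy, list)
              and isinstance(gv, list) and len(gv) == len(gx)
              and all(isinstance(r, list) and len(r) == len(gy) for r in gv))
        if not ok:
            diags.append(Diagnostic(
                f"{path}.map2D",
                "gridValues must be a |gridX| x |gridY| matrix"))
            return
        flat = [v for row in gv for v in row]
        if any(not _is_num(v) or v < 0 for v in flat):
            diags.append(Diagnostic(f"{path}.map2D.gridValues",
                                    "densities must be >= 0"))
        elif not any(v > 0 for v in flat):
            diags.append(Diagnostic(f"{path}.map2D.gridValues",
                                    "densities must not all be zero"))
    elif kind == "distance":
        _check_funcstring(diags, f"{path}.distance", spec.get("expr", ""),
                          _DIST_VARS)
    else:  # sectionGroups
        if not isinstance(spec, dict) or not spec:
            diags.append(Diagnostic(f"{path}.sectionGroups",
                                    "must be a non-empty mapping"))
            return
        if any(not _is_num(v) or v < 0 for v in spec.values()):
            diags.append(Diagnostic(f"{path}.sectionGroups",
                                    "fractions must be >= 0"))
        elif sum(spec.values()) <= 0:
            diags.append(Diagnostic(f"{path}.sectionGroups",
                                    "fractions must not all be zero"))


# ---------------------------------------------------------------------------
# main validator

def validate_netparams(spec):
    """Validate a full spec document; return a list of diagnostics.

    An empty list means every invariant holds and every cross-reference
    (pop labels, cell types, synaptic mechanisms, stim sources)
    resolves.  Validation never raises on malformed content and never
    mutates its input.
    """
    diags = []
    if not isinstance(spec, dict):
        return [Diagnostic("", "document must be a JSON object")]
    net = spec.get("netParams", spec)
    if not isinstance(net, dict):
        return [Diagnostic("netParams", "must be a JSON object")]
    cfg = complete_simconfig(spec.get("simConfig")
                             if isinstance(spec.get("simConfig"), dict)
                             else {})

    pops = net.get("popParams", {})
    cells = net.get("cellParams", {})
    syns = net.get("synMechParams", {})
    conns = net.get("connParams", {})
    subconns = net.get("subConnParams", {})
    stim_src = net.get("stimSourceParams", {})
    stim_tgt = net.get("stimTargetParams", {})
    rxd = net.get("rxdParams", {})
    for name, section in (("popParams", pops), ("cellParams", cells),
                          ("synMechParams", syns), ("connParams", conns),
                          ("subConnParams", subconns),
                          ("stimSourceParams", stim_src),
                          ("stimTargetParams", stim_tgt),
                          ("rxdParams", rxd)):
        if not isinstance(section, dict):
            return [Diagnostic(f"netParams.{name}", "must be a JSON object")]

    # --- simConfig invariants
    if not _is_num(cfg["duration"]) or cfg["duration"] <= 0:
        diags.append(Diagnostic("simConfig.duration", "must be > 0"))
    if not _is_num(cfg["dt"]) or cfg["dt"] <= 0:
        diags.append(Diagnostic("simConfig.dt", "must be > 0"))
    elif cfg["dt"] > cfg["recordStep"]:
        diags.append(Diagnostic("simConfig.recordStep",
                                "must be >= dt"))
    for ax in ("sizeX", "sizeY", "sizeZ"):
        if not _is_num(cfg[ax]) or cfg[ax] <= 0:
            diags.append(Diagnostic(f"simConfig.{ax}", "must be > 0"))

    # --- populations
    cell_types = set()
    for pname, pop in pops.items():
        path = f"popParams.{pname}"
        if not isinstance(pop, dict):
            diags.append(Diagnostic(path, "population must be a mapping"))
            continue
        cell_types.add(pop.get("cellType"))
        has_n = "numCells" in pop
        has_d = "density" in pop
        if has_n == has_d:
            diags.append(Diagnostic(
                path, "exactly one of numCells / density must be given"))
        if has_n and (not isinstance(pop["numCells"], int)
                      or isinstance(pop["numCells"], bool)
                      or pop["numCells"] < 0):
            diags.append(Diagnostic(f"{path}.numCells",
                                    "must be a nonnegative integer"))
        if has_d and (not _is_num(pop["density"]) or pop["density"] < 0):
            diags.append(Diagnostic(f"{path}.density", "must be >= 0"))
        model = pop.get("cellModel", "compartmental")
        if model not in CELL_MODELS:
            diags.append(Diagnostic(
                f"{path}.cellModel",
                f"must be one of {', '.join(CELL_MODELS)}"))
        for ax in ("x", "y", "z"):
            if f"{ax}Range" in pop:
                _check_range(diags, f"{path}.{ax}Range", pop[f"{ax}Range"])
            if f"{ax}normRange" in pop:
                _check_range(diags, f"{path}.{ax}normRange",
                             pop[f"{ax}normRange"], 0.0, 1.0)
            if f"{ax}Range" in pop and f"{ax}normRange" in pop:
                diags.append(Diagnostic(
                    f"{path}.{ax}Range",
                    f"give either {ax}Range or {ax}normRange, not both"))

    # --- cell rules
    for rname, rule in cells.items():
        path = f"cellParams.{rname}"
        if not isinstance(rule, dict):
            diags.append(Diagnostic(path, "cell rule must be a mapping"))
            continue
        _check_conds(diags, f"{path}.conds", rule.get("conds", {}))
        has_secs = "secs" in rule
        has_point = "pointParams" in rule
        if has_secs:
            _validate_sections(diags, f"{path}.secs", rule["secs"])
            if isinstance(rule["secs"], dict) and "soma" not in rule["secs"]:
                diags.append(Diagnostic(
                    f"{path}.secs",
                    "compartmental rules need a section named 'soma'"))
        if has_point and not isinstance(rule["pointParams"], dict):
            diags.append(Diagnostic(f"{path}.pointParams",
                                    "must be a mapping"))
        if not has_secs and not has_point:
            diags.append(Diagnostic(path,
                                    "rule needs secs or pointParams"))
        sec_lists = rule.get("secLists", {})
        if sec_lists and isinstance(rule.get("secs"), dict):
            for gname, slist in sec_lists.items():
                missing = [s for s in slist if s not in rule["secs"]]
                if missing:
                    diags.append(Diagnostic(
                        f"{path}.secLists.{gname}",
                        f"unknown sections: {', '.join(missing)}"))

    # --- synaptic mechanisms
    for sname, syn in syns.items():
        path = f"synMechParams.{sname}"
        if not isinstance(syn, dict):
            diags.append(Diagnostic(path, "must be a mapping"))
            continue
        mode = syn.get("mode", "exp")
        if mode not in ("exp", "exp2"):
            diags.append(Diagnostic(f"{path}.mode", "must be exp or exp2"))
        elif mode == "exp":
            tau = syn.get("tau")
            if not _is_num(tau) or tau <= 0:
                diags.append(Diagnostic(f"{path}.tau", "must be > 0"))
        else:
            t1, t2 = syn.get("tau1"), syn.get("tau2")
            if not _is_num(t1) or t1 <= 0 or not _is_num(t2) or t2 <= 0:
                diags.append(Diagnostic(path, "tau1 and tau2 must be > 0"))
            elif t1 >= t2:
                diags.append(Diagnostic(path, "tau1 must be < tau2"))
        if not _is_num(syn.get("e", 0.0)):
            diags.append(Diagnostic(f"{path}.e", "must be a number"))

    # --- connectivity rules
    pop_names = set(pops)
    for cname, rule in conns.items():
        path = f"connParams.{cname}"
        if not isinstance(rule, dict):
            diags.append(Diagnostic(path, "must be a mapping"))
            continue
        _check_conds(diags, f"{path}.preConds", rule.get("preConds", {}))
        _check_conds(diags, f"{path}.postConds", rule.get("postConds", {}))
        for side in ("preConds", "postConds"):
            cond = rule.get(side, {})
            if isinstance(cond, dict):
                for attr in ("pop", "cellType"):
                    vals = cond.get(attr)
                    if vals is None:
                        continue
                    vals = vals if isinstance(vals, list) else [vals]
                    known = pop_names if attr == "pop" else cell_types
                    for v in vals:
                        if v not in known:
                            diags.append(Diagnostic(
                                f"{path}.{side}.{attr}",
                                f"unresolved reference {v!r}"))
        mechs = rule.get("synMech")
        for m in (mechs if isinstance(mechs, list) else
                  [mechs] if mechs is not None else []):
            if m not in syns:
                diags.append(Diagnostic(
                    f"{path}.synMech",
                    f"unresolved synaptic mechanism {m!r}"))
        func = rule.get("connFunc")
        has_matrix = "connMatrix" in rule
        if (func is None) == (not has_matrix):
            diags.append(Diagnostic(
                path, "exactly one of connFunc / connMatrix must be given"))
        if func is not None and func not in CONN_FUNCS:
            diags.append(Diagnostic(f"{path}.connFunc",
                                    f"must be one of {', '.join(CONN_FUNCS)}"))
        if func == "probConn":
            _num_or_funcstring(diags, f"{path}.probability",
                               rule.get("probability"), 0.0)
            if rule.get("probability") is None:
                diags.append(Diagnostic(f"{path}.probability",
                                        "required for probConn"))
        if func == "convConn" and rule.get("convergence") is None:
            diags.append(Diagnostic(f"{path}.convergence",
                                    "required for convConn"))
        if func == "divConn" and rule.get("divergence") is None:
            diags.append(Diagnostic(f"{path}.divergence",
                                    "required for divConn"))
        _num_or_funcstring(diags, f"{path}.convergence",
                           rule.get("convergence"), 0)
        _num_or_funcstring(diags, f"{path}.divergence",
                           rule.get("divergence"), 0)
        _num_or_funcstring(diags, f"{path}.weight", rule.get("weight"))
        delay = rule.get("delay")
        _num_or_funcstring(diags, f"{path}.delay", delay)
        if _is_num(delay) and delay < cfg["dt"]:
            diags.append(Diagnostic(f"{path}.delay",
                                    f"must be >= dt ({cfg['dt']} ms)"))
        if has_matrix:
            mat = rule["connMatrix"]
            if not (isinstance(mat, list)
                    and all(isinstance(r, list) for r in mat)):
                diags.append(Diagnostic(f"{path}.connMatrix",
                                        "must be a 2D boolean matrix"))

    # --- subcellular rules
    for sname, rule in subconns.items():
        path = f"subConnParams.{sname}"
        if not isinstance(rule, dict):
            diags.append(Diagnostic(path, "must be a mapping"))
            continue
        _check_conds(diags, f"{path}.preConds", rule.get("preConds", {}))
        _check_conds(diags, f"{path}.postConds", rule.get("postConds", {}))
        _validate_density(diags, f"{path}.density", rule.get("density", {}))

    # --- stimulation
    nyquist = 1000.0 / (2.0 * cfg["dt"]) if _is_num(cfg["dt"]) \
        and cfg["dt"] > 0 else float("inf")  # Hz
    for sname, src in stim_src.items():
        path = f"stimSourceParams.{sname}"
        if not isinstance(src, dict):
            diags.append(Diagnostic(path, "must be a mapping"))
            continue
        stype = src.get("type")
        if stype not in STIM_TYPES:
            diags.append(Diagnostic(f"{path}.type",
                                    f"must be one of {', '.join(STIM_TYPES)}"))
            continue
        if stype == "NetStim":
            rate = src.get("rate", 0.0)
            if not _is_num(rate) or rate < 0:
                diags.append(Diagnostic(f"{path}.rate", "must be >= 0"))
            noise = src.get("noise", 0.0)
            if not _is_num(noise) or not 0.0 <= noise <= 1.0:
                diags.append(Diagnostic(f"{path}.noise",
                                        "must be in [0, 1]"))
        elif stype == "IClamp":
            for par in ("del", "dur", "amp"):
                if not _is_num(src.get(par, 0.0)):
                    diags.append(Diagnostic(f"{path}.{par}",
                                            "must be a number"))
        else:  # BandNoise
            flow, fhigh = src.get("fLow"), src.get("fHigh")
            if not (_is_num(flow) and _is_num(fhigh)
                    and 0 <= flow < fhigh < nyquist):
                diags.append(Diagnostic(
                    path, f"need 0 <= fLow < fHigh < Nyquist ({nyquist} Hz)"))
    for tname, tgt in stim_tgt.items():
        path = f"stimTargetParams.{tname}"
        if not isinstance(tgt, dict):
            diags.append(Diagnostic(path, "must be a mapping"))
            continue
        if tgt.get("source") not in stim_src:
            diags.append(Diagnostic(f"{path}.source",
                                    f"unresolved stim source "
                                    f"{tgt.get('source')!r}"))
        _check_conds(diags, f"{path}.conds", tgt.get("conds", {}))
        mech = tgt.get("synMech")
        if mech is not None and mech not in syns:
            diags.append(Diagnostic(f"{path}.synMech",
                                    f"unresolved synaptic mechanism "
                                    f"{mech!r}"))

    # --- reaction kinetics
    if rxd:
        species = rxd.get("species", {})
        regions = rxd.get("regions", {})
        for sp, sdef in species.items():
            for reg in (sdef or {}).get("regions", []):
                if reg not in regions:
                    diags.append(Diagnostic(
                        f"rxdParams.species.{sp}.regions",
                        f"unresolved region {reg!r}"))
        from .rxd import parse_stoichiometry
        for rn, rdef in rxd.get("reactions", {}).items():
            path = f"rxdParams.reactions.{rn}"
            for side in ("reactants", "products"):
                try:
                    stoich = parse_stoichiometry((rdef or {}).get(side, {}))
                except ValueError as err:
                    diags.append(Diagnostic(f"{path}.{side}", str(err)))
                    continue
                for sp in stoich:
                    if sp not in species:
                        diags.append(Diagnostic(
                            f"{path}.{side}",
                            f"undeclared species {sp!r}"))
        for rn, rdef in rxd.get("rates", {}).items():
            path = f"rxdParams.rates.{rn}"
            sp = (rdef or {}).get("species")
            if sp not in species:
                diags.append(Diagnostic(f"{path}.species",
                                        f"undeclared species {sp!r}"))
            _check_funcstring(diags, f"{path}.rate",
                              str((rdef or {}).get("rate", "0")),
                              frozenset(species))

    # --- every population must have a matching cell rule
    for pname, pop in pops.items():
        if not isinstance(pop, dict):
            continue
        tags = {"pop": pname, "cellType": pop.get("cellType")}
        matched = any(_conds_match_tags(rule.get("conds", {}), tags)
                      for rule in cells.values() if isinstance(rule, dict))
        if cells and not matched:
            diags.append(Diagnostic(f"popParams.{pname}",
                                    "no cell rule matches this population"))
    return diags


def _conds_match_tags(conds, tags):
    """True if every declared condition is satisfied by the tags."""
    for attr, want in (conds or {}).items():
        have = tags.get(attr)
        if isinstance(want, list):
            if isinstance(want, list) and len(want) == 2 \
                    and all(_is_num(v) for v in want) \
                    and attr in ("x", "y", "z", "xnorm", "ynorm", "znorm"):
                if have is None or not want[0] <= have <= want[1]:
                    return False
            elif have not in want:
                return False
        elif have != want:
            return False
    return True


# ---------------------------------------------------------------------------
# canonical JSON round-trip

def _canonicalize(obj):
    if isinstance(obj, FuncString):
        return obj.source
    if isinstance(obj, dict):
        return {str(k): _canonicalize(obj[k]) for k in obj}
    if isinstance(obj, (list, tuple)):
        return [_canonicalize(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None  # NaN/inf (e.g. undefined ISI CV) -> JSON null
    return obj


def canonical_json(obj):
    """Serialize with sorted keys and full float precision."""
    return json.dumps(_canonicalize(obj), sort_keys=True, indent=1,
                      allow_nan=False)


def spec_roundtrip(spec):
    """Canonicalize a spec document through JSON.

    Serializes and re-parses the document; the result is the canonical
    form (sorted keys, simConfig completed with defaults).  Idempotent:
    round-tripping a canonical document returns an equal document.
    """
    doc = {
        "netParams": spec.get("netParams", {}),
        "simConfig": complete_simconfig(spec.get("simConfig")),
    }
    try:
        text = canonical_json(doc)
    except (TypeError, ValueError) as err:
        raise ValueError(f"spec is not JSON-serializable: {err}") from err
    return json.loads(text)
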