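"""Well-mixed per-compartment reaction kinetics.

Implements the declarative regions / species / reactions / rates
subset: each (segment, region) pair is an independent well-mixed pool;
reactions follow mass-action kinetics (forward flux = rate_f ×
Π [reactant]^stoich), explicit rate laws add arbitrary d[S]/dt terms,
and declared couplings convert transmembrane ionic currents into
concentration fluxes (−I / (z·F·V), with V the compartment volume
scaled by the region's fractional volume).

Integration is classical RK4 per engine timestep (operator splitting:
the membrane advances first, then the chemistry).  Concentrations are
clipped at zero; a per-step relative change above 10 aborts with a
diagnostic suggesting a smaller dt.
"""

from __future__ import annotations

import math
import re

import numpy as np

from .diagnostics import BuildError, Diagnostic, SimulationError
from .funcstring import parse_func_string
from .specs import _conds_match_tags

__all__ = ["ReactionSystem", "build_reaction_system",
           "parse_stoichiometry", "FARADAY"]

FARADAY = 96485.33212  # C/mol

_TERM = re.compile(r"^\s*(\d+)?\s*\*?\s*([A-Za-z_]\w*)\s*$")


def parse_stoichiometry(spec):
    """Parse a reaction side into {species: positive int}.

    Accepts a mapping, or strings like ``"2 ca + buf"`` / ``"2*ca+buf"``
    / ``"cabuf"``; an empty value means no species (e.g. a degradation
    product).
    """
    if spec is None or spec == "" or spec == {}:
        return {}
    if isinstance(spec, dict):
        out = {}
        for sp, coef in spec.items():
            if not isinstance(coef, int) or isinstance(coef, bool) \
                    or coef < 1:
                raise ValueError(
                    f"stoichiometric coefficient for {sp!r} must be a "
                    f"positive integer")
            out[str(sp)] = coef
        return out
    if not isinstance(spec, str):
        raise ValueError("reaction side must be a string or mapping")
    out = {}
    for term in spec.split("+"):
        m = _TERM.match(term)
        if not m:
            raise ValueError(f"cannot parse reaction term {term.strip()!r}")
        coef = int(m.group(1) or 1)
        if coef < 1:
            raise ValueError("stoichiometric coefficients must be >= 1")
        out[m.group(2)] = out.get(m.group(2), 0) + coef
    return out


class ReactionSystem:
    """State and dynamics of all reaction compartments.

    ``conc`` has shape (n_compartments, n_species); entries for species
    absent from a compartment's region are masked by ``present``.
    """

    def __init__(self, species_names, volumes, present, initial):
        self.species_names = list(species_names)
        self.sp_index = {s: i for i, s in enumerate(self.species_names)}
        self.volumes = np.asarray(volumes, dtype=float)      # µm³
        self.n_comp = len(self.volumes)
        self.n_species = len(self.species_names)
        self.present = np.asarray(present, dtype=bool)
        self.conc = np.where(self.present,
                             np.asarray(initial, dtype=float), 0.0)
        self.reactions = []   # (stoich_r, stoich_p, kf, kb, comp_mask)
        self.rates = []       # (sp_idx, FuncString, comp_mask)
        self.couplings = []   # (comp_idx array, sp_idx, current nA, valence)
        self.charge = {}      # species -> valence
        self.clip_events = 0
        self._seg_lookup = {} # species -> {forest seg index: comp index}

    # -- construction helpers ----------------------------------------
    def add_reaction(self, reactants, products, rate_f, rate_b=0.0,
                     comp_mask=None):
        sr = np.zeros(self.n_species)
        sp = np.zeros(self.n_species)
        for s, c in parse_stoichiometry(reactants).items():
            sr[self.sp_index[s]] = c
        for s, c in parse_stoichiometry(products).items():
            sp[self.sp_index[s]] = c
        if comp_mask is None:
            involved = (sr + sp) > 0
            comp_mask = np.all(self.present[:, involved], axis=1)
        self.reactions.append((sr, sp, float(rate_f), float(rate_b),
                               comp_mask))

    def add_rate(self, species, expr, comp_mask=None):
        idx = self.sp_index[species]
        fs = parse_func_string(str(expr), frozenset(self.species_names))
        if comp_mask is None:
            comp_mask = self.present[:, idx].copy()
        self.rates.append((idx, fs, comp_mask))

    # -- dynamics -----------------------------------------------------
    def deriv(self, conc, influx=None):
        d = np.zeros_like(conc)
        safe = np.maximum(conc, 0.0)
        for sr, sp, kf, kb, mask in self.reactions:
            flux = np.full(self.n_comp, kf)
            for i in np.nonzero(sr)[0]:
                flux = flux * safe[:, i] ** sr[i]
            if kb:
                back = np.full(self.n_comp, kb)
                for i in np.nonzero(sp)[0]:
                    back = back * safe[:, i] ** sp[i]
                flux = flux - back
            flux = np.where(mask, flux, 0.0)
            d += flux[:, None] * (sp - sr)[None, :]
        for idx, fs, mask in self.rates:
            env = {s: safe[:, self.sp_index[s]]
                   for s in fs.used_variables}
            val = fs.eval(env)
            d[:, idx] += np.where(mask, val, 0.0)
        if influx is not None:
            d = d + influx
        return d

    def step(self, dt, engine=None):
        """RK4 update of every compartment; returns self."""
        influx = self._coupling_influx() if self.couplings else None
        c0 = self.conc
        k1 = self.deriv(c0, influx)
        k2 = self.deriv(c0 + 0.5 * dt * k1, influx)
        k3 = self.deriv(c0 + 0.5 * dt * k2, influx)
        k4 = self.deriv(c0 + dt * k3, influx)
        new = c0 + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        # stiffness guard: per-compartment change measured against the
        # compartment's own concentration scale, so pools that start
        # empty may fill without tripping it
        scale = np.maximum(np.abs(c0).max(axis=1, initial=0.0), 1e-6)
        rel = np.abs(new - c0) / scale[:, None]
        if np.any(rel[self.present] > 10.0):
            raise SimulationError(
                "reaction kinetics changing too fast per step "
                "(|Δ[S]|/[S] > 10); use a smaller dt")
        below = new < 0.0
        if below.any():
            self.clip_events += int(np.count_nonzero(below & self.present))
            new = np.maximum(new, 0.0)
        self.conc = np.where(self.present, new, 0.0)
        return self

    def _coupling_influx(self):
        influx = np.zeros_like(self.conc)
        for comp_idx, sp_idx, current, valence in self.couplings:
            # nA -> mM/ms: -I * 1e6 / (z F V[µm³])
            flux = -current * 1e6 / (valence * FARADAY
                                     * self.volumes[comp_idx])
            influx[comp_idx, sp_idx] += flux
        return influx

    # -- queries ------------------------------------------------------
    def concentration_at(self, seg_idx, species):
        """Concentrations of ``species`` at forest segment indices
        (0 where the species has no pool on that segment)."""
        lookup = self._seg_lookup.get(species, {})
        i = self.sp_index[species]
        out = np.zeros(len(seg_idx))
        for k, si in enumerate(np.asarray(seg_idx)):
            ci = lookup.get(int(si))
            if ci is not None:
                out[k] = self.conc[ci, i]
        return out

    def totals(self, weights=None):
        """Σ over compartments of (optionally stoichiometry-weighted)
        amounts; useful for conservation checks."""
        w = np.ones(self.n_species) if weights is None \
            else np.asarray(weights, dtype=float)
        return (self.conc * w[None, :]).sum(axis=0)

    @classmethod
    def well_mixed(cls, species, volume=1.0):
        """One-compartment system for isolated kinetics (no network).

        ``species`` maps name -> initial concentration (mM).
        """
        names = list(species)
        init = np.array([[species[s] for s in names]])
        present = np.ones((1, len(names)), dtype=bool)
        return cls(names, [volume], present, init)


# ---------------------------------------------------------------------------

def _region_segments(region, cells, forest):
    """Forest segment indices and volumes for one region declaration."""
    sel = region.get("cells", "all")
    secs = region.get("secs", "all")
    frac = float(region.get("volume_fraction", 1.0))
    out = []
    for cell in cells:
        if sel != "all":
            if isinstance(sel, list):
                if cell.gid not in sel:
                    continue
            elif isinstance(sel, dict):
                tags = dict(cell.tags)
                tags.update({"pop": cell["pop"], "gid": cell.gid})
                if not _conds_match_tags(sel, tags):
                    continue
        for sname, sec in cell.secs.items():
            if secs != "all" and sname not in secs:
                continue
            for seg in sec.segments:
                gi = forest.seg_of[(cell.gid, sname, seg.index)]
                vol = math.pi * (seg.diam / 2.0) ** 2 * seg.L * frac
                out.append((gi, vol))
    return out


def build_reaction_system(rxd_params, network, cells=None, forest=None):
    """Compile declarative reaction parameters against a network.

    Creates one pool per (segment, region) per species declared there,
    compiles reactions to mass-action flux functions and rate laws to
    expressions over species concentrations, and registers declared
    current couplings.
    """
    if forest is None:
        from .engine import Engine  # pragma: no cover - convenience path
        raise BuildError(Diagnostic(
            "rxdParams", "reaction systems are built by the engine"))
    cells = cells if cells is not None else [
        c for c in network.cells if c.model == "compartmental"]
    regions = rxd_params.get("regions", {})
    species = rxd_params.get("species", {})
    if not species:
        sys = ReactionSystem([], [], np.zeros((0, 0), dtype=bool),
                             np.zeros((0, 0)))
        return sys

    region_segs = {rname: _region_segments(rdef, cells, forest)
                   for rname, rdef in regions.items()}
    # compartment = (region, forest segment)
    comp_key = []
    volumes = []
    for rname, segs in region_segs.items():
        for gi, vol in segs:
            comp_key.append((rname, gi))
            volumes.append(vol)
    comp_index = {k: i for i, k in enumerate(comp_key)}
    names = list(species)
    present = np.zeros((len(comp_key), len(names)), dtype=bool)
    initial = np.zeros((len(comp_key), len(names)))
    for j, (sname, sdef) in enumerate(species.items()):
        for rname in sdef.get("regions", []):
            if rname not in regions:
                raise BuildError(Diagnostic(
                    f"rxdParams.species.{sname}",
                    f"unresolved region {rname!r}"))
            for gi, _ in region_segs[rname]:
                i = comp_index[(rname, gi)]
                present[i, j] = True
                initial[i, j] = float(sdef.get("initial", 0.0))

    sys = ReactionSystem(names, volumes, present, initial)
    for sname, sdef in species.items():
        sys.charge[sname] = int(sdef.get("charge", 0))
        lookup = {}
        for rname in sdef.get("regions", []):
            for gi, _ in region_segs[rname]:
                lookup.setdefault(gi, comp_index[(rname, gi)])
        sys._seg_lookup[sname] = lookup

    def region_mask(rnames, involved_cols):
        if rnames:
            mask = np.array([k[0] in rnames for k in comp_key])
        else:
            mask = np.ones(len(comp_key), dtype=bool)
        if involved_cols:
            mask &= np.all(present[:, involved_cols], axis=1)
        return mask

    for rname, rdef in (rxd_params.get("reactions") or {}).items():
        try:
            sr = parse_stoichiometry(rdef.get("reactants", {}))
            sp = parse_stoichiometry(rdef.get("products", {}))
        except ValueError as err:
            raise BuildError(Diagnostic(
                f"rxdParams.reactions.{rname}", str(err)))
        for s in list(sr) + list(sp):
            if s not in sys.sp_index:
                raise BuildError(Diagnostic(
                    f"rxdParams.reactions.{rname}",
                    f"undeclared species {s!r}"))
        cols = [sys.sp_index[s] for s in set(sr) | set(sp)]
        mask = region_mask(rdef.get("regions"), cols)
        sys.add_reaction(sr, sp, float(rdef.get("rate_f", 0.0)),
                         float(rdef.get("rate_b", 0.0)), mask)

    for rname, rdef in (rxd_params.get("rates") or {}).items():
        spn = rdef.get("species")
        if spn not in sys.sp_index:
            raise BuildError(Diagnostic(
                f"rxdParams.rates.{rname}",
                f"undeclared species {spn!r}"))
        mask = region_mask(rdef.get("regions"), [sys.sp_index[spn]])
        mask &= present[:, sys.sp_index[spn]]
        sys.add_rate(spn, rdef.get("rate", "0"), mask)

    for cdef in (rxd_params.get("couplings") or []):
        spn = cdef.get("species")
        if spn not in sys.sp_index:
            raise BuildError(Diagnostic(
                "rxdParams.couplings",
                f"undeclared species {spn!r}"))
        lookup = sys._seg_lookup[spn]
        secs = cdef.get("secs", "all")
        conds = cdef.get("conds", {})
        comp_idx = []
        for cell in cells:
            tags = dict(cell.tags)
            tags.update({"pop": cell["pop"], "gid": cell.gid})
            if conds and not _conds_match_tags(conds, tags):
                continue
            for sname, sec in cell.secs.items():
                if secs != "all" and sname not in secs:
                    continue
                for seg in sec.segments:
                    gi = forest.seg_of[(cell.gid, sname, seg.index)]
                    if gi in lookup:
                        comp_idx.append(lookup[gi])
        valence = int(cdef.get("valence",
                               abs(sys.charge.get(spn, 2)) or 2))
        sys.couplings.append((np.asarray(comp_idx, dtype=np.int64),
                              sys.sp_index[spn],
                              float(cdef.get("current", 0.0)),
                              valence))
    return sys
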