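# Methods

This note documents the models, numerical choices and conventions
behind netsim, in the order of the workflow: specification →
instantiation → simulation → extracellular potentials → analysis →
batch optimization. It also states what the built-in demonstration
fixtures do and do not emulate.

## Units and coordinate conventions

Space µm, time ms, voltage mV, point currents nA, synaptic weight µS
(peak conductance), density conductances S/cm², axial resistivity
Ω·cm, specific capacitance µF/cm², concentrations mM, cell density
cells/mm³. Internally the engine works in the consistent set
{mV, ms, nA, µS, nF}, in which `C·dV/dt`, `g·V` and injected currents
are all nA.

The network bounding box is `sizeX × sizeY × sizeZ` µm. The y axis is
cortical depth: `ynorm = y/sizeY` runs from 0 at the pia to 1 at the
white matter. Normalized population ranges (`ynormRange` etc.) resolve
against the box; volumetric densities convert to counts as
`round(density × boxVolume(mm³) × rangeFractions)`, rounded
half-to-even so counts are platform-independent.

Expression variables for connectivity rules: `pre_*`/`post_*`
coordinates and their normalized forms, `dist_3D` (Euclidean),
`dist_2D` (lateral distance in the xz plane, i.e. at equal depth) and
`dist_y = |Δy|`. This vocabulary is frozen here; it is a superset of
what the rule examples need.

## The expression language

Probability, weight, delay, degree and density-map parameters may be
strings over that vocabulary with functions
`exp, log, sqrt, abs, sin, cos, min, max` and stochastic terms
`uniform(a,b)`, `normal(mu,sd)`. A hand-written recursive-descent
parser builds a small AST; the host language's `eval` is never
involved, so a spec document cannot execute code. Evaluation is
*totalized*: `log` and `sqrt` clamp their domains, division clamps the
divisor away from zero, `a^b` uses `|a|` for fractional exponents
(keeping the sign for odd integer ones), and every intermediate result
is clipped to ±1e150. Consequence: any accepted expression evaluates
to a finite float for finite inputs — a property the test suite
checks over randomly generated expressions. The trade-off is that the
guarded semantics differ from IEEE arithmetic exactly at the singular
points; for modeling purposes (densities, probabilities, delays) this
is the behavior you want.

Stochastic terms draw only from the stream scoped to the entity being
generated (the connection's pair stream), never from global state.
Density-map expressions are evaluated once per segment and should be
deterministic.

## Replicable random streams

Every stochastic build decision uses a `numpy` Philox (counter-based)
generator keyed by a splitmix64 hash chain over
`(globalSeed, purposeConstant, purposeSeed, id1, id2)`:

| purpose  | ids            | used for                              |
|----------|----------------|---------------------------------------|
| `loc`    | (gid, 0)       | cell positions (x, then y, then z)    |
| `conn`   | (pre, post)    | pair coin-flips, stochastic weights   |
| `conn`   | (anchor, 0)    | convergence/divergence sampling       |
| `synloc` | (pre, post)    | subcellular synapse placement         |
| `stim`   | (gid, srcIdx)  | stimulus trains and noise waveforms   |

`synloc` shares the `conn` purposive seed (subcellular placement is a
connectivity property). Because no stream is shared between entities,
the instantiated network is independent of iteration order and of any
round-robin partitioning of cells across workers — the test suite
verifies byte-identical connection lists for 1/2/4/8 simulated
partitions and reversed processing order. Changing `seeds.global`
changes everything; changing `seeds.conn` rewires the network without
moving cells or changing stimulus trains.

For probabilistic rules the first draw from the pair stream is the
uniform compared against p; stochastic terms inside p, then weight,
then delay, then loc consume subsequent draws in that order.

## Build semantics

- Cell rules: first-declared matching rule wins. Connectivity rules
  are cumulative — multiple rules may add parallel connections.
- Self-connections are excluded when the pre and post sets overlap;
  `simConfig.allowSelfConns` overrides.
- Fixed convergence/divergence is exact: k distinct partners sampled
  by a partial Fisher-Yates shuffle driven by the anchor cell's
  stream; k larger than the partner pool is a build error, never a
  silent clip.
- A resolved delay below dt is a build error (events must fall on a
  future step).
- Sections without 3D points get a stylized straight line along +y
  from their parent attachment point; explicit `pt3d` lists are
  interpreted relative to the cell position. Segment areas are
  cylinder lateral surfaces π·diam·L/nseg.
- Subcellular density rules resample a connection's (section, loc)
  with probability ∝ density(segment) × segment length. 1D/2D maps
  use nearest-bin lookup with edges at grid midpoints; positions
  beyond the outer half-bin have zero density (a single-point grid
  covers everything). Grid coordinates lying inside [0, 1] are
  interpreted as normalized depth unless `norm` says otherwise.
  Section-group fractions renormalize to 1 and spread within each
  group by length. An all-zero density over a target arbor is an
  error.
- Artificial spike generators interpolate periodic↔Poisson: interval
  = (1−noise)/rate + Exp(noise/rate). At noise = 0 the first spike is
  exactly at `start` (so 10 Hz for 1 s gives spikes at 0, 100, …,
  900 ms); for noise > 0 the first interval is drawn like every
  other, which keeps the mean count at rate × duration.

## The simulation engine

Fixed step dt (default 0.025 ms), fixed-order update loop: deliver
events → accumulate synaptic conductances → injected currents →
implicit compartmental step → explicit point-model step → spike
detection → event routing → reaction step → synaptic decay →
recording.

**Point models.** Forward Euler. Izhikevich: v is updated first and
the recovery variable sees the new v; reaching 30 mV resets in the
following step (spike recorded then). Note the classic
regular-spiking parameter set rests at −70 mV (the fixed point of
0.04v²+5v+140 = u with u = bv), not at the −65 mV initial condition.
LIF: `tau_m dv/dt = −(v − v_rest) + r_m·I` with threshold/reset and an
optional absolute refractory period. For point models synaptic
conductances inject `g·(e − v)` directly into the model's current
term (model units for Izhikevich, nA×MΩ = mV scale for LIF).

**Compartmental cells.** Backward Euler on the branched cable
equation. Gates advance first by Rush-Larsen (exact exponential update
against rates evaluated at the start-of-step voltage), making the
membrane system linear in V; the tree matrix is solved exactly by
Hines elimination. The elimination is vectorized over tree-depth
levels (all segments at a depth are eliminated into their parents with
a handful of array operations), so whole populations advance together
— the chain topology is the worst case, a soma with many branches the
best. Axial conductances use the standard half-segment series
resistances. Backward Euler was chosen over Crank-Nicolson for
robustness (no ringing at coarse dt); the cost is first-order accuracy
in dt. Measured behavior on the single-compartment Hodgkin-Huxley
fixture: halving dt moves spike times by ~0.13 ms at dt = 0.005 ms,
and spike times at dt = 0.005 ms sit within 0.2 ms of a dt = 0.001 ms
reference over 230 ms. Accuracy-sensitive work should use dt ≤ 0.01 ms;
network demos use 0.05–0.1 ms where spike timing tolerances are a few
tenths of a millisecond.

**Mechanisms.** `hh` is the classic squid-axon formulation (6.3 °C
rates, no q10 temperature scaling), singularities handled by a stable
x/(1−e^{−x}) form. `pas` is linear leak. `kca` is a calcium-dependent
potassium conductance `g = gmax·[Ca]/([Ca]+Kd)` reading the cytosolic
calcium pool — the minimal mechanism needed to close the
chemistry→electrophysiology loop (raise [Ca] → more K conductance →
hyperpolarization → less firing).

**Synapses.** `exp`: on event g += w, then exponential decay. `exp2`:
normalized difference of exponentials (peak conductance = w). Spike
detection for compartmental cells is a somatic upward crossing of
`spikeThreshold` (default 0 mV, configurable) with a 2 ms minimum
inter-detection interval.

**Stimulation.** IClamp adds a rectangular current; band-limited noise
is Gaussian white noise FFT-masked to [fLow, fHigh] and scaled to RMS
= amp, one realization per target from its `stim` stream.

**Membrane-current bookkeeping.** When LFP recording is on, each
segment stores its total transmembrane current
`c·dV/dt + I_ion + I_syn` at every record step. Because axial currents
are internal, these sum to zero over a cell (to ~1e-14 nA, the
elimination residual) — and exactly to the injected current when a
clamp is attached. This is also what guarantees the far field of an
intact cell is a dipole (1/d²), which the tests check.

**Replay.** A saved run's spike lists suffice to re-simulate any
single cell: its afferent events are reconstructed from the recorded
presynaptic spike times and delays, and since the cell's arithmetic is
identical to the full-network run (same per-cell arrays, same event
steps), the somatic trace matches to solver tolerance (measured: to
the last bit).

**Determinism.** Given a spec, every output — spike times, traces,
LFP — is bitwise reproducible; saved networks reload and re-simulate
to identical JSON. The engine orders sections canonically
(topological, sorted names) so a serialization round-trip cannot
change segment ordering.

## Reaction kinetics

Regions select (cell, section) sets with a fractional volume; each
(segment, region) pair is one independent well-mixed pool (no spatial
diffusion — the deliberate scope boundary of this implementation).
Reactions are mass action: forward flux `rate_f·Π[reactant]^stoich`,
optional backward flux; rate laws add arbitrary d[S]/dt expressions
over the species. Integration is RK4 per engine step under operator
splitting (membrane first, then chemistry). Concentrations clip at
zero (clips are counted); a per-step change exceeding 10× the
compartment's own concentration scale aborts with a diagnostic
suggesting a smaller dt — RK4 is explicit, so genuinely stiff systems
must reduce dt rather than silently lose accuracy.

Current coupling converts nA to mM/ms as `−I·10⁶/(z·F·V[µm³])`
(inward currents negative, so they raise the concentration). The
buffering fixture's rate constants (`rate_f = 1 mM⁻²ms⁻¹`,
`rate_b = 0.1 ms⁻¹`, degradation 0.001 ms⁻¹, initial Ca = Buf = 1 mM)
are illustrative values chosen to relax visibly within a 200 ms
simulation; they are not measurements.

## Extracellular potentials

Line-source approximation in an infinite Ohmic medium, default
σ = 0.3 S/m (a standard cortical value). The transfer resistance of a
segment is the exact integral of 1/(4πσ·distance) along its axis; with
distances in µm, `R[MΩ] = 1/(4πσ·d[µm])` for the point-source limit
(1 nA at 100 µm → 2.653 µV). The radial distance is clamped below at
the segment radius so an electrode on the axis stays finite
(configurable). Point-cell contributions (their synaptic + injected
currents as a point source) are off by default
(`simConfig.lfpIncludePoint`) because point-model currents are not
calibrated transmembrane currents; compartmental contributions are
always included. LFP is reported in µV; the matrix is electrodes ×
record steps, also exportable as CSV.

## Analysis

Per-population rates, quartiles, ISI CV (cells with fewer than 3
spikes report NaN and are excluded from boxplots), and a synchrony
index: the variance of the population-mean binned rate divided by the
mean single-cell variance (5 ms bins). This ratio is 1 for identical
trains and ~1/N for independent ones; it is the frozen substitute for
the unspecified synchrony measure this workflow's figures call for.
PSDs are Welch averages (Hann, 50% overlap, default 1 s segments,
5 ms rate bins — configurable), normalized so the integral of the PSD
recovers the signal variance within 1%. Spectrograms are STFT
magnitude². All statistics are pure functions of the output; plotting
renders to files and the numbers are always returned separately, so
nothing ever parses an image.

## Batch exploration and optimization

Grid search enumerates the Cartesian product of declared value lists
in odometer order over declaration order. The evolutionary optimizer
is a clean-room generational GA: tournament selection (size 3),
uniform crossover, per-gene Gaussian mutation (probability 0.2, sd
0.1× the parameter range, clipped to bounds), elitism 1, population
20 — defaults frozen here since the underlying method leaves them as
user options. Minimization is the convention; maximize by negating.
Fitness comes from per-population rate targets, expressions over
summary scalars, or expressions over the parameters themselves
(`paramExpr`, usable with `simulate: false` to benchmark the optimizer
on analytic functions). Trials carry fixed parameters and seeds, so
any recorded trial reproduces exactly and results are independent of
the worker count (a process pool replaces HPC queue runners; a
shell-script emitter for SLURM/PBS generates submission scripts
without executing them).

## Fixtures: what they emulate, and what they do not

- `two_cell` — a stimulus→A→B chain; the smallest causal circuit.
- `three_layer` — three excitatory Izhikevich populations at
  increasing cortical depth plus fast-spiking inhibition,
  distance-dependent probabilistic wiring, Poisson background. Rates
  land in a cortex-like regime (E ≈ 5–8 Hz, I ≈ 54 Hz).
- `lfp_demo` — 120 five-compartment cells (hh soma, passive apical
  chain) spread across depth with four depth electrodes.
- `buffering` — one hh cell with the calcium-buffering reaction set.

These are demonstrations, not data-driven models: point neurons have
no morphology, the five-compartment cell is a stylized chain, drives
are homogeneous Poisson, and all parameters are round numbers. Passing
tests therefore demonstrate that the machinery is correct (exact
combinatorics, closed-form physics, statistical oracles,
reproducibility), not that any fixture reproduces a particular
biological dataset.

## Problem sizes used in the checks

The verification suite and `scripts/acceptance.py` use: 10–100-cell
nets for exact connectivity counts; 200 seeds for the binomial
probabilistic-connectivity check; a 41-compartment cable for the cosh
profile; 200–230 ms of single-cell Hodgkin-Huxley at dt = 0.005 vs
0.001 ms; n = 4000 synapses for multinomial placement proportions; 20
seeded optimizer repeats on the sphere function; and the four fixtures
end-to-end (the LFP demo trimmed to 250 ms). These sizes put every
statistical tolerance (3σ, binomial 99% CI) well inside a few minutes
of desk-scale compute.

## Known limitations

- No spatial diffusion (1D/3D) or extracellular reaction space; no
  endoplasmic-reticulum kinetics (IP3R/SERCA).
- No gap junctions, plasticity, or AdEx/pre-computed point models.
- Backward Euler is first-order in dt; spike times at network dt
  (0.05–0.1 ms) carry a few tenths of a millisecond of discretization
  bias.
- MPI-parallel single simulations are out of scope; parallelism is at
  the batch level (process pool).
- Persistence is JSON only; HDF5 is an extension point.
- No NeuroML/SONATA interchange and no import of foreign cell models.
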