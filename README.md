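# netsim

Declarative multiscale modeling of neural circuits, self-contained: a
JSON specification language for networks and simulations, rule-based
network instantiation with replicable gid-keyed random streams, a
built-in fixed-step simulation backend (point and multicompartment
conductance-based neurons with per-compartment reaction kinetics),
extracellular potentials by the line-source approximation, analysis
statistics and figures, and automated grid / evolutionary parameter
exploration.

It is aimed at desk-scale computational neuroscience: models of tens to
a few hundred neurons where you want the *whole* workflow — specify →
instantiate → simulate → analyze → save → optimize — reproducible to
the byte from a single seed, with no external simulator dependency.

## The model, briefly

**Specification.** A model is one JSON document
`{"netParams": ..., "simConfig": ...}`. `netParams` declares
populations (`numCells` or volumetric `density` in cells/mm³, spatial
ranges absolute in µm or normalized to the network bounding box),
cell rules matched to cells by attribute conditions (point models:
Izhikevich `dv/dt = 0.04v² + 5v + 140 − u + I`, leaky
integrate-and-fire; or compartmental trees with `hh` / `pas` /
calcium-dependent `kca` membrane mechanisms), synaptic mechanisms
(single- or double-exponential conductances), connectivity rules
(all-to-all, probabilistic, fixed convergence/divergence, explicit
matrix), subcellular synapse-density maps (1D/2D grids over cortical
depth, path-distance expressions, section groups), stimulation
(current clamps, periodic↔Poisson spike generators, band-limited
noise currents) and mass-action reaction kinetics (regions, species,
reactions, rates — e.g. calcium buffering `2Ca + Buf ⇌ CaBuf` with
buffer degradation). Parameters like connection probability may be
arithmetic expressions over pre-/post-synaptic properties
(`"0.4*exp(-dist_3D/200)"`), parsed by a safe recursive-descent parser
— never the host `eval`.

**Instantiation.** Every random decision (a cell's position, a pair's
connection coin-flip, a synapse's dendritic location, a stimulus spike
train) draws from a private counter-based stream keyed by
`(globalSeed, purpose, purposeSeed, gid₁, gid₂)`. Results are
therefore independent of iteration order and of how cells are
partitioned across workers, and changing one purposive seed (e.g.
`seeds.conn`) re-randomizes only that aspect of the model.

**Simulation.** Compartmental cells advance by backward Euler on the
branched cable equation, solved exactly each step by Hines-style
elimination vectorized over tree depth; Hodgkin-Huxley gates use the
Rush-Larsen exponential update. Reaction kinetics are operator-split
(RK4 per timestep) and couple bidirectionally to the membrane (calcium
currents add `−I/(zFV)` flux; `kca` reads `[Ca]`). Spikes are routed
through an event queue with per-connection delays (delay ≥ dt enforced
at build time).

**LFP.** Each segment's total transmembrane current (capacitive +
ionic + synaptic) contributes `I × transferR` to each electrode, with
the transfer resistance from the line-source approximation in an Ohmic
medium (`σ = 0.3 S/m` by default): `1/(4πσΔs)·ln[(√(h²+r²)+h)/(√(l²+r²)+l)]`,
radially clamped at the segment radius.

## Worked example

```bash
netsim fixtures three_layer > three_layer.json
netsim run three_layer.json --out demo_out --plots raster,rates
```

prints:

```
instantiated 80 cells, 708 connections, 80 stimulators
1456 spikes; population rates: E2=5.80 Hz, E4=7.65 Hz, E5=5.25 Hz, I=54.10 Hz
outputs in demo_out
```

The fixture is a three-layer cortical sketch: three excitatory
populations of 20 regular-spiking Izhikevich cells at increasing
normalized depth, one fast-spiking inhibitory population, probabilistic
distance-dependent feed-forward wiring (`0.4·exp(−dist_3D/200)`), and a
40 Hz Poisson background drive. The 80 cells receive 708 connections;
excitatory cells settle at cortex-like 5–8 Hz while the inhibitory
cells fire fast (54 Hz). `demo_out/` holds the simulation output
(`output.json`), the instantiated network (`net.json`, reloadable and
re-simulatable without re-instantiation), per-population statistics
(`spike_stats.json`: rates, ISI CV, synchrony index), a spike TSV, the
figures, and a manifest with the spec hash and seeds. Running the same
command twice produces byte-identical `output.json`.

The same workflow is available as a library:

```python
import netsim
spec = netsim.fixture("three_layer")
net = netsim.build_network(spec)      # validate + instantiate
out = netsim.run(net)                  # spikes, traces, LFP
stats = netsim.spike_stats(out, net.pops, spec["simConfig"]["duration"])
```

Other fixtures: `two_cell` (a stimulus→A→B chain), `lfp_demo` (120
five-compartment neurons with four depth electrodes), `buffering`
(one Hodgkin-Huxley cell with calcium buffering and buffer
degradation). Batch exploration runs from a JSON description via
`netsim batch` (grid or evolutionary; see `docs/methods.md`).

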