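# pcxdend

Analysis toolbox for **circuit-specific dendritic development in layer 2 of
the anterior piriform cortex (aPCx)** — written for slice physiologists and
computational neuroscientists who need a tested, scriptable version of the
full analysis chain:

* **Morphometry** of SWC-reconstructed neurons: branch decomposition
  (stems / intermediates / tips), branch number NB, total dendritic branch
  length TDBL, mean branch length BL, branch-density profiles, soma depth
  normalized to the layer-2 width (layer 2a = superficial third, layer 2b =
  deep two-thirds), and classification of apical branch terminations into
  the sensory (L1A) and recurrent (L1B, L2) input zones.
* **Population Ca²⁺-imaging analysis**: ΔF/F normalization to the
  lowest-SD six-sample window, event detection (> 2.5 noise-SD for ≥ 2
  consecutive frames, incomplete edge events excluded), local neuropil
  subtraction, the layer-2 global event rate, and per-neuron *coactivity* —
  the fraction of detected neurons in the field of view active at the same
  time, as a function of depth in layer 2.
* **Current-clamp feature extraction**: Vm, Rin, τ, Cm from hyperpolarizing
  steps; AP threshold (1% of maximal dV/dt), fAHP, instantaneous firing
  frequency; EPSP amplitude and area under the curve in a 60-ms window
  after the third pulse of a 3 × 50 Hz train, with paired NMDAR-block
  comparisons.
* **A two-layer dendritic integration model** linking branch length to the
  probability of clustered-input dendritic NMDA-spikes (below).
* **Seeded synthetic-data generators** with ground truth for every pipeline
  stage, so the whole chain is testable without any recorded data.

## The integration model

A neuron with total dendritic length TDBL and mean branch length BL is
treated as a two-layer unit receiving `S` active synapses placed uniformly
over its dendrite. It fires if the total input reaches the distributed
threshold `n_dist = 40`, **or** if any single branch collects at least
`n_clus = 10` synapses, triggering a dendritic NMDA-spike. With constant
synaptic density, a branch receives a Poisson share with mean
`λ_b = S·BL/TDBL`, and branches are independent (Poisson splitting), so the
clustered response probability is

```
P(S, BL) = 1 − (1 − P[Pois(S·BL/TDBL) ≥ n_clus])^(TDBL/BL)
```

Long branches concentrate input on the same branch: across the measured BL
range (40–110 µm at TDBL ≈ 1800 µm), `P(70, BL)` rises from ≈ 0.03 % to
≈ 19 % — a candidate mechanism for the survival bias toward long apical
branches during developmental pruning. A multinomial-placement Monte-Carlo
oracle validates the analytic formula, and the circuit census (3700
glomeruli, 9.7 × 10⁷ synapses, 41 000 neurons, ≤ 70 active synapses/odor)
yields the derived constants 2366 synapses/neuron and 109 glomeruli/odor.

## Worked example

```pycon
>>> from pcxdend import model
>>> params = model.IntegrationModelParams()
>>> model.derive_census(params)
CircuitCensus(synapses_per_neuron=2366, glomeruli_per_odor=109,
              max_branches=45, min_branches=16)
>>> 100 * model.response_probability(params, s=70, bl=40.0)   # short branches
0.0252...
>>> 100 * model.response_probability(params, s=70, bl=110.0)  # long branches
18.594...
```

So at the same input strength (70 active synapses), a long-branched neuron
is ~700× more likely to fire a dendritic spike than a short-branched one.
The same contrast end to end on synthetic imaging data:

```pycon
>>> from pcxdend import calcium
>>> from pcxdend.synth import CaFovSpec, gen_ca_fov
>>> fov = gen_ca_fov(CaFovSpec(), seed=1)          # 95 cells, 5 min at 10 Hz
>>> events = calcium.detect_fov_events(fov.rois)
>>> records, thirds = calcium.coactivity(events, fov.rois)
>>> thirds
   depth_third      mean  count
0  superficial  0.302591     33
1       middle  0.375741     27
2         deep  0.331451     35
```

Deep layer-2b cells are coactive with a larger fraction of the network than
superficial layer-2a cells (0.33 vs 0.30 in this field of view; the
deep-vs-superficial ordering holds in ~99 of 100 simulated fields),
mirroring their depth-graded recruitment into global network events.

Command-line equivalents: `pcxdend morpho`, `pcxdend ca-events`,
`pcxdend ephys`, `pcxdend model`, `pcxdend simulate` (each writes a
`manifest.json` with version, seed, parameters and input checksums).

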