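# Methods

This note documents the models, conventions and numerical choices behind
`pcxdend`, and what the synthetic-data generators do and do not emulate.

## Morphometry

**Branch decomposition.** A dendritic tree (SWC; type 1 = soma, 3 = basal,
4 = apical) is split into branches at soma attachments, bifurcations and
terminal points; chains of degree-2 nodes are merged, and a node with k > 2
children (reconstruction software can emit multifurcations) starts k
daughter branches. Branch length is the sum of 3-D Euclidean inter-node
segment lengths, including the edge from the anchor (soma node or branch
point), so branch lengths exactly partition the tree's edge lengths:
TDBL = Σ branch lengths = Σ parent–child edge lengths.

**Branch kinds.** A branch leaving the soma is a *stem*, one ending in a
terminal point a *tip*, one ending in a bifurcation an *intermediate*. A
soma-attached branch counts as a stem regardless of how it ends (stem >
tip > intermediate precedence), giving the identity
NB = stems + intermediates + tips. Because conventions differ on whether
stems count toward NB, `nb_excluding_stems` is always reported alongside.

**Density profiles.** Branch positions are summarized by the Euclidean
distance from the soma centroid to each branch's arc-length midpoint. The
density over that variable (and, per input layer, over branch length) is a
Gaussian KDE with Silverman bandwidth on a grid of step 2.5 µm,
renormalized to integrate to 1 on the grid; with fewer than two distinct
values the profile degrades to a narrow Gaussian bump (σ = 5 µm) so it
remains a proper density. A fine-binned histogram serves as the test
oracle; the estimator choice matters only for display, not for any scalar
statistic.

**Laminar geometry.** Boundaries (L1a/L1b, L1b/L2a, L2/L3) are traced
polylines in the slice plane; a depth-orientation flag fixes which way is
deep. Soma depth is the smallest Euclidean distance to the L1b/L2a
boundary, normalized by the local layer-2 width measured along the ray
from the nearest boundary point through the soma to the L2/L3 boundary
(for parallel straight boundaries this is the perpendicular width).
Cells with depth < 1/3 are layer 2a, otherwise layer 2b; the tie at
exactly 1/3 goes to 2b ("deep two-thirds"). Termination layers are decided
by the side of each boundary containing the branch's distal point, with
boundary ties assigned to the deeper layer; points beyond a polyline's
traced extent use linear extrapolation of the end segment and are flagged.
Coordinates are µm; lengths are always 3-D even though layer assignment
uses the slice plane.

## Ca²⁺-event analysis

**Normalization.** F0 is the mean of the contiguous six-sample window with
the lowest SD (earliest window on ties); ΔF/F = (F − F0)/F0. The window's
SD is reported in ΔF/F units.

**Noise scale and threshold.** Events are runs of ΔF/F exceeding the
baseline level by > 2.5 noise-SD for ≥ 2 consecutive frames; runs touching
either end of the recording are discarded as incomplete. Two numerical
facts shape the default pipeline:

1. the minimum-SD window is an order statistic and *underestimates* the
   noise SD of a long stationary trace by a large factor (≈ 7× for a 5-min
   white-noise trace), so the per-ROI threshold scale defaults to a robust
   MAD estimate of the full ΔF/F trace (`noise_method="mad"`); the literal
   window SD remains available;
2. the six-sample F0 carries a level error of a few percent
   (SD/√6 relative to baseline), which shifts the whole ΔF/F trace; the
   threshold is therefore measured from the trace's median ΔF/F rather
   than from zero.

Even so, a 2.5-SD / 2-frame rule has a per-frame-pair false-positive
probability of ≈ 3.9 × 10⁻⁵ under Gaussian noise — about 0.12 spurious
events per 5-min trace, or ~11 per 95-ROI field of view. This is inherent
to the rule (manual curation historically removed such events); the
package exposes optional amplitude/width/inter-event-interval filters
(defaults off) instead of a curation step, and the acceptance machinery
reports the measured zero-event-null fraction rather than assuming it is
one.

**Neuropil correction.** The neuropil trace is the frame-mean of N
non-cell pixels (N = ROI size) drawn uniformly without replacement within
70 px of the ROI centroid by a seeded PRNG; both traces are normalized with
the same rule and subtracted. Detection runs on the corrected trace by
default (pre-correction detection available via flag).

**Coactivity.** For each event of an active ROI, the coactive set is the
other detected ROIs with ≥ 1 event overlapping the reference span by at
least one frame; the fraction uses all detected ROIs in the field of view
minus the reference cell as denominator (the self-inclusive convention is
reported alongside), and is averaged over the ROI's events. Records are
binned into depth thirds of layer 2; the superficial-vs-deep contrast is
the headline comparison. Inactive ROIs yield no record rather than zero.

## Current-clamp features

Vm is the pre-step baseline mean (≥ 100 ms required). Rin uses the steady
state taken as the mean of the last 20 % of the step; τ comes from a
single-exponential fit of the full onset transient (Cm = τ/Rin; a failed
fit leaves τ and Cm missing with a diagnostic). AP detection: voltage
peaks above 0 mV with ≥ 1 ms separation. AP threshold is the voltage where
dV/dt (central differences on the already low-pass-filtered trace; no
additional smoothing at 20 kHz) first reaches 1 % of that AP's maximal
slope, found by backward search from the peak; fAHP is threshold minus the
voltage minimum within 5 ms after the peak; instantaneous frequency is the
inverse first ISI. All are taken from the first 600-ms step eliciting ≥ 9
APs. EPSP metrics use a 50-ms pre-stimulus baseline and a 60-ms window
after the third pulse of a 3 × 50 Hz train; amplitude is the window peak
of the baseline-subtracted trace (the window mean is also emitted, since
"amplitude" is convention-dependent), AUC its trapezoidal integral in
mV·ms. For paired NMDAR-block comparisons the largest-stimulus sweep
without an AP in the window is selected per condition.

## Integration model

Parameters (defaults): 3700 glomeruli, 9.7 × 10⁷ synapses onto 41 000
layer-2 neurons, ≤ 70 active synapses per neuron per odor, thresholds
n_dist = 40 (somatic, distributed) and n_clus = 10 (same-branch dendritic
spike), TDBL = 1800 µm, BL ∈ [40, 110] µm (mean 72). Derived census:
round(9.7e7/41000) = 2366 synapses/neuron; floor(3700·70/2366) = 109
glomeruli/odor; floor(1800/40) = 45 and floor(1800/110) = 16 branches
(rounding modes chosen to match the published derivation exactly).

The clustered response probability treats branch loads as independent
Poissons with mean λ_b = S·BL/TDBL and uses the real-valued exponent
TDBL/BL. The Monte-Carlo oracle draws a Poisson(S) total and places
synapses uniformly on floor(TDBL/BL) branches — by Poisson splitting this
is *exactly* the independent-branch model at integer branch count, so the
oracle comparison uses the matching integer parameterisation (λ_b = S/NB,
exponent NB); both parameterisations are exposed and differ only at
non-divisor BL (e.g. 0.186 vs 0.207 at S = 70, BL = 110). Monotonicity in
BL and S holds analytically for the continuous variant and is asserted on
every computed curve.

Two tail variants exist because the source formula as printed starts its
sum at k = 1, omitting the k = 0 Poisson mass: `standard_tail` (the true
survival function P(X ≥ n), the default) and `printed_eq` (kept for exact
textual replication; it is not a valid tail — it equals 1 at n = 1 and
dominates the standard tail pointwise). At S = 70, BL = 110 the standard
tail gives 18.6 %, consistent with the published "close to 0 % up to
~17 %" contrast; the printed variant gives 35.4 %. Thresholds are ≥ n
(consistent with "n or more"); a strict-inequality reading can be obtained
by passing n + 1.

## Synthetic data

The generators are pure functions of (spec, seed) and return the ground
truth needed to score every downstream extractor.

**Morphology cohorts.** Trees grow in the slice plane: stems leave the
soma, then randomly chosen open tips bifurcate until the branch count is
reached (NB = stems + 2·bifurcations). Branch lengths are log-normal
(CV 0.5 by default — positive and right-skewed like measured branch-length
densities) with mean TDBL_target/E[NB], making cohort-mean TDBL unbiased
for its target; lengths are floored at 5 µm. Apical trees head toward the
superficial layers, basal trees deeper, inside a straight-boundary laminar
frame (layer-2 width 120 µm, layer 1b 80 µm), so depth normalization and
termination classification run end to end. The default cohort encodes the
critical-period targets (apical TDBL 1800 µm, mean BL ~72 µm in both
classes) and the superficial-to-deep basal gradient: smaller basal targets
for layer 2a than 2b, plus a within-group scaling of basal TDBL with
depth. What is *not* emulated: tortuosity statistics, 3-D z-structure,
diameter tapering, spines — so passing tests certify the measurement
chain, not biological realism of tree shape.

**Ca²⁺ fields of view.** Defaults mirror the recorded conditions: 95 cells
per FOV (the recorded average), 5 min at 10 Hz, ΔF/F noise SD 0.05.
Transients have an instantaneous rise, a 3–8-frame plateau, and a single-
exponential decay (τ = 0.5 s, a generic GCaMP6f-like kinetic); amplitudes
are log-normal with median 5 noise-SD truncated at 3 SD (network events
are large relative to noise). Global events (1/min) recruit each cell by
an independent Bernoulli draw rising linearly from 0.4 (depth 0) to 0.8
(depth 1); independent per-cell events (0.5/min) dilute the synchrony.
Scoring convention: recall requires a detection overlapping the injected
plateau; precision counts any detection within the transient's full
support (plateau + 5τ decay) as true, since injected signal is present
there. Not emulated: photon/shot noise statistics, motion, cross-ROI
contamination beyond the neuropil term, bursting temporal structure.

**Ephys sweeps.** RC responses are exact single exponentials (closed-form
ground truth). Stylized APs have a piecewise-linear upstroke whose slope
profile is designed so the sample where dV/dt first reaches 1 % of the
maximal slope is known a priori (pre-threshold segments at 0.5 % of max,
the threshold sample starting a ≥ 2 % run), with a 2-ms descent to a
trough of known depth. EPSP triplets use square or alpha-function pulses
with known per-pulse amplitudes; a square third pulse spanning the whole
60-ms window yields amplitude A and AUC 60·A exactly.

## Problem sizes and tolerances

The test suite and acceptance script use: 100 000 Monte-Carlo trials per
grid point on the 5 × 5 (S, BL) grid, compared at 3 binomial SE (with the
SE floored at the rare-event binomial bound √(max(p̂, p)/n)); 6 fields of
view pooled for recall/precision and 100 seeds each for the zero-rate null
and the coactivity contrast; cohorts of 30 cells/group compared at 3 SE;
100 seeds of noisy RC recovery at a 1 % bound. Exponential fits use
Levenberg–Marquardt with the steady state as initial asymptote; all
stochastic stages derive from a single seed.

## Known limitations

* The morphometry assumes soma-rooted trees; axon nodes are ignored, not
  analyzed.
* Layer boundaries are treated as single-valued functions of the lateral
  coordinate for side tests (fine for near-straight tracings; strongly
  folded boundaries would need a different representation).
* The event detector inherits the threshold rule's false-positive floor
  (see above); population statistics on real data would still require
  curation or the provided filters.
* The combined (distributed OR clustered) response mode is Monte-Carlo
  only; no closed form is claimed.
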