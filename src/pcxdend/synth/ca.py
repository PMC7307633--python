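"""Synthetic population Ca²⁺ fields of view with ground-truth events.

Traces emulate GCaMP6f recordings of neonatal spontaneous network events:
a flat fluorescence baseline, injected transients with an instantaneous
rise, a short plateau and a single-exponential decay (tau 0.5 s), and white
Gaussian noise.  Two event sources are mixed: independent per-cell events,
and *global* network events that recruit each cell by an independent
Bernoulli draw whose probability increases linearly with the cell's depth
in layer 2 — the depth-graded synchrony whose recovery the coactivity
analysis is tested on.

Defaults mirror the recorded study conditions: 95 cells per field of view
(the recorded average), 5 min at 10 Hz, event amplitudes log-normal (median
5 noise-SD, truncated at 3 SD — spontaneous network transients are large
relative to noise) with plateau widths of 3-8 frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..calcium import RoiTraceSet


@dataclass(frozen=True)
class CaFovSpec:
    n_cells: int = 95
    frames: int = 3000
    sampling_rate: float = 10.0            # Hz
    noise_sd: float = 0.05                 # ΔF/F units; the "SD unit" of amplitudes
    baseline_f: float = 100.0              # raw fluorescence baseline
    amp_median_sd: float = 5.0             # event amplitude median, in noise SDs
    amp_sigma_log: float = 0.4
    amp_min_sd: float = 3.0                # truncation floor
    width_range: tuple[int, int] = (3, 8)  # plateau frames at peak amplitude
    decay_tau_s: float = 0.5
    cell_event_rate_per_min: float = 0.5   # independent events per cell
    global_event_rate_per_min: float = 1.0
    recruit_superficial: float = 0.4       # Bernoulli recruitment at depth 0
    recruit_deep: float = 0.8              # ... at depth 1

    def __post_init__(self) -> None:
        if min(self.n_cells, self.frames) <= 0 or self.noise_sd < 0:
            raise ValueError("invalid FOV dimensions or noise level")
        if not (0 <= self.recruit_superficial <= 1
                and 0 <= self.recruit_deep <= 1):
            raise ValueError("recruitment probabilities must be in [0, 1]")
        if min(self.cell_event_rate_per_min, self.global_event_rate_per_min) < 0:
            raise ValueError("rates must be non-negative")
        if self.width_range[0] < 1 or self.width_range[1] < self.width_range[0]:
            raise ValueError("invalid width_range")


@dataclass
class CaFov:
    rois: RoiTraceSet
    truth_events: pd.DataFrame     # roi_id, onset, offset, amplitude_dff, source
    global_onsets: np.ndarray


def gen_ca_fov(spec: CaFovSpec, seed: int = 0) -> CaFov:
    """Generate one field of view of traces plus its ground-truth events.

    Ground-truth onset/offset bracket the plateau of each injected
    transient; amplitudes are in ΔF/F units.  Events are kept clear of the
    trace edges so every injected event is complete within the recording
    (matching the analysis rule that discards incomplete edge events).
    """
    rng = np.random.default_rng(seed)
    duration_min = spec.frames / spec.sampling_rate / 60.0
    depth = rng.uniform(0.0, 1.0, size=spec.n_cells)
    dff = np.zeros((spec.n_cells, spec.frames))
    rows = []

    # global network events with depth-dependent recruitment
    n_global = rng.poisson(spec.global_event_rate_per_min * duration_min)
    margin = spec.width_range[1] + int(5 * spec.decay_tau_s * spec.sampling_rate)
    lo, hi = 2, max(3, spec.frames - margin - 2)
    global_onsets = np.sort(rng.integers(lo, hi, size=n_global))
    p_recruit = spec.recruit_superficial + \
        (spec.recruit_deep - spec.recruit_superficial) * depth
    for onset in global_onsets:
        recruited = rng.random(spec.n_cells) < p_recruit
        for i in np.flatnonzero(recruited):
            rows.append(_inject(dff[i], int(onset), spec, rng, int(i), "global"))

    # independent per-cell events
    for i in range(spec.n_cells):
        n_ev = rng.poisson(spec.cell_event_rate_per_min * duration_min)
        for onset in rng.integers(lo, hi, size=n_ev):
            rows.append(_inject(dff[i], int(onset), spec, rng, i, "cell"))

    noise = rng.normal(0.0, spec.noise_sd, size=dff.shape)
    traces = spec.baseline_f * (1.0 + dff + noise)
    rois = RoiTraceSet(roi_ids=np.arange(spec.n_cells), traces=traces,
                       sampling_rate=spec.sampling_rate, depth_norm=depth)
    truth = pd.DataFrame(
        rows, columns=["roi_id", "onset", "offset", "amplitude_dff", "source"])
    # full injected support of each transient (plateau + decay tail); a
    # detection inside this window sits on real injected signal and is not a
    # false positive
    n_decay = int(5 * spec.decay_tau_s * spec.sampling_rate)
    truth["match_offset"] = (truth["offset"] + n_decay).clip(
        upper=spec.frames - 1)
    truth = truth.sort_values(["roi_id", "onset"]).reset_index(drop=True)
    return CaFov(rois, truth, global_onsets)


def _inject(trace: np.ndarray, onset: int, spec: CaFovSpec,
            rng: np.random.Generator, roi_id: int, source: str) -> tuple:
    amp_sd = max(spec.amp_min_sd,
                 spec.amp_median_sd * rng.lognormal(0.0, spec.amp_sigma_log))
    amp = amp_sd * spec.noise_sd if spec.noise_sd > 0 else amp_sd * 0.01
    width = int(rng.integers(spec.width_range[0], spec.width_range[1] + 1))
    offset = min(onset + width - 1, trace.size - 1)
    trace[onset:offset + 1] += amp
    n_decay = int(5 * spec.decay_tau_s * spec.sampling_rate)
    t = np.arange(1, n_decay + 1)
    stop = min(offset + 1 + n_decay, trace.size)
    trace[offset + 1:stop] += amp * np.exp(
        -t[:stop - offset - 1] / (spec.decay_tau_s * spec.sampling_rate))
    return (roi_id, onset, offset, amp, source)


def match_events(truth: pd.DataFrame, detected: pd.DataFrame
                 ) -> tuple[float, float]:
    """(recall, precision) of detected against ground-truth events.

    A detected event counts as a true positive when its [onset, offset]
    span shares at least one frame with a ground-truth event of the same
    ROI (including the event's suprathreshold decay tail, ``match_offset``);
    recall is the fraction of truth events whose plateau span is covered.
    """
    if truth.empty:
        return (float("nan"), 1.0 if detected.empty else 0.0)
    if detected.empty:
        return 0.0, float("nan")
    hits_truth = 0
    hits_det = np.zeros(len(detected), dtype=bool)
    det_by_roi = {rid: grp for rid, grp in detected.groupby("roi_id")}
    for ev in truth.itertuples():
        grp = det_by_roi.get(ev.roi_id)
        if grp is None:
            continue
        end = getattr(ev, "match_offset", ev.offset)
        overlap_recall = (grp["onset"] <= ev.offset) & (grp["offset"] >= ev.onset)
        overlap_prec = (grp["onset"] <= end) & (grp["offset"] >= ev.onset)
        if overlap_recall.any():
            hits_truth += 1
        hits_det[grp.index[overlap_prec]] = True
    return hits_truth / len(truth), float(hits_det.mean())


# ---------------------------------------------------------------------------
# small movie + label mask (for neuropil correction and the global-event ROI)


def gen_ca_movie(seed: int = 0, frames: int = 600, shape: tuple[int, int] = (64, 64),
                 n_cells: int = 6, cell_radius: int = 4,
                 sampling_rate: float = 10.0, noise_sd: float = 0.02,
                 baseline_f: float = 100.0, n_global: int = 4,
                 neuropil_gain: float = 0.3
                 ) -> tuple[np.ndarray, np.ndarray, dict]:
    """A miniature movie with disk ROIs, a neuropil background signal, and
    injected global transients; returns (movie, labels, truth)."""
    rng = np.random.default_rng(seed)
    h, w = shape
    labels = np.zeros(shape, dtype=int)
    centers = []
    for rid in range(1, n_cells + 1):
        for _ in range(100):
            cy, cx = rng.integers(cell_radius + 2, h - cell_radius - 2), \
                rng.integers(cell_radius + 2, w - cell_radius - 2)
            if all((cy - y) ** 2 + (cx - x) ** 2 > (3 * cell_radius) ** 2
                   for y, x in centers):
                break
        centers.append((cy, cx))
        yy, xx = np.ogrid[:h, :w]
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius ** 2] = rid

    margin = 40
    onsets = np.sort(rng.integers(5, frames - margin, size=n_global))
    global_dff = np.zeros(frames)
    for onset in onsets:
        width = int(rng.integers(3, 7))
        amp = 5.0 * noise_sd
        global_dff[onset:onset + width] += amp
        # decay truncated at 3 tau (residual ~0.1 pixel-SD): the band average
        # is almost noise-free, and a longer tail would graze the detection
        # threshold for many frames
        n_decay = int(3 * 0.5 * sampling_rate)
        t = np.arange(1, n_decay + 1)
        stop = min(onset + width + n_decay, frames)
        global_dff[onset + width:stop] += amp * np.exp(
            -t[:stop - onset - width] / (0.5 * sampling_rate))

    cell_gain = np.where(labels > 0, 1.0, neuropil_gain)
    movie = baseline_f * (1.0 + global_dff[:, None, None] * cell_gain
                          + rng.normal(0, noise_sd, size=(frames, h, w)))
    truth = {"global_onsets": onsets, "centers": centers,
             "global_dff": global_dff}
    return movie, labels, truth
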