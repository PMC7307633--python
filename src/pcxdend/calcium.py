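"""Population Ca²⁺-imaging analysis: ΔF/F, event detection, coactivity.

The analysis follows the classic recipe for spontaneous network events in
neonatal cortex.  Each fluorescence trace is normalized to the contiguous
six-sample window with the lowest SD (the quietest stretch of baseline);
events are maximal runs of frames with ΔF/F above 2.5 noise-SDs lasting at
least two consecutive samples, with runs touching either end of the
recording discarded as incomplete.  Per active neuron, *coactivity* is the
fraction of detected layer-2 neurons in the field of view with a temporally
overlapping event, averaged over the neuron's events — an indirect measure
of functional connectivity that, in aPCx, increases with depth in layer 2.

A note on the noise scale: the minimum-SD window is an order statistic and
systematically underestimates the noise SD of a long stationary trace (by
~7x for a 5-min white-noise trace), which would make a 2.5-SD threshold fire
continuously.  The event threshold therefore defaults to a robust MAD
estimate of the full ΔF/F trace (``noise_method="mad"``); the literal
baseline-window SD remains available via ``noise_method="baseline_window"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASELINE_WINDOW = 6
EVENT_THRESHOLD_SD = 2.5
EVENT_MIN_WIDTH = 2
MIN_RECORDING_S = 300.0   # fields of view need >= 5 min of recording
MIN_ROI_PIXELS = 70
NEUROPIL_RADIUS_PX = 70

EVENT_COLUMNS = ["roi_id", "onset", "offset", "peak_dff"]


@dataclass
class RoiTraceSet:
    """Per-ROI fluorescence traces of one field of view.

    traces has shape (n_rois, n_frames); depth_norm is the soma depth of
    each ROI normalized to the layer-2 width (0 superficial, 1 deep).
    """

    roi_ids: np.ndarray
    traces: np.ndarray
    sampling_rate: float
    depth_norm: np.ndarray | None = None
    pixel_counts: np.ndarray | None = None
    centroids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        self.roi_ids = np.asarray(self.roi_ids)
        if self.traces.shape[0] != self.roi_ids.size:
            raise ValueError("traces and roi_ids disagree on ROI count")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_rois(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sampling_rate

    def filter_small_rois(self, min_pixels: int = MIN_ROI_PIXELS) -> "RoiTraceSet":
        if self.pixel_counts is None:
            return self
        keep = self.pixel_counts >= min_pixels
        return RoiTraceSet(
            roi_ids=self.roi_ids[keep], traces=self.traces[keep],
            sampling_rate=self.sampling_rate,
            depth_norm=None if self.depth_norm is None else self.depth_norm[keep],
            pixel_counts=self.pixel_counts[keep],
            centroids=None if self.centroids is None else self.centroids[keep],
        )


@dataclass
class DffResult:
    dff: np.ndarray
    baseline_mean: float
    baseline_sd: float        # SD of the chosen window, in ΔF/F units
    window_start: int


def delta_f_over_f(trace: np.ndarray, window: int = BASELINE_WINDOW) -> DffResult:
    """Normalize a trace to the contiguous window with the lowest SD.

    F0 is the mean of the earliest minimum-SD window of ``window`` samples;
    ΔF/F = (F − F0)/F0 and the window SD is returned in ΔF/F units.  A
    non-positive F0 is non-physical fluorescence and raises ``ValueError``.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < window:
        raise ValueError(f"trace shorter than the {window}-sample baseline window")
    views = np.lib.stride_tricks.sliding_window_view(trace, window)
    sds = views.std(axis=1)
    start = int(np.argmin(sds))           # argmin returns the earliest tie
    f0 = float(views[start].mean())
    if f0 <= 0:
        raise ValueError(f"baseline mean {f0:.3g} is not positive")
    return DffResult((trace - f0) / f0, f0, float(sds[start]) / f0, start)


def noise_sd(dff: np.ndarray) -> float:
    """Robust noise SD of a ΔF/F trace (scaled median absolute deviation)."""
    dff = np.asarray(dff, dtype=float)
    return float(1.4826 * np.median(np.abs(dff - np.median(dff))))


def detect_events(dff: np.ndarray, baseline_sd: float,
                  threshold_sd: float = EVENT_THRESHOLD_SD,
                  min_width: int = EVENT_MIN_WIDTH,
                  roi_id: int = 0, baseline_level: float = 0.0) -> pd.DataFrame:
    """Maximal suprathreshold runs of ΔF/F, as an event table.

    A run qualifies as an event when dff exceeds ``baseline_level`` (the
    resting level of the ΔF/F trace, 0 by default) by more than
    threshold_sd * baseline_sd for at least ``min_width`` consecutive
    frames, and touches neither the first nor the last frame (incomplete
    events are excluded).  Onset and offset are the inclusive run bounds;
    peak_dff is the run maximum above the baseline level.
    """
    dff = np.asarray(dff, dtype=float)
    if baseline_sd < 0:
        raise ValueError("baseline_sd must be non-negative")
    if baseline_sd == 0:
        warnings.warn("baseline SD is zero; any positive excursion counts")
    mask = dff - baseline_level > threshold_sd * baseline_sd
    rows = []
    for onset, offset in _runs(mask):
        if onset == 0 or offset == dff.size - 1:
            continue
        if offset - onset + 1 < min_width:
            continue
        rows.append({"roi_id": roi_id, "onset": onset, "offset": offset,
                     "peak_dff": float(dff[onset:offset + 1].max()
                                       - baseline_level)})
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) inclusive bounds of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1) - 1
    return list(zip(starts, stops))


def filter_events(events: pd.DataFrame, sampling_rate: float,
                  min_amplitude: float | None = None,
                  min_width: int | None = None,
                  min_iei_s: float | None = None) -> pd.DataFrame:
    """Optional post-hoc filters standing in for manual curation (all off by
    default): minimum peak ΔF/F, minimum width, minimum inter-event interval
    (of two events closer than min_iei the smaller-peak one is dropped)."""
    out = events.copy()
    if min_amplitude is not None:
        out = out[out["peak_dff"] >= min_amplitude]
    if min_width is not None:
        out = out[out["offset"] - out["onset"] + 1 >= min_width]
    if min_iei_s is not None:
        kept = []
        for _, grp in out.groupby("roi_id"):
            grp = grp.sort_values("onset")
            rows = list(grp.itertuples())
            i = 0
            while i + 1 < len(rows):
                gap = (rows[i + 1].onset - rows[i].offset) / sampling_rate
                if gap < min_iei_s:
                    drop = i if rows[i].peak_dff < rows[i + 1].peak_dff else i + 1
                    rows.pop(drop)
                else:
                    i += 1
            kept.extend(rows)
        out = pd.DataFrame([r._asdict() for r in kept]).drop(columns="Index",
                                                             errors="ignore")
        if out.empty:
            out = pd.DataFrame(columns=EVENT_COLUMNS)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# neuropil correction


def neuropil_correct(movie: np.ndarray, labels: np.ndarray, roi_id: int,
                     seed: int, radius_px: int = NEUROPIL_RADIUS_PX,
                     n_pixels: int | None = None
                     ) -> tuple[np.ndarray, dict]:
    """ΔF/F of one ROI minus a local neuropil ΔF/F estimate.

    The neuropil trace is the frame-mean over ``n_pixels`` (default: the ROI
    size) non-cell pixels drawn uniformly without replacement within
    ``radius_px`` of the ROI centroid, with a seeded PRNG so identical seeds
    give identical pixel selections.  Both traces are normalized with the
    same lowest-SD-window rule before subtraction.
    """
    movie = np.asarray(movie, dtype=float)
    roi_mask = labels == roi_id
    if not roi_mask.any():
        raise ValueError(f"roi_id {roi_id} not present in label mask")
    rr, cc = np.nonzero(roi_mask)
    centroid = np.array([rr.mean(), cc.mean()])
    if n_pixels is None:
        n_pixels = rr.size
    rows, cols = np.mgrid[0:labels.shape[0], 0:labels.shape[1]]
    dist2 = (rows - centroid[0]) ** 2 + (cols - centroid[1]) ** 2
    eligible = (labels == 0) & (dist2 <= radius_px ** 2)
    er, ec = np.nonzero(eligible)
    if er.size == 0:
        raise ValueError("no non-cell pixels within the neuropil radius")
    n_take = n_pixels
    if er.size < n_pixels:
        warnings.warn(f"only {er.size} eligible neuropil pixels for ROI "
                      f"{roi_id} (requested {n_pixels}); using all")
        n_take = er.size
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(er.size, size=n_take, replace=False))
    neuropil_trace = movie[:, er[idx], ec[idx]].mean(axis=1)
    roi_trace = movie[:, rr, cc].mean(axis=1)
    roi_dff = delta_f_over_f(roi_trace)
    np_dff = delta_f_over_f(neuropil_trace)
    corrected = roi_dff.dff - np_dff.dff
    info = {"pixel_rows": er[idx], "pixel_cols": ec[idx],
            "roi_dff": roi_dff, "neuropil_dff": np_dff}
    return corrected, info


# ---------------------------------------------------------------------------
# global layer-2 events


@dataclass
class GlobalEventResult:
    status: str                       # "ok" | "excluded: < 5 min"
    rate_per_min: float | None = None
    events: pd.DataFrame | None = None
    trace_dff: np.ndarray | None = None


def global_event_rate(movie: np.ndarray, layer2_band: tuple[int, int],
                      sampling_rate: float,
                      allow_short: bool = False) -> GlobalEventResult:
    """Rate of spontaneous network events from the layer-2 band average.

    The trace is the frame-mean over all pixels of a rectangular ROI
    spanning layer 2 (rows ``layer2_band[0]:layer2_band[1]``), neuropil
    included.  Recordings shorter than 5 min are excluded unless
    ``allow_short`` (a testing override) is set.
    """
    movie = np.asarray(movie, dtype=float)
    trace = movie[:, layer2_band[0]:layer2_band[1], :].mean(axis=(1, 2))
    return global_event_rate_from_trace(trace, sampling_rate, allow_short)


def global_event_rate_from_trace(trace: np.ndarray, sampling_rate: float,
                                 allow_short: bool = False) -> GlobalEventResult:
    trace = np.asarray(trace, dtype=float)
    duration_s = trace.size / sampling_rate
    if duration_s < MIN_RECORDING_S and not allow_short:
        return GlobalEventResult(status="excluded: < 5 min")
    res = delta_f_over_f(trace)
    events = detect_events(res.dff, noise_sd(res.dff),
                           baseline_level=float(np.median(res.dff)))
    rate = len(events) / (duration_s / 60.0)
    return GlobalEventResult("ok", rate, events, res.dff)


# ---------------------------------------------------------------------------
# field-of-view pipeline and coactivity


def detect_fov_events(rois: RoiTraceSet,
                      threshold_sd: float = EVENT_THRESHOLD_SD,
                      min_width: int = EVENT_MIN_WIDTH,
                      noise_method: str = "mad") -> pd.DataFrame:
    """Per-ROI ΔF/F + event detection over a whole field of view.

    With the default robust noise model the threshold is measured from the
    trace's median ΔF/F rather than from zero: the six-sample F0 estimate
    carries a few-percent level error, which would otherwise shift the whole
    trace relative to an absolute threshold ("2.5 SDs *from baseline*").
    """
    if noise_method not in ("mad", "baseline_window"):
        raise ValueError("noise_method must be 'mad' or 'baseline_window'")
    tables = []
    for i in range(rois.n_rois):
        res = delta_f_over_f(rois.traces[i])
        if noise_method == "baseline_window":
            sd, level = res.baseline_sd, 0.0
        else:
            sd, level = noise_sd(res.dff), float(np.median(res.dff))
        tables.append(detect_events(res.dff, sd, threshold_sd, min_width,
                                    roi_id=int(rois.roi_ids[i]),
                                    baseline_level=level))
    tables = [t for t in tables if not t.empty]
    return pd.concat(tables, ignore_index=True) if tables else \
        pd.DataFrame(columns=EVENT_COLUMNS)


def coactivity(events: pd.DataFrame, rois: RoiTraceSet
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean coactive fraction per active ROI, plus the depth-thirds contrast.

    For every event of an active ROI, the coactive set is the other detected
    ROIs in the field of view with at least one event whose [onset, offset]
    span shares a frame with the reference event.  The primary fraction uses
    all detected ROIs minus the reference cell as denominator
    (``coactive_frac``); the self-inclusive convention over all detected
    ROIs is reported alongside (``coactive_frac_incl``).  Fractions are
    averaged over the ROI's events; inactive ROIs yield no record.  Records
    are binned into depth thirds of layer 2 and the superficial-vs-deep
    comparison is returned as the second table.
    """
    n_detected = rois.n_rois
    if n_detected < 1 or events.empty:
        raise ValueError("coactivity requires at least one active ROI")
    # per-frame activity raster of every detected ROI
    active = np.zeros((n_detected, rois.n_frames), dtype=bool)
    roi_index = {int(r): i for i, r in enumerate(rois.roi_ids)}
    for ev in events.itertuples():
        active[roi_index[int(ev.roi_id)], ev.onset:ev.offset + 1] = True

    records = []
    for rid, grp in events.groupby("roi_id"):
        i = roi_index[int(rid)]
        fracs_excl, fracs_incl = [], []
        for ev in grp.itertuples():
            co = active[:, ev.onset:ev.offset + 1].any(axis=1)
            n_co = int(co.sum()) - 1          # other coactive ROIs
            fracs_excl.append(n_co / (n_detected - 1) if n_detected > 1 else 0.0)
            fracs_incl.append((n_co + 1) / n_detected)
        rec = {"roi_id": int(rid), "n_events": len(grp),
               "coactive_frac": float(np.mean(fracs_excl)),
               "coactive_frac_incl": float(np.mean(fracs_incl))}
        if rois.depth_norm is not None:
            rec["depth_norm"] = float(rois.depth_norm[i])
            rec["depth_third"] = depth_third(rois.depth_norm[i])
        records.append(rec)
    records_df = pd.DataFrame(records)

    comparison = pd.DataFrame()
    if "depth_third" in records_df:
        comparison = (records_df.groupby("depth_third")["coactive_frac"]
                      .agg(["mean", "count"]).reindex(
                          ["superficial", "middle", "deep"]).reset_index())
    return records_df, comparison


def depth_third(depth: float) -> str:
    if depth < 1 / 3:
        return "superficial"
    if depth < 2 / 3:
        return "middle"
    return "deep"


def rois_from_labels(movie: np.ndarray, labels: np.ndarray,
                     sampling_rate: float,
                     min_pixels: int = MIN_ROI_PIXELS) -> RoiTraceSet:
    """Mean-trace ROI set from a movie and an integer label mask
    (0 = background); ROIs smaller than ``min_pixels`` are rejected."""
    movie = np.asarray(movie, dtype=float)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    keep, traces, counts, cents = [], [], [], []
    for rid in ids:
        rr, cc = np.nonzero(labels == rid)
        if rr.size < min_pixels:
            continue
        keep.append(int(rid))
        traces.append(movie[:, rr, cc].mean(axis=1))
        counts.append(rr.size)
        cents.append((rr.mean(), cc.mean()))
    if not keep:
        raise ValueError(f"no ROI has >= {min_pixels} pixels")
    return RoiTraceSet(roi_ids=np.array(keep), traces=np.array(traces),
                       sampling_rate=sampling_rate,
                       pixel_counts=np.array(counts),
                       centroids=np.array(cents))


def analyze_movie(movie: np.ndarray, labels: np.ndarray, sampling_rate: float,
                  seed: int, correct_neuropil: bool = True,
                  threshold_sd: float = EVENT_THRESHOLD_SD,
                  min_width: int = EVENT_MIN_WIDTH,
                  min_pixels: int = MIN_ROI_PIXELS
                  ) -> tuple[RoiTraceSet, pd.DataFrame]:
    """Single-cell pipeline on a movie + label mask: per-ROI ΔF/F with
    (by default) local neuropil subtraction, then event detection on the
    corrected trace with a robust noise scale.  The per-ROI neuropil draw is
    seeded from ``seed`` + the ROI id."""
    rois = rois_from_labels(movie, labels, sampling_rate, min_pixels)
    tables = []
    for rid in rois.roi_ids:
        if correct_neuropil:
            dff, _ = neuropil_correct(movie, labels, int(rid),
                                      seed=seed + int(rid))
        else:
            dff = delta_f_over_f(
                rois.traces[list(rois.roi_ids).index(rid)]).dff
        tables.append(detect_events(dff, noise_sd(dff), threshold_sd,
                                    min_width, roi_id=int(rid),
                                    baseline_level=float(np.median(dff))))
    tables = [t for t in tables if not t.empty]
    events = pd.concat(tables, ignore_index=True) if tables else \
        pd.DataFrame(columns=EVENT_COLUMNS)
    return rois, events


def read_movie_tiff(path) -> np.ndarray:
    """Multi-page TIFF movie as a (frames, rows, cols) float array."""
    import tifffile
    return np.asarray(tifffile.imread(path), dtype=float)


def read_labels_tiff(path) -> np.ndarray:
    """Integer ROI label mask (0 = background) from a single-page TIFF."""
    import tifffile
    return np.asarray(tifffile.imread(path)).astype(int)


def read_roi_traces_csv(path, sampling_rate: float,
                        depth: pd.DataFrame | None = None) -> RoiTraceSet:
    """Load a long-format (frame, roi_id, F) trace table into a RoiTraceSet."""
    df = pd.read_csv(path)
    wide = df.pivot(index="roi_id", columns="frame", values="F").sort_index()
    depth_norm = None
    if depth is not None:
        depth_norm = depth.set_index("roi_id").loc[wide.index, "depth_norm"].to_numpy()
    return RoiTraceSet(roi_ids=wide.index.to_numpy(), traces=wide.to_numpy(),
                       sampling_rate=sampling_rate, depth_norm=depth_norm)
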