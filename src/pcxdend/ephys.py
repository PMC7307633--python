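"""Current-clamp feature extraction: passive properties, AP features, EPSPs.

Conventions follow standard slice-physiology practice at 20 kHz sampling:

* passive membrane properties from the voltage response to a hyperpolarizing
  current step — resting potential Vm as the pre-step baseline mean, input
  resistance Rin from the steady-state deflection, membrane time constant
  tau from a single-exponential fit of the onset transient, Cm = tau/Rin;
* AP threshold as the membrane potential where dV/dt first reaches 1% of
  its maximum for that AP; fast AHP as threshold minus the voltage minimum
  within 5 ms after the peak; instantaneous firing frequency from the first
  inter-spike interval, all taken from the first 600-ms step eliciting at
  least nine APs;
* EPSP size for a 3 x 50 Hz stimulus train as the amplitude and the area
  under the baseline-subtracted curve in a 60-ms window after the third
  pulse, with a 50-ms pre-stimulus baseline.

dV/dt uses central differences on the (already low-pass-filtered) trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

AP_PEAK_THRESHOLD_MV = 0.0
AP_REFRACTORY_MS = 1.0
SLOPE_FRACTION = 0.01            # threshold at 1% of max dV/dt
FAHP_WINDOW_MS = 5.0
EPSP_WINDOW_MS = 60.0
EPSP_BASELINE_MS = 50.0
MIN_APS_FOR_STEP = 9
STEADY_STATE_FRACTION = 0.2      # last 20% of the step


@dataclass
class SweepSet:
    """One current-clamp sweep: voltage trace plus stimulus metadata."""

    voltage: np.ndarray              # mV
    sampling_rate: float             # Hz
    step_amplitude_pa: float | None = None
    step_onset_s: float | None = None
    step_duration_s: float | None = None
    stim_times_s: list[float] | None = None   # e.g. three pulses at 50 Hz
    current: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.current is not None and len(self.current) != len(self.voltage):
            raise ValueError("voltage and current must have equal length")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def index(self, t_s: float) -> int:
        return int(round(t_s * self.sampling_rate))


@dataclass
class PassiveProperties:
    vm_mv: float
    rin_mohm: float
    tau_ms: float | None
    cm_pf: float | None
    fit_message: str = "ok"


def passive_properties(sweep: SweepSet) -> PassiveProperties:
    """Vm, Rin, tau and Cm from a hyperpolarizing current step.

    Vm is the pre-step baseline mean (>= 100 ms of baseline required).
    Rin = dV_steady / I with the steady state taken as the mean of the last
    20% of the step.  tau comes from a single-exponential fit of the full
    onset transient; Cm = tau / Rin.  A failed fit leaves tau and Cm missing
    with a diagnostic message.
    """
    if not sweep.step_amplitude_pa:
        raise ValueError("step amplitude must be non-zero")
    i_on = sweep.index(sweep.step_onset_s)
    i_off = sweep.index(sweep.step_onset_s + sweep.step_duration_s)
    if i_on * sweep.dt < 0.1:
        raise ValueError("need >= 100 ms of pre-step baseline")
    vm = float(sweep.voltage[:i_on].mean())
    n_steady = max(1, int(STEADY_STATE_FRACTION * (i_off - i_on)))
    v_steady = float(sweep.voltage[i_off - n_steady:i_off].mean())
    delta_v = v_steady - vm                                   # mV
    rin = delta_v / sweep.step_amplitude_pa * 1e3             # mV/pA -> MΩ
    t = (np.arange(i_off - i_on)) * sweep.dt * 1e3            # ms
    v = sweep.voltage[i_on:i_off]

    def model(t, v_inf, dv, tau):
        return v_inf + dv * np.exp(-t / tau)

    tau_ms = cm_pf = None
    message = "ok"
    try:
        p0 = (v_steady, vm - v_steady, max((i_off - i_on) * sweep.dt * 1e3 / 10, 1.0))
        popt, _ = curve_fit(model, t, v, p0=p0, maxfev=10000)
        tau_ms = float(abs(popt[2]))
        cm_pf = tau_ms / rin * 1e3                            # ms/MΩ -> nF -> pF
    except (RuntimeError, ValueError) as exc:
        message = f"exponential fit failed: {exc}"
    return PassiveProperties(vm, float(rin), tau_ms, cm_pf, message)


# ---------------------------------------------------------------------------
# action potentials


def detect_aps(sweep: SweepSet,
               peak_threshold_mv: float = AP_PEAK_THRESHOLD_MV) -> np.ndarray:
    """Indices of AP peaks: local maxima above 0 mV with >= 1 ms separation."""
    distance = max(1, int(AP_REFRACTORY_MS * 1e-3 * sweep.sampling_rate))
    peaks, _ = find_peaks(sweep.voltage, height=peak_threshold_mv,
                          distance=distance)
    return peaks


@dataclass
class SpikeFeatures:
    ap_threshold_mv: float | None
    fahp_mv: float | None
    instant_freq_hz: float | None
    chosen_step: int | None
    status: str = "ok"


def spike_features(sweeps: list[SweepSet], min_aps: int = MIN_APS_FOR_STEP
                   ) -> SpikeFeatures:
    """AP threshold, fAHP and instantaneous frequency from a step family.

    The features are measured on the first AP of the first step that
    elicits at least ``min_aps`` APs (the comparability rule: features from a fixed firing regime).
    """
    for k, sweep in enumerate(sweeps):
        peaks = detect_aps(sweep)
        if len(peaks) >= min_aps:
            thr, fahp = _first_ap_features(sweep, peaks)
            freq = None
            if len(peaks) >= 2:
                freq = float(sweep.sampling_rate / (peaks[1] - peaks[0]))
            return SpikeFeatures(thr, fahp, freq, k)
    return SpikeFeatures(None, None, None, None,
                         f"no step elicited >= {min_aps} APs")


def ap_threshold_index(sweep: SweepSet, peak: int, search_start: int) -> int:
    """Sample where dV/dt first reaches 1% of this AP's maximal slope.

    The search walks backward from the AP peak within [search_start, peak];
    the threshold is the earliest sample of the contiguous stretch before
    the peak on which dV/dt stays at or above 1% of the AP's maximum slope.
    """
    v = sweep.voltage
    dvdt = np.gradient(v) * sweep.sampling_rate          # mV/s, central diff
    seg = slice(search_start, peak + 1)
    max_slope = dvdt[seg].max()
    i = peak
    while i > search_start and dvdt[i - 1] >= SLOPE_FRACTION * max_slope:
        i -= 1
    return i


def _first_ap_features(sweep: SweepSet, peaks: np.ndarray
                       ) -> tuple[float, float]:
    peak = int(peaks[0])
    # backward search for the first AP is bounded by the step onset (later
    # APs would use the preceding ISI midpoint)
    start = sweep.index(sweep.step_onset_s) if sweep.step_onset_s else 0
    thr_idx = ap_threshold_index(sweep, peak, start)
    threshold = float(sweep.voltage[thr_idx])
    n_win = int(FAHP_WINDOW_MS * 1e-3 * sweep.sampling_rate)
    trough = float(sweep.voltage[peak + 1:peak + 1 + n_win].min())
    return threshold, threshold - trough


# ---------------------------------------------------------------------------
# EPSPs


@dataclass
class EpspMetrics:
    amplitude_mv: float          # peak of the baseline-subtracted window
    amplitude_mean_mv: float     # window mean, alternative convention
    auc_mv_ms: float             # trapezoidal integral over the window
    baseline_mv: float
    has_ap: bool                 # AP inside the analysis window flags the sweep


def epsp_metrics(sweep: SweepSet) -> EpspMetrics:
    """EPSP amplitude and AUC in the 60-ms window after the third pulse.

    Baseline is the 50-ms period before the first stimulus; amplitude is the
    maximum of V - baseline within the window (the window mean is also
    reported) and AUC its trapezoidal integral in mV*ms.
    """
    if not sweep.stim_times_s or len(sweep.stim_times_s) < 3:
        raise ValueError("three stimulus times are required")
    t1, t3 = sweep.stim_times_s[0], sweep.stim_times_s[2]
    i_base0 = sweep.index(t1 - EPSP_BASELINE_MS * 1e-3)
    i_base1 = sweep.index(t1)
    if i_base0 < 0:
        raise ValueError("trace too short for the 50-ms pre-stimulus baseline")
    i_w0 = sweep.index(t3)
    i_w1 = sweep.index(t3 + EPSP_WINDOW_MS * 1e-3)
    if i_w1 > len(sweep.voltage):
        raise ValueError("60-ms analysis window exceeds the trace")
    baseline = float(sweep.voltage[i_base0:i_base1].mean())
    seg = sweep.voltage[i_w0:i_w1 + 1] - baseline
    dt_ms = sweep.dt * 1e3
    return EpspMetrics(
        amplitude_mv=float(seg.max()),
        amplitude_mean_mv=float(seg.mean()),
        auc_mv_ms=float(np.trapezoid(seg, dx=dt_ms)),
        baseline_mv=baseline,
        has_ap=bool((sweep.voltage[i_w0:i_w1 + 1] > AP_PEAK_THRESHOLD_MV).any()),
    )


def apv_comparison(pre: list[tuple[float, SweepSet]],
                   post: list[tuple[float, SweepSet]]) -> dict:
    """Paired EPSP metrics before/after NMDAR block.

    Per condition the largest-stimulus sweep that did not evoke an AP is
    selected (sweeps with an AP in the analysis window are flagged and
    skipped), quantifying the NMDAR contribution to the subthreshold
    response.
    """
    out = {}
    for name, sweeps in (("pre", pre), ("post", post)):
        chosen = None
        for intensity, sweep in sorted(sweeps, key=lambda x: -x[0]):
            m = epsp_metrics(sweep)
            if not m.has_ap:
                chosen = (intensity, m)
                break
        if chosen is None:
            raise ValueError(f"every {name} sweep evoked an AP in the window")
        out[name] = {"intensity": chosen[0],
                     "amplitude_mv": chosen[1].amplitude_mv,
                     "auc_mv_ms": chosen[1].auc_mv_ms}
    out["delta_amplitude_mv"] = out["post"]["amplitude_mv"] - out["pre"]["amplitude_mv"]
    out["delta_auc_mv_ms"] = out["post"]["auc_mv_ms"] - out["pre"]["auc_mv_ms"]
    return out
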