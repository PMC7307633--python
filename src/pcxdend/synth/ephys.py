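"""Synthetic current-clamp sweeps with closed-form ground truth.

Three fixture families: RC step responses (exact single-exponential
charging, so passive-property extraction has a closed-form answer),
stylized AP trains whose upstroke is piecewise linear with a designed slope
profile (the sample where dV/dt first reaches 1% of the maximal slope is
known by construction), and EPSP triplets at 50 Hz with known per-pulse
amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

import json
from pathlib import Path

from ..ephys import SweepSet


@dataclass(frozen=True)
class EphysSpec:
    r_mohm: float = 200.0
    tau_ms: float = 20.0
    vm_mv: float = -70.0
    step_pa: float = -80.0
    sampling_rate: float = 20_000.0
    baseline_s: float = 0.2
    step_s: float = 0.5
    post_s: float = 0.1
    noise_sd_mv: float = 0.0

    def __post_init__(self) -> None:
        if min(self.r_mohm, self.tau_ms, self.sampling_rate) <= 0:
            raise ValueError("R, tau and sampling_rate must be positive")
        if self.sampling_rate < 10_000:
            raise ValueError("sampling_rate must be >= 10 kHz")


def gen_rc_sweep(spec: EphysSpec, seed: int = 0) -> tuple[SweepSet, dict]:
    """Ideal RC response to a current step, plus ground-truth parameters.

    dV_steady = I * R (in mV for pA and MΩ after the 1e-3 factor);
    Cm = tau / R in nF -> pF.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / spec.sampling_rate
    n_base = int(spec.baseline_s / dt)
    n_step = int(spec.step_s / dt)
    n_post = int(spec.post_s / dt)
    dv = spec.step_pa * spec.r_mohm * 1e-3               # mV
    tau_s = spec.tau_ms * 1e-3
    t = np.arange(n_step) * dt
    v = np.concatenate([
        np.full(n_base, spec.vm_mv),
        spec.vm_mv + dv * (1.0 - np.exp(-t / tau_s)),
        spec.vm_mv + dv * (1.0 - np.exp(-spec.step_s / tau_s))
        * np.exp(-np.arange(n_post) * dt / tau_s),
    ])
    if spec.noise_sd_mv > 0:
        v = v + rng.normal(0.0, spec.noise_sd_mv, size=v.size)
    sweep = SweepSet(voltage=v, sampling_rate=spec.sampling_rate,
                     step_amplitude_pa=spec.step_pa,
                     step_onset_s=spec.baseline_s, step_duration_s=spec.step_s)
    truth = {"vm_mv": spec.vm_mv, "rin_mohm": spec.r_mohm,
             "tau_ms": spec.tau_ms,
             "cm_pf": spec.tau_ms / spec.r_mohm * 1e3}
    return sweep, truth


# ---------------------------------------------------------------------------
# stylized action potentials

# fractions of the maximal slope assigned to successive upstroke segments;
# the first segment at/above 1% starts AT the designed threshold sample, and
# central differences cross 1% exactly there (mean of 0.005 and 0.02 > 0.01,
# mean of 0.005 and 0.005 < 0.01)
_UPSTROKE_SLOPES = (0.005, 0.005, 0.005, 0.02, 0.1, 0.4, 1.0, 1.0, 0.6, 0.2)


def _ap_waveform(threshold_mv: float, peak_mv: float, fahp_mv: float,
                 sampling_rate: float) -> tuple[np.ndarray, int]:
    """Piecewise-linear AP; returns (waveform - start value, threshold index)."""
    slopes = np.array(_UPSTROKE_SLOPES)
    rise = np.concatenate([[0.0], np.cumsum(slopes)])
    rise *= (peak_mv - threshold_mv) / rise[-1]
    upstroke = threshold_mv + rise
    thr_idx = 3                                  # first sample of the >=2% run
    trough = threshold_mv - fahp_mv
    n_down = int(round(2e-3 * sampling_rate))    # peak -> trough in 2 ms
    down = np.linspace(peak_mv, trough, n_down + 1)[1:]
    n_rec = int(round(3e-3 * sampling_rate))
    recover = np.linspace(trough, threshold_mv - fahp_mv * 0.3, n_rec + 1)[1:]
    wave = np.concatenate([upstroke, down, recover])
    return wave, thr_idx


def gen_spike_step(n_aps: int = 10, first_isi_ms: float = 25.0,
                   threshold_mv: float = -40.0, peak_mv: float = 30.0,
                   fahp_mv: float = 8.0, holding_mv: float = -55.0,
                   step_pa: float = 200.0, sampling_rate: float = 20_000.0,
                   baseline_s: float = 0.1, step_s: float = 0.6,
                   vm_mv: float = -70.0) -> tuple[SweepSet, dict]:
    """A 600-ms depolarizing step carrying ``n_aps`` stylized APs.

    The first two APs are ``first_isi_ms`` apart (instantaneous frequency
    1000/first_isi_ms); later APs accommodate slightly.  Ground truth:
    threshold voltage, its sample index, fAHP, and the first-ISI frequency.
    """
    dt = 1.0 / sampling_rate
    n_base = int(baseline_s / dt)
    n_step = int(step_s / dt)
    v = np.concatenate([np.full(n_base, vm_mv),
                        np.full(n_step, holding_mv),
                        np.full(int(0.05 / dt), vm_mv)])
    wave, thr_off = _ap_waveform(threshold_mv, peak_mv, fahp_mv, sampling_rate)
    # ramp from holding to threshold ahead of each AP so the pre-threshold
    # slope stays well under 1% of the AP's maximal slope
    n_ramp = int(round(5e-3 * sampling_rate))
    ramp = np.linspace(holding_mv, threshold_mv, n_ramp + 1)[:-1]
    isis_ms = first_isi_ms * (1.0 + 0.1 * np.arange(max(0, n_aps - 1)))
    starts = [n_base + int(0.02 / dt)]
    for isi in isis_ms[:n_aps - 1]:
        starts.append(starts[-1] + int(isi * 1e-3 / dt))
    thr_indices = []
    for s in starts:
        v[s - n_ramp:s] = ramp
        v[s:s + wave.size] = wave
        thr_indices.append(s + thr_off)
    sweep = SweepSet(voltage=v, sampling_rate=sampling_rate,
                     step_amplitude_pa=step_pa, step_onset_s=baseline_s,
                     step_duration_s=step_s)
    # the designed crossing sample sits a fraction of a mV above the nominal
    # threshold parameter; ground truth is read off the constructed waveform
    thr_true = float(v[thr_indices[0]])
    truth = {"threshold_mv": thr_true, "threshold_indices": thr_indices,
             "fahp_mv": thr_true - (threshold_mv - fahp_mv),
             "instant_freq_hz": 1000.0 / first_isi_ms, "n_aps": n_aps}
    return sweep, truth


# ---------------------------------------------------------------------------
# EPSP triplets


def gen_epsp_sweep(amplitudes_mv=(1.0, 1.5, 2.0), shape: str = "alpha",
                   vm_mv: float = -70.0, stim_start_s: float = 0.2,
                   stim_hz: float = 50.0, sampling_rate: float = 20_000.0,
                   duration_s: float = 0.5, alpha_tau_ms: float = 10.0,
                   square_ms: float = 60.0, noise_sd_mv: float = 0.0,
                   seed: int = 0) -> tuple[SweepSet, dict]:
    """Three EPSPs at 50 Hz with known per-pulse peak amplitudes.

    ``shape="square"`` makes each pulse a flat depolarization of
    ``square_ms`` (a square of the third pulse spanning the whole analysis
    window gives amplitude = A and AUC = 60 * A exactly);
    ``shape="alpha"`` uses the standard alpha-function synaptic waveform.
    """
    rng = np.random.default_rng(seed)
    n = int(duration_s * sampling_rate)
    v = np.full(n, vm_mv)
    stim_times = [stim_start_s + k / stim_hz for k in range(3)]
    for amp, t0 in zip(amplitudes_mv, stim_times):
        i0 = int(round(t0 * sampling_rate))
        if shape == "square":
            i1 = min(n, i0 + int(square_ms * 1e-3 * sampling_rate) + 1)
            v[i0:i1] += amp
        elif shape == "alpha":
            t = np.arange(n - i0) / sampling_rate * 1e3      # ms
            tau = alpha_tau_ms
            v[i0:] += amp * (t / tau) * np.exp(1.0 - t / tau)
        else:
            raise ValueError("shape must be 'square' or 'alpha'")
    if noise_sd_mv > 0:
        v = v + rng.normal(0.0, noise_sd_mv, size=n)
    sweep = SweepSet(voltage=v, sampling_rate=sampling_rate,
                     stim_times_s=stim_times)
    truth = {"amplitudes_mv": tuple(amplitudes_mv), "stim_times_s": stim_times,
             "baseline_mv": vm_mv}
    return sweep, truth


# ---------------------------------------------------------------------------
# file export


def gen_ephys_sweeps_dir(spec: EphysSpec, out_dir, seed: int = 0) -> dict:
    """Write one RC, one spike-train and one EPSP sweep as CSV traces with
    JSON sidecars (sampling rate, step/stimulus metadata) plus the combined
    ground truth; returns the truth dictionary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth: dict = {}

    rc, rc_truth = gen_rc_sweep(spec, seed)
    _write_sweep(out_dir / "rc_step", rc, {"kind": "rc_step"})
    truth["rc_step"] = rc_truth

    spk, spk_truth = gen_spike_step(sampling_rate=spec.sampling_rate)
    _write_sweep(out_dir / "spike_step", spk, {"kind": "spike_step"})
    truth["spike_step"] = {k: v for k, v in spk_truth.items()
                           if k != "threshold_indices"}

    ep, ep_truth = gen_epsp_sweep(sampling_rate=spec.sampling_rate, seed=seed)
    _write_sweep(out_dir / "epsp", ep, {"kind": "epsp"})
    truth["epsp"] = {"amplitudes_mv": list(ep_truth["amplitudes_mv"]),
                     "stim_times_s": ep_truth["stim_times_s"]}

    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return truth


def _write_sweep(stem: Path, sweep: SweepSet, extra: dict) -> None:
    np.savetxt(stem.with_suffix(".csv"), sweep.voltage, delimiter=",")
    meta = {"sampling_rate": sweep.sampling_rate,
            "step_amplitude_pa": sweep.step_amplitude_pa,
            "step_onset_s": sweep.step_onset_s,
            "step_duration_s": sweep.step_duration_s,
            "stim_times_s": sweep.stim_times_s, **extra}
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))
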