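"""Scalar electrophysiological features from voltage traces.

Conventions:

- spike detection threshold is -20 mV; the spike time is the time of the
  voltage peak within the contiguous suprathreshold window;
- spike-dependent features are *absent* (missing from the mapping), never
  zero, when the trace carries no spike;
- units: mV, ms, Hz, MOhm.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize as _opt
from scipy import stats as _stats

__all__ = [
    "SPIKE_THRESHOLD_MV",
    "detect_spikes",
    "timing_features",
    "adaptation_index",
    "shape_features",
    "subthreshold_features",
    "membrane_time_constant",
    "input_resistance",
    "extract_all",
    "trend_and_group_stats",
    "FEATURE_NAMES",
]

SPIKE_THRESHOLD_MV = -20.0

FEATURE_NAMES = (
    "voltage_base", "steady_state_voltage", "voltage_deflection",
    "sag_amplitude", "spikecount_stimint", "time_to_first_spike",
    "time_to_last_spike", "inv_first_ISI", "inv_second_ISI",
    "inv_third_ISI", "inv_fourth_ISI", "inv_fifth_ISI", "inv_last_ISI",
    "mean_frequency", "adaptation_index", "AP_amplitude", "AP_width",
    "membrane_time_constant", "input_resistance",
)

_ISI_ORDINALS = ("first", "second", "third", "fourth", "fifth")


def detect_spikes(trace, threshold: float = SPIKE_THRESHOLD_MV) -> np.ndarray:
    """Spike times (ms): one per contiguous suprathreshold window, at the
    window's voltage peak."""
    t = np.asarray(trace.time, float)
    v = np.asarray(trace.voltage, float)
    above = v > threshold
    if not above.any():
        return np.empty(0)
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(v))
    times = []
    for s, e in zip(starts, ends):
        times.append(t[s + int(np.argmax(v[s:e]))])
    return np.asarray(times)


def timing_features(spike_times, stim_window) -> dict:
    """Spike-timing features restricted to the stimulus interval."""
    onset, offset = stim_window
    if offset <= onset:
        raise ValueError("invalid stimulus window")
    st = np.asarray(spike_times, float)
    st = st[(st >= onset) & (st <= offset)]
    out = {"spikecount_stimint": float(len(st)),
           "mean_frequency": 1000.0 * len(st) / (offset - onset)}
    if len(st) >= 1:
        out["time_to_first_spike"] = float(st[0] - onset)
        out["time_to_last_spike"] = float(st[-1] - onset)
    isis = np.diff(st)
    for k, ordinal in enumerate(_ISI_ORDINALS):
        if len(isis) > k:
            out[f"inv_{ordinal}_ISI"] = 1000.0 / isis[k]
    if len(isis) >= 1:
        out["inv_last_ISI"] = 1000.0 / isis[-1]
    return out


def adaptation_index(spike_times):
    """Mean of (ISI_{i+1} - ISI_i)/(ISI_{i+1} + ISI_i); needs >= 3 spikes."""
    st = np.asarray(spike_times, float)
    if len(st) < 3:
        return None
    isis = np.diff(st)
    pairs = (isis[1:] - isis[:-1]) / (isis[1:] + isis[:-1])
    return float(np.mean(pairs))


def shape_features(trace, spike_times=None,
                   threshold: float = SPIKE_THRESHOLD_MV) -> dict:
    """First-AP amplitude/width at the threshold, plus the phase plot.

    AP_amplitude = peak voltage minus the voltage at the upward threshold
    crossing; AP_width = time between upward and downward threshold
    crossings around the peak.  Spikes truncated at the trace edge yield no
    AP features.
    """
    t = np.asarray(trace.time, float)
    v = np.asarray(trace.voltage, float)
    if spike_times is None:
        spike_times = detect_spikes(trace, threshold)
    out = {}
    dv = np.gradient(v, t)
    out["phase_plot"] = np.column_stack([v, dv])
    if len(spike_times) == 0:
        return out
    ipk = int(np.argmin(np.abs(t - spike_times[0])))
    above = v > threshold
    s = ipk
    while s > 0 and above[s - 1]:
        s -= 1
    e = ipk
    while e < len(v) - 1 and above[e + 1]:
        e += 1
    if s == 0 or e == len(v) - 1:
        return out  # truncated at the trace edge
    # sub-sample linear interpolation of the crossing times
    t_up = t[s - 1] + (threshold - v[s - 1]) / (v[s] - v[s - 1]) * (t[s] - t[s - 1])
    t_dn = t[e] + (threshold - v[e]) / (v[e + 1] - v[e]) * (t[e + 1] - t[e])
    out["AP_amplitude"] = float(v[ipk] - threshold)
    out["AP_width"] = float(t_dn - t_up)
    return out


def subthreshold_features(trace, stim_window=None,
                          steady_fraction: float = 0.1) -> dict:
    """Base/steady-state voltages, deflection and sag amplitude.

    steady_state_voltage averages the final ``steady_fraction`` of the
    stimulus; sag_amplitude = steady state minus stimulus minimum (>= 0).
    """
    if stim_window is None:
        stim_window = trace.stimulus_window()
    onset, offset = stim_window
    t = np.asarray(trace.time, float)
    v = np.asarray(trace.voltage, float)
    if onset < t[0] or offset > t[-1] + 1e-9:
        raise ValueError("stimulus window outside trace")
    pre = v[t < onset]
    base = float(np.mean(pre)) if pre.size else float(v[0])
    tail = v[(t >= offset - steady_fraction * (offset - onset)) & (t <= offset)]
    steady = float(np.mean(tail))
    during = v[(t >= onset) & (t <= offset)]
    out = {
        "voltage_base": base,
        "steady_state_voltage": steady,
        "voltage_deflection": steady - base,
        "sag_amplitude": max(0.0, steady - float(during.min())),
    }
    return out


def membrane_time_constant(trace, stim_window=None, cap_ms: float = 100.0):
    """Single-exponential fit of the initial hyperpolarizing response.

    The fit window runs from stimulus onset to the time of the voltage
    minimum, capped at ``cap_ms``.  Returns tau in ms, or None with no
    convergence.
    """
    if stim_window is None:
        stim_window = trace.stimulus_window()
    onset, offset = stim_window
    t = np.asarray(trace.time, float)
    v = np.asarray(trace.voltage, float)
    pre = v[t < onset]
    base = float(np.mean(pre)) if pre.size else float(v[0])
    during = (t >= onset) & (t <= offset)
    vmin_t = t[during][int(np.argmin(v[during]))]
    if v[during].min() >= base:
        raise ValueError("membrane_time_constant requires a hyperpolarizing "
                         "response")
    end = min(vmin_t, onset + cap_ms)
    sel = (t >= onset) & (t <= end)
    ts = t[sel] - onset
    vs = v[sel]
    amp0 = vs[-1] - base

    def model(ts, amp, tau):
        return base + amp * (1.0 - np.exp(-ts / tau))

    try:
        popt, _ = _opt.curve_fit(model, ts, vs, p0=(amp0, 15.0),
                                 bounds=([-np.inf, 1e-3], [np.inf, 1e4]),
                                 maxfev=5000)
    except RuntimeError:
        return None
    tau = float(abs(popt[1]))
    return tau if np.isfinite(tau) and tau > 0 else None


def input_resistance(traces) -> float:
    """Ohm's law on the smallest-magnitude negative injection, in MOhm."""
    neg = [tr for tr in traces if tr.meta.get("amplitude", 0) < 0]
    if not neg:
        raise ValueError("input_resistance needs a negative injection")
    tr = min(neg, key=lambda tr: abs(tr.meta["amplitude"]))
    f = subthreshold_features(tr)
    return f["voltage_deflection"] / tr.meta["amplitude"]  # mV/nA = MOhm


def extract_all(trace, stim_window=None,
                threshold: float = SPIKE_THRESHOLD_MV) -> dict:
    """All single-trace features applicable to ``trace``."""
    if stim_window is None:
        stim_window = trace.stimulus_window()
    spikes = detect_spikes(trace, threshold)
    out = dict(subthreshold_features(trace, stim_window))
    out.update(timing_features(spikes, stim_window))
    ai = adaptation_index(spikes[(spikes >= stim_window[0])
                                 & (spikes <= stim_window[1])])
    if ai is not None:
        out["adaptation_index"] = ai
    shape = shape_features(trace, spikes, threshold)
    for key in ("AP_amplitude", "AP_width"):
        if key in shape:
            out[key] = shape[key]
    if trace.meta.get("amplitude", 0) < 0:
        try:
            tau = membrane_time_constant(trace, stim_window)
        except ValueError:
            tau = None
        if tau is not None:
            out["membrane_time_constant"] = tau
    return out


def trend_and_group_stats(table, feature: str, amplitude_col: str = "amplitude",
                          species_col: str = "species",
                          cell_col: str = "cell",
                          normality_alpha: float = 0.05) -> dict:
    """Per-species OLS slope of mean feature vs amplitude, plus per-amplitude
    two-sample comparisons (t-test when both groups pass a Shapiro normality
    gate, Mann-Whitney rank-sum otherwise).  No multiple-testing correction.
    """
    import pandas as pd

    df = pd.DataFrame(table) if not hasattr(table, "groupby") else table
    df = df.dropna(subset=[feature])
    out = {"feature": feature, "slopes": {}, "per_amplitude": {}}
    for sp, sub in df.groupby(species_col):
        means = sub.groupby(amplitude_col)[feature].mean()
        if len(means) < 2:
            continue
        slope, intercept = np.polyfit(means.index.values, means.values, 1)
        out["slopes"][sp] = float(slope)
    species = sorted(df[species_col].unique())
    if len(species) == 2:
        a_name, b_name = species
        for amp, sub in df.groupby(amplitude_col):
            a = sub.loc[sub[species_col] == a_name, feature].values
            b = sub.loc[sub[species_col] == b_name, feature].values
            if len(a) < 2 or len(b) < 2:
                continue
            normal = True
            for grp in (a, b):
                if len(grp) >= 3 and np.ptp(grp) > 0:
                    normal &= _stats.shapiro(grp).pvalue > normality_alpha
                else:
                    normal = False
            if normal:
                test, stat = "t", _stats.ttest_ind(a, b)
            else:
                test, stat = "ranksum", _stats.mannwhitneyu(
                    a, b, alternative="two-sided")
            out["per_amplitude"][float(amp)] = {
                "test": test, "p_value": float(stat.pvalue),
                "mean_" + a_name: float(np.mean(a)),
                "mean_" + b_name: float(np.mean(b)),
            }
    return out
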