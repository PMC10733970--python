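"""Independent reference implementations used as test oracles.

Deliberately written as plain loops / first-principles formulas, sharing no
code with the package, so that agreement is evidence and not tautology.
"""

import math

import numpy as np


# -- feature extraction (straight transcription of the definitions) ---------

def spikes_oracle(t, v, threshold=-20.0):
    out = []
    i, n = 0, len(v)
    while i < n:
        if v[i] > threshold:
            j = i
            while j < n and v[j] > threshold:
                j += 1
            best = i
            for k in range(i, j):
                if v[k] > v[best]:
                    best = k
            out.append(t[best])
            i = j
        else:
            i += 1
    return out


def timing_oracle(spike_times, onset, offset):
    st = [s for s in spike_times if onset <= s <= offset]
    out = {"spikecount_stimint": float(len(st)),
           "mean_frequency": 1000.0 * len(st) / (offset - onset)}
    if st:
        out["time_to_first_spike"] = st[0] - onset
        out["time_to_last_spike"] = st[-1] - onset
    isis = [st[i + 1] - st[i] for i in range(len(st) - 1)]
    ordinals = ["first", "second", "third", "fourth", "fifth"]
    for k, name in enumerate(ordinals):
        if len(isis) > k:
            out[f"inv_{name}_ISI"] = 1000.0 / isis[k]
    if isis:
        out["inv_last_ISI"] = 1000.0 / isis[-1]
    return out


def adaptation_oracle(spike_times):
    if len(spike_times) < 3:
        return None
    isis = [spike_times[i + 1] - spike_times[i]
            for i in range(len(spike_times) - 1)]
    acc = 0.0
    for i in range(len(isis) - 1):
        acc += (isis[i + 1] - isis[i]) / (isis[i + 1] + isis[i])
    return acc / (len(isis) - 1)


def subthreshold_oracle(t, v, onset, offset, steady_fraction=0.1):
    pre = [vv for tt, vv in zip(t, v) if tt < onset]
    base = sum(pre) / len(pre) if pre else v[0]
    t0 = offset - steady_fraction * (offset - onset)
    tail = [vv for tt, vv in zip(t, v) if t0 <= tt <= offset]
    steady = sum(tail) / len(tail)
    during = [vv for tt, vv in zip(t, v) if onset <= tt <= offset]
    return {"voltage_base": base,
            "steady_state_voltage": steady,
            "voltage_deflection": steady - base,
            "sag_amplitude": max(0.0, steady - min(during))}


def ap_shape_oracle(t, v, threshold=-20.0):
    spikes = spikes_oracle(t, v, threshold)
    if not spikes:
        return {}
    ipk = min(range(len(t)), key=lambda i: abs(t[i] - spikes[0]))
    s = ipk
    while s > 0 and v[s - 1] > threshold:
        s -= 1
    e = ipk
    while e < len(v) - 1 and v[e + 1] > threshold:
        e += 1
    if s == 0 or e == len(v) - 1:
        return {}
    t_up = t[s - 1] + (threshold - v[s - 1]) / (v[s] - v[s - 1]) \
        * (t[s] - t[s - 1])
    t_dn = t[e] + (threshold - v[e]) / (v[e + 1] - v[e]) * (t[e + 1] - t[e])
    return {"AP_amplitude": v[ipk] - threshold, "AP_width": t_dn - t_up}


# -- linear algebra ----------------------------------------------------------

def pca_oracle(X):
    """Eigendecomposition of the sample covariance; returns eigenvalues in
    decreasing order and the projection variances."""
    X = np.asarray(X, float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    scores = Xc @ V
    return w, scores, V.T


# -- cable theory ------------------------------------------------------------

def rc_step_response(t, i_nA, c_pF, g_nS, e_mV, delay, duration):
    """Closed-form membrane response of an RC compartment to a current step."""
    tau = c_pF / g_nS  # ms
    dv = i_nA / g_nS * 1e3  # mV
    out = np.full_like(np.asarray(t, float), e_mV)
    on = (t >= delay) & (t < delay + duration)
    out[on] = e_mV + dv * (1 - np.exp(-(t[on] - delay) / tau))
    t_off = t[t >= delay + duration]
    if t_off.size:
        v_end = e_mV + dv * (1 - math.exp(-duration / tau))
        out[t >= delay + duration] = e_mV + (v_end - e_mV) * np.exp(
            -(t_off - delay - duration) / tau)
    return out


def cable_lambda_um(diam_um, rm_ohm_cm2, ra_ohm_cm):
    lam_cm = math.sqrt(diam_um * 1e-4 * rm_ohm_cm2 / (4 * ra_ohm_cm))
    return lam_cm * 1e4
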