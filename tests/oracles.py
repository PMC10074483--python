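"""Independent brute-force oracles used to validate the implementations.

These deliberately trade speed for obviousness: plain per-sample state
machines and direct formula evaluations, kept separate from the package.
"""

from __future__ import annotations

import numpy as np


def detect_oracle(v, sampling_rate, high, low, energy_window_ms, refractory_ms, max_wave_ms):
    """Naive sample-by-sample threshold-crossing state machine.

    Returns a list of (onset_sample, last_crossing_sample, amplitude).
    """
    v = np.asarray(v, dtype=float)
    to_samples = lambda ms: max(1, int(round(ms * sampling_rate / 1000.0)))
    ew = to_samples(energy_window_ms)
    ref = to_samples(refractory_ms)
    cap = to_samples(max_wave_ms)

    events = []
    open_event = False
    onset = last = 0
    last_onset = -ref - 1

    def close():
        events.append((onset, last, float(np.max(np.abs(v[onset : last + 1])))))

    for t in range(len(v)):
        crossing = v[t] > high or v[t] < low
        if open_event:
            if crossing and t - onset <= cap and t - last <= ew:
                last = t
                continue
            if crossing or t - last > ew or t - onset > cap:
                close()
                last_onset = onset
                open_event = False
            else:
                continue
        if not open_event and crossing and t - last_onset >= ref:
            open_event = True
            onset = last = t
    if open_event:
        close()
    return events


def segment_oracle(times, max_gap):
    """Brute-force discharge segmentation: scan pairwise gaps."""
    groups = []
    current = []
    for t in times:
        if current and t - current[-1] > max_gap:
            groups.append(current)
            current = []
        current.append(t)
    if current:
        groups.append(current)
    return groups


def mwu_u(x, y):
    """U statistic of x by direct pairwise comparison (ties count 1/2)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def chi2_2x2(k1, n1, k2, n2):
    """Pearson chi-square from the expected-count definition."""
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    return float(((obs - expected) ** 2 / expected).sum())


def kruskal_h(groups):
    """Tie-corrected Kruskal-Wallis H from the rank-sum formula."""
    from scipy.stats import rankdata

    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    pos = 0
    for g in groups:
        r = ranks[pos : pos + len(g)]
        h += r.sum() ** 2 / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction
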