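"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain frame-by-frame Python, deliberately
sharing no code with the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def boxcar_reference(signal, width):
    """Windowed mean over {t - w//2 .. t + w - w//2 - 1}, loop form."""
    n = len(signal)
    left = width // 2
    right = width - left - 1
    out = []
    for t in range(n):
        window = [signal[i] for i in range(max(0, t - left), min(n, t + right + 1))]
        out.append(sum(window) / len(window))
    return np.array(out)


def runs_reference(signal, valid, tau):
    """Maximal runs with signal >= tau on valid frames, by linear scan."""
    runs = []
    start = None
    for i in range(len(signal)):
        active = signal[i] >= tau and valid[i]
        if active and start is None:
            start = i
        elif not active and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(signal) - 1))
    return runs


def event_chain_reference(au12, au06, valid, fps, *, width=4, tau=0.5,
                          min_s=1.0, overlap_thr=0.5):
    """Reference for the full smooth -> detect -> filter -> classify chain.

    Returns a list of dicts with the same content as the package's
    SmileEvent: inclusive frame indices, type, overlap fraction and means of
    the smoothed signals.
    """
    s12 = boxcar_reference(au12, width)
    s06 = boxcar_reference(au06, width)
    runs12 = [r for r in runs_reference(s12, valid, tau)
              if (r[1] - r[0] + 1) / fps >= min_s]
    active06 = [s06[i] >= tau and valid[i] for i in range(len(au06))]
    events = []
    for a, b in runs12:
        frames = list(range(a, b + 1))
        covered = sum(1 for i in frames if active06[i])
        frac = covered / len(frames)
        events.append({
            "start": a,
            "end": b,
            "type": "SO" if frac >= overlap_thr else "SI",
            "overlap": frac,
            "mean12": float(np.mean([s12[i] for i in frames])),
            "mean06": float(np.mean([s06[i] for i in frames])),
            "duration": len(frames) / fps,
        })
    return events


def hotelling_t2_f(x1, x2):
    """Two-sample Hotelling T^2 and its exact F transform, computed directly."""
    x1 = np.atleast_2d(np.asarray(x1, float))
    x2 = np.atleast_2d(np.asarray(x2, float))
    n1, p = x1.shape
    n2 = x2.shape[0]
    d = x1.mean(axis=0) - x2.mean(axis=0)
    s1 = np.cov(x1, rowvar=False, ddof=1).reshape(p, p)
    s2 = np.cov(x2, rowvar=False, ddof=1).reshape(p, p)
    s_pooled = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    t2 = (n1 * n2) / (n1 + n2) * d @ np.linalg.solve(s_pooled, d)
    n = n1 + n2
    f = t2 * (n - p - 1) / ((n - 2) * p)
    return float(t2), float(f), p, n - p - 1


def pearson_chi2(table):
    """Uncorrected Pearson chi-squared on a contingency table, by hand."""
    table = np.asarray(table, float)
    total = table.sum()
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / total
    return float(((table - expected) ** 2 / expected).sum())
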