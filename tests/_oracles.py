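"""Independent brute-force oracles: plain Python loops, no vectorization.

These re-implement the smoothing filter and the four onset estimators
naively so the package implementations can be checked against a second,
independently written route.  They intentionally share no code with
``delmep``.
"""

import math


def naive_smooth(x, window):
    """Per-position mean over the centered window, shrunk at the edges."""
    h = window // 2
    out = []
    for i in range(len(x)):
        lo = max(0, i - h)
        hi = min(len(x), i + h + 1)
        out.append(sum(x[lo:hi]) / (hi - lo))
    return out


def _to_ms(idx, fs_hz, trim_start_ms):
    return trim_start_ms + 1000.0 * idx / fs_hz


def naive_signal_hunter(x, fs_hz=3000.0, magic=5, window=3, trim_start_ms=10.0):
    """Returns latency in ms, or None if discarded."""
    s = naive_smooth(list(x), window)
    d = [s[i + 1] - s[i] for i in range(len(s) - 1)]
    if all(abs(di) < 1e-30 for di in d):
        return None
    mean = sum(d) / len(d)
    sd = math.sqrt(sum((di - mean) ** 2 for di in d) / len(d))
    best_i, best_v = 0, None
    for i, di in enumerate(d):
        v = abs(di) - sd
        if best_v is None or v > best_v:
            best_i, best_v = i, v
    idx = best_i - magic
    if idx < 0:
        return None
    return _to_ms(idx, fs_hz, trim_start_ms)


def naive_ahte(x, fs_hz=3000.0, magic=5, v_thr=0.10, trim_start_ms=10.0):
    a = [abs(xi) for xi in x]
    peak = max(a)
    if peak <= 0.0:
        return None
    thr = v_thr * peak
    cross = None
    for i, ai in enumerate(a):
        if ai >= thr:
            cross = i
            break
    idx = cross - magic
    if idx < 0:
        return None
    return _to_ms(idx, fs_hz, trim_start_ms)


def naive_shte(x, fs_hz=3000.0, magic=5, v_thr=0.10, trim_start_ms=10.0):
    a = [xi * xi for xi in x]
    peak = max(a)
    if peak <= 0.0:
        return None
    thr = v_thr * peak
    cross = None
    for i, ai in enumerate(a):
        if ai >= thr:
            cross = i
            break
    idx = cross - magic
    if idx < 0:
        return None
    return _to_ms(idx, fs_hz, trim_start_ms)


def naive_bigoni(x, fs_hz=3000.0, min_run=5, trim_start_ms=10.0):
    a = [abs(xi) for xi in x]
    if max(a) - min(a) < 1e-30:
        return None
    peak = a.index(max(a))
    d = [a[i + 1] - a[i] for i in range(peak)]
    if not d:
        return None
    runs = []  # (start, length) of every maximal positive run
    i = 0
    while i < len(d):
        if d[i] > 0.0:
            j = i
            while j < len(d) and d[j] > 0.0:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    if not runs:
        return None
    best_len = max(length for _, length in runs)
    if best_len < min_run:
        return None
    for start, length in runs:  # earliest maximal run
        if length == best_len:
            return _to_ms(start, fs_hz, trim_start_ms)
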