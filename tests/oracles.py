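"""Independent brute-force reference implementations used as test oracles.

Everything here is written directly from the definitions, with plain loops
and no shared code with the package, so agreement with the package is a
genuine dual-route check.
"""

import math

import numpy as np


def sampen_naive(x, m=2, r_factor=0.2):
    """Sample entropy by explicit template counting (O(n^2) loops)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = np.sqrt(np.mean((x - x.mean()) ** 2))
    r = r_factor * sd

    def matches(mm):
        # n - m templates at both lengths (standard convention)
        count = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    count += 1
        return count

    b = matches(m)
    a = matches(m + 1)
    if b == 0 or a == 0:
        return math.nan
    return -math.log(a / b)


def prsa_waveform_naive(x, kind, wing=50):
    """Anchor-window averaging by explicit loops."""
    x = np.asarray(x, dtype=float)
    windows = []
    for i in range(1, len(x)):
        is_anchor = x[i] > x[i - 1] if kind == "decel" else x[i] < x[i - 1]
        if is_anchor and i - wing >= 0 and i + wing <= len(x):
            windows.append(x[i - wing : i + wing])
    if not windows:
        return None
    return np.mean(np.stack(windows), axis=0)


def fragmentation_naive(x):
    """PIP/PAS/PSS/IALS by direct enumeration of sign runs.

    Zero increments terminate runs, are never inflections and belong to no
    segment.  Run lengths are counted in increments; an NN interval lies
    inside a run (or alternation stretch) if it bounds one of its
    increments; alternation stretches qualify at >= 4 NN intervals.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    s = [int(np.sign(d)) for d in np.diff(x)]
    if not any(s):
        return {"pip": 0.0, "pas": 0.0, "pss": 100.0, "ials": 0.0}

    inflections = 0
    for i in range(1, len(s)):
        if s[i] != 0 and s[i - 1] != 0 and s[i] != s[i - 1]:
            inflections += 1
    pip = 100.0 * inflections / n

    runs = []
    i = 0
    while i < len(s):
        if s[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < len(s) and s[j + 1] == s[i]:
            j += 1
        runs.append((i, j - i + 1))
        i = j + 1
    ials = 1.0 / (sum(L for _, L in runs) / len(runs))

    in_short = [False] * n
    for start, L in runs:
        if L < 3:
            for k in range(start, start + L + 1):
                in_short[k] = True
    pss = 100.0 * sum(in_short) / n

    in_alt = [False] * n
    i = 0
    while i < len(s):
        if s[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < len(s) and s[j + 1] != 0 and s[j + 1] != s[j]:
            j += 1
        if (j - i + 2) >= 4:
            for k in range(i, j + 2):
                in_alt[k] = True
        i = j + 1
    pas = 100.0 * sum(in_alt) / n
    return {"pip": pip, "pas": pas, "pss": pss, "ials": ials}
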