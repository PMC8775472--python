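"""Independent brute-force reference implementations used as test oracles.

These are deliberately written as plain-Python double loops straight from
the definitions, with no shared code with the package implementations.
"""

import math

import numpy as np
from scipy import signal as _sig


def naive_sample_entropy(x, m, r):
    """O(N^2) sample entropy: Chebyshev distance, self-matches excluded,
    N-m templates for both lengths."""
    x = list(map(float, x))
    n = len(x)
    nt = n - m
    a = b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if dm <= r:
                b += 1
                if max(dm, abs(x[i + m] - x[j + m])) <= r:
                    a += 1
    if a == 0 or b == 0:
        return -math.log(2.0 / ((n - m - 1) * (n - m)))
    return -math.log(a / b)


def naive_fuzzy_entropy(x, m, nexp, r):
    """O(N^2) fuzzy entropy: mean-centred templates, membership
    exp(-d^n / r), N-m templates for both lengths."""
    x = list(map(float, x))
    n = len(x)
    nt = n - m

    def phi(length):
        tot = 0.0
        cnt = 0
        for i in range(nt - 1):
            ci = sum(x[i:i + length]) / length
            for j in range(i + 1, nt):
                cj = sum(x[j:j + length]) / length
                d = max(abs((x[i + k] - ci) - (x[j + k] - cj))
                        for k in range(length))
                tot += math.exp(-(d ** nexp) / r)
                cnt += 1
        return tot / cnt

    pm, pm1 = phi(m), phi(m + 1)
    if pm <= 0 or pm1 <= 0:
        return -math.log(2.0 / ((n - m - 1) * (n - m)))
    return -math.log(pm1 / pm)


def naive_multiscale_entropy(x, tau, m, r):
    """Coarse-grain by hand (block means), then naive sample entropy with
    the radius anchored to the original series."""
    x = list(map(float, x))
    nb = len(x) // tau
    coarse = [sum(x[i * tau:(i + 1) * tau]) / tau for i in range(nb)]
    return naive_sample_entropy(coarse, m, r)


def band_power(x, rate, lo, hi):
    """Direct (single-window) periodogram power in [lo, hi) Hz; independent
    of the package's Welch-based spectral path."""
    f, p = _sig.periodogram(np.asarray(x, float), fs=rate)
    mask = (f >= lo) & (f < hi)
    return float(np.sum(p[mask]))
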