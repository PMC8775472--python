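"""Regularity measures on single-channel EEG epochs.

Three estimators are provided:

* :func:`sample_entropy` -- SampEn(m, r): the negative log conditional
  probability that two sequences matching for m points (Chebyshev distance
  <= r, self-matches excluded) also match for m+1 points.
* :func:`fuzzy_entropy` -- FuzzyEn(m, n, r): the hard match threshold is
  replaced by an exponential membership exp(-d^n / r) evaluated on
  mean-centred templates, which grades near-matches smoothly.
* :func:`multiscale_entropy` -- SampEn evaluated on a coarse-grained series
  (non-overlapping block means of tau consecutive samples), with the match
  radius anchored to the ORIGINAL series' standard deviation.

Both SampEn and FuzzyEn compare the N - m templates starting at indices
0 .. N-m-1, for both template lengths, so the two counts are taken over the
same pair set. The O(N^2) pair scans are compiled with numba.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .exceptions import DataError

__all__ = ["sample_entropy", "fuzzy_entropy", "multiscale_entropy",
           "coarse_grain", "sampen_cap"]


@njit(cache=True)
def _sampen_pair_counts(x, m, r):  # pragma: no cover - compiled
    n = x.shape[0] - m
    a = 0
    b = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = 0.0
            for k in range(m):
                t = abs(x[i + k] - x[j + k])
                if t > d:
                    d = t
            if d <= r:
                b += 1
                t = abs(x[i + m] - x[j + m])
                if t > d:
                    d = t
                if d <= r:
                    a += 1
    return a, b


@njit(cache=True, fastmath=True)
def _fuzzy_phi(x, mlen, ntempl, nexp, r):  # pragma: no cover - compiled
    means = np.empty(ntempl)
    for i in range(ntempl):
        s = 0.0
        for k in range(mlen):
            s += x[i + k]
        means[i] = s / mlen
    # beyond d_cut the membership is < exp(-45) ~ 3e-20: far below the
    # 1e-12 accuracy of the estimator, so those pairs skip the exp
    d_cut = (45.0 * r) ** (1.0 / nexp)
    is_sq = nexp == 2.0
    phi = 0.0
    for i in range(ntempl - 1):
        ci = means[i]
        for j in range(i + 1, ntempl):
            cj = means[j]
            d = 0.0
            for k in range(mlen):
                t = abs((x[i + k] - ci) - (x[j + k] - cj))
                if t > d:
                    d = t
            if d <= d_cut:
                if is_sq:
                    phi += math.exp(-(d * d) / r)
                else:
                    phi += math.exp(-(d ** nexp) / r)
    return phi / (ntempl * (ntempl - 1) / 2.0)


def sampen_cap(n: int, m: int) -> float:
    """Finite-sample upper bound -ln(2 / ((N-m-1)(N-m))) used as a sentinel
    when no template pair matches at length m+1."""
    return -math.log(2.0 / ((n - m - 1) * (n - m)))


def sample_entropy(x, m: int = 2, r: float | None = None,
                   r_mult: float = 0.2) -> float:
    """SampEn(m, r) with Chebyshev distance and self-matches excluded.

    ``r`` is the absolute match radius; if None it defaults to
    ``r_mult * std(x)``. A perfectly regular series gives 0; when no pair
    matches at length m+1 the capped sentinel :func:`sampen_cap` is returned
    so downstream feature matrices stay finite.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    n = x.size
    if n < m + 2:
        raise DataError(f"need at least m+2={m + 2} samples, got {n}")
    if r is None:
        r = r_mult * float(np.std(x))
    if r < 0:
        raise DataError("match radius r must be non-negative")
    a, b = _sampen_pair_counts(x, m, float(r))
    if a == 0 or b == 0:
        return sampen_cap(n, m)
    return -math.log(a / b)


def fuzzy_entropy(x, m: int = 2, n_exp: float = 2.0,
                  r: float | None = None, r_mult: float = 0.3) -> float:
    """FuzzyEn(m, n, r): -ln(phi_{m+1} / phi_m) with membership
    exp(-d^n / r) on mean-centred templates.

    ``r`` is the absolute fuzziness parameter; if None it defaults to
    ``r_mult * std(x)``.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    n = x.size
    if n < m + 2:
        raise DataError(f"need at least m+2={m + 2} samples, got {n}")
    if n_exp < 1:
        raise DataError("membership exponent n must be >= 1")
    if r is None:
        r = r_mult * float(np.std(x))
    if r <= 0:
        raise DataError("fuzzy entropy requires r > 0")
    ntempl = n - m
    phi_m = _fuzzy_phi(x, m, ntempl, float(n_exp), float(r))
    phi_m1 = _fuzzy_phi(x, m + 1, ntempl, float(n_exp), float(r))
    if phi_m1 <= 0 or phi_m <= 0:
        return sampen_cap(n, m)
    return -math.log(phi_m1 / phi_m)


def coarse_grain(x, tau: int) -> np.ndarray:
    """Non-overlapping block means of ``tau`` consecutive samples; the
    trailing partial block is dropped."""
    x = np.asarray(x, dtype=np.float64)
    if tau < 1:
        raise DataError("scale factor tau must be >= 1")
    nblocks = x.size // tau
    if nblocks == 0:
        raise DataError("series shorter than one block")
    return x[: nblocks * tau].reshape(nblocks, tau).mean(axis=1)


def multiscale_entropy(x, tau: int = 11, m: int = 2,
                       r: float | None = None, r_mult: float = 0.15) -> float:
    """Sample entropy of the scale-``tau`` coarse-grained series.

    The match radius defaults to ``r_mult * std`` of the ORIGINAL series
    (not the coarse series), per the usual multiscale-entropy convention.
    Returns a single scalar at the requested scale, not a curve.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < tau * (m + 2):
        raise DataError(
            f"need at least tau*(m+2)={tau * (m + 2)} samples, got {x.size}")
    if r is None:
        r = r_mult * float(np.std(x))
    return sample_entropy(coarse_grain(x, tau), m=m, r=r)
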