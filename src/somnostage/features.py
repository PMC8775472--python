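"""Per-epoch feature extraction: the fixed 20-feature set used for staging.

Eight time-domain statistics (extrema, mean, median, dispersion, shape),
nine spectral quantities from a Welch periodogram (spectral centroid fc,
spectral bandwidth f_sigma, PSD at the centroid pfc, and six band densities
gamma/beta/alpha/theta/delta/Kc), and three regularity measures (fuzzy,
sample and multiscale entropy).

Normalisation notes
-------------------
* Skewness and kurtosis use a 1/(N-1) normalisation (so Gaussian kurtosis
  is ~3*N/(N-1), not excess kurtosis); the conventional biased estimator is
  available via ``FeatureConfig(moment_normalization="conventional")``.
* Band "density" is the mean PSD over the band in uV^2/Hz; integrated band
  power is available via ``band_mode="power"``.
* Entropy radii are relative to the epoch SD (SampEN r=0.2*SD,
  MSES r=0.15*SD at scale tau=11). FUEN is evaluated on the SD-normalised
  epoch with absolute r=0.3, which makes the feature amplitude-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .entropy import fuzzy_entropy, multiscale_entropy, sample_entropy
from .exceptions import DataError

__all__ = ["FEATURE_NAMES", "BANDS", "FeatureConfig", "time_domain_features",
           "spectral_features", "feature_vector", "extract_features"]

#: Fixed feature order of the 20-dimensional vector.
FEATURE_NAMES: tuple[str, ...] = (
    "MINV", "MAXV", "AMV", "MNV", "SD", "V", "S", "K",
    "fc", "fsigma", "pfc",
    "gamma", "beta", "alpha", "theta", "delta", "Kc",
    "FUEN", "SampEN", "MSES",
)

#: Band edges in Hz. "Kc" is the K-complex / sub-delta band.
BANDS: dict[str, tuple[float, float]] = {
    "gamma": (25.0, 40.0),
    "beta": (13.0, 25.0),
    "alpha": (8.0, 13.0),
    "theta": (4.0, 8.0),
    "delta": (1.5, 4.0),
    "Kc": (0.0, 1.5),
}


@dataclass
class FeatureConfig:
    """Settings for spectral estimation and the entropy parameters.

    The PSD is a Welch averaged periodogram: ``seg_seconds`` segments with
    ``overlap`` fractional overlap and a Hann window by default. Entropy
    parameters are (m, r-multiplier) pairs; FUEN adds the membership
    exponent n, MSES the scale factor tau.
    """

    rate: float = 100.0
    seg_seconds: float = 4.0
    overlap: float = 0.5
    window: str = "hann"
    bands: dict = field(default_factory=lambda: dict(BANDS))
    band_mode: str = "density"            # "density" (mean PSD) | "power"
    fmax: float = 40.0
    moment_normalization: str = "printed"  # 1/(N-1) | "conventional" 1/N
    fuen_m: int = 2
    fuen_n: float = 2.0
    fuen_r: float = 0.3
    sampen_m: int = 2
    sampen_r: float = 0.2
    mses_tau: int = 11
    mses_m: int = 2
    mses_r: float = 0.15

    def __post_init__(self):
        edges = sorted(self.bands.values())
        for (l0, h0), (l1, h1) in zip(edges, edges[1:]):
            if not (l0 < h0 <= l1 < h1):
                raise DataError("band edges must be strictly increasing and disjoint")
        if min(self.fuen_r, self.sampen_r, self.mses_r) <= 0:
            raise DataError("entropy r multipliers must be > 0")
        if self.mses_tau < 1 or min(self.fuen_m, self.sampen_m, self.mses_m) < 1:
            raise DataError("entropy m and tau must be >= 1")


def time_domain_features(x) -> dict[str, float]:
    """MINV, MAXV, AMV, MNV, SD, V, S, K of one epoch.

    The median follows the sorted-sequence definition (mean of the two
    central order statistics for even N). Skewness and kurtosis default to
    the 1/(N-1) normalisation; a constant epoch returns S = K = 0 by
    convention with a ``degenerate_sd`` flag in the returned dict.
    """
    return _time_domain(np.asarray(x, dtype=float), "printed")


def _time_domain(x: np.ndarray, normalization: str) -> dict[str, float]:
    n = x.size
    if n < 4:
        raise DataError("time-domain features need at least 4 samples")
    amv = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    out = {
        "MINV": float(np.min(x)),
        "MAXV": float(np.max(x)),
        "AMV": amv,
        "MNV": float(np.median(x)),
        "SD": sd,
        "V": sd * sd,
    }
    if sd == 0.0:
        out["S"] = 0.0
        out["K"] = 0.0
        out["degenerate_sd"] = True
        return out
    z = (x - amv) / sd
    denom = (n - 1) if normalization == "printed" else n
    out["S"] = float(np.sum(z ** 3) / denom)
    out["K"] = float(np.sum(z ** 4) / denom)
    return out


def _welch(x: np.ndarray, cfg: FeatureConfig):
    nperseg = int(round(cfg.seg_seconds * cfg.rate))
    nperseg = min(nperseg, x.size)
    noverlap = int(round(cfg.overlap * nperseg))
    f, p = signal.welch(x, fs=cfg.rate, window=cfg.window,
                        nperseg=nperseg, noverlap=noverlap)
    keep = f <= cfg.fmax
    return f[keep], p[keep]


def spectral_features(x, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """fc, fsigma, pfc and the six band densities of one epoch.

    fc is the power-weighted spectral centroid over 0..fmax, fsigma the
    power-weighted standard deviation about fc, and pfc the PSD linearly
    interpolated at fc. Band features are the mean PSD inside the band
    (or the integrated power when ``band_mode="power"``). An all-zero
    epoch returns zeros with a ``degenerate_psd`` flag.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float)
    f, p = _welch(x, cfg)
    total = float(np.sum(p))
    out: dict[str, float] = {}
    if total <= 0.0:
        out.update({"fc": 0.0, "fsigma": 0.0, "pfc": 0.0,
                    "degenerate_psd": True})
        for name in cfg.bands:
            out[name] = 0.0
        return out
    fc = float(np.sum(f * p) / total)
    fsigma = float(np.sqrt(np.sum((f - fc) ** 2 * p) / total))
    out["fc"] = fc
    out["fsigma"] = fsigma
    out["pfc"] = float(np.interp(fc, f, p))
    df = f[1] - f[0] if f.size > 1 else 1.0
    for name, (lo, hi) in cfg.bands.items():
        mask = (f >= lo) & (f < hi)
        if name == _top_band(cfg.bands):
            mask = (f >= lo) & (f <= hi)
        if not mask.any():
            out[name] = 0.0
        elif cfg.band_mode == "power":
            out[name] = float(np.sum(p[mask]) * df)
        else:
            out[name] = float(np.mean(p[mask]))
    return out


def _top_band(bands: dict) -> str:
    return max(bands, key=lambda k: bands[k][1])


def feature_vector(x, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """All 20 features of one preprocessed epoch, keyed by FEATURE_NAMES.

    Degenerate-case flags (``degenerate_sd``, ``degenerate_psd``) are
    carried through when raised by the component extractors.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise DataError("epoch contains non-finite samples")
    out = _time_domain(x, cfg.moment_normalization)
    out.update(spectral_features(x, cfg))
    sd = float(np.std(x))
    if sd > 0:
        xn = x / sd
        out["FUEN"] = fuzzy_entropy(xn, m=cfg.fuen_m, n_exp=cfg.fuen_n,
                                    r=cfg.fuen_r)
        out["SampEN"] = sample_entropy(x, m=cfg.sampen_m, r=cfg.sampen_r * sd)
        out["MSES"] = multiscale_entropy(x, tau=cfg.mses_tau, m=cfg.mses_m,
                                         r=cfg.mses_r * sd)
    else:
        # flat epoch: perfectly regular by convention
        out["FUEN"] = 0.0
        out["SampEN"] = 0.0
        out["MSES"] = 0.0
    return out


def extract_features(epochs, cfg: FeatureConfig | None = None,
                     stages=None, subject_id: str | None = None) -> pd.DataFrame:
    """Feature matrix for a stack of epochs.

    epochs : (n_epochs, n_samples) array.
    Returns a DataFrame with the 20 feature columns in fixed order plus
    ``epoch_index`` (and ``stage`` / ``subject`` when provided).
    """
    cfg = cfg or FeatureConfig()
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    rows = [feature_vector(ep, cfg) for ep in epochs]
    df = pd.DataFrame(rows).reindex(columns=list(FEATURE_NAMES))
    df.insert(0, "epoch_index", np.arange(len(rows)))
    if stages is not None:
        df["stage"] = list(stages)
    if subject_id is not None:
        df["subject"] = subject_id
    return df
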