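"""Signal conditioning before feature extraction.

The canonical order is: resample to 100 Hz, zero-phase 0.5-40 Hz band-pass,
spatial repair of misaligned channels, ICA-based ocular-artifact removal,
then segmentation into 30-s epochs. :func:`preprocess` applies the enabled
steps in that order and records the applied order in the recording metadata.
"""

from __future__ import annotations

from fractions import Fraction
import warnings

import numpy as np
from scipy import signal

from .exceptions import ConfigurationError, DataError, UnsupportedOperationError
from .types import EEGRecording, EPOCH_SECONDS

__all__ = ["resample", "bandpass", "repair_channel", "remove_eog_artifacts",
           "epoch_record", "preprocess", "ELECTRODE_POS", "DEFAULT_ADJACENCY"]

#: Schematic 2-D positions of the 10-20 electrodes used here (unit head,
#: nose up). Only relative distances matter, for inverse-distance weights.
ELECTRODE_POS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.12, 0.48), "Fp2": (0.12, 0.48), "Fpz": (0.0, 0.50),
    "F3": (-0.20, 0.27), "F4": (0.20, 0.27), "Fz": (0.0, 0.25),
    "C3": (-0.25, 0.0), "C4": (0.25, 0.0), "Cz": (0.0, 0.0),
    "P3": (-0.20, -0.27), "P4": (0.20, -0.27), "Pz": (0.0, -0.25),
    "O1": (-0.12, -0.48), "O2": (0.12, -0.48), "Oz": (0.0, -0.50),
    "T3": (-0.50, 0.0), "T4": (0.50, 0.0),
    "T5": (-0.42, -0.27), "T6": (0.42, -0.27),
}

#: Physically adjacent channels for the montage used in this package.
DEFAULT_ADJACENCY: dict[str, list[str]] = {
    "O1": ["Oz", "Pz"], "O2": ["Oz", "Pz"], "Oz": ["O1", "O2", "Pz"],
    "Pz": ["Cz", "Oz"], "Cz": ["C3", "C4", "Pz"],
    "C3": ["Cz"], "C4": ["Cz"],
}


def resample(rec: EEGRecording, target_rate: float = 100.0) -> EEGRecording:
    """Resample all channels to ``target_rate`` (anti-aliased polyphase).

    Only downsampling (or the identity) is supported; upsampling raises
    :class:`UnsupportedOperationError`.
    """
    if rec.rate < target_rate:
        raise UnsupportedOperationError(
            f"upsampling {rec.rate} -> {target_rate} Hz is not supported")
    if rec.rate == target_rate:
        return rec.copy_with(data=rec.data.copy())
    frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator,
                                axis=1)
    return rec.copy_with(
        data=data, rate=rec.rate * frac.numerator / frac.denominator)


def bandpass(rec: EEGRecording, low: float = 0.5,
             high: float = 40.0) -> EEGRecording:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward).

    Zero-phase filtering preserves transient morphology (K-complexes) and
    introduces no epoch-boundary time shift.
    """
    if not (0.0 < low < high):
        raise ConfigurationError("need 0 < low < high")
    if high >= rec.rate / 2:
        raise ConfigurationError(
            f"high edge {high} Hz >= Nyquist {rec.rate / 2} Hz")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rec.rate,
                        output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=data)


def repair_channel(rec: EEGRecording, bad: str,
                   adjacency: dict[str, list[str]] | None = None,
                   weights: dict[str, float] | None = None) -> EEGRecording:
    """Replace ``bad`` with a spatially weighted average of its neighbours.

    Default weights are inverse distances from the standard 10-20 layout
    (:data:`ELECTRODE_POS`); channels without known positions fall back to
    uniform weights. Explicit per-neighbour ``weights`` override both.
    """
    adjacency = adjacency if adjacency is not None else DEFAULT_ADJACENCY
    neighbors = [c for c in adjacency.get(bad, []) if c in rec.channels]
    if not neighbors:
        raise DataError(f"no neighbours of {bad!r} present in the record")
    if weights is not None:
        w = np.array([weights[c] for c in neighbors], dtype=float)
    elif bad in ELECTRODE_POS and all(c in ELECTRODE_POS for c in neighbors):
        p0 = np.array(ELECTRODE_POS[bad])
        d = np.array([np.linalg.norm(np.array(ELECTRODE_POS[c]) - p0)
                      for c in neighbors])
        w = 1.0 / np.maximum(d, 1e-9)
    else:
        w = np.ones(len(neighbors))
    w = w / w.sum()
    data = rec.data.copy()
    idx = rec.channel_index(bad)
    data[idx] = sum(wi * rec.channel(c) for wi, c in zip(w, neighbors))
    rec2 = rec.copy_with(data=data)
    rec2.meta.setdefault("repaired", []).append(
        {"channel": bad, "neighbors": neighbors, "weights": w.tolist()})
    return rec2


def remove_eog_artifacts(rec: EEGRecording, threshold: float = 0.8,
                         seed: int = 0, max_iter: int = 1000) -> EEGRecording:
    """Remove ocular components from the EEG channels by ICA.

    The EEG channels are decomposed with FastICA (one component per channel,
    reduced to the numerical rank of the data); any component whose absolute
    Pearson correlation with an EOG channel exceeds ``threshold`` is zeroed
    and the record reconstructed. EOG channels themselves are untouched.
    When no component crosses the threshold the input is returned unchanged.
    """
    from sklearn.decomposition import FastICA

    eeg = rec.eeg_channels
    eog = rec.eog_channels
    if len(eeg) < 2 or len(eog) < 1:
        raise DataError("need >= 2 EEG channels and >= 1 EOG channel")
    idx = [rec.channel_index(c) for c in eeg]
    X = rec.data[idx].T  # (n_samples, n_eeg)
    sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    rank = int(np.sum(sv > sv[0] * 1e-10)) if sv[0] > 0 else 0
    if rank < 2:
        raise DataError(
            f"EEG data numerically rank-deficient (rank {rank}); "
            "cannot decompose into independent components")
    n_comp = min(len(eeg), rank)
    ica = FastICA(n_components=n_comp, random_state=seed, max_iter=max_iter,
                  whiten="unit-variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # FastICA convergence chatter
        S = ica.fit_transform(X)  # (n_samples, n_comp)
    eog_sig = rec.data[[rec.channel_index(c) for c in eog]]
    reject = []
    for k in range(n_comp):
        for e in eog_sig:
            c = np.corrcoef(S[:, k], e)[0, 1]
            if np.isfinite(c) and abs(c) > threshold:
                reject.append(k)
                break
    if not reject:
        return rec.copy_with(data=rec.data.copy())
    keep = [k for k in range(n_comp) if k not in reject]
    X_clean = S[:, keep] @ ica.mixing_[:, keep].T + ica.mean_
    data = rec.data.copy()
    data[idx] = X_clean.T
    rec2 = rec.copy_with(data=data)
    rec2.meta.setdefault("ica_rejected", []).append(
        {"components": reject, "threshold": threshold})
    return rec2


def epoch_record(rec: EEGRecording, channel: str,
                 epoch_s: float = EPOCH_SECONDS) -> np.ndarray:
    """Cut one channel into consecutive 30-s epochs.

    Returns an (n_epochs, epoch_s*rate) array; the trailing partial window
    is dropped (whole epochs only).
    """
    if rec.duration_s < epoch_s:
        raise DataError(f"record shorter than one {epoch_s:g}-s epoch")
    n = int(round(epoch_s * rec.rate))
    x = rec.channel(channel)
    n_epochs = x.size // n
    return x[: n_epochs * n].reshape(n_epochs, n)


def preprocess(rec: EEGRecording, target_rate: float = 100.0,
               low: float = 0.5, high: float = 40.0,
               repair: dict[str, list[str]] | None = None,
               remove_eog: bool = False, eog_threshold: float = 0.8,
               seed: int = 0) -> EEGRecording:
    """Apply the full conditioning chain in its fixed order.

    ``repair`` maps bad-channel labels to their neighbour lists (or to None
    for the default adjacency). The applied step order is recorded under
    ``meta["preprocessing"]``.
    """
    applied = []
    if rec.rate != target_rate:
        rec = resample(rec, target_rate)
        applied.append(f"resample:{target_rate:g}Hz")
    rec = bandpass(rec, low, high)
    applied.append(f"bandpass:{low:g}-{high:g}Hz")
    for bad, neigh in (repair or {}).items():
        rec = repair_channel(rec, bad,
                             adjacency=None if neigh is None else {bad: neigh})
        applied.append(f"repair:{bad}")
    if remove_eog and rec.eog_channels and len(rec.eeg_channels) >= 2:
        rec = remove_eog_artifacts(rec, threshold=eog_threshold, seed=seed)
        applied.append("ica_eog")
    rec.meta["preprocessing"] = applied
    return rec
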