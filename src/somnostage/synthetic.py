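"""Ground-truth-labelled synthetic polysomnography.

Two generators and a cohort wrapper:

* :func:`simulate_hypnogram` -- a semi-Markov bout model of sleep
  architecture. A night starts with a wake/N1 run realising the sampled
  sleep-onset latency, enters sleep through a forced first cycle
  (N2 -> N3 -> N2 -> REM, so every night of >= 3 h contains at least one
  complete N1 -> N2 -> N3 -> REM cycle), then alternates stage bouts drawn
  from an embedded transition chain with stage-specific dwell times, and
  ends with a morning wake run. Dwell times within a bout (rather than
  per-epoch transitions) keep the hypnogram from fragmenting unrealistically.
* :func:`synthesize_eeg` -- stage-conditioned EEG as a sum of band-limited
  noise processes whose per-band gains follow the hypnogram (smoothed so the
  signal is continuous across epoch boundaries), plus sleep transients
  (13.5-Hz spindle bursts and biphasic K-complexes in N2) and slow eye
  movements on the EOG channels during wake and REM.
* :func:`simulate_cohort` -- a two-group cohort (default 21 exposed vs 20
  sham) whose exposed arm is generated from parameters shifted by a
  :class:`GroupEffect`; per-subject seeds are spawned reproducibly from the
  master seed.

Default architecture parameters are calibrated so that ground-truth metrics
of a 9-h night land in the range of a normal adapted night (N1 ~6%, N2 ~48%,
N3 ~23.5%, REM ~22.5% of TST; SOL ~30 min; SE ~85%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigurationError, DataError
from .types import EEGRecording, Hypnogram, STAGES, STAGE_TO_CODE

__all__ = ["ArchitectureParams", "SpectralTemplate", "GroupEffect",
           "SubjectRecord", "simulate_hypnogram", "synthesize_eeg",
           "simulate_cohort", "stationary_occupancy"]

_SLEEP = ("N1", "N2", "N3", "REM")

_DEFAULT_BOUT = {"N0": 2.5, "N1": 8.0, "N2": 15.7, "N3": 14.0, "REM": 14.3}

_DEFAULT_TRANSITION = {
    "N1": {"N2": 1.0},
    "N2": {"N3": 0.55, "REM": 0.35, "N1": 0.095, "N0": 0.005},
    "N3": {"N2": 0.70, "REM": 0.30},
    "REM": {"N2": 0.68, "N1": 0.30, "N0": 0.02},
    "N0": {"N1": 0.60, "N2": 0.40},
}


@dataclass
class ArchitectureParams:
    """Generative parameters of a night's sleep architecture.

    mean_bout : mean dwell per stage, in epochs (> 0).
    transition : stage -> {stage: weight} embedded-chain weights; rows are
        normalised, a non-normalisable row is a configuration error.
    bout_cv : coefficient of variation of dwell times.
    homeostasis : gain of the slow-wave/REM pressure feedback: the entry
        weights of N3 and REM are scaled by exp(gain * deficit), where the
        deficit is (expected - accrued) stage time in units of one mean
        bout. This emulates declining SWS pressure as SWS accrues and keeps
        night-to-night stage percentages realistically stable; 0 disables.
    sol_mean_min / sol_sd_min : sleep-onset-latency distribution (minutes).
    wake_tail_mean_min / wake_tail_sd_min : morning wake run (minutes).
    tsc_hours : total collection time; the hypnogram has tsc_hours*120 epochs.
    n_cycles : nominal number of sleep cycles; shapes the within-night drift
        of N3 (front-loaded) and REM (back-loaded) dwell times.
    """

    mean_bout: dict = field(default_factory=lambda: dict(_DEFAULT_BOUT))
    transition: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 _DEFAULT_TRANSITION.items()})
    bout_cv: float = 0.2
    homeostasis: float = 1.0
    sol_mean_min: float = 30.0
    sol_sd_min: float = 7.0
    wake_tail_mean_min: float = 42.0
    wake_tail_sd_min: float = 14.0
    tsc_hours: float = 9.0
    n_cycles: int = 5

    def __post_init__(self):
        self.validate()

    def validate(self):
        for s in STAGES:
            if self.mean_bout.get(s, 0) <= 0:
                raise ConfigurationError(f"mean bout for {s} must be > 0")
        for s, row in self.transition.items():
            if any(w < 0 for w in row.values()):
                raise ConfigurationError(f"negative transition weight from {s}")
            if sum(row.values()) <= 0:
                raise ConfigurationError(
                    f"transition row for {s} not normalizable (sum <= 0)")
        if self.sol_mean_min < 0 or self.sol_sd_min < 0:
            raise ConfigurationError("SOL distribution must be >= 0")
        if self.tsc_hours <= 0 or self.n_cycles < 1:
            raise ConfigurationError("tsc_hours > 0 and n_cycles >= 1 required")

    @property
    def n_epochs(self) -> int:
        return int(round(self.tsc_hours * 120))

    @classmethod
    def scaled_to(cls, tsc_hours: float, **kw) -> "ArchitectureParams":
        """Architecture for a short recording: latencies (SOL, morning wake)
        shrink linearly with TSC and bout dwells with sqrt(TSC/9), so a
        short night still traverses every stage several times."""
        ref = cls(**kw)
        if tsc_hours >= 9.0:
            return replace(ref, tsc_hours=tsc_hours)
        lin = tsc_hours / 9.0
        dw = max(0.2, lin ** 0.5)
        mb = {s: max(1.0, d * dw) for s, d in ref.mean_bout.items()}
        return replace(
            ref, tsc_hours=tsc_hours, mean_bout=mb,
            sol_mean_min=ref.sol_mean_min * lin,
            sol_sd_min=ref.sol_sd_min * lin,
            wake_tail_mean_min=ref.wake_tail_mean_min * lin,
            wake_tail_sd_min=ref.wake_tail_sd_min * lin)

    def normalized_transition(self) -> dict:
        out = {}
        for s, row in self.transition.items():
            tot = sum(row.values())
            out[s] = {t: w / tot for t, w in row.items()}
        return out

    def with_stage_targets(self, targets: dict[str, float]) -> "ArchitectureParams":
        """Return a copy whose dwell means are re-solved so the expected
        stage occupancies (% of sleep time) match ``targets``.

        Expected occupancy of stage i under the embedded chain is
        pi_i * d_i / sum_j pi_j * d_j, so dwell means proportional to
        target_i / pi_i realise the targets; the overall dwell scale is kept
        so that mean cycle length is unchanged.
        """
        tot = sum(targets.values())
        if not np.isclose(tot, 100.0, atol=1.0):
            raise ConfigurationError("stage targets must sum to ~100%")
        pi = _embedded_stationary(self.normalized_transition())
        old_scale = sum(pi[s] * self.mean_bout[s] for s in _SLEEP)
        raw = {s: (targets[s] / 100.0) / pi[s] for s in _SLEEP}
        new_scale = sum(pi[s] * raw[s] for s in _SLEEP)
        k = old_scale / new_scale
        mb = dict(self.mean_bout)
        for s in _SLEEP:
            mb[s] = raw[s] * k
        return replace(self, mean_bout=mb)


def _embedded_stationary(P: dict) -> dict[str, float]:
    """Stationary distribution of the embedded (bout-to-bout) chain."""
    n = len(STAGES)
    M = np.zeros((n, n))
    for s, row in P.items():
        for t, w in row.items():
            M[STAGE_TO_CODE[s], STAGE_TO_CODE[t]] = w
    # solve pi M = pi, sum pi = 1
    A = np.vstack([M.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 1e-12, None)
    pi /= pi.sum()
    return {s: float(pi[STAGE_TO_CODE[s]]) for s in STAGES}


def stationary_occupancy(params: ArchitectureParams) -> dict[str, float]:
    """Expected % of sleep time per sleep stage under the bout chain
    (ignoring the forced first cycle and the wake bookends)."""
    pi = _embedded_stationary(params.normalized_transition())
    w = {s: pi[s] * params.mean_bout[s] for s in _SLEEP}
    tot = sum(w.values())
    return {s: 100.0 * w[s] / tot for s in _SLEEP}


@dataclass
class GroupEffect:
    """Additive shifts applied to the exposed group's generative parameters.

    d_n3_dwell / d_n2_dwell : epochs added to the mean N3 / N2 bout.
    d_sol_min : minutes added to the mean sleep-onset latency.
    d_se_pct : target sleep-efficiency gain in % points, realised by
        removing d_se_pct/100 * TSC of wake time from the morning tail.
    """

    d_n3_dwell: float = 0.0
    d_n2_dwell: float = 0.0
    d_sol_min: float = 0.0
    d_se_pct: float = 0.0

    def apply(self, params: ArchitectureParams) -> ArchitectureParams:
        mb = dict(params.mean_bout)
        mb["N3"] = mb["N3"] + self.d_n3_dwell
        mb["N2"] = mb["N2"] + self.d_n2_dwell
        if mb["N3"] <= 0 or mb["N2"] <= 0:
            raise ConfigurationError("effect drives a dwell mean <= 0")
        sol = max(0.0, params.sol_mean_min + self.d_sol_min)
        tail = max(0.0, params.wake_tail_mean_min
                   - self.d_se_pct / 100.0 * params.tsc_hours * 60.0)
        return replace(params, mean_bout=mb, sol_mean_min=sol,
                       wake_tail_mean_min=tail)

    @classmethod
    def reference(cls) -> "GroupEffect":
        """An exposure effect of the size seen in the magnetostatic-mattress
        comparison this package models: ~+2 %-points N3, ~-1.5 %-points N2,
        -4.8 min SOL, ~+3.5 %-points SE."""
        return cls(d_n3_dwell=1.5, d_n2_dwell=-0.6, d_sol_min=-4.76,
                   d_se_pct=3.5)


def _dwell(rng: np.random.Generator, mean: float, cv: float) -> int:
    return max(1, int(round(rng.normal(mean, cv * mean))))


def simulate_hypnogram(params: ArchitectureParams | None = None,
                       seed: int | np.random.Generator = 0) -> Hypnogram:
    """Simulate one night's hypnogram (tsc_hours * 120 epochs).

    The first N2 epoch falls exactly at the sampled SOL (rounded to the
    epoch grid); identical (seed, params) give identical label sequences.
    """
    params = params or ArchitectureParams()
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n_total = params.n_epochs
    P = params.normalized_transition()
    mb, cv = params.mean_bout, params.bout_cv

    sol_min = max(0.0, rng.normal(params.sol_mean_min, params.sol_sd_min))
    sol_ep = min(int(round(sol_min * 2.0)), max(0, n_total - 1))
    tail_min = max(0.0, rng.normal(params.wake_tail_mean_min,
                                   params.wake_tail_sd_min))
    tail_ep = min(int(round(tail_min * 2.0)), n_total // 4)

    seq: list[int] = []
    # pre-sleep run: wake, then N1 immediately before onset
    n1_pre = min(sol_ep, _dwell(rng, mb["N1"], cv))
    seq += [STAGE_TO_CODE["N0"]] * (sol_ep - n1_pre)
    seq += [STAGE_TO_CODE["N1"]] * n1_pre

    nc = max(1, params.n_cycles)
    budget = n_total - tail_ep

    def mult(stage: str) -> float:
        # within-night drift: N3 front-loaded, REM back-loaded; the cycle
        # index advances with elapsed night time in nc steps
        frac = min(1.0, len(seq) / max(1, budget))
        cyc = min(nc, 1 + int(frac * nc))
        x = (cyc - 1) / max(1, nc - 1)
        if stage == "N3":
            return float(np.clip(1.3 - 0.6 * x, 0.5, 1.5))
        if stage == "REM":
            return float(np.clip(0.7 + 0.6 * x, 0.5, 1.5))
        if stage == "N2" and cyc == 1:
            return 1.2  # long first cycle
        return 1.0

    def emit(stage: str):
        seq.extend([STAGE_TO_CODE[stage]]
                   * _dwell(rng, mb[stage] * mult(stage), cv))

    # forced deep first cycle guarantees one complete N1->N2->N3->REM pass
    # and a realistically delayed first REM period
    for s in ("N2", "N3", "N2", "N3", "N2", "REM"):
        emit(s)
    # homeostatic pressure: expected share of post-onset time per stage
    occ = _embedded_stationary(P)
    share = {s: occ[s] * mb[s] for s in _SLEEP}
    tot_share = sum(share.values())
    share = {s: v / tot_share for s, v in share.items()}

    state = "REM"
    h_gain = params.homeostasis
    while len(seq) < budget:
        row = P[state]
        targets = list(row.keys())
        w = np.array([row[t] for t in targets])
        if h_gain > 0:
            elapsed = max(1, len(seq) - sol_ep)
            for ti, t in enumerate(targets):
                if t in ("N3", "REM"):
                    accrued = seq.count(STAGE_TO_CODE[t])
                    deficit = (share[t] * elapsed - accrued) / mb[t]
                    w[ti] *= float(np.exp(np.clip(h_gain * deficit, -2.0, 2.0)))
        w = w / w.sum()
        nxt = rng.choice(targets, p=w)
        emit(nxt)
        state = nxt
    del seq[budget:]
    seq += [STAGE_TO_CODE["N0"]] * (n_total - len(seq))
    return Hypnogram(np.array(seq, dtype=np.int8))


# ---------------------------------------------------------------------------
# EEG synthesis


_DEFAULT_BAND_WEIGHTS = {
    # per-stage band amplitudes (uV std of the band-limited process);
    # each stage has a distinct dominant band by construction:
    # N0 -> alpha, N1 -> theta, N2 -> Kc, N3 -> delta, REM -> beta.
    "N0": {"Kc": 2.0, "delta": 3.0, "theta": 4.0, "alpha": 12.0,
           "beta": 5.0, "gamma": 1.0},
    "N1": {"Kc": 3.0, "delta": 5.0, "theta": 10.0, "alpha": 4.0,
           "beta": 3.0, "gamma": 1.0},
    "N2": {"Kc": 14.0, "delta": 8.0, "theta": 7.0, "alpha": 3.0,
           "beta": 3.0, "gamma": 1.0},
    "N3": {"Kc": 8.0, "delta": 20.0, "theta": 5.0, "alpha": 2.0,
           "beta": 1.5, "gamma": 0.5},
    "REM": {"Kc": 2.0, "delta": 4.0, "theta": 6.0, "alpha": 3.0,
            "beta": 9.0, "gamma": 2.0},
}

_BAND_EDGES = {"Kc": (0.0, 1.5), "delta": (1.5, 4.0), "theta": (4.0, 8.0),
               "alpha": (8.0, 13.0), "beta": (13.0, 25.0),
               "gamma": (25.0, 40.0)}


@dataclass
class SpectralTemplate:
    """Stage-conditioned spectral signatures for EEG synthesis.

    band_weights : stage -> band -> amplitude (uV); the dominant band of
        each stage must be unique across stages.
    spindle_rate / kcomplex_rate : N2 transient rates per minute.
    sem_rate : slow-eye-movement rate per minute on EOG channels (wake, REM).
    noise_uv : broadband noise-floor amplitude (uV).
    """

    band_weights: dict = field(
        default_factory=lambda: {s: dict(w) for s, w in
                                 _DEFAULT_BAND_WEIGHTS.items()})
    spindle_rate: float = 3.0
    kcomplex_rate: float = 1.5
    sem_rate: float = 4.0
    noise_uv: float = 1.5
    eog_leak: float = 0.08

    def __post_init__(self):
        dom = {}
        for s, w in self.band_weights.items():
            if any(v < 0 for v in w.values()):
                raise ConfigurationError("band weights must be non-negative")
            dom[s] = max(w, key=w.get)
        if len(set(dom.values())) != len(dom):
            raise ConfigurationError(
                f"dominant bands must be unique per stage, got {dom}")

    def dominant_band(self, stage: str) -> str:
        w = self.band_weights[stage]
        return max(w, key=w.get)


def _band_noise(rng, n, lo, hi, rate):
    white = rng.standard_normal(n)
    nyq = rate / 2
    if lo <= 0:
        sos = sps.butter(4, hi, btype="lowpass", fs=rate, output="sos")
    elif hi >= nyq:
        sos = sps.butter(4, lo, btype="highpass", fs=rate, output="sos")
    else:
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _smooth_gain(per_epoch: np.ndarray, spe: int, rate: float) -> np.ndarray:
    g = np.repeat(per_epoch, spe)
    width = max(3, int(rate))  # ~1-s raised-cosine smoothing
    win = np.hanning(width)
    win /= win.sum()
    return np.convolve(g, win, mode="same")


def synthesize_eeg(hypnogram: Hypnogram, template: SpectralTemplate | None = None,
                   rate: float = 100.0,
                   eeg_channels: tuple[str, ...] = ("Pz-Oz",),
                   seed: int | np.random.Generator = 0,
                   subject_id: str = "", group: str = "unknown") -> EEGRecording:
    """Generate a multi-channel recording consistent with a hypnogram.

    Each EEG channel is a sum over bands of unit-variance band-limited noise
    scaled by the stage's band amplitude (gain trajectories smoothed over
    ~1 s so there are no inter-epoch jumps), plus N2 transients. Two EOG
    channels carry slow eye movements during wake and REM; a small fraction
    of the EOG signal leaks into the EEG channels, giving the ocular-artifact
    removal step something real to do.
    """
    template = template or SpectralTemplate()
    if rate < 100.0:
        raise ConfigurationError("rate must be >= 100 Hz")
    if len(hypnogram) == 0:
        raise DataError("empty hypnogram")
    for s in set(hypnogram.labels):
        if s not in template.band_weights:
            raise DataError(f"no spectral template for stage {s!r}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    spe = int(round(hypnogram.epoch_s * rate))
    n = spe * len(hypnogram)
    labels = hypnogram.labels

    eog = _synth_eog(rng, labels, spe, rate, template)
    channels = list(eeg_channels) + ["EOG1", "EOG2"]
    data = np.empty((len(channels), n))
    for ci in range(len(eeg_channels)):
        x = np.zeros(n)
        for band, (lo, hi) in _BAND_EDGES.items():
            gains = np.array([template.band_weights[s][band] for s in labels])
            x += _smooth_gain(gains, spe, rate) * _band_noise(rng, n, lo, hi, rate)
        x += template.noise_uv * rng.standard_normal(n)
        x += _n2_transients(rng, labels, spe, rate, template)
        x += template.eog_leak * eog[0]
        data[ci] = x
    data[len(eeg_channels)] = eog[0]
    data[len(eeg_channels) + 1] = eog[1]
    return EEGRecording(data=data, channels=channels, rate=rate,
                        subject_id=subject_id, group=group,
                        meta={"synthetic": True})


def _n2_transients(rng, labels, spe, rate, template):
    out = np.zeros(spe * len(labels))
    t_sp = np.arange(int(round(1.0 * rate))) / rate
    spindle = np.hanning(t_sp.size) * np.sin(2 * np.pi * 13.5 * t_sp)
    t_kc = np.arange(int(round(0.8 * rate))) / rate
    # biphasic sharp negative then slow positive deflection
    kcomplex = (np.sin(2 * np.pi * t_kc / 0.8) *
                np.hanning(t_kc.size)) * -1.0
    epoch_min = spe / rate / 60.0
    for i, s in enumerate(labels):
        if s != "N2":
            continue
        start = i * spe
        for _ in range(rng.poisson(template.spindle_rate * epoch_min)):
            _insert(out, start + rng.integers(0, spe - spindle.size),
                    15.0 * spindle)
        for _ in range(rng.poisson(template.kcomplex_rate * epoch_min)):
            _insert(out, start + rng.integers(0, spe - kcomplex.size),
                    40.0 * kcomplex)
    return out


def _synth_eog(rng, labels, spe, rate, template):
    n = spe * len(labels)
    base1 = 3.0 * _band_noise(rng, n, 0.0, 5.0, rate)
    base2 = 3.0 * _band_noise(rng, n, 0.0, 5.0, rate)
    sem = np.zeros(n)
    t_ev = np.arange(int(round(1.5 * rate))) / rate
    wave = np.hanning(t_ev.size) * np.sin(2 * np.pi * t_ev / 1.5)
    epoch_min = spe / rate / 60.0
    for i, s in enumerate(labels):
        if s not in ("N0", "REM"):
            continue
        start = i * spe
        for _ in range(rng.poisson(template.sem_rate * epoch_min)):
            _insert(sem, start + rng.integers(0, spe - wave.size), 50.0 * wave)
    return sem + base1, -sem + base2  # roughly antiphase eye channels


def _insert(buf, start, wave):
    start = int(start)
    stop = min(start + wave.size, buf.size)
    buf[start:stop] += wave[: stop - start]


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "exposed" | "sham"
    hypnograms: list  # one Hypnogram per night
    recordings: list  # matching EEGRecording or None
    seed: int


def simulate_cohort(n_exposed: int = 21, n_sham: int = 20,
                    base: ArchitectureParams | None = None,
                    effect: GroupEffect | None = None,
                    nights: int = 1, seed: int = 0,
                    generate_eeg: bool = False,
                    template: SpectralTemplate | None = None,
                    rate: float = 100.0) -> list[SubjectRecord]:
    """Simulate a labelled two-group cohort.

    The sham arm is generated from ``base``; the exposed arm from
    ``effect.apply(base)`` (an all-zero effect makes the two generative
    parameter sets identical). Per-subject random streams are spawned from
    the master ``seed`` so any subject is reproducible in isolation.
    """
    if n_exposed < 2 or n_sham < 2:
        raise ConfigurationError("need at least 2 subjects per group")
    base = base or ArchitectureParams()
    effect = effect or GroupEffect()
    exposed_params = effect.apply(base)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_exposed + n_sham)
    cohort = []
    for i in range(n_exposed + n_sham):
        group = "exposed" if i < n_exposed else "sham"
        params = exposed_params if group == "exposed" else base
        sub_seed = int(children[i].generate_state(1)[0] % (2 ** 31))
        night_rngs = [np.random.default_rng(c)
                      for c in children[i].spawn(nights)]
        hyps, recs = [], []
        sid = f"S{i + 1:03d}"
        for rng in night_rngs:
            h = simulate_hypnogram(params, seed=rng)
            hyps.append(h)
            recs.append(synthesize_eeg(h, template, rate=rate, seed=rng,
                                       subject_id=sid, group=group)
                        if generate_eeg else None)
        cohort.append(SubjectRecord(subject_id=sid, group=group,
                                    hypnograms=hyps, recordings=recs,
                                    seed=sub_seed))
    return cohort
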