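"""Sleep-architecture metrics computed from a hypnogram.

Definitions (TSC = total collection time, default 9 h; epoch = 30 s):

* TST (h): summed duration of all non-wake epochs.
* N1%, N2%, N3%, REM%: stage duration as a percentage of TST.
* SE (%): TST / TSC x 100.
* SOL (min): lights-off to the first N2 epoch (entering N2 counts as
  falling asleep).
* RL (h): first N1 epoch to the first REM epoch; RL% = RL / TST x 100.
* WN: number of awakenings, counted as maximal wake runs strictly inside
  the sleep period (after the first N2, before the final non-wake epoch).
  Pre-onset and morning wake are not awakenings.

Metrics are kept at full precision internally; table exports round to two
decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import UndefinedMetricError
from .types import Hypnogram, STAGE_TO_CODE

__all__ = ["SleepMetrics", "total_sleep_time", "stage_percentages",
           "sleep_efficiency", "sleep_onset_latency", "rem_latency",
           "awakening_count", "sleep_metrics", "cohort_metrics_table",
           "METRIC_COLUMNS"]

_N0 = STAGE_TO_CODE["N0"]
_N1 = STAGE_TO_CODE["N1"]
_N2 = STAGE_TO_CODE["N2"]
_REM = STAGE_TO_CODE["REM"]

#: Column order of the cohort comparison tables.
METRIC_COLUMNS = ["N1%", "N2%", "N3%", "REM%", "SE%", "WN", "SOL", "RL"]


@dataclass
class SleepMetrics:
    tst_h: float
    n1_pct: float
    n2_pct: float
    n3_pct: float
    rem_pct: float
    se_pct: float
    sol_min: float
    rl_h: float
    rl_pct: float
    wn: float
    tsc_h: float

    def as_row(self) -> dict:
        """Metric row keyed like the comparison tables."""
        return {"N1%": self.n1_pct, "N2%": self.n2_pct, "N3%": self.n3_pct,
                "REM%": self.rem_pct, "SE%": self.se_pct, "WN": self.wn,
                "SOL": self.sol_min, "RL": self.rl_h, "RL%": self.rl_pct,
                "TST": self.tst_h}


def total_sleep_time(h: Hypnogram) -> float:
    """TST in hours: total duration of non-wake epochs."""
    return float(np.sum(h.stages != _N0)) * h.epoch_s / 3600.0


def stage_percentages(h: Hypnogram) -> dict[str, float]:
    """N1%/N2%/N3%/REM% of TST; undefined when TST = 0."""
    counts = {s: int(np.sum(h.stages == STAGE_TO_CODE[s]))
              for s in ("N1", "N2", "N3", "REM")}
    tot = sum(counts.values()) + 0  # wake excluded by definition
    tst_epochs = int(np.sum(h.stages != _N0))
    if tst_epochs == 0:
        raise UndefinedMetricError("stage percentages undefined with TST = 0")
    assert tot == tst_epochs
    return {f"{s}%": 100.0 * c / tst_epochs for s, c in counts.items()}


def sleep_efficiency(tst_h: float, tsc_h: float = 9.0) -> float:
    """SE = TST / TSC x 100, clamped to [0, 100]."""
    if tsc_h <= 0:
        raise UndefinedMetricError("TSC must be > 0")
    se = 100.0 * tst_h / tsc_h
    if se > 100.0:
        import warnings
        warnings.warn(f"TST {tst_h} h exceeds TSC {tsc_h} h; SE clamped")
    return float(np.clip(se, 0.0, 100.0))


def sleep_onset_latency(h: Hypnogram) -> float:
    """SOL in minutes: lights-off to the first N2 epoch."""
    idx = np.flatnonzero(h.stages[h.lights_off_epoch:] == _N2)
    if idx.size == 0:
        raise UndefinedMetricError("no N2 epoch: SOL undefined")
    return float(idx[0]) * h.epoch_s / 60.0


def rem_latency(h: Hypnogram) -> tuple[float, float]:
    """(RL in hours, RL% of TST): first N1 to first REM."""
    n1 = np.flatnonzero(h.stages == _N1)
    rem = np.flatnonzero(h.stages == _REM)
    if n1.size == 0 or rem.size == 0 or rem[0] < n1[0]:
        raise UndefinedMetricError("RL needs an N1 epoch preceding REM")
    rl_h = float(rem[0] - n1[0]) * h.epoch_s / 3600.0
    tst = total_sleep_time(h)
    if tst <= 0:
        raise UndefinedMetricError("RL% undefined with TST = 0")
    return rl_h, 100.0 * rl_h / tst


def awakening_count(h: Hypnogram) -> int:
    """WN: maximal wake runs strictly between sleep onset (first N2) and
    the final non-wake epoch."""
    n2 = np.flatnonzero(h.stages == _N2)
    if n2.size == 0:
        return 0
    onset = int(n2[0])
    sleep_idx = np.flatnonzero(h.stages != _N0)
    last_sleep = int(sleep_idx[-1])
    wake = (h.stages == _N0).astype(int)
    count = 0
    i = onset + 1
    while i < last_sleep:
        if wake[i] and not wake[i - 1]:
            # run must end before last_sleep (interior)
            j = i
            while j < len(wake) and wake[j]:
                j += 1
            if j - 1 < last_sleep:
                count += 1
            i = j
        else:
            i += 1
    return count


def sleep_cycles(h: Hypnogram) -> list[tuple[int, int]]:
    """Descriptive NREM/REM cycle segmentation.

    A cycle runs from sleep onset (or the end of the previous REM run) to
    the end of the next REM run; a trailing NREM segment with no REM is
    reported as a final incomplete cycle. Returns (start, end) epoch index
    pairs, end exclusive.
    """
    n2 = np.flatnonzero(h.stages == _N2)
    if n2.size == 0:
        return []
    sleep_idx = np.flatnonzero(h.stages != _N0)
    last = int(sleep_idx[-1]) + 1
    cycles = []
    start = int(n2[0])
    i = start
    while i < last:
        if h.stages[i] == _REM:
            while i < last and h.stages[i] == _REM:
                i += 1
            cycles.append((start, i))
            start = i
        else:
            i += 1
    if start < last:
        cycles.append((start, last))
    return cycles


def sleep_metrics(h: Hypnogram, tsc_h: float | None = None) -> SleepMetrics:
    """All metrics for one night. SOL/RL that are undefined for this
    hypnogram are reported as NaN (nights can then be excluded downstream)."""
    tst = total_sleep_time(h)
    tsc = tsc_h if tsc_h is not None else len(h) * h.epoch_s / 3600.0
    pct = stage_percentages(h) if tst > 0 else \
        {"N1%": np.nan, "N2%": np.nan, "N3%": np.nan, "REM%": np.nan}
    try:
        sol = sleep_onset_latency(h)
    except UndefinedMetricError:
        sol = float("nan")
    try:
        rl, rl_pct = rem_latency(h)
    except UndefinedMetricError:
        rl, rl_pct = float("nan"), float("nan")
    return SleepMetrics(
        tst_h=tst, n1_pct=pct["N1%"], n2_pct=pct["N2%"], n3_pct=pct["N3%"],
        rem_pct=pct["REM%"], se_pct=sleep_efficiency(tst, tsc),
        sol_min=sol, rl_h=rl, rl_pct=rl_pct, wn=awakening_count(h),
        tsc_h=tsc)


def cohort_metrics_table(cohort, tsc_h: float | None = None) -> pd.DataFrame:
    """Per-subject metric table for a cohort of SubjectRecord-like objects.

    Subjects with several nights contribute the mean of their per-night
    metrics (one row per subject avoids pseudo-replication); pass each night
    as its own subject for a per-night analysis.
    """
    rows = []
    for rec in cohort:
        night_rows = [sleep_metrics(hyp, tsc_h).as_row()
                      for hyp in rec.hypnograms]
        mean_row = pd.DataFrame(night_rows).mean().to_dict()
        mean_row["subject"] = rec.subject_id
        mean_row["group"] = rec.group
        rows.append(mean_row)
    df = pd.DataFrame(rows)
    cols = ["subject", "group"] + METRIC_COLUMNS + ["RL%", "TST"]
    return df[cols]
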