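"""Behavioral scoring of simulated trajectories.

The model is scored as awake whenever the MA firing rate exceeds a
threshold (default 1/s, between the ~5/s wake plateau and the ~0/s sleep
level).  From the resulting binary hypnogram we compute the metrics used to
compare species: total daily sleep duration, mean sleep-bout length,
episodes per circadian cycle, transition durations, and a zone label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .integrator import SimResult

__all__ = [
    "WAKE",
    "SLEEP",
    "Hypnogram",
    "Episode",
    "SleepMetrics",
    "classify_state",
    "segment_episodes",
    "sleep_metrics",
    "transition_durations",
    "raster",
]

WAKE = "WAKE"
SLEEP = "SLEEP"

#: Default MA firing-rate threshold separating wake from sleep (1/s).
DEFAULT_Q_THRESHOLD = 1.0


@dataclass
class Hypnogram:
    """Binary arousal-state series aligned with the source sampling."""

    times: np.ndarray   # h
    wake: np.ndarray    # bool; True = WAKE

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wake = np.asarray(self.wake, dtype=bool)
        if self.times.shape != self.wake.shape:
            raise ValueError("times and state must be aligned")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def state(self) -> np.ndarray:
        return np.where(self.wake, WAKE, SLEEP)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["time_h\tstate"]
        lines += [f"{t:.17g}\t{s}" for t, s in zip(self.times, self.state)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Hypnogram":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(times=df["time_h"].to_numpy(),
                   wake=(df["state"] == WAKE).to_numpy())


@dataclass(frozen=True)
class Episode:
    """Maximal run of constant state.  Truncated episodes touch a record edge."""

    state: str
    start: float   # h
    end: float     # h
    truncated: bool

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SleepMetrics:
    total_daily_sleep: float        # h per day
    mean_bout_length: float         # min (non-truncated sleep episodes)
    bouts_per_day: float            # sleep-episode onsets per day
    mean_transition_duration: float # min; nan if not computed
    n_episodes_per_cycle: int       # sleep episodes per 24 h cycle (rounded)
    zone: str                       # NO_WAKE / NO_SLEEP / MONOPHASIC / POLYPHASIC

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def classify_state(sim: SimResult,
                   q_threshold: float = DEFAULT_Q_THRESHOLD) -> Hypnogram:
    """Score WAKE where ``Q_m > q_threshold`` (strict), else SLEEP."""
    if len(sim) == 0:
        raise ValueError("empty simulation")
    return Hypnogram(times=sim.times, wake=sim.Q_m > q_threshold)


def segment_episodes(h: Hypnogram) -> list[Episode]:
    """Maximal constant-state runs covering the record.

    Episode boundaries are placed at the midpoint between the last sample of
    one state and the first of the next; the first and last episodes are
    flagged truncated (their true onset/offset lies outside the record) and
    are excluded from bout-length statistics downstream.
    """
    if len(h) == 0:
        raise ValueError("empty hypnogram")
    w = h.wake
    t = h.times
    change = np.flatnonzero(w[1:] != w[:-1])  # index of last sample of each run
    starts = [t[0]]
    for c in change:
        starts.append(0.5 * (t[c] + t[c + 1]))
    ends = starts[1:] + [t[-1]]
    run_first = np.concatenate([[0], change + 1])
    episodes = []
    for i, (s, e) in enumerate(zip(starts, ends)):
        episodes.append(Episode(
            state=WAKE if w[run_first[i]] else SLEEP,
            start=s,
            end=e,
            truncated=(i == 0 or i == len(starts) - 1),
        ))
    return episodes


def _min_bout_filter(h: Hypnogram, min_bout_min: float) -> Hypnogram:
    """Remove episodes shorter than ``min_bout_min`` by merging them into the
    preceding state (noise debounce; off by default)."""
    eps = segment_episodes(h)
    wake = h.wake.copy()
    for e in eps:
        if not e.truncated and e.duration * 60.0 < min_bout_min:
            sel = (h.times >= e.start) & (h.times <= e.end)
            wake[sel] = (e.state == SLEEP)  # flip to the surrounding state
    return Hypnogram(times=h.times, wake=wake)


def sleep_metrics(h: Hypnogram,
                  min_bout_min: float = 0.0,
                  no_state_frac: float = 0.01) -> SleepMetrics:
    """Behavioral metrics of a hypnogram covering >= 2 circadian cycles.

    Zone rules: NO_WAKE if the wake fraction is below ``no_state_frac``,
    NO_SLEEP likewise for sleep, MONOPHASIC if there is exactly one sleep
    episode per 24 h cycle, else POLYPHASIC.
    """
    span = h.times[-1] - h.times[0]
    if span < 48.0:
        raise ValueError(
            f"record spans {span:.1f} h; need >= 2 full circadian cycles (48 h)"
        )
    if min_bout_min > 0:
        h = _min_bout_filter(h, min_bout_min)

    days = span / 24.0
    sleep_frac = 1.0 - h.wake.mean()
    total_daily_sleep = sleep_frac * 24.0

    episodes = segment_episodes(h)
    sleep_eps = [e for e in episodes if e.state == SLEEP]
    full_sleep = [e for e in sleep_eps if not e.truncated]
    # Onset-counted rate: robust to episodes straddling day boundaries.
    n_onsets = sum(1 for e in sleep_eps if not (e is episodes[0]))
    bouts_per_day = n_onsets / days
    mean_bout = (np.mean([e.duration for e in full_sleep]) * 60.0
                 if full_sleep else float("nan"))

    wake_frac = 1.0 - sleep_frac
    n_cycle = int(round(bouts_per_day))
    if wake_frac < no_state_frac:
        zone = "NO_WAKE"
    elif sleep_frac < no_state_frac:
        zone = "NO_SLEEP"
    elif n_cycle == 1:
        zone = "MONOPHASIC"
    else:
        zone = "POLYPHASIC"

    return SleepMetrics(
        total_daily_sleep=float(total_daily_sleep),
        mean_bout_length=float(mean_bout),
        bouts_per_day=float(bouts_per_day),
        mean_transition_duration=float("nan"),
        n_episodes_per_cycle=n_cycle,
        zone=zone,
    )


def transition_durations(sim: SimResult,
                         frac_lo: float = 0.05,
                         frac_hi: float = 0.95,
                         q_threshold: float = DEFAULT_Q_THRESHOLD,
                         slope_frac: float = 0.02,
                         window_h: float = 2.0) -> list[float]:
    """Durations (min) of the rapid wake<->sleep switching segments.

    The wake and sleep plateaus of the attractor drift slowly for hours
    around each flip as the homeostatic level creeps, so crossing times of
    fixed fractions of the *global* wake plateau conflate that creep with
    the switch itself.  Instead, each state flip (threshold crossing of
    ``Q_m``) is localized; within ``window_h`` hours of the flip the rapid
    segment is taken as the maximal contiguous interval over which
    ``|dQ_m/dt|`` stays above ``slope_frac`` of its per-flip peak, and the
    duration reported is the time ``Q_m`` spends between ``frac_lo`` and
    ``frac_hi`` of that segment's own span.  Returns one duration per flip;
    empty list if the record has no transitions.
    """
    if not (0.0 < frac_lo < frac_hi < 1.0):
        raise ValueError("need 0 < frac_lo < frac_hi < 1")
    t, q = sim.times, sim.Q_m
    if len(t) < 3:
        return []
    wake = q > q_threshold
    flips = np.flatnonzero(wake[1:] != wake[:-1])
    if len(flips) == 0:
        return []
    dq = np.gradient(q, t)
    dt_samp = np.median(np.diff(t))
    w = max(1, int(round(window_h / dt_samp)))
    durs = []
    for f in flips:
        a, b = max(0, f - w), min(len(q) - 1, f + w)
        peak = np.abs(dq[a:b + 1]).max()
        if peak == 0:
            continue
        thr = slope_frac * peak
        i = f
        while i > a and abs(dq[i - 1]) >= thr:
            i -= 1
        j = f
        while j < b and abs(dq[j + 1]) >= thr:
            j += 1
        seg = q[i:j + 1]
        lo_v, hi_v = seg.min(), seg.max()
        span = hi_v - lo_v
        if span <= 0:
            continue
        band_lo = lo_v + frac_lo * span
        band_hi = lo_v + frac_hi * span
        in_band = (seg > band_lo) & (seg < band_hi)
        durs.append(float(in_band.sum() * dt_samp * 60.0))
    return durs


def raster(h: Hypnogram, codes: dict[str, str] | None = None) -> list[str]:
    """Per-day strings of per-minute state codes (one row per simulated day),
    for actogram-style export.  Default codes: W = wake, S = sleep."""
    codes = codes or {WAKE: "W", SLEEP: "S"}
    t0 = h.times[0]
    minutes = np.rint((h.times - t0) * 60.0).astype(int)
    n_days = int(np.ceil((h.times[-1] - t0) / 24.0))
    grid = np.full(n_days * 1440, "-", dtype=object)
    for m, s in zip(minutes, h.state):
        if m < len(grid):
            grid[m] = codes[s]
    return ["".join(grid[d * 1440:(d + 1) * 1440]) for d in range(n_days)]
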