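"""Synthetic hypnogram fixtures with known ground truth.

Stands in for behavioral/EEG scoring records: alternating wake/sleep bouts
on a one-minute grid, with exponentially distributed sleep-bout lengths
(the distribution reported for mammalian sleep episodes) and a circadian
modulation of sleep propensity.  The generating parameters are returned
alongside the record so scoring/metrics code can be validated against a
known answer.
"""

from __future__ import annotations

import numpy as np

from .metrics import Hypnogram

__all__ = ["generate_hypnogram_fixture"]


def generate_hypnogram_fixture(bout_mean: float = 6.0,
                               bouts_per_day: float = 40.0,
                               days: int = 10,
                               seed: int | None = None,
                               circadian_mod: float = 0.5,
                               grid_min: float = 1.0) -> tuple[Hypnogram, dict]:
    """Generate a noisy hypnogram with known bout statistics.

    Parameters
    ----------
    bout_mean : mean sleep-bout length in minutes (exponential distribution);
        the default 6 min is rat-like.
    bouts_per_day : target number of sleep bouts per day; fixes the mean
        wake-bout length via the cycle budget 1440/bouts_per_day.
    days : record length; 0 yields an empty hypnogram.
    seed : RNG seed; a fixed seed reproduces the fixture exactly.
    circadian_mod : relative amplitude (0..1) of a 24 h sinusoidal
        modulation of wake-bout length (sleep propensity highest at the
        subjective night); 0 disables it.
    grid_min : sampling grid in minutes.

    Returns
    -------
    (hypnogram, truth) where ``truth`` records the generating parameters and
    the realized per-record mean sleep-bout length and bout count.
    """
    if bout_mean <= 0 or bouts_per_day <= 0 or grid_min <= 0:
        raise ValueError("bout_mean, bouts_per_day and grid_min must be positive")
    if days < 0:
        raise ValueError("days must be >= 0")
    if not (0.0 <= circadian_mod < 1.0):
        raise ValueError("circadian_mod must be in [0, 1)")

    rng = np.random.default_rng(seed)
    total_min = days * 1440.0
    n = int(round(total_min / grid_min))
    times = np.arange(n) * grid_min / 60.0  # h
    wake = np.ones(n, dtype=bool)

    cycle_mean = 1440.0 / bouts_per_day
    wake_mean = max(cycle_mean - bout_mean, grid_min)

    t = 0.0
    sleep_bouts = []
    awake = True
    while t < total_min and n > 0:
        if awake:
            # Sleep propensity peaks 12 h after t=0: longer wake bouts early.
            mod = 1.0 + circadian_mod * np.cos(2.0 * np.pi * t / 1440.0)
            dur = rng.exponential(wake_mean * mod)
        else:
            dur = rng.exponential(bout_mean)
            sleep_bouts.append(dur)
        i0 = int(round(t / grid_min))
        i1 = min(int(round((t + dur) / grid_min)), n)
        if not awake:
            wake[i0:i1] = False
        t += dur
        awake = not awake

    truth = {
        "bout_mean_min": bout_mean,
        "bouts_per_day": bouts_per_day,
        "days": days,
        "seed": seed,
        "realized_mean_sleep_bout_min": float(np.mean(sleep_bouts)) if sleep_bouts else float("nan"),
        "realized_n_sleep_bouts": len(sleep_bouts),
    }
    return Hypnogram(times=times, wake=wake), truth
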