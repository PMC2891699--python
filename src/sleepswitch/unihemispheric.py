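"""Two-hemisphere extension: contralateral VLPO-VLPO inhibition.

Two identical copies of the single-hemisphere switch, each with its own
homeostatic level driven by its own MA firing, are coupled by adding an
inhibitory term ``nu_inh * Q_v'`` (contralateral VLPO firing) to each VLPO
potential equation.  Weak coupling leaves sleep bihemispheric; sufficiently
strong coupling prevents the two VLPOs from activating together, producing
alternating left/right unihemispheric sleep as seen in cetaceans, with the
diverging homeostatic pressures of the two hemispheres driving the
alternation.

A deterministic run from perfectly symmetric initial conditions stays
synchronized forever, so by default the two initial homeostatic levels
differ by 5% to seed the asymmetry (noise is an alternative); the
desynchronization mechanism is a modeling choice, not a measured quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .core_model import SwitchParams, HemiState, SECONDS_PER_HOUR, firing_rate
from .integrator import SimConfig, SimResult, IntegrationError, _sigmoid
from .metrics import classify_state, DEFAULT_Q_THRESHOLD

__all__ = [
    "CoupledParams",
    "CoupledResult",
    "simulate_coupled",
    "find_thresholds",
    "furseal_protocol",
    "BW", "BS", "LUS", "RUS",
]

BW, BS, LUS, RUS = "BW", "BS", "LUS", "RUS"

#: Minimum duration (min) for a unihemispheric (or bihemispheric-sleep)
#: episode to count as such, guarding against transition skew between the
#: hemispheres being scored as unihemispheric sleep.
DEFAULT_MIN_EPISODE_MIN = 5.0


@dataclass(frozen=True)
class CoupledParams:
    """Shared single-hemisphere parameters plus the contralateral weight.

    ``nu_inh`` (mV.s) is the VLPO->VLPO inhibitory weight; <= 0.  A ramp
    schedule can be supplied to :func:`simulate_coupled` instead of the
    constant value.
    """

    hemi: SwitchParams = field(default_factory=SwitchParams)
    nu_inh: float = 0.0

    def __post_init__(self) -> None:
        if self.nu_inh > 0:
            raise ValueError("nu_inh must be <= 0 (inhibitory)")


@dataclass
class CoupledResult:
    """Aligned left/right trajectories and the derived four-state series."""

    left: SimResult
    right: SimResult
    state: np.ndarray      # str array in {BW, BS, LUS, RUS}

    @property
    def times(self) -> np.ndarray:
        return self.left.times

    def state_fractions(self) -> dict[str, float]:
        n = len(self.state)
        return {s: float(np.sum(self.state == s)) / n for s in (BW, BS, LUS, RUS)}

    def episodes(self, which: str,
                 min_duration_min: float = DEFAULT_MIN_EPISODE_MIN) -> list[tuple[float, float]]:
        """(start, end) of runs of the given four-state code lasting at least
        ``min_duration_min`` minutes."""
        sel = self.state == which
        t = self.times
        out = []
        i = 0
        while i < len(sel):
            if sel[i]:
                j = i
                while j + 1 < len(sel) and sel[j + 1]:
                    j += 1
                if (t[j] - t[i]) * 60.0 >= min_duration_min:
                    out.append((float(t[i]), float(t[j])))
                i = j + 1
            else:
                i += 1
        return out

    def raster_tsv(self, path: str | Path) -> None:
        """Four-state raster (day, minute-of-day, code), one row per minute."""
        lines = ["day\tminute_of_day\tstate"]
        t0 = self.times[0]
        for t, s in zip(self.times, self.state):
            m = int(round((t - t0) * 60.0))
            lines.append(f"{m // 1440}\t{m % 1440}\t{s}")
        Path(path).write_text("\n".join(lines) + "\n")


def _four_state(left_wake: np.ndarray, right_wake: np.ndarray) -> np.ndarray:
    out = np.empty(left_wake.shape, dtype=object)
    out[left_wake & right_wake] = BW
    out[~left_wake & ~right_wake] = BS
    out[~left_wake & right_wake] = LUS
    out[left_wake & ~right_wake] = RUS
    return out


def simulate_coupled(p: CoupledParams, cfg: SimConfig,
                     init_left: HemiState | None = None,
                     init_right: HemiState | None = None,
                     nu_inh_schedule: Callable[[float], float] | None = None,
                     q_threshold: float = DEFAULT_Q_THRESHOLD) -> CoupledResult:
    """Integrate both hemispheres with mutual VLPO-VLPO inhibition.

    ``nu_inh_schedule``, if given, overrides ``p.nu_inh`` with a function of
    time (hours) — used for the fur-seal neuromodulation ramp.  With
    ``nu_inh = 0`` and identical initial states the two hemispheres remain
    bitwise identical (decoupling limit).  Default initial states are
    asymmetric: the right hemisphere starts with 5% less somnogen.
    """
    hemi = p.hemi
    if init_left is None:
        init_left = HemiState()
    if init_right is None:
        init_right = HemiState(V_m=init_left.V_m, V_v=init_left.V_v,
                               H=0.95 * init_left.H)
    nu_of_t = nu_inh_schedule if nu_inh_schedule is not None else (lambda t: p.nu_inh)

    dt_h = cfg.dt / SECONDS_PER_HOUR
    n_steps = int(round(cfg.duration / dt_h))
    discard = int(round(cfg.transient_discard / dt_h))
    tau_m_h, tau_v_h = hemi.tau_m_h, hemi.tau_v_h

    stochastic = hemi.sigma_noise > 0
    seed = cfg.seed
    if stochastic:
        if seed is None:
            seed = int(np.random.SeedSequence().entropy % (2**31))
        rng = np.random.default_rng(seed)
        amp = hemi.sigma_noise / math.sqrt(dt_h)

    def rhs(y, t, nu):
        Vm1, Vv1, H1, Vm2, Vv2, H2 = y
        Qm1, Qv1 = _sigmoid(Vm1, hemi), _sigmoid(Vv1, hemi)
        Qm2, Qv2 = _sigmoid(Vm2, hemi), _sigmoid(Vv2, hemi)
        circ = hemi.nu_vc_c0 + hemi.circ_amp * math.cos(hemi.omega * t + hemi.phi)
        return (
            (-Vm1 + hemi.nu_mv * Qv1 + hemi.A_drive) / tau_m_h,
            (-Vv1 + hemi.nu_vm * Qm1 + hemi.nu_vh * H1 + circ + nu * Qv2) / tau_v_h,
            (-H1 + hemi.mu * Qm1) / hemi.chi,
            (-Vm2 + hemi.nu_mv * Qv2 + hemi.A_drive) / tau_m_h,
            (-Vv2 + hemi.nu_vm * Qm2 + hemi.nu_vh * H2 + circ + nu * Qv1) / tau_v_h,
            (-H2 + hemi.mu * Qm2) / hemi.chi,
        )

    y = [init_left.V_m, init_left.V_v, max(init_left.H, 0.0),
         init_right.V_m, init_right.V_v, max(init_right.H, 0.0)]
    samples = []
    for i in range(n_steps + 1):
        t = i * dt_h
        if i >= discard and (i - discard) % cfg.sample_every == 0:
            samples.append((t, *y))
        if i == n_steps:
            break
        nu = nu_of_t(t)
        if nu > 0:
            raise ValueError(f"nu_inh schedule returned positive value at t={t:.3f} h")
        if stochastic:
            f = rhs(y, t, nu)
            xi = rng.standard_normal(4)
            y = [y[0] + dt_h * (f[0] + amp * xi[0]),
                 y[1] + dt_h * (f[1] + amp * xi[1]),
                 y[2] + dt_h * f[2],
                 y[3] + dt_h * (f[3] + amp * xi[2]),
                 y[4] + dt_h * (f[4] + amp * xi[3]),
                 y[5] + dt_h * f[5]]
        else:
            k1 = rhs(y, t, nu)
            y2 = [a + 0.5 * dt_h * b for a, b in zip(y, k1)]
            k2 = rhs(y2, t + 0.5 * dt_h, nu)
            y3 = [a + 0.5 * dt_h * b for a, b in zip(y, k2)]
            k3 = rhs(y3, t + 0.5 * dt_h, nu)
            y4 = [a + dt_h * b for a, b in zip(y, k3)]
            k4 = rhs(y4, t + dt_h, nu)
            y = [a + dt_h / 6.0 * (b1 + 2 * b2 + 2 * b3 + b4)
                 for a, b1, b2, b3, b4 in zip(y, k1, k2, k3, k4)]
        y[2] = max(y[2], 0.0)
        y[5] = max(y[5], 0.0)
        if not all(math.isfinite(v) for v in y):
            raise IntegrationError(
                f"non-finite coupled state at step {i + 1} (t = {t + dt_h:.4f} h): {y}"
            )

    arr = np.asarray(samples)
    times = arr[:, 0]

    def mk(vm, vv, h) -> SimResult:
        return SimResult(times=times, V_m=vm, V_v=vv,
                         Q_m=firing_rate(vm, hemi), Q_v=firing_rate(vv, hemi),
                         H=h, params=hemi, config=cfg, seed=seed)

    left = mk(arr[:, 1], arr[:, 2], arr[:, 3])
    right = mk(arr[:, 4], arr[:, 5], arr[:, 6])
    state = _four_state(left.Q_m > q_threshold, right.Q_m > q_threshold)
    return CoupledResult(left=left, right=right, state=state)


def _uhs_per_day(res: CoupledResult, min_min: float) -> float:
    days = (res.times[-1] - res.times[0]) / 24.0
    n = len(res.episodes(LUS, min_min)) + len(res.episodes(RUS, min_min))
    return n / days


def _has_bs(res: CoupledResult, min_min: float) -> bool:
    return len(res.episodes(BS, min_min)) > 0


def find_thresholds(p: CoupledParams, cfg: SimConfig,
                    tol: float | None = None,
                    nu_max: float = 3.0,
                    n_scan: int = 13,
                    min_episode_min: float = DEFAULT_MIN_EPISODE_MIN) -> tuple[float, float]:
    """Locate the two coupling thresholds bounding the unihemispheric regime.

    ``nu_t1``: weakest ``|nu_inh|`` at which at least one unihemispheric
    sleep episode per day occurs in steady state.  ``nu_t2``: weakest
    ``|nu_inh|`` at which no bihemispheric sleep remains.  Both returned as
    the (negative) coupling weights, ``|nu_t2| >= |nu_t1|``.

    A coarse ``n_scan``-point scan over ``[0, nu_max]`` verifies that both
    indicator properties are monotone in the coupling strength before the
    bisections run; a non-monotone scan raises with the scan table attached.
    ``tol`` defaults to 1% of the scanned range.
    """
    if tol is None:
        tol = 0.01 * nu_max
    strengths = np.linspace(0.0, nu_max, n_scan)

    def probe(s: float) -> tuple[bool, bool]:
        res = simulate_coupled(CoupledParams(hemi=p.hemi, nu_inh=-s), cfg)
        return (_uhs_per_day(res, min_episode_min) >= 1.0,
                not _has_bs(res, min_episode_min))

    table = [(s, *probe(s)) for s in strengths]
    for flag_idx, name in ((1, "unihemispheric onset"), (2, "bihemispheric-sleep loss")):
        flags = [row[flag_idx] for row in table]
        if any(flags[i] and not flags[i + 1] for i in range(len(flags) - 1)):
            raise RuntimeError(
                f"non-monotone {name} over the coupling scan; "
                f"scan table (strength, uhs, no_bs): {table}"
            )
    if not table[-1][1] or not table[-1][2]:
        raise RuntimeError(
            f"nu_max={nu_max} too weak: purely unihemispheric regime not reached; "
            f"scan table: {table}"
        )

    def bisect(flag_idx: int) -> float:
        lo = max(s for s, *f in table if not f[flag_idx - 1])
        hi = min(s for s, *f in table if f[flag_idx - 1])
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if probe(mid)[flag_idx - 1]:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    nu_t1 = bisect(1)
    nu_t2 = bisect(2)
    return -nu_t1, -nu_t2


def furseal_protocol(p: CoupledParams, ramp_days: tuple[float, float],
                     cfg: SimConfig,
                     nu_final: float | None = None) -> CoupledResult:
    """Terrestrial-to-aquatic transition via a linear coupling ramp.

    The contralateral weight is 0 before ``ramp_days[0]`` (land: polyphasic
    bihemispheric sleep), ramps linearly to ``nu_final`` across the window,
    and stays there (water: unihemispheric sleep).  ``nu_final`` defaults to
    ``p.nu_inh``.  Times are days since the start of the *returned* record,
    i.e. after the configured transient discard.
    """
    start, end = (d * 24.0 for d in ramp_days)
    if not (0 <= start <= end <= cfg.duration - cfg.transient_discard):
        raise ValueError("ramp_days must lie within the recorded span")
    target = p.nu_inh if nu_final is None else nu_final
    if target > 0:
        raise ValueError("nu_final must be <= 0")
    t0 = cfg.transient_discard

    def schedule(t: float) -> float:
        rel = t - t0
        if rel <= start:
            return 0.0
        if rel >= end:
            return target
        return target * (rel - start) / (end - start) if end > start else target

    return simulate_coupled(p, cfg, nu_inh_schedule=schedule)
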