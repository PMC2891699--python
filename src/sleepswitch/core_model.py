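"""Single-hemisphere sleep-wake switch: parameters, state, and vector field.

The model describes two mutually inhibitory neuronal populations — the
wake-active monoaminergic brainstem nuclei (MA) and the sleep-active
ventrolateral preoptic area (VLPO) — each characterized by a mean cell-body
potential ``V`` (mV, relative to resting) and a sigmoidal population firing
rate ``Q(V)``.  Mutual inhibition makes the pair a bistable flip-flop; state
transitions are driven by a homeostatic somnogen concentration ``H`` (nM)
that accumulates with MA firing and clears with time constant ``chi``, and
by an entrained sinusoidal circadian drive to the VLPO.

Time is measured in **hours** at the API surface.  The neuromodulator decay
times ``tau_m``/``tau_v`` are specified in seconds (their natural scale) and
converted internally; the firing-rate/weight products are scale-free
(``nu`` in mV.s times ``Q`` in 1/s yields mV), so no other conversion is
required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SwitchParams",
    "HemiState",
    "SECONDS_PER_HOUR",
    "firing_rate",
    "circadian_drive",
    "vlpo_drive",
    "derivatives",
    "flip_flop_fixed_points",
    "PRESETS",
    "get_preset",
    "save_params",
    "load_params",
]

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class SwitchParams:
    """All constants of the single-hemisphere switch.

    Attributes
    ----------
    Q_max : float
        Maximum population firing rate (1/s).
    theta : float
        Mean firing threshold relative to resting (mV).
    sigma_prime : float
        Standard deviation of the firing threshold (mV).
    nu_mv : float
        Weight of VLPO input to MA (mV.s); negative (inhibitory).
    nu_vm : float
        Weight of MA input to VLPO (mV.s); negative (inhibitory).
    nu_vh : float
        Homeostatic weight (mV/nM); positive, so somnogen promotes sleep.
    nu_vc_c0 : float
        Mean (constant) component of the circadian drive to the VLPO (mV).
        This is the "mean drive to VLPO" swept across species; negative for
        a net wake-promoting circadian input.
    circ_amp : float
        Amplitude of the sinusoidal circadian component as delivered to the
        VLPO (mV).  Signed: the nominal value equals the (negative)
        circadian coupling strength, so the delivered drive is
        ``nu_vc_c0 + circ_amp*cos(omega*t + phi)``.
    A_drive : float
        Constant cholinergic/orexinergic drive to the MA group (mV), held
        at its average level to smooth out ultradian REM/NREM dynamics.
    tau_m, tau_v : float
        Neuromodulator decay times (seconds).
    mu : float
        Homeostatic production constant (nM.s): production rate is
        ``mu*Q_m/chi``, so the isolated-H equilibrium is ``mu*Q_m`` nM.
    chi : float
        Homeostatic time constant (hours).  ~45 h for humans; minutes to
        hours for polyphasic sleepers.
    omega : float
        Circadian angular frequency (rad/h); 2*pi/24 when entrained.
    phi : float
        Initial circadian phase (rad).  Nocturnal species use a 12 h
        (pi rad) shift.
    sigma_noise : float
        Additive noise amplitude on the potential equations (mV.h^1/2);
        0 gives the deterministic model.
    """

    Q_max: float = 100.0
    theta: float = 10.0
    sigma_prime: float = 3.0
    nu_mv: float = -1.8
    nu_vm: float = -2.1
    nu_vh: float = 1.0
    nu_vc_c0: float = -13.05
    circ_amp: float = -2.9
    A_drive: float = 1.3
    tau_m: float = 10.0
    tau_v: float = 10.0
    mu: float = 4.4
    chi: float = 45.0
    omega: float = 2.0 * math.pi / 24.0
    phi: float = 0.0
    sigma_noise: float = 0.0

    def __post_init__(self) -> None:
        if not (self.Q_max > 0 and self.sigma_prime > 0):
            raise ValueError("Q_max and sigma_prime must be positive")
        if not (self.tau_m > 0 and self.tau_v > 0):
            raise ValueError("tau_m and tau_v must be positive")
        if not (self.chi > 0 and self.mu > 0):
            raise ValueError("chi and mu must be positive")
        if self.nu_mv >= 0 or self.nu_vm >= 0:
            raise ValueError("MA<->VLPO weights must be negative (mutual inhibition)")
        if self.nu_vh <= 0:
            raise ValueError("nu_vh must be positive (somnogen promotes sleep)")
        # nu_vc_c0 is negative in the physiological calibration (SCN output
        # promotes wake), but non-negative values are permitted: the no-wake
        # extreme of the parameter map (lesion-like loss of wake drive) is
        # only reachable when the mean drive crosses zero.
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be non-negative")

    # -- convenience ---------------------------------------------------
    @property
    def tau_m_h(self) -> float:
        """MA decay time in hours."""
        return self.tau_m / SECONDS_PER_HOUR

    @property
    def tau_v_h(self) -> float:
        """VLPO decay time in hours."""
        return self.tau_v / SECONDS_PER_HOUR

    def replace(self, **kwargs) -> "SwitchParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SwitchParams":
        return cls(**d)


@dataclass
class HemiState:
    """Instantaneous state of one hemisphere: potentials (mV) and somnogen (nM)."""

    V_m: float = 1.0
    V_v: float = -10.0
    H: float = 10.0

    def as_array(self) -> np.ndarray:
        return np.array([self.V_m, self.V_v, self.H], dtype=float)


def firing_rate(V, p: SwitchParams):
    """Sigmoid population firing rate ``Q(V) = Q_max / (1 + exp(-(V-theta)/sigma'))``.

    Strictly increasing in ``V``, bounded in (0, Q_max), with
    ``Q(theta) = Q_max/2`` exactly.  Accepts scalars or arrays.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("firing_rate: non-finite potential")
    with np.errstate(over="ignore"):  # deep hyperpolarization saturates to 0
        out = p.Q_max / (1.0 + np.exp(-(V - p.theta) / p.sigma_prime))
    return float(out) if out.ndim == 0 else out


def circadian_drive(t, p: SwitchParams):
    """Circadian drive to the VLPO at time ``t`` (hours): mean plus 24 h sinusoid."""
    t = np.asarray(t, dtype=float)
    out = p.nu_vc_c0 + p.circ_amp * np.cos(p.omega * t + p.phi)
    return float(out) if out.ndim == 0 else out


def vlpo_drive(H, t, p: SwitchParams):
    """Total drive to the VLPO: homeostatic ``nu_vh*H`` plus circadian components."""
    H = np.asarray(H, dtype=float)
    if np.any(H < 0):
        raise ValueError("vlpo_drive: somnogen concentration must be non-negative")
    out = p.nu_vh * H + circadian_drive(t, p)
    return float(out) if out.ndim == 0 else out


def derivatives(s: HemiState, t: float, p: SwitchParams) -> tuple[float, float, float]:
    """Vector field (dV_m/dt, dV_v/dt, dH/dt) in units of mV/h, mV/h, nM/h.

    tau_m dV_m/dt = -V_m + nu_mv*Q(V_v) + A
    tau_v dV_v/dt = -V_v + nu_vm*Q(V_m) + D_v(H, t)
    chi   dH/dt   = -H + mu*Q(V_m)
    """
    Q_m = firing_rate(s.V_m, p)
    Q_v = firing_rate(s.V_v, p)
    D_v = vlpo_drive(max(s.H, 0.0), t, p)
    dVm = (-s.V_m + p.nu_mv * Q_v + p.A_drive) / p.tau_m_h
    dVv = (-s.V_v + p.nu_vm * Q_m + D_v) / p.tau_v_h
    dH = (-s.H + p.mu * Q_m) / p.chi
    return dVm, dVv, dH


def flip_flop_fixed_points(D_v: float, p: SwitchParams,
                           v_range: tuple[float, float] = (-40.0, 20.0),
                           n_grid: int = 2000) -> list[dict]:
    """Fixed points of the frozen (V_m, V_v) flip-flop at constant VLPO drive.

    With H frozen (drive ``D_v`` constant) the fixed points satisfy
    ``V_m = nu_mv*Q(V_v) + A`` and ``V_v = nu_vm*Q(V_m) + D_v``; substituting
    gives a scalar root problem in ``V_v``, solved by bracketing on a grid
    and Brent's method.  Returns one dict per fixed point with keys
    ``V_m``, ``V_v``, ``stable`` (bool from the Jacobian eigenvalues),
    sorted by ``V_m`` ascending (sleep-like first, wake-like last).

    For intermediate drives the flip-flop is bistable: two stable fixed
    points (wake-like, high V_m; sleep-like, low V_m) separated by a saddle.
    """

    def resid(V_v: float) -> float:
        V_m = p.nu_mv * firing_rate(V_v, p) + p.A_drive
        return p.nu_vm * firing_rate(V_m, p) + D_v - V_v

    grid = np.linspace(v_range[0], v_range[1], n_grid)
    vals = np.array([resid(v) for v in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(resid, grid[i], grid[i + 1], xtol=1e-12))

    out = []
    for V_v in roots:
        V_m = p.nu_mv * firing_rate(V_v, p) + p.A_drive
        # Jacobian of the (V_m, V_v) subsystem (common time rescale drops out
        # of the stability question since tau_m, tau_v > 0).
        dQ = lambda V: (firing_rate(V, p) / p.Q_max) * (1 - firing_rate(V, p) / p.Q_max) * p.Q_max / p.sigma_prime
        J = np.array([
            [-1.0 / p.tau_m_h, p.nu_mv * dQ(V_v) / p.tau_m_h],
            [p.nu_vm * dQ(V_m) / p.tau_v_h, -1.0 / p.tau_v_h],
        ])
        stable = bool(np.all(np.real(np.linalg.eigvals(J)) < 0))
        out.append({"V_m": V_m, "V_v": V_v, "stable": stable})
    out.sort(key=lambda r: r["V_m"])
    return out


# ---------------------------------------------------------------------------
# Presets and config serialization
# ---------------------------------------------------------------------------

#: Named parameter sets.  ``human_nominal`` is the calibrated human set; the
#: other presets are representatives of the corresponding regions of the
#: (mean drive, chi) map, not literature-pinned values.
PRESETS: dict[str, SwitchParams] = {
    "human_nominal": SwitchParams(),
    "rodent_like": SwitchParams(chi=0.5, nu_vc_c0=-8.0),
    "elephant_like": SwitchParams(chi=8.0, nu_vc_c0=-14.5),
    "seal_like": SwitchParams(chi=6.0, nu_vc_c0=-10.0),
    "opossum_like": SwitchParams(chi=1.0, nu_vc_c0=-7.0, phi=math.pi),
}


def get_preset(name: str) -> SwitchParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def save_params(p: SwitchParams, path: str | Path) -> None:
    """Write parameters as a flat YAML mapping (key = field, value = number)."""
    import yaml

    Path(path).write_text(yaml.safe_dump(p.to_dict(), sort_keys=True))


def load_params(path: str | Path) -> SwitchParams:
    """Read parameters written by :func:`save_params`; missing keys default."""
    import yaml

    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise ValueError(f"{path}: expected a flat key/value mapping")
    unknown = set(d) - set(SwitchParams.__dataclass_fields__)
    if unknown:
        raise ValueError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    return SwitchParams(**d)
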