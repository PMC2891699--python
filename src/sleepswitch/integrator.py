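"""Time integration of the switch model, deterministic or with additive noise.

Deterministic runs use classical RK4 on the smooth vector field; stochastic
runs use Euler-Maruyama, adding independent standard-normal deviates to the
two potential equations each step with amplitude ``sigma_noise/sqrt(dt)``
(so the realized noise variance over a fixed physical interval is
independent of the step size).  Both schemes share one right-hand side.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .core_model import (
    SwitchParams,
    HemiState,
    SECONDS_PER_HOUR,
    firing_rate,
    vlpo_drive,
)

__all__ = ["SimConfig", "SimResult", "IntegrationError", "simulate"]


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


@dataclass(frozen=True)
class SimConfig:
    """Integration settings.

    duration is the total integrated span in hours *including* the
    transient; the first ``transient_discard`` hours are integrated but
    excluded from the returned series.  ``dt`` is the step in seconds
    (default 10 s, comparable to the neuromodulator decay times);
    ``sample_every`` stores one sample per that many steps (default 6,
    i.e. one per minute at the default step).
    """

    duration: float = 360.0
    dt: float = 10.0
    sample_every: int = 6
    seed: int | None = None
    transient_discard: float = 120.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if not (self.duration > self.transient_discard >= 0):
            raise ValueError("need duration > transient_discard >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SimResult:
    """Sampled trajectory of one hemisphere plus provenance snapshots."""

    times: np.ndarray          # h
    V_m: np.ndarray            # mV
    V_v: np.ndarray            # mV
    Q_m: np.ndarray            # 1/s
    Q_v: np.ndarray            # 1/s
    H: np.ndarray              # nM
    params: SwitchParams
    config: SimConfig
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.times)

    # -- TSV round trip -------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the series as TSV with a ``# key = value`` provenance header."""
        lines = []
        for k, v in self.params.to_dict().items():
            lines.append(f"# param.{k} = {v!r}")
        for k, v in self.config.to_dict().items():
            lines.append(f"# config.{k} = {v!r}")
        lines.append(f"# seed = {self.seed!r}")
        lines.append("time_h\tVm_mV\tVv_mV\tQm_s-1\tQv_s-1\tH_nM")
        for i in range(len(self.times)):
            lines.append("\t".join(
                format(x, ".17g")
                for x in (self.times[i], self.V_m[i], self.V_v[i],
                          self.Q_m[i], self.Q_v[i], self.H[i])
            ))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimResult":
        import ast

        import pandas as pd

        text = Path(path).read_text()
        meta: dict[str, object] = {}
        body = []
        for line in text.splitlines():
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = ast.literal_eval(val.strip())
            else:
                body.append(line)
        df = pd.read_csv(io.StringIO("\n".join(body)), sep="\t",
                         float_precision="round_trip")
        params = SwitchParams.from_dict(
            {k[len("param."):]: v for k, v in meta.items() if k.startswith("param.")}
        )
        config = SimConfig(
            **{k[len("config."):]: v for k, v in meta.items() if k.startswith("config.")}
        )
        return cls(
            times=df["time_h"].to_numpy(),
            V_m=df["Vm_mV"].to_numpy(),
            V_v=df["Vv_mV"].to_numpy(),
            Q_m=df["Qm_s-1"].to_numpy(),
            Q_v=df["Qv_s-1"].to_numpy(),
            H=df["H_nM"].to_numpy(),
            params=params,
            config=config,
            seed=meta.get("seed"),
        )


def _sigmoid(V: float, p: SwitchParams) -> float:
    # Scalar firing rate for the hot loop; the exp argument is clamped so a
    # diverging trajectory yields inf potentials (caught by the finiteness
    # check) instead of an OverflowError inside exp().
    x = -(V - p.theta) / p.sigma_prime
    if x > 700.0:
        return 0.0
    if x < -700.0:
        return p.Q_max
    return p.Q_max / (1.0 + math.exp(x))


def _rhs(V_m: float, V_v: float, H: float, t: float, p: SwitchParams,
         tau_m_h: float, tau_v_h: float):
    Q_m = _sigmoid(V_m, p)
    Q_v = _sigmoid(V_v, p)
    D_v = p.nu_vh * H + p.nu_vc_c0 + p.circ_amp * math.cos(p.omega * t + p.phi)
    return (
        (-V_m + p.nu_mv * Q_v + p.A_drive) / tau_m_h,
        (-V_v + p.nu_vm * Q_m + D_v) / tau_v_h,
        (-H + p.mu * Q_m) / p.chi,
    )


def simulate(p: SwitchParams, cfg: SimConfig,
             init: HemiState | None = None) -> SimResult:
    """Integrate the single-hemisphere model and return the sampled trajectory.

    Deterministic (``sigma_noise == 0``) runs use RK4 and are bitwise
    reproducible.  Stochastic runs use Euler-Maruyama with one
    ``numpy.random.Generator`` per simulation; the resolved seed is recorded
    in the result.  ``H`` is clamped non-negative after each step (negative
    values can only arise from noise/discretization artifacts).
    """
    if init is None:
        init = HemiState()
    V_m, V_v, H = float(init.V_m), float(init.V_v), float(max(init.H, 0.0))

    dt_h = cfg.dt / SECONDS_PER_HOUR
    n_steps = int(round(cfg.duration / dt_h))
    discard_steps = int(round(cfg.transient_discard / dt_h))
    tau_m_h, tau_v_h = p.tau_m_h, p.tau_v_h

    stochastic = p.sigma_noise > 0
    seed = cfg.seed
    if stochastic:
        if seed is None:
            seed = int(np.random.SeedSequence().entropy % (2**31))
        rng = np.random.default_rng(seed)
        amp = p.sigma_noise / math.sqrt(dt_h)  # mV/h noise term on the RHS

    times, vms, vvs, hs = [], [], [], []
    for i in range(n_steps + 1):
        t = i * dt_h
        if i >= discard_steps and (i - discard_steps) % cfg.sample_every == 0:
            times.append(t)
            vms.append(V_m)
            vvs.append(V_v)
            hs.append(H)
        if i == n_steps:
            break
        if stochastic:
            f = _rhs(V_m, V_v, H, t, p, tau_m_h, tau_v_h)
            xi_m, xi_v = rng.standard_normal(2)
            V_m += dt_h * (f[0] + amp * xi_m)
            V_v += dt_h * (f[1] + amp * xi_v)
            H += dt_h * f[2]
        else:
            k1 = _rhs(V_m, V_v, H, t, p, tau_m_h, tau_v_h)
            k2 = _rhs(V_m + 0.5 * dt_h * k1[0], V_v + 0.5 * dt_h * k1[1],
                      H + 0.5 * dt_h * k1[2], t + 0.5 * dt_h, p, tau_m_h, tau_v_h)
            k3 = _rhs(V_m + 0.5 * dt_h * k2[0], V_v + 0.5 * dt_h * k2[1],
                      H + 0.5 * dt_h * k2[2], t + 0.5 * dt_h, p, tau_m_h, tau_v_h)
            k4 = _rhs(V_m + dt_h * k3[0], V_v + dt_h * k3[1],
                      H + dt_h * k3[2], t + dt_h, p, tau_m_h, tau_v_h)
            V_m += dt_h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            V_v += dt_h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            H += dt_h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        if H < 0.0:
            H = 0.0
        if not (math.isfinite(V_m) and math.isfinite(V_v) and math.isfinite(H)):
            raise IntegrationError(
                f"non-finite state at step {i + 1} (t = {t + dt_h:.4f} h): "
                f"V_m={V_m}, V_v={V_v}, H={H}"
            )

    times_a = np.asarray(times)
    vm_a = np.asarray(vms)
    vv_a = np.asarray(vvs)
    return SimResult(
        times=times_a,
        V_m=vm_a,
        V_v=vv_a,
        Q_m=firing_rate(vm_a, p),
        Q_v=firing_rate(vv_a, p),
        H=np.asarray(hs),
        params=p,
        config=cfg,
        seed=seed,
    )
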