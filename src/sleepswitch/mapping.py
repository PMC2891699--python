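"""Parameter-plane sweeps and species inversion.

Interspecies differences are captured by two parameters: the mean drive to
the VLPO (mV; sets daily sleep duration) and the homeostatic time constant
chi (h; sets the wake-sleep cycling rate).  Sweeping this plane and scoring
each cell's attractor yields a map whose zones (no wake, no sleep,
monophasic, polyphasic) classify mammalian sleep patterns; a species'
reported metric ranges invert to a region of the plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import SwitchParams
from .integrator import SimConfig, simulate, IntegrationError
from .metrics import SleepMetrics, classify_state, sleep_metrics

__all__ = [
    "ParamMap",
    "SpeciesSpec",
    "sweep_map",
    "monophasic_boundary",
    "fit_species_region",
    "load_species_table",
]

#: Default sweep extents (mV and h).  The drive axis brackets the calibrated
#: human mean drive and spans from the no-sleep to the no-wake regime; chi is
#: log-spaced from rodent (minutes) to beyond-human (days) scales.
DEFAULT_DRIVE_RANGE = (-17.0, -9.0)
DEFAULT_CHI_RANGE = (0.1, 100.0)

#: Per-cell simulation: 10 scored days after a 5-day transient, matching the
#: steady-state patterns being classified.
DEFAULT_CELL_CONFIG = SimConfig(duration=360.0, transient_discard=120.0)


@dataclass
class ParamMap:
    """Grid over (mean VLPO drive, chi) with per-cell metrics and zones."""

    drive_grid: np.ndarray            # mV, shape (n_d,)
    chi_grid: np.ndarray              # h, shape (n_c,)
    cells: np.ndarray                 # object array (n_d, n_c) of SleepMetrics or None
    zone_labels: np.ndarray           # str array (n_d, n_c); "ERROR" for failed cells

    def metric(self, name: str) -> np.ndarray:
        """Float matrix of one SleepMetrics field (nan for failed cells)."""
        out = np.full(self.cells.shape, np.nan)
        for idx, m in np.ndenumerate(self.cells):
            if m is not None:
                out[idx] = getattr(m, name)
        return out

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for i, d in enumerate(self.drive_grid):
            for j, c in enumerate(self.chi_grid):
                m = self.cells[i, j]
                rows.append({
                    "drive_mV": d,
                    "chi_h": c,
                    "total_daily_sleep_h": m.total_daily_sleep if m else np.nan,
                    "mean_bout_length_min": m.mean_bout_length if m else np.nan,
                    "bouts_per_day": m.bouts_per_day if m else np.nan,
                    "n_episodes_per_cycle": m.n_episodes_per_cycle if m else -1,
                    "zone": self.zone_labels[i, j],
                })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SpeciesSpec:
    """Reported sleep metrics of one species, used to invert to a region."""

    name: str
    daily_sleep_range: tuple[float, float]   # h
    bout_length_range: tuple[float, float]   # min
    body_mass: float                         # kg
    chi_upper_bound: float | None = None     # h; monophasic (primate) clip

    def __post_init__(self) -> None:
        if self.daily_sleep_range[0] > self.daily_sleep_range[1]:
            raise ValueError("daily_sleep_range must be (lo, hi)")
        if self.bout_length_range[0] > self.bout_length_range[1]:
            raise ValueError("bout_length_range must be (lo, hi)")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")


def sweep_map(drive_grid, chi_grid, base: SwitchParams,
              cfg: SimConfig = DEFAULT_CELL_CONFIG) -> ParamMap:
    """Simulate and score every (drive, chi) cell.

    Cells are mutually independent (identical ``cfg``, fresh initial state),
    so results do not depend on evaluation order.  A cell whose integration
    fails is recorded as zone ``"ERROR"`` with no metrics rather than
    aborting the sweep.  Requires a deterministic configuration.
    """
    if base.sigma_noise > 0:
        raise ValueError("sweep_map requires a deterministic base (sigma_noise = 0)")
    drive_grid = np.asarray(drive_grid, dtype=float)
    chi_grid = np.asarray(chi_grid, dtype=float)
    if drive_grid.size == 0 or chi_grid.size == 0:
        raise ValueError("grids must be non-empty")
    cells = np.empty((drive_grid.size, chi_grid.size), dtype=object)
    zones = np.empty(cells.shape, dtype=object)
    for i, d in enumerate(drive_grid):
        for j, c in enumerate(chi_grid):
            p = base.replace(nu_vc_c0=float(d), chi=float(c))
            try:
                sim = simulate(p, cfg)
                m = sleep_metrics(classify_state(sim))
            except IntegrationError:
                cells[i, j] = None
                zones[i, j] = "ERROR"
            else:
                cells[i, j] = m
                zones[i, j] = m.zone
    return ParamMap(drive_grid=drive_grid, chi_grid=chi_grid,
                    cells=cells, zone_labels=zones)


def _n_episodes(chi: float, drive: float, base: SwitchParams,
                cfg: SimConfig) -> int:
    p = base.replace(chi=float(chi), nu_vc_c0=float(drive))
    return sleep_metrics(classify_state(simulate(p, cfg))).n_episodes_per_cycle


def monophasic_boundary(drive: float, base: SwitchParams,
                        tol: float = 0.25,
                        chi_lo: float = 1.0,
                        chi_hi: float = 45.0,
                        cfg: SimConfig = DEFAULT_CELL_CONFIG) -> float:
    """Bisect chi for the polyphasic -> monophasic transition at fixed drive.

    Returns the infimum of the monophasic chi range to tolerance ``tol``
    (hours).  Raises if the bracket is invalid (``chi_hi`` must be
    monophasic and ``chi_lo`` polyphasic at the given drive).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    n_hi = _n_episodes(chi_hi, drive, base, cfg)
    n_lo = _n_episodes(chi_lo, drive, base, cfg)
    if n_hi != 1 or n_lo <= 1:
        raise ValueError(
            f"bracket not found: chi={chi_lo} h gives {n_lo} episodes/day, "
            f"chi={chi_hi} h gives {n_hi}; need polyphasic at the bottom and "
            "monophasic at the top"
        )
    lo, hi = chi_lo, chi_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _n_episodes(mid, drive, base, cfg) == 1:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def fit_species_region(spec: SpeciesSpec, pmap: ParamMap) -> dict:
    """Cells of the map consistent with a species' reported metric ranges.

    The region is the axis-aligned preimage of the metric intervals: a cell
    belongs iff its total daily sleep and mean bout length both fall inside
    the species' ranges; species with a ``chi_upper_bound`` (monophasic
    primates) are additionally clipped at that chi.  Returns a dict with the
    boolean ``mask``, number of matching cells, a warning flag if the region
    is thinner than 2 cells, and — when empty — the nearest-miss cell and
    its metric distances.
    """
    ts = pmap.metric("total_daily_sleep")
    bl = pmap.metric("mean_bout_length")
    ts_lo, ts_hi = spec.daily_sleep_range
    bl_lo, bl_hi = spec.bout_length_range
    mask = (ts >= ts_lo) & (ts <= ts_hi) & (bl >= bl_lo) & (bl <= bl_hi)
    if spec.chi_upper_bound is not None:
        mask &= pmap.chi_grid[None, :] <= spec.chi_upper_bound
    result = {
        "species": spec.name,
        "mask": mask,
        "n_cells": int(mask.sum()),
        "resolution_warning": 0 < int(mask.sum()) < 2,
    }
    if not mask.any():
        # Nearest miss: smallest summed relative distance outside the box.
        with np.errstate(invalid="ignore"):
            d_ts = np.maximum(0, np.maximum(ts_lo - ts, ts - ts_hi)) / max(ts_hi, 1e-9)
            d_bl = np.maximum(0, np.maximum(bl_lo - bl, bl - bl_hi)) / max(bl_hi, 1e-9)
            dist = np.where(np.isnan(ts) | np.isnan(bl), np.inf, d_ts + d_bl)
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        result["nearest_miss"] = {
            "drive_mV": float(pmap.drive_grid[i]),
            "chi_h": float(pmap.chi_grid[j]),
            "total_daily_sleep_h": float(ts[i, j]),
            "mean_bout_length_min": float(bl[i, j]),
        }
    return result


def load_species_table(path: str | Path) -> list[SpeciesSpec]:
    """Read a species metrics CSV (columns: species, daily_sleep_lo_h,
    daily_sleep_hi_h, bout_lo_min, bout_hi_min, body_mass_kg, optional
    chi_upper_bound_h, optional placeholder flag).  Rows flagged as
    placeholder are skipped: they mark entries awaiting transcription from
    the primary literature and must not be treated as data."""
    df = pd.read_csv(path, comment="#")
    specs = []
    for _, r in df.iterrows():
        if "placeholder" in df.columns and bool(r["placeholder"]):
            continue
        ub = r.get("chi_upper_bound_h")
        specs.append(SpeciesSpec(
            name=str(r["species"]),
            daily_sleep_range=(float(r["daily_sleep_lo_h"]), float(r["daily_sleep_hi_h"])),
            bout_length_range=(float(r["bout_lo_min"]), float(r["bout_hi_min"])),
            body_mass=float(r["body_mass_kg"]),
            chi_upper_bound=None if pd.isna(ub) else float(ub),
        ))
    return specs
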