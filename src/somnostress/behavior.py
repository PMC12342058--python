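"""Social-interaction scoring from arena trajectories.

The social-interaction test consists of two consecutive 3 min trials in a
30x30 cm arena holding a 9x9 cm wire cage: first with the cage empty,
then with a novel aggressor mouse inside it. The social-interaction ratio

    SIR = t_f / t_e

compares time spent in the interaction zone with the target present
(``t_f``) to time in the same zone with the cage empty (``t_e``).
SIR > 1.1 marks resilience, SIR < 0.9 susceptibility; ratios in the
closed band [0.9, 1.1] are excluded from sleep analyses (but kept in
behavioral tables).

The interaction zone is the set of points within 15 cm of the cage. By
default that distance is measured from the cage *boundary* — a 15 cm
radius from the centre of a 9 cm cage would barely extend past the cage
itself — with centre-distance available as an option. Trajectories are
resampled to a uniform 10 Hz grid before time integration.
"""

from __future__ import annotations

import numpy as np

from .core import ArenaSpec, Trajectory

RESILIENT_SIR = 1.1
SUSCEPTIBLE_SIR = 0.9

RESAMPLE_HZ = 10.0


def _resample(traj: Trajectory, fs: float = RESAMPLE_HZ):
    n = int(round((traj.t_s[-1] - traj.t_s[0]) * fs)) + 1
    t = traj.t_s[0] + np.arange(n) / fs
    x = np.interp(t, traj.t_s, traj.x_cm)
    y = np.interp(t, traj.t_s, traj.y_cm)
    return t, x, y


def _distance_to_cage(x, y, spec: ArenaSpec, mode: str) -> np.ndarray:
    cx, cy = spec.cage_center
    if mode == "center":
        return np.hypot(x - cx, y - cy)
    if mode != "boundary":
        raise ValueError(f"unknown zone mode {mode!r}")
    half = spec.cage_side_cm / 2.0
    dx = np.maximum(np.abs(x - cx) - half, 0.0)
    dy = np.maximum(np.abs(y - cy) - half, 0.0)
    return np.hypot(dx, dy)  # 0 inside the cage footprint


def zone_time(traj: Trajectory, spec: ArenaSpec | None = None,
              mode: str = "boundary") -> float:
    """Seconds spent within the interaction zone.

    Each uniform 10 Hz sample inside the zone contributes one sample
    interval; the result never exceeds the trial duration.
    """
    spec = spec or traj.arena
    if traj.n_samples < 2:
        raise ValueError("need at least 2 trajectory samples")
    _, x, y = _resample(traj)
    inside = _distance_to_cage(x, y, spec, mode) <= spec.interaction_radius_cm
    return float(np.sum(inside) / RESAMPLE_HZ)


def interaction_ratio(t_f: float, t_e: float) -> float:
    """SIR = t_f / t_e (dimensionless)."""
    if t_e <= 0:
        raise ValueError("t_e = 0: interaction ratio undefined; "
                         "flag subject for manual review")
    return t_f / t_e


def classify_phenotype(sir: float) -> str:
    """Map an interaction ratio onto {resilient, susceptible, excluded}.

    The boundaries 0.9 and 1.1 belong to the excluded band.
    """
    if not np.isfinite(sir) or sir < 0:
        raise ValueError(f"invalid interaction ratio {sir}")
    if sir > RESILIENT_SIR:
        return "resilient"
    if sir < SUSCEPTIBLE_SIR:
        return "susceptible"
    return "excluded"


def distance_traveled(traj: Trajectory) -> float:
    """Total path length (cm), the sum of consecutive step lengths."""
    if traj.n_samples < 2:
        raise ValueError("need at least 2 trajectory samples")
    return float(np.sum(np.hypot(np.diff(traj.x_cm), np.diff(traj.y_cm))))


def occupancy_grid(traj: Trajectory, cell_cm: float,
                   spec: ArenaSpec | None = None) -> np.ndarray:
    """Dwell-time grid (seconds per cell); grid sum equals trial time.

    Cells index as ``grid[ix, iy]`` with x/y in cm from the arena origin.
    """
    spec = spec or traj.arena
    n_cells = spec.side_cm / cell_cm
    if abs(n_cells - round(n_cells)) > 1e-9:
        raise ValueError(f"cell size {cell_cm} must divide {spec.side_cm} cm")
    n = int(round(n_cells))
    _, x, y = _resample(traj)
    ix = np.clip((x / cell_cm).astype(int), 0, n - 1)
    iy = np.clip((y / cell_cm).astype(int), 0, n - 1)
    grid = np.zeros((n, n))
    np.add.at(grid, (ix, iy), 1.0 / RESAMPLE_HZ)
    return grid


def score_interaction_test(traj_empty: Trajectory, traj_target: Trajectory,
                           spec: ArenaSpec | None = None,
                           mode: str = "boundary") -> dict:
    """Full scoring of one pre- or post-defeat test (both trials).

    Returns ``t_e``, ``t_f``, ``sir``, ``phenotype`` and per-trial
    distance traveled.
    """
    spec = spec or traj_empty.arena
    t_e = zone_time(traj_empty, spec, mode)
    t_f = zone_time(traj_target, spec, mode)
    sir = interaction_ratio(t_f, t_e)
    return {
        "t_e": t_e,
        "t_f": t_f,
        "sir": sir,
        "phenotype": classify_phenotype(sir),
        "distance_empty_cm": distance_traveled(traj_empty),
        "distance_target_cm": distance_traveled(traj_target),
    }
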