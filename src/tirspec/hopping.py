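"""Hopping-event detection, gap-criterion replay and population statistics.

The simplified surface-hopping scheme analysed here switches the active
electronic state deterministically whenever the energy gap to the adjacent
lower state drops below a threshold (2 kcal/mol by default) — the hopping
probability is unity every time two surfaces come close. Back-hops among
excited states are allowed under the same gap rule; once a trajectory has
reached the ground state, up-hops are forbidden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import circmean, circstd

from .constants import KCALMOL_TO_EV
from .coords import CoordinateSpec, evaluate

__all__ = [
    "HopEvent",
    "HopCriterion",
    "detect_hops_from_states",
    "find_rule_violations",
    "apply_gap_criterion",
    "population_curves",
    "hop_geometry_stats",
    "hop_times",
    "mean_hop_time",
]

#: 2 kcal/mol in eV — the default gap threshold.
DEFAULT_GAP_THRESHOLD_EV = 2.0 * KCALMOL_TO_EV


@dataclass(frozen=True)
class HopEvent:
    time: float  # fs
    frame_index: int
    from_state: int
    to_state: int
    trajectory_id: str = ""

    def __post_init__(self):
        if self.from_state == self.to_state:
            raise ValueError("a hop must change the state")


@dataclass(frozen=True)
class HopCriterion:
    gap_threshold_ev: float = DEFAULT_GAP_THRESHOLD_EV
    forbid_up_from_gs: bool = True

    def __post_init__(self):
        if self.gap_threshold_ev <= 0:
            raise ValueError("gap threshold must be positive")


def detect_hops_from_states(traj) -> list[HopEvent]:
    """One HopEvent per change in the recorded active-state series,
    timestamped at the later frame."""
    if traj.state_series is None:
        raise ValueError("trajectory has no state series")
    s = traj.state_series
    times = traj.times
    events = []
    for k in np.flatnonzero(np.diff(s) != 0):
        events.append(
            HopEvent(
                time=float(times[k + 1]),
                frame_index=int(k + 1),
                from_state=int(s[k]),
                to_state=int(s[k + 1]),
                trajectory_id=traj.id,
            )
        )
    return events


def find_rule_violations(events, criterion: HopCriterion | None = None) -> list[HopEvent]:
    """Hops that violate the no-up-hop-from-the-ground-state rule."""
    criterion = criterion or HopCriterion()
    if not criterion.forbid_up_from_gs:
        return []
    return [e for e in events if e.from_state == 0]


def apply_gap_criterion(energies, active_state_0: int, criterion: HopCriterion | None = None) -> np.ndarray:
    """Deterministic replay of the gap-based hopping scheme.

    ``energies`` is (n_frames, n_states) in eV. At every frame, if the gap
    between the active state and the adjacent lower state is below the
    threshold, the trajectory hops down (probability one). Among excited
    states, an up-hop to the adjacent higher state is taken under the same
    rule (down-hops have priority). From the ground state no hops occur.
    Returns the per-frame active-state series; the reported state at a hop
    frame is the post-hop state.
    """
    criterion = criterion or HopCriterion()
    energies = np.asarray(energies, dtype=float)
    if energies.ndim != 2 or energies.shape[1] < 2:
        raise ValueError("need per-frame energies for at least two states")
    n_frames, n_states = energies.shape
    if not 0 <= active_state_0 < n_states:
        raise ValueError("initial state outside the available states")
    thr = criterion.gap_threshold_ev
    out = np.empty(n_frames, dtype=int)
    active = active_state_0
    for k in range(n_frames):
        if active > 0 and energies[k, active] - energies[k, active - 1] < thr:
            active -= 1
        elif (
            active >= 1
            and active + 1 < n_states
            and energies[k, active + 1] - energies[k, active] < thr
        ):
            active += 1
        out[k] = active
    return out


def population_curves(ensemble) -> pd.DataFrame:
    """Fraction of trajectories in each state versus time.

    Returns a DataFrame indexed by time (fs) with one ``S<k>`` column per
    state; rows sum to 1. Trajectories are truncated to the shortest member.
    """
    series = []
    for tr in ensemble:
        if tr.state_series is None:
            raise ValueError(f"trajectory '{tr.id}' has no state series")
        series.append(tr.state_series)
    n = min(len(s) for s in series)
    times = ensemble.trajectories[0].times[:n]
    stacked = np.stack([s[:n] for s in series])  # (n_traj, n_frames)
    n_states = int(stacked.max()) + 1
    fractions = np.stack([(stacked == k).mean(axis=0) for k in range(n_states)], axis=1)
    return pd.DataFrame(fractions, index=pd.Index(times, name="time"), columns=[f"S{k}" for k in range(n_states)])


def hop_times(ensemble, transition) -> np.ndarray:
    """Times (fs) of all hops matching ``transition=(from_state, to_state)``."""
    frm, to = transition
    out = []
    for tr in ensemble:
        for e in detect_hops_from_states(tr):
            if e.from_state == frm and e.to_state == to:
                out.append(e.time)
    return np.asarray(out, dtype=float)


def mean_hop_time(ensemble, transition):
    """Sample mean and standard error of matching hop times.

    For exponentially distributed hop times the sample mean is the maximum-
    likelihood estimate of the decay constant, with s.e. = mean/√n.
    """
    t = hop_times(ensemble, transition)
    if len(t) == 0:
        raise ValueError("no matching hops")
    return float(t.mean()), float(t.mean() / np.sqrt(len(t)))


def hop_geometry_stats(ensemble, coordinate_specs, transition, bins: int = 36) -> dict:
    """Coordinate statistics at matching hop geometries.

    For each CoordinateSpec, evaluates the coordinate at every matching hop
    frame across the ensemble and reports mean, standard deviation (circular
    statistics for dihedrals), the raw values, and a histogram. An empty
    result (``{"n_hops": 0}``) flags that no hop matched.
    """
    frm, to = transition
    values: dict[str, list[float]] = {s.name: [] for s in coordinate_specs}
    n_hops = 0
    for tr in ensemble:
        hops = [e for e in detect_hops_from_states(tr) if e.from_state == frm and e.to_state == to]
        if not hops:
            continue
        coords = tr.coords
        for e in hops:
            n_hops += 1
            for spec in coordinate_specs:
                values[spec.name].append(float(evaluate(coords[e.frame_index], spec)))
    result: dict = {"n_hops": n_hops, "transition": (frm, to), "coordinates": {}}
    for spec in coordinate_specs:
        v = np.asarray(values[spec.name])
        if len(v) == 0:
            continue
        if spec.kind == "dihedral":
            mean = float(np.degrees(circmean(np.radians(v))))
            std = float(np.degrees(circstd(np.radians(v))))
        else:
            mean = float(v.mean())
            std = float(v.std())
        hist, edges = np.histogram(v, bins=bins)
        result["coordinates"][spec.name] = {
            "mean": mean,
            "std": std,
            "values": v,
            "hist": hist,
            "bin_edges": edges,
        }
    return result
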