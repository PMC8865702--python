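"""Hybrid integration of the cell-cycle model and cycle-level metrics.

The continuous dynamics are integrated piecewise with a stiff-capable adaptive
solver; each segment ends at the first armed threshold crossing, the event's
assignments are applied atomically, and integration restarts with fresh solver
state.  The result is a :class:`Trajectory`: a dense (<= 1 min spacing) record
of all 29 continuous variables, the discrete mode, and an event log.

Cycle metrics are derived from the event log.  The reference event for the
cell-cycle period is replication initiation — it occurs exactly once per cycle
in the wild type; at steady state division (Z-ring) events give the same
period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .events import EventRule, apply_rule, builtin_event_table
from .parameters import ParameterSet, default_initial_state, default_parameters
from .state import STATE_INDEX, STATE_NAMES, CellState

__all__ = [
    "Trajectory",
    "CycleMetrics",
    "SimulationError",
    "ArrestedCycleError",
    "simulate",
    "simulate_qssa",
    "cycle_period",
    "sphase_interval",
    "classify_phenotype",
    "OBSERVABLE_MAP",
]

#: Measured ("western blot") observables are totals over phospho-forms.
OBSERVABLE_MAP: dict[str, tuple[str, ...]] = {
    "CtrA": ("CtrA", "CtrAP"),
    "CpdR": ("CpdR", "CpdRP"),
    "PleD": ("PleD", "PleDP"),
}


class SimulationError(RuntimeError):
    """Integration failure; carries the last good time and state."""

    def __init__(self, message: str, t: float, state: CellState):
        super().__init__(message)
        self.t = t
        self.state = state


class ArrestedCycleError(RuntimeError):
    """Raised when a cycle metric is requested from a non-oscillatory run."""


@dataclass(frozen=True)
class EventRecord:
    id: str
    time: float
    cycle: int


@dataclass
class Trajectory:
    """Dense time-stamped record of a simulation with its event log."""

    t: np.ndarray
    y: np.ndarray  # (n_states, n_samples)
    ks_zring: np.ndarray
    dna: np.ndarray
    count: np.ndarray
    events: list[EventRecord]
    params_digest: str
    solver: dict = field(default_factory=dict)
    qssa: bool = False

    def __post_init__(self):
        if np.any(np.diff(self.t) < 0):
            raise ValueError("trajectory time grid must be non-decreasing")

    def species(self, name: str) -> np.ndarray:
        return self.y[STATE_INDEX[name]]

    def observable(self, name: str) -> np.ndarray:
        """Series as an experiment would see it (phospho-forms summed)."""
        parts = OBSERVABLE_MAP.get(name, (name,))
        return sum(self.species(p) for p in parts)

    def at(self, name: str, times) -> np.ndarray:
        return np.interp(np.asarray(times, dtype=float), self.t, self.observable(name))

    def event_times(self, event_id: str) -> np.ndarray:
        return np.array([e.time for e in self.events if e.id == event_id])

    def final_state(self) -> CellState:
        return CellState(
            y=self.y[:, -1].copy(),
            dna=float(self.dna[-1]),
            count=int(self.count[-1]),
            ks_zring=float(self.ks_zring[-1]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one column per state variable plus the discrete mode."""
        df = pd.DataFrame(self.y.T, columns=list(STATE_NAMES))
        df.insert(0, "time_min", self.t)
        df["DNA"] = self.dna
        df["Count"] = self.count
        df["ks_zring"] = self.ks_zring
        return df

    def to_long(self) -> pd.DataFrame:
        """Tidy long table (time_min, variable, value)."""
        return self.to_frame().melt(
            id_vars="time_min", var_name="variable", value_name="value"
        )

    def event_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.id, e.time, e.cycle) for e in self.events],
            columns=["event", "time_min", "cycle"],
        )


def _segment_grid(t0: float, t1: float, dt: float) -> np.ndarray:
    """Sample points in (t0, t1] no more than dt apart."""
    if t1 <= t0:
        return np.array([t1])
    n = max(1, int(math.ceil((t1 - t0) / dt)))
    return np.linspace(t0, t1, n + 1)[1:]


def simulate(
    params: ParameterSet | None = None,
    init: CellState | None = None,
    duration: float = 600.0,
    *,
    qssa: bool = False,
    rules: Sequence[EventRule] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_step: float = 5.0,
    sample_dt: float = 1.0,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the hybrid system for ``duration`` minutes.

    Deterministic given inputs and tolerances.  ``duration = 0`` returns a
    trajectory holding only the initial state.
    """
    from .dynamics import _rhs

    if params is None:
        params = default_parameters()
    if init is None:
        init = default_initial_state()
    if duration < 0:
        raise ValueError("duration must be >= 0")
    init.validate(ccka_total=params.CckA_T)

    rules = list(builtin_event_table(params) if rules is None else rules)
    pv = params.to_vector()
    state = init
    t = 0.0
    plec_origin = 0.0
    cycle = 0

    ts: list[np.ndarray] = [np.array([0.0])]
    ys: list[np.ndarray] = [state.y[:, None].copy()]
    mode_rows: list[tuple[float, float, int]] = [(state.ks_zring, state.dna, state.count)]
    n_mode: list[int] = [1]
    events: list[EventRecord] = []

    guard = 0
    while t < duration - 1e-9:
        guard += 1
        if guard > 100_000:
            raise SimulationError("event loop did not terminate", t, state)
        armed = [r for r in rules if r.armed(state)]
        ev_funs = []
        for rule in armed:
            idx = STATE_INDEX[rule.trigger_variable]
            thr = rule.threshold

            def g(tt, yy, *_args, _idx=idx, _thr=thr):
                return yy[_idx] - _thr

            g.terminal = True
            g.direction = 1.0
            ev_funs.append(g)

        sol = solve_ivp(
            _rhs,
            (t, duration),
            state.y,
            args=(pv, state.ks_zring, plec_origin, qssa),
            method=method,
            rtol=rtol,
            atol=atol,
            max_step=max_step,
            events=ev_funs,
            dense_output=True,
        )
        if sol.status < 0:
            raise SimulationError(f"solver failed: {sol.message}", t, state)

        t_end = sol.t[-1]
        grid = _segment_grid(t, t_end, sample_dt)
        seg = sol.sol(grid) if len(sol.t) > 1 else np.repeat(state.y[:, None], len(grid), axis=1)
        ts.append(grid)
        ys.append(seg)
        mode_rows.append((state.ks_zring, state.dna, state.count))
        n_mode.append(len(grid))

        if sol.status == 1:  # an event fired
            hit = min(
                (k for k, te in enumerate(sol.t_events) if len(te)),
                key=lambda k: (sol.t_events[k][0], k),  # tie-break: table order
            )
            te = float(sol.t_events[hit][0])
            rule = armed[hit]
            pre = CellState(
                y=sol.y_events[hit][0].copy(),
                dna=state.dna,
                count=state.count,
                ks_zring=state.ks_zring,
            )
            state = apply_rule(rule, pre)
            if rule.id == "initiation":
                cycle += 1
            if rule.resets_plec_clock:
                plec_origin = te
            events.append(EventRecord(rule.id, te, cycle))
            # record the post-event state at the event time (discontinuity)
            ts.append(np.array([te]))
            ys.append(state.y[:, None].copy())
            mode_rows.append((state.ks_zring, state.dna, state.count))
            n_mode.append(1)
            t = te
        else:
            state = CellState(
                y=sol.y[:, -1].copy(),
                dna=state.dna,
                count=state.count,
                ks_zring=state.ks_zring,
            )
            t = t_end

    tgrid = np.concatenate(ts)
    Y = np.hstack(ys)
    # integration overshoot below zero is a solver artifact; clip at 0
    low = Y.min()
    if low < -1e-7:
        raise SimulationError(f"state went negative ({low:.3g})", t, state)
    Y = np.clip(Y, 0.0, None)

    ksz = np.repeat([m[0] for m in mode_rows], n_mode)
    dna = np.repeat([m[1] for m in mode_rows], n_mode)
    cnt = np.repeat([m[2] for m in mode_rows], n_mode).astype(int)
    return Trajectory(
        t=tgrid,
        y=Y,
        ks_zring=ksz,
        dna=dna,
        count=cnt,
        events=events,
        params_digest=params.digest(),
        solver={"method": method, "rtol": rtol, "atol": atol, "max_step": max_step},
        qssa=qssa,
    )


def simulate_qssa(params=None, init=None, duration: float = 600.0, **kw) -> Trajectory:
    """Simulate with Complex3 at quasi-steady state (k3+ cdG^2 C2 / k3-).

    The reduced model integrates the same state vector with the Complex3
    column replaced post hoc by its algebraic value.
    """
    traj = simulate(params, init, duration, qssa=True, **kw)
    p = params if params is not None else default_parameters()
    c3 = p.k3_plus * traj.species("cdG") ** 2 * traj.species("Complex2") / p.k3_minus
    traj.y[STATE_INDEX["Complex3"]] = c3
    return traj


@dataclass(frozen=True)
class CyclePeriod:
    period: float
    intervals: np.ndarray
    converged: bool


def cycle_period(
    traj: Trajectory,
    reference: str = "initiation",
    discard: int = 2,
    converge_rtol: float = 0.01,
) -> CyclePeriod:
    """Cell-cycle period from the settled inter-event intervals.

    Discards the first ``discard`` transient cycles, averages the remaining
    inter-event intervals of the reference event, and flags convergence when
    the last two intervals agree within ``converge_rtol``.

    Raises
    ------
    ArrestedCycleError
        If fewer than 3 reference events remain after the transient.
    """
    times = traj.event_times(reference)
    if len(times) < 3:
        raise ArrestedCycleError(
            f"only {len(times)} {reference!r} events; phenotype is arrested "
            "(need >= 3 for a period)"
        )
    discard = min(discard, len(times) - 3)
    iv = np.diff(times[discard:])
    converged = bool(abs(iv[-1] - iv[-2]) <= converge_rtol * iv[-1]) if len(iv) >= 2 else False
    return CyclePeriod(period=float(iv.mean()), intervals=iv, converged=converged)


def sphase_interval(traj: Trajectory, cycle: int = -1) -> float:
    """Initiation-to-constriction interval of one settled cycle (minutes).

    The Z-ring clock rises linearly at ks_Zring_on from the initiation event,
    so the interval is analytically 1/ks_Zring_on (~ 90.9 min at 0.011/min).
    """
    inits = traj.event_times("initiation")
    rings = traj.event_times("zring")
    pairs = [(ti, rings[rings > ti][0]) for ti in inits if np.any(rings > ti)]
    if not pairs:
        raise ArrestedCycleError("no completed initiation -> Z-ring pair in trajectory")
    ti, tz = pairs[cycle]
    return float(tz - ti)


@dataclass(frozen=True)
class CycleMetrics:
    """Summary metrics of a settled cycle."""

    phenotype: str  # oscillatory | arrested | damped
    period: float | None
    period_converged: bool
    sphase_min: float | None
    init_to_termination: float | None
    species_range: pd.DataFrame | None

    def summary(self) -> str:
        lines = [f"phenotype: {self.phenotype}"]
        if self.period is not None:
            lines.append(f"cycle period T_c: {self.period:.2f} min"
                         f" (converged: {self.period_converged})")
        if self.sphase_min is not None:
            lines.append(f"initiation -> constriction: {self.sphase_min:.2f} min")
        if self.init_to_termination is not None:
            lines.append(f"initiation -> termination: {self.init_to_termination:.2f} min")
        return "\n".join(lines)


def _last_cycle_window(traj: Trajectory) -> tuple[float, float] | None:
    inits = traj.event_times("initiation")
    if len(inits) < 2:
        return None
    return float(inits[-2]), float(inits[-1])


def classify_phenotype(
    traj: Trajectory,
    reference: str = "initiation",
    damped_fraction: float = 0.10,
) -> CycleMetrics:
    """Classify a run as oscillatory, arrested or damped, with metrics.

    Arrested: fewer than 3 reference events (no recurring cycle).
    Damped: the system has not reached a limit cycle and its total-CtrA
    oscillation is dying out — the inter-event intervals have not converged
    while the last cycle's CtrA amplitude has fallen below
    ``damped_fraction`` of the first cycle's and is still shrinking.
    A sustained limit cycle (converged period) is oscillatory even when its
    CtrA amplitude is small.
    """
    times = traj.event_times(reference)
    if len(times) < 3:
        return CycleMetrics("arrested", None, False, None, None, None)

    def amplitude(t0, t1):
        sel = (traj.t >= t0) & (traj.t <= t1)
        tot = traj.observable("CtrA")[sel]
        return float(tot.max() - tot.min())

    first_amp = amplitude(times[0], times[1])
    penult_amp = amplitude(times[-3], times[-2]) if len(times) >= 3 else first_amp
    last_amp = amplitude(times[-2], times[-1])

    try:
        cp = cycle_period(traj, reference=reference)
        period, conv = cp.period, cp.converged
    except ArrestedCycleError:
        period, conv = None, False

    damped = (
        not conv
        and first_amp > 0
        and last_amp < damped_fraction * first_amp
        and last_amp < 0.8 * penult_amp
    )

    try:
        sphase = sphase_interval(traj)
    except ArrestedCycleError:
        sphase = None
    terms = traj.event_times("termination")
    inits = traj.event_times("initiation")
    i2t = None
    for ti in inits:
        later = terms[terms > ti]
        if len(later):
            i2t = float(later[0] - ti)

    window = _last_cycle_window(traj)
    ranges = None
    if window:
        sel = (traj.t >= window[0]) & (traj.t <= window[1])
        rows = []
        for name in STATE_NAMES:
            s = traj.species(name)[sel]
            rows.append((name, s.min(), s.max(), s.max() - s.min()))
        ranges = pd.DataFrame(rows, columns=["species", "min", "max", "amplitude"])

    phenotype = "damped" if damped else ("oscillatory" if period is not None else "arrested")
    return CycleMetrics(phenotype, period, conv, sphase, i2t, ranges)
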