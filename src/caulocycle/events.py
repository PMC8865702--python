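"""Discrete events of the cell cycle: threshold rules and their application.

Five instantaneous events punctuate the continuous dynamics:

==========================  =================  =========================================
event                       condition          changes
==========================  =================  =========================================
replication initiation      Ini = P_elong      Ini:=0, Elong:=elong_at_initiation,
                                               DNA:=1.05, Count:=2, ks_Zring:=on,
                                               h_Cori:=1
fork passes *ccrM* locus    Elong = 0.2        h_ccrM := 1
fork passes *ctrA* locus    Elong = 0.375      h_ctrA := 1
elongation terminates       Elong = 1          Elong := 0
Z-ring constriction         Zring = 1          Zring:=0, ks_Zring:=0, DNA:=1, Count:=1,
                                               PleC clock restarts
==========================  =================  =========================================

All rules trigger on upward crossings: every trigger variable increases toward
its threshold and is reset below it by an event, so downward crossings are
reset artifacts and are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.optimize import brentq

from .parameters import ParameterSet
from .state import STATE_INDEX, CellState

__all__ = ["EventRule", "builtin_event_table", "locate_and_apply", "apply_rule"]

_MODE_FIELDS = {"DNA", "Count", "ks_zring"}


@dataclass(frozen=True)
class EventRule:
    """A threshold condition on one state variable plus instantaneous assignments."""

    id: str
    trigger_variable: str
    threshold: float
    assignments: Mapping[str, float] = field(default_factory=dict)
    direction: int = +1
    one_shot_per_cycle: bool = True
    resets_plec_clock: bool = False

    def __post_init__(self):
        if self.trigger_variable not in STATE_INDEX:
            raise KeyError(f"unknown trigger variable: {self.trigger_variable}")
        for k in self.assignments:
            if k not in STATE_INDEX and k not in _MODE_FIELDS:
                raise KeyError(f"assignment targets unknown field: {k}")

    def gap(self, state: CellState) -> float:
        """Signed distance of the trigger variable below its threshold."""
        return state[self.trigger_variable] - self.threshold

    def armed(self, state: CellState, tol: float = 1e-12) -> bool:
        """An event is armed only while its trigger variable sits below the
        threshold; assignments move triggers below their thresholds, which
        naturally enforces once-per-cycle semantics."""
        return self.gap(state) < -tol


def builtin_event_table(params: ParameterSet) -> list[EventRule]:
    """The five built-in event rules, in canonical (tie-break) order."""
    return [
        EventRule(
            id="initiation",
            trigger_variable="Ini",
            threshold=params.Pelong,
            assignments={
                "Ini": 0.0,
                "Elong": params.elong_at_initiation,
                "hCori": 1.0,
                "DNA": 1.05,
                "Count": 2,
                "ks_zring": params.ks_Zring_on,
            },
        ),
        EventRule(
            id="fork_ccrM",
            trigger_variable="Elong",
            threshold=params.elong_ccrM_locus,
            assignments={"hccrM": 1.0},
        ),
        EventRule(
            id="fork_ctrA",
            trigger_variable="Elong",
            threshold=params.elong_ctrA_locus,
            assignments={"hctrA": 1.0},
        ),
        EventRule(
            id="termination",
            trigger_variable="Elong",
            threshold=params.elong_termination,
            assignments={"Elong": 0.0},
        ),
        EventRule(
            id="zring",
            trigger_variable="Zring",
            threshold=params.zring_division,
            assignments={"Zring": 0.0, "ks_zring": 0.0, "DNA": 1.0, "Count": 1},
            resets_plec_clock=True,
        ),
    ]


def apply_rule(rule: EventRule, state: CellState) -> CellState:
    """Apply a rule's assignments atomically; non-assigned fields are untouched."""
    return state.with_values(**dict(rule.assignments))


def locate_and_apply(
    rule: EventRule,
    interpolant: Callable[[float], np.ndarray],
    t1: float,
    t2: float,
    mode: Mapping[str, float] | None = None,
    xtol: float = 1e-10,
) -> tuple[float, CellState]:
    """Locate the upward crossing of ``rule`` in [t1, t2] and apply it.

    ``interpolant(t)`` must return the continuous state vector (for example a
    dense-output solution); ``mode`` carries the discrete fields of the
    pre-event state.  The crossing is located by root-finding to ``xtol``
    minutes.  Raises if the bracket does not actually contain a crossing.
    """
    idx = STATE_INDEX[rule.trigger_variable]

    def g(t: float) -> float:
        return float(interpolant(t)[idx]) - rule.threshold

    g1, g2 = g(t1), g(t2)
    if g1 > 0 or g2 < 0:
        raise RuntimeError(
            f"event {rule.id}: no upward crossing in [{t1}, {t2}] (g: {g1}..{g2})"
        )
    te = t2 if g2 == 0.0 else (t1 if g1 == 0.0 else brentq(g, t1, t2, xtol=xtol))
    mode = dict(mode or {})
    pre = CellState(
        y=np.asarray(interpolant(te), dtype=float).copy(),
        dna=float(mode.get("DNA", 1.0)),
        count=int(mode.get("Count", 1)),
        ks_zring=float(mode.get("ks_zring", 0.0)),
    )
    return float(te), apply_rule(rule, pre)
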