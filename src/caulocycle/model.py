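"""Model/Results facade over the simulator and the fitting machinery.

``CellCycleModel`` bundles a parameter set and an initial state;
``simulate()`` returns a :class:`SimulationResults` wrapping the trajectory
with its cycle metrics, and ``fit()`` returns a :class:`FitResults` carrying
the Pareto archive of the two-objective parameter search.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import CycleObjectives, OptimizeResult, optimize_mop
from .mutants import MutantSpec, apply_mutant
from .observations import ObservationSet
from .parameters import (
    ParameterSet,
    SearchBox,
    default_initial_state,
    default_parameters,
    default_search_box,
)
from .simulate import (
    CycleMetrics,
    Trajectory,
    classify_phenotype,
    simulate,
    simulate_qssa,
)
from .state import CellState

__all__ = ["CellCycleModel", "SimulationResults", "FitResults"]


class CellCycleModel:
    """The hybrid ODE/discrete-event cell-cycle model.

    Parameters
    ----------
    params : ParameterSet, optional
        Kinetic constants; the packaged best-fit set by default.
    init : CellState, optional
        Starting state; the packaged newborn-swarmer state by default.

    Examples
    --------
    >>> model = CellCycleModel()
    >>> res = model.simulate(duration=2000)
    >>> round(res.period, 1)
    150.0
    """

    def __init__(self, params: ParameterSet | None = None, init: CellState | None = None):
        self.params = params or default_parameters()
        self.init = init or default_initial_state()

    @classmethod
    def from_files(cls, params_path: str | Path, init_path: str | Path | None = None):
        init = None
        if init_path is not None:
            from .parameters import _parse_flat_file

            init = CellState.from_mapping(_parse_flat_file(Path(init_path).read_text()))
        return cls(ParameterSet.from_file(params_path), init)

    def mutant(self, spec: MutantSpec) -> "CellCycleModel":
        """A new model with the mutant's parameter overrides applied."""
        return CellCycleModel(apply_mutant(self.params, spec), self.init)

    def simulate(self, duration: float = 600.0, *, qssa: bool = False, **kw) -> "SimulationResults":
        fn = simulate_qssa if qssa else simulate
        traj = fn(self.params, self.init, duration, **kw)
        return SimulationResults(self, traj)

    def fit(
        self,
        obs: ObservationSet,
        box: SearchBox | None = None,
        *,
        population: int = 100,
        generations: int = 100,
        seed: int = 0,
        **kw,
    ) -> "FitResults":
        """Two-objective parameter estimation against an observation set."""
        box = box or default_search_box()
        result = optimize_mop(
            box, obs, self.params,
            population=population, generations=generations, seed=seed, **kw,
        )
        return FitResults(self, box, result)


class SimulationResults:
    """A simulated trajectory with derived cycle metrics."""

    def __init__(self, model: CellCycleModel, trajectory: Trajectory):
        self.model = model
        self.trajectory = trajectory
        self._metrics: CycleMetrics | None = None

    @property
    def metrics(self) -> CycleMetrics:
        if self._metrics is None:
            self._metrics = classify_phenotype(self.trajectory)
        return self._metrics

    @property
    def phenotype(self) -> str:
        return self.metrics.phenotype

    @property
    def period(self) -> float | None:
        return self.metrics.period

    def summary(self) -> str:
        t = self.trajectory
        head = [
            "Caulobacter cell-cycle simulation",
            f"  duration: {t.t[-1]:.0f} min   solver: {t.solver.get('method')}"
            f" (rtol={t.solver.get('rtol')}, atol={t.solver.get('atol')})"
            + ("   [QSSA]" if t.qssa else ""),
            f"  parameters: sha1 {t.params_digest[:12]}",
            f"  events: {len(t.events)} "
            f"({len(t.event_times('initiation'))} replication initiations)",
        ]
        return "\n".join(head) + "\n" + self.metrics.summary()

    def plot(self, species=("CtrA", "DnaA", "GcrA", "CcrM", "SciP"), ax=None):
        """Quick time-course plot of observable totals (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        for sp in species:
            ax.plot(self.trajectory.t, self.trajectory.observable(sp), label=sp)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("concentration (a.u.)")
        ax.legend(frameon=False)
        return ax


class FitResults:
    """Pareto archive of a two-objective parameter search."""

    def __init__(self, model: CellCycleModel, box: SearchBox, result: OptimizeResult):
        self.model = model
        self.box = box
        self.result = result

    @property
    def pareto(self):
        return self.result.archive

    def params_at(self, i: int) -> ParameterSet:
        return self.box.apply(self.model.params, self.pareto.X[i])

    def best_params(self, objective: int = 0) -> ParameterSet:
        x, _ = self.pareto.best(objective)
        return self.box.apply(self.model.params, x)

    def to_frame(self) -> pd.DataFrame:
        return self.pareto.to_frame()

    def summary(self) -> str:
        F = self.pareto.F
        lines = [
            "Two-objective parameter fit (NSGA-II)",
            f"  searched parameters: {len(self.box)}",
            f"  objective evaluations: {self.result.n_evaluations}",
            f"  archive size: {len(self.pareto)} (nondominated: "
            f"{self.pareto.is_nondominated()})",
            f"  f1 range: [{F[:, 0].min():.4g}, {F[:, 0].max():.4g}]",
            f"  f2 range: [{F[:, 1].min():.4g}, {F[:, 1].max():.4g}] min",
        ]
        return "\n".join(lines)
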