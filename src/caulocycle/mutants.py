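"""Mutant strain definitions and phenotype classification.

Knockouts are modelled by zeroing the corresponding synthesis rate constant
(k_s,i = 0); the non-proteolysable ctrA allele by reducing the cyclic CtrA
proteolysis rate to 10 %; and the "constant proteolysis" variants by setting
the corresponding Michaelis constant J_d,* to 0, which turns the
Complex1/Complex3-dependent degradation term into a constant-rate term.
All mutants reuse the wild-type equations and initial values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .parameters import ParameterSet, default_parameters
from .simulate import classify_phenotype, simulate

__all__ = ["MutantSpec", "apply_mutant", "builtin_panel", "run_panel"]


@dataclass(frozen=True)
class MutantSpec:
    """Named parameter overrides with the experimentally expected phenotype."""

    name: str
    overrides: Mapping[str, float] = field(default_factory=dict)
    multipliers: Mapping[str, float] = field(default_factory=dict)
    expected_phenotype: str = "oscillatory"
    note: str = ""

    def __post_init__(self):
        for v in self.multipliers.values():
            if v < 0:
                raise ValueError("multipliers must be >= 0")


def apply_mutant(params: ParameterSet, spec: MutantSpec) -> ParameterSet:
    """Return a new parameter set with only the given overrides changed."""
    updates = {k: float(v) for k, v in spec.overrides.items()}
    for k, m in spec.multipliers.items():
        updates[k] = params[k] * m
    return params.with_updates(updates)


def builtin_panel() -> list[MutantSpec]:
    """The eleven built-in mutant scenarios.

    Seven strains (one arrested, six viable) plus the four constant-proteolysis
    variants that probe the hierarchical ClpXP module.
    """
    return [
        MutantSpec("ccrM_del", {"ks_ccrM": 0.0}, expected_phenotype="oscillatory",
                   note="viable; ~164 min cycle; hemimethylation never returns to 0"),
        MutantSpec("gcrA_del", {"ks_gcrA": 0.0}, expected_phenotype="oscillatory",
                   note="viable; cycle ~10 min longer than wild type"),
        MutantSpec("dnaA_del", {"ks_dnaA": 0.0}, expected_phenotype="arrested",
                   note="replication initiation requires DnaA; cycle arrests"),
        MutantSpec("ctrA_D3Omega", multipliers={"kd_CtrA_ClpXP": 0.1},
                   expected_phenotype="oscillatory",
                   note="non-proteolysable CtrA allele: cyclic proteolysis at 10 %; "
                        "higher, flatter CtrA"),
        MutantSpec("cdG0", {"ks_cdG": 0.0}, expected_phenotype="oscillatory",
                   note="viable; CtrA raised with less fluctuation"),
        MutantSpec("pdeA_del", {"ks_PdeA": 0.0}, expected_phenotype="oscillatory",
                   note="viable; raised cdG levels"),
        MutantSpec("pleD_del", {"ks_PleD": 0.0}, expected_phenotype="oscillatory",
                   note="viable; lower cdG levels"),
        MutantSpec("ctrA_proteolysis_const", {"Jd_CtrA_ClpXP": 0.0},
                   expected_phenotype="defective",
                   note="CtrA cyclic proteolysis replaced by a constant rate: "
                        "longer cycle, reduced CtrA/SciP amplitude"),
        MutantSpec("cpdR_proteolysis_const", {"Jd_CpdR": 0.0},
                   expected_phenotype="defective",
                   note="CpdR cyclic proteolysis replaced by a constant rate: "
                        "CtrA oscillation nearly disappears"),
        MutantSpec("rcdA_proteolysis_const", {"Jd_RcdA": 0.0},
                   expected_phenotype="defective",
                   note="RcdA cyclic proteolysis replaced by a constant rate: "
                        "CtrA oscillation nearly disappears"),
        MutantSpec("proteolysis_const_all",
                   {"Jd_CtrA_ClpXP": 0.0, "Jd_CpdR": 0.0, "Jd_RcdA": 0.0},
                   expected_phenotype="defective",
                   note="all three cyclic proteolysis terms constant; similar to "
                        "the CtrA-only variant"),
    ]


def get_mutant(name: str) -> MutantSpec:
    panel = {m.name: m for m in builtin_panel()}
    if name not in panel:
        raise KeyError(
            f"unknown mutant {name!r}; builtin panel: {sorted(panel)}"
        )
    return panel[name]


def run_panel(
    params: ParameterSet | None = None,
    specs: list[MutantSpec] | None = None,
    duration: float = 2500.0,
    include_wildtype: bool = True,
    **simulate_kw,
) -> pd.DataFrame:
    """Simulate every panel mutant and summarize phenotype and metrics.

    Returns one row per strain: phenotype class, period, total-CtrA
    amplitude over the last cycle, and mean cdG over the settled half of the
    run.  Wild type is included for comparison by default.
    """
    params = params or default_parameters()
    specs = builtin_panel() if specs is None else specs
    rows = []
    runs = [("wildtype", params, "oscillatory")] if include_wildtype else []
    runs += [(s.name, apply_mutant(params, s), s.expected_phenotype) for s in specs]
    for name, p, expected in runs:
        traj = simulate(p, duration=duration, **simulate_kw)
        m = classify_phenotype(traj)
        sel = traj.t >= duration / 2
        cdg = float(traj.species("cdG")[sel].mean())
        ctra = traj.observable("CtrA")[sel]
        rows.append({
            "strain": name,
            "phenotype": m.phenotype,
            "expected": expected,
            "period_min": m.period,
            "ctra_amplitude": float(ctra.max() - ctra.min()),
            "cdg_mean": cdg,
        })
    return pd.DataFrame(rows)
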