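"""The cell state: 29 continuous variables plus discrete mode flags.

Continuous variables follow the model's grouping: DNA-cycle progress variables
(``Ini``, ``Elong``, ``Zring``), per-locus hemimethylation probabilities
(``hCori``, ``hccrM``, ``hctrA``), six mRNAs, six regulator protein forms and
eleven protease-pathway species.  ``DNA`` (1 or 1.05) and ``Count`` (chromosome
count, 1 or 2) are event-driven bookkeeping; ``ks_zring`` is the current
Z-ring clock rate (0 before replication initiation, 0.011 min^-1 during
S phase/constriction).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

__all__ = ["CellState", "STATE_NAMES", "STATE_INDEX"]

#: Canonical ordering of the continuous state vector.
STATE_NAMES: tuple[str, ...] = (
    "Ini", "Elong", "Zring", "hCori", "hccrM", "hctrA",
    "IccrM", "ccrM", "dnaA", "gcrA", "sciP", "ctrA",
    "CcrM", "DnaA", "GcrA", "SciP", "CtrA", "CtrAP",
    "CckAP", "Complex1", "CpdR", "CpdRP", "Complex2", "RcdA", "Complex3",
    "PleD", "PleDP", "PdeA", "cdG",
)
STATE_INDEX: dict[str, int] = {n: i for i, n in enumerate(STATE_NAMES)}

_UNIT_INTERVAL = {"hCori", "hccrM", "hctrA"}


@dataclass(frozen=True)
class CellState:
    """A full model state: continuous concentrations plus discrete mode."""

    y: np.ndarray
    dna: float = 1.0
    count: int = 1
    ks_zring: float = 0.0

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        if y.shape != (len(STATE_NAMES),):
            raise ValueError(f"state vector must have {len(STATE_NAMES)} entries")
        object.__setattr__(self, "y", y)

    @classmethod
    def from_mapping(cls, values: Mapping[str, float]) -> "CellState":
        vals = dict(values)
        dna = float(vals.pop("DNA", 1.0))
        count = int(vals.pop("Count", 1))
        ksz = float(vals.pop("ks_zring", 0.0))
        unknown = set(vals) - set(STATE_NAMES)
        if unknown:
            raise KeyError(f"unknown state variable(s): {sorted(unknown)}")
        missing = set(STATE_NAMES) - set(vals)
        if missing:
            raise KeyError(f"missing state variable(s): {sorted(missing)}")
        y = np.array([float(vals[n]) for n in STATE_NAMES])
        return cls(y=y, dna=dna, count=count, ks_zring=ksz)

    def __getitem__(self, name: str) -> float:
        return float(self.y[STATE_INDEX[name]])

    def asdict(self) -> dict[str, float]:
        d = {n: float(v) for n, v in zip(STATE_NAMES, self.y)}
        d["DNA"] = self.dna
        d["Count"] = self.count
        d["ks_zring"] = self.ks_zring
        return d

    def with_values(self, **kw: float) -> "CellState":
        """Return a copy with the named continuous/discrete fields replaced."""
        y = self.y.copy()
        mode = {}
        for k, v in kw.items():
            if k in STATE_INDEX:
                y[STATE_INDEX[k]] = float(v)
            elif k == "DNA":
                mode["dna"] = float(v)
            elif k == "Count":
                mode["count"] = int(v)
            elif k == "ks_zring":
                mode["ks_zring"] = float(v)
            else:
                raise KeyError(f"unknown state field: {k}")
        return replace(self, y=y, **mode)

    def validate(self, ccka_total: float | None = None) -> None:
        """Raise ValueError if the state violates its physical invariants."""
        if not np.all(np.isfinite(self.y)):
            raise ValueError("state contains non-finite values")
        if np.any(self.y < 0):
            bad = [STATE_NAMES[i] for i in np.flatnonzero(self.y < 0)]
            raise ValueError(f"negative concentration(s): {bad}")
        for n in _UNIT_INTERVAL:
            v = self[n]
            if v > 1.0 + 1e-9:
                raise ValueError(f"hemimethylation probability {n} > 1: {v}")
        if ccka_total is not None and self["CckAP"] > ccka_total + 1e-9:
            raise ValueError("CckAP exceeds the total CckA pool")
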