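"""Kinetic parameters, initial state and optimization search box.

The :class:`ParameterSet` is the single source of kinetic truth for the model:
all 86 rate/binding/scaling constants, the coefficients of the PleC forcing
function, and the constants of the discrete-event machinery (the Z-ring clock
rate, the replication-fork locus positions and the division threshold).
The packaged defaults are the published best-fit values; load them with
:func:`default_parameters`.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "ParameterSet",
    "SearchBox",
    "default_parameters",
    "default_initial_state",
    "default_search_box",
    "PARAM_NAMES",
]

# J_*, Theta_* and Ji/Ja/Jd/Jm constants must stay strictly positive (they sit in
# denominators of Hill and Michaelis terms); every other constant only needs to be
# non-negative so that knockout overrides (k = 0) remain valid parameter sets.
_STRICTLY_POSITIVE_PREFIXES = ("Ja_", "Ji_", "Jm_", "Theta_")

_INT_FIELDS = {"Count"}


def _parse_flat_file(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed line in flat parameter file: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = float(val)
    return out


def _data_text(name: str) -> str:
    return resources.files("caulocycle.data").joinpath(name).read_text()


def _load_names() -> tuple[str, ...]:
    return tuple(_parse_flat_file(_data_text("parameters.txt")))


#: Canonical parameter order; defines the layout of the packed vector handed to
#: the compiled right-hand side.
PARAM_NAMES: tuple[str, ...] = _load_names()
_PARAM_INDEX: dict[str, int] = {n: i for i, n in enumerate(PARAM_NAMES)}


class ParameterSet(Mapping[str, float]):
    """Immutable named collection of the model's kinetic constants.

    Behaves as a read-only mapping with attribute access
    (``p.ks_ccrM`` == ``p["ks_ccrM"]``).  Use :meth:`with_updates` to derive
    mutants or trial parameter vectors without touching the original.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        unknown = set(values) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(values)
        if missing:
            raise KeyError(f"missing parameter name(s): {sorted(missing)}")
        vals = {k: float(values[k]) for k in PARAM_NAMES}
        for k, v in vals.items():
            if not np.isfinite(v):
                raise ValueError(f"parameter {k} is not finite: {v}")
            if k.startswith(_STRICTLY_POSITIVE_PREFIXES):
                if v <= 0:
                    raise ValueError(f"binding/scaling constant {k} must be > 0, got {v}")
            elif not k.startswith("plec_") and v < 0:
                raise ValueError(f"rate constant {k} must be >= 0, got {v}")
        object.__setattr__(self, "_values", vals)

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(PARAM_NAMES)

    def __len__(self) -> int:
        return len(PARAM_NAMES)

    def __getattr__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise AttributeError(name) from None

    def __repr__(self) -> str:
        return f"ParameterSet({len(self)} constants, sha1={self.digest()[:10]})"

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    def __hash__(self) -> int:
        return hash(tuple(self._values.values()))

    # Construction helpers -------------------------------------------------
    def with_updates(self, updates: Mapping[str, float] | None = None, **kw: float) -> "ParameterSet":
        """Return a new set with the given entries replaced."""
        merged = dict(self._values)
        for src in (updates or {}), kw:
            for k, v in src.items():
                if k not in merged:
                    raise KeyError(f"unknown parameter name: {k}")
                merged[k] = float(v)
        return ParameterSet(merged)

    def to_vector(self) -> np.ndarray:
        """Pack into the canonical PARAM_NAMES order (used by the ODE kernel)."""
        return np.array([self._values[k] for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ParameterSet":
        if len(vec) != len(PARAM_NAMES):
            raise ValueError(f"expected {len(PARAM_NAMES)} entries, got {len(vec)}")
        return cls(dict(zip(PARAM_NAMES, map(float, vec))))

    # Serialization --------------------------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "ParameterSet":
        return cls(_parse_flat_file(Path(path).read_text()))

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k} = {self._values[k]!r}" for k in PARAM_NAMES]
        Path(path).write_text("\n".join(lines) + "\n")

    def digest(self) -> str:
        """SHA-1 of the parameter values; recorded as trajectory provenance."""
        payload = ",".join(f"{k}={self._values[k]!r}" for k in PARAM_NAMES)
        return hashlib.sha1(payload.encode()).hexdigest()


class SearchBox:
    """Box constraints and starting point for the 47 free parameters."""

    def __init__(self, names, lower, upper, start):
        self.names = tuple(names)
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        self.start = np.asarray(start, dtype=float)
        if not (len(self.names) == len(self.lower) == len(self.upper) == len(self.start)):
            raise ValueError("names, lower, upper and start must have equal length")
        unknown = set(self.names) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"search box references unknown parameters: {sorted(unknown)}")
        if not np.all(self.lower < self.upper):
            raise ValueError("search box requires lower < upper componentwise")
        if not (np.all(self.start >= self.lower) and np.all(self.start <= self.upper)):
            raise ValueError("starting point must lie inside the box")

    def __len__(self) -> int:
        return len(self.names)

    def subset(self, names) -> "SearchBox":
        """Restrict the box to a subset of parameters (order preserved)."""
        idx = [self.names.index(n) for n in names]
        return SearchBox([self.names[i] for i in idx], self.lower[idx],
                         self.upper[idx], self.start[idx])

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def apply(self, base: ParameterSet, x: np.ndarray) -> ParameterSet:
        """Overlay a candidate vector onto a full parameter set."""
        return base.with_updates(dict(zip(self.names, x)))

    @classmethod
    def from_file(cls, path: str | Path) -> "SearchBox":
        return cls._parse(Path(path).read_text())

    @classmethod
    def _parse(cls, text: str) -> "SearchBox":
        names, lo, hi, st = [], [], [], []
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            name, l, u, s = line.split()
            names.append(name)
            lo.append(float(l))
            hi.append(float(u))
            st.append(float(s))
        return cls(names, lo, hi, st)


def default_parameters() -> ParameterSet:
    """The packaged best-fit parameter set."""
    return ParameterSet(_parse_flat_file(_data_text("parameters.txt")))


def default_initial_state():
    """The packaged newborn-swarmer initial state (a :class:`~caulocycle.state.CellState`)."""
    from .state import CellState

    raw = _parse_flat_file(_data_text("initial_state.txt"))
    return CellState.from_mapping(raw)


def default_search_box() -> SearchBox:
    """The packaged 47-parameter optimization box."""
    return SearchBox._parse(_data_text("search_box.txt"))
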