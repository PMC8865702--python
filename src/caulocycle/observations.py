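"""Observation time courses: normalization, rescaling and synthetic fixtures.

Experimental cell-cycle data (western blots, mRNA measurements from
synchronized populations) come from heterogeneous sources with arbitrary
units.  The fitting pipeline therefore min-max normalizes each species to
[0, 1] and then rescales it to a per-species target range on the simulation's
concentration scale.

Because the original digitized blot values are not published, this module also
generates "experiment-like" synthetic observation sets by sampling the
simulator's own trajectories at sparse time points and adding truncated
Gaussian noise — the standard substitute that keeps the fitting machinery
fully testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Trajectory

__all__ = [
    "FIT_SPECIES",
    "ObservationSet",
    "normalize_unit_interval",
    "rescale_to_simulation",
    "generate_fixture",
]

#: The 15 observable species used for parameter fitting: five mRNAs
#: (lower-case, italicised gene names) and ten proteins.  Protein "CtrA",
#: "CpdR" and "PleD" are blot totals over phospho-forms.
FIT_SPECIES: tuple[str, ...] = (
    "ccrM", "dnaA", "gcrA", "sciP", "ctrA",
    "CcrM", "DnaA", "GcrA", "SciP", "CtrA",
    "CpdR", "RcdA", "PleD", "PdeA", "cdG",
)


def normalize_unit_interval(values) -> np.ndarray:
    """Affine map of a series onto [0, 1]: z = (x - min x) / (max x - min x)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to normalize")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant series cannot be min-max normalized")
    return (x - lo) / (hi - lo)


def rescale_to_simulation(z, target_range) -> np.ndarray:
    """Map normalized values onto a simulation-scale range [lo, hi]."""
    lo, hi = float(target_range[0]), float(target_range[1])
    if not (hi > lo >= 0):
        raise ValueError(f"target range must satisfy hi > lo >= 0, got [{lo}, {hi}]")
    return lo + np.asarray(z, dtype=float) * (hi - lo)


@dataclass
class ObservationSet:
    """Per-species (time, value) records with normalization metadata.

    ``data`` has columns (species, time_min, value, z); ``ranges`` maps each
    species to its target simulation range [lo, hi].
    """

    data: pd.DataFrame
    ranges: dict[str, tuple[float, float]]
    source: str = "synthetic"

    def __post_init__(self):
        required = {"species", "time_min", "value", "z"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"observation table must have columns {sorted(required)}")
        unknown = set(self.data["species"]) - set(FIT_SPECIES)
        if unknown:
            raise ValueError(f"species outside the observable set: {sorted(unknown)}")
        for sp, grp in self.data.groupby("species"):
            z = grp["z"].to_numpy()
            if not (np.isclose(z.min(), 0.0) and np.isclose(z.max(), 1.0)):
                raise ValueError(f"normalized values of {sp} must span [0, 1]")
            if sp not in self.ranges:
                raise ValueError(f"no target range for species {sp}")

    @classmethod
    def from_raw(cls, records: dict[str, tuple[np.ndarray, np.ndarray]],
                 ranges: dict[str, tuple[float, float]],
                 source: str = "user") -> "ObservationSet":
        """Build from per-species (times, raw values), normalizing on the way in."""
        rows = []
        for sp, (t, v) in records.items():
            t = np.asarray(t, dtype=float)
            v = np.asarray(v, dtype=float)
            z = normalize_unit_interval(v)
            for ti, vi, zi in zip(t, v, z):
                rows.append((sp, ti, vi, zi))
        df = pd.DataFrame(rows, columns=["species", "time_min", "value", "z"])
        return cls(df, dict(ranges), source)

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    def times(self, sp: str) -> np.ndarray:
        return self.data.loc[self.data["species"] == sp, "time_min"].to_numpy()

    def z(self, sp: str) -> np.ndarray:
        return self.data.loc[self.data["species"] == sp, "z"].to_numpy()

    def rescaled(self, sp: str) -> np.ndarray:
        """Observations on the simulation scale (z mapped to the target range)."""
        return rescale_to_simulation(self.z(sp), self.ranges[sp])

    def n_points(self, sp: str) -> int:
        return int((self.data["species"] == sp).sum())

    # --- round-trip through a tidy table file ---
    def to_frame(self) -> pd.DataFrame:
        df = self.data.copy()
        df["range_lo"] = df["species"].map(lambda s: self.ranges[s][0])
        df["range_hi"] = df["species"].map(lambda s: self.ranges[s][1])
        df["source"] = self.source
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservationSet":
        df = pd.read_csv(path)
        ranges = {
            sp: (float(g["range_lo"].iloc[0]), float(g["range_hi"].iloc[0]))
            for sp, g in df.groupby("species")
        }
        source = str(df["source"].iloc[0]) if "source" in df else "file"
        return cls(df[["species", "time_min", "value", "z"]].copy(), ranges, source)


def generate_fixture(
    traj: Trajectory,
    species=FIT_SPECIES,
    n_points: int = 10,
    noise_sd: float = 0.05,
    seed: int | None = 0,
    window: tuple[float, float] = (0.0, 150.0),
) -> ObservationSet:
    """Sample a trajectory into an experiment-like observation set.

    For each species, ``n_points`` sampling times are drawn uniformly on
    ``window``, the observable (phospho-totals summed) is interpolated there,
    and zero-mean Gaussian noise with standard deviation
    ``noise_sd * amplitude`` is added and truncated at 0.  The per-species
    target range is the sampled min/max, so a noiseless fixture rescales back
    to the generating trajectory exactly.  Fully reproducible from ``seed``.
    """
    if traj.t[-1] < window[1]:
        raise ValueError("trajectory does not cover the observation window")
    unknown = set(species) - set(FIT_SPECIES)
    if unknown:
        raise ValueError(f"species outside the observable set: {sorted(unknown)}")
    # one independent stream per species, so a species' sampling times depend
    # only on (seed, species position), not on other species' noise draws
    streams = np.random.SeedSequence(seed).spawn(len(species))
    records, ranges = {}, {}
    for sp, stream in zip(species, streams):
        rng = np.random.default_rng(stream)
        t = np.sort(rng.uniform(window[0], window[1], size=n_points))
        v = traj.at(sp, t)
        amp = float(v.max() - v.min())
        if amp == 0:
            raise ValueError(f"species {sp} is constant over the window")
        if noise_sd > 0:
            v = np.clip(v + rng.normal(0.0, noise_sd * amp, size=v.shape), 0.0, None)
        records[sp] = (t, v)
        ranges[sp] = (float(v.min()), float(v.max()))
    return ObservationSet.from_raw(records, ranges, source=f"fixture(seed={seed})")
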