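"""Gate-distance time series and summary statistics.

The opening of a conformational gate is monitored as the per-frame
Euclidean separation between two marker atoms (canonically the
alpha-carbons of the loop residue and its partner on the facing domain,
Q80 and Y261 in NQO).  Distances are invariant under rigid-body
superposition, so the optional pre-alignment only matters for workflow
parity with pipelines that superpose everything first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import AtomSelection, Trajectory, select_atoms, superpose

__all__ = ["DistanceSeries", "GateStats", "distance_series", "gate_stats",
           "write_series_csv", "write_stats_json"]


@dataclass(frozen=True)
class DistanceSeries:
    values: np.ndarray              # per-frame distances, A
    atom_pair: tuple[str, str]      # the two selection descriptors
    system_label: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 1 or len(v) == 0:
            raise ValueError("distance series must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("distances must be finite and non-negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class GateStats:
    mean: float                     # A
    sd: float                       # A, population SD
    n_frames: int


def _resolve_single(trajectory: Trajectory, expression: str) -> int:
    sel = select_atoms(trajectory.topology, expression)
    if len(sel) != 1:
        raise ValueError(
            f"selection {expression!r} resolves to {len(sel)} atoms, need "
            f"exactly 1")
    return int(sel.indices[0])


def distance_series(trajectory: Trajectory, atom_a: str, atom_b: str,
                    superpose_first: bool = False,
                    fit_selection: AtomSelection | None = None,
                    system_label: str = "") -> DistanceSeries:
    """Per-frame distance between two single-atom selections.

    ``superpose_first`` aligns each frame to frame 0 before measuring;
    since pair distances are isometry-invariant this does not change the
    result, and the flag exists only to mirror pipelines that align first.
    """
    ia = _resolve_single(trajectory, atom_a)
    ib = _resolve_single(trajectory, atom_b)
    xyz = trajectory.xyz
    if superpose_first:
        ref = xyz[0]
        moved = np.empty_like(xyz)
        for f in range(trajectory.n_frames):
            _, moved[f] = superpose(xyz[f], ref, fit_selection)
        xyz = moved
    values = np.linalg.norm(xyz[:, ia, :] - xyz[:, ib, :], axis=1)
    return DistanceSeries(values=values, atom_pair=(atom_a, atom_b),
                          system_label=system_label)


def gate_stats(series: DistanceSeries) -> GateStats:
    """Arithmetic mean and population SD of an (equilibrated) series.

    Equilibration trimming is deliberately the caller's job
    (``trajectory.trim_equilibration``) so the statistics are transparent
    about which frames they describe.
    """
    v = series.values
    return GateStats(mean=float(np.mean(v)), sd=float(np.std(v)),
                     n_frames=len(v))


def write_series_csv(series: DistanceSeries, path: str | Path) -> None:
    pd.DataFrame({"frame": np.arange(len(series.values)),
                  "distance_A": series.values}).to_csv(path, index=False)


def write_stats_json(stats: GateStats, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(stats), indent=2) + "\n")
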