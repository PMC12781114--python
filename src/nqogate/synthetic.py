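"""Synthetic gate ensembles and kinetic datasets.

The structural generator emulates a two-state (open/closed) conformational
gate: the distance between a designated residue pair follows a two-state
Markov chain with state-dependent Gaussian means and a shared fluctuation
width, while all other residues jitter independently about a fixed
reference chain.  The kinetics generators forward-evaluate the ping-pong
bi-bi rate law (with optional NADH substrate inhibition) and the
double-exponential stopped-flow transient with hyperbolically saturating
fast-phase rate.

Defaults encode the study conditions of the NQO loop-3 gating system:
closed and open gate separations of 11.6 and 21.0 Angstrom, steady-state
grids of tens-of-micromolar NADH/CoQ0, and stopped-flow NADH from 90 to
500 uM.  Noise magnitudes are assumptions (no instrument noise figures are
available) and are documented in docs/methods.md.

Randomness: each generator derives independent child streams from the spec
seed via ``numpy``'s spawning mechanism, in a fixed documented order
(states, distances, jitter for ensembles; one stream per replicate for
rates; one stream per concentration for traces), so increasing the number
of replicates or concentrations never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectory import Structure, Trajectory

__all__ = [
    "EnsembleSpec",
    "KineticsSimSpec",
    "RateDataset",
    "StoppedFlowTrace",
    "SpecError",
    "simulate_gate_ensemble",
    "simulate_rates",
    "simulate_traces",
    "pingpong_rate",
    "biexponential",
    "saturation_kobs",
    "write_rates_csv",
    "read_rates_csv",
    "write_trace_csv",
    "read_trace_csv",
]


class SpecError(ValueError):
    """Raised when a simulation spec violates its invariants."""


def _require(cond: bool, fieldname: str, msg: str):
    if not cond:
        raise SpecError(f"{fieldname}: {msg}")


# ---------------------------------------------------------------------------
# Structural ensemble generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of a two-state gate ensemble.

    Distances in Angstrom; transition probabilities are per-frame.  The
    default closed/open separations (11.6 / 21.0 A) and fluctuation widths
    follow the wild-type and mutant gate statistics of the NQO system.
    """

    n_residues: int = 40
    atoms_per_residue: int = 3           # 1 CA + up to 3 pseudo-heavy side atoms
    closed_mean_distance: float = 11.6   # A
    open_mean_distance: float = 21.0     # A
    fluctuation_sd: float = 1.4          # A, shared by both states
    p_open_to_closed: float = 0.02
    p_closed_to_open: float = 0.02
    n_frames: int = 2000
    gate_pair: tuple[int, int] = (10, 30)   # 1-based residue indices
    start_state: str = "closed"             # "closed" | "open"
    rng_seed: int = 0

    def validate(self) -> None:
        _require(self.n_residues >= 2, "n_residues", "must be >= 2")
        _require(1 <= self.atoms_per_residue <= 4, "atoms_per_residue",
                 "must be in 1..4")
        _require(self.open_mean_distance > self.closed_mean_distance,
                 "open_mean_distance", "must exceed closed_mean_distance")
        _require(self.fluctuation_sd >= 0, "fluctuation_sd", "must be >= 0")
        for name in ("p_open_to_closed", "p_closed_to_open"):
            p = getattr(self, name)
            _require(0.0 <= p <= 1.0, name, "must be in [0, 1]")
        _require(self.n_frames >= 1, "n_frames", "must be >= 1")
        a, b = self.gate_pair
        _require(1 <= a <= self.n_residues and 1 <= b <= self.n_residues
                 and a != b, "gate_pair", "indices must be distinct residues")
        _require(self.start_state in ("closed", "open"), "start_state",
                 "must be 'closed' or 'open'")


_SIDE_OFFSETS = np.array([[0.0, 1.5, 0.0], [0.0, 0.0, 1.5], [0.0, 1.5, 1.5]])
_SIDE_NAMES = ["CB", "CG", "OD1"]
_SIDE_ELEMENTS = ["C", "C", "O"]


def _reference_topology(spec: EnsembleSpec) -> Structure:
    """A linear pseudo-peptide chain: CA every 3.8 A plus side pseudo-atoms."""
    names, elements, resids, resnames, chains, coords = [], [], [], [], [], []
    for r in range(spec.n_residues):
        ca = np.array([3.8 * r, 0.0, 0.0])
        names.append("CA"); elements.append("C")
        resids.append(r + 1); resnames.append("GLY"); chains.append("A")
        coords.append(ca)
        for k in range(spec.atoms_per_residue - 1):
            names.append(_SIDE_NAMES[k]); elements.append(_SIDE_ELEMENTS[k])
            resids.append(r + 1); resnames.append("GLY"); chains.append("A")
            coords.append(ca + _SIDE_OFFSETS[k])
    return Structure(names=np.array(names), elements=np.array(elements),
                     resids=np.array(resids, dtype=int),
                     resnames=np.array(resnames), chains=np.array(chains),
                     xyz=np.array(coords, dtype=float))


def simulate_gate_ensemble(spec: EnsembleSpec, return_states: bool = False):
    """Generate a toy ensemble whose gate distance follows a 2-state chain.

    Per frame the hidden gate state evolves by the Markov transition
    probabilities; the gate CA-CA distance is drawn from a Gaussian with the
    state's mean and the shared ``fluctuation_sd``; the second gate residue
    is placed rigidly along the gate axis so that the CA-CA separation
    equals the drawn distance exactly; all non-gate residues receive
    independent isotropic Gaussian jitter (sd = ``fluctuation_sd``) about
    the reference chain.

    Returns ``(Structure, Trajectory)`` (plus the hidden 0/1 open-state
    array when ``return_states`` is set).  Deterministic given ``rng_seed``.
    """
    spec.validate()
    top = _reference_topology(spec)
    rng_states, rng_dist, rng_jitter = np.random.default_rng(
        spec.rng_seed).spawn(3)

    n = spec.n_frames
    open_state = np.empty(n, dtype=bool)
    state = spec.start_state == "open"
    u = rng_states.random(n)
    for f in range(n):
        open_state[f] = state
        if state:
            state = not (u[f] < spec.p_open_to_closed)
        else:
            state = u[f] < spec.p_closed_to_open
    means = np.where(open_state, spec.open_mean_distance,
                     spec.closed_mean_distance)
    distances = np.maximum(means + spec.fluctuation_sd * rng_dist.standard_normal(n),
                           0.1)

    res_of_atom = top.residue_index_per_atom()
    ia, ib = spec.gate_pair[0] - 1, spec.gate_pair[1] - 1
    atoms_a = np.nonzero(res_of_atom == ia)[0]
    atoms_b = np.nonzero(res_of_atom == ib)[0]
    ca_a = atoms_a[top.names[atoms_a] == "CA"][0]
    ca_b = atoms_b[top.names[atoms_b] == "CA"][0]
    axis = top.xyz[ca_b] - top.xyz[ca_a]
    axis = axis / np.linalg.norm(axis)
    nongate = np.nonzero((res_of_atom != ia) & (res_of_atom != ib))[0]

    xyz = np.broadcast_to(top.xyz, (n,) + top.xyz.shape).copy()
    jitter = rng_jitter.standard_normal((n, len(nongate), 3))
    xyz[:, nongate, :] += spec.fluctuation_sd * jitter
    # rigid placement of gate residue B at the drawn separation from A's CA
    target = top.xyz[ca_a] + distances[:, None] * axis      # (n, 3)
    shift = target - top.xyz[ca_b]                          # (n, 3)
    xyz[:, atoms_b, :] = top.xyz[atoms_b] + shift[:, None, :]

    traj = Trajectory(topology=top, xyz=xyz)
    if return_states:
        return top, traj, open_state
    return top, traj


# ---------------------------------------------------------------------------
# Kinetics generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticsSimSpec:
    """Ground-truth parameters and sampling design for simulated kinetics.

    Rate constants in s^-1, affinities in uM.  ``true_Kis=None`` selects the
    plain ping-pong law (no NADH substrate inhibition).  ``noise_cv`` is the
    relative SD of the multiplicative Gaussian noise on initial rates; the
    default 1% CV is anchored to the precision of published steady-state
    parameter tables for this system (a Fisher-information analysis shows
    standard errors of that size are only achievable at ~1% rate noise on
    these concentration grids).  ``trace_noise_sd`` is the additive
    absorbance noise (AU) on stopped-flow traces, an assumption at a
    typical instrument scale.
    """

    true_kcat: float = 11.0
    true_Ka: float = 130.0          # K_NADH, uM
    true_Kb: float = 10.0           # K_CoQ0, uM
    true_Kis: float | None = None   # uM; None -> no substrate inhibition
    true_kred: float = 4.8
    true_Kd: float = 450.0          # uM
    slow_phase_rate: float = 0.1    # s^-1, substrate independent
    slow_phase_fraction: float = 0.08
    nadh_grid: tuple[float, ...] = (10., 20., 40., 60., 80., 100.)
    coq0_grid: tuple[float, ...] = (2., 4., 6., 8., 10.)
    noise_cv: float = 0.01
    replicates: int = 3
    total_amplitude: float = 0.10   # AU, B1 + B2
    offset: float = 0.02            # AU, absorbance at infinite time
    trace_noise_sd: float = 0.002   # AU
    points_per_trace: int = 400
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("true_kcat", "true_Ka", "true_Kb", "true_kred",
                     "true_Kd", "slow_phase_rate"):
            _require(getattr(self, name) > 0, name, "must be > 0")
        if self.true_Kis is not None:
            _require(self.true_Kis > 0, "true_Kis", "must be > 0 or None")
        _require(0.0 <= self.slow_phase_fraction < 0.1, "slow_phase_fraction",
                 "must be in [0, 0.1): the slow phase is a minor component")
        _require(self.noise_cv >= 0, "noise_cv", "must be >= 0")
        _require(self.replicates >= 1, "replicates", "must be >= 1")
        _require(len(self.nadh_grid) > 0 and len(self.coq0_grid) > 0,
                 "concentration_grid", "grids must be non-empty")
        for grid, name in ((self.nadh_grid, "nadh_grid"),
                           (self.coq0_grid, "coq0_grid")):
            _require(all(c > 0 for c in grid), name,
                     "concentrations must be > 0")
        _require(self.trace_noise_sd >= 0, "trace_noise_sd", "must be >= 0")


def pingpong_rate(A, B, kcat: float, Ka: float, Kb: float,
                  Kis: float | None = None):
    """Ping-pong bi-bi turnover v0/e at NADH concentration A and CoQ0 B.

    Without inhibition:  v0/e = A*B*kcat / (A*Kb + B*Ka + A*B).
    With a finite NADH inhibition constant Kis, the Kb*A term is scaled by
    (1 + A/Kis), describing a dead-end NADH complex of the reduced enzyme.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if np.any(A <= 0) or np.any(B <= 0):
        raise ValueError("concentrations must be > 0")
    if Kis is None:
        denom = A * Kb + B * Ka + A * B
    else:
        denom = Ka * B + Kb * A * (1.0 + A / Kis) + A * B
    return A * B * kcat / denom


def biexponential(t, B1: float, B2: float, k1: float, k2: float, C: float):
    """A(t) = B1 exp(-k1 t) + B2 exp(-k2 t) + C."""
    t = np.asarray(t, float)
    return B1 * np.exp(-k1 * t) + B2 * np.exp(-k2 * t) + C


def saturation_kobs(S, kred: float, Kd: float):
    """Hyperbolic saturation with zero intercept: kobs = kred*S/(Kd+S)."""
    S = np.asarray(S, float)
    return kred * S / (Kd + S)


@dataclass(frozen=True)
class RateDataset:
    """Steady-state initial-rate table: v0/e at each (NADH, CoQ0) point."""

    table: pd.DataFrame    # columns NADH_uM, CoQ0_uM, replicate, v0_over_e_per_s
    provenance: str = ""

    def __post_init__(self):
        required = {"NADH_uM", "CoQ0_uM", "replicate", "v0_over_e_per_s"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"rate table missing columns: {sorted(missing)}")
        if (self.table["NADH_uM"] <= 0).any() or (self.table["CoQ0_uM"] <= 0).any():
            raise ValueError("concentrations must be > 0")

    @property
    def A(self) -> np.ndarray:
        return self.table["NADH_uM"].to_numpy(float)

    @property
    def B(self) -> np.ndarray:
        return self.table["CoQ0_uM"].to_numpy(float)

    @property
    def v(self) -> np.ndarray:
        return self.table["v0_over_e_per_s"].to_numpy(float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class StoppedFlowTrace:
    """Absorbance-vs-time transient at 461 nm for one substrate concentration."""

    times: np.ndarray               # s, strictly increasing
    absorbance: np.ndarray          # AU
    substrate_concentration: float  # uM

    def __post_init__(self):
        t = np.asarray(self.times, float)
        a = np.asarray(self.absorbance, float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and absorbance must be matching 1-D arrays")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(a))):
            raise ValueError("trace values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbance", a)


def simulate_rates(spec: KineticsSimSpec) -> RateDataset:
    """Forward-simulate a steady-state initial-rate table.

    Rates are the ping-pong law evaluated on the full (NADH x CoQ0) grid,
    replicated, with multiplicative Gaussian noise of relative SD
    ``noise_cv``.  Seed-deterministic; replicate r always uses the r-th
    child stream, so adding replicates appends rather than reshuffles.
    """
    spec.validate()
    A, B = np.meshgrid(spec.nadh_grid, spec.coq0_grid, indexing="ij")
    A, B = A.ravel(), B.ravel()
    v_true = pingpong_rate(A, B, spec.true_kcat, spec.true_Ka, spec.true_Kb,
                           spec.true_Kis)
    streams = np.random.default_rng(spec.rng_seed).spawn(spec.replicates)
    rows = []
    for r, rng in enumerate(streams, start=1):
        noise = 1.0 + spec.noise_cv * rng.standard_normal(len(v_true))
        v = np.maximum(v_true * noise, 1e-12)
        rows.append(pd.DataFrame({
            "NADH_uM": A, "CoQ0_uM": B, "replicate": r,
            "v0_over_e_per_s": v}))
    table = pd.concat(rows, ignore_index=True)
    label = ("pingpong+NADH-inhibition" if spec.true_Kis is not None
             else "pingpong")
    return RateDataset(table=table, provenance=f"simulated:{label}")


def simulate_traces(spec: KineticsSimSpec,
                    substrate_concentrations: Sequence[float],
                    ) -> list[StoppedFlowTrace]:
    """Forward-simulate stopped-flow reduction transients at 461 nm.

    For each NADH concentration S the noiseless trace is the
    double-exponential ``B1 exp(-kobs1 t) + B2 exp(-kobs2 t) + C`` with
    kobs1 = kred*S/(Kd+S) (hyperbolic saturation), kobs2 the substrate-
    independent slow-phase rate, and B2/(B1+B2) the slow-phase amplitude
    fraction.  Time points are logarithmically spaced from 1 ms to
    5/min(kobs1, kobs2) so both phases are resolved.  Additive Gaussian
    noise of SD ``trace_noise_sd``; one child stream per concentration.
    """
    spec.validate()
    S = np.asarray(list(substrate_concentrations), float)
    if S.size == 0 or np.any(S <= 0):
        raise ValueError("substrate concentrations must be positive and non-empty")
    B2 = spec.total_amplitude * spec.slow_phase_fraction
    B1 = spec.total_amplitude - B2
    streams = np.random.default_rng(spec.rng_seed).spawn(len(S))
    traces = []
    for s, rng in zip(S, streams):
        k1 = float(saturation_kobs(s, spec.true_kred, spec.true_Kd))
        k2 = spec.slow_phase_rate
        t_end = 5.0 / min(k1, k2)
        t = np.geomspace(1e-3, t_end, spec.points_per_trace)
        a = biexponential(t, B1, B2, k1, k2, spec.offset)
        a = a + spec.trace_noise_sd * rng.standard_normal(t.shape)
        traces.append(StoppedFlowTrace(times=t, absorbance=a,
                                       substrate_concentration=float(s)))
    return traces


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def write_rates_csv(dataset: RateDataset, path: str | Path) -> None:
    dataset.table.to_csv(path, index=False)


def read_rates_csv(path: str | Path, provenance: str = "") -> RateDataset:
    return RateDataset(table=pd.read_csv(path),
                       provenance=provenance or str(path))


def write_trace_csv(trace: StoppedFlowTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times, "A461": trace.absorbance}).to_csv(
        path, index=False)


def read_trace_csv(path: str | Path,
                   substrate_concentration: float) -> StoppedFlowTrace:
    df = pd.read_csv(path)
    return StoppedFlowTrace(times=df["time_s"].to_numpy(float),
                            absorbance=df["A461"].to_numpy(float),
                            substrate_concentration=substrate_concentration)
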