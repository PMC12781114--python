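"""Structures, trajectories, atom selection and superposition.

These are the substrate operations for every structural stage of the
pipeline: PCA of backbone fluctuations, residue-contact analysis and
gate-distance series all consume the :class:`Structure` / :class:`Trajectory`
containers defined here.

Coordinates are in Angstrom throughout (PDB convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Structure",
    "Trajectory",
    "AtomSelection",
    "SuperpositionResult",
    "ParseError",
    "SelectionError",
    "read_structure",
    "read_models",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "select_atoms",
    "superpose",
    "kabsch",
    "rmsd",
    "rmsd_series",
    "trim_equilibration",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


class ParseError(ValueError):
    """Raised when a structure/trajectory file cannot be parsed."""


class SelectionError(ValueError):
    """Raised when a selection expression is invalid or resolves badly."""


@dataclass(frozen=True)
class Structure:
    """A fixed topology: per-atom records plus one coordinate set (Angstrom).

    Residue identity is the pair (chain id, residue index) so multi-chain
    topologies cannot collide.
    """

    names: np.ndarray          # str per atom, e.g. "CA"
    elements: np.ndarray       # str per atom, e.g. "C"
    resids: np.ndarray         # int per atom (author numbering)
    resnames: np.ndarray       # str per atom
    chains: np.ndarray         # str per atom
    xyz: np.ndarray            # (n_atoms, 3) float, Angstrom

    def __post_init__(self):
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise ValueError(f"xyz must be (n_atoms, 3), got {xyz.shape}")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")
        n = xyz.shape[0]
        for attr in ("names", "elements", "resids", "resnames", "chains"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} length != n_atoms")
        object.__setattr__(self, "xyz", xyz)

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[0]

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, resid) pairs, in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chains, self.resids):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def residue_index_per_atom(self) -> np.ndarray:
        """Map each atom to a 0-based compact residue index."""
        keys = {k: i for i, k in enumerate(self.residue_keys())}
        return np.array(
            [keys[(str(c), int(r))] for c, r in zip(self.chains, self.resids)],
            dtype=int,
        )

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys())

    def with_coordinates(self, xyz: np.ndarray) -> "Structure":
        return Structure(self.names, self.elements, self.resids,
                         self.resnames, self.chains, np.asarray(xyz, float))


@dataclass(frozen=True)
class Trajectory:
    """Ordered coordinate frames over a fixed topology."""

    topology: Structure
    xyz: np.ndarray                 # (n_frames, n_atoms, 3) Angstrom
    frame_interval: float | None = None   # optional time per frame

    def __post_init__(self):
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.ndim != 3 or xyz.shape[2] != 3:
            raise ValueError(f"xyz must be (n_frames, n_atoms, 3), got {xyz.shape}")
        if xyz.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {xyz.shape[1]} != topology atom count "
                f"{self.topology.n_atoms}")
        object.__setattr__(self, "xyz", xyz)

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class AtomSelection:
    indices: np.ndarray        # ordered, unique atom indices
    descriptor: str

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selection indices must be unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray       # 3x3 proper rotation
    translation: np.ndarray    # applied after rotation, Angstrom
    rmsd: float                # over the fitted selection, Angstrom


# ---------------------------------------------------------------------------
# PDB I/O.  The reader is deliberately strict: malformed ATOM/HETATM records
# and missing coordinates raise ParseError with the offending line number
# rather than producing silent NaNs.
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip() or "A"
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM/HETATM record at line {lineno}: "
                         f"{line.rstrip()!r} ({exc})") from None
    element = line[76:78].strip() if len(line) >= 77 else ""
    if not element:
        # fall back on the convention that the element starts the atom name
        element = "".join(ch for ch in name if ch.isalpha())[:1] or "X"
    return name, element.capitalize(), resid, resname, chain, (x, y, z)


def read_models(path: str | Path) -> list[Structure]:
    """Read every MODEL of a PDB file as a list of structures."""
    models: list[list] = []
    current: list = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if current:
                    models.append(current)
                current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(
                        f"ATOM/HETATM record at line {lineno} is missing "
                        f"coordinates: {line.rstrip()!r}")
                current.append(_parse_atom_line(line, lineno))
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise ParseError(f"no ATOM/HETATM records found in {path}")

    out = []
    for atoms in models:
        names, elements, resids, resnames, chains, coords = zip(*atoms)
        out.append(Structure(
            names=np.array(names), elements=np.array(elements),
            resids=np.array(resids, dtype=int), resnames=np.array(resnames),
            chains=np.array(chains), xyz=np.array(coords, dtype=float)))
    return out


def read_structure(path: str | Path, format: str = "pdb",
                   model: int = 0) -> Structure:
    """Read a single structure (model 1 of a multi-model PDB by default)."""
    if format.lower() != "pdb":
        raise ValueError(f"unsupported structure format: {format!r}")
    return read_models(path)[model]


def write_structure(structure: Structure, path: str | Path) -> None:
    with open(path, "w") as fh:
        _write_model(fh, structure, structure.xyz)
        fh.write("END\n")


def _write_model(fh, top: Structure, xyz: np.ndarray) -> None:
    for i in range(top.n_atoms):
        name = str(top.names[i])
        # PDB column-13 convention: 1-2 letter element names start in col 14
        pname = f" {name:<3s}" if len(name) < 4 else name
        fh.write(
            "ATOM  {serial:>5d} {name:4s} {res:<3s} {chain:1s}{resid:>4d}    "
            "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n".format(
                serial=(i + 1) % 100000, name=pname, res=str(top.resnames[i])[:3],
                chain=str(top.chains[i])[:1], resid=int(top.resids[i]) % 10000,
                x=xyz[i, 0], y=xyz[i, 1], z=xyz[i, 2],
                el=str(top.elements[i])[:2].upper()))


def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str = "dcd") -> None:
    """Write frames as DCD (via mdtraj) or as a multi-model PDB."""
    format = format.lower()
    if format == "dcd":
        from mdtraj.formats import DCDTrajectoryFile
        with DCDTrajectoryFile(str(path), "w") as fh:
            fh.write(np.asarray(traj.xyz, dtype=np.float32))
    elif format in ("pdb", "multipdb", "multi-pdb"):
        with open(path, "w") as fh:
            for f in range(traj.n_frames):
                fh.write(f"MODEL     {f + 1:>4d}\n")
                _write_model(fh, traj.topology, traj.xyz[f])
                fh.write("ENDMDL\n")
            fh.write("END\n")
    else:
        raise ValueError(f"unsupported trajectory format: {format!r}")


def read_trajectory(path: str | Path, topology: Structure,
                    format: str | None = None) -> Trajectory:
    """Read an ordered-frame trajectory against a known topology.

    Formats: ``dcd`` (mdtraj reader, endianness auto-detected), ``pdb``
    (multi-model) and ``xyz``.  An atom-count mismatch with the topology is
    an error, not a silent truncation.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "dcd"
    format = format.lower()
    if format == "dcd":
        from mdtraj.formats import DCDTrajectoryFile
        with DCDTrajectoryFile(str(path)) as fh:
            xyz, _, _ = fh.read()
        xyz = np.asarray(xyz, dtype=float)
    elif format in ("pdb", "multipdb", "multi-pdb"):
        xyz = np.array([m.xyz for m in read_models(path)], dtype=float)
    elif format == "xyz":
        from mdtraj.formats import XYZTrajectoryFile
        with XYZTrajectoryFile(str(path)) as fh:
            xyz = np.asarray(fh.read(), dtype=float) * 10.0  # mdtraj reads nm
    else:
        raise ValueError(f"unsupported trajectory format: {format!r}")
    if xyz.ndim != 3 or xyz.shape[1] != topology.n_atoms:
        raise ParseError(
            f"trajectory atom count {xyz.shape[1] if xyz.ndim == 3 else '?'} "
            f"does not match topology ({topology.n_atoms} atoms)")
    return Trajectory(topology=topology, xyz=xyz)


# ---------------------------------------------------------------------------
# Selection mini-language.
#
# grammar:   expr   := term ("or" term)*
#            term   := factor ("and" factor)*
#            factor := "not" factor | primitive
# primitives: all | backbone | heavy | sidechain
#             name N1 N2 ...      (atom names)
#             resid A | resid A:B | resid A to B
#             element E1 E2 ...
#             chain C1 C2 ...
# ---------------------------------------------------------------------------

_KEYWORDS = {"and", "or", "not", "all", "backbone", "heavy", "sidechain",
             "name", "resid", "element", "chain", "to"}


class _SelParser:
    def __init__(self, structure: Structure, expression: str):
        self.s = structure
        self.tokens = expression.replace(":", " : ").split()
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self):
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self):
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self):
        if self.peek() == "not":
            self.take()
            return ~self.factor()
        return self.primitive()

    def _values(self) -> list[str]:
        vals = []
        while (tok := self.peek()) is not None and tok.lower() not in _KEYWORDS:
            vals.append(self.take())
        if not vals:
            raise SelectionError("expected one or more values")
        return vals

    def primitive(self):
        tok = self.take()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        low = tok.lower()
        s = self.s
        if low == "all":
            return np.ones(s.n_atoms, dtype=bool)
        if low == "backbone":
            return np.isin(s.names, BACKBONE_NAMES)
        if low == "heavy":
            return ~np.char.equal(np.char.upper(s.elements.astype(str)), "H")
        if low == "sidechain":
            return ~np.isin(s.names, BACKBONE_NAMES)
        if low == "name":
            return np.isin(s.names, self._values())
        if low == "element":
            vals = [v.capitalize() for v in self._values()]
            return np.isin(np.char.capitalize(s.elements.astype(str)), vals)
        if low == "chain":
            return np.isin(s.chains, self._values())
        if low == "resid":
            lo = self._int(self.take())
            if self.peek() in (":", "to"):
                self.take()
                hi = self._int(self.take())
            else:
                hi = lo
            return (s.resids >= lo) & (s.resids <= hi)
        raise SelectionError(f"unknown token {tok!r} in selection expression")

    @staticmethod
    def _int(tok):
        try:
            return int(tok)
        except (TypeError, ValueError):
            raise SelectionError(f"expected residue number, got {tok!r}") from None


def select_atoms(structure: Structure, expression: str) -> AtomSelection:
    """Resolve a selection expression to an ordered, unique atom index set."""
    mask = _SelParser(structure, expression).parse()
    return AtomSelection(indices=np.nonzero(mask)[0], descriptor=expression)


# ---------------------------------------------------------------------------
# Superposition (Kabsch) and RMSD
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` minimizes the RMSD to
    ``reference``.  ``R`` is a proper rotation (det +1).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("need matching coordinate sets with >= 3 atoms")
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    H = (mobile - cm).T @ (reference - cr)
    U, S, Vt = np.linalg.svd(H)
    # guard against degenerate (collinear / coincident) selections
    if S[1] <= 1e-10 * max(S[0], 1e-30):
        raise ValueError("degenerate selection: atoms are collinear or coincident")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    return R, t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no fitting)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: AtomSelection | None = None,
              reference_selection: AtomSelection | None = None,
              ) -> tuple[SuperpositionResult, np.ndarray]:
    """Superpose a full frame onto a reference using a fitted subset.

    The rotation/translation is computed on the selected atoms but applied to
    ALL atoms of ``mobile``, so downstream contacts and distances share one
    frame of reference.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    idx = selection.indices if selection is not None else np.arange(len(mobile))
    ridx = (reference_selection.indices if reference_selection is not None
            else idx)
    if len(idx) != len(ridx):
        raise ValueError("mobile and reference selections differ in size")
    R, t = kabsch(mobile[idx], reference[ridx])
    moved = mobile @ R.T + t
    res = SuperpositionResult(rotation=R, translation=t,
                              rmsd=rmsd(moved[idx], reference[ridx]))
    return res, moved


def rmsd_series(trajectory: Trajectory, reference: np.ndarray,
                selection: AtomSelection | None = None) -> np.ndarray:
    """Per-frame RMSD over the selection after superposing each frame."""
    out = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        res, _ = superpose(trajectory.xyz[f], reference, selection)
        out[f] = res.rmsd
    return out


def trim_equilibration(trajectory: Trajectory,
                       keep_last_fraction: float) -> Trajectory:
    """Keep the last ceil(fraction * n_frames) frames, order preserved.

    Mirrors the usual practice of analyzing only the equilibrated tail of a
    simulation (e.g. the last 0.8 of a 1.0 us run).
    """
    if not 0.0 < keep_last_fraction <= 1.0:
        raise ValueError(
            f"keep_last_fraction must be in (0, 1], got {keep_last_fraction}")
    n = trajectory.n_frames
    keep = math.ceil(keep_last_fraction * n)
    return Trajectory(topology=trajectory.topology,
                      xyz=trajectory.xyz[n - keep:],
                      frame_interval=trajectory.frame_interval)
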