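"""Principal component analysis of backbone fluctuations.

Frames of one or more trajectories are superposed onto a single common
reference, the variance-covariance matrix of the selected Cartesian
coordinates is built over the POOLED frames, and its eigendecomposition
yields collective motions ordered by captured variance.  Pooling makes the
principal components directly comparable across systems (wild type vs
mutant, ligand-free vs ligand-bound), so all systems can be projected into
one shared PC space and overlaid as 2D densities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, ndimage

from .trajectory import AtomSelection, Trajectory, superpose

__all__ = [
    "PCModel",
    "Projection",
    "DensityMap",
    "fit_pca",
    "superposed_selected_coords",
    "project",
    "scree",
    "density2d",
    "most_probable_frame",
    "most_probable_frame_1d",
    "export_mode_structures",
]


@dataclass(frozen=True)
class PCModel:
    """Mean structure and eigenbasis of the pooled backbone covariance."""

    mean_coordinates: np.ndarray    # (3m,) A, over the selected atoms
    eigenvectors: np.ndarray        # (k, 3m), orthonormal rows
    eigenvalues: np.ndarray         # (k,), A^2, non-increasing
    reference: np.ndarray           # (n_atoms_ref, 3) superposition reference
    reference_selection: AtomSelection
    align: bool = True              # whether frames are rigid-fit first

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues * 0.0

    @property
    def rank(self) -> int:
        return int(np.sum(self.eigenvalues > 1e-10 * max(self.eigenvalues.max(), 1e-30)))


@dataclass(frozen=True)
class Projection:
    scores: np.ndarray              # (n_frames, n_components), A
    system_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "scores",
                           np.atleast_2d(np.asarray(self.scores, float)))

    @property
    def n_frames(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class DensityMap:
    """Normalized 2D probability density over a shared (PC1, PC2) grid."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray             # (nx, ny), sums to 1
    system_label: str = ""

    @property
    def mode_bin(self) -> tuple[int, int]:
        """Highest-density bin; ties resolved to the lowest flat index."""
        flat = int(np.argmax(self.density))
        return np.unravel_index(flat, self.density.shape)

    def mode_center(self) -> np.ndarray:
        i, j = self.mode_bin
        cx = 0.5 * (self.x_edges[i] + self.x_edges[i + 1])
        cy = 0.5 * (self.y_edges[j] + self.y_edges[j + 1])
        return np.array([cx, cy])


def superposed_selected_coords(trajectory: Trajectory,
                               selection: AtomSelection,
                               reference: np.ndarray,
                               reference_selection: AtomSelection | None = None,
                               align: bool = True) -> np.ndarray:
    """Superpose every frame to the reference; return selected coords
    flattened to (n_frames, 3m).  ``align=False`` skips the rigid fit and
    uses raw coordinates (for pre-aligned or abstract ensembles)."""
    if not align:
        return trajectory.xyz[:, selection.indices, :].reshape(
            trajectory.n_frames, -1)
    rsel = reference_selection or selection
    out = np.empty((trajectory.n_frames, 3 * len(selection)))
    for f in range(trajectory.n_frames):
        _, moved = superpose(trajectory.xyz[f], reference, selection, rsel)
        out[f] = moved[selection.indices].ravel()
    return out


def fit_pca(trajectories: list[Trajectory], selection: AtomSelection,
            reference: np.ndarray | None = None,
            reference_selection: AtomSelection | None = None,
            align: bool = True) -> PCModel:
    """Fit the pooled-covariance PC model.

    ``reference`` defaults to the first frame of the first trajectory (the
    conventional choice: every system is aligned to one frame so the PCs
    live in a single coordinate frame).  The covariance is mass-unweighted
    and population-normalized; eigenvalues are clipped at zero and sorted
    descending; each eigenvector's sign is fixed so its largest-magnitude
    entry is positive.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    if reference is None:
        reference = trajectories[0].xyz[0]
    rsel = reference_selection or selection
    blocks = [superposed_selected_coords(t, selection, reference, rsel, align)
              for t in trajectories]
    X = np.vstack(blocks)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 pooled frames for a covariance")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / X.shape[0]
    evals, evecs = linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T                      # rows are components
    # reproducible sign convention
    for k in range(evecs.shape[0]):
        i = int(np.argmax(np.abs(evecs[k])))
        if evecs[k, i] < 0:
            evecs[k] = -evecs[k]
    return PCModel(mean_coordinates=mean, eigenvectors=evecs,
                   eigenvalues=evals, reference=np.asarray(reference, float),
                   reference_selection=rsel, align=align)


def project(trajectory: Trajectory, model: PCModel,
            selection: AtomSelection, n_components: int = 2,
            system_label: str = "") -> Projection:
    """Project frames onto the leading eigenvectors.

    score(frame, k) = (superposed selected coords - mean) . eigenvector_k
    """
    if n_components > model.eigenvectors.shape[0]:
        raise ValueError(f"n_components={n_components} exceeds model rank")
    X = superposed_selected_coords(trajectory, selection, model.reference,
                                   model.reference_selection, model.align)
    if X.shape[1] != model.mean_coordinates.shape[0]:
        raise ValueError("selection size does not match the fitted model")
    scores = (X - model.mean_coordinates) @ model.eigenvectors[:n_components].T
    return Projection(scores=scores, system_label=system_label)


def scree(model: PCModel) -> np.ndarray:
    """Cumulative variance fractions by eigenvalue rank (ends at 1)."""
    return np.cumsum(model.variance_fractions)


def _scott_sigma_bins(scores: np.ndarray, edges: np.ndarray) -> float:
    """Scott-rule bandwidth converted to grid-bin units."""
    n = len(scores)
    sd = float(np.std(scores))
    if sd == 0 or n < 2:
        return 0.0
    bw = sd * n ** (-1.0 / 6.0)    # Scott rule for 2D KDE, per-dimension
    width = float(edges[1] - edges[0])
    return bw / width


def density2d(projections: list[Projection], bins: int = 60,
              smoothing: float | None = None) -> list[DensityMap]:
    """Normalized 2D densities of (PC1, PC2) scores on one shared grid.

    All systems share the grid (pooled score range padded by 5%), so their
    modes and overlaps are directly comparable.  ``smoothing`` is a
    Gaussian kernel SD in score units; the default uses a Scott-type rule
    from the pooled scores.  Each map is renormalized to sum to 1.
    """
    if not projections:
        raise ValueError("need at least one projection")
    pooled = np.vstack([p.scores[:, :2] for p in projections])
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 frames to build a density")
    lo, hi = pooled.min(axis=0), pooled.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    lo, hi = lo - 0.05 * span, hi + 0.05 * span
    x_edges = np.linspace(lo[0], hi[0], bins + 1)
    y_edges = np.linspace(lo[1], hi[1], bins + 1)
    maps = []
    for p in projections:
        H, _, _ = np.histogram2d(p.scores[:, 0], p.scores[:, 1],
                                 bins=[x_edges, y_edges])
        if smoothing is None:
            sx = _scott_sigma_bins(pooled[:, 0], x_edges)
            sy = _scott_sigma_bins(pooled[:, 1], y_edges)
        else:
            sx = smoothing / float(x_edges[1] - x_edges[0])
            sy = smoothing / float(y_edges[1] - y_edges[0])
        if sx > 0 or sy > 0:
            H = ndimage.gaussian_filter(H, sigma=(sx, sy), mode="constant")
        total = H.sum()
        if total <= 0:
            raise ValueError("degenerate score cloud: empty density")
        maps.append(DensityMap(x_edges=x_edges, y_edges=y_edges,
                               density=H / total,
                               system_label=p.system_label))
    return maps


def overlap_coefficient(a: DensityMap, b: DensityMap) -> float:
    """Histogram overlap sum(min(pa, pb)) on the shared grid, in [0, 1]."""
    if a.density.shape != b.density.shape:
        raise ValueError("density maps must share a grid")
    return float(np.minimum(a.density, b.density).sum())


def most_probable_frame(projection: Projection, density: DensityMap) -> int:
    """Frame nearest (Euclidean in PC space) to the 2D mode bin center.

    Ties go to the lowest frame index.  The density must have been built
    from this projection's system.
    """
    if projection.n_frames == 0:
        raise ValueError("empty projection")
    center = density.mode_center()
    d2 = np.sum((projection.scores[:, :2] - center) ** 2, axis=1)
    return int(np.argmin(d2))   # argmin returns the first (lowest) index on ties


def most_probable_frame_1d(projection: Projection, component: int = 0,
                           bins: int = 60) -> int:
    """Frame nearest the 1D marginal mode of a single component.

    Companion to :func:`most_probable_frame` for the case where the most
    probable state along one PC is wanted irrespective of the other.
    """
    if projection.n_frames == 0:
        raise ValueError("empty projection")
    s = projection.scores[:, component]
    hist, edges = np.histogram(s, bins=bins)
    i = int(np.argmax(hist))
    center = 0.5 * (edges[i] + edges[i + 1])
    return int(np.argmin(np.abs(s - center)))


def export_mode_structures(model: PCModel, component: int,
                           scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Mean +/- scaled eigenvector as two selected-atom coordinate sets.

    Intended for writing a PDB pair that visualizes one collective motion.
    """
    v = model.eigenvectors[component] * scale * np.sqrt(
        max(model.eigenvalues[component], 0.0))
    plus = (model.mean_coordinates + v).reshape(-1, 3)
    minus = (model.mean_coordinates - v).reshape(-1, 3)
    return plus, minus
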