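"""Rigid-body superposition (Kabsch) and RMSD series/distributions.

The RMSD of a trajectory frame against a reference, minimized over all
proper rigid motions, is the standard readout of conformational stability:
a stable fold gives a distribution concentrated at low RMSD, a
destabilized one drifts to higher values.

The Kabsch solution is computed from the SVD of the weighted cross-
covariance of the centered point sets, with the reflection branch
corrected by the determinant sign so only proper rotations are returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Structure, Trajectory
from .distributions import Distribution, histogram_distribution
from .errors import DegenerateGeometryError, DimensionError, SelectionError


@dataclass(frozen=True)
class AtomSelection:
    """Predicate over atoms: by atom name, chain, and residue-number range.

    ``None`` in a field means "all".  The conventional whole-system
    stability selection is ``AtomSelection(atom_names=frozenset({"CA"}))``:
    Cα of every chain, which is robust to side-chain differences between
    mutants.
    """

    atom_names: frozenset[str] | None = None
    chains: frozenset[str] | None = None
    residue_range: tuple[int, int] | None = None

    def indices(self, structure: Structure) -> np.ndarray:
        """Indices of matching atoms in structure order.

        Raises :class:`SelectionError` if nothing matches.
        """
        out = []
        for i, a in enumerate(structure.atoms):
            if self.atom_names is not None and a.atom_name not in self.atom_names:
                continue
            if self.chains is not None and a.chain_id not in self.chains:
                continue
            if self.residue_range is not None:
                lo, hi = self.residue_range
                if not (lo <= a.residue_seq <= hi):
                    continue
            out.append(i)
        if not out:
            raise SelectionError(f"selection matched no atoms: {self}")
        return np.asarray(out, dtype=np.intp)


#: Cα of every chain: the default stability selection.
CA_SELECTION = AtomSelection(atom_names=frozenset({"CA"}))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rigid motion superposing *mobile* onto *reference*.

    Returns ``(rotation, translation, rmsd)`` with the convention
    ``aligned = mobile @ rotation.T + translation``, and *rmsd* the
    minimum weighted RMSD (Å) over all proper rigid motions.

    Raises
    ------
    DimensionError
        If the point sets differ in shape or have fewer than 3 points.
    DegenerateGeometryError
        If either set is (near-)collinear or coincident, leaving the
        rotation underdetermined.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape:
        raise DimensionError(f"point sets differ in shape: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise DimensionError(f"need (n>=3, 3) point sets, got {mobile.shape}")

    n = mobile.shape[0]
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (n,):
            raise DimensionError(f"weights shape {w.shape} does not match {n} points")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        w = w / w.sum()

    cm_mob = w @ mobile
    cm_ref = w @ reference
    x = mobile - cm_mob
    y = reference - cm_ref

    _check_nondegenerate(x, w)
    _check_nondegenerate(y, w)

    # weighted cross-covariance and its SVD
    h = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d])
    rotation = vt.T @ np.diag(diag) @ u.T

    # residual computed explicitly after rotation: immune to the
    # catastrophic cancellation of the E0 - 2*sum(s) closed form
    resid = x @ rotation.T - y
    rmsd = float(np.sqrt(np.sum(w * np.sum(resid * resid, axis=1))))
    translation = cm_ref - rotation @ cm_mob
    return rotation, translation, rmsd


def _check_nondegenerate(centered: np.ndarray, w: np.ndarray, tol: float = 1e-8) -> None:
    """A point set whose weighted spread has rank < 2 (all coincident or
    collinear) does not pin down a rotation."""
    cov = (centered * w[:, None]).T @ centered
    eig = np.linalg.eigvalsh(cov)
    scale = max(eig[-1], tol)
    if eig[1] / scale < tol or eig[-1] < tol * tol:
        raise DegenerateGeometryError(
            "point set is coincident or collinear; superposition is underdetermined"
        )


@dataclass(frozen=True)
class RMSDSeries:
    """Per-frame minimized RMSD (Å) against a fixed reference."""

    values: np.ndarray
    times: np.ndarray
    reference_tag: str
    selection: AtomSelection

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("RMSD values must be nonnegative")


def rmsd_series(
    traj: Trajectory,
    reference: int | Structure = 0,
    selection: AtomSelection = CA_SELECTION,
    weights: str = "uniform",
) -> RMSDSeries:
    """Minimized RMSD of every frame against a reference.

    Parameters
    ----------
    reference
        Either a frame index of *traj* (default 0: each system drifts
        relative to its own start) or an external :class:`Structure`
        (e.g. the energy-minimized starting model), which must resolve
        the same selection.
    weights
        ``"uniform"`` or ``"mass"`` (per-atom masses from the topology).
    """
    idx = selection.indices(traj.topology)
    if idx.size < 3:
        raise SelectionError(f"selection yields {idx.size} atoms; superposition needs >= 3")
    if weights == "uniform":
        w = None
    elif weights == "mass":
        w = traj.topology.masses[idx]
    else:
        raise ValueError(f"weights must be 'uniform' or 'mass', got {weights!r}")

    if isinstance(reference, Structure):
        ref_idx = selection.indices(reference)
        if ref_idx.size != idx.size:
            raise DimensionError(
                f"selection resolves {ref_idx.size} atoms on the reference but "
                f"{idx.size} on the trajectory topology"
            )
        ref_xyz = reference.coords[ref_idx]
        tag = "external"
    else:
        if not (0 <= reference < traj.n_frames):
            raise IndexError(f"reference frame {reference} out of range [0, {traj.n_frames})")
        ref_xyz = traj.frames[reference][idx]
        tag = f"frame:{reference}"

    values = np.empty(traj.n_frames, dtype=np.float64)
    for i in range(traj.n_frames):
        _, _, values[i] = kabsch_superpose(traj.frames[i][idx], ref_xyz, w)
    return RMSDSeries(values=values, times=traj.times.copy(), reference_tag=tag, selection=selection)


def rmsd_distribution(
    series: RMSDSeries,
    n_bins: int = 50,
    hist_range: tuple[float, float] | None = None,
) -> Distribution:
    """Density-normalized RMSD histogram with summary statistics.

    Pass a pooled *hist_range* when overlaying several systems so they
    share bin edges.
    """
    return histogram_distribution(series.values, n_bins, hist_range)
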