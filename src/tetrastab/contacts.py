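"""Residue contact maps via a rational switching function, trajectory
averages, mutant-minus-reference difference maps, and divergence flagging.

A contact between residues i and j at distance r is scored with the
rational sigmoid

    C(r) = (1 - (r/r0)^n) / (1 - (r/r0)^m),   m > n,

which is 1 at r = 0, has the removable-singularity value n/m at r = r0,
and decays to 0 at long range.  Averaging C over frames gives a map in
[0, 1]; the elementwise |mutant - reference| difference highlights
residues whose contact environment diverged, flagged above a threshold
(conventionally read in the 0.25–0.5 band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .core import Structure, Trajectory
from .errors import AlignmentError, RangeError, SelectionError

#: |x - 1| below which the switching function takes its limit value n/m.
_SINGULARITY_TOL = 1e-12


@dataclass(frozen=True)
class SwitchingParams:
    """Parameters of the rational switching function.

    Defaults (r0 = 8.5 Å, n = 6, m = 10) are the conventional Cα-contact
    settings for this functional form; all three are explicit
    configuration, never hard-coded downstream.
    """

    r0: float = 8.5
    n_exp: int = 6
    m_exp: int = 10

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError(f"r0 must be positive, got {self.r0}")
        if self.n_exp <= 0 or self.m_exp <= 0:
            raise ValueError("exponents must be positive integers")
        if self.m_exp <= self.n_exp:
            raise ValueError(f"m_exp must exceed n_exp, got n={self.n_exp}, m={self.m_exp}")


def switching_contact(r, params: SwitchingParams = SwitchingParams()):
    """Contact degree C(r) in (0, 1] for distance(s) r >= 0 (Å).

    Vectorized over arrays; the removable singularity at r = r0 returns
    the limit n/m.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("distances must be nonnegative")
    x = r / params.r0
    num = 1.0 - x**params.n_exp
    den = 1.0 - x**params.m_exp
    limit = params.n_exp / params.m_exp
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(np.abs(x - 1.0) < _SINGULARITY_TOL, limit, num / den)
    if c.ndim == 0:
        return float(c)
    return c


@dataclass(frozen=True)
class ContactMap:
    """Square symmetric residue-pair matrix with entries in [0, 1],
    diagonal fixed at 1, labels like ``A:337`` in topology order."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    frames_averaged: int

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(m, m.T):
            raise ValueError("contact map must be symmetric")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("contact map entries must lie in [0, 1]")


@dataclass(frozen=True)
class DifferenceMap:
    """|target - reference| of two aligned contact maps; zero diagonal."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    reference_system: str
    target_system: str


@dataclass(frozen=True)
class FlagReport:
    """Residues whose contact environment diverged by >= threshold.

    ``flagged_residues`` is sorted by descending per-residue maximum
    difference; ``max_diff_per_residue`` covers every residue, flagged
    or not.
    """

    threshold: float
    flagged_residues: tuple[str, ...]
    max_diff_per_residue: dict[str, float]


def residue_labels(structure: Structure) -> tuple[str, ...]:
    """``chain:resSeq`` labels: chains in topology order, residues
    ascending within each chain."""
    out = []
    for ch in structure.chain_ids:
        for seq in structure.residues_of_chain(ch):
            out.append(f"{ch}:{seq}")
    return tuple(out)


def _representative_indices(structure: Structure, representation: str) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Atom indices (and masses) representing each residue, in label order."""
    idx_sets: list[np.ndarray] = []
    mass_sets: list[np.ndarray] = []
    for ch in structure.chain_ids:
        for seq in structure.residues_of_chain(ch):
            rname, atom_idx = structure.residue(ch, seq)
            if representation == "ca":
                hit = [i for i in atom_idx if structure.atoms[i].atom_name == "CA"]
                if not hit:
                    raise SelectionError(f"residue ({ch}, {seq}, {rname}) has no CA atom")
                sel = np.asarray(hit[:1], dtype=np.intp)
            elif representation == "residue_com":
                heavy = [i for i in atom_idx if structure.atoms[i].element.upper() not in ("H", "D")]
                if not heavy:
                    raise SelectionError(f"residue ({ch}, {seq}, {rname}) has no heavy atoms")
                sel = np.asarray(heavy, dtype=np.intp)
            else:
                raise ValueError(f"representation must be 'ca' or 'residue_com', got {representation!r}")
            idx_sets.append(sel)
            mass_sets.append(structure.masses[sel])
    return idx_sets, mass_sets


def _representative_points(frame: np.ndarray, idx_sets, mass_sets) -> np.ndarray:
    pts = np.empty((len(idx_sets), 3), dtype=np.float64)
    for k, (idx, m) in enumerate(zip(idx_sets, mass_sets)):
        if idx.size == 1:
            pts[k] = frame[idx[0]]
        else:
            pts[k] = (m[:, None] * frame[idx]).sum(axis=0) / m.sum()
    return pts


def frame_contact_map(
    frame: np.ndarray,
    structure: Structure,
    representation: str = "ca",
    params: SwitchingParams = SwitchingParams(),
) -> ContactMap:
    """Contact map of a single frame (diagonal = 1 by convention)."""
    labels = residue_labels(structure)
    idx_sets, mass_sets = _representative_indices(structure, representation)
    pts = _representative_points(np.asarray(frame, dtype=np.float64), idx_sets, mass_sets)
    mat = squareform(switching_contact(pdist(pts), params))
    np.fill_diagonal(mat, 1.0)
    return ContactMap(labels=labels, matrix=mat, frames_averaged=1)


def average_contact_map(
    traj: Trajectory,
    representation: str = "ca",
    params: SwitchingParams = SwitchingParams(),
    frame_range: tuple[int, int] | None = None,
) -> ContactMap:
    """Elementwise mean of per-frame contact maps over a frame range
    (half-open, default all frames)."""
    start, stop = (0, traj.n_frames) if frame_range is None else frame_range
    if stop is None:
        stop = traj.n_frames
    if not (0 <= start < stop <= traj.n_frames):
        raise RangeError(f"frame range [{start}, {stop}) invalid for {traj.n_frames} frames")

    labels = residue_labels(traj.topology)
    idx_sets, mass_sets = _representative_indices(traj.topology, representation)
    acc = np.zeros((len(labels), len(labels)), dtype=np.float64)
    for fi in range(start, stop):
        pts = _representative_points(traj.frames[fi], idx_sets, mass_sets)
        acc += squareform(switching_contact(pdist(pts), params))
    acc /= stop - start
    np.fill_diagonal(acc, 1.0)
    return ContactMap(labels=labels, matrix=acc, frames_averaged=stop - start)


def contact_map_difference(
    target: ContactMap,
    reference: ContactMap,
    target_system: str = "target",
    reference_system: str = "reference",
) -> DifferenceMap:
    """|target - reference|, requiring byte-identical residue label lists.

    Maps from different constructs must be aligned by construction (same
    chain order, same residue numbering); silent reindexing would corrupt
    the comparison, so any discrepancy is an error naming the first
    mismatch.
    """
    if target.labels != reference.labels:
        n = min(len(target.labels), len(reference.labels))
        for k in range(n):
            if target.labels[k] != reference.labels[k]:
                raise AlignmentError(
                    f"residue label mismatch at position {k}: "
                    f"{target.labels[k]!r} vs {reference.labels[k]!r}"
                )
        raise AlignmentError(
            f"residue label lists differ in length: {len(target.labels)} vs {len(reference.labels)}"
        )
    diff = np.abs(target.matrix - reference.matrix)
    np.fill_diagonal(diff, 0.0)
    return DifferenceMap(
        labels=target.labels,
        matrix=diff,
        reference_system=reference_system,
        target_system=target_system,
    )


def flag_divergent_residues(
    diff: DifferenceMap,
    threshold: float = 0.25,
    per_pair: bool = False,
    exclude_near_diagonal: bool = False,
) -> FlagReport:
    """Residues whose contact difference reaches *threshold*.

    By default a residue is flagged iff the maximum over its row of the
    difference matrix is >= threshold.  ``per_pair=True`` instead flags
    both members of every pair whose single entry reaches the threshold
    (the two rules coincide for the flagged set; they differ only in how
    the per-residue maximum is reported when near-diagonal exclusion is
    active).  ``exclude_near_diagonal`` ignores same-chain pairs with
    |i - j| <= 2 (bonded-neighbor signal).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    mat = diff.matrix.copy()
    if exclude_near_diagonal:
        chains = [lab.split(":")[0] for lab in diff.labels]
        n = len(diff.labels)
        for i in range(n):
            for j in range(max(0, i - 2), min(n, i + 3)):
                if chains[i] == chains[j]:
                    mat[i, j] = 0.0

    row_max = mat.max(axis=1) if mat.size else np.zeros(0)
    max_per = {lab: float(row_max[k]) for k, lab in enumerate(diff.labels)}
    if per_pair:
        hit = set()
        ii, jj = np.nonzero(mat >= threshold)
        for i, j in zip(ii, jj):
            hit.add(diff.labels[i])
            hit.add(diff.labels[j])
        flagged = sorted(hit, key=lambda lab: (-max_per[lab], lab))
    else:
        flagged = sorted(
            (lab for k, lab in enumerate(diff.labels) if row_max[k] >= threshold),
            key=lambda lab: (-max_per[lab], lab),
        )
    return FlagReport(
        threshold=threshold,
        flagged_residues=tuple(flagged),
        max_diff_per_residue=max_per,
    )
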