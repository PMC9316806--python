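"""Inter-chain functional-group distances and salt-bridge occupancy.

The tetramerization interface of the p53 dimer-of-dimers is held together
by reciprocal Arg337–Asp352 salt bridges across each primary dimer.  With
pairing (A,B) and (C,D) and residue positions 337/352 this gives four
ordered arrangements — 337.A-352.B, 337.B-352.A, 337.C-352.D and
337.D-352.C — whose center-of-mass distance distributions over a
trajectory read out whether the bridge persists in a given mutant.

Distances are between *mass-weighted centers of the side-chain functional
groups* (guanidinium, carboxylate, imidazole, ...), heavy atoms only, so
that protonation variants with identical heavy-atom groups are directly
comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ChainPairing, Structure, Trajectory
from .distributions import Distribution, histogram_distribution
from .errors import SelectionError

logger = logging.getLogger(__name__)

#: Default heavy-atom functional groups of the charged/titratable side
#: chains relevant at positions 337/352 across the studied mutants.
DEFAULT_FUNCTIONAL_GROUPS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "CZ", "NH1", "NH2"),   # guanidinium
    "ASP": ("CG", "OD1", "OD2"),         # carboxylate
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),  # imidazole
    "CYS": ("SG",),                      # thiol
    "GLU": ("CD", "OE1", "OE2"),         # carboxylate
}

#: Conventional COM–COM cutoff for a formed charged-group interaction, Å.
DEFAULT_SALTBRIDGE_CUTOFF = 4.5


@dataclass(frozen=True)
class FunctionalGroupSpec:
    """Residue name -> ordered heavy-atom names of its functional group."""

    groups: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for rname, atoms in self.groups.items():
            if not atoms:
                raise ValueError(f"functional group for {rname} lists no atoms")

    def atoms_for(self, residue_name: str) -> tuple[str, ...]:
        try:
            return self.groups[residue_name]
        except KeyError:
            raise SelectionError(
                f"no functional group defined for residue {residue_name!r}; "
                f"known: {sorted(self.groups)}"
            ) from None


DEFAULT_GROUP_SPEC = FunctionalGroupSpec(groups=dict(DEFAULT_FUNCTIONAL_GROUPS))


@dataclass(frozen=True)
class Arrangement:
    """One ordered inter-chain residue pair, e.g. 337.A-352.B."""

    res_i_chain: str
    res_i_seq: int
    res_j_chain: str
    res_j_seq: int

    def __post_init__(self) -> None:
        if self.res_i_chain == self.res_j_chain:
            raise ValueError("an arrangement must span two distinct chains")

    @property
    def label(self) -> str:
        return f"{self.res_i_seq}.{self.res_i_chain}-{self.res_j_seq}.{self.res_j_chain}"


@dataclass(frozen=True)
class ArrangementDistanceSeries:
    """Per-frame COM–COM distance (Å) for one arrangement."""

    arrangement: Arrangement
    distances: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.distances) < 0):
            raise ValueError("distances must be nonnegative")


@dataclass(frozen=True)
class OccupancyResult:
    """Fraction of frames in which an arrangement's distance is at or
    below the cutoff."""

    label: str
    cutoff: float
    fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError(f"fraction must be in [0,1], got {self.fraction}")


def enumerate_arrangements(
    pairing: ChainPairing,
    res_i_seq: int,
    res_j_seq: int,
    structure: Structure | None = None,
) -> list[Arrangement]:
    """The ordered arrangements of an (i, j) residue pair across each
    primary dimer: for a pair (X, Y), i-in-X vs j-in-Y and i-in-Y vs
    j-in-X, in pairing order.

    If *structure* is given, verifies that every involved residue exists.
    """
    out: list[Arrangement] = []
    for x, y in pairing.pairs:
        out.append(Arrangement(x, res_i_seq, y, res_j_seq))
        out.append(Arrangement(y, res_i_seq, x, res_j_seq))
    if structure is not None:
        for arr in out:
            structure.residue(arr.res_i_chain, arr.res_i_seq)
            structure.residue(arr.res_j_chain, arr.res_j_seq)
    return out


def _group_indices_and_masses(
    structure: Structure,
    chain: str,
    res_seq: int,
    spec: FunctionalGroupSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Atom indices and masses of a residue's functional group.

    Hydrogens are never included; listed atoms missing from the residue
    are skipped with a warning, but at least one must resolve.
    """
    res_name, atom_idx = structure.residue(chain, res_seq)
    wanted = spec.atoms_for(res_name)
    found: list[int] = []
    for name in wanted:
        hit = [i for i in atom_idx if structure.atoms[i].atom_name == name]
        if hit:
            i = hit[0]
            if structure.atoms[i].element.upper() in ("H", "D"):
                continue
            found.append(i)
        else:
            logger.warning(
                "functional-group atom %s missing from residue (%s, %d, %s); skipped",
                name, chain, res_seq, res_name,
            )
    if not found:
        raise SelectionError(
            f"none of the functional-group atoms {wanted} found in residue "
            f"({chain}, {res_seq}, {res_name})"
        )
    idx = np.asarray(found, dtype=np.intp)
    return idx, structure.masses[idx]


def functional_group_com(
    frame: np.ndarray,
    structure: Structure,
    chain: str,
    res_seq: int,
    spec: FunctionalGroupSpec = DEFAULT_GROUP_SPEC,
) -> np.ndarray:
    """Mass-weighted center of a residue's functional group in one frame (Å)."""
    idx, masses = _group_indices_and_masses(structure, chain, res_seq, spec)
    frame = np.asarray(frame, dtype=np.float64)
    return (masses[:, None] * frame[idx]).sum(axis=0) / masses.sum()


def interchain_distance_series(
    traj: Trajectory,
    arrangements: list[Arrangement],
    spec: FunctionalGroupSpec = DEFAULT_GROUP_SPEC,
) -> list[ArrangementDistanceSeries]:
    """COM–COM distance of every arrangement in every frame."""
    out: list[ArrangementDistanceSeries] = []
    for arr in arrangements:
        idx_i, m_i = _group_indices_and_masses(traj.topology, arr.res_i_chain, arr.res_i_seq, spec)
        idx_j, m_j = _group_indices_and_masses(traj.topology, arr.res_j_chain, arr.res_j_seq, spec)
        com_i = np.einsum("a,fax->fx", m_i, traj.frames[:, idx_i, :]) / m_i.sum()
        com_j = np.einsum("a,fax->fx", m_j, traj.frames[:, idx_j, :]) / m_j.sum()
        dist = np.linalg.norm(com_i - com_j, axis=1)
        out.append(ArrangementDistanceSeries(arrangement=arr, distances=dist, times=traj.times.copy()))
    return out


def saltbridge_occupancy(
    series: ArrangementDistanceSeries,
    cutoff: float = DEFAULT_SALTBRIDGE_CUTOFF,
) -> OccupancyResult:
    """Fraction of frames with distance <= cutoff (Å)."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    frac = float(np.mean(series.distances <= cutoff))
    return OccupancyResult(label=series.arrangement.label, cutoff=cutoff, fraction=frac)


def distance_distribution(
    series: ArrangementDistanceSeries,
    n_bins: int = 50,
    hist_range: tuple[float, float] | None = None,
) -> Distribution:
    """Density histogram of an arrangement's distance series."""
    return histogram_distribution(series.distances, n_bins, hist_range)


def count_bridges_in_structure(
    structure: Structure,
    pairing: ChainPairing,
    res_i_seq: int,
    res_j_seq: int,
    spec: FunctionalGroupSpec = DEFAULT_GROUP_SPEC,
    cutoff: float = DEFAULT_SALTBRIDGE_CUTOFF,
) -> dict[tuple[str, str], int]:
    """Formed bridges per dimer in a single static structure.

    For each chain pair, counts how many of its two ordered arrangements
    have functional-group COM distance <= cutoff.  The intact
    tetramerization-domain dimer shows two (the reciprocal 337–352
    bridges).
    """
    coords = structure.coords
    counts: dict[tuple[str, str], int] = {}
    for x, y in pairing.pairs:
        n = 0
        for arr in (Arrangement(x, res_i_seq, y, res_j_seq), Arrangement(y, res_i_seq, x, res_j_seq)):
            ci = functional_group_com(coords, structure, arr.res_i_chain, arr.res_i_seq, spec)
            cj = functional_group_com(coords, structure, arr.res_j_chain, arr.res_j_seq, spec)
            if float(np.linalg.norm(ci - cj)) <= cutoff:
                n += 1
        counts[(x, y)] = n
    return counts
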