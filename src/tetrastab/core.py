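"""Shared data model: atoms, structures, trajectories, chain pairings.

Conventions used throughout the package:

* Coordinates are Ångström everywhere in memory; unit conversion happens
  only inside file readers/writers.
* Times are nanoseconds.
* Residues are addressed by *author numbering* exactly as found in the
  coordinate file (canonical p53 numbering for the tetramerization
  domain, e.g. Arg337/Asp352); nothing is ever renumbered.
* Histidine force-field dialects (HID/HIE/HIP/HSD/HSE/HSP) are treated as
  HIS for residue addressing, so protonation variants of the same mutant
  select identically.  The tautomer is metadata (`SystemLabel`), not part
  of the structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError, DimensionError, SelectionError
from .masses import mass_of

#: Residue-name dialects collapsed for selection purposes.
_HIS_DIALECTS = {"HID", "HIE", "HIP", "HSD", "HSE", "HSP"}


def canonical_resname(res_name: str) -> str:
    """Map force-field specific residue names onto the canonical 3-letter code."""
    name = res_name.strip().upper()
    if name in _HIS_DIALECTS:
        return "HIS"
    return name


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus coordinates (Å) and mass (Da)."""

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    coords: tuple[float, float, float]
    element: str
    mass: float

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if self.mass <= 0:
            raise ValueError(f"atom mass must be positive, got {self.mass}")
        if len(self.chain_id) != 1:
            raise ValueError(f"chain_id must be a single character, got {self.chain_id!r}")


class Structure:
    """An ordered collection of atoms with chain/residue lookup.

    Parameters
    ----------
    atoms
        Ordered list of :class:`AtomRecord`.  The (chain, residue, atom
        name) triple must be unique.

    Notes
    -----
    ``residue_index`` maps ``(chain_id, residue_seq)`` to the canonical
    residue name and the atom indices of that residue, in file order.
    Lookups of missing residues raise, never return empty: silently
    returning nothing for a typo'd residue number would invalidate every
    downstream distance.
    """

    def __init__(self, atoms: list[AtomRecord]):
        if not atoms:
            raise ValueError("a Structure needs at least one atom")
        self.atoms: list[AtomRecord] = list(atoms)

        chain_ids: list[str] = []
        residue_index: dict[tuple[str, int], tuple[str, list[int]]] = {}
        seen: set[tuple[str, int, str]] = set()
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_seq, a.atom_name)
            if key in seen:
                raise ConsistencyError(
                    f"duplicate atom (chain {a.chain_id}, residue {a.residue_seq}, "
                    f"atom {a.atom_name!r}) in structure"
                )
            seen.add(key)
            if a.chain_id not in chain_ids:
                chain_ids.append(a.chain_id)
            rkey = (a.chain_id, a.residue_seq)
            rname = canonical_resname(a.residue_name)
            if rkey not in residue_index:
                residue_index[rkey] = (rname, [i])
            else:
                prev_name, idx = residue_index[rkey]
                if prev_name != rname:
                    raise ConsistencyError(
                        f"residue ({a.chain_id}, {a.residue_seq}) has conflicting "
                        f"names {prev_name} and {rname}"
                    )
                idx.append(i)

        self.chain_ids: list[str] = chain_ids
        self.residue_index: dict[tuple[str, int], tuple[str, list[int]]] = residue_index

        self._coords = np.array([a.coords for a in self.atoms], dtype=np.float64)
        self._masses = np.array([a.mass for a in self.atoms], dtype=np.float64)

    # -- basic accessors -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float64 array, Å.  A view; do not mutate."""
        return self._coords

    @property
    def masses(self) -> np.ndarray:
        """(n_atoms,) float64 array, Da."""
        return self._masses

    def residue(self, chain_id: str, residue_seq: int) -> tuple[str, list[int]]:
        """Canonical residue name and atom indices of one residue.

        Raises :class:`SelectionError` if the residue is absent — a missing
        residue is a user error, not an empty result.
        """
        try:
            return self.residue_index[(chain_id, residue_seq)]
        except KeyError:
            raise SelectionError(
                f"residue {residue_seq} not found in chain {chain_id!r}"
            ) from None

    def residues_of_chain(self, chain_id: str) -> list[int]:
        """Sorted residue numbers of one chain."""
        if chain_id not in self.chain_ids:
            raise SelectionError(f"chain {chain_id!r} not in structure (has {self.chain_ids})")
        return sorted(seq for (ch, seq) in self.residue_index if ch == chain_id)

    def atom_index(self, chain_id: str, residue_seq: int, atom_name: str) -> int:
        _, idx = self.residue(chain_id, residue_seq)
        for i in idx:
            if self.atoms[i].atom_name == atom_name:
                return i
        raise SelectionError(
            f"atom {atom_name!r} not found in residue ({chain_id}, {residue_seq})"
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, Structure) and self.atoms == other.atoms

    def __repr__(self) -> str:
        return (
            f"<Structure: {self.n_atoms} atoms, chains {''.join(self.chain_ids)}, "
            f"{len(self.residue_index)} residues>"
        )


def make_atom(
    serial: int,
    atom_name: str,
    residue_name: str,
    chain_id: str,
    residue_seq: int,
    xyz,
    element: str | None = None,
) -> AtomRecord:
    """Convenience constructor that infers the element from the atom name
    if not given and assigns the mass from the internal table."""
    if element is None:
        element = _element_from_atom_name(atom_name)
    return AtomRecord(
        serial=serial,
        atom_name=atom_name,
        residue_name=residue_name,
        chain_id=chain_id,
        residue_seq=residue_seq,
        coords=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
        element=element,
        mass=mass_of(element),
    )


def _element_from_atom_name(atom_name: str) -> str:
    """PDB-convention element guess: strip digits, first letter (two for
    common two-letter elements when unambiguous)."""
    stripped = "".join(c for c in atom_name if c.isalpha())
    if not stripped:
        raise SelectionError(f"cannot infer element from atom name {atom_name!r}")
    upper = stripped.upper()
    for two in ("CL", "BR", "SE", "NA", "MG", "ZN", "FE", "MN", "CU"):
        if upper == two:
            return two
    return upper[0]


class Trajectory:
    """Frames of coordinates tied to a topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; ``times`` is one
    nanosecond timestamp per frame, monotone nondecreasing.
    """

    def __init__(self, topology: Structure, frames: np.ndarray, times: np.ndarray | None = None):
        frames = np.asarray(frames, dtype=np.float64)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise DimensionError(f"frames must have shape (n_frames, n_atoms, 3), got {frames.shape}")
        if frames.shape[0] < 1:
            raise DimensionError("a Trajectory needs at least one frame")
        if frames.shape[1] != topology.n_atoms:
            raise DimensionError(
                f"frame atom count {frames.shape[1]} does not match "
                f"topology atom count {topology.n_atoms}"
            )
        if times is None:
            times = np.arange(frames.shape[0], dtype=np.float64)
        times = np.asarray(times, dtype=np.float64)
        if times.shape != (frames.shape[0],):
            raise DimensionError(
                f"times length {times.shape} does not match n_frames {frames.shape[0]}"
            )
        if np.any(np.diff(times) < 0):
            raise ConsistencyError("frame times must be monotone nondecreasing")
        self.topology = topology
        self.frames = frames
        self.times = times

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def slice_frames(self, start: int = 0, stop: int | None = None, step: int = 1) -> "Trajectory":
        """Sub-trajectory over a frame range (e.g. to drop an equilibration
        window).  Raises :class:`~tetrastab.errors.RangeError` if empty."""
        from .errors import RangeError

        frames = self.frames[start:stop:step]
        if frames.shape[0] == 0:
            raise RangeError(f"frame range [{start}:{stop}:{step}] selects no frames")
        return Trajectory(self.topology, frames, self.times[start:stop:step])

    def __repr__(self) -> str:
        return f"<Trajectory: {self.n_frames} frames x {self.n_atoms} atoms>"


@dataclass(frozen=True)
class ChainPairing:
    """Which chains form the primary dimers of the dimer-of-dimers
    (canonically A with B and C with D for the p53 tetramer)."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for a, b in self.pairs:
            if a == b:
                raise ConsistencyError(f"a chain cannot pair with itself: ({a}, {b})")
            for c in (a, b):
                if c in seen:
                    raise ConsistencyError(f"chain {c!r} appears in more than one pair")
                seen.add(c)

    def validate_against(self, structure: Structure) -> None:
        for a, b in self.pairs:
            for c in (a, b):
                if c not in structure.chain_ids:
                    raise ConsistencyError(
                        f"pairing names chain {c!r} absent from structure "
                        f"(has {structure.chain_ids})"
                    )

    @classmethod
    def from_string(cls, text: str) -> "ChainPairing":
        """Parse ``"A:B,C:D"``."""
        pairs = []
        for chunk in text.split(","):
            left, _, right = chunk.strip().partition(":")
            if not left or not right:
                raise ConsistencyError(f"malformed chain pair {chunk!r}; expected like 'A:B'")
            pairs.append((left.strip(), right.strip()))
        return cls(pairs=tuple(pairs))


@dataclass(frozen=True)
class SystemLabel:
    """Identity of a simulated system (WT, R337C, R337H_delta, ...).

    The name vocabulary is open: histidine-protonation variants of the same
    mutation are distinct systems, with the tautomer recorded in
    ``protonation_note``.
    """

    name: str
    protonation_note: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("SystemLabel.name must be nonempty")


@dataclass(frozen=True)
class MDProvenance:
    """Descriptive record of how an input trajectory was produced
    (force field, thermostat settings, ...).  Pure metadata: no analysis
    in this package reads it."""

    force_field: str = ""
    water_model: str = ""
    salt_mM: float = 0.0
    temperature_K: float = 0.0
    pressure_bar: float = 0.0
    timestep_fs: float = 0.0
    length_ns: float = 0.0
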