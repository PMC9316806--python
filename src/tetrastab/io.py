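"""Readers and writers for topologies and trajectories.

Topology comes in as PDB (parsed with biotite).  Trajectories come in two
dialects:

``dcd``
    The standard CHARMM/NAMD binary format, read and written through
    mdtraj's low-level ``DCDTrajectoryFile`` (coordinates are Å-native in
    DCD, so no unit conversion is needed).  DCD carries no absolute
    timestamps, so times are frame-index based (1 ns per frame) unless
    the caller overrides them.

``xyz_text``
    A plain-text multi-frame fixture dialect:

    .. code-block:: text

        natoms nframes
        t=<ns>
        chain resSeq resName atomName x y z     (natoms lines)
        t=<ns>
        ...

    Lossless at the declared decimal precision; used for small text
    fixtures and reproducible round trips.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np

from .core import AtomRecord, Structure, Trajectory, make_atom
from .errors import DimensionError, FormatError

logger = logging.getLogger(__name__)

TRAJECTORY_FORMATS = ("dcd", "xyz_text")


def read_pdb(path) -> Structure:
    """Parse a PDB file into a :class:`~tetrastab.core.Structure`.

    Only the first MODEL of a multi-model file is used (with a warning);
    alternate locations are resolved by keeping the blank/'A' altLoc.
    Coordinates are Å as in the file; masses come from the internal
    element table.
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    try:
        pdb_file = pdb.PDBFile.read(str(path))
    except OSError:
        raise
    except Exception as exc:  # biotite raises its own parse errors
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc

    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise FormatError(f"no ATOM/HETATM records in {path}")
    if n_models > 1:
        logger.warning("%s contains %d models; using the first only", path, n_models)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        arr = pdb_file.get_structure(model=1, altloc="first")
    if arr.array_length() == 0:
        raise FormatError(f"no ATOM/HETATM records in {path}")

    atoms: list[AtomRecord] = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]) or None
        name = str(arr.atom_name[i])
        chain = str(arr.chain_id[i]) or " "
        atoms.append(
            make_atom(
                serial=i + 1,
                atom_name=name,
                residue_name=str(arr.res_name[i]),
                chain_id=chain[0],
                residue_seq=int(arr.res_id[i]),
                xyz=arr.coord[i],
                element=element if element else None,
            )
        )
    structure = Structure(atoms)
    logger.info(
        "read_pdb: %s -> %d atoms, chains %s",
        path,
        structure.n_atoms,
        "".join(structure.chain_ids),
    )
    return structure


# ---------------------------------------------------------------------------
# trajectory I/O


def read_trajectory(topology: Structure, path, format: str = "xyz_text") -> Trajectory:
    """Read a trajectory and bind it to *topology*.

    Raises :class:`DimensionError` if the per-frame atom count disagrees
    with the topology, and :class:`FormatError` on zero frames.
    """
    path = Path(path)
    if format == "dcd":
        frames, times = _read_dcd(path)
    elif format == "xyz_text":
        frames, times = _read_xyz_text(path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}; choose from {TRAJECTORY_FORMATS}")

    if frames.shape[0] == 0:
        raise FormatError(f"trajectory {path} contains zero frames")
    if frames.shape[1] != topology.n_atoms:
        raise DimensionError(
            f"trajectory {path} has {frames.shape[1]} atoms per frame, "
            f"topology has {topology.n_atoms}"
        )
    traj = Trajectory(topology, frames, times)
    logger.info("read_trajectory: %s (%s) -> %d frames x %d atoms", path, format, traj.n_frames, traj.n_atoms)
    return traj


def write_trajectory(traj: Trajectory, path, format: str = "xyz_text", precision: int = 6) -> None:
    """Write a trajectory; ``read_trajectory`` round-trips it.

    For ``xyz_text`` the coordinates are written with *precision* decimals,
    so the round-trip error is bounded by half a unit in the last place
    (5e-4 Å at 3 decimals).
    """
    path = Path(path)
    if format == "dcd":
        _write_dcd(traj, path)
    elif format == "xyz_text":
        _write_xyz_text(traj, path, precision)
    else:
        raise ValueError(f"unknown trajectory format {format!r}; choose from {TRAJECTORY_FORMATS}")
    logger.info("write_trajectory: %s (%s) <- %d frames x %d atoms", path, format, traj.n_frames, traj.n_atoms)


def _read_dcd(path: Path) -> tuple[np.ndarray, np.ndarray]:
    from mdtraj.formats import DCDTrajectoryFile

    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    with DCDTrajectoryFile(str(path)) as f:
        xyz, _cell_lengths, _cell_angles = f.read()
    frames = np.asarray(xyz, dtype=np.float64)  # DCD stores Å natively
    times = np.arange(frames.shape[0], dtype=np.float64)
    return frames, times


def _write_dcd(traj: Trajectory, path: Path) -> None:
    from mdtraj.formats import DCDTrajectoryFile

    with DCDTrajectoryFile(str(path), "w") as f:
        f.write(traj.frames.astype(np.float32))


def _read_xyz_text(path: Path) -> tuple[np.ndarray, np.ndarray]:
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise FormatError(f"empty trajectory file {path}")
    header = lines[0].split()
    if len(header) != 2:
        raise FormatError(f"{path}: first line must be 'natoms nframes', got {lines[0]!r}")
    try:
        natoms, nframes = int(header[0]), int(header[1])
    except ValueError:
        raise FormatError(f"{path}: non-integer header {lines[0]!r}") from None
    if nframes < 1:
        raise FormatError(f"{path} declares zero frames")

    frames = np.empty((nframes, natoms, 3), dtype=np.float64)
    times = np.empty(nframes, dtype=np.float64)
    pos = 1
    for fi in range(nframes):
        if pos >= len(lines):
            raise FormatError(f"{path}: truncated at frame {fi}")
        tline = lines[pos].strip()
        if not tline.startswith("t="):
            raise FormatError(f"{path}: expected 't=<ns>' line at frame {fi}, got {tline!r}")
        try:
            times[fi] = float(tline[2:])
        except ValueError:
            raise FormatError(f"{path}: bad time {tline!r} at frame {fi}") from None
        pos += 1
        for ai in range(natoms):
            if pos >= len(lines):
                raise FormatError(f"{path}: truncated in frame {fi}, atom {ai}")
            parts = lines[pos].split()
            if len(parts) != 7:
                raise FormatError(
                    f"{path}: atom line must be 'chain resSeq resName atomName x y z', "
                    f"got {lines[pos]!r}"
                )
            try:
                frames[fi, ai] = [float(parts[4]), float(parts[5]), float(parts[6])]
            except ValueError:
                raise FormatError(f"{path}: bad coordinates in {lines[pos]!r}") from None
            pos += 1
    return frames, times


def _write_xyz_text(traj: Trajectory, path: Path, precision: int) -> None:
    top = traj.topology
    fmt = f"{{:.{precision}f}}"
    with open(path, "w") as fh:
        fh.write(f"{traj.n_atoms} {traj.n_frames}\n")
        for fi in range(traj.n_frames):
            fh.write(f"t={traj.times[fi]:.6f}\n")
            frame = traj.frames[fi]
            for ai, atom in enumerate(top.atoms):
                x, y, z = (fmt.format(v) for v in frame[ai])
                fh.write(
                    f"{atom.chain_id} {atom.residue_seq} {atom.residue_name} "
                    f"{atom.atom_name} {x} {y} {z}\n"
                )


def write_pdb(structure: Structure, path) -> None:
    """Write a minimal ATOM-record PDB (fixed columns, TER between chains)."""
    path = Path(path)
    with open(path, "w") as fh:
        prev_chain = None
        for atom in structure.atoms:
            if prev_chain is not None and atom.chain_id != prev_chain:
                fh.write("TER\n")
            prev_chain = atom.chain_id
            name = atom.atom_name
            # PDB column convention: 1-3 char names start in column 14
            name_field = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = atom.coords
            fh.write(
                f"ATOM  {atom.serial:>5d} {name_field}{'':1s}{atom.residue_name:>3s} "
                f"{atom.chain_id}{atom.residue_seq:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{atom.element:>2s}\n"
            )
        fh.write("TER\nEND\n")
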