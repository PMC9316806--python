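"""Synthetic tetramer structures, trajectories, and reporter plates with
known ground truth.

The generator is a *statistical fixture factory*, not an MD engine: it
builds an idealized four-helix bundle whose geometry encodes the
dimer-of-dimers salt-bridge architecture of the p53 tetramerization
domain (reciprocal Arg-like/Asp-like functional groups 3.5 Å apart
across each primary dimer), then perturbs it with models simple enough
to have closed-form expectations:

* iid per-coordinate Gaussian fluctuation of scale sigma — the minimized
  RMSD against the clean reference then concentrates at sqrt(3)·sigma
  for large atom counts;
* ``drift_open``: the second chain of each selected pair translates
  along the interface normal, linearly from 0 to ``open_shift`` over the
  trajectory (a progressively separating interface);
* ``two_state``: per-frame Bernoulli bound/unbound with the unbound
  state shifted by ``open_shift`` (a bridge that breaks and reforms),
  so occupancy estimates have an exact binomial reference;
* a rigidly displaced residue segment, for contact-difference flagging.

Reporter plates mirror the multiplicative structure of an OD-normalized
luminescence assay: reads are OD x (background + dose-scaled allele
activity) x lognormal noise, with empty-vector wells carrying activity 0.

Everything is reproducible from an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ChainPairing, Structure, Trajectory, make_atom
from .errors import ConfigError, ConstructionError

#: Allele label of empty-vector control wells in plate tables.
EMPTY_ALLELE = "EMPTY"

#: In-reference COM-COM distance of each bridge site, Å.
_BRIDGE_DISTANCE = 3.5


@dataclass(frozen=True)
class ToyTetramerSpec:
    """Geometry of the idealized four-helix bundle.

    Residues are author-numbered from ``first_residue`` (default 320, so
    the default 41-residue chains span 320-360 and the bridge positions
    can be addressed as 337/352, mirroring canonical p53 numbering).
    ``bridge_positions`` is (Arg-like position, Asp-like position).
    """

    n_res_per_chain: int = 41
    first_residue: int = 320
    helix_rise: float = 1.5
    helix_radius: float = 2.3
    turn_deg: float = 100.0
    bundle_radius: float = 8.5
    bridge_positions: tuple[int, int] = (337, 352)
    chain_ids: tuple[str, str, str, str] = ("A", "B", "C", "D")

    def __post_init__(self) -> None:
        if self.n_res_per_chain < 10:
            raise ValueError("n_res_per_chain must be >= 10")
        if len(set(self.chain_ids)) != 4:
            raise ValueError("need four distinct chain ids")
        lo = self.first_residue
        hi = self.first_residue + self.n_res_per_chain - 1
        for pos in self.bridge_positions:
            if not (lo <= pos <= hi):
                raise ValueError(f"bridge position {pos} outside residue range [{lo}, {hi}]")
        if self.bridge_positions[0] == self.bridge_positions[1]:
            raise ValueError("bridge positions must differ")

    @property
    def pairing(self) -> ChainPairing:
        a, b, c, d = self.chain_ids
        return ChainPairing(pairs=((a, b), (c, d)))


# offsets (local frame) of group atoms; shifted so the mass-weighted COM
# lands exactly on the designated center
_ARG_GROUP = (("NE", "N", (0.0, 0.0, -0.65)), ("CZ", "C", (0.0, 0.0, 0.0)),
              ("NH1", "N", (0.0, 0.55, 0.55)), ("NH2", "N", (0.0, -0.55, 0.55)))
_ASP_GROUP = (("CG", "C", (0.0, 0.0, 0.0)), ("OD1", "O", (0.0, 0.55, 0.45)),
              ("OD2", "O", (0.0, -0.55, 0.45)))


def _chain_axis_xy(spec: ToyTetramerSpec, k: int) -> np.ndarray:
    theta = np.deg2rad(90.0 * k + 45.0)
    return spec.bundle_radius * np.array([np.cos(theta), np.sin(theta)])


def _ca_position(spec: ToyTetramerSpec, k: int, i: int) -> np.ndarray:
    """Cα of residue index i (0-based) of chain index k; chains at odd
    k run antiparallel (descending z)."""
    axis = _chain_axis_xy(spec, k)
    phi = np.deg2rad(spec.turn_deg * i)
    z = (i - (spec.n_res_per_chain - 1) / 2.0) * spec.helix_rise
    if k % 2 == 1:
        z = -z
    return np.array([
        axis[0] + spec.helix_radius * np.cos(phi),
        axis[1] + spec.helix_radius * np.sin(phi),
        z,
    ])


def _place_group(template, center: np.ndarray, u: np.ndarray, masses_of) -> list[tuple[str, str, np.ndarray]]:
    """Place template atoms in the local frame (u = interface normal,
    w = horizontal perpendicular, z = bundle axis), then shift so the
    mass-weighted COM is exactly *center*."""
    w = np.array([-u[1], u[0], 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    raw = []
    masses = []
    for name, element, (du, dw, dz) in template:
        pos = center + du * u + dw * w + dz * ez
        raw.append((name, element, pos))
        masses.append(masses_of(element))
    m = np.asarray(masses)
    com = sum(mi * p for mi, (_, _, p) in zip(m, raw)) / m.sum()
    shift = center - com
    return [(name, element, pos + shift) for name, element, pos in raw]


def make_toy_tetramer(spec: ToyTetramerSpec = ToyTetramerSpec(), seed: int = 0) -> Structure:
    """Idealized four-helix bundle with salt-bridge functional groups.

    Four helical Cα traces sit antiparallel on a cylinder of
    ``bundle_radius``; the Arg-like position of each chain carries a
    guanidinium-like group (NE, CZ, NH1, NH2) and the Asp-like position a
    carboxylate-like group (CG, OD1, OD2), placed so that across each
    primary dimer the two reciprocal group-COM distances are exactly
    3.5 Å in the reference.  Construction is deterministic; *seed* is
    accepted for interface symmetry with the simulators.

    This structure also serves as the package's synthetic stand-in for
    deposited tetramerization-domain coordinates: synthetic geometry, not
    experimental data.
    """
    from .masses import mass_of

    arg_pos, asp_pos = spec.bridge_positions
    n = spec.n_res_per_chain

    atoms = []
    serial = 1

    # backbone Cα traces; bridge residues named ARG/ASP, others GLY
    ca_xyz: dict[tuple[str, int], np.ndarray] = {}
    for k, ch in enumerate(spec.chain_ids):
        for i in range(n):
            res_seq = spec.first_residue + i
            if res_seq == arg_pos:
                rname = "ARG"
            elif res_seq == asp_pos:
                rname = "ASP"
            else:
                rname = "GLY"
            pos = _ca_position(spec, k, i)
            ca_xyz[(ch, res_seq)] = pos
            atoms.append(make_atom(serial, "CA", rname, ch, res_seq, pos, element="C"))
            serial += 1

    # two reciprocal bridge sites per primary dimer
    group_atoms: list = []
    for x, y in spec.pairing.pairs:
        kx = spec.chain_ids.index(x)
        ky = spec.chain_ids.index(y)
        ax, ay = _chain_axis_xy(spec, kx), _chain_axis_xy(spec, ky)
        mid = 0.5 * (ax + ay)
        u3 = np.array([ay[0] - ax[0], ay[1] - ax[1], 0.0])
        u3 /= np.linalg.norm(u3)

        for arg_chain, asp_chain, sign in ((x, y, -1.0), (y, x, +1.0)):
            z_site = 0.5 * (ca_xyz[(arg_chain, arg_pos)][2] + ca_xyz[(asp_chain, asp_pos)][2])
            m3 = np.array([mid[0], mid[1], z_site])
            c_arg = m3 + sign * (_BRIDGE_DISTANCE / 2.0) * u3
            c_asp = m3 - sign * (_BRIDGE_DISTANCE / 2.0) * u3
            group_atoms.append((arg_chain, arg_pos, _place_group(_ARG_GROUP, c_arg, u3, mass_of)))
            group_atoms.append((asp_chain, asp_pos, _place_group(_ASP_GROUP, c_asp, u3, mass_of)))

    all_ca = np.array(list(ca_xyz.values()))
    for ch, res_seq, placed in group_atoms:
        for name, element, pos in placed:
            dmin = float(np.min(np.linalg.norm(all_ca - pos, axis=1)))
            if dmin < 1.2:
                raise ConstructionError(
                    f"functional-group atom {name} of ({ch}, {res_seq}) would "
                    f"overlap the backbone (min Cα distance {dmin:.2f} Å); "
                    "widen bundle_radius"
                )
            atoms.append(make_atom(serial, name, "ARG" if name.startswith(("N", "CZ")) else "ASP",
                                   ch, res_seq, pos, element=element))
            serial += 1

    return Structure(atoms)


@dataclass(frozen=True)
class TrajectorySimConfig:
    """Perturbation model applied to a reference structure.

    ``sigma`` is the per-coordinate Gaussian fluctuation (Å).  In mode
    ``drift_open`` the second chain of each pair in ``open_pairs``
    translates along the interface normal from 0 to ``open_shift`` (Å)
    linearly over the frames; in ``two_state`` the shift is applied in
    the frames sampled unbound (probability ``1 - bound_prob``).  The
    default ``open_shift`` of 5.5 Å takes a 3.5 Å bridge to a 9 Å
    separated state.  ``perturbed_segment`` rigidly displaces a residue
    range of one chain radially outward in every frame.
    """

    n_frames: int = 200
    sigma: float = 0.5
    mode: str = "stable"  # stable | drift_open | two_state
    open_pairs: tuple[tuple[str, str], ...] = ()
    bound_prob: float = 0.7
    open_shift: float = 5.5
    perturbed_segment: tuple[str, tuple[int, int], float] | None = None
    frame_dt_ns: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.mode not in ("stable", "drift_open", "two_state"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.bound_prob <= 1.0):
            raise ValueError("bound_prob must lie in [0, 1]")
        if self.open_shift < 0:
            raise ValueError("open_shift must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """The simulation config echoed, plus the expectations it implies.

    ``expected_mean_rmsd`` is the large-atom-count limit sqrt(3)·sigma of
    the minimized Cα RMSD against the *clean* reference structure.
    ``expected_occupancy`` maps arrangement labels to the exact fraction
    of frames whose nominal (noise-free) bridge distance is at or below
    ``occupancy_cutoff``, computed from the realized state sequence.
    """

    config: TrajectorySimConfig
    expected_mean_rmsd: float
    occupancy_cutoff: float
    expected_occupancy: dict[str, float]
    perturbed_residues: tuple[tuple[str, int], ...]


def simulate_trajectory(
    structure: Structure,
    config: TrajectorySimConfig,
    spec: ToyTetramerSpec = ToyTetramerSpec(),
    occupancy_cutoff: float = 6.0,
) -> tuple[Trajectory, GroundTruth]:
    """Simulate frames around *structure* under *config*.

    Fully reproducible: the same structure, config and spec give
    bit-identical output.  Raises :class:`ConfigError` if ``open_pairs``
    names chains absent from the structure.
    """
    problems = [
        f"open pair ({x}, {y}) names a chain absent from the structure"
        for x, y in config.open_pairs
        for c in (x, y)
        if c not in structure.chain_ids
    ]
    if problems:
        raise ConfigError(problems)

    rng = np.random.default_rng(config.seed)
    n_frames = config.n_frames
    ref = structure.coords
    frames = ref[None, :, :] + rng.normal(0.0, config.sigma, size=(n_frames, ref.shape[0], 3))

    # per-frame shift magnitude of each opening pair's second chain
    if config.mode == "drift_open" and config.open_pairs:
        ramp = (
            np.linspace(0.0, config.open_shift, n_frames)
            if n_frames > 1
            else np.array([config.open_shift])
        )
        shifts = ramp
        bound_mask = None
    elif config.mode == "two_state" and config.open_pairs:
        bound_mask = rng.random(n_frames) < config.bound_prob
        shifts = np.where(bound_mask, 0.0, config.open_shift)
    else:
        shifts = np.zeros(n_frames)
        bound_mask = None

    chain_atom_idx = {
        ch: np.asarray([i for i, a in enumerate(structure.atoms) if a.chain_id == ch], dtype=np.intp)
        for ch in structure.chain_ids
    }

    opened_pairs = config.open_pairs if config.mode in ("drift_open", "two_state") else ()
    for x, y in opened_pairs:
        kx = spec.chain_ids.index(x)
        ky = spec.chain_ids.index(y)
        ax, ay = _chain_axis_xy(spec, kx), _chain_axis_xy(spec, ky)
        u3 = np.array([ay[0] - ax[0], ay[1] - ax[1], 0.0])
        u3 /= np.linalg.norm(u3)
        frames[:, chain_atom_idx[y], :] += shifts[:, None, None] * u3[None, None, :]

    perturbed: list[tuple[str, int]] = []
    if config.perturbed_segment is not None:
        ch, (lo, hi), disp = config.perturbed_segment
        if ch not in structure.chain_ids:
            raise ConfigError([f"perturbed segment names absent chain {ch!r}"])
        k = spec.chain_ids.index(ch)
        axis = _chain_axis_xy(spec, k)
        radial = np.array([axis[0], axis[1], 0.0])
        radial /= np.linalg.norm(radial)
        idx = np.asarray(
            [i for i, a in enumerate(structure.atoms) if a.chain_id == ch and lo <= a.residue_seq <= hi],
            dtype=np.intp,
        )
        frames[:, idx, :] += disp * radial[None, None, :]
        perturbed = [(ch, seq) for seq in range(lo, hi + 1) if (ch, seq) in structure.residue_index]

    times = np.arange(n_frames, dtype=np.float64) * config.frame_dt_ns
    traj = Trajectory(structure, frames, times)

    arg_pos, asp_pos = spec.bridge_positions
    opened = {frozenset(p) for p in opened_pairs}
    expected_occ: dict[str, float] = {}
    for x, y in spec.pairing.pairs:
        if frozenset((x, y)) in opened:
            nominal = _BRIDGE_DISTANCE + shifts
            occ = float(np.mean(nominal <= occupancy_cutoff))
        else:
            occ = 1.0 if _BRIDGE_DISTANCE <= occupancy_cutoff else 0.0
        expected_occ[f"{arg_pos}.{x}-{asp_pos}.{y}"] = occ
        expected_occ[f"{arg_pos}.{y}-{asp_pos}.{x}"] = occ

    truth = GroundTruth(
        config=config,
        expected_mean_rmsd=float(np.sqrt(3.0) * config.sigma),
        occupancy_cutoff=occupancy_cutoff,
        expected_occupancy=expected_occ,
        perturbed_residues=tuple(perturbed),
    )
    return traj, truth


def simulate_reporter_plate(
    alleles: list[str],
    doses: list[float],
    effects: dict[str, float],
    background: float = 10.0,
    noise_cv: float = 0.1,
    n_transformants: int = 5,
    seed: int = 0,
    strains: tuple[str, ...] = ("p21-5p",),
    od_range: tuple[float, float] = (0.3, 0.8),
) -> pd.DataFrame:
    """Synthetic luminescence/OD plate table.

    Each well reads ``luminescence = OD x (background + dose_scale x
    activity) x lognormal(cv)`` with OD uniform in *od_range*.  The
    default background of 10 models a low reporter-independent
    expression, an order of magnitude under a strong allele's activity
    on the default scale of 100.  ``dose_scale`` is ``dose /
    max(doses)`` (1 when all doses are 0), and activity is 0 for the
    included empty-vector wells.  The lognormal noise
    factor has mean 1 and coefficient of variation *noise_cv*, so the
    noiseless plate (``noise_cv=0``) round-trips exactly through
    OD normalization and background subtraction.

    Columns: allele, reporter_strain, galactose_pct, transformant_id,
    luminescence, od600.
    """
    if n_transformants < 1:
        raise ValueError("n_transformants must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    missing = [a for a in alleles if a not in effects]
    if missing:
        raise ValueError(f"no activity effect declared for alleles: {missing}")

    rng = np.random.default_rng(seed)
    max_dose = max(doses) if doses and max(doses) > 0 else None
    sigma_ln = float(np.sqrt(np.log1p(noise_cv**2)))

    rows = []
    for strain in strains:
        for dose in doses:
            scale = 1.0 if max_dose is None else dose / max_dose
            for allele in list(alleles) + [EMPTY_ALLELE]:
                activity = 0.0 if allele == EMPTY_ALLELE else effects[allele] * scale
                for t in range(1, n_transformants + 1):
                    od = float(rng.uniform(*od_range))
                    if noise_cv > 0:
                        noise = float(rng.lognormal(-0.5 * sigma_ln**2, sigma_ln))
                    else:
                        noise = 1.0
                    lum = od * (background + activity) * noise
                    rows.append(
                        {
                            "allele": allele,
                            "reporter_strain": strain,
                            "galactose_pct": float(dose),
                            "transformant_id": t,
                            "luminescence": lum,
                            "od600": od,
                        }
                    )
    return pd.DataFrame(rows)
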