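"""Per-system stability profiles and WT-referenced destabilization calls.

This stage aggregates the three structural readouts — RMSD distribution,
salt-bridge occupancies, contact-map divergence — into one profile per
system and a rule-based comparison against a reference (WT) system.  The
comparison is an explicit operationalization of qualitative reasoning:
a system is called destabilized when its mean RMSD rises enough, when
the bridge is lost in at least two of the four ordered arrangements, or
when contact-map flagging fires.  All three thresholds are configuration,
never hidden constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import DifferenceMap, flag_divergent_residues
from .core import SystemLabel
from .errors import ConsistencyError
from .saltbridge import ArrangementDistanceSeries, OccupancyResult, saltbridge_occupancy
from .superpose import RMSDSeries


@dataclass(frozen=True)
class ReportConfig:
    """Thresholds of the destabilization call.

    ``t_rmsd``: mean-RMSD excess over reference (Å) that counts as drift.
    ``t_occ``: occupancy loss per arrangement that counts as a broken bridge.
    ``min_lost_arrangements``: how many broken arrangements trigger the call
    (default 2: an interface is lost in at least two residue pairs).
    ``t_flag``: number of contact-flagged residues that triggers the call.
    ``flag_threshold``: contact-difference threshold for flagging.
    ``occupancy_cutoff``: COM–COM distance cutoff (Å) for occupancy.
    """

    t_rmsd: float = 0.5
    t_occ: float = 0.3
    min_lost_arrangements: int = 2
    t_flag: int = 1
    flag_threshold: float = 0.25
    occupancy_cutoff: float = 4.5


@dataclass(frozen=True)
class StabilityProfile:
    """One system's structural readouts in comparable form."""

    system: SystemLabel
    mean_rmsd: float
    rmsd_std: float
    occupancies: tuple[OccupancyResult, ...]
    n_flagged_residues: int
    mean_abs_contact_diff: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_abs_contact_diff <= 1.0):
            raise ValueError("mean_abs_contact_diff must lie in [0, 1]")


@dataclass(frozen=True)
class DestabilizationComparison:
    """Target-vs-reference deltas and the rule-based verdict."""

    target: SystemLabel
    reference: SystemLabel
    delta_mean_rmsd: float
    min_occupancy_loss: float
    n_lost_arrangements: int
    n_flagged: int
    verdict: str  # "WT_like" | "destabilized"


def build_profile(
    system: SystemLabel,
    rmsd: RMSDSeries,
    sb: list[ArrangementDistanceSeries],
    diff: DifferenceMap | None,
    config: ReportConfig = ReportConfig(),
) -> StabilityProfile:
    """Aggregate one system's series into a :class:`StabilityProfile`.

    *diff* is the system's contact difference against the reference; pass
    ``None`` for the reference system itself (zero divergence by
    definition).
    """
    if diff is not None and diff.target_system not in ("target", system.name):
        raise ConsistencyError(
            f"difference map is for system {diff.target_system!r}, "
            f"profile is for {system.name!r}"
        )
    occupancies = tuple(saltbridge_occupancy(s, config.occupancy_cutoff) for s in sb)
    if diff is None:
        n_flagged = 0
        mean_diff = 0.0
    else:
        report = flag_divergent_residues(diff, config.flag_threshold)
        n_flagged = len(report.flagged_residues)
        off = ~np.eye(diff.matrix.shape[0], dtype=bool)
        mean_diff = float(diff.matrix[off].mean()) if off.any() else 0.0
    return StabilityProfile(
        system=system,
        mean_rmsd=float(np.mean(rmsd.values)),
        rmsd_std=float(np.std(rmsd.values)),
        occupancies=occupancies,
        n_flagged_residues=n_flagged,
        mean_abs_contact_diff=mean_diff,
    )


def compare_systems(
    target: StabilityProfile,
    reference: StabilityProfile,
    config: ReportConfig = ReportConfig(),
) -> DestabilizationComparison:
    """Rule-based destabilization call of *target* against *reference*.

    destabilized iff any of:
      * mean RMSD exceeds the reference's by >= ``t_rmsd``;
      * occupancy dropped by >= ``t_occ`` in >= ``min_lost_arrangements``
        ordered arrangements;
      * >= ``t_flag`` residues flagged in the contact difference.
    """
    t_labels = [o.label for o in target.occupancies]
    r_labels = [o.label for o in reference.occupancies]
    if t_labels != r_labels:
        raise ConsistencyError(
            f"arrangement sets differ between profiles: {t_labels} vs {r_labels}"
        )
    delta_rmsd = target.mean_rmsd - reference.mean_rmsd
    losses = [r.fraction - t.fraction for t, r in zip(target.occupancies, reference.occupancies)]
    n_lost = sum(1 for loss in losses if loss >= config.t_occ)
    min_loss = float(min(losses)) if losses else 0.0
    destabilized = (
        delta_rmsd >= config.t_rmsd
        or n_lost >= config.min_lost_arrangements
        or target.n_flagged_residues >= config.t_flag
    )
    return DestabilizationComparison(
        target=target.system,
        reference=reference.system,
        delta_mean_rmsd=float(delta_rmsd),
        min_occupancy_loss=min_loss,
        n_lost_arrangements=int(n_lost),
        n_flagged=target.n_flagged_residues,
        verdict="destabilized" if destabilized else "WT_like",
    )


def _severity(cmp: DestabilizationComparison, key: str) -> tuple:
    if key == "delta_mean_rmsd":
        return (cmp.delta_mean_rmsd,)
    if key == "composite":
        n_criteria = (cmp.verdict == "destabilized") + cmp.n_lost_arrangements
        return (n_criteria, cmp.n_flagged, cmp.delta_mean_rmsd)
    raise ValueError(f"ranking key must be 'delta_mean_rmsd' or 'composite', got {key!r}")


def rank_systems(
    comparisons: list[DestabilizationComparison],
    key: str = "delta_mean_rmsd",
) -> list[DestabilizationComparison]:
    """Stable sort, most destabilized first; ties broken by system name
    (lexicographic ascending)."""
    refs = {c.reference.name for c in comparisons}
    if len(refs) > 1:
        raise ConsistencyError(f"comparisons use mixed references: {sorted(refs)}")
    return sorted(
        comparisons,
        key=lambda c: tuple(-v for v in _severity(c, key)) + (c.target.name,),
    )
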