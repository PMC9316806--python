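"""Normalized histograms with summary statistics, shared by the RMSD and
inter-chain distance analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Distribution:
    """A density-normalized histogram over a 1-D series (units: Å here).

    ``densities`` integrates to 1 over the bins; ``mode_bin_center`` is the
    center of the highest-density bin (leftmost on ties).
    """

    bin_edges: np.ndarray
    densities: np.ndarray
    mean: float
    median: float
    std: float
    mode_bin_center: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def histogram_distribution(values, n_bins: int, hist_range: tuple[float, float] | None = None) -> Distribution:
    """Density histogram plus summary stats of a nonempty series.

    *hist_range* lets several systems share bin edges (pooled min/max) so
    their distributions are directly overlayable.  A constant series (or a
    degenerate range) gets a single bin of width 1 centered on the value,
    so that the density still integrates to 1.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot build a distribution from an empty series")
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")

    lo, hi = hist_range if hist_range is not None else (float(values.min()), float(values.max()))
    if hi <= lo:  # constant series: one unit-width bin around the value
        lo, hi = lo - 0.5, lo + 0.5
        n_bins = 1
    densities, edges = np.histogram(values, bins=n_bins, range=(lo, hi), density=True)
    imode = int(np.argmax(densities))
    return Distribution(
        bin_edges=edges,
        densities=densities,
        mean=float(values.mean()),
        median=float(np.median(values)),
        std=float(values.std()),
        mode_bin_center=float(0.5 * (edges[imode] + edges[imode + 1])),
    )
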