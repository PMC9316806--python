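"""Independent oracles used by the tests.

The rotation-grid RMSD oracle searches proper rotations on an Euler-angle
grid (with hierarchical refinement) after matching centroids, entirely
independent of the SVD-based implementation it checks.
"""

import numpy as np
from scipy.spatial.transform import Rotation


def grid_rmsd_oracle(mobile, reference, coarse_deg=10.0, refinements=3):
    """Brute-force minimum RMSD over proper rotations.

    Returns ``(rmsd, resolution_deg)`` where *resolution_deg* is the final
    grid step; the true minimum lies within ``max_radius * step`` (radians)
    of the reported value.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    n = x.shape[0]

    def best_over(alphas, betas, gammas):
        grid = np.stack(np.meshgrid(alphas, betas, gammas, indexing="ij"), axis=-1).reshape(-1, 3)
        rots = Rotation.from_euler("zyz", grid, degrees=True)
        best = (np.inf, (0.0, 0.0, 0.0))
        # chunk to bound memory
        for start in range(0, len(grid), 4096):
            sl = slice(start, start + 4096)
            mats = rots[sl].as_matrix()
            rotated = np.einsum("rij,nj->rni", mats, x)
            msd = ((rotated - y[None]) ** 2).sum(axis=(1, 2)) / n
            k = int(np.argmin(msd))
            if msd[k] < best[0]:
                best = (float(msd[k]), tuple(grid[sl][k]))
        return np.sqrt(best[0]), best[1]

    step = coarse_deg
    rmsd, (a, b, g) = best_over(
        np.arange(0.0, 360.0, step), np.arange(0.0, 180.0 + step, step), np.arange(0.0, 360.0, step)
    )
    for _ in range(refinements):
        new_step = step / 5.0
        offs = np.arange(-step, step + 1e-9, new_step)
        rmsd, (a, b, g) = best_over(a + offs, b + offs, g + offs)
        step = new_step
    return rmsd, step
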