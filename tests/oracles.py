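"""Independent oracles used by the test suite.

These deliberately avoid the code paths they validate: the superposition
oracle minimizes RMSD by brute force over a dense rotation grid (with a
local polish), never touching the SVD solution.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_min_rmsd(P: np.ndarray, Q: np.ndarray, grid_deg: float = 6.0) -> float:
    """Minimum RMSD of R@(P-Pc)+t vs Q over rigid transforms, by search.

    Dense Euler-angle grid (``grid_deg`` spacing) followed by Nelder-Mead
    polishes started from the best grid points (multi-start escapes basin
    boundaries of the coarse grid).  The optimal translation for any
    rotation aligns the centroids, so only rotations are searched.
    """
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    n = len(P0)

    a = np.deg2rad(np.arange(0.0, 360.0, grid_deg))
    b = np.deg2rad(np.arange(0.0, 180.0 + grid_deg, grid_deg))
    grid = np.array(np.meshgrid(a, b, a, indexing="ij")).reshape(3, -1).T
    mats = Rotation.from_euler("zyz", grid).as_matrix()
    moved = np.einsum("rij,nj->rni", mats, P0)
    rmsds = np.sqrt(((moved - Q0) ** 2).sum(axis=(1, 2)) / n)

    def objective(rv: np.ndarray) -> float:
        diff = P0 @ Rotation.from_rotvec(rv).as_matrix().T - Q0
        return float(np.sqrt((diff**2).sum() / n))

    best = float(rmsds.min())
    for k in np.argsort(rmsds)[:3]:
        res = minimize(
            objective,
            Rotation.from_euler("zyz", grid[int(k)]).as_rotvec(),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        best = min(best, float(res.fun))
    return best
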