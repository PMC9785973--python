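"""Shared fixtures and independent oracle implementations.

The oracles here deliberately use brute-force / alternative algorithms
(direct lag loops, 27-image pair scans, half-space intersections) so that
package results are checked against independent code paths.
"""

from itertools import product

import numpy as np
import pytest
from scipy.spatial import ConvexHull, HalfspaceIntersection

from hydrolayer import Topology


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def direct_acf(series: np.ndarray, max_lag_idx: int) -> np.ndarray:
    """O(N^2) lag-loop autocorrelation, pooled over columns, all origins."""
    series = np.atleast_2d(series.T).T
    n = series.shape[0]
    out = np.empty(max_lag_idx + 1)
    for k in range(max_lag_idx + 1):
        out[k] = (series[: n - k] * series[k:]).sum() / ((n - k) * series.shape[1])
    return out


def brute_force_surface_distances(water_o: np.ndarray, solute: np.ndarray,
                                  box: np.ndarray) -> np.ndarray:
    """All-pairs minimum over solute atoms and their 27 periodic images
    (sites wrapped into the primary box first so one image shell suffices)."""
    water_o = water_o - box * np.floor(water_o / box)
    solute = solute - box * np.floor(solute / box)
    shifts = np.array(list(product((-1, 0, 1), repeat=3)), dtype=float) * box
    images = (solute[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    d = np.linalg.norm(water_o[:, None, :] - images[None, :, :], axis=-1)
    return d.min(axis=1)


def halfspace_voronoi_volumes(points: np.ndarray, box: np.ndarray,
                              n_neighbors: int = 60) -> np.ndarray:
    """Periodic Voronoi volumes via half-space intersection of bisector planes
    (independent of the vertex/convex-hull route used by the package)."""
    points = np.asarray(points, dtype=float)
    box = np.asarray(box, dtype=float)
    pts = points - box * np.floor(points / box)
    n = pts.shape[0]
    shift_tuples = list(product((-1, 0, 1), repeat=3))
    images = np.concatenate([pts + box * np.asarray(s, dtype=float)
                             for s in shift_tuples])
    central_offset = shift_tuples.index((0, 0, 0)) * n
    vols = np.empty(n)
    for i in range(n):
        p = pts[i]
        others = np.delete(images, central_offset + i, axis=0)
        d = np.linalg.norm(others - p, axis=1)
        others = others[np.argsort(d)[:n_neighbors]]
        normals = others - p  # bisector planes in the frame centred on p
        offsets = -0.5 * (normals * normals).sum(axis=1)
        hs = HalfspaceIntersection(np.hstack([normals, offsets[:, None]]),
                                   np.zeros(3))
        vols[i] = ConvexHull(hs.intersections).volume
    return vols


# --------------------------------------------------------------------------
# topology builders
# --------------------------------------------------------------------------

def solute_plus_waters_topology(n_solute: int, n_waters: int,
                                charges=(-0.82, 0.41)) -> Topology:
    qO, qH = charges
    n = n_solute + 3 * n_waters
    element = np.array(["C"] * n_solute
                       + ["O", "H", "H"] * n_waters, dtype=object)
    mass = np.array([12.011] * n_solute + [15.999, 1.008, 1.008] * n_waters)
    charge = np.array([0.0] * n_solute + [qO, qH, qH] * n_waters)
    mol = np.concatenate([np.zeros(n_solute, dtype=int),
                          np.repeat(np.arange(n_waters) + 1, 3)])
    role = np.array(["protein"] * n_solute + ["water"] * (3 * n_waters),
                    dtype=object)
    return Topology(atom_id=np.arange(n), element=element, mass=mass,
                    charge=charge, molecule_id=mol, role=role)


@pytest.fixture()
def rng():
    # fresh generator per test: draws are deterministic and independent of
    # which other tests ran first
    return np.random.default_rng(20260928)
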