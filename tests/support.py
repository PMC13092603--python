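"""Shared test helpers and independent oracles.

The oracles deliberately avoid the package's own algorithms:

* GeodesicWrapOracle -- brute-force shortest path on a dense sphere-surface
  graph (fibonacci lattice, great-arc edge weights) plus free-space
  visibility edges, solved with Dijkstra.  Upper-bounds the true shortest
  wrapped path to well under 0.5 %.
* brute_force_sphere_fit -- coarse center grid followed by Nelder-Mead
  descent on the geometric residual (radius profiled out analytically).
* wilcoxon_exact_two_sided -- exhaustive 2^n sign-flip enumeration.
* friedman_chi2_direct / friedman_exact_perm_p -- textbook tie-corrected
  Friedman statistic and its exact row-permutation null.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize, sparse, stats
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from rsaplan.synthetic_cohort import GlenoidSurface, PatientAnatomy, TruePathology


# ---------------------------------------------------------------------------
# graph-geodesic wrapping oracle
# ---------------------------------------------------------------------------
def fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1)


class GeodesicWrapOracle:
    """Dense sphere-surface + visibility graph shortest-path solver."""

    def __init__(self, n_nodes: int = 20000, neighbor_rad: float = 0.15):
        self.n = n_nodes
        self.dirs = fibonacci_sphere(n_nodes)
        tree = cKDTree(self.dirs)
        self.pairs = tree.query_pairs(2.0 * np.sin(neighbor_rad / 2.0),
                                      output_type="ndarray")
        dots = np.einsum("ij,ij->i", self.dirs[self.pairs[:, 0]],
                         self.dirs[self.pairs[:, 1]])
        self.unit_arc = np.arccos(np.clip(dots, -1.0, 1.0))

    @staticmethod
    def _segments_clear(a: np.ndarray, B: np.ndarray, c: np.ndarray, r: float) -> np.ndarray:
        """True where the segment a->B[i] does not enter the open ball."""
        ab = B - a
        denom = np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-300)
        t = np.clip(((c - a) @ ab.T) / denom, 0.0, 1.0)
        closest = a + t[:, None] * ab
        return np.linalg.norm(closest - c, axis=1) >= r - 1e-9

    def shortest(self, p, q, center, radius) -> float:
        p = np.asarray(p, float)
        q = np.asarray(q, float)
        c = np.asarray(center, float)
        r = float(radius)
        nodes = c + r * self.dirs
        N = self.n
        rows = [self.pairs[:, 0]]
        cols = [self.pairs[:, 1]]
        w = [r * self.unit_arc]
        for idx, endpoint in ((N, p), (N + 1, q)):
            ok = np.where(self._segments_clear(endpoint, nodes, c, r))[0]
            rows.append(np.full(len(ok), idx))
            cols.append(ok)
            w.append(np.linalg.norm(nodes[ok] - endpoint, axis=1))
        if self._segments_clear(p, q[None, :], c, r)[0]:
            rows.append(np.array([N]))
            cols.append(np.array([N + 1]))
            w.append(np.array([float(np.linalg.norm(q - p))]))
        g = sparse.coo_matrix(
            (np.concatenate(w), (np.concatenate(rows), np.concatenate(cols))),
            shape=(N + 2, N + 2)).tocsr()
        dist = dijkstra(g, directed=False, indices=N)
        return float(dist[N + 1])


# ---------------------------------------------------------------------------
# brute-force sphere fit oracle
# ---------------------------------------------------------------------------
def brute_force_sphere_fit(points: np.ndarray) -> tuple:
    """(center, radius) minimizing sum((|p - c| - r)^2), by coarse grid over
    the center followed by Nelder-Mead descent; r profiled out as the mean
    distance for each candidate center."""
    pts = np.asarray(points, float)
    centroid = pts.mean(axis=0)
    r0 = float(np.mean(np.linalg.norm(pts - centroid, axis=1)))

    def cost(cvec):
        d = np.linalg.norm(pts - cvec, axis=1)
        return float(np.sum((d - d.mean()) ** 2))

    best, best_cost = centroid, cost(centroid)
    span = np.linspace(-0.8 * r0, 0.8 * r0, 9)
    for dx in span:
        for dy in span:
            for dz in span:
                cand = centroid + np.array([dx, dy, dz])
                cc = cost(cand)
                if cc < best_cost:
                    best, best_cost = cand, cc
    out = optimize.minimize(cost, best, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-16,
                                     "maxiter": 20000, "maxfev": 20000})
    center = out.x
    radius = float(np.mean(np.linalg.norm(pts - center, axis=1)))
    return center, radius


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------
def wilcoxon_exact_two_sided(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided signed-rank p by full 2^n sign enumeration (zero
    differences dropped, average ranks)."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    ws = np.array([float(np.dot(signs, ranks))
                   for signs in itertools.product([0.0, 1.0], repeat=n)])
    cdf = float(np.mean(ws <= w_obs + 1e-12))
    sf = float(np.mean(ws >= w_obs - 1e-12))
    return min(1.0, 2.0 * min(cdf, sf))


def friedman_chi2_direct(matrix: np.ndarray) -> float:
    """Tie-corrected Friedman statistic, written out from the textbook
    definition (independent of the package and of scipy's implementation)."""
    m = np.asarray(matrix, float)
    n, k = m.shape
    ranks = np.vstack([stats.rankdata(row) for row in m])
    col_sums = ranks.sum(axis=0)
    s = float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2))
    tie = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie += float(np.sum(counts ** 3 - counts))
    denom = n * k * (k + 1) / 12.0 - tie / (12.0 * (k - 1))
    return s / denom


def friedman_exact_perm_p(matrix: np.ndarray) -> float:
    """Exact permutation p-value of the Friedman statistic under row-wise
    exchangeability (enumerates (k!)^n within-row permutations)."""
    m = np.asarray(matrix, float)
    n, k = m.shape
    obs = friedman_chi2_direct(m)
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for combo in itertools.product(perms, repeat=n):
        pm = np.vstack([m[i, list(combo[i])] for i in range(n)])
        total += 1
        if friedman_chi2_direct(pm) >= obs - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# anatomy helpers
# ---------------------------------------------------------------------------
def transform_anatomy(a: PatientAnatomy, R: np.ndarray, t: np.ndarray) -> PatientAnatomy:
    """Apply a rigid transform (R, t) to every geometric element."""
    P = lambda p: np.asarray(np.atleast_2d(p) @ R.T + t).reshape(np.shape(p))
    D = lambda v: R @ np.asarray(v, float)
    truth = a.true_pathology
    return PatientAnatomy(
        patient_id=a.patient_id, side=a.side, diagnosis=a.diagnosis,
        hamada_grade=a.hamada_grade,
        scapular_landmarks={k: P(v) for k, v in a.scapular_landmarks.items()},
        humeral_head_points=P(a.humeral_head_points),
        glenoid_surface=GlenoidSurface(P(a.glenoid_surface.points),
                                       a.glenoid_surface.vault_depth_mm),
        anatomical_neck_plane=(P(a.anatomical_neck_plane[0]), D(a.anatomical_neck_plane[1])),
        greater_tuberosity_point=P(a.greater_tuberosity_point),
        premorbid_gt_point=P(a.premorbid_gt_point),
        humeral_shaft_axis=(P(a.humeral_shaft_axis[0]), D(a.humeral_shaft_axis[1])),
        muscle_sites={k: {"origin": P(v["origin"]), "insertion": P(v["insertion"])}
                      for k, v in a.muscle_sites.items()},
        true_pathology=TruePathology(
            subluxation_pct=truth.subluxation_pct,
            vault_loss_pct=truth.vault_loss_pct,
            erosion_depth_mm=truth.erosion_depth_mm,
            central_recession_mm=truth.central_recession_mm,
            premorbid_glenoid=GlenoidSurface(P(truth.premorbid_glenoid.points),
                                             truth.premorbid_glenoid.vault_depth_mm),
            head_radius_mm=truth.head_radius_mm,
            head_center=P(truth.head_center),
            premorbid_head_center=P(truth.premorbid_head_center),
            glenoid_inclination_deg=truth.glenoid_inclination_deg,
            glenoid_retroversion_deg=truth.glenoid_retroversion_deg,
        ),
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
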