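"""SMLM receptor-density analysis: NeNA precision, temporal linking,
DBSCAN clustering and cluster density per cell area.

The chain mirrors standard dSTORM post-processing: estimate the
experimental localization precision from nearest-neighbour displacements
between consecutive frames (NeNA), merge repeated localizations of the
same blinking event (link radius six times the NeNA value capped at
0.45 px, up to 5 dark frames), cluster the linked localizations with
DBSCAN (radius twice the NeNA value capped at 0.15 px, minimum 10
localizations) and report clusters per µm² of cell area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .presets import load_presets

__all__ = [
    "ClusterResult",
    "nena_precision",
    "link_localizations",
    "dbscan_clusters",
    "cluster_density",
    "link_radius_nm",
    "dbscan_eps_nm",
    "NOISE_LABEL",
]

NOISE_LABEL = -1


@dataclass
class ClusterResult:
    """DBSCAN labels (noise = -1), cluster count and density."""

    labels: np.ndarray
    n_clusters: int
    density_per_um2: float | None
    eps_nm: float
    min_pts: int

    def __post_init__(self) -> None:
        distinct = set(self.labels.tolist()) - {NOISE_LABEL}
        if len(distinct) != self.n_clusters:
            raise ValueError("n_clusters inconsistent with labels")


def _nena_model(d: np.ndarray, sigma: float, amp: float, bg: float) -> np.ndarray:
    """Single-emitter displacement density plus a linear background term.

    ``p(d) = amp * (d / (2 sigma^2)) * exp(-d^2 / (4 sigma^2)) + bg * d``;
    the 4 sigma^2 scale arises because both localizations of the pair
    carry precision sigma.
    """
    return amp * (d / (2.0 * sigma**2)) * np.exp(-(d**2) / (4.0 * sigma**2)) + bg * d


def nena_precision(
    table: pd.DataFrame,
    max_distance_nm: float = 200.0,
    bins: int = 100,
) -> float:
    """Localization precision sigma (nm) by nearest-neighbour analysis.

    For every localization, the nearest neighbour in the *next* frame is
    found; the histogram of those distances is fitted with the NeNA
    displacement model plus a linear (uncorrelated-neighbour) background.
    """
    if len(table) < 100:
        raise ValueError("need >= 100 localizations for NeNA")
    frames = np.sort(table["frame"].unique())
    if len(frames) < 2:
        raise ValueError("need localizations spanning >= 2 frames")
    xy = table[["x_nm", "y_nm"]].to_numpy(float)
    fr = table["frame"].to_numpy()
    dists = []
    for f in frames[:-1]:
        cur = xy[fr == f]
        nxt = xy[fr == f + 1]
        if len(cur) == 0 or len(nxt) == 0:
            continue
        d, _ = cKDTree(nxt).query(cur, k=1, distance_upper_bound=max_distance_nm)
        d = d[np.isfinite(d)]
        dists.append(d)
    if not dists:
        raise ValueError("no consecutive-frame neighbour pairs found")
    dists = np.concatenate(dists)
    if len(dists) < 50:
        raise ValueError(f"only {len(dists)} neighbour pairs; too few for the fit")
    counts, edges = np.histogram(dists, bins=bins, range=(0.0, max_distance_nm))
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / max(1, counts.sum()) / np.diff(edges)
    sigma0 = max(np.sqrt(np.mean(dists**2) / 4.0), 1e-3)
    popt, _ = curve_fit(
        _nena_model,
        centers,
        density,
        p0=(sigma0, 1.0, 1e-6),
        bounds=([1e-4, 0.0, 0.0], [max_distance_nm, np.inf, np.inf]),
        maxfev=20_000,
    )
    return float(popt[0])


def link_radius_nm(sigma_nm: float) -> float:
    """Linking radius: 6×NeNA capped at 0.45 px (157 nm/px)."""
    s = load_presets()["smlm"]
    return min(6.0 * sigma_nm, s["link_radius_max_px"] * s["pixel_size_nm"])


def dbscan_eps_nm(sigma_nm: float) -> float:
    """DBSCAN radius: 2×NeNA capped at 0.15 px (157 nm/px)."""
    s = load_presets()["smlm"]
    return min(2.0 * sigma_nm, s["dbscan_eps_max_px"] * s["pixel_size_nm"])


def link_localizations(
    table: pd.DataFrame, radius_nm: float, max_dark_frames: int = 5
) -> pd.DataFrame:
    """Merge repeated localizations of the same emitter across frames.

    Two localizations are joined when they lie within ``radius_nm`` and
    their frame indices differ by at most ``max_dark_frames`` (a value of
    5 therefore admits up to 4 intervening dark frames); linking is
    transitive, and each linked group is replaced by its mean position at
    the group's first frame.  The output never has more rows than the
    input and merged positions lie in the convex hull of their group.
    """
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    n = len(table)
    if n == 0:
        return table.copy()
    xy = table[["x_nm", "y_nm"]].to_numpy(float)
    fr = table["frame"].to_numpy()
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    tree = cKDTree(xy)
    for i, j in tree.query_pairs(radius_nm):
        if abs(int(fr[i]) - int(fr[j])) <= max_dark_frames:
            union(i, j)

    roots = np.array([find(i) for i in range(n)])
    rows = []
    for root in np.unique(roots):
        members = roots == root
        rows.append(
            {
                "x_nm": float(xy[members, 0].mean()),
                "y_nm": float(xy[members, 1].mean()),
                "frame": int(fr[members].min()),
                "n_linked": int(members.sum()),
            }
        )
    out = pd.DataFrame(rows).sort_values("frame", kind="stable").reset_index(drop=True)
    return out


def dbscan_clusters(
    table: pd.DataFrame,
    eps_nm: float,
    min_pts: int = 10,
    area_um2: float | None = None,
) -> ClusterResult:
    """Deterministic DBSCAN over localization positions.

    Standard semantics: a core point has at least ``min_pts`` neighbours
    within ``eps_nm`` *including itself*; clusters grow by
    neighbourhood expansion from core points in input (scan) order, and a
    border point joins the first core cluster that reaches it.  Noise
    points keep the label -1.
    """
    if eps_nm <= 0 or min_pts < 1:
        raise ValueError("need eps > 0 and min_pts >= 1")
    xy = table[["x_nm", "y_nm"]].to_numpy(float)
    n = len(xy)
    labels = np.full(n, NOISE_LABEL, dtype=int)
    if n:
        tree = cKDTree(xy)
        neighbors = tree.query_ball_point(xy, eps_nm)
        core = np.array([len(nb) >= min_pts for nb in neighbors])
        cluster = 0
        for i in range(n):
            if not core[i] or labels[i] != NOISE_LABEL:
                continue
            labels[i] = cluster
            stack = [i]
            while stack:
                j = stack.pop()
                for k in sorted(neighbors[j]):
                    if labels[k] == NOISE_LABEL:
                        labels[k] = cluster
                        if core[k]:
                            stack.append(k)
            cluster += 1
        n_clusters = cluster
    else:
        n_clusters = 0
    density = n_clusters / area_um2 if area_um2 else None
    return ClusterResult(
        labels=labels,
        n_clusters=n_clusters,
        density_per_um2=density,
        eps_nm=eps_nm,
        min_pts=min_pts,
    )


def cluster_density(result: ClusterResult, area_um2: float) -> float:
    """Clusters per µm² of cell area."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    return result.n_clusters / area_um2
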