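"""SMLM density chain: NeNA, linking, DBSCAN, density."""

import numpy as np
import pandas as pd
import pytest

from fretarch.simulate import FieldParams, simulate_localization_field
from fretarch.smlm import (
    NOISE_LABEL,
    cluster_density,
    dbscan_clusters,
    dbscan_eps_nm,
    link_localizations,
    link_radius_nm,
    nena_precision,
)


def loc_table(rows):
    return pd.DataFrame(rows, columns=["x_nm", "y_nm", "frame"])


def immobile_emitters(rng, n_emitters, sigma, n_frames=40, side=20_000.0):
    pos = rng.uniform(0, side, size=(n_emitters, 2))
    rows = []
    for f in range(n_frames):
        jitter = rng.normal(0, sigma, size=pos.shape)
        for (x, y) in pos + jitter:
            rows.append((x, y, f))
    return loc_table(rows)


class TestNena:
    def test_recovers_injected_precision(self):
        rng = np.random.default_rng(0)
        table = immobile_emitters(rng, 80, sigma=10.0)
        assert nena_precision(table) == pytest.approx(10.0, abs=1.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        s1 = nena_precision(immobile_emitters(rng, 80, sigma=10.0))
        s2 = nena_precision(immobile_emitters(rng, 80, sigma=20.0))
        assert s2 / s1 == pytest.approx(2.0, rel=0.1)

    def test_degenerate_zero_jitter(self):
        rng = np.random.default_rng(2)
        table = immobile_emitters(rng, 60, sigma=1e-6)
        assert nena_precision(table) < 1.0

    def test_rejects_single_frame(self):
        rng = np.random.default_rng(3)
        t = loc_table([(x, 0.0, 0) for x in rng.uniform(0, 1e4, 200)])
        with pytest.raises(ValueError):
            nena_precision(t)


def brute_force_link_groups(table, radius, max_dark):
    """Independent transitive-closure oracle over all pairs."""
    xy = table[["x_nm", "y_nm"]].to_numpy(float)
    fr = table["frame"].to_numpy()
    n = len(table)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if (
                np.hypot(*(xy[i] - xy[j])) <= radius
                and abs(int(fr[i]) - int(fr[j])) <= max_dark
            ):
                adj[i].append(j)
                adj[j].append(i)
    seen, groups = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k])
        seen |= comp
        groups.append(frozenset(comp))
    return set(groups)


class TestLinking:
    def test_consecutive_same_position_merged(self):
        t = loc_table([(100.0, 100.0, 0), (100.0, 100.0, 1)])
        assert len(link_localizations(t, 50.0, 5)) == 1

    def test_six_frame_gap_not_linked_with_five_dark_frames(self):
        t = loc_table([(100.0, 100.0, 0), (100.0, 100.0, 6)])
        assert len(link_localizations(t, 50.0, 5)) == 2

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            t = loc_table(
                [
                    (x, y, f)
                    for x, y, f in zip(
                        rng.uniform(0, 500, 40),
                        rng.uniform(0, 500, 40),
                        rng.integers(0, 20, 40),
                    )
                ]
            )
            linked = link_localizations(t, 60.0, 5)
            oracle = brute_force_link_groups(t, 60.0, 5)
            assert len(linked) == len(oracle)

    def test_never_increases_count_and_stays_in_hull(self):
        rng = np.random.default_rng(5)
        t = loc_table(
            [
                (x, y, f)
                for x, y, f in zip(
                    rng.uniform(0, 300, 60),
                    rng.uniform(0, 300, 60),
                    rng.integers(0, 10, 60),
                )
            ]
        )
        linked = link_localizations(t, 80.0, 5)
        assert len(linked) <= len(t)
        assert linked["x_nm"].between(t["x_nm"].min(), t["x_nm"].max()).all()
        assert linked["y_nm"].between(t["y_nm"].min(), t["y_nm"].max()).all()


def brute_force_dbscan(xy, eps, min_pts):
    """Independent DBSCAN oracle: repeated full scans, same tie rules."""
    n = len(xy)
    nb = [
        [j for j in range(n) if np.hypot(*(xy[i] - xy[j])) <= eps]
        for i in range(n)
    ]
    core = [len(nb[i]) >= min_pts for i in range(n)]
    labels = [NOISE_LABEL] * n
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != NOISE_LABEL:
            continue
        labels[i] = cluster
        frontier = [i]
        while frontier:
            j = frontier.pop()
            for k in sorted(nb[j]):
                if labels[k] == NOISE_LABEL:
                    labels[k] = cluster
                    if core[k]:
                        frontier.append(k)
        cluster += 1
    return np.array(labels)


class TestDbscan:
    def test_coincident_points_form_one_cluster(self):
        t = loc_table([(50.0, 50.0, f) for f in range(10)])
        res = dbscan_clusters(t, eps_nm=1.0, min_pts=10)
        assert res.n_clusters == 1
        assert (res.labels == 0).all()

    def test_isolated_point_is_noise(self):
        t = loc_table([(0.0, 0.0, 0)])
        res = dbscan_clusters(t, eps_nm=10.0, min_pts=2)
        assert res.n_clusters == 0
        assert res.labels[0] == NOISE_LABEL

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        xy = rng.uniform(0, 400, size=(200, 2))
        t = loc_table([(x, y, 0) for x, y in xy])
        res = dbscan_clusters(t, eps_nm=30.0, min_pts=4)
        oracle = brute_force_dbscan(xy, 30.0, 4)
        np.testing.assert_array_equal(res.labels, oracle)

    def test_agrees_with_sklearn_on_cluster_count(self):
        from sklearn.cluster import DBSCAN

        rng = np.random.default_rng(7)
        blobs = np.concatenate(
            [rng.normal(c, 5.0, size=(30, 2)) for c in ((0, 0), (200, 0), (0, 200))]
        )
        noise = rng.uniform(-100, 300, size=(20, 2))
        xy = np.concatenate([blobs, noise])
        t = loc_table([(x, y, 0) for x, y in xy])
        mine = dbscan_clusters(t, eps_nm=20.0, min_pts=10)
        ref = DBSCAN(eps=20.0, min_samples=10).fit(xy)
        assert mine.n_clusters == len(set(ref.labels_) - {-1}) == 3
        # identical noise assignment
        np.testing.assert_array_equal(mine.labels == -1, ref.labels_ == -1)

    def test_permutation_invariant_partition(self):
        rng = np.random.default_rng(8)
        blobs = np.concatenate(
            [rng.normal(c, 4.0, size=(25, 2)) for c in ((0, 0), (300, 300))]
        )
        t = loc_table([(x, y, 0) for x, y in blobs])
        res1 = dbscan_clusters(t, 15.0, 5)
        perm = rng.permutation(len(t))
        res2 = dbscan_clusters(t.iloc[perm].reset_index(drop=True), 15.0, 5)

        def canonical(labels):
            parts = {}
            for i, lab in enumerate(labels):
                if lab != NOISE_LABEL:
                    parts.setdefault(lab, set()).add(i)
            return {frozenset(v) for v in parts.values()}

        inv = np.empty(len(perm), dtype=int)
        inv[perm] = np.arange(len(perm))
        remapped = np.full(len(t), NOISE_LABEL)
        for new_i, old_i in enumerate(perm):
            remapped[old_i] = res2.labels[new_i]
        assert canonical(res1.labels) == canonical(remapped)


class TestDensity:
    def test_arithmetic(self):
        t = loc_table([(50.0 + 1000 * k, 50.0, f) for k in range(28) for f in range(10)])
        res = dbscan_clusters(t, eps_nm=5.0, min_pts=10)
        assert res.n_clusters == 28
        assert cluster_density(res, 10.0) == pytest.approx(2.8)

    def test_zero_clusters(self):
        res = dbscan_clusters(loc_table([]), 10.0, 10)
        assert cluster_density(res, 5.0) == 0.0

    def test_end_to_end_recovery_within_poisson_error(self):
        fp = FieldParams(area_um2=100.0, cluster_density=3.0, seed=9)
        table, centers = simulate_localization_field(fp)
        sigma = nena_precision(table)
        assert sigma == pytest.approx(fp.localization_precision, rel=0.1)
        linked = link_localizations(table, link_radius_nm(sigma), 5)
        res = dbscan_clusters(linked, dbscan_eps_nm(sigma), 10)
        true_n = len(centers)
        assert abs(res.n_clusters - true_n) <= 3 * np.sqrt(true_n)
        d = cluster_density(res, fp.area_um2)
        assert d == pytest.approx(fp.cluster_density, rel=0.15)
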