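"""Accessible-volume engine: geometry, oracles, pair statistics."""

import numpy as np
import pytest

from fretarch.avsim import (
    AccessibleVolume,
    AVParameters,
    EmptyAVError,
    compute_av,
    load_structure,
    pair_distance_stats,
    predict_pair_table,
)
from fretarch.simulate import make_toy_structure
from conftest import atom

PARAMS = AVParameters(linker_length=10.0, linker_width=4.5, dye_radii=(3.5,),
                      grid_spacing=1.0)


class TestStructureLoading:
    def test_malformed_record_reports_line_number(self):
        bad = "ATOM      1  CA  ALA A   1      bad coords here              \n"
        with pytest.raises(ValueError, match=r"lines \[1\]"):
            load_structure(bad)

    def test_write_read_idempotent(self, toy_dimer):
        from biotite.structure.io.pdb import PDBFile
        import io

        pdb = PDBFile()
        pdb.set_structure(toy_dimer.array)
        again = load_structure("\n".join(pdb.lines))
        np.testing.assert_allclose(again.coords, toy_dimer.coords, atol=1e-3)

    def test_per_chain_atom_counts(self, toy_dimer):
        a = (toy_dimer.array.chain_id == "A").sum()
        b = (toy_dimer.array.chain_id == "B").sum()
        assert a == b == 11


class TestComputeAV:
    def test_free_site_fills_ball(self, lone_site):
        av = compute_av(lone_site, "A", 1, PARAMS)
        np.testing.assert_allclose(av.centroid, [0, 0, 0], atol=1e-9)
        r = np.linalg.norm(av.points, axis=1)
        assert r.max() <= PARAMS.linker_length + 1e-9
        assert abs(av.weights.sum() - 1.0) < 1e-12

    def test_all_points_within_linker_and_clash_free(self, wall_site):
        av = compute_av(wall_site, "A", 1, PARAMS)
        dist_from_anchor = np.linalg.norm(av.points - av.attachment, axis=1)
        assert (dist_from_anchor <= PARAMS.linker_length + 1e-9).all()
        wall = wall_site.coords[wall_site.array.chain_id == "B"]
        vdw = 1.70
        for r_dye in PARAMS.dye_radii:
            d = np.linalg.norm(
                av.points[:, None, :] - wall[None, :, :], axis=2
            ).min(axis=1)
            assert (d >= vdw + min(PARAMS.dye_radii) - 1e-9).all()

    def test_wall_centroid_matches_rejection_sampling_oracle(self, wall_site):
        av = compute_av(wall_site, "A", 1, PARAMS)
        # oracle: uniform points in the linker-length ball around the
        # effective anchor; keep dye positions clearing every wall atom
        rng = np.random.default_rng(0)
        n = 2_000_000
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= (rng.uniform(0, 1, n) ** (1 / 3) * PARAMS.linker_length)[:, None]
        wall = wall_site.coords[wall_site.array.chain_id == "B"]
        clearance = 1.70 + PARAMS.dye_radii[0]
        # wall is dense; the binding constraint is the z distance to the
        # plane of atoms at z = -1
        keep = pts[:, 2] + 1.0 >= clearance
        # also require reachability: wall blocks nothing above it
        oracle_centroid = pts[keep].mean(axis=0)
        assert np.linalg.norm(av.centroid - oracle_centroid) < PARAMS.grid_spacing

    def test_grid_refinement_converges(self, lone_site):
        coarse = compute_av(lone_site, "A", 1, PARAMS)
        fine = compute_av(
            lone_site,
            "A",
            1,
            AVParameters(10.0, 4.5, (3.5,), grid_spacing=0.5),
        )
        assert np.linalg.norm(coarse.centroid - fine.centroid) < PARAMS.grid_spacing

    def test_buried_site_reported_distinctly(self):
        atoms = [atom("CB", "A", 1, [0.0, 0.0, 0.0], res_name="CYS")]
        k = 0
        # a closed cage of atoms all around the site
        for x in np.arange(-6, 6.1, 2.0):
            for y in np.arange(-6, 6.1, 2.0):
                for z in np.arange(-6, 6.1, 2.0):
                    if max(abs(x), abs(y), abs(z)) < 4:
                        continue
                    k += 1
                    atoms.append(atom("X", "C", 100 + k, [x, y, z]))
        s = load_structure(make_toy_structure(atoms)[1])
        with pytest.raises(EmptyAVError):
            compute_av(s, "A", 1, PARAMS)

    def test_missing_attachment_atom(self, lone_site):
        with pytest.raises(KeyError):
            compute_av(lone_site, "A", 99, PARAMS)


def point_av(coords, weights=None):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    w = np.full(len(coords), 1.0 / len(coords)) if weights is None else weights
    return AccessibleVolume(
        points=coords, weights=w, attachment=coords[0],
        params=AVParameters(10.0, 4.5, (3.0,)),
    )


class TestPairStats:
    def test_two_single_points(self):
        d_nm = 5.0
        av1 = point_av([[0, 0, 0]])
        av2 = point_av([[d_nm * 10, 0, 0]])
        mean_r, mean_e, r_e = pair_distance_stats(av1, av2, R0_nm=6.34)
        assert mean_r == pytest.approx(d_nm)
        assert r_e == pytest.approx(d_nm)
        assert mean_e == pytest.approx(1 / (1 + (d_nm / 6.34) ** 6))

    def test_two_by_two_hand_enumeration(self):
        # collinear {0, d} x {0, d}: pairs at 0 twice? no — distances
        # {30, 0 ... } enumerate by hand in Å: points 0 and 30 on each side
        av1 = point_av([[0, 0, 0], [30.0, 0, 0]])
        av2 = point_av([[60.0, 0, 0], [90.0, 0, 0]])
        R0 = 6.34
        d_nm = np.array([6.0, 9.0, 3.0, 6.0])  # 4 pair distances in nm
        mean_r, mean_e, r_e = pair_distance_stats(av1, av2, R0_nm=R0)
        assert mean_r == pytest.approx(d_nm.mean(), rel=1e-12)
        e = 1 / (1 + (d_nm / R0) ** 6)
        assert mean_e == pytest.approx(e.mean(), rel=1e-12)
        assert r_e == pytest.approx(R0 * (1 / e.mean() - 1) ** (1 / 6), rel=1e-12)

    def test_fret_averaged_distance_below_mean_for_spread_clouds(self):
        # Jensen: averaging E (convex at large r) exceeds E(mean_R),
        # hence R_E <= mean_R
        rng = np.random.default_rng(3)
        av1 = point_av(rng.normal(0, 8.0, size=(200, 3)))
        av2 = point_av(rng.normal(120.0, 8.0, size=(200, 3)))
        mean_r, mean_e, r_e = pair_distance_stats(av1, av2, R0_nm=6.34)
        assert mean_e > 1 / (1 + (mean_r / 6.34) ** 6)
        assert r_e < mean_r


class TestPredictTable:
    @pytest.fixture
    def prediction(self, toy_dimer):
        donor = AVParameters(10.0, 4.5, (3.4, 8.2, 3.0), grid_spacing=1.2)
        acceptor = AVParameters(10.0, 4.5, (7.15, 4.5, 1.5), grid_spacing=1.2)
        sites = {"H": (("A", 64), ("B", 64)), "T": (("A", 280), ("B", 280))}
        r0 = {"T-T": 6.34, "H-H": 6.30, "T-H": 6.34, "H-T": 6.34}
        return predict_pair_table(
            toy_dimer, sites, donor, acceptor, r0, form="toy"
        )

    def test_three_merged_entries(self, prediction):
        assert set(prediction.entries) == {"H-H", "T-T", "H-T/T-H"}

    def test_mixed_pair_symmetry(self, toy_dimer):
        # mirror-symmetric dimer: the H->T and T->H predictions agree
        donor = AVParameters(10.0, 4.5, (3.4,), grid_spacing=1.0)
        sites = {"H": (("A", 64), ("B", 64)), "T": (("A", 280), ("B", 280))}
        av_h1 = compute_av(toy_dimer, "A", 64, donor)
        av_t2 = compute_av(toy_dimer, "B", 280, donor)
        av_t1 = compute_av(toy_dimer, "A", 280, donor)
        av_h2 = compute_av(toy_dimer, "B", 64, donor)
        ht = pair_distance_stats(av_h1, av_t2, 6.34)
        th = pair_distance_stats(av_t1, av_h2, 6.34)
        assert ht[0] == pytest.approx(th[0], abs=0.05)

    def test_rigid_transform_invariance(self, toy_dimer):
        from scipy.spatial.transform import Rotation

        donor = AVParameters(10.0, 4.5, (3.4,), grid_spacing=1.0)
        av1 = compute_av(toy_dimer, "A", 64, donor)
        av2 = compute_av(toy_dimer, "B", 64, donor)
        ref = pair_distance_stats(av1, av2, 6.34)

        rot = Rotation.from_euler("xyz", [20, -35, 110], degrees=True).as_matrix()
        moved = toy_dimer.array.copy()
        moved.coord = toy_dimer.coords @ rot.T + np.array([13.0, -7.0, 4.0])
        from fretarch.avsim import structure_from_atom_array

        s2 = structure_from_atom_array(moved)
        bv1 = compute_av(s2, "A", 64, donor)
        bv2 = compute_av(s2, "B", 64, donor)
        out = pair_distance_stats(bv1, bv2, 6.34)
        # grid discretisation limits exactness under rotation
        assert out[0] == pytest.approx(ref[0], abs=0.1)
        assert out[1] == pytest.approx(ref[1], abs=0.02)
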