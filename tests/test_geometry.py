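"""Vector geometry: centroids, torsions, carbene plane, Re/Si assignment."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import paddleface as pf
from paddleface.errors import GeometryError
from paddleface.geometry import dihedral_coords


def _frame(coords, elements=None):
    coords = np.asarray(coords, float)
    elements = elements or tuple("C" for _ in coords)
    return pf.Frame(tuple(elements), coords)


class TestCentroid:
    def test_hexagon_center(self):
        pts = [
            (math.cos(math.radians(60 * k)), math.sin(math.radians(60 * k)), 0.0)
            for k in range(6)
        ]
        c = pf.centroid(_frame(pts), range(6))
        np.testing.assert_allclose(c, [0, 0, 0], atol=1e-12)

    def test_single_and_pair(self):
        fr = _frame([(1, 2, 3), (2, 0, 0), (0, 0, 0)])
        np.testing.assert_allclose(pf.centroid(fr, [0]), [1, 2, 3])
        np.testing.assert_allclose(pf.centroid(fr, [1, 2]), [1, 0, 0])

    def test_empty_selection(self):
        with pytest.raises(GeometryError):
            pf.centroid(_frame([(0, 0, 0)]), [])


class TestDihedral:
    def test_planar_cis_and_trans(self):
        cis = _frame([(1, 1, 0), (1, 0, 0), (-1, 0, 0), (-1, 1, 0)])
        trans = _frame([(1, 1, 0), (1, 0, 0), (-1, 0, 0), (-1, -1, 0)])
        assert pf.dihedral(cis, 0, 1, 2, 3) == pytest.approx(0.0, abs=1e-9)
        assert abs(pf.dihedral(trans, 0, 1, 2, 3)) == pytest.approx(180.0, abs=1e-9)

    @pytest.mark.parametrize("sign", [+1, -1])
    def test_staggered_newman_construction(self, sign):
        # explicit Newman-projection oracle: rotate the far substituent's
        # perpendicular component by ±60° about the j→k axis
        j, k = np.zeros(3), np.array([0.0, 0.0, 1.54])
        i = j + np.array([1.4, 0.0, -0.5])
        ang = math.radians(sign * 60)
        l = k + np.array([1.4 * math.cos(ang), 1.4 * math.sin(ang), 0.5])
        assert dihedral_coords(i, j, k, l) == pytest.approx(sign * 60, abs=1e-9)

    def test_matches_independent_oracle_on_random_geometries(self, rng):
        from MDAnalysis.lib.distances import calc_dihedrals

        for _ in range(150):
            p = rng.normal(0, 3, (4, 3))
            try:
                mine = dihedral_coords(*p)
            except GeometryError:
                continue
            ref = math.degrees(
                calc_dihedrals(p[0][None], p[1][None], p[2][None], p[3][None])[0]
            )
            assert abs((mine - ref + 180) % 360 - 180) < 1e-3

    @given(st.integers(0, 10_000))
    def test_reversal_invariance_and_mirror_antisymmetry(self, seed):
        # the IUPAC torsion does not depend on which end you read from;
        # it changes sign only under mirror reflection
        p = np.random.default_rng(seed).normal(0, 2, (4, 3))
        # skip nearly collinear draws where the torsion is ill-conditioned
        n1 = np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[1]))
        n2 = np.linalg.norm(np.cross(p[2] - p[1], p[3] - p[2]))
        if min(n1, n2) < 1e-2:
            return
        fwd = dihedral_coords(*p)
        rev = dihedral_coords(*p[::-1])
        assert abs((fwd - rev + 180) % 360 - 180) == pytest.approx(0.0, abs=1e-6)
        mirrored = p * np.array([-1.0, 1.0, 1.0])
        mir = dihedral_coords(*mirrored)
        assert abs((fwd + mir + 180) % 360 - 180) == pytest.approx(0.0, abs=1e-6)

    def test_collinear_is_degenerate(self):
        fr = _frame([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0)])
        with pytest.raises(GeometryError):
            pf.dihedral(fr, 0, 1, 2, 3)


class TestCarbenePlane:
    def test_ideal_trigonal_normal(self, neutral_template):
        frame, topo = neutral_template
        n, point = pf.carbene_plane(frame, topo)
        assert np.linalg.norm(n) == pytest.approx(1.0, abs=1e-12)
        c = frame.coords[topo.carbene_c]
        for idx in (topo.rh_carbene, topo.ester_c, topo.aryl_ring[0]):
            v = frame.coords[idx] - c
            assert abs(np.dot(v, n)) < 1e-9

    def test_translation_invariance(self, neutral_template):
        frame, topo = neutral_template
        n0, _ = pf.carbene_plane(frame, topo)
        shifted = pf.Frame(frame.elements, frame.coords + np.array([5.0, -3.0, 2.0]))
        n1, _ = pf.carbene_plane(shifted, topo)
        np.testing.assert_allclose(n0, n1, atol=1e-12)

    def test_rotation_equivariance(self, neutral_template, rng):
        frame, topo = neutral_template
        n0, _ = pf.carbene_plane(frame, topo)
        R = Rotation.random(random_state=np.random.RandomState(4)).as_matrix()
        rotated = pf.Frame(frame.elements, frame.coords @ R.T)
        n1, _ = pf.carbene_plane(rotated, topo)
        np.testing.assert_allclose(n1, R @ n0, atol=1e-9)

    def test_collinear_anchors_degenerate(self, neutral_template):
        frame, topo = neutral_template
        coords = frame.coords.copy()
        for idx in (topo.carbene_c, topo.rh_carbene, topo.ester_c, topo.aryl_ring[0]):
            coords[idx] = [0, 0, float(idx)]
        with pytest.raises(GeometryError):
            pf.carbene_plane(pf.Frame(frame.elements, coords), topo)


class TestAssignFace:
    def _fixture_topo_frame(self):
        # hand-built trigonal carbene in the z = 0 plane:
        # Rh at azimuth 0°, ester C at 120°, aryl ipso at 240°.
        # Viewed from +z the priority sequence Rh → ester → aryl runs
        # counterclockwise, so it appears clockwise from −z: Re is −z.
        coords = [
            (0, 0, 0),                       # carbene C
            (2, 0, 0),                       # Rh (carbene-bearing)
            (0, 0, -5),                      # distal Rh (unused here)
            (-1.0, math.sqrt(3), 0),         # ester C
            (-1.0, -math.sqrt(3), 0),        # aryl ipso
            (-2.0, -2 * math.sqrt(3), 0),    # rest of a fake aryl ring
            (-3.0, -2 * math.sqrt(3), 0),
            (-3.0, -3 * math.sqrt(3), 0),
            (-2.0, -3 * math.sqrt(3), 0),
        ] + [(float(i), 10.0, 0.0) for i in range(26)]  # filler arm atoms
        frame = _frame(coords, ["C", "Rh", "Rh", "C"] + ["C"] * 31)
        arm = pf.Arm(
            carboxylate_c=9, alpha_c=10, dihedral_quad=(11, 9, 10, 12),
            blocking_ring=tuple(range(13, 19)), imide_group=(12,),
        )
        arms = (arm,
                pf.Arm(14, 15, (13, 14, 15, 16), tuple(range(17, 23)), (16,)),
                pf.Arm(19, 20, (18, 19, 20, 21), tuple(range(22, 28)), (21,)),
                pf.Arm(24, 25, (23, 24, 25, 26), tuple(range(27, 33)), (26,)))
        topo = pf.TopologyMap(
            rh_carbene=1, rh_distal=2, carbene_c=0, ester_c=3,
            aryl_ring=(4, 5, 6, 7, 8), arms=arms,
        )
        return frame, topo

    def test_frozen_hand_derived_orientation(self):
        frame, topo = self._fixture_topo_frame()
        below = pf.assign_face(frame, topo, np.array([0.0, 0.0, -1.0]))
        above = pf.assign_face(frame, topo, np.array([0.0, 0.0, 1.0]))
        assert below.face == "Re" and below.signed_offset == pytest.approx(1.0)
        assert above.face == "Si" and above.signed_offset == pytest.approx(-1.0)

    def test_in_plane_point_is_ambiguous(self):
        frame, topo = self._fixture_topo_frame()
        fa = pf.assign_face(frame, topo, np.array([0.3, -0.2, 0.0]))
        assert fa.face == "ambiguous"
        assert abs(fa.signed_offset) < pf.AMBIGUITY_BAND

    def test_mirror_antisymmetry_on_random_queries(self, neutral_template, rng):
        frame, topo = neutral_template
        n_swapped = 0
        for _ in range(100):
            q = rng.normal(0, 5, 3)
            fa = pf.assign_face(frame, topo, q)
            mirrored_frame = pf.mirror_frame(frame)
            q_m = q * np.array([-1.0, 1.0, 1.0])
            fa_m = pf.assign_face(mirrored_frame, topo, q_m)
            assert fa_m.signed_offset == pytest.approx(-fa.signed_offset, abs=1e-9)
            if fa.face in ("Re", "Si"):
                assert fa_m.face == {"Re": "Si", "Si": "Re"}[fa.face]
                n_swapped += 1
        assert n_swapped > 50  # most random queries are off-plane

    def test_reflection_through_arbitrary_plane_swaps_faces(
        self, neutral_template, rng
    ):
        frame, topo = neutral_template
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        origin = rng.normal(size=3)

        def reflect(pts):
            d = (pts - origin) @ n
            return pts - 2 * np.outer(d, n)

        refl = pf.Frame(frame.elements, reflect(frame.coords))
        for _ in range(50):
            q = rng.normal(0, 5, 3)
            fa = pf.assign_face(frame, topo, q)
            fa_m = pf.assign_face(refl, topo, reflect(q[None])[0])
            assert fa_m.signed_offset == pytest.approx(-fa.signed_offset, abs=1e-9)
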