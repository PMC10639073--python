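"""Active-site descriptors: closed-form cases, construction round trips,
rigid-motion invariance."""

import numpy as np
import pytest

import polsensor as ps
from conftest import random_rigid_transform, rigidly_move


class TestSensorAngle:
    def test_collinear_and_right_angle(self):
        assert ps.angle_deg((0, 0, 0), (1, 0, 0), (2, 0, 0)) == pytest.approx(180.0)
        assert ps.angle_deg((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(90.0)

    @pytest.mark.parametrize("requested", [30.0, 100.0, 160.0, 180.0])
    def test_construction_round_trip(self, requested):
        s, site = ps.make_active_site(ps.SiteParams(sensor_angle=requested))
        assert ps.sensor_angle(s, site) == pytest.approx(requested, abs=1e-6)

    def test_valine_sensor_uses_cg1(self):
        s, site = ps.make_active_site(
            ps.SiteParams(sensor_identity="VAL", sensor_angle=120.0))
        assert ps.sensor_angle(s, site) == pytest.approx(120.0, abs=1e-6)

    def test_sensor_without_any_cg_rejected(self, default_site):
        s, site = default_site
        stripped = ps.Structure(
            [a for a in s.atoms if not (a.res_num == 828 and a.name in ("CG", "CG1"))],
            s.model_id)
        with pytest.raises(ps.UnsupportedResidueError):
            ps.sensor_angle(stripped, site)


class TestDistances:
    def test_gate_distance_round_trip(self):
        s, site = ps.make_active_site(ps.SiteParams(gate_distance=3.4))
        assert ps.gate_distance(s, site) == pytest.approx(3.4, abs=1e-6)

    def test_ribo_deoxy_gate_offset(self):
        """A ribonucleotide built 0.6 Å further from the gate measures
        exactly that offset."""
        d, sd = ps.make_active_site(ps.SiteParams(sugar="deoxy", gate_distance=3.4))
        r, sr = ps.make_active_site(ps.SiteParams(sugar="ribo", gate_distance=4.0))
        delta = ps.gate_distance(r, sr) - ps.gate_distance(d, sd)
        assert delta == pytest.approx(0.6, abs=1e-9)

    def test_catalytic_gap_round_trip_and_reduction(self):
        wide, sw = ps.make_active_site(ps.SiteParams(catalytic_gap=8.0))
        narrow, sn = ps.make_active_site(ps.SiteParams(catalytic_gap=7.0))
        assert ps.catalytic_gap(wide, sw) == pytest.approx(8.0, abs=1e-9)
        assert ps.catalytic_gap(wide, sw) - ps.catalytic_gap(narrow, sn) == \
               pytest.approx(1.0, abs=1e-9)

    def test_missing_atom_raises(self, default_site):
        s, site = default_site
        stripped = ps.Structure(
            [a for a in s.atoms if a.name != "CD1"], s.model_id)
        with pytest.raises(ps.MissingAtomError):
            ps.gate_distance(stripped, site)


class TestAtomDisplacement:
    SENSOR_SEL = ps.AtomSelector(chain="A", res_nums=(828,),
                                 atom_names=("CB", "CG", "OD1", "ND2"))

    def test_identity_pair(self, default_site):
        s, site = default_site
        rep = ps.atom_displacement(s, s, "palm", self.SENSOR_SEL, site, site)
        assert rep.max == pytest.approx(0.0, abs=1e-9)

    def test_constructed_sensor_shift(self):
        s1, s2, site = ps.make_structure_pair(ps.SiteParams(), sensor_shift=3.1)
        rep = ps.atom_displacement(s1, s2, "palm", self.SENSOR_SEL, site, site)
        assert rep.fit_rmsd < 1e-9
        assert rep.max == pytest.approx(3.1, abs=1e-6)
        assert rep.mean == pytest.approx(3.1, abs=1e-6)  # rigid side-chain shift

    def test_constructed_d877_shift_under_finger_palm(self):
        s1, s2, site = ps.make_structure_pair(ps.SiteParams(), d877_shift=1.0)
        sel = ps.AtomSelector(chain="A", res_nums=(877,), atom_names=("CA",))
        rep = ps.atom_displacement(s1, s2, "finger_palm", sel, site, site)
        assert rep.max == pytest.approx(1.0, abs=1e-6)

    def test_rigid_motion_invariance(self, rng):
        """A whole-structure rigid move adds no apparent displacement."""
        s1, s2, site = ps.make_structure_pair(ps.SiteParams(), sensor_shift=2.0)
        moved = rigidly_move(s2, random_rigid_transform(rng))
        rep_a = ps.atom_displacement(s1, s2, "palm", self.SENSOR_SEL, site, site)
        rep_b = ps.atom_displacement(s1, moved, "palm", self.SENSOR_SEL, site, site)
        assert rep_a.max == pytest.approx(rep_b.max, abs=1e-6)
        pure = rigidly_move(s1, random_rigid_transform(rng))
        rep_c = ps.atom_displacement(s1, pure, "palm", self.SENSOR_SEL, site, site)
        assert rep_c.max == pytest.approx(0.0, abs=1e-6)


class TestCoplanarity:
    def test_coplanar_rings(self):
        s, site = ps.make_active_site(ps.SiteParams(coplanarity=0.0))
        assert ps.base_pair_coplanarity(s, site) == pytest.approx(0.0, abs=1e-6)

    def test_fifteen_degree_tilt_matches_svd_plane_oracle(self):
        s, site = ps.make_active_site(ps.SiteParams(coplanarity=15.0))
        assert ps.base_pair_coplanarity(s, site) == pytest.approx(15.0, abs=1e-6)
        # independent plane-fit oracle on the same rings
        from polsensor.descriptors import PURINE_RING, PYRIMIDINE_RING

        def oracle_normal(names, chain):
            pts = np.array([a.pos for a in s.atoms
                            if a.chain == chain and a.name in names])
            pts = pts - pts.mean(axis=0)
            w, v = np.linalg.eigh(pts.T @ pts)
            return v[:, 0]  # eigenvector of smallest eigenvalue

        n1 = oracle_normal(PURINE_RING, "T")
        n2 = oracle_normal(PYRIMIDINE_RING, "N")
        ang = np.degrees(np.arccos(np.clip(abs(n1 @ n2), 0, 1)))
        assert ang == pytest.approx(15.0, abs=1e-6)

    def test_too_few_ring_atoms(self, default_site):
        s, site = default_site
        # keep only two template ring atoms: plane fit undefined
        stripped = ps.Structure(
            [a for a in s.atoms if a.chain != "T" or a.name in ("N9", "C8")],
            s.model_id)
        with pytest.raises(ValueError, match="ring atoms"):
            ps.base_pair_coplanarity(stripped, site)


class TestClassifyState:
    @pytest.mark.parametrize("angle,expected", [
        (160.0, "locked"), (100.0, "unlocked"), (140.0, "locked"),
        (139.999, "unlocked"), (0.0, "unlocked"), (180.0, "locked"),
    ])
    def test_threshold_semantics(self, angle, expected):
        assert ps.classify_state(angle) == expected

    def test_custom_threshold(self):
        assert ps.classify_state(150.0, threshold=155.0) == "unlocked"

    def test_out_of_range_rejected(self):
        for bad in (-1.0, 180.5):
            with pytest.raises(ValueError):
                ps.classify_state(bad)


class TestRigidInvarianceOfAllDescriptors:
    def test_hundred_random_rigid_motions(self, rng):
        """Every scalar descriptor is invariant to 1e-6 under 100 random
        proper rigid motions of the whole structure."""
        s, site = ps.make_active_site(
            ps.SiteParams(sensor_angle=147.0, gate_distance=3.7,
                          catalytic_gap=7.3, coplanarity=9.0, sugar="ribo"))
        ref = (ps.sensor_angle(s, site), ps.gate_distance(s, site),
               ps.catalytic_gap(s, site), ps.base_pair_coplanarity(s, site))
        for _ in range(100):
            m = rigidly_move(s, random_rigid_transform(rng))
            got = (ps.sensor_angle(m, site), ps.gate_distance(m, site),
                   ps.catalytic_gap(m, site), ps.base_pair_coplanarity(m, site))
            assert np.allclose(got, ref, atol=1e-6)
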