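"""Geometry, Stokes-Einstein coefficients and cluster-diffusion composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from fclsim.model_core import (
    DiffusionSpec,
    InvalidParameterError,
    PhysicalEnvironment,
    RigidMolecule,
    compose_cluster_diffusion,
    membrane_snap_pose,
    place_bound_partner,
    plane_normal,
    site_world_coordinates,
    stokes_einstein,
)


class TestStokesEinstein:
    def test_translational_reference_value(self):
        # k_B T / (6 pi eta r) at T=298.15 K, eta=8.9e-4 Pa s, r=1 nm
        # evaluates to 2.4537e-10 m^2/s = 245.37 um^2/s (hand evaluation)
        env = PhysicalEnvironment(temperature=298.15, viscosity=8.9e-4)
        d = stokes_einstein(1.0, env, "translational")
        assert d == pytest.approx(245.37, rel=1e-3)

    def test_scaling_laws(self):
        d1 = stokes_einstein(2.0, mode="translational")
        d2 = stokes_einstein(4.0, mode="translational")
        assert d1 / d2 == pytest.approx(2.0, rel=1e-12)
        r1 = stokes_einstein(2.0, mode="rotational")
        r2 = stokes_einstein(4.0, mode="rotational")
        assert r1 / r2 == pytest.approx(8.0, rel=1e-12)

    def test_invalid_radius(self):
        with pytest.raises(InvalidParameterError):
            stokes_einstein(0.0)
        with pytest.raises(InvalidParameterError):
            stokes_einstein(-1.0)


class TestComposeClusterDiffusion:
    def test_singleton_identity(self):
        spec = DiffusionSpec.clathrin_default()
        out = compose_cluster_diffusion([spec])
        np.testing.assert_allclose(out.trans, spec.trans)
        np.testing.assert_allclose(out.rot, spec.rot)

    @pytest.mark.parametrize("n", range(1, 7))
    def test_identical_members_closed_form(self, n):
        # n identical members: D/n translational, D_R/n^3 rotational
        spec = DiffusionSpec.isotropic(12.0, 0.08)
        out = compose_cluster_diffusion([spec] * n)
        np.testing.assert_allclose(out.trans, 12.0 / n, rtol=1e-12)
        np.testing.assert_allclose(out.rot, 0.08 / n**3, rtol=1e-12)

    def test_ap2_member_pins_cluster_to_membrane(self):
        out = compose_cluster_diffusion(
            [DiffusionSpec.clathrin_default()] * 2 + [DiffusionSpec.ap2_default()]
        )
        assert out.d_trans[2] == 0.0
        assert out.d_rot[0] == 0.0 and out.d_rot[1] == 0.0
        assert out.d_trans[0] > 0 and out.d_rot[2] > 0

    def test_monotone_shrinkage(self, rng):
        specs = [
            DiffusionSpec.isotropic(rng.uniform(1, 20), rng.uniform(0.01, 1))
            for _ in range(5)
        ]
        out = compose_cluster_diffusion(specs)
        mins_t = np.min([s.trans for s in specs], axis=0)
        mins_r = np.min([s.rot for s in specs], axis=0)
        assert np.all(out.trans <= mins_t + 1e-12)
        assert np.all(out.rot <= mins_r + 1e-12)

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            compose_cluster_diffusion([])

    def test_negative_rejected(self):
        with pytest.raises(InvalidParameterError):
            DiffusionSpec.isotropic(-1.0, 0.1)


class TestSiteGeometry:
    def test_identity_orientation_offsets(self, membrane_clathrin, geometry):
        sites = site_world_coordinates(membrane_clathrin, geometry)
        np.testing.assert_allclose(
            sites, membrane_clathrin.position + geometry.site_offsets, atol=1e-12
        )

    def test_threefold_symmetry_permutes_legs(self, membrane_clathrin, geometry):
        rot = Rotation.from_euler("z", 120, degrees=True)
        turned = RigidMolecule(
            id=1,
            species="clathrin",
            position=membrane_clathrin.position,
            orientation=(rot * membrane_clathrin.rotation).as_quat(),
        )
        s0 = site_world_coordinates(membrane_clathrin, geometry)
        s1 = site_world_coordinates(turned, geometry)
        # 120 deg about the AP-2-site axis carries leg s onto leg (s+1) mod 3
        for s in range(3):
            assert np.max(np.abs(s1[s] - s0[(s + 1) % 3])) < 1e-9

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_rigidity_under_rotation(self, seed):
        rng = np.random.default_rng(seed)
        q = Rotation.random(random_state=rng).as_quat()
        mol = RigidMolecule(
            id=0, species="clathrin", position=rng.uniform(0, 1000, 3), orientation=q
        )
        sites = site_world_coordinates(mol)
        ref = site_world_coordinates(
            RigidMolecule(id=1, species="clathrin", position=np.zeros(3))
        )
        d = lambda s: [np.linalg.norm(s[a] - s[b]) for a in range(4) for b in range(a)]
        np.testing.assert_allclose(d(sites), d(ref), atol=1e-9)


class TestPlaceBoundPartner:
    def test_bond_gap_exact(self, membrane_clathrin, geometry):
        partner = place_bound_partner(membrane_clathrin, 0, geometry, "clathrin_clathrin", 1)
        sa = site_world_coordinates(membrane_clathrin, geometry)[0]
        sb = site_world_coordinates(partner, geometry)[partner.bonds[0][0]]
        assert np.linalg.norm(sa - sb) == pytest.approx(geometry.bond_gap, abs=1e-9)

    def test_coplanarity(self, geometry, rng):
        # arbitrary starting orientation: centers and all six legs coplanar
        q = Rotation.random(random_state=rng).as_quat()
        mol = RigidMolecule(
            id=0, species="clathrin", position=np.array([400.0, 450.0, 300.0]), orientation=q
        )
        partner = place_bound_partner(mol, 1, geometry, "clathrin_clathrin", 1)
        pts = np.vstack(
            [
                mol.position,
                partner.position,
                site_world_coordinates(mol, geometry)[:3],
                site_world_coordinates(partner, geometry)[:3],
            ]
        )
        n = plane_normal(mol)
        residuals = (pts - mol.position) @ n
        assert np.max(np.abs(residuals)) < 1e-6

    def test_partners_beyond_excluded_volume(self, membrane_clathrin, geometry):
        partner = place_bound_partner(membrane_clathrin, 2, geometry, "clathrin_clathrin", 1)
        gap = np.linalg.norm(partner.position - membrane_clathrin.position)
        assert gap >= geometry.excluded_diameter
        assert gap == pytest.approx(2 * geometry.leg_radius + geometry.bond_gap)

    def test_ap2_binding_perpendicular(self, geometry, rng):
        q = Rotation.random(random_state=rng).as_quat()
        mol = RigidMolecule(
            id=0, species="clathrin", position=np.array([100.0, 100.0, 6.0]), orientation=q
        )
        snapped, ap2 = place_bound_partner(mol, 3, geometry, "clathrin_ap2", 99)
        axis = snapped.rotation.apply([0.0, 0.0, -1.0])
        assert abs(abs(axis @ [0, 0, 1]) - 1.0) < 1e-9
        assert ap2.position[2] == 0.0
        # AP-2 directly beneath the site, site exactly on the membrane
        site = site_world_coordinates(snapped, geometry)[3]
        np.testing.assert_allclose(site, ap2.position, atol=1e-9)
        # leg plane parallel to the membrane
        assert abs(plane_normal(snapped) @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_hexagonal_ring_closure(self, geometry):
        # six head-to-head bonds around a ring return to the starting site
        mol = RigidMolecule(
            id=0, species="clathrin", position=np.array([500.0, 500.0, 2.0])
        )
        ring = [mol]
        # alternate the outgoing leg to turn 60 degrees per step
        legs = [0, 1, 0, 1, 0, 1]
        # grow 5 partners; the 6th bond should close onto molecule 0
        current = mol
        for k in range(5):
            nxt = place_bound_partner(current, legs[k] if k == 0 else out_leg, geometry,
                                      "clathrin_clathrin", k + 1)
            bound = nxt.bonds[0][0]
            # choose the other leg that continues the hexagon
            out_leg = {0: 1, 1: 2, 2: 0}[bound]
            ring.append(nxt)
            current = nxt
        first_site = site_world_coordinates(ring[0], geometry)[2]
        last_sites = site_world_coordinates(ring[-1], geometry)
        dmin = np.min(np.linalg.norm(last_sites[:3] - first_site, axis=1))
        assert dmin <= geometry.bond_gap + 1e-6

    def test_membrane_snap_preserves_xy(self, geometry, rng):
        q = Rotation.random(random_state=rng).as_quat()
        mol = RigidMolecule(
            id=0, species="clathrin", position=np.array([123.0, 456.0, 7.0]), orientation=q
        )
        snapped = membrane_snap_pose(mol, geometry)
        assert snapped.position[0] == 123.0 and snapped.position[1] == 456.0
        assert snapped.position[2] == geometry.ap2_site_depth


class TestRigidMoleculeValidation:
    def test_non_unit_quaternion_rejected(self):
        with pytest.raises(InvalidParameterError):
            RigidMolecule(0, "clathrin", np.zeros(3), orientation=np.array([0, 0, 0, 2.0]))

    def test_duplicate_site_bond_rejected(self):
        with pytest.raises(InvalidParameterError):
            RigidMolecule(
                0, "clathrin", np.zeros(3), bonds=[(0, 1, 0), (0, 2, 1)]
            )

    def test_ap2_off_membrane_rejected(self):
        with pytest.raises(InvalidParameterError):
            RigidMolecule(5, "ap2", np.array([0.0, 0.0, 3.0]))
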