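"""Order parameters: P2 anchors, closed-form tilt recovery, S_CD geometry."""

import numpy as np
import pytest

from bilayerlab.core import Frame, Trajectory
from bilayerlab.order import (
    HALF_TETRAHEDRAL_DEG,
    cg_order_p2,
    chain_bonds,
    deuterium_order_scd,
)
from bilayerlab.synth import BilayerSpec, generate

from conftest import bond_trajectory, make_table, static_trajectory


def p2_closed_form(theta_deg):
    c = np.cos(np.deg2rad(theta_deg))
    return 1.5 * c * c - 0.5


class TestCgOrderP2:
    def test_parallel_bond_is_one(self):
        table, traj = bond_trajectory((0, 0, 0.3))
        res = cg_order_p2(traj, [(0, 1)])
        assert np.allclose(res.mean, 1.0, atol=1e-14)

    def test_in_plane_bond_is_minus_half(self):
        table, traj = bond_trajectory((0.3, 0, 0))
        res = cg_order_p2(traj, [(0, 1)])
        assert np.allclose(res.mean, -0.5, atol=1e-14)

    def test_isotropic_bonds_average_to_zero(self):
        rng = np.random.default_rng(42)
        n = 200_000
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        coords = np.empty((2 * n, 3))
        coords[0::2] = 50.0
        coords[1::2] = 50.0 + 0.3 * u
        table = None  # not needed by cg_order_p2
        traj = Trajectory([Frame(0.0, (100, 100, 100), coords),
                           Frame(1.0, (100, 100, 100), coords)])
        bonds = np.column_stack([np.arange(0, 2 * n, 2), np.arange(1, 2 * n, 2)])
        res = cg_order_p2(traj, bonds, labels=["iso"] * n)
        assert abs(res.mean[0]) < 0.01

    def test_minimum_image_bond_vector_used(self):
        # bond wrapped across the boundary still reads as short and vertical
        table, traj = bond_trajectory((0, 0, 0.9), box=(1, 1, 1), origin=(0.5, 0.5, 0.05))
        res = cg_order_p2(traj, [(0, 1)])
        assert np.allclose(res.mean, 1.0, atol=1e-12)

    def test_zero_length_bonds_skipped_with_warning(self):
        table, traj = bond_trajectory((0, 0, 0))
        with pytest.warns(UserWarning, match="zero length"):
            res = cg_order_p2(traj, [(0, 1)])
        assert res.n_skipped == res.n_samples
        assert np.isnan(res.mean[0])

    @pytest.mark.parametrize("theta", np.linspace(0.0, 90.0, 10))
    def test_fixed_tilt_closed_form_recovery(self, theta):
        """Generator at a fixed tilt angle reproduces (3cos^2(t)-1)/2 to 1e-12."""
        spec = BilayerSpec(n_per_leaflet=16, tilt_mode="fixed_angle",
                           tilt_param=float(theta), d_lat=0.0, seed=1)
        table, traj = generate(spec, 4, 10.0)
        bonds, labels = chain_bonds(table, "sn1")
        res = cg_order_p2(traj, bonds, labels)
        expected = p2_closed_form(theta)
        assert np.allclose(res.mean, expected, rtol=1e-12, atol=1e-12)

    def test_reflection_and_translation_invariance(self):
        spec = BilayerSpec(n_per_leaflet=16, tilt_mode="wrapped_gaussian",
                           tilt_param=20.0, d_lat=0.0, seed=2)
        table, traj = generate(spec, 4, 10.0)
        bonds, labels = chain_bonds(table, "sn1")
        base = cg_order_p2(traj, bonds, labels).mean
        flipped = Trajectory(
            [Frame(f.time, f.box, f.coords * np.array([1, 1, -1])) for f in traj.frames]
        )
        shifted = Trajectory(
            [Frame(f.time, f.box, f.coords + np.array([1.3, -0.7, 0.0]))
             for f in traj.frames]
        )
        assert np.allclose(cg_order_p2(flipped, bonds, labels).mean, base, atol=1e-12)
        assert np.allclose(cg_order_p2(shifted, bonds, labels).mean, base, atol=1e-12)


def straight_chain_system(direction, n_carbons=6, box=(20.0, 20.0, 20.0)):
    """One molecule: a straight chain of carbons along ``direction``."""
    direction = np.asarray(direction, float)
    direction /= np.linalg.norm(direction)
    recs, coords = [], []
    origin = np.array([10.0, 10.0, 10.0])
    for k in range(n_carbons):
        recs.append(dict(site_id=k, site_name=f"C{k+1}", residue_name="LIP",
                         molecule_id=1, polarity_class="apolar",
                         chain_label="sn1", chain_position=k + 1))
        coords.append(origin + 0.15 * k * direction)
    return make_table(recs), np.asarray(coords), box


class TestDeuteriumScd:
    def test_all_trans_vertical_chain_gives_half(self):
        table, coords, box = straight_chain_system((0, 0, 1))
        traj = static_trajectory(coords, box)
        res = deuterium_order_scd(traj, table, "sn1", h_mode="reconstructed")
        assert res.labels == [2, 3, 4, 5]  # terminal carbons omitted
        assert np.allclose(res.mean, 0.5, atol=1e-12)

    def test_explicit_h_vertical_chain_gives_half(self):
        table, coords, box = straight_chain_system((0, 0, 1), n_carbons=3)
        # attach two in-plane H to the middle carbon
        recs = table.df.to_dict("records")
        h_xyz = [coords[1] + [0.1, 0, 0], coords[1] - [0.1, 0, 0]]
        for i, xyz in enumerate(h_xyz):
            recs.append(dict(site_id=len(recs), site_name=f"H{i}", residue_name="LIP",
                             molecule_id=1, mass=1.0, charge=0.0, electrons=1.0,
                             polarity_class="apolar", chain_label=None,
                             chain_position=None))
        table2 = make_table(recs)
        traj = static_trajectory(np.vstack([coords, h_xyz]), box)
        res = deuterium_order_scd(traj, table2, "sn1", h_mode="explicit_H",
                                  h_map={1: [3, 4]})
        assert np.allclose(res.mean, 0.5, atol=1e-12)

    def test_magic_angle_rotational_average_vanishes(self):
        """A chain tilted at the magic angle with its C-H vectors rotated
        uniformly about the chain axis averages to S_CD = 0: the addition
        theorem gives P2(cos t0) * P2(cos 90) = 0, and a brute-force
        average over the rotation angle confirms it to machine precision
        (the integrand is a degree-2 trigonometric polynomial, which a
        uniform grid integrates exactly)."""
        theta = np.deg2rad(HALF_TETRAHEDRAL_DEG)
        d = np.array([np.sin(theta), 0.0, np.cos(theta)])
        e1 = np.array([np.cos(theta), 0.0, -np.sin(theta)])  # unit, e1 . d = 0
        e2 = np.cross(d, e1)
        table, coords, box = straight_chain_system(d, n_carbons=3)
        recs = table.df.to_dict("records")
        recs.append(dict(site_id=3, site_name="H1", residue_name="LIP",
                         molecule_id=1, polarity_class="apolar"))
        table2 = make_table(recs)
        frames = []
        alphas = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        for i, alpha in enumerate(alphas):
            h = np.cos(alpha) * e1 + np.sin(alpha) * e2
            c = np.vstack([coords, coords[1] + 0.11 * h])
            frames.append(Frame(float(i), np.asarray(box), c))
        res = deuterium_order_scd(Trajectory(frames), table2, "sn1",
                                  h_mode="explicit_H", h_map={1: [3]})
        # independent brute-force oracle over the same rotation grid
        hz = np.cos(alphas) * e1[2] + np.sin(alphas) * e2[2]
        oracle = np.mean(1.5 * hz**2 - 0.5)
        assert abs(oracle) < 1e-12
        assert np.allclose(res.mean, abs(oracle), atol=1e-12)

    def test_isotropic_chain_orientations_vanish(self):
        """A zigzag chain under uniform random 3D rotations has no
        preferred C-H direction, so the reconstructed S_CD tends to 0."""
        from scipy.spatial.transform import Rotation

        zig = np.array([[0, 0, 0], [0.1, 0, 0.12], [0, 0, 0.24],
                        [0.1, 0, 0.36], [0, 0, 0.48]])
        recs = [dict(site_id=k, site_name=f"C{k+1}", residue_name="LIP",
                     molecule_id=1, polarity_class="apolar",
                     chain_label="sn1", chain_position=k + 1)
                for k in range(5)]
        table = make_table(recs)
        rng = np.random.default_rng(3)
        origin = np.array([10.0, 10.0, 10.0])
        frames = []
        for i in range(3000):
            rot = Rotation.random(rng=rng)
            frames.append(Frame(float(i), (20, 20, 20), origin + rot.apply(zig)))
        res = deuterium_order_scd(Trajectory(frames), table, "sn1")
        assert np.all(res.mean < 0.025)

    def test_values_in_range_on_generator_data(self):
        spec = BilayerSpec(n_per_leaflet=16, tilt_mode="wrapped_gaussian",
                           tilt_param=25.0, d_lat=0.0, seed=4, chain_sites=5)
        table, traj = generate(spec, 10, 10.0)
        res = deuterium_order_scd(traj, table, "sn1")
        assert np.all(res.mean >= 0.0) and np.all(res.mean <= 1.0)
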