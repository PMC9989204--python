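"""Shared fixtures: tiny hand-built systems with exactly known geometry."""

from __future__ import annotations

import numpy as np
import pytest

from bilayerlab.core import Frame, SiteTable, Trajectory


def make_table(records):
    """SiteTable from minimal record dicts (defaults filled in)."""
    return SiteTable.from_records(records)


def static_trajectory(coords, box, n_frames=2, dt=1.0):
    """A trajectory that repeats one coordinate set (times 0, dt, ...)."""
    coords = np.asarray(coords, float)
    return Trajectory(
        [Frame(i * dt, np.asarray(box, float), coords.copy()) for i in range(n_frames)],
        dt=dt,
    )


def bond_trajectory(vec, box=(10.0, 10.0, 10.0), origin=(5.0, 5.0, 5.0), n_frames=2):
    """Two sites forming one bond with displacement ``vec``."""
    origin = np.asarray(origin, float)
    coords = np.stack([origin, origin + np.asarray(vec, float)])
    table = make_table(
        [
            dict(site_id=0, site_name="B1", residue_name="MOL", molecule_id=1),
            dict(site_id=1, site_name="B2", residue_name="MOL", molecule_id=1),
        ]
    )
    return table, static_trajectory(coords, box, n_frames=n_frames)


@pytest.fixture
def flat_bilayer():
    """64+64-lipid noise-free bilayer with straight vertical chains."""
    from bilayerlab.synth import BilayerSpec, build_bilayer, simulate_dynamics

    spec = BilayerSpec(
        n_per_leaflet=64, apl=0.5625, phosphate_plane_sep=4.0,
        chain_sites=4, tilt_mode="fixed_angle", tilt_param=0.0,
        d_lat=0.0, seed=7,
    )
    table, frame0 = build_bilayer(spec)
    traj = simulate_dynamics(table, frame0, 5, 10.0, spec)
    return spec, table, traj
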