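"""Domain types, periodic geometry and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bilayerlab.core import (
    BilayerError,
    Frame,
    GeometryError,
    SiteTable,
    Trajectory,
    minimum_image_vector,
)
from bilayerlab.io import (
    GroParseError,
    UnsupportedBoxError,
    read_gro,
    read_site_table,
    read_trjtxt,
    write_gro,
    write_site_table,
    write_trjtxt,
)

from conftest import make_table, static_trajectory


class TestMinimumImage:
    def test_wraps_across_boundary(self):
        v = minimum_image_vector((0, 0, 0), (0.95, 0, 0), (1, 1, 1))
        assert np.allclose(v, (-0.05, 0, 0))
        assert np.isclose(np.linalg.norm(v), 0.05)

    def test_identity_and_no_wrap(self):
        assert np.allclose(minimum_image_vector((1, 2, 3), (1, 2, 3), (5, 5, 5)), 0)
        v = minimum_image_vector((0.1, 0.1, 0.1), (0.2, 0.2, 0.2), (10, 10, 10))
        assert np.isclose(np.linalg.norm(v), np.sqrt(0.03))

    def test_zero_box_edge_rejected(self):
        with pytest.raises(GeometryError):
            minimum_image_vector((0, 0, 0), (1, 1, 1), (1, 0, 1))

    @settings(max_examples=200, deadline=None)
    @given(
        a=st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        b=st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        box=st.lists(st.floats(0.5, 20), min_size=3, max_size=3),
    )
    def test_norm_symmetric_and_bounded(self, a, b, box):
        box = np.array(box)
        v_ab = minimum_image_vector(a, b, box)
        v_ba = minimum_image_vector(b, a, box)
        assert np.isclose(np.linalg.norm(v_ab), np.linalg.norm(v_ba), atol=1e-9)
        assert np.linalg.norm(v_ab) <= np.linalg.norm(box / 2) + 1e-9
        assert np.all(v_ab > -box / 2 - 1e-12) and np.all(v_ab <= box / 2 + 1e-12)


class TestDomainTypes:
    def test_site_table_invariants(self):
        with pytest.raises(BilayerError):
            make_table([dict(site_id=1, site_name="A", residue_name="X", molecule_id=1)])
        with pytest.raises(BilayerError):
            make_table(
                [dict(site_id=0, site_name="A", residue_name="X", molecule_id=1, mass=0.0)]
            )
        with pytest.raises(BilayerError):
            make_table(
                [
                    dict(
                        site_id=0, site_name="A", residue_name="X", molecule_id=1,
                        chain_position=2,
                    )
                ]
            )

    def test_frame_rejects_bad_box(self):
        with pytest.raises(GeometryError):
            Frame(0.0, (1.0, -1.0, 1.0), np.zeros((2, 3)))

    def test_trajectory_requires_increasing_times(self):
        f = lambda t: Frame(t, (1, 1, 1), np.zeros((1, 3)))
        with pytest.raises(BilayerError):
            Trajectory([f(0.0), f(0.0)])


class TestGro:
    GRO_2ATOM = (
        "two beads\n"
        "    2\n"
        "    1MOL     B1    1   0.000   0.000   0.000\n"
        "    1MOL     B2    2   0.100   0.200   0.300\n"
        "   1.00000   1.00000   1.00000\n"
    )

    def test_reads_coordinates_verbatim(self, tmp_path):
        p = tmp_path / "two.gro"
        p.write_text(self.GRO_2ATOM)
        table, frame = read_gro(p)
        assert len(table) == 2
        assert np.allclose(frame.coords, [[0, 0, 0], [0.1, 0.2, 0.3]])
        assert np.allclose(frame.box, 1.0)
        assert table.df.attrs["title"] == "two beads"

    def test_roundtrip_identity_to_gro_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 5, (7, 3))
        table = make_table(
            [
                dict(site_id=i, site_name=f"A{i}", residue_name="MOL", molecule_id=1)
                for i in range(7)
            ]
        )
        frame = Frame(0.0, (5, 5, 5), coords)
        p = tmp_path / "rt.gro"
        write_gro(table, frame, p)
        _, back = read_gro(p)
        assert np.allclose(back.coords, coords, atol=5e-4)

    def test_formatting_rule(self, tmp_path):
        table = make_table(
            [dict(site_id=0, site_name="A", residue_name="MOL", molecule_id=1)]
        )
        p = tmp_path / "fmt.gro"
        write_gro(table, Frame(0.0, (1, 1, 1), [[0.05, 0.05, 0.05]]), p)
        assert "0.050   0.050   0.050" in p.read_text()

    def test_wrong_atom_count_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.gro"
        p.write_text("t\n    3\n    1MOL     B1    1   0.000   0.000   0.000\n   1.0 1.0 1.0\n")
        with pytest.raises(GroParseError):
            read_gro(p)

    def test_malformed_count_line_names_line(self, tmp_path):
        p = tmp_path / "bad2.gro"
        p.write_text("t\nnot_a_number\n")
        with pytest.raises(GroParseError) as err:
            read_gro(p)
        assert err.value.line_no == 2

    def test_triclinic_box_rejected(self, tmp_path):
        p = tmp_path / "tri.gro"
        p.write_text(
            "t\n    1\n    1MOL     B1    1   0.000   0.000   0.000\n"
            "   1.0 1.0 1.0 0.0 0.0 0.5 0.0 0.0 0.0\n"
        )
        with pytest.raises(UnsupportedBoxError):
            read_gro(p)

    def test_empty_table_write_rejected(self, tmp_path):
        import pandas as pd
        from bilayerlab.core import SITE_TABLE_COLUMNS

        empty = SiteTable(pd.DataFrame(columns=SITE_TABLE_COLUMNS))
        with pytest.raises(BilayerError):
            write_gro(empty, Frame(0.0, (1, 1, 1), np.zeros((0, 3))), tmp_path / "e.gro")

    def test_multiframe_roundtrip(self, tmp_path):
        table = make_table(
            [dict(site_id=0, site_name="A", residue_name="MOL", molecule_id=1)]
        )
        traj = static_trajectory([[1.0, 2.0, 3.0]], (5, 5, 5), n_frames=3, dt=10.0)
        p = tmp_path / "multi.gro"
        write_gro(table, traj, p)
        _, back = read_gro(p)
        assert isinstance(back, Trajectory)
        assert back.n_frames == 3
        assert np.allclose(back.times, [0, 10, 20])

    def test_agrees_with_mdanalysis_reader(self, tmp_path):
        """Independent cross-check of the GRO writer/reader pair."""
        mda = pytest.importorskip("MDAnalysis")
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 4, (5, 3))
        table = make_table(
            [
                dict(site_id=i, site_name=f"A{i}", residue_name="MOL", molecule_id=1)
                for i in range(5)
            ]
        )
        p = tmp_path / "x.gro"
        write_gro(table, Frame(0.0, (4, 4, 4), coords), p)
        u = mda.Universe(str(p))
        assert np.allclose(u.atoms.positions / 10.0, coords, atol=5e-4)  # A -> nm
        ours = read_gro(p)[1]
        assert np.allclose(ours.coords, u.atoms.positions / 10.0, atol=1e-6)


class TestTrjtxtAndSiteTableTsv:
    def test_trjtxt_roundtrip_bit_exact_values(self, tmp_path):
        rng = np.random.default_rng(1)
        frames = [
            Frame(10.0 * i, (3, 3, 6), rng.uniform(0, 3, (4, 3))) for i in range(3)
        ]
        traj = Trajectory(frames, dt=10.0)
        p = tmp_path / "t.trjtxt"
        write_trjtxt(traj, p)
        back = read_trjtxt(p)
        assert back.n_frames == 3 and back.dt == 10.0
        assert np.allclose(back.coords_array(), traj.coords_array(), atol=1e-6)
        assert np.allclose(back.boxes(), traj.boxes())

    def test_site_table_tsv_roundtrip(self, tmp_path):
        table = make_table(
            [
                dict(
                    site_id=0, site_name="PO4", residue_name="LIP", molecule_id=1,
                    mass=94.97, charge=-1.0, electrons=47,
                    polarity_class="phosphate",
                ),
                dict(
                    site_id=1, site_name="C1", residue_name="LIP", molecule_id=1,
                    mass=56.0, polarity_class="apolar", chain_label="sn1",
                    chain_position=1,
                ),
            ]
        )
        p = tmp_path / "sites.tsv"
        write_site_table(table, p)
        back = read_site_table(p)
        assert back.df["site_name"].tolist() == ["PO4", "C1"]
        assert back.df["chain_label"].tolist()[1] == "sn1"
        assert np.isclose(back.df["mass"].iloc[0], 94.97)
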