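"""AA -> pseudo-CG mapping, bonded distributions, JSD scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bilayerlab.cgmap import (
    MappingError,
    MappingSpec,
    TermHistogram,
    bonded_distributions,
    distribution_distance,
    jensen_shannon_bits,
    map_aa_to_cg,
    overlap_coefficient,
    validation_report,
)
from bilayerlab.core import Frame, Trajectory

from conftest import make_table, static_trajectory


def aa_system(coords, masses=None, names=None, box=(10.0, 10.0, 10.0)):
    coords = np.asarray(coords, float)
    n = len(coords)
    names = names or [f"A{i+1}" for i in range(n)]
    recs = [dict(site_id=i, site_name=names[i], residue_name="MOL", molecule_id=1,
                 mass=1.0 if masses is None else float(masses[i]))
            for i in range(n)]
    return make_table(recs), static_trajectory(coords, box)


class TestMappingSpec:
    def test_atom_in_two_beads_rejected(self):
        with pytest.raises(MappingError):
            MappingSpec(beads={"B1": ["A1", "A2"], "B2": ["A2"]})

    def test_bonded_terms_must_reference_declared_beads(self):
        with pytest.raises(MappingError):
            MappingSpec(beads={"B1": ["A1"]}, bonds=[("B1", "B9")])

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "map.yaml"
        p.write_text(
            "beads:\n  B1: [A1, A2]\n  B2: [A3]\n"
            "bonds:\n  - [B1, B2]\n"
        )
        m = MappingSpec.from_yaml(p)
        assert m.beads["B1"] == ["A1", "A2"] and m.bonds == [("B1", "B2")]


class TestMapAaToCg:
    def test_equal_mass_midpoint(self):
        table, traj = aa_system([[0, 0, 0], [0, 0, 1]])
        m = MappingSpec(beads={"B1": ["A1", "A2"]})
        _, cg = map_aa_to_cg(traj, table, m)
        assert np.allclose(cg.frames[0].coords[0], [0, 0, 0.5])

    def test_mass_weighted_com(self):
        table, traj = aa_system([[0, 0, 0], [1, 0, 0]], masses=[1.0, 3.0])
        m = MappingSpec(beads={"B1": ["A1", "A2"]})
        _, cg = map_aa_to_cg(traj, table, m)
        assert np.allclose(cg.frames[0].coords[0], [0.75, 0, 0])

    def test_periodic_reconstruction(self):
        # atoms at 0.05 and 9.95 in a 10 nm box straddle the boundary:
        # the centre of mass is 0.00, not 5.0
        table, traj = aa_system([[0.05, 0, 0], [9.95, 0, 0]])
        m = MappingSpec(beads={"B1": ["A1", "A2"]})
        _, cg = map_aa_to_cg(traj, table, m)
        assert abs(cg.frames[0].coords[0, 0]) < 1e-9

    def test_translation_commutes(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(2, 4, (4, 3))
        table, traj = aa_system(coords, masses=[1, 2, 3, 4])
        m = MappingSpec(beads={"B1": ["A1", "A2"], "B2": ["A3", "A4"]})
        _, cg1 = map_aa_to_cg(traj, table, m)
        shift = np.array([0.3, -0.2, 0.9])
        _, cg2 = map_aa_to_cg(static_trajectory(coords + shift, (10, 10, 10)), table, m)
        assert np.allclose(cg2.frames[0].coords, cg1.frames[0].coords + shift, atol=1e-9)

    def test_overwide_bead_rejected(self):
        # after reconstruction around the first atom the other two sit at
        # +3 and -3: a 6 nm spread in a 10 nm box is an ill-defined COM
        table, traj = aa_system([[0, 0, 0], [3.0, 0, 0], [7.0, 0, 0]])
        m = MappingSpec(beads={"B1": ["A1", "A2", "A3"]})
        with pytest.raises(MappingError):
            map_aa_to_cg(traj, table, m)


class TestBondedDistributions:
    def test_collinear_angle_is_180_and_bond_delta(self):
        coords = [[1, 1, 1], [1, 1, 1.47], [1, 1, 1.94]]
        table, traj = aa_system(coords)
        m = MappingSpec(
            beads={f"B{i}": [f"A{i}"] for i in range(1, 4)},
            bonds=[("B1", "B2")],
            angles=[("B1", "B2", "B3")],
        )
        ct, cg = map_aa_to_cg(traj, table, m)
        dists = bonded_distributions(cg, ct, m)
        bond = dists[("bond", ("B1", "B2"))]
        assert bond.probs.max() == 1.0
        lo, hi = bond.edges[np.argmax(bond.probs)], bond.edges[np.argmax(bond.probs) + 1]
        assert lo <= 0.47 < hi
        ang = dists[("angle", ("B1", "B2", "B3"))]
        idx = np.argmax(ang.probs)
        assert ang.probs[idx] == 1.0
        assert ang.edges[idx] <= 180.0 <= ang.edges[idx + 1] + 1e-9

    def test_planar_cis_dihedral_is_zero(self):
        # four sites in a plane, end beads on the same side: dihedral 0
        coords = [[1, 1, 1], [2, 1, 1], [2, 2, 1], [1, 2, 1]]
        table, traj = aa_system(coords)
        m = MappingSpec(
            beads={f"B{i}": [f"A{i}"] for i in range(1, 5)},
            dihedrals=[("B1", "B2", "B3", "B4")],
        )
        ct, cg = map_aa_to_cg(traj, table, m)
        dists = bonded_distributions(cg, ct, m)
        hist = dists[("dihedral", ("B1", "B2", "B3", "B4"))]
        idx = np.argmax(hist.probs)
        assert hist.edges[idx] <= 0.0 <= hist.edges[idx + 1]

    def test_histograms_normalized(self):
        rng = np.random.default_rng(4)
        frames = [Frame(float(i), (10, 10, 10), rng.uniform(3, 5, (3, 3)))
                  for i in range(20)]
        table, _ = aa_system(np.zeros((3, 3)))
        m = MappingSpec(beads={f"B{i}": [f"A{i}"] for i in range(1, 4)},
                        bonds=[("B1", "B2"), ("B2", "B3")],
                        angles=[("B1", "B2", "B3")])
        ct, cg = map_aa_to_cg(Trajectory(frames), table, m)
        dists = bonded_distributions(cg, ct, m)
        for th in dists.terms.values():
            assert np.isclose(th.probs.sum(), 1.0)


class TestDistributionDistance:
    def test_identical_is_zero_and_full_overlap(self):
        p = np.array([0.25, 0.25, 0.5])
        assert jensen_shannon_bits(p, p) == pytest.approx(0.0, abs=1e-12)
        assert overlap_coefficient(p, p) == pytest.approx(1.0)

    def test_disjoint_is_one_bit_zero_overlap(self):
        assert jensen_shannon_bits([1, 0], [0, 1]) == pytest.approx(1.0)
        assert overlap_coefficient([1, 0], [0, 1]) == 0.0

    def test_half_vs_point_mass_value(self):
        """Hand evaluation: JSD((1/2,1/2),(1,0)) = 3/2 - (3/4)log2(3)
        = 0.311278... bits."""
        expected = 1.5 - 0.75 * np.log2(3.0)
        got = jensen_shannon_bits([0.5, 0.5], [1.0, 0.0])
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.3113, abs=5e-5)

    def test_mismatched_binning_is_error(self):
        p = TermHistogram("bond", np.linspace(0, 1, 5), np.full(4, 0.25), 10)
        q = TermHistogram("bond", np.linspace(0, 2, 5), np.full(4, 0.25), 10)
        with pytest.raises(MappingError):
            distribution_distance(p, q)

    @settings(max_examples=150, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=12),
           st.lists(st.floats(0.0, 1.0), min_size=2, max_size=12))
    def test_jsd_properties_against_scipy(self, a, b):
        """Symmetry, bounds, and agreement with an independent
        implementation (scipy's jensenshannon distance, squared)."""
        from scipy.spatial.distance import jensenshannon

        n = min(len(a), len(b))
        p = np.asarray(a[:n]) + 1e-12
        q = np.asarray(b[:n]) + 1e-12
        p /= p.sum()
        q /= q.sum()
        jsd = jensen_shannon_bits(p, q)
        assert jsd == pytest.approx(jensen_shannon_bits(q, p), abs=1e-12)
        assert -1e-12 <= jsd <= 1.0 + 1e-12
        assert jsd == pytest.approx(jensenshannon(p, q, base=2) ** 2, abs=1e-9)
        ov = overlap_coefficient(p, q)
        assert 0.0 <= ov <= 1.0 + 1e-12


class TestValidationReport:
    def _dists(self, probs_by_term):
        from bilayerlab.cgmap import BondedDistributions

        terms = {}
        for (ttype, beads), probs in probs_by_term.items():
            probs = np.asarray(probs, float)
            edges = np.linspace(0, 1, len(probs) + 1)
            terms[(ttype, beads)] = TermHistogram(ttype, edges, probs, 100)
        return BondedDistributions(terms)

    def test_identical_inputs_all_pass(self):
        d = self._dists({("bond", ("B1", "B2")): [0.5, 0.5],
                         ("angle", ("B1", "B2", "B3")): [0.2, 0.8]})
        rep = validation_report(d, d, jsd_threshold=0.0)
        assert rep.passed.all() and rep.attrs["overall_pass"]

    def test_disjoint_term_fails_overall_and_is_named(self):
        da = self._dists({("bond", ("B1", "B2")): [1.0, 0.0]})
        db = self._dists({("bond", ("B1", "B2")): [0.0, 1.0]})
        rep = validation_report(da, db, jsd_threshold=0.05)
        assert not rep.attrs["overall_pass"]
        assert rep[~rep.passed].term.tolist() == ["B1-B2"]

    def test_missing_term_untestable(self):
        da = self._dists({("bond", ("B1", "B2")): [1.0, 0.0],
                          ("bond", ("B2", "B3")): [0.5, 0.5]})
        db = self._dists({("bond", ("B1", "B2")): [1.0, 0.0]})
        rep = validation_report(da, db)
        assert not rep.attrs["overall_pass"]
        row = rep[rep.term == "B2-B3"].iloc[0]
        assert not row.passed and "untestable" in row.note
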