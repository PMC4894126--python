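"""Contacts, equilibrated distances and coarse-grained geometry."""

import numpy as np
import pytest
from MDAnalysis.lib.distances import calc_dihedrals

from actinmech.core import (
    FilamentModel,
    ResidueGroupSpec,
    Trajectory,
)
from actinmech.geometry import (
    CG_GROUPS,
    ContactSpec,
    TABLE_CONTACTS,
    cg_geometry,
    contact_table,
    count_contacts,
    equilibrated_distance,
    pair_distance,
    trajectory_cg_summary,
)
from actinmech.simulate import generate_filament_ensemble, synthetic_subunit
from conftest import random_rotation


@pytest.fixture(scope="module")
def filament_traj():
    sub = synthetic_subunit(seed=8)
    return generate_filament_ensemble(
        sub, n_subunits=4, sigma_xyz=0.4, n_frames=5, seed=9
    )


def brute_force_distance(frame, spec, i):
    a = frame.subunits[i][spec.residue_a]["CA"]
    b = frame.subunits[i + spec.subunit_offset][spec.residue_b]["CA"]
    return float(np.sqrt(((a - b) ** 2).sum()))


class TestPairDistance:
    def test_coincident_residues(self):
        sub = {41: {"CA": np.zeros(3)}, 374: {"CA": np.zeros(3)}}
        frame = FilamentModel([sub] * 3)
        spec = ContactSpec("x", 41, 374, 0)
        assert pair_distance(frame, spec, 0) == 0.0

    def test_three_four_five(self):
        subs = [
            {1: {"CA": np.array([0.0, 0, 0])}, 2: {"CA": np.array([9.0, 9, 9])}},
            {1: {"CA": np.array([3.0, 4, 0])}, 2: {"CA": np.array([9.0, 9, 9])}},
        ]
        frame = FilamentModel(subs)
        assert pair_distance(frame, ContactSpec("x", 1, 1, 1), 0) == pytest.approx(5.0)

    def test_all_table_pairs_match_brute_force(self, filament_traj):
        frame = filament_traj.frames[0]
        for spec in TABLE_CONTACTS:
            for i in range(frame.n_subunits - spec.subunit_offset):
                assert pair_distance(frame, spec, i) == pytest.approx(
                    brute_force_distance(frame, spec, i), abs=1e-9
                )

    def test_out_of_range_subunit(self, filament_traj):
        frame = filament_traj.frames[0]
        with pytest.raises(IndexError):
            pair_distance(frame, ContactSpec("x", 41, 374, 2), frame.n_subunits - 1)


class TestEquilibratedDistance:
    def test_static_trajectory_has_zero_sd(self):
        sub = synthetic_subunit(seed=1)
        traj = generate_filament_ensemble(sub, 4, sigma_xyz=0.0, n_frames=3)
        summary = equilibrated_distance(traj, TABLE_CONTACTS[0])
        assert summary.sd == pytest.approx(0.0, abs=1e-9)

    def test_two_frame_population_sd(self):
        # distances 10 and 12 across frames -> mean 11, population SD 1
        def frame(d):
            return FilamentModel(
                [
                    {41: {"CA": np.zeros(3)}},
                    {41: {"CA": np.array([d, 0.0, 0.0])}},
                ]
            )

        traj = Trajectory([frame(10.0), frame(12.0)])
        spec = ContactSpec("x", 41, 41, 1)
        s = equilibrated_distance(traj, spec)
        assert s.mean == pytest.approx(11.0)
        assert s.sd == pytest.approx(1.0)
        assert equilibrated_distance(traj, spec, ddof=1).sd == pytest.approx(
            np.sqrt(2.0)
        )

    def test_frame_order_invariance(self):
        def frame(d):
            return FilamentModel(
                [{1: {"CA": np.zeros(3)}}, {1: {"CA": np.array([d, 0.0, 0.0])}}]
            )

        spec = ContactSpec("x", 1, 1, 1)
        a = equilibrated_distance(Trajectory([frame(7.0), frame(9.0)]), spec)
        b = equilibrated_distance(Trajectory([frame(9.0), frame(7.0)]), spec)
        assert a.mean == b.mean and a.sd == b.sd

    def test_noisy_endpoints_match_simulation_oracle(self):
        # both endpoints jittered with sigma -> distance is a noncentral
        # 3D norm; oracle = direct Monte Carlo of that norm
        d0, sigma, n_frames = 10.0, 1.0, 4000
        rng = np.random.default_rng(17)
        frames = [
            FilamentModel(
                [
                    {1: {"CA": rng.normal(0.0, sigma, 3)}},
                    {1: {"CA": np.array([d0, 0, 0]) + rng.normal(0.0, sigma, 3)}},
                ]
            )
            for _ in range(n_frames)
        ]
        s = equilibrated_distance(Trajectory(frames), ContactSpec("x", 1, 1, 1))
        oracle_rng = np.random.default_rng(99)
        draws = np.linalg.norm(
            np.array([d0, 0, 0])
            + oracle_rng.normal(0, sigma * np.sqrt(2), (200_000, 3)),
            axis=1,
        )
        se = s.sd / np.sqrt(n_frames)
        assert abs(s.mean - draws.mean()) < 3 * se

    def test_offset_exceeding_filament_errors(self):
        frame = FilamentModel([{1: {"CA": np.zeros(3)}},
                               {1: {"CA": np.ones(3)}}])
        with pytest.raises(ValueError):
            equilibrated_distance(
                Trajectory([frame]), ContactSpec("x", 1, 1, 2)
            )


class TestCountContacts:
    def setup_method(self):
        rng = np.random.default_rng(23)
        self.frame = FilamentModel(
            [
                {r: {"CA": rng.normal(scale=6, size=3)} for r in range(1, 21)}
                for _ in range(4)
            ]
        )
        self.ga = ResidueGroupSpec("a", ((1, 8),))
        self.gb = ResidueGroupSpec("b", ((10, 20),))

    def test_tiny_cutoff_counts_nothing(self):
        res = count_contacts(self.frame, self.ga, self.gb, 2, cutoff=1e-9)
        assert res.mean_count == 0.0

    def test_saturating_cutoff_counts_all_pairs(self):
        res = count_contacts(self.frame, self.ga, self.gb, 2, cutoff=1e6)
        assert np.all(res.counts == 8 * 11)

    def test_matches_brute_force(self):
        cutoff = 8.0
        res = count_contacts(self.frame, self.ga, self.gb, 2, cutoff=cutoff)
        for i in range(2):
            n = 0
            for ra in self.ga.residues:
                for rb in self.gb.residues:
                    d = np.linalg.norm(
                        self.frame.subunits[i][ra]["CA"]
                        - self.frame.subunits[i + 2][rb]["CA"]
                    )
                    n += d <= cutoff
            assert res.counts[i] == n

    def test_monotone_in_cutoff(self):
        counts = [
            count_contacts(self.frame, self.ga, self.gb, 2, cutoff=c).mean_count
            for c in (2.0, 5.0, 8.0, 12.0, 20.0)
        ]
        assert counts == sorted(counts)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            count_contacts(self.frame, self.ga, self.gb, 2, cutoff=0.0)


def quad_model(points):
    """Filament whose SG-group COGs are the four given points."""
    sub = {}
    for g, p in zip(CG_GROUPS, points):
        for r in g.residues:
            sub[r] = {"CA": np.asarray(p, dtype=float)}
    return FilamentModel([sub, sub])


class TestCGGeometry:
    def test_hand_geometry(self):
        g = cg_geometry(
            quad_model([(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 1, 1)]), 0
        )
        assert g.bond_r1_r2 == pytest.approx(1.0)
        assert g.angle_r2_r1_r3 == pytest.approx(90.0)
        assert abs(g.dihedral_r2_r1_r3_r4) == pytest.approx(90.0)
        # documented sign convention: this arrangement is -90
        assert g.dihedral_r2_r1_r3_r4 == pytest.approx(-90.0)

    def test_square_planar_dihedral(self):
        g = cg_geometry(
            quad_model([(1, 0, 0), (0, 0, 0), (1, 1, 0), (0, 1, 0)]), 0
        )
        assert abs(g.dihedral_r2_r1_r3_r4) in (
            pytest.approx(0.0, abs=1e-9),
            pytest.approx(180.0, abs=1e-9),
        )

    def test_dihedral_matches_mdanalysis(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            pts = rng.normal(scale=5, size=(4, 3))
            try:
                g = cg_geometry(quad_model(pts), 0)
            except Exception:
                continue
            # MDAnalysis order (p1,p2,p3,p4) = (R2,R1,R3,R4)
            ref = np.degrees(
                calc_dihedrals(
                    pts[1][None], pts[0][None], pts[2][None], pts[3][None]
                )[0]
            )
            # MDAnalysis computes in float32; match to that precision
            assert g.dihedral_r2_r1_r3_r4 == pytest.approx(ref, abs=1e-4)

    def test_rigid_transform_invariance_and_reflection(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(scale=5, size=(4, 3))
        g0 = cg_geometry(quad_model(pts), 0)
        rot = random_rotation(rng)
        shift = rng.normal(size=3)
        g1 = cg_geometry(quad_model(pts @ rot.T + shift), 0)
        for attr in ("bond_r1_r2", "bond_r1_r3", "bond_r3_r4",
                     "angle_r1_r3_r4", "angle_r2_r1_r3"):
            assert getattr(g1, attr) == pytest.approx(getattr(g0, attr), abs=1e-9)
        assert g1.dihedral_r2_r1_r3_r4 == pytest.approx(
            g0.dihedral_r2_r1_r3_r4, abs=1e-9
        )
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        g2 = cg_geometry(quad_model(mirrored), 0)
        assert g2.dihedral_r2_r1_r3_r4 == pytest.approx(
            -g0.dihedral_r2_r1_r3_r4, abs=1e-9
        )

    def test_collinear_triple_rejected(self):
        from actinmech.core import DegenerateGeometryError

        with pytest.raises(DegenerateGeometryError):
            cg_geometry(
                quad_model([(0, 0, 0), (1, 0, 0), (2, 0, 0), (0, 1, 1)]), 0
            )


class TestTrajectoryCGSummary:
    def test_static_filament_zero_sd(self):
        sub = synthetic_subunit(seed=2)
        traj = generate_filament_ensemble(sub, 3, sigma_xyz=0.0, n_frames=3)
        table = trajectory_cg_summary(traj, representation="ca")
        assert np.allclose(table["sd"], 0.0, atol=1e-9)

    def test_row_order(self, filament_traj):
        table = trajectory_cg_summary(filament_traj, representation="ca")
        assert list(table["parameter"]) == [
            "R1-R2", "R1-R3", "R3-R4", "R1-R3-R4", "R2-R1-R3", "R2-R1-R3-R4",
        ]

    def test_noisy_means_near_noise_free(self):
        sub = synthetic_subunit(seed=4)
        ref = trajectory_cg_summary(
            generate_filament_ensemble(sub, 3, sigma_xyz=0.0, n_frames=1),
            representation="ca",
        )
        noisy = trajectory_cg_summary(
            generate_filament_ensemble(sub, 3, sigma_xyz=0.2, n_frames=200,
                                       seed=6),
            representation="ca",
        )
        for (_, r_ref), (_, r_noisy) in zip(ref.iterrows(), noisy.iterrows()):
            se = r_noisy["sd"] / np.sqrt(r_noisy["n"]) + 1e-6
            assert abs(r_noisy["mean"] - r_ref["mean"]) < 4 * se

    def test_contact_table_shape(self, filament_traj):
        table = contact_table(filament_traj)
        assert len(table) == len(TABLE_CONTACTS)
        assert (table["mean_A"] > 0).all()
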