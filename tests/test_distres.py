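"""Segment minimum distances, residency intervals, backbone RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from amphitraj.distres import (
    backbone_rmsd,
    kabsch_rotation,
    residency,
    segment_min_distances,
)
from amphitraj.schema import LigandSchema

from conftest import make_topology, make_trajectory

SCHEMA = LigandSchema(
    head_atoms=frozenset({"O1"}),
    tail_atoms=("C2", "C3"),
    head_oxygen="O1",
    segments={"HEAD": frozenset({"O1"}), "TAIL": frozenset({"C2", "C3"})},
    analysis_tail=frozenset({"C3"}),
)


def two_subunit_system(head_pos, tail_pos=(10.0, 10.0, 10.0)):
    top = make_topology(
        [
            ("CB", 1, "LEU", "A", "protein"),
            ("CB", 1, "LEU", "B", "protein"),
            ("O1", 1, "DHA", "L", "ligand"),
            ("C2", 1, "DHA", "L", "ligand"),
            ("C3", 1, "DHA", "L", "ligand"),
        ]
    )
    coords = [[40, 50, 50], [60, 50, 50], list(head_pos), list(tail_pos), [11, 10, 10]]
    return top, make_trajectory(top, [coords])


class TestSegmentMinDistances:
    def test_single_minimum(self):
        _, traj = two_subunit_system((44.2, 50, 50))
        prof = segment_min_distances(traj, SCHEMA, "role:protein")
        a = prof.subunits.index("A")
        h = prof.segments.index("HEAD")
        assert prof.distances[0, a, h] == pytest.approx(4.2)

    def test_equidistant_ligand_recorded_for_both_subunits(self):
        _, traj = two_subunit_system((50.0, 50, 50))
        prof = segment_min_distances(traj, SCHEMA, "role:protein")
        h = prof.segments.index("HEAD")
        assert prof.distances[0, 0, h] == pytest.approx(prof.distances[0, 1, h])

    def test_min_of_mins_identity(self, small_system, schema22):
        """Union over segments equals the unsegmented protein-ligand
        minimum distance."""
        top, traj, _ = small_system
        prof = segment_min_distances(traj, schema22, "role:protein")
        from amphitraj.core import minimum_image_displacement
        from amphitraj.selection import resolve

        prot = resolve("role:protein", top)
        names = set().union(*schema22.segments.values())
        lig = np.array(
            [i for i in resolve("role:ligand", top) if top.names[i] in names]
        )
        for fi in (0, 17):
            for si, sub in enumerate(prof.subunits):
                sidx = np.array([i for i in prot if top.chain_ids[i] == sub])
                d = minimum_image_displacement(
                    traj.xyz[fi, sidx][:, None], traj.xyz[fi, lig][None], traj.boxes[fi]
                )
                direct = np.sqrt((d**2).sum(axis=-1)).min()
                assert prof.distances[fi, si].min() == pytest.approx(direct)

    def test_se_invariant_to_subunit_relabelling(self, small_system, schema22):
        top, traj, _ = small_system
        prof = segment_min_distances(traj, schema22, "role:protein")
        se = prof.summary()["stderr_A"].to_numpy()
        perm = prof.distances[:, ::-1, :]
        per_sub = perm.mean(axis=0)
        se_perm = per_sub.std(axis=0, ddof=1) / np.sqrt(per_sub.shape[0])
        assert se == pytest.approx(se_perm)

    def test_head_tail12_22_mode(self, small_system, schema22):
        _, traj, _ = small_system
        prof = segment_min_distances(
            traj, schema22, "role:protein", segmentation="head_tail12_22"
        )
        assert set(prof.segments) == {"head", "analysis_tail"}

    def test_empty_subunit_selection_names_subunit(self):
        # subunit B contributes only hydrogens, which the heavy-atom policy
        # strips: the error must name the offending subunit
        top = make_topology(
            [
                ("CB", 1, "LEU", "A", "protein"),
                ("HB", 1, "LEU", "B", "protein"),
                ("O1", 1, "DHA", "L", "ligand"),
                ("C2", 1, "DHA", "L", "ligand"),
                ("C3", 1, "DHA", "L", "ligand"),
            ]
        )
        traj = make_trajectory(
            top, [[[40, 50, 50], [60, 50, 50], [45, 50, 50], [10, 10, 10], [11, 10, 10]]]
        )
        with pytest.raises(ValueError, match="'B'"):
            segment_min_distances(traj, SCHEMA, "role:protein")

    def test_unknown_segmentation(self):
        _, traj = two_subunit_system((44, 50, 50))
        with pytest.raises(ValueError, match="segmentation"):
            segment_min_distances(traj, SCHEMA, "role:protein", segmentation="bogus")


def residency_fixture(pattern, dt=1.0):
    """One target atom; one mobile ligand molecule following the pattern."""
    top = make_topology(
        [("CB", 1, "LEU", "A", "protein"), ("O1", 1, "DHA", "L", "ligand")]
    )
    coords = [
        [[50, 50, 50], [51.0 if hit else 80.0, 50, 50]] for hit in pattern
    ]
    return make_trajectory(top, coords, dt=dt)


class TestResidency:
    def test_single_block_interval(self):
        traj = residency_fixture([True] * 10 + [False] * 90)
        rec = residency(traj, "role:protein", "role:ligand", cutoff=2.0)
        assert rec.intervals[("L", 1)] == [(0.0, 10.0)]
        assert rec.counts[:10].tolist() == [1] * 10
        assert rec.counts[10:].sum() == 0

    def test_never_resident(self):
        traj = residency_fixture([False] * 20)
        rec = residency(traj, "role:protein", "role:ligand", cutoff=2.0)
        assert rec.intervals[("L", 1)] == []

    def test_gap_tolerance_merges_single_frame_gap(self):
        pattern = [True] * 5 + [False] + [True] * 5 + [False] * 9
        strict = residency(residency_fixture(pattern), "role:protein", "role:ligand", 2.0, gap_frames=0)
        merged = residency(residency_fixture(pattern), "role:protein", "role:ligand", 2.0, gap_frames=1)
        assert len(strict.intervals[("L", 1)]) == 2
        assert len(merged.intervals[("L", 1)]) == 1
        assert merged.intervals[("L", 1)][0][1] - merged.intervals[("L", 1)][0][0] == pytest.approx(11.0)

    def test_counts_equal_interval_coverage(self, planted_system):
        (top, traj, _), _ = planted_system
        rec = residency(traj, "role:protein", "role:ligand", cutoff=3.5)
        for fi, t in enumerate(rec.times_ns):
            covering = sum(
                any(a - 1e-9 <= t < b - 1e-9 or (fi == traj.n_frames - 1 and a <= t <= b)
                    for a, b in ivs)
                for ivs in rec.intervals.values()
            )
            assert covering == rec.counts[fi]

    def test_planted_residency_intervals_recovered(self, planted_system):
        (top, traj, truth), contacts = planted_system
        rec = residency(traj, "role:protein", "role:ligand", cutoff=3.5)
        for pc in contacts:
            ivs = rec.intervals[("L", pc.ligand_id + 1)]
            assert len(ivs) == 1
            a, b = ivs[0]
            lo, hi = pc.intervals[0]
            # realised interval covers the planted one to frame resolution
            assert a == pytest.approx(lo, abs=traj.dt_ns)
            assert (b - a) == pytest.approx(hi - lo + traj.dt_ns, abs=traj.dt_ns)

    def test_cutoff_beyond_half_box_rejected(self):
        traj = residency_fixture([True])
        with pytest.raises(ValueError, match="half"):
            residency(traj, "role:protein", "role:ligand", cutoff=60.0)


def backbone_fixture(n_atoms=12, n_frames=4, seed=0, displace=None):
    rng = np.random.default_rng(seed)
    base = rng.uniform(0, 20, (n_atoms, 3))
    spec = [("CA", i + 1, "ALA", "A", "protein") for i in range(n_atoms)]
    top = make_topology(spec)
    coords = [base.copy() for _ in range(n_frames)]
    if displace is not None:
        frame, atom, delta = displace
        coords[frame] = coords[frame].copy()
        coords[frame][atom] += delta
    return top, make_trajectory(top, coords)


class TestBackboneRmsd:
    def test_identical_frames_zero(self):
        _, traj = backbone_fixture()
        series = backbone_rmsd(traj, "role:protein")
        assert series.rmsd_A == pytest.approx(np.zeros(traj.n_frames), abs=1e-9)

    def test_rigid_rotation_gives_zero(self):
        top, traj = backbone_fixture(n_frames=1)
        R = Rotation.from_euler("xyz", [90, 30, -40], degrees=True).as_matrix()
        rotated = traj.xyz[0] @ R.T + np.array([5.0, -3.0, 2.0])
        traj2 = make_trajectory(top, [traj.xyz[0], rotated], dt=1.0)
        series = backbone_rmsd(traj2, "role:protein")
        assert series.rmsd_A == pytest.approx([0.0, 0.0], abs=1e-9)

    def test_displaced_atom_matches_scipy_superposition_oracle(self):
        """Two-frame RMSD agrees with an independent quaternion-based
        superposition (scipy Rotation.align_vectors)."""
        n = 10
        top, traj = backbone_fixture(
            n_atoms=n, n_frames=2, displace=(1, 0, np.array([1.0, 0, 0]))
        )
        series = backbone_rmsd(traj, "role:protein")

        A = traj.xyz[0] - traj.xyz[0].mean(axis=0)
        B = traj.xyz[1] - traj.xyz[1].mean(axis=0)
        avg = (A + B) / 2  # frames already aligned to frame 0's frame
        avg -= avg.mean(axis=0)
        expected = []
        for X in (A, B):
            rot, _ = Rotation.align_vectors(avg, X)
            expected.append(
                np.sqrt(np.mean(np.sum((X @ rot.as_matrix().T - avg) ** 2, axis=1)))
            )
        # pass 1 of the implementation aligns frame 1 onto frame 0 first;
        # for a 1-atom displacement that alignment is a small rotation, so
        # agree to a loose tolerance on the oracle and exactly on symmetry
        assert series.rmsd_A == pytest.approx(expected, abs=5e-3)

    def test_invariant_under_random_rigid_motion_of_frames(self):
        top, traj = backbone_fixture(n_frames=5, seed=3)
        rng = np.random.default_rng(8)
        base = backbone_rmsd(traj, "role:protein").rmsd_A
        moved = []
        for fi in range(traj.n_frames):
            R = Rotation.random(random_state=np.random.RandomState(fi + 1)).as_matrix()
            t = rng.uniform(-10, 10, 3)
            moved.append(traj.xyz[fi] @ R.T + t)
        traj2 = make_trajectory(top, moved)
        assert backbone_rmsd(traj2, "role:protein").rmsd_A == pytest.approx(
            base, abs=1e-9
        )

    def test_collinear_geometry_rejected(self):
        spec = [("CA", i + 1, "ALA", "A", "protein") for i in range(5)]
        top = make_topology(spec)
        coords = [[[float(i), 0, 0] for i in range(5)]]
        traj = make_trajectory(top, coords)
        with pytest.raises(ValueError, match="collinear"):
            backbone_rmsd(traj, "role:protein")

    def test_kabsch_recovers_known_rotation(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(20, 3))
        P -= P.mean(axis=0)
        R_true = Rotation.from_euler("zyx", [10, 60, -130], degrees=True).as_matrix()
        Q = P @ R_true.T
        R = kabsch_rotation(P, Q)
        assert R == pytest.approx(R_true, abs=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0)
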