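"""Contact detection, persistence filtering, region roll-ups, proximity
counts — each checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from amphitraj.contacts import (
    ContactCriterion,
    ContactTable,
    contact_table,
    detect_contacts,
    proximity_count,
    region_summary,
)
from amphitraj.core import minimum_image_distance
from amphitraj.schema import LigandSchema

from conftest import make_topology, make_trajectory


def two_atom_system(distance):
    """One protein CB and one ligand head atom a given distance apart."""
    top = make_topology(
        [("CB", 10, "LEU", "A", "protein"), ("O1", 1, "DHA", "L", "ligand"), ("C2", 1, "DHA", "L", "ligand")]
    )
    coords = [[50, 50, 50], [50 + distance, 50, 50], [10, 10, 10]]
    return make_trajectory(top, [coords])


SIMPLE_SCHEMA = LigandSchema(
    head_atoms=frozenset({"O1"}), tail_atoms=("C2",), head_oxygen="O1"
)


class TestDetection:
    @pytest.mark.parametrize("d,expected", [(3.4, True), (3.6, False)])
    def test_cutoff_boundary(self, d, expected):
        traj = two_atom_system(d)
        events = detect_contacts(
            traj, ContactCriterion(3.5, 0.0), "role:protein", SIMPLE_SCHEMA
        )
        head = events.parts.index("head")
        assert bool(events.events[0, 0, head]) is expected

    def test_cutoff_beyond_half_box_rejected(self):
        traj = two_atom_system(3.0)
        with pytest.raises(ValueError, match="half"):
            detect_contacts(
                traj, ContactCriterion(60.0, 0.0), "role:protein", SIMPLE_SCHEMA
            )

    def test_grid_equals_brute_force_on_random_instances(self):
        """Neighbor-grid detection is defined to equal O(N²) brute force."""
        rng = np.random.default_rng(10)
        for trial in range(100):
            n_prot, n_lig = 30, 12
            box = rng.uniform(20, 40, 3)
            spec = []
            for i in range(n_prot):
                spec.append(("CB", int(i // 3) + 1, "LEU", "A", "protein"))
            for i in range(n_lig):
                spec.append((rng.choice(["O1", "C2"]), 1, "DHA", "L", "ligand"))
            top = make_topology(spec)
            coords = rng.uniform(-10, 50, (2, n_prot + n_lig, 3))
            traj = make_trajectory(top, list(coords), box=tuple(box))
            cutoff = float(rng.uniform(1.0, 8.0))
            crit = ContactCriterion(cutoff, 0.0)
            events = detect_contacts(traj, crit, "role:protein", SIMPLE_SCHEMA)

            for fi in range(2):
                for ri, (chain, resid, _) in enumerate(events.residues):
                    ridx = [
                        i
                        for i, a in enumerate(top.atoms)
                        if a.chain_id == chain and a.residue_id == resid
                    ]
                    for pi, part in enumerate(events.parts):
                        name = "O1" if part == "head" else "C2"
                        pidx = [
                            i for i, a in enumerate(top.atoms)
                            if a.role.value == "ligand" and a.name == name
                        ]
                        if not pidx:
                            continue
                        dmin = min(
                            minimum_image_distance(
                                traj.xyz[fi, i], traj.xyz[fi, j], box
                            )
                            for i in ridx
                            for j in pidx
                        )
                        assert bool(events.events[fi, ri, pi]) == (dmin <= cutoff)

    def test_enlarging_cutoff_never_removes_contacts(self, planted_system, schema22):
        (top, traj, _), _ = planted_system
        small = detect_contacts(
            traj, ContactCriterion(3.5, 0.0), "role:protein", schema22
        )
        large = detect_contacts(
            traj, ContactCriterion(5.0, 0.0), "role:protein", schema22
        )
        assert np.all(large.events[small.events])


class TestTable:
    def make_events_trajectory(self, pattern, dt=10.0):
        """Ligand head within range in exactly the frames marked True."""
        top = make_topology(
            [("CB", 10, "LEU", "A", "protein"), ("O1", 1, "DHA", "L", "ligand"), ("C2", 1, "DHA", "L", "ligand")]
        )
        coords = []
        for hit in pattern:
            x = 52.0 if hit else 80.0
            coords.append([[50, 50, 50], [x, 50, 50], [10, 10, 10]])
        return make_trajectory(top, coords, dt=dt)

    def test_boundary_exactly_at_threshold_excluded(self):
        """30 of 100 frames at dt 10 ns → cumulative 300 ns, frequency 0.3,
        excluded by the strict 'more than 300 ns' filter."""
        pattern = [True] * 30 + [False] * 70
        traj = self.make_events_trajectory(pattern)
        crit = ContactCriterion(3.5, 300.0)
        table = contact_table(
            detect_contacts(traj, crit, "role:protein", SIMPLE_SCHEMA), traj
        )
        row = table.raw.iloc[0]
        assert row.cumulative_ns == pytest.approx(300.0)
        assert row.frequency == pytest.approx(0.3)
        assert len(table.filtered) == 0
        # one instant more and it qualifies
        crit2 = ContactCriterion(3.5, 299.999)
        table2 = ContactTable(table.raw, crit2, table.total_time_ns)
        assert len(table2.filtered) == 1

    def test_always_in_contact_frequency_one(self):
        traj = self.make_events_trajectory([True] * 20)
        table = contact_table(
            detect_contacts(traj, ContactCriterion(3.5, 0.0), "role:protein", SIMPLE_SCHEMA),
            traj,
        )
        assert table.raw.iloc[0].frequency == pytest.approx(1.0)

    def test_planted_interval_cumulative_sum(self):
        """Intervals [2,5] and [8,9] ns on a 0.1 ns grid → 4.0 ns within one
        frame quantum."""
        dt = 0.1
        n = 120
        pattern = [(2.0 <= i * dt <= 5.0) or (8.0 <= i * dt <= 9.0) for i in range(n)]
        traj = self.make_events_trajectory(pattern, dt=dt)
        table = contact_table(
            detect_contacts(traj, ContactCriterion(3.5, 0.0), "role:protein", SIMPLE_SCHEMA),
            traj,
        )
        # boundary frames are inclusive, so the realised sum is the planted
        # 4 ns plus one frame quantum per interval edge
        assert table.raw.iloc[0].cumulative_ns == pytest.approx(4.0, abs=3 * dt)

    def test_longest_continuous_mode(self):
        pattern = [True] * 5 + [False] + [True] * 10 + [False] * 4
        traj = self.make_events_trajectory(pattern, dt=1.0)
        crit = ContactCriterion(3.5, 8.0, persistence_mode="longest_continuous")
        table = contact_table(
            detect_contacts(traj, crit, "role:protein", SIMPLE_SCHEMA), traj
        )
        assert table.raw.iloc[0].longest_continuous_ns == pytest.approx(10.0)
        assert len(table.filtered) == 1

    def test_raising_threshold_never_adds_rows(self):
        pattern = [True] * 30 + [False] * 70
        traj = self.make_events_trajectory(pattern)
        events = detect_contacts(
            traj, ContactCriterion(3.5, 0.0), "role:protein", SIMPLE_SCHEMA
        )
        table = contact_table(events, traj)
        sizes = []
        for thr in (0.0, 100.0, 200.0, 299.0, 300.0, 400.0):
            t = ContactTable(table.raw, ContactCriterion(3.5, thr), table.total_time_ns)
            sizes.append(len(t.filtered))
        assert sizes == sorted(sizes, reverse=True)

    def test_frequency_normalisation_identity(self, planted_system, schema22):
        (top, traj, _), _ = planted_system
        events = detect_contacts(
            traj, ContactCriterion(3.5, 0.0), "role:protein", schema22
        )
        table = contact_table(events, traj)
        durations = traj.frame_durations()
        for _, row in table.raw.iterrows():
            ri = events.residues.index(
                (row.chain_id, row.residue_id, row.residue_name)
            )
            pi = events.parts.index(row.ligand_part)
            expected = durations[events.events[:, ri, pi]].sum()
            assert row.cumulative_ns == pytest.approx(expected)


class TestRegionSummary:
    def make_table(self, rows):
        df = pd.DataFrame(
            rows,
            columns=[
                "chain_id", "residue_id", "residue_name", "ligand_part",
                "cumulative_ns", "longest_continuous_ns", "frequency", "region",
                "extracellular", "residue_class",
            ],
        )
        return ContactTable(df, ContactCriterion(3.5, 0.0), 100.0)

    def test_s3_s4_fraction_arithmetic(self, small_system):
        top = small_system[0]
        rows = [
            ("A", 326 + i, "LEU", "tail", 50.0, 50.0, 0.5, "S4", True, "hydrophobic")
            for i in range(4)
        ] + [("A", 301, "LEU", "tail", 50.0, 50.0, 0.5, "S1", False, "hydrophobic")]
        summary = region_summary(self.make_table(rows), top)
        assert summary.fraction_s3_s4["tail"] == pytest.approx(0.8)
        frac = summary.per_part
        assert frac[frac.ligand_part == "tail"]["fraction"].sum() == pytest.approx(1.0)

    def test_empty_table_reports_zero_counts(self, small_system):
        summary = region_summary(self.make_table([]), small_system[0])
        assert summary.counts == {}
        assert summary.tail_head_ratio is None

    def test_tail_head_ratio(self, small_system):
        rows = [
            ("A", 326, "LEU", "tail", 50.0, 50.0, 0.5, "S4", True, "hydrophobic"),
            ("A", 327, "ILE", "tail", 50.0, 50.0, 0.5, "S4", True, "hydrophobic"),
            ("A", 322, "SER", "head", 50.0, 50.0, 0.5, "S3-S4_linker", True, "polar"),
        ]
        summary = region_summary(self.make_table(rows), small_system[0])
        assert summary.tail_head_ratio == pytest.approx(2.0)

    def test_planted_85_percent_on_s3_s4(self):
        """17 of 20 qualifying tail rows on S3/S4 → fraction 0.85."""
        rows = []
        for i in range(17):
            region = "S3" if i % 2 else "S4"
            rows.append(("A", 316 + i, "LEU", "tail", 50.0, 50.0, 0.5, region, True, "hydrophobic"))
        for i in range(3):
            rows.append(("A", 301 + i, "LEU", "tail", 50.0, 50.0, 0.5, "S1", False, "hydrophobic"))
        from conftest import make_topology

        top = make_topology([("CB", 1, "LEU", "A", "protein")])
        summary = region_summary(self.make_table(rows), top)
        assert summary.fraction_s3_s4["tail"] == pytest.approx(0.85)


class TestProximityCount:
    def test_two_ions_one_inside(self):
        top = make_topology(
            [("CB", 1, "LEU", "A", "protein"), ("NA", 1, "NA", "I", "ion"), ("NA", 2, "NA", "I", "ion")]
        )
        coords = [[50, 50, 50], [53.0, 50, 50], [55.0, 50, 50]]
        traj = make_trajectory(top, [coords])
        counts = proximity_count(traj, "role:protein", "role:ion", 3.5)
        assert counts.tolist() == [1]

    def test_probe_equals_target_excludes_self_pairing(self):
        top = make_topology(
            [("NA", 1, "NA", "I", "ion"), ("NA", 2, "NA", "I", "ion")]
        )
        traj = make_trajectory(top, [[[50, 50, 50], [52, 50, 50]]])
        # both atoms have a non-self neighbour within 3.5 → both count
        assert proximity_count(traj, "role:ion", "role:ion", 3.5).tolist() == [2]
        lone = make_trajectory(
            make_topology([("NA", 1, "NA", "I", "ion")]), [[[50, 50, 50]]]
        )
        assert proximity_count(lone, "role:ion", "role:ion", 3.5).tolist() == [0]

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(77)
        for _ in range(30)        :
            n_t, n_p = 15, 10
            box = (30.0, 30.0, 30.0)
            spec = [("CB", i + 1, "LEU", "A", "protein") for i in range(n_t)] + [
                ("NA", i + 1, "NA", "I", "ion") for i in range(n_p)
            ]
            top = make_topology(spec)
            coords = rng.uniform(0, 30, (1, n_t + n_p, 3))
            traj = make_trajectory(top, list(coords), box=box)
            cutoff = float(rng.uniform(2, 10))
            got = proximity_count(traj, "role:protein", "role:ion", cutoff)[0]
            expected = 0
            for j in range(n_t, n_t + n_p):
                dmin = min(
                    minimum_image_distance(coords[0, j], coords[0, i], np.array(box))
                    for i in range(n_t)
                )
                expected += dmin <= cutoff
            assert got == expected

    def test_molecule_grouping(self):
        top = make_topology(
            [("CB", 1, "LEU", "A", "protein"),
             ("C1", 5, "POP", "M", "lipid"), ("C2", 5, "POP", "M", "lipid")]
        )
        coords = [[50, 50, 50], [52, 50, 50], [53, 50, 50]]
        traj = make_trajectory(top, [coords])
        atoms = proximity_count(traj, "role:protein", "role:lipid", 3.5)
        mols = proximity_count(traj, "role:protein", "role:lipid", 3.5, group_by_molecule=True)
        assert atoms.tolist() == [2] and mols.tolist() == [1]
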