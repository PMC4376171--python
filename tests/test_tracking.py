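import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxypath.annotation import CavityDefinition, HelixTable
from oxypath.errors import ParameterError, TopologyError
from oxypath.tracking import (
    CrossingEvent,
    EscapeEvent,
    LigandTrack,
    TrackingParams,
    cavity_occupancy,
    classify_portal,
    detect_crossings,
    detect_escape,
    is_interface_resident,
    min_surface_distance,
    summarize_pathways,
)
from oxypath.trajio import AtomTable, Trajectory


def _track(surface=None, subunit=None, positions=None, nearest=None, copy=1):
    n = len(surface) if surface is not None else len(subunit)
    return LigandTrack(
        copy=copy,
        positions=np.zeros((n, 3)) if positions is None else np.asarray(positions, float),
        surface_dist=np.zeros(n) if surface is None else np.asarray(surface, float),
        nearest_chain=np.array(["A"] * n if nearest is None else nearest, dtype=object),
        subunit=np.array(["A"] * n if subunit is None else subunit, dtype=object),
    )


class TestMinSurfaceDistance:
    def test_single_atom(self):
        assert min_surface_distance(np.array([0.0, 0.0, 6.0]),
                                    np.array([[0.0, 0.0, 0.0]])) == pytest.approx(6.0)

    def test_coincident(self):
        p = np.array([[1.0, 2.0, 3.0]])
        assert min_surface_distance(p[0], p) == 0.0

    def test_center_of_diatomic(self):
        lig = np.array([[0.0, 0.0, 5.4], [0.0, 0.0, 6.6]])  # center at z=6
        assert min_surface_distance(lig, np.array([[0.0, 0.0, 0.0]])) == pytest.approx(6.0)

    def test_matches_bruteforce_cloud(self, rng):
        for _ in range(20):
            cloud = rng.normal(size=(50, 3)) * 8
            center = rng.normal(size=3) * 8
            expected = np.min(np.linalg.norm(cloud - center, axis=1))
            got = min_surface_distance(center, cloud)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_minimum_image_box(self):
        box = np.array([10.0, 10.0, 10.0])
        got = min_surface_distance(np.array([9.5, 0.0, 0.0]),
                                   np.array([[0.5, 0.0, 0.0]]), box=box)
        assert got == pytest.approx(1.0)

    def test_empty_protein_raises(self):
        with pytest.raises(ValueError):
            min_surface_distance(np.zeros(3), np.zeros((0, 3)))


class TestDetectEscape:
    def test_basic_event(self):
        ev = detect_escape(np.array([1, 2, 6, 7, 8.0]), threshold=5, persistence=2)
        assert ev.frame == 2

    def test_non_escaper(self):
        assert detect_escape(np.array([1, 2, 3, 4.0]), 5, 2) is None

    def test_flicker_filtered(self):
        # enumerated by hand: runs are [1] at idx 1 and [3,4,5]; only the
        # second satisfies persistence 3
        ev = detect_escape(np.array([1, 6, 1, 6, 6, 6.0]), 5, persistence=3)
        assert ev.frame == 3

    def test_run_to_trajectory_end_counts(self):
        ev = detect_escape(np.array([1.0, 6.0]), 5, persistence=3)
        assert ev.frame == 1

    def test_persistence_validation(self):
        with pytest.raises(ParameterError):
            detect_escape(np.array([1.0]), 5, persistence=0)

    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=40),
           st.integers(1, 5))
    @settings(max_examples=200, deadline=None)
    def test_raising_threshold_never_earlier(self, series, persistence):
        lo = detect_escape(np.asarray(series), 3.0, persistence)
        hi = detect_escape(np.asarray(series), 6.0, persistence)
        if hi is not None:
            assert lo is not None
            assert hi.frame >= lo.frame

    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=40),
           st.integers(1, 5))
    @settings(max_examples=200, deadline=None)
    def test_against_window_enumeration(self, series, persistence):
        """Independent oracle: the first index whose (end-truncated)
        persistence window lies entirely above the threshold."""
        s = np.asarray(series)
        expected = next(
            (i for i in range(len(s))
             if all(x > 5.0 for x in s[i:i + persistence])),
            None,
        )
        got = detect_escape(s, 5.0, persistence)
        assert (got.frame if got else None) == expected


def _portal_fixture():
    """Three one-atom helices on chain A; classification point at origin."""
    n = 4
    atoms = AtomTable(
        serial=np.arange(1, n + 1),
        name=np.array(["CA"] * n, dtype=object),
        element=np.array(["C"] * n, dtype=object),
        resname=np.array(["GLY"] * n, dtype=object),
        resid=np.array([1, 2, 3, 4]),
        chain=np.array(["A"] * n, dtype=object),
        role=np.array(["protein"] * n, dtype=object),
        copy_index=np.zeros(n, dtype=int),
    )
    table = HelixTable(helices={("A", "A"): (1, 1), ("A", "B"): (2, 2),
                                ("A", "C"): (3, 3)},
                       corners={("A", "FG"): (4, 4)})
    coords = np.zeros((2, n, 3), dtype=np.float32)
    return atoms, table, coords


class TestClassifyPortal:
    def test_tie_break_smaller_labels(self):
        atoms, table, coords = _portal_fixture()
        # all three helices exactly 5 A away; corner far
        coords[:, 0] = [5.0, 0, 0]
        coords[:, 1] = [0, 5.0, 0]
        coords[:, 2] = [0, 0, 5.0]
        coords[:, 3] = [30.0, 0, 0]
        traj = Trajectory(coords=coords, dt=1.0)
        track = _track(surface=[1.0, 6.0])
        ev = EscapeEvent(copy=1, frame=1)
        assert classify_portal(track, ev, table, atoms, traj) == "A-B"

    def test_alphabetical_pair_order(self):
        atoms, table, coords = _portal_fixture()
        coords[:, 0] = [40.0, 0, 0]   # helix A far
        coords[:, 1] = [0, 6.0, 0]    # helix B near
        coords[:, 2] = [0, 0, 4.0]    # helix C nearest
        coords[:, 3] = [30.0, 0, 0]
        traj = Trajectory(coords=coords, dt=1.0)
        ev = EscapeEvent(copy=1, frame=1)
        assert classify_portal(_track(surface=[1.0, 6.0]), ev, table, atoms, traj) == "B-C"

    def test_corner_wins_when_nearest(self):
        atoms, table, coords = _portal_fixture()
        coords[:, 0] = [0, 8.0, 0]
        coords[:, 1] = [0, 0, 9.0]
        coords[:, 2] = [0, -10.0, 0]
        coords[:, 3] = [3.0, 0, 0]    # corner atom nearest
        traj = Trajectory(coords=coords, dt=1.0)
        ev = EscapeEvent(copy=1, frame=1)
        assert classify_portal(_track(surface=[1.0, 6.0]), ev, table, atoms, traj) \
            == "corner:FG"

    def test_unclassified_beyond_bound(self):
        atoms, table, coords = _portal_fixture()
        for i, p in enumerate([[40.0, 0, 0], [0, 45.0, 0], [0, 0, 50.0], [60.0, 0, 0]]):
            coords[:, i] = p
        traj = Trajectory(coords=coords, dt=1.0)
        ev = EscapeEvent(copy=1, frame=1)
        assert classify_portal(_track(surface=[1.0, 6.0]), ev, table, atoms, traj) \
            == "unclassified"

    def test_opposite_chain_is_interface(self):
        atoms, table, coords = _portal_fixture()
        traj = Trajectory(coords=coords, dt=1.0)
        track = _track(surface=[1.0, 6.0], nearest=["B", "B"], subunit=["A", "A"])
        ev = EscapeEvent(copy=1, frame=1)
        assert classify_portal(track, ev, table, atoms, traj) == "interface"

    def test_requires_event(self):
        atoms, table, coords = _portal_fixture()
        traj = Trajectory(coords=coords, dt=1.0)
        with pytest.raises(ValueError):
            classify_portal(_track(surface=[1.0, 6.0]), None, table, atoms, traj)


class TestCavityOccupancy:
    def _fixture(self):
        atoms, _, _ = _portal_fixture()
        cav_a = CavityDefinition("Beta", 4.5, [("A", 1), ("A", 2), ("A", 3)])
        cav_b = CavityDefinition("Alpha", 4.5, [("A", 2), ("A", 3), ("A", 4)])
        return atoms, [cav_a, cav_b]

    def test_scripted_center(self, toy_protein, analyzed_run):
        protein, traj, truth, result = analyzed_run
        for kstr, rec in truth["copies"].items():
            if rec["outcome"] == "escape":
                ev = [e for e in result.escapes if e.copy == int(kstr)][0]
                assert ev.last_cavity == rec["last_cavity"]

    def test_exact_tie_alphabetical(self):
        atoms, cavs = self._fixture()
        coords = np.zeros((1, 4, 3), dtype=np.float32)
        # both cavity centroids coincide at the origin -> exact tie
        coords[0, 0] = [1, 0, 0]; coords[0, 1] = [-0.5, 1, 0]
        coords[0, 2] = [-0.5, -1, 0]; coords[0, 3] = [0, 0, 0]
        cavs[1].residues = [("A", 1), ("A", 2), ("A", 3)]  # same centroid
        traj = Trajectory(coords=coords, dt=1.0)
        track = _track(surface=[1.0], positions=[[0.0, 0.0, 0.0]])
        labels, _ = cavity_occupancy(track, cavs, traj, atoms)
        assert labels[0] == "Alpha"

    def test_outside_cutoff_is_none(self):
        atoms, cavs = self._fixture()
        coords = np.zeros((1, 4, 3), dtype=np.float32)
        traj = Trajectory(coords=coords, dt=1.0)
        track = _track(surface=[1.0], positions=[[30.0, 0.0, 0.0]])
        labels, last = cavity_occupancy(track, cavs, traj, atoms, escape_frame=1)
        assert labels[0] is None and last is None


class TestDetectCrossings:
    def test_confirmed_crossing(self):
        sub = ["A"] * 50 + ["interface"] * 5 + ["B"] * 50
        events = detect_crossings(_track(subunit=sub), dwell=10)
        assert len(events) == 1
        ev = events[0]
        assert (ev.origin, ev.destination, ev.returned) == ("A", "B", False)
        assert ev.departure_frame == 49 and ev.arrival_frame == 55

    def test_flicker_shorter_than_dwell(self):
        sub = ["A"] * 50 + ["B"] * 4 + ["A"] * 50
        assert detect_crossings(_track(subunit=sub), dwell=10) == []

    def test_round_trip_returned(self):
        sub = ["A"] * 40 + ["B"] * 40 + ["A"] * 40
        events = detect_crossings(_track(subunit=sub), dwell=10)
        assert len(events) == 1
        assert events[0].returned is True
        assert events[0].origin == events[0].destination == "A"

    def test_single_chain_topology_rejected(self):
        from tests.test_trajio import _small_table
        table = _small_table()
        table.chain[:] = "A"
        with pytest.raises(TopologyError, match="single-chain"):
            detect_crossings(_track(subunit=["A", "A"]), dwell=1, atoms=table)

    def test_dwell_validation(self):
        with pytest.raises(ParameterError):
            detect_crossings(_track(subunit=["A", "B"]), dwell=0)

    def test_interface_resident_flag(self):
        tr = _track(subunit=["A"] * 10 + ["interface"] * 90)
        assert is_interface_resident(tr, escaped=False, dwell=25)
        assert not is_interface_resident(tr, escaped=True, dwell=25)
        assert not is_interface_resident(_track(subunit=["A"] * 100),
                                         escaped=False, dwell=25)


class TestSummarize:
    def test_no_events(self):
        s = summarize_pathways([], [], n_copies=14)
        assert s.non_escaped == 14
        s.validate()

    def test_accounting_identity(self):
        events = [EscapeEvent(copy=i, frame=10 * i, portal="B-G") for i in range(1, 6)]
        s = summarize_pathways(events, [], 14, interface_resident={7, 8})
        assert sum(s.portal_counts.values()) + s.non_escaped + s.interface_resident == 14
        assert s.portal_counts == {"B-G": 5}
        assert s.non_escaped == 7

    def test_duplicate_copy_rejected(self):
        events = [EscapeEvent(copy=1, frame=5, portal="B-G"),
                  EscapeEvent(copy=1, frame=9, portal="E-F")]
        with pytest.raises(ValueError, match="duplicate"):
            summarize_pathways(events, [], 14)

    def test_escaper_cannot_be_resident(self):
        with pytest.raises(ValueError):
            summarize_pathways([EscapeEvent(copy=1, frame=5, portal="B-G")],
                               [], 14, interface_resident={1})

    def test_crossing_event_invariants(self):
        with pytest.raises(ValueError):
            CrossingEvent(copy=1, departure_frame=10, arrival_frame=5,
                          origin="A", destination="B")
        with pytest.raises(ValueError):
            CrossingEvent(copy=1, departure_frame=1, arrival_frame=5,
                          origin="A", destination="A", returned=False)
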