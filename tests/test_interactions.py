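"""Geometric interaction criteria, frame scanning and aggregation."""

import dataclasses
import math

import numpy as np
import pytest

from conftest import events_as_set, make_random_frame, oracle_scan
from hemelock.errors import ContractViolation, UnresolvedGeometryError
from hemelock.interactions import (
    AcceptorSpec,
    Category,
    DonorSpec,
    GeometricCriteria,
    aggregate,
    default_acceptors,
    detect_hbond,
    detect_salt_bridge,
    load_donor_dictionary,
    scan_frame,
)
from hemelock.io_structures import Atom, Structure

ACC = AcceptorSpec("A", "O1A", ("CGA",))
ACC_XYZ = (0.0, 0.0, 0.0)
Y_XYZ = {"CGA": (1.25, 0.0, 0.0)}  # D-A-Y measured against the carboxylate C


def _donor_at(d, xda=120.0, day=120.0):
    """Donor at distance d from the acceptor with prescribed angles."""
    th = math.radians(day)
    dpos = np.array([d * math.cos(th), d * math.sin(th), 0.0])
    a_hat = -dpos / np.linalg.norm(dpos)
    q = np.cross(a_hat, [0.0, 0.0, 1.0])
    q /= np.linalg.norm(q)
    xi = math.radians(xda)
    xpos = dpos + 1.5 * (math.cos(xi) * a_hat + math.sin(xi) * q)
    return tuple(dpos), tuple(xpos)


class TestCriteriaDefaults:
    def test_published_cutoffs_are_the_defaults(self):
        c = GeometricCriteria()
        assert (c.d_max_NO, c.d_max_SC, c.d_max_saltbridge) == (3.4, 3.8, 5.6)
        assert (c.angle_min, c.angle_max) == (90.0, 180.0)

    @pytest.mark.parametrize("kwargs", [
        {"d_max_NO": 4.0, "d_max_SC": 3.8},     # NO cutoff above SC cutoff
        {"d_max_saltbridge": 3.0},              # below the SC cutoff
        {"angle_min": 100.0, "angle_max": 90.0},
        {"angle_max": 200.0},
    ])
    def test_invalid_criteria_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeometricCriteria(**kwargs)


class TestDetectHbond:
    N_DONOR = DonorSpec("ASN", "ND2", "sidechain_polar", ("CG",))
    CA_DONOR = DonorSpec("ALA", "CA", "backbone_carbon", ("N",))
    O_DONOR = DonorSpec("SER", "OG", "sidechain_polar", ("CB",))

    def _run(self, spec, d, xda=120.0, day=120.0, ant_name=None):
        dpos, xpos = _donor_at(d, xda, day)
        ants = {ant_name or spec.antecedent_atoms[0]: xpos}
        return detect_hbond(spec, dpos, ants, ACC, ACC_XYZ, Y_XYZ)

    def test_nitrogen_donor_inside_thresholds(self):
        ev = self._run(self.N_DONOR, 3.0)
        assert ev is not None and ev.category is Category.SC_H
        assert ev.d == pytest.approx(3.0)
        assert ev.angle_xda == pytest.approx(120.0, abs=1e-6)
        assert ev.angle_day == pytest.approx(120.0, abs=1e-6)

    def test_nitrogen_donor_beyond_3p4(self):
        assert self._run(self.N_DONOR, 3.5) is None

    def test_carbon_donor_uses_relaxed_cutoff(self):
        ev = self._run(self.CA_DONOR, 3.6, xda=150.0, day=100.0)
        assert ev is not None and ev.category is Category.BB_CH

    def test_carbon_donor_beyond_3p8(self):
        assert self._run(self.CA_DONOR, 3.9) is None

    def test_angle_below_window_rejected(self):
        assert self._run(self.O_DONOR, 3.0, xda=85.0) is None

    def test_day_angle_below_window_rejected(self):
        assert self._run(self.O_DONOR, 3.0, day=80.0) is None

    def test_any_antecedent_combination_suffices(self):
        spec = DonorSpec("HIS", "ND1", "sidechain_polar", ("CG", "CE1"))
        dpos, bad_x = _donor_at(3.0, xda=60.0)
        _, good_x = _donor_at(3.0, xda=130.0)
        ev = detect_hbond(spec, dpos, {"CG": bad_x, "CE1": good_x},
                          ACC, ACC_XYZ, Y_XYZ)
        assert ev is not None and ev.angle_xda == pytest.approx(130.0, abs=1e-6)

    def test_missing_antecedent_raises(self):
        dpos, _ = _donor_at(3.0)
        with pytest.raises(UnresolvedGeometryError, match="ND2"):
            detect_hbond(self.N_DONOR, dpos, {}, ACC, ACC_XYZ, Y_XYZ)


class TestDetectSaltBridge:
    def test_lysine_within_cutoff(self):
        ev = detect_salt_bridge("LYS", {"NZ": (5.0, 0.0, 0.0)}, ACC, ACC_XYZ)
        assert ev is not None
        assert ev.category is Category.SC_SB and ev.d == pytest.approx(5.0)

    def test_arginine_all_beyond_cutoff(self):
        charged = {"NH1": (5.7, 0.0, 0.0), "NH2": (6.5, 0.0, 0.0),
                   "NE": (7.0, 0.0, 0.0)}
        assert detect_salt_bridge("ARG", charged, ACC, ACC_XYZ) is None

    def test_minimum_distance_atom_reported(self):
        charged = {"NH1": (5.5, 0.0, 0.0), "NH2": (4.0, 0.0, 0.0)}
        ev = detect_salt_bridge("ARG", charged, ACC, ACC_XYZ)
        assert ev.donor_atom == "NH2" and ev.d == pytest.approx(4.0)

    def test_non_basic_residue_rejected(self):
        with pytest.raises(ContractViolation):
            detect_salt_bridge("GLU", {"OE1": (3.0, 0.0, 0.0)}, ACC, ACC_XYZ)


def _frame_with(atoms_spec):
    atoms = []
    serial = 1
    from conftest import HEME_FRAGMENT
    for name, xyz in HEME_FRAGMENT.items():
        el = "FE" if name == "FE" else name[0]
        atoms.append(Atom(serial, name, el, "HEM", "X", 400, xyz))
        serial += 1
    for resname, seq, name, xyz in atoms_spec:
        atoms.append(Atom(serial, name, name[0], resname, "A", seq, xyz))
        serial += 1
    return Structure(atoms)


def _place_near_o1a(d, xda=140.0, day=140.0):
    """Donor/antecedent at distance d from the heme's O1A, angles valid.

    Mirrors the origin-frame construction into the heme frame, where O1A
    sits at (1.25, 0, 0) and its carboxylate carbon CGA at the origin.
    """
    dpos, xpos = _donor_at(d, xda, day)
    mirror = lambda p: (1.25 - p[0], p[1], p[2])
    return mirror(dpos), mirror(xpos)


O1A_ONLY = [AcceptorSpec("A", "O1A", ("CGA",))]


class TestScanFrame:
    def test_single_backbone_event(self):
        # Cα 3.7 Å from O1A with valid angles (carbon cutoff applies)
        dpos, xpos = _place_near_o1a(3.7)
        frame = _frame_with([("ALA", 181, "CA", dpos), ("ALA", 181, "N", xpos)])
        events = scan_frame(frame, acceptors=O1A_ONLY)
        assert [e.category for e in events] == [Category.BB_CH]
        assert events[0].acceptor_atom == "O1A"

    def test_all_donors_far_gives_empty(self):
        frame = _frame_with([("ALA", 181, "CA", (10.0, 10.0, 10.0)),
                             ("ALA", 181, "N", (11.0, 10.0, 10.0))])
        assert scan_frame(frame) == []

    def test_no_heme_raises(self):
        frame = Structure([Atom(1, "CA", "C", "ALA", "A", 1, (0.0, 0.0, 0.0)),
                           Atom(2, "N", "N", "ALA", "A", 1, (1.0, 0.0, 0.0))])
        with pytest.raises(ContractViolation, match="HEM"):
            scan_frame(frame)

    def test_close_lysine_gives_both_saltbridge_and_hbond(self):
        # NZ inside 3.4 Å with valid angles: the two criteria are independent
        dpos, xpos = _place_near_o1a(3.2)
        frame = _frame_with([("LYS", 39, "NZ", dpos), ("LYS", 39, "CE", xpos)])
        cats = {e.category for e in scan_frame(frame, acceptors=O1A_ONLY)}
        assert cats == {Category.SC_SB, Category.SC_H}

    def test_salt_bridge_priority_mode_drops_duplicate(self):
        dpos, xpos = _place_near_o1a(3.2)
        frame = _frame_with([("LYS", 39, "NZ", dpos), ("LYS", 39, "CE", xpos)])
        events = scan_frame(frame, acceptors=O1A_ONLY, salt_bridge_priority=True)
        assert [e.category for e in events] == [Category.SC_SB]

    def test_matches_oracle_on_random_frames(self, rng):
        for _ in range(100):
            frame = make_random_frame(rng, n_residues=int(rng.integers(1, 4)))
            assert events_as_set(scan_frame(frame)) == oracle_scan(frame)

    @pytest.mark.parametrize("loose,tight", [
        (GeometricCriteria(), GeometricCriteria(d_max_NO=3.0, d_max_SC=3.3,
                                                d_max_saltbridge=5.0)),
        (GeometricCriteria(angle_min=80.0), GeometricCriteria(angle_min=110.0)),
    ])
    def test_monotonicity_under_cutoff_changes(self, rng, loose, tight):
        """Tightening any cutoff never adds events."""
        for _ in range(30):
            frame = make_random_frame(rng, 3)
            loose_set = events_as_set(scan_frame(frame, criteria=loose))
            tight_set = events_as_set(scan_frame(frame, criteria=tight))
            assert tight_set <= loose_set


class TestAggregate:
    @staticmethod
    def _events(frames_with_event, d=3.0, cat=Category.BB_CH, seq=181):
        from hemelock.interactions import InteractionEvent
        return [
            InteractionEvent(f, ("A", seq, "ALA"), "CA", "A", "O1A", cat,
                             d, 120.0, 120.0)
            for f in frames_with_event
        ]

    def test_frame_fraction(self):
        summary = aggregate(self._events(range(7)), n_frames=10)
        stats = summary.category_stats(181)
        assert stats[Category.BB_CH][0] == pytest.approx(0.7)

    def test_mean_distance(self):
        ev = self._events([0], d=3.0) + self._events([1], d=3.4)
        summary = aggregate(ev, n_frames=2)
        assert summary.category_stats(181)[Category.BB_CH][1] == pytest.approx(3.2)

    def test_zero_event_category_flagged(self):
        summary = aggregate(self._events([0]), n_frames=1)
        freq, dist = summary.category_stats(181)[Category.SC_H]
        assert freq == 0.0 and np.isnan(dist)

    def test_events_per_frame_mode_geq_frame_fraction(self):
        # two events in one frame (two acceptor atoms)
        from hemelock.interactions import InteractionEvent
        ev = self._events([0, 1]) + [
            InteractionEvent(0, ("A", 181, "ALA"), "CA", "A", "O2A",
                             Category.BB_CH, 3.1, 120.0, 120.0)
        ]
        ff = aggregate(ev, 4, mode="frame_fraction").category_stats(181)
        epf = aggregate(ev, 4, mode="events_per_frame").category_stats(181)
        assert epf[Category.BB_CH][0] >= ff[Category.BB_CH][0]
        assert 0.0 <= ff[Category.BB_CH][0] <= 1.0

    def test_order_independent_over_frames(self, rng):
        ev = self._events(range(5), d=3.0) + self._events([2, 4], d=3.3,
                                                          cat=Category.SC_H)
        shuffled = list(ev)
        rng.shuffle(shuffled)
        a = aggregate(ev, 5).table
        b = aggregate(shuffled, 5).table
        assert a.equals(b)

    def test_requires_scanned_frames(self):
        with pytest.raises(ContractViolation):
            aggregate([], n_frames=0)


def test_donor_dictionary_covers_backbone_of_all_residues():
    donors = load_donor_dictionary()
    from hemelock.interactions import STANDARD_RESIDUES
    for res in STANDARD_RESIDUES:
        assert any(s.donor_class == "backbone_carbon" and s.atom_name == "CA"
                   for s in donors.for_residue(res))
    assert donors.salt_bridge_atoms["ARG"] == ("NE", "NH1", "NH2")
    assert donors.salt_bridge_atoms["LYS"] == ("NZ",)


def test_default_acceptors_cover_both_propionates():
    accs = default_acceptors()
    assert {a.atom_name for a in accs} == {"O1A", "O2A", "O1D", "O2D"}
    restricted = default_acceptors(["A"])
    assert {a.atom_name for a in restricted} == {"O1A", "O2A"}
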