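"""Donor/acceptor enumeration, bond tracing, occupancy and +/- calls."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mfe2dh import (
    BondProgram,
    BondWatch,
    HBondParams,
    bond_report,
    classify_bond,
    enumerate_donors_acceptors,
    find_replacement_partners,
    load_watchlist,
    make_toy_dimer,
    occupancy,
    simulate_trajectory,
    trace_bond,
)
from mfe2dh.chemistry import SIDECHAIN_ACCEPTORS, SIDECHAIN_DONORS
from mfe2dh.hbonds import BondTrace
from mfe2dh.structure import Frame, Topology, Trajectory


def _trace(distances, watch=None):
    distances = np.asarray(distances, dtype=float)
    watch = watch or BondWatch(("A", 1, "N"), ("A", 2, "O"))
    return BondTrace(watch, np.arange(len(distances), dtype=float), distances)


class TestEnumeration:
    def test_glycine_backbone_only(self):
        f = make_toy_dimer(6, seed=0, residue_types={i: "GLY" for i in range(1, 7)})
        donors, acceptors = enumerate_donors_acceptors(f)
        assert {a for _, _, a in donors} == {"N"}
        assert {a for _, _, a in acceptors} == {"O"}

    def test_threonine_hydroxyl_donates_and_accepts(self, toy_dimer):
        donors, acceptors = enumerate_donors_acceptors(toy_dimer)
        assert ("A", 5, "OG1") in donors and ("A", 5, "OG1") in acceptors

    def test_counts_match_bruteforce_over_chemistry_table(self, toy_dimer):
        donors, acceptors = enumerate_donors_acceptors(toy_dimer)
        top = toy_dimer.topology
        exp_d, exp_a = set(), set()
        for i in range(top.n_atoms):
            addr = (str(top.chain_ids[i]), int(top.residue_numbers[i]), str(top.atom_names[i]))
            res, atom = str(top.residue_names[i]), addr[2]
            if (atom == "N" and res != "PRO") or atom in SIDECHAIN_DONORS.get(res, ()):
                exp_d.add(addr)
            if atom == "O" or atom in SIDECHAIN_ACCEPTORS.get(res, ()):
                exp_a.add(addr)
        assert donors == exp_d and acceptors == exp_a

    def test_unknown_residue_warned_and_skipped(self):
        top = Topology(["A", "A"], [1, 2], ["GLY", "LIG"], ["N", "N"])
        f = Frame(top, np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        with pytest.warns(UserWarning, match="LIG"):
            donors, _ = enumerate_donors_acceptors(f)
        assert donors == {("A", 1, "N")}


class TestTraceBond:
    def test_static_geometry_constant_trace(self):
        top = Topology(["A", "A"], [1, 2], ["GLY", "GLY"], ["N", "O"])
        coords = np.tile(np.array([[0.0, 0, 0], [3.0, 0, 0]]), (10, 1, 1))
        traj = Trajectory(top, coords, np.arange(10.0))
        d = trace_bond(traj, BondWatch(("A", 1, "N"), ("A", 2, "O"))).distances
        assert np.allclose(d, 3.0)

    def test_group_shorthand_is_min_of_members(self):
        top = Topology(
            ["A", "A", "A"], [1, 1, 2], ["ARG", "ARG", "GLY"], ["NH1", "NH2", "O"]
        )
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 5, size=(8, 3, 3))
        traj = Trajectory(top, coords, np.arange(8.0))
        grouped = trace_bond(traj, BondWatch(("A", 1, "NH"), ("A", 2, "O"))).distances
        d1 = trace_bond(traj, BondWatch(("A", 1, "NH1"), ("A", 2, "O"))).distances
        d2 = trace_bond(traj, BondWatch(("A", 1, "NH2"), ("A", 2, "O"))).distances
        assert np.allclose(grouped, np.minimum(d1, d2))

    def test_missing_atom_raises(self, jitter_trajectory):
        from mfe2dh.structure import MissingAtomError

        with pytest.raises(MissingAtomError):
            trace_bond(jitter_trajectory, BondWatch(("A", 5, "NH"), ("A", 9, "N")))


class TestOccupancy:
    def test_always_bound_and_never_bound(self):
        assert occupancy(_trace([3.0] * 20), threshold=3.5, window=(0, 1)) == 1.0
        assert occupancy(_trace([5.0] * 20), threshold=3.5, window=(0, 1)) == 0.0

    def test_hand_counted_window_fraction(self):
        # 100 frames; inside window [0.4, 1.0] (60 frames) exactly 40 are bound
        d = np.full(100, 5.0)
        d[40:80] = 3.0
        assert occupancy(_trace(d)) == pytest.approx(40 / 60)

    def test_matches_bruteforce_frame_count(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(2.5, 4.5, size=137)
        got = occupancy(_trace(d), threshold=3.5, window=(0.25, 0.8))
        lo, hi = int(np.floor(0.25 * 137)), int(np.floor(0.8 * 137))
        expected = sum(1 for x in d[lo:hi] if x <= 3.5) / (hi - lo)
        assert got == pytest.approx(expected)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            occupancy(_trace([3.0] * 10), window=(0.5, 0.5))

    @given(
        st.lists(st.floats(min_value=2.0, max_value=6.0), min_size=5, max_size=60),
        st.floats(min_value=2.0, max_value=6.0),
        st.floats(min_value=0.0, max_value=2.0),
    )
    def test_monotone_in_threshold(self, dists, thr, bump):
        tr = _trace(dists)
        assert occupancy(tr, thr, (0, 1)) <= occupancy(tr, thr + bump, (0, 1))

    @given(st.lists(st.floats(min_value=2.0, max_value=6.0), min_size=10, max_size=60))
    def test_invariant_to_frame_permutation_within_window(self, dists):
        d = np.asarray(dists)
        full = occupancy(_trace(d), 3.5, (0, 1))
        rng = np.random.default_rng(0)
        assert occupancy(_trace(rng.permutation(d)), 3.5, (0, 1)) == pytest.approx(full)


class TestClassification:
    def test_consensus_requires_both_monomers(self, toy_dimer):
        # stable in A, broken in B -> consensus fluctuating
        progs = {
            BondWatch(("A", 5, "OG1"), ("A", 9, "N")): BondProgram("stable"),
            BondWatch(("B", 5, "OG1"), ("B", 9, "N")): BondProgram(
                "breaking", 3.0, 6.0, break_fraction=0.0
            ),
        }
        traj = simulate_trajectory(toy_dimer, progs, n_frames=120, seed=21)
        call = classify_bond(traj, BondWatch(("A", 5, "OG1"), ("A", 9, "N")))
        assert call.per_monomer["A"][1] == "+"
        assert call.per_monomer["B"][1] == "-"
        assert call.consensus == "-"

    def test_both_monomers_stable_gives_consensus_plus(self, toy_dimer):
        progs = {
            BondWatch((c, 5, "OG1"), (c, 9, "N")): BondProgram("stable") for c in "AB"
        }
        traj = simulate_trajectory(toy_dimer, progs, n_frames=120, seed=22)
        call = classify_bond(traj, BondWatch(("A", 5, "OG1"), ("A", 9, "N")))
        assert call.consensus == "+"
        # consensus-stable implies every per-monomer occupancy >= cutoff
        assert all(occ >= call.params.occupancy_cutoff for occ, _ in call.per_monomer.values())

    def test_degenerate_cutoffs(self, breaking_trajectory):
        watch = BondWatch(("A", 5, "OG1"), ("A", 9, "N"))
        always = classify_bond(
            breaking_trajectory, watch, HBondParams(occupancy_cutoff=0.0)
        )
        never = classify_bond(
            breaking_trajectory, watch, HBondParams(occupancy_cutoff=1.0001)
        )
        assert always.consensus == "+" and never.consensus == "-"

    def test_occupancy_recovers_programmed_fraction(self, toy_dimer):
        # breaking at 0.5 with window [0.4, 1.0]: bound fraction = (0.5-0.4)/0.6
        prog = BondProgram("breaking", 3.0, 6.0, break_fraction=0.5)
        progs = {BondWatch((c, 5, "OG1"), (c, 9, "N")): prog for c in "AB"}
        traj = simulate_trajectory(toy_dimer, progs, n_frames=600, seed=23)
        occ = occupancy(trace_bond(traj, BondWatch(("A", 5, "OG1"), ("A", 9, "N"))))
        expected = (0.5 - 0.4) / 0.6
        n_window = 360
        sigma = np.sqrt(expected * (1 - expected) / n_window)
        assert abs(occ - expected) <= 3 * sigma + 1e-9


class TestReplacementPartners:
    def test_isolated_donor_empty_list(self):
        top = Topology(["A", "A"], [1, 5], ["GLY", "GLY"], ["N", "O"])
        coords = np.tile(np.array([[0.0, 0, 0], [30.0, 0, 0]]), (5, 1, 1))
        traj = Trajectory(top, coords, np.arange(5.0))
        watch = BondWatch(("A", 1, "N"), ("A", 5, "O"))
        assert find_replacement_partners(traj, watch, radius=5.0) == []

    def test_forming_partner_ranked_first(self, toy_dimer):
        # lose OG1->Asn9 N, while OG1 stays bonded to Ser4 O nearby
        lost = BondWatch(("A", 5, "OG1"), ("A", 9, "N"))
        formed = BondWatch(("A", 5, "OG1"), ("A", 4, "O"))
        progs = {
            lost: BondProgram("breaking", 3.0, 7.0, break_fraction=0.0),
            formed: BondProgram("stable", jitter_sd=0.05),
        }
        traj = simulate_trajectory(toy_dimer, progs, n_frames=100, seed=31)
        ranked = find_replacement_partners(traj, lost, radius=6.0)
        assert ranked and ranked[0][0] == ("A", 4, "O")
        assert ranked[0][1] > 0.9

    def test_ranking_matches_bruteforce(self, breaking_trajectory):
        watch = BondWatch(("A", 5, "OG1"), ("A", 9, "N"))
        ranked = find_replacement_partners(breaking_trajectory, watch, radius=6.0)
        _, acceptors = enumerate_donors_acceptors(breaking_trajectory[0])
        ref = breaking_trajectory[0]
        donor_pos = ref.select_atom("A", 5, "OG1").coordinates
        expected = []
        for addr in acceptors:
            if addr == watch.acceptor or addr[:2] == ("A", 5):
                continue
            pos = ref.select_atom(*addr).coordinates
            if np.linalg.norm(pos - donor_pos) > 6.0:
                continue
            occ = occupancy(trace_bond(breaking_trajectory, BondWatch(watch.donor, addr)))
            expected.append((addr, occ))
        expected.sort(key=lambda t: (-t[1], t[0]))
        assert ranked == expected


class TestBondReport:
    def test_all_stable_set_all_plus(self, toy_dimer):
        watches = [
            BondWatch(("A", 5, "OG1"), ("A", 9, "N")),
            BondWatch(("A", 2, "N"), ("A", 3, "O")),
        ]
        progs = {}
        for w in watches:
            for c in "AB":
                progs[w.in_chains(c, c)] = BondProgram("stable", jitter_sd=0.05)
        trajs = {
            "X": simulate_trajectory(toy_dimer, progs, 100, seed=41, global_jitter_sd=0.02),
            "Y": simulate_trajectory(toy_dimer, progs, 100, seed=42, global_jitter_sd=0.02),
        }
        rep = bond_report(trajs, watches)
        assert (rep[["X", "Y"]] == "+").all().all()
        assert list(rep.columns[:2]) == ["scope", "label"]

    def test_packaged_watchlist_loads_18_bonds(self):
        from mfe2dh.datasets import load_bond_watchlist

        watches, table = load_bond_watchlist()
        assert len(watches) == 18
        assert table["bond_id"].is_unique
        assert {w.scope for w in watches} == {"intra_monomer", "inter_monomer"}

    def test_scope_consistency_enforced(self):
        with pytest.raises(ValueError):
            BondWatch(("A", 1, "N"), ("B", 2, "O"), scope="intra_monomer")
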