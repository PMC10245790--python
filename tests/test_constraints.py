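"""Steric clash, chain connectivity and crosslink restraint filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import line_structure
from multifold.assembler import AssemblyParams, Subcomplex, canonical_fingerprint
from multifold.constraints import (
    ConstraintSet,
    Restraint,
    apply_groups,
    chain_links_from_catalog,
    clash_filter,
    connectivity_filter,
    linker_bound,
    load_crosslinks,
    restraint_filter,
)
from multifold.job_planner import SubunitDefinition
from multifold.model_io import RigidTransform


def make_candidate(reps, placements):
    placements = dict(placements)
    instances = tuple(sorted(placements))
    return Subcomplex(
        instances=instances,
        placements=placements,
        usages=(),
        score=100.0,
        canonical_id=canonical_fingerprint(instances, placements, reps),
    )


def shift(x, y=0.0, z=0.0):
    return RigidTransform(np.eye(3), np.array([x, y, z], dtype=float))


class TestClashFilter:
    """Two 100-residue line subunits, residues 10 Å apart: each residue's
    4 backbone atoms sit within 1.2 Å of its CA, so overlapping the first k
    residues clashes exactly 4k of 400 atoms (k%)."""

    def setup_method(self):
        self.a = line_structure("a", n_res=100)
        self.b = line_structure("b", n_res=100)
        self.reps = {"a": self.a, "b": self.b}
        self.params = AssemblyParams()

    def overlap_candidate(self, k):
        """Place b so its first k residues coincide with a's last k."""
        placements = {
            ("a", 0): RigidTransform.identity(),
            ("b", 0): shift((100 - k) * 10.0),
        }
        return make_candidate(self.reps, placements)

    def run_filter(self, cand):
        return clash_filter(
            cand, (((("a", 0)),), ((("b", 0)),)), self.reps, self.params
        )

    def test_distant_instances_keep(self):
        cand = make_candidate(
            self.reps,
            {("a", 0): RigidTransform.identity(), ("b", 0): shift(0.0, 500.0)},
        )
        assert self.run_filter(cand)

    def test_full_superposition_discards(self):
        cand = make_candidate(
            self.reps,
            {("a", 0): RigidTransform.identity(), ("b", 0): shift(0.0)},
        )
        assert not self.run_filter(cand)

    def test_four_percent_overlap_keeps(self):
        assert self.run_filter(self.overlap_candidate(4))

    def test_six_percent_overlap_discards(self):
        assert not self.run_filter(self.overlap_candidate(6))

    def test_exactly_five_percent_keeps(self):
        # the rule is strictly "more than 5%"
        assert self.run_filter(self.overlap_candidate(5))

    def test_penetration_threshold_strict(self):
        """CA-CA at exactly (r_i + r_j − 1.0) = 2.4 Å is not a clash;
        slightly closer is."""
        a = line_structure("a", n_res=40)
        b = line_structure("b", n_res=40)
        reps = {"a": a, "b": b}
        at_limit = make_candidate(
            reps, {("a", 0): RigidTransform.identity(), ("b", 0): shift(0, 2.4 + 0.61)}
        )
        # b's O atoms sit 0.6 Å above its CA line; offset so the closest
        # approach (O of b to O of a at same x) is exactly 2.4... use CA-CA:
        at_limit = make_candidate(
            reps, {("a", 0): RigidTransform.identity(), ("b", 0): shift(0.25, 3.3)}
        )
        params = AssemblyParams()
        assert clash_filter(at_limit, ((("a", 0),), (("b", 0),)), reps, params)

    def test_low_plddt_residues_ignored(self):
        """Disordered (low-plDDT) residues are static copies of the
        representative and do not count as clash probes."""
        floppy = line_structure("b", n_res=100, plddt=50.0)
        reps = {"a": self.a, "b": floppy}
        cand = make_candidate(
            reps, {("a", 0): RigidTransform.identity(), ("b", 0): shift(0.0)}
        )
        assert clash_filter(cand, ((("a", 0),), (("b", 0),)), reps, self.params)

    def test_symmetric_in_sides(self):
        for k in (4, 6):
            cand = self.overlap_candidate(k)
            fwd = clash_filter(
                cand, ((("a", 0),), (("b", 0),)), self.reps, self.params
            )
            rev = clash_filter(
                cand, ((("b", 0),), (("a", 0),)), self.reps, self.params
            )
            assert fwd == rev


class TestConnectivityFilter:
    def setup_method(self):
        # 5-residue lines, spacing 3.8: last CA at x=15.2 within each
        self.pred = line_structure("n_term", n_res=5, spacing=3.8)
        self.succ = line_structure("c_term", n_res=5, spacing=3.8)
        self.reps = {"n_term": self.pred, "c_term": self.succ}

    def candidate_with_gap(self, gap):
        """Place the successor so the tail-to-head CA gap is exactly `gap`."""
        last_ca = self.pred.ca_coords[-1]
        placements = {
            ("n_term", 0): RigidTransform.identity(),
            ("c_term", 0): shift(last_ca[0] + gap),
        }
        return make_candidate(self.reps, placements)

    @pytest.mark.parametrize(
        "linker,gap,keep",
        [
            (5, 14.0, True),  # bound 15
            (5, 16.0, False),
            (0, 3.8, True),  # floor 4.0 covers a peptide bond
            (0, 4.5, False),
            (2, 6.0, True),
        ],
    )
    def test_linker_bound(self, linker, gap, keep):
        cand = self.candidate_with_gap(gap)
        links = [("n_term", "c_term", linker)]
        assert connectivity_filter(cand, links, self.reps) is keep

    def test_bound_formula(self):
        assert linker_bound(5) == 15.0
        assert linker_bound(0) == 4.0

    def test_absent_endpoint_skipped(self):
        cand = make_candidate(
            {"n_term": self.pred}, {("n_term", 0): RigidTransform.identity()}
        )
        assert connectivity_filter(cand, [("n_term", "c_term", 0)], self.reps)

    def test_copies_matched_greedily(self):
        """Two copies of each segment: the best pairing decides."""
        last = self.pred.ca_coords[-1][0]
        placements = {
            ("n_term", 0): RigidTransform.identity(),
            ("n_term", 1): shift(0.0, 100.0),
            ("c_term", 0): shift(last + 3.8),
            ("c_term", 1): shift(last + 3.8, 100.0),
        }
        cand = make_candidate(self.reps, placements)
        assert connectivity_filter(cand, [("n_term", "c_term", 0)], self.reps)

    def test_chain_links_from_catalog(self):
        catalog = [
            SubunitDefinition("b2", "AA", parent_chain="X", start_res=51, linker_to_next=0),
            SubunitDefinition("b1", "AA", parent_chain="X", start_res=1, linker_to_next=3),
            SubunitDefinition("solo", "AA"),
        ]
        assert chain_links_from_catalog(catalog) == [("b1", "b2", 3)]


class TestRestraintFilter:
    def setup_method(self):
        self.a = line_structure("a", n_res=20)
        self.b = line_structure("b", n_res=20)
        self.reps = {"a": self.a, "b": self.b}
        self.params = AssemblyParams()
        # a and b side by side, 10 Å apart in y
        self.cand = make_candidate(
            self.reps,
            {("a", 0): RigidTransform.identity(), ("b", 0): shift(0.0, 10.0)},
        )

    def restraint(self, res_a=1, res_b=1, max_dist=25.0):
        return Restraint("a", res_a, "b", res_b, max_dist)

    def test_eleven_of_twelve_satisfied_keeps(self):
        good = [self.restraint(i + 1, i + 1) for i in range(11)]
        bad = [self.restraint(1, 20, max_dist=15.0)]  # 1→20: ~72 Å apart
        assert restraint_filter(self.cand, good + bad, self.reps, self.params)

    def test_three_of_twelve_satisfied_discards(self):
        good = [self.restraint(i + 1, i + 1) for i in range(3)]
        bad = [self.restraint(1, 15 + i % 5, max_dist=2.0) for i in range(9)]
        assert not restraint_filter(self.cand, good + bad, self.reps, self.params)

    def test_exactly_seventy_percent_violated_discards(self):
        good = [self.restraint(i + 1, i + 1) for i in range(3)]
        bad = [self.restraint(1, 10 + i, max_dist=2.0) for i in range(7)]
        assert not restraint_filter(self.cand, good + bad, self.reps, self.params)

    def test_just_below_seventy_percent_keeps(self):
        good = [self.restraint(i + 1, i + 1) for i in range(4)]
        bad = [self.restraint(1, 10 + i, max_dist=2.0) for i in range(6)]  # 60%
        assert restraint_filter(self.cand, good + bad, self.reps, self.params)

    def test_ambiguous_restraint_satisfied_by_one_copy_pairing(self):
        """Homodimer: the crosslink holds if any copy pairing satisfies it."""
        reps = {"a": self.a}
        cand = make_candidate(
            reps,
            {("a", 0): RigidTransform.identity(), ("a", 1): shift(0.0, 500.0)},
        )
        # residue 1 of one copy to residue 2 of some copy: satisfied
        # intra-frame even though the far copy pairing violates it
        r = Restraint("a", 1, "a", 2, 25.0, ambiguous=True)
        assert restraint_filter(cand, [r], reps, self.params)

    def test_absent_subunit_restraints_not_counted(self):
        """Restraints naming a type absent from the candidate do not enter
        the violated fraction (validation is a load-time concern)."""
        absent = [Restraint("zz", 1, "a", 1, 0.1) for _ in range(10)]
        assert restraint_filter(self.cand, absent, self.reps, self.params)

    def test_unknown_residue_rejected(self):
        r = self.restraint(res_a=99)
        with pytest.raises(ValueError, match="outside"):
            restraint_filter(self.cand, [r], self.reps, self.params)

    def test_monotone_in_satisfied_restraints(self):
        """Adding a satisfied restraint can never flip keep to discard."""
        rng = np.random.default_rng(0)
        base = [self.restraint(1, 10 + i, max_dist=2.0) for i in range(3)]
        base += [self.restraint(i + 1, i + 1) for i in range(2)]
        kept_before = restraint_filter(self.cand, base, self.reps, self.params)
        extra = self.restraint(5, 5)  # satisfied (10 Å apart, bound 25)
        kept_after = restraint_filter(
            self.cand, base + [extra], self.reps, self.params
        )
        assert not kept_before or kept_after


def test_filters_order_independent():
    """The three filters inspect disjoint properties; any application order
    yields the same conjunction."""
    a = line_structure("a", n_res=20)
    b = line_structure("b", n_res=20)
    reps = {"a": a, "b": b}
    params = AssemblyParams()
    cand = make_candidate(
        reps, {("a", 0): RigidTransform.identity(), ("b", 0): shift(0.0, 10.0)}
    )
    links = [("a", "b", 10)]
    restraints = [Restraint("a", 1, "b", 1, 25.0)]
    sides = ((("a", 0),), (("b", 0),))

    def run(order):
        checks = {
            "clash": lambda: clash_filter(cand, sides, reps, params),
            "conn": lambda: connectivity_filter(cand, links, reps),
            "restr": lambda: restraint_filter(cand, restraints, reps, params),
        }
        return all(checks[name]() for name in order)

    results = {run(order) for order in itertools.permutations(["clash", "conn", "restr"])}
    assert len(results) == 1


class TestGroups:
    def test_no_groups_single_stage(self):
        plan = apply_groups({"a": 1, "b": 1}, [])
        assert plan.group_stages == () and plan.remaining == {"a": 1, "b": 1}

    def test_two_groups_and_final_stage(self):
        plan = apply_groups(
            {"a": 1, "b": 2, "c": 1, "d": 1}, [{"a", "b"}, {"c"}]
        )
        assert plan.group_stages == ({"a": 1, "b": 2}, {"c": 1})
        assert plan.remaining == {"d": 1}

    def test_group_equal_to_full_stoichiometry(self):
        plan = apply_groups({"a": 1, "b": 1}, [{"a", "b"}])
        assert plan.remaining == {} and plan.group_stages == ({"a": 1, "b": 1},)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            apply_groups({"a": 1, "b": 1}, [{"a"}, {"a", "b"}])

    def test_unknown_member_rejected(self):
        with pytest.raises(ValueError, match="zz"):
            apply_groups({"a": 1}, [{"zz"}])


def test_load_crosslinks_round_trip(tmp_path):
    df = pd.DataFrame(
        {
            "subunit_a": ["x", "y"],
            "res_a": [1, 5],
            "subunit_b": ["y", "x"],
            "res_b": [3, 2],
            "max_dist": [25.0, 30.0],
        }
    )
    path = tmp_path / "links.csv"
    df.to_csv(path, index=False)
    restraints = load_crosslinks(path, {"x": 2, "y": 1})
    assert len(restraints) == 2
    assert restraints[0].max_dist == 25.0
    assert restraints[0].ambiguous  # x has two copies
    missing = tmp_path / "bad.csv"
    missing.write_text("a,b\n1,2\n")
    with pytest.raises(ValueError, match="missing columns"):
        load_crosslinks(missing)
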