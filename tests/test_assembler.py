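"""Hierarchical assembly: expansion, scoring, clustering, retention."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from multifold.assembler import (
    Assembler,
    AssemblyParams,
    Subcomplex,
    Usage,
    assemble,
    canonical_fingerprint,
    cluster,
    confidence,
    copy_aware_rmsd,
    expand,
    retain_top_k,
    symmetry_reward,
)
from multifold.fixtures import NoiseSpec, make_chain, make_pair_models, make_subunit
from multifold.model_io import RigidTransform, SubunitStructure
from multifold.transform_library import (
    PairwiseTransformation,
    TransformationLibrary,
    score_transformation,
)


def _transform(seed: int, shift=(20.0, 0.0, 0.0)) -> RigidTransform:
    rot = Rotation.from_euler("z", 10.0 * seed, degrees=True).as_matrix()
    return RigidTransform(rot, np.asarray(shift, dtype=float) + seed)


def _pt(tid, from_id, to_id, transform, avg_pae=2.0):
    return PairwiseTransformation(
        transform_id=tid,
        from_subunit=from_id,
        to_subunit=to_id,
        transform=transform,
        score=score_transformation(avg_pae),
        source_model=tid,
        avg_pae=avg_pae,
    )


def _toy_library(n_transforms=3) -> TransformationLibrary:
    reps = {
        "a": make_subunit(15, seed=1, subunit_id="a"),
        "b": make_subunit(15, seed=2, subunit_id="b"),
    }
    lib = TransformationLibrary(representatives=reps)
    for k in range(n_transforms):
        lib.add(_pt(f"t{k}", "a", "b", _transform(k)))
    return lib


def _subcomplex(reps, placements, usages=(), params=None):
    placements = dict(placements)
    instances = tuple(sorted(placements))
    comp = tuple(sid for sid, _ in instances)
    from multifold.assembler import _weighted_score

    return Subcomplex(
        instances=instances,
        placements=placements,
        usages=tuple(usages),
        score=_weighted_score(tuple(usages), comp, params or AssemblyParams()),
        canonical_id=canonical_fingerprint(instances, placements, reps),
    )


class TestExpand:
    def test_three_transforms_three_candidates(self):
        lib = _toy_library(3)
        asm = Assembler(lib)
        out = expand(asm.monomer("a"), asm.monomer("b"), lib)
        assert len(out) == 3
        assert all(c.size == 2 for c in out)

    def test_dimer_plus_monomer_candidate_count(self):
        reps = {
            "a": make_subunit(15, seed=1, subunit_id="a"),
            "b": make_subunit(15, seed=2, subunit_id="b"),
        }
        lib = TransformationLibrary(representatives=reps)
        lib.add(_pt("taa", "a", "a", _transform(1)))
        lib.add(_pt("tab", "a", "b", _transform(2)))
        asm = Assembler(lib)
        left = _subcomplex(
            reps,
            {
                ("a", 0): RigidTransform.identity(),
                ("b", 0): _transform(2),
            },
            usages=[Usage("tab", ("a", "b"), 99.0, 15, 15)],
        )
        out = expand(left, asm.monomer("a"), lib)
        # anchors: (a0, a-new) via the a-a transform; (b0, a-new) via the
        # inverted a-b transform — one candidate each
        assert len(out) == 2

    def test_relative_pose_matches_transform(self):
        lib = _toy_library(1)
        asm = Assembler(lib)
        (cand,) = expand(asm.monomer("a"), asm.monomer("b"), lib)
        t = lib.by_pair[("a", "b")][0].transform
        pa = cand.placements[("a", 0)]
        pb = cand.placements[("b", 0)]
        rel = pa.inverse().compose(pb)
        assert np.allclose(rel.rotation, t.rotation, atol=1e-9)
        assert np.allclose(rel.translation, t.translation, atol=1e-9)

    def test_apply_then_invert_restores_relative_pose(self):
        t = _transform(4)
        assert np.allclose(
            t.compose(t.inverse()).rotation, np.eye(3), atol=1e-12
        )


class TestScoring:
    def _usages(self, score, n, tid="t0", pair=("s", "s")):
        return [Usage(tid, pair, score, 30, 30) for _ in range(n)]

    def _sub_with(self, copies, usages):
        reps = {"s": make_subunit(12, seed=3, subunit_id="s")}
        placements = {
            ("s", k): RigidTransform(np.eye(3), np.array([40.0 * k, 0, 0]))
            for k in range(copies)
        }
        return _subcomplex(reps, placements, usages)

    def test_reward_at_six_same_transform_copies(self):
        sub = self._sub_with(6, self._usages(80.0, 5))
        assert symmetry_reward(sub) == pytest.approx(96.0)

    def test_reward_fixed_point_at_hundred(self):
        sub = self._sub_with(6, self._usages(100.0, 5))
        assert symmetry_reward(sub) == pytest.approx(100.0)

    def test_no_reward_for_five_copies(self):
        sub = self._sub_with(5, self._usages(80.0, 4))
        assert symmetry_reward(sub) == pytest.approx(80.0)

    def test_no_reward_for_mixed_transforms(self):
        usages = self._usages(80.0, 3) + self._usages(80.0, 2, tid="t1")
        sub = self._sub_with(6, usages)
        assert symmetry_reward(sub) == pytest.approx(80.0)

    def test_confidence_single_usage(self):
        sub = self._sub_with(2, [Usage("t0", ("s", "s"), 80.0, 30, 30)])
        assert confidence(sub) == pytest.approx(80.0)

    def test_confidence_weighted_mean(self):
        usages = [
            Usage("t0", ("s", "s"), 100.0, 100, 100),
            Usage("t1", ("s", "s"), 50.0, 40, 60),
        ]
        sub = self._sub_with(3, usages)
        assert confidence(sub) == pytest.approx((100 * 200 + 50 * 100) / 300)

    def test_equal_scores_cancel_weights(self):
        usages = [
            Usage("t0", ("s", "s"), 73.0, 10, 250),
            Usage("t1", ("s", "s"), 73.0, 400, 30),
        ]
        sub = self._sub_with(3, usages)
        assert confidence(sub) == pytest.approx(73.0)

    def test_monomer_confidence_is_hundred(self):
        sub = self._sub_with(1, [])
        assert confidence(sub) == 100.0


class TestClusterAndRmsd:
    @pytest.fixture
    def homotrimer(self):
        reps = {"s": make_subunit(20, seed=5, subunit_id="s")}
        placements = {
            ("s", 0): RigidTransform.identity(),
            ("s", 1): RigidTransform(np.eye(3), np.array([30.0, 0, 0])),
            ("s", 2): RigidTransform(np.eye(3), np.array([15.0, 25.0, 0])),
        }
        return reps, placements

    def test_permuted_copies_have_zero_rmsd(self, homotrimer):
        reps, placements = homotrimer
        a = _subcomplex(reps, placements)
        rotated = {
            ("s", 0): placements[("s", 1)],
            ("s", 1): placements[("s", 2)],
            ("s", 2): placements[("s", 0)],
        }
        b = _subcomplex(reps, rotated)
        assert copy_aware_rmsd(a, b, reps) < 1e-6

    def test_permuted_duplicates_collapse_to_one_cluster(self, homotrimer):
        reps, placements = homotrimer
        a = _subcomplex(reps, placements)
        rotated = {
            ("s", 0): placements[("s", 2)],
            ("s", 1): placements[("s", 0)],
            ("s", 2): placements[("s", 1)],
        }
        b = _subcomplex(reps, rotated)
        assert len(cluster([a, b], AssemblyParams(), reps)) == 1

    def test_distinct_poses_stay_separate(self, homotrimer):
        reps, placements = homotrimer
        a = _subcomplex(reps, placements)
        shifted = dict(placements)
        shifted[("s", 2)] = RigidTransform(np.eye(3), np.array([15.0, 35.0, 0]))
        b = _subcomplex(reps, shifted)
        assert copy_aware_rmsd(a, b, reps) > 1.0  # well beyond the cluster radius
        assert len(cluster([a, b], AssemblyParams(), reps)) == 2

    def test_empty_cluster_input(self):
        assert cluster([], AssemblyParams(), {}) == []

    def test_heterodimer_plain_rmsd_no_swaps(self):
        reps = {
            "a": make_subunit(15, seed=1, subunit_id="a"),
            "b": make_subunit(15, seed=2, subunit_id="b"),
        }
        placements = {
            ("a", 0): RigidTransform.identity(),
            ("b", 0): RigidTransform(np.eye(3), np.array([25.0, 0, 0])),
        }
        a = _subcomplex(reps, placements)
        b = _subcomplex(reps, placements)
        assert copy_aware_rmsd(a, b, reps) < 1e-9

    def test_composition_mismatch_rejected(self):
        reps = {
            "a": make_subunit(15, seed=1, subunit_id="a"),
            "b": make_subunit(15, seed=2, subunit_id="b"),
        }
        a = _subcomplex(reps, {("a", 0): RigidTransform.identity()})
        b = _subcomplex(reps, {("b", 0): RigidTransform.identity()})
        with pytest.raises(ValueError, match="composition"):
            copy_aware_rmsd(a, b, reps)


class TestRetention:
    def _stub(self, score, tag):
        reps = {"s": make_subunit(12, seed=3, subunit_id="s")}
        placements = {("s", 0): RigidTransform(np.eye(3), np.array([float(tag), 0, 0]))}
        sub = _subcomplex(reps, placements)
        sub.score = score
        return sub

    def test_truncates_to_k(self):
        subs = [self._stub(float(i), i) for i in range(7)]
        kept = retain_top_k({("s",): subs}, AssemblyParams(k_best=3))
        assert [s.score for s in kept[("s",)]] == [6.0, 5.0, 4.0]

    def test_small_lists_kept_whole(self):
        subs = [self._stub(1.0, 0), self._stub(2.0, 1)]
        kept = retain_top_k({("s",): subs}, AssemblyParams(k_best=100))
        assert len(kept[("s",)]) == 2

    def test_tie_cut_deterministic(self):
        subs = [self._stub(5.0, i) for i in range(5)]
        kept1 = retain_top_k({("s",): list(subs)}, AssemblyParams(k_best=2))
        kept2 = retain_top_k({("s",): list(reversed(subs))}, AssemblyParams(k_best=2))
        assert [s.canonical_id for s in kept1[("s",)]] == [
            s.canonical_id for s in kept2[("s",)]
        ]


class TestAssemble:
    def test_two_subunits_one_transform(self):
        lib = _toy_library(1)
        results = assemble(lib, {"a": 1, "b": 1})
        assert len(results) == 1
        (dimer,) = results
        assert dimer.size == 2 and dimer.score == pytest.approx(99.0)

    def test_empty_library_rejected(self):
        reps = {"a": make_subunit(15, seed=1, subunit_id="a")}
        lib = TransformationLibrary(representatives=reps)
        with pytest.raises(ValueError, match="empty"):
            assemble(lib, {"a": 2})

    def test_unknown_subunit_rejected(self):
        lib = _toy_library(1)
        with pytest.raises(ValueError, match="unknown"):
            assemble(lib, {"a": 1, "zz": 1})

    def test_unreachable_subunit_gives_partial_without_it(self, chain3, chain3_library):
        lib = chain3_library
        pruned = TransformationLibrary(representatives=lib.representatives)
        for t in lib.by_pair[("su0", "su1")]:
            pruned.add(t)  # su2 has no transforms at all
        results = assemble(pruned, {"su0": 1, "su1": 1, "su2": 1})
        assert results[0].size == 2
        assert all("su2" not in sub.composition for sub in results)

    def test_chain_recovered_exactly(self, chain3, chain3_library):
        from multifold.evaluation import compare_assembly

        results = assemble(chain3_library, chain3.stoichiometry)
        rmsd, _ = compare_assembly(
            results[0], list(chain3.instances), chain3_library.representatives
        )
        assert rmsd < 1e-3

    def test_invariant_to_copy_label_permutation_and_global_motion(self, chain3):
        """Same canonical ids and scores when a model is rigidly moved and
        its copy labels renamed."""
        from multifold.model_io import ModelInstance, PredictedModel
        from multifold.transform_library import build_library

        models = make_pair_models(
            chain3, NoiseSpec(pae_base=2.0, pae_jitter=0.0, seed=5), include_decoys=False
        )
        motion = RigidTransform(
            Rotation.random(random_state=11).as_matrix(), np.array([12.0, 3.0, -8.0])
        )
        mangled = [
            PredictedModel(
                model_id=m.model_id,
                instances=tuple(
                    ModelInstance(i.subunit_id, f"Z{k}", i.structure.transformed(motion))
                    for k, i in enumerate(m.instances)
                ),
                pae=m.pae,
            )
            for m in models
        ]
        res_ref = assemble(build_library(models), chain3.stoichiometry)
        res_mangled = assemble(build_library(mangled), chain3.stoichiometry)
        assert [s.canonical_id for s in res_ref] == [
            s.canonical_id for s in res_mangled
        ]
        assert [s.score for s in res_ref] == pytest.approx(
            [s.score for s in res_mangled]
        )

    def test_noise_transforms_do_not_remove_best_assembly(self, chain3, chain3_library):
        """Adding pure-noise (score 1) transforms must not displace the
        previously attainable best assembly before K-truncation."""
        ref = assemble(chain3_library, chain3.stoichiometry)
        noisy = TransformationLibrary(representatives=chain3_library.representatives)
        for transforms in chain3_library.by_pair.values():
            for t in transforms:
                noisy.add(t)
        noisy.add(_pt("junk", "su0", "su2", _transform(9, shift=(35.0, 5.0, 0.0)), avg_pae=30.0))
        got = assemble(noisy, chain3.stoichiometry)
        assert got[0].canonical_id == ref[0].canonical_id
        assert got[0].score == pytest.approx(ref[0].score)
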