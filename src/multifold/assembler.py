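"""Combinatorial hierarchical assembly of subunits.

The assembly runs N iterations (N = total subunit copies).  At iteration i,
subcomplexes of size i are built by merging every disjoint pair of stored
subcomplexes of sizes k and i-k: for each cross pair of instances whose
types have library transforms, each transform is applied to move the whole
second subcomplex next to the first.  Candidates are filtered (clashes,
chain connectivity, distance restraints), deduplicated, clustered by
copy-aware CA RMSD, and the K best per subunit composition survive.

A subcomplex's score is the weighted mean of the scores of the transforms
used to build it, weighted by the residue counts of the two subsets each
transform merged — one definition serves both intermediate ranking and the
final model confidence.  Symmetric subcomplexes (more than five copies of
one type all placed by the same transform) receive a score reward
``S + S·(100-S)/100`` on those transforms, compensating the pairwise
decomposition of what a joint prediction would score more confidently.

Everything is deterministic: there is no randomness anywhere and all ties
break lexicographically (score, then canonical id).
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .constraints import (
    ClashChecker,
    ConstraintSet,
    apply_groups,
    connectivity_filter,
    restraint_filter,
)
from .model_io import RigidTransform, SubunitStructure
from .transform_library import TransformationLibrary, _kabsch, _kabsch_rmsd, _lsq_fit

__all__ = [
    "AssemblyParams",
    "Usage",
    "Subcomplex",
    "Assembler",
    "assemble",
    "expand",
    "confidence",
    "symmetry_reward",
    "cluster",
    "copy_aware_rmsd",
    "retain_top_k",
]

Instance = tuple[str, int]  # (subunit type, copy index)


@dataclass
class AssemblyParams:
    """Tunable knobs of the assembly stage, with their standard defaults.

    ``k_best``: subcomplexes kept per composition and iteration.
    ``rmsd_cluster``: copy-aware CA RMSD threshold (Å) for clustering.
    ``clash_penetration`` / ``clash_fraction`` / ``plddt_clash_min``: an
    atom clashes when it penetrates > 1 Å into another's vdW sphere; a
    candidate dies when > 5% of an instance's considered backbone atoms
    (residue plDDT > 80) clash with one partner.
    ``restraint_violation_fraction``: discard at this violated fraction.
    ``interaction_cutoff``: CA-CA distance (Å) defining an interaction.
    ``symmetry_min_copies``: minimum identical copies ("over five" = 6)
    for the symmetry reward.
    ``weight_mode``: how a merge's weight derives from the residue counts
    of its two sides ("sum" default; "min", "product" as alternatives).
    """

    k_best: int = 100
    rmsd_cluster: float = 1.0
    clash_penetration: float = 1.0
    clash_fraction: float = 0.05
    plddt_clash_min: float = 80.0
    restraint_violation_fraction: float = 0.7
    interaction_cutoff: float = 8.0
    symmetry_min_copies: int = 6
    weight_mode: str = "sum"

    def __post_init__(self) -> None:
        if self.k_best < 1:
            raise ValueError("k_best must be positive")
        for name in ("rmsd_cluster", "clash_penetration", "interaction_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("clash_fraction", "restraint_violation_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.weight_mode not in ("sum", "min", "product"):
            raise ValueError("weight_mode must be sum, min or product")


@dataclass(frozen=True)
class Usage:
    """One merge in a subcomplex's assembly tree: which transform joined
    which two subsets (by residue count)."""

    transform_id: str
    pair: tuple[str, str]  # (from, to) subunit types of the transform
    score: float
    n_res_left: int
    n_res_right: int


@dataclass
class Subcomplex:
    """A set of placed subunit instances with the tree that built it.

    ``instances`` are sorted (type, copy-index) pairs; copies are
    renumbered canonically after every merge so labels carry no meaning.
    ``canonical_id`` is a rigid-motion- and label-invariant fingerprint of
    the geometry (quantized centroid-distance profiles), used for
    deduplication and deterministic tie-breaking.
    """

    instances: tuple[Instance, ...]
    placements: dict[Instance, RigidTransform]
    usages: tuple[Usage, ...]
    score: float
    canonical_id: tuple
    dist_profile: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def size(self) -> int:
        return len(self.instances)

    @property
    def composition(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.instances)


# ---------------------------------------------------------------------------
# scoring


def _rewarded_usage_scores(
    usages: Sequence[Usage], composition: Sequence[str], params: AssemblyParams
) -> list[float]:
    """Per-usage scores with the symmetry reward applied where it holds."""
    counts = Counter(composition)
    rewarded: set[str] = set()
    for sid, copies in counts.items():
        if copies < params.symmetry_min_copies:
            continue
        self_usages = [u for u in usages if u.pair == (sid, sid)]
        ids = {u.transform_id for u in self_usages}
        if len(self_usages) >= copies - 1 and len(ids) == 1:
            rewarded.add(next(iter(ids)))
    out = []
    for u in usages:
        s = u.score
        if u.transform_id in rewarded and u.pair[0] == u.pair[1]:
            s = s + s * (100.0 - s) / 100.0
        out.append(s)
    return out


def _usage_weight(u: Usage, mode: str) -> float:
    if mode == "sum":
        return float(u.n_res_left + u.n_res_right)
    if mode == "min":
        return float(min(u.n_res_left, u.n_res_right))
    return float(u.n_res_left * u.n_res_right)


def _weighted_score(
    usages: Sequence[Usage], composition: Sequence[str], params: AssemblyParams
) -> float:
    """Weighted mean of (possibly rewarded) transform scores; 100 for a
    monomer, which has no usages."""
    if not usages:
        return 100.0
    scores = _rewarded_usage_scores(usages, composition, params)
    weights = [_usage_weight(u, params.weight_mode) for u in usages]
    return float(np.dot(scores, weights) / np.sum(weights))


def confidence(subcomplex: Subcomplex, params: AssemblyParams | None = None) -> float:
    """Final model confidence: recompute the weighted-usage score."""
    params = params or AssemblyParams()
    return _weighted_score(subcomplex.usages, subcomplex.composition, params)


def symmetry_reward(subcomplex: Subcomplex, params: AssemblyParams | None = None) -> float:
    """Score after the symmetry reward; unchanged when the condition
    (> 5 copies of one type, all placed by one transform) does not hold."""
    return confidence(subcomplex, params)


# ---------------------------------------------------------------------------
# canonical geometry fingerprints and copy-aware RMSD


def _sort_key(sub: Subcomplex) -> tuple:
    """Deterministic ranking: score first, then (on exact ties) trees built
    from fewer distinct transforms — uniform trees are the ones that can
    earn the symmetry reward as they grow — then transform ids and the
    geometry fingerprint."""
    ids = sorted({u.transform_id for u in sub.usages})
    return (-sub.score, len(ids), tuple(ids), sub.canonical_id)


def _fingerprint(
    instances: Sequence[Instance], cents: np.ndarray
) -> tuple[tuple, np.ndarray]:
    """(canonical id, sorted flat distance vector) from instance centroids.

    Both are invariant to global rigid motion and to copy labelling: the id
    lists each instance as (type, its sorted quantized distances to the
    others), sorted; the vector is the sorted multiset of all pairwise
    distances, used as a cheap lower bound during clustering.
    """
    n = len(instances)
    if n == 1:
        return (instances[0][0],), np.zeros(0)
    d = cdist(cents, cents)
    rows = np.round(np.sort(d, axis=1)[:, 1:], 1)
    parts = sorted((instances[i][0], rows[i].tobytes()) for i in range(n))
    iu = np.triu_indices(n, k=1)
    return tuple(parts), np.sort(d[iu])


def canonical_fingerprint(
    instances: Sequence[Instance],
    placements: Mapping[Instance, RigidTransform],
    representatives: Mapping[str, SubunitStructure],
) -> tuple:
    """Rigid-motion- and label-invariant geometry fingerprint key."""
    cents = np.array(
        [placements[i].apply(representatives[i[0]].centroid()) for i in instances]
    )
    return _fingerprint(tuple(instances), cents)[0]


def _type_groups(types: Sequence[str]) -> list[np.ndarray]:
    """Index groups of same-type copies (only groups with >= 2 members)."""
    groups: dict[str, list[int]] = {}
    for i, t in enumerate(types):
        groups.setdefault(t, []).append(i)
    return [np.array(g) for g in groups.values() if len(g) > 1]


def _icp_assign(
    cents_a: np.ndarray,
    cents_b: np.ndarray,
    groups: list[np.ndarray],
    mapping: np.ndarray,
    rounds: int = 10,
) -> tuple[np.ndarray, float]:
    """Refine a copy correspondence by alternating centroid superposition
    with optimal per-type assignment until it stabilises."""
    from scipy.optimize import linear_sum_assignment

    rmsd = _kabsch_rmsd(cents_b[mapping], cents_a)
    for _ in range(rounds):
        rot, trans, rmsd = _kabsch(cents_b[mapping], cents_a)
        if not groups:
            break
        moved = cents_b @ rot.T + trans
        new_mapping = mapping.copy()
        for g in groups:
            rows, cols = linear_sum_assignment(cdist(cents_a[g], moved[mapping[g]]))
            new_mapping[g[rows]] = mapping[g][cols]
        if np.array_equal(new_mapping, mapping):
            break
        mapping = new_mapping
        rmsd = _kabsch_rmsd(cents_b[mapping], cents_a)
    return mapping, rmsd


def _candidate_mappings(
    types: Sequence[str],
    cents_a: np.ndarray,
    cents_b: np.ndarray,
    slack: float = 0.25,
    cap: int = 32,
    consistency_tol: float = 3.0,
) -> tuple[list[np.ndarray], float]:
    """Centroid-level candidate copy correspondences, best first.

    Starts from the identity correspondence (assignment iteration) and adds
    triple-anchored restarts: three reference instances are tentatively
    matched to compatible ordered triples of the other complex (pruned by
    pairwise-distance consistency), the pose implied by each triple is
    scored, and the most promising assignments are refined.  All mappings
    whose centroid RMSD comes within ``slack`` of the best are returned:
    symmetric arrangements (rings) admit several centroid-perfect
    correspondences — cyclic shifts and flips — that only full-CA
    comparison can tell apart, so the caller must discriminate.
    """
    from scipy.optimize import linear_sum_assignment

    n = len(types)
    groups = _type_groups(types)
    found: dict[tuple, float] = {}
    mapping, rmsd = _icp_assign(cents_a, cents_b, groups, np.arange(n))
    found[tuple(mapping)] = rmsd
    if groups and n >= 3 and rmsd >= 1e-3:
        d_a = cdist(cents_a, cents_a)
        d_b = cdist(cents_b, cents_b)
        tol = consistency_tol
        triples = [
            (j0, j1, j2)
            for j0 in range(n)
            if types[j0] == types[0]
            for j1 in range(n)
            if j1 != j0
            and types[j1] == types[1]
            and abs(d_b[j0, j1] - d_a[0, 1]) < tol
            for j2 in range(n)
            if j2 not in (j0, j1)
            and types[j2] == types[2]
            and abs(d_b[j0, j2] - d_a[0, 2]) < tol
            and abs(d_b[j1, j2] - d_a[1, 2]) < tol
        ]
        scored: list[tuple[float, tuple]] = []
        for triple in triples[:400]:
            rot, trans, _ = _kabsch(cents_b[list(triple)], cents_a[:3])
            moved = cents_b @ rot.T + trans
            trial = np.arange(n)
            for g in groups:
                rows, cols = linear_sum_assignment(cdist(cents_a[g], moved[g]))
                trial[g[rows]] = g[cols]
            scored.append((_kabsch_rmsd(cents_b[trial], cents_a), tuple(trial)))
        scored.sort()
        for _, trial in scored[:8]:
            refined, r = _icp_assign(
                cents_a, cents_b, groups, np.array(trial), rounds=3
            )
            key = tuple(refined)
            if key not in found or r < found[key]:
                found[key] = r
    best = min(found.values())
    ranked = sorted(found.items(), key=lambda kv: (kv[1], kv[0]))
    mappings = [np.array(k) for k, v in ranked if v <= best + slack][:cap]
    return mappings, best


def _copy_aware_alignment(
    types: Sequence[str],
    cas_a: Sequence[np.ndarray],
    cas_b: Sequence[np.ndarray],
) -> tuple[float, list[int]]:
    """Copy-aware CA RMSD between two placed complexes of equal composition.

    The correspondence between same-type copies is found on subunit
    centroids (assignment iteration with a triple-anchored restart), then
    polished by accepting pairwise swaps that lower the full CA RMSD until
    none does; the final correspondence gives the CA RMSD after CA-level
    superposition.
    """
    n = len(types)
    cents_a = np.array([c.mean(axis=0) for c in cas_a])
    cents_b = np.array([c.mean(axis=0) for c in cas_b])
    stack_a = np.concatenate(cas_a)

    def ca_rmsd(m) -> float:
        return _kabsch_rmsd(np.concatenate([cas_b[j] for j in m]), stack_a)

    swappable = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if types[i] == types[j]
    ]
    if not swappable:
        return ca_rmsd(list(range(n))), list(range(n))
    if n >= 3:
        cands, _ = _candidate_mappings(types, cents_a, cents_b)
        mapping = list(min(cands, key=ca_rmsd))
    else:
        mapping = list(range(n))
    best = ca_rmsd(mapping)
    improved = True
    rounds = 0
    while improved and rounds < 200:
        improved = False
        rounds += 1
        for i, j in swappable:
            trial = mapping.copy()
            trial[i], trial[j] = trial[j], trial[i]
            c = ca_rmsd(trial)
            if c < best - 1e-12:
                mapping, best = trial, c
                improved = True
    return best, [int(j) for j in mapping]


def copy_aware_rmsd(
    a: Subcomplex,
    b: Subcomplex,
    representatives: Mapping[str, SubunitStructure],
) -> float:
    """Copy-aware CA RMSD between two subcomplexes of identical composition."""
    if a.composition != b.composition:
        raise ValueError("subcomplexes have different compositions")
    types = [sid for sid, _ in a.instances]
    cas_a = [
        a.placements[i].apply(representatives[i[0]].ca_coords) for i in a.instances
    ]
    cas_b = [
        b.placements[i].apply(representatives[i[0]].ca_coords) for i in b.instances
    ]
    rmsd, _ = _copy_aware_alignment(types, cas_a, cas_b)
    return rmsd


# ---------------------------------------------------------------------------
# the assembler


class Assembler:
    """Holds the library, parameters and per-type caches for one run."""

    def __init__(
        self,
        library: TransformationLibrary,
        params: AssemblyParams | None = None,
        constraints: ConstraintSet | None = None,
    ) -> None:
        if library.n_transforms == 0:
            raise ValueError("transformation library is empty")
        self.library = library
        self.params = params or AssemblyParams()
        self.constraints = constraints or ConstraintSet.empty()
        self.representatives = library.representatives
        self.clash_checker = ClashChecker(self.representatives, self.params)
        self._n_res = {sid: rep.n_residues for sid, rep in self.representatives.items()}
        self._rep_centroid = {
            sid: rep.centroid() for sid, rep in self.representatives.items()
        }
        self._rep_ca = {sid: rep.ca_coords for sid, rep in self.representatives.items()}
        cc = self.clash_checker
        self._clash_coords = cc._coords
        self._clash_radii = cc._radii
        self._clash_center = cc._center
        self._clash_bound = cc._bound
        self._max_contact = 2 * 1.70 - self.params.clash_penetration
        self._directed_cache: dict[tuple[str, str], list] = {}
        # clash decisions keyed by (types, quantized relative pose): the
        # same few relative poses recur across thousands of candidates
        self._clash_memo: dict[tuple, bool] = {}
        #: per-iteration counts of generated/filtered candidates
        self.iteration_stats: list[dict] = []

    def _directed(self, a: str, b: str):
        key = (a, b)
        if key not in self._directed_cache:
            self._directed_cache[key] = self.library.directed(a, b)
        return self._directed_cache[key]

    # -- building blocks ----------------------------------------------------

    def monomer(self, subunit_id: str) -> Subcomplex:
        inst = (subunit_id, 0)
        placements = {inst: RigidTransform.identity()}
        canon, profile = _fingerprint(
            (inst,), self._rep_centroid[subunit_id][None, :]
        )
        return Subcomplex(
            instances=(inst,),
            placements=placements,
            usages=(),
            score=100.0,
            canonical_id=canon,
            dist_profile=profile,
        )

    def _n_res_of(self, sub: Subcomplex) -> int:
        return sum(self._n_res[sid] for sid, _ in sub.instances)

    def _placed(self, sub: Subcomplex) -> dict:
        """Cached placed arrays for a stored subcomplex: clash atoms,
        clash-sphere centers/bounds, CA coords and centroids per instance."""
        cache = getattr(sub, "_placed_arrays", None)
        if cache is not None:
            return cache
        atoms, centers, bounds, cas, cents = [], [], [], [], []
        for inst in sub.instances:
            sid = inst[0]
            place = sub.placements[inst]
            rot_t = place.rotation.T
            atoms.append(self._clash_coords[sid] @ rot_t + place.translation)
            centers.append(place.apply(self._clash_center[sid]))
            bounds.append(self._clash_bound[sid])
            ca = self._rep_ca[sid] @ rot_t + place.translation
            cas.append(ca)
            cents.append(place.apply(self._rep_centroid[sid]))
        cache = {
            "atoms": atoms,
            "centers": np.array(centers),
            "bounds": np.array(bounds),
            "cas": cas,
            "cents": np.array(cents),
        }
        sub._placed_arrays = cache
        return cache

    def _clash_ok_arrays(
        self,
        sub_l: Subcomplex,
        arr_l: dict,
        sub_r: Subcomplex,
        arr_r: dict,
        rot_t: np.ndarray,
        trans: np.ndarray,
        moved_centers: np.ndarray,
    ) -> bool:
        """Cross-side clash test; right-side atoms are moved lazily, only
        for instance pairs whose bounding spheres actually approach."""
        frac = self.params.clash_fraction
        pen_thr = self.params.clash_penetration
        bounds_r = arr_r["bounds"]
        memo = self._clash_memo
        moved_atoms: dict[int, np.ndarray] = {}
        for li, l_inst in enumerate(sub_l.instances):
            la = arr_l["atoms"][li]
            if la.shape[0] == 0:
                continue
            lr = self._clash_radii[l_inst[0]]
            lcent = arr_l["centers"][li]
            lbound = arr_l["bounds"][li]
            pl = sub_l.placements[l_inst]
            rl_t = pl.rotation.T
            for ri, r_inst in enumerate(sub_r.instances):
                d = moved_centers[ri] - lcent
                if math.sqrt(d @ d) > lbound + bounds_r[ri] + self._max_contact:
                    continue
                # relative pose of moved-right vs left, quantized, as key
                pr = sub_r.placements[r_inst]
                rel_rot = rl_t @ (rot_t.T @ pr.rotation)
                rel_tr = rl_t @ (
                    rot_t.T @ pr.translation + trans - pl.translation
                )
                key = (
                    l_inst[0],
                    r_inst[0],
                    np.round(rel_rot, 4).tobytes(),
                    np.round(rel_tr, 3).tobytes(),
                )
                hit = memo.get(key)
                if hit is not None:
                    if hit:
                        continue
                    return False
                ra_arr = moved_atoms.get(ri)
                if ra_arr is None:
                    ra_arr = arr_r["atoms"][ri] @ rot_t + trans
                    moved_atoms[ri] = ra_arr
                if ra_arr.shape[0] == 0:
                    continue
                rr = self._clash_radii[r_inst[0]]
                pen = (lr[:, None] + rr[None, :]) - cdist(la, ra_arr)
                clash = pen > pen_thr
                ok = not (
                    float(clash.any(axis=1).mean()) > frac
                    or float(clash.any(axis=0).mean()) > frac
                )
                memo[key] = ok
                if not ok:
                    return False
        return True

    def _build_candidate(
        self,
        left: Subcomplex,
        right: Subcomplex,
        move: RigidTransform,
        usage: Usage,
        moved_cents: np.ndarray,
        canon: str,
        profile: np.ndarray,
        score: float,
    ) -> Subcomplex:
        """Assemble the merged Subcomplex with canonical copy renumbering."""
        arr_l = self._placed(left)
        entries = []  # (sid, rounded centroid key, placement)
        for idx, inst in enumerate(left.instances):
            cent = arr_l["cents"][idx]
            entries.append((inst[0], tuple(np.round(cent, 3)), left.placements[inst]))
        for idx, inst in enumerate(right.instances):
            cent = moved_cents[idx]
            pr = right.placements[inst]
            placed = RigidTransform._unsafe(
                move.rotation @ pr.rotation,
                move.rotation @ pr.translation + move.translation,
            )
            entries.append((inst[0], tuple(np.round(cent, 3)), placed))
        entries.sort(key=lambda e: (e[0], e[1]))
        placements: dict[Instance, RigidTransform] = {}
        instances: list[Instance] = []
        counters: Counter = Counter()
        for sid, _, place in entries:
            inst = (sid, counters[sid])
            counters[sid] += 1
            instances.append(inst)
            placements[inst] = place
        return Subcomplex(
            instances=tuple(instances),
            placements=placements,
            usages=left.usages + right.usages + (usage,),
            score=score,
            canonical_id=canon,
            dist_profile=profile,
        )

    # -- expansion ----------------------------------------------------------

    def _merge_into(
        self,
        left: Subcomplex,
        right: Subcomplex,
        stats: dict,
        pools: dict,
        rejected: dict,
    ) -> None:
        """Generate, screen and pool all merge candidates of two stored
        subcomplexes.

        The canonical geometry fingerprint is computed first, from centroids
        alone: a geometry already pooled with a better rank, or already
        rejected by a geometric filter, is skipped before any atom work —
        each distinct geometry pays for clash/connectivity/restraint checks
        exactly once per iteration.
        """
        arr_l = self._placed(left)
        arr_r = self._placed(right)
        n_left = self._n_res_of(left)
        n_right = self._n_res_of(right)
        types_comb = [inst[0] for inst in left.instances] + [
            inst[0] for inst in right.instances
        ]
        type_keys = [(sid, 0) for sid in types_comb]
        comp = tuple(sorted(types_comb))
        pool = pools.setdefault(comp, {})
        rej = rejected.setdefault(comp, set())
        usages_base = left.usages + right.usages
        for a in left.instances:
            pa = left.placements[a]
            ra, ta = pa.rotation, pa.translation
            for b in right.instances:
                pb = right.placements[b]
                rb_t = pb.rotation.T
                tb_inv = -(rb_t @ pb.translation)
                for tid, x, score_t in self._directed(a[0], b[0]):
                    stats["generated"] += 1
                    # move = pa ∘ x ∘ pb⁻¹, composed on raw arrays
                    r_ax = ra @ x.rotation
                    rot = r_ax @ rb_t
                    trans = r_ax @ tb_inv + ra @ x.translation + ta
                    rot_t = rot.T
                    moved_cents = arr_r["cents"] @ rot_t + trans
                    canon, profile = _fingerprint(
                        type_keys, np.concatenate([arr_l["cents"], moved_cents])
                    )
                    if canon in rej:
                        stats["dedup"] += 1
                        continue
                    usage = Usage(
                        transform_id=tid,
                        pair=(a[0], b[0]),
                        score=score_t,
                        n_res_left=n_left,
                        n_res_right=n_right,
                    )
                    usages = usages_base + (usage,)
                    score = _weighted_score(usages, comp, self.params)
                    prev = pool.get(canon)
                    if prev is not None:
                        ids = sorted({u.transform_id for u in usages})
                        if (-score, len(ids), tuple(ids), canon) >= _sort_key(prev):
                            stats["dedup"] += 1
                            continue
                    if not self._clash_ok_arrays(
                        left, arr_l, right, arr_r, rot_t, trans,
                        arr_r["centers"] @ rot_t + trans,
                    ):
                        stats["clash"] += 1
                        rej.add(canon)
                        continue
                    move = RigidTransform._unsafe(rot, trans)
                    sub = self._build_candidate(
                        left, right, move, usage, moved_cents, canon, profile, score
                    )
                    if self.constraints.chain_links and not connectivity_filter(
                        sub, self.constraints.chain_links, self.representatives
                    ):
                        stats["connectivity"] += 1
                        rej.add(canon)
                        continue
                    if self.constraints.restraints and not restraint_filter(
                        sub,
                        self.constraints.restraints,
                        self.representatives,
                        self.params,
                    ):
                        stats["restraints"] += 1
                        rej.add(canon)
                        continue
                    pool[canon] = sub

    def expand_candidates(
        self, left: Subcomplex, right: Subcomplex
    ) -> list[Subcomplex]:
        """All merge candidates of *left* and *right*, without any
        filtering (the expansion stage in isolation)."""
        out: list[Subcomplex] = []
        arr_l = self._placed(left)
        arr_r = self._placed(right)
        n_left = self._n_res_of(left)
        n_right = self._n_res_of(right)
        types_comb = [inst[0] for inst in left.instances] + [
            inst[0] for inst in right.instances
        ]
        type_keys = [(sid, 0) for sid in types_comb]
        comp = tuple(sorted(types_comb))
        usages_base = left.usages + right.usages
        for a in left.instances:
            pa = left.placements[a]
            for b in right.instances:
                pb_inv = right.placements[b].inverse()
                for tid, x, score_t in self._directed(a[0], b[0]):
                    move = pa.compose(x).compose(pb_inv)
                    rot_t = move.rotation.T
                    moved_cents = arr_r["cents"] @ rot_t + move.translation
                    canon, profile = _fingerprint(
                        type_keys, np.concatenate([arr_l["cents"], moved_cents])
                    )
                    usage = Usage(
                        transform_id=tid,
                        pair=(a[0], b[0]),
                        score=score_t,
                        n_res_left=n_left,
                        n_res_right=n_right,
                    )
                    score = _weighted_score(usages_base + (usage,), comp, self.params)
                    out.append(
                        self._build_candidate(
                            left, right, move, usage, moved_cents, canon, profile, score
                        )
                    )
        return out

    # -- clustering and retention -------------------------------------------

    def cluster(
        self, subcomplexes: Sequence[Subcomplex], max_leaders: int | None = None
    ) -> list[Subcomplex]:
        """Greedy leader clustering at the copy-aware RMSD threshold.

        A sorted-distance-profile bound prunes pairs that cannot possibly
        lie within the threshold before any superposition is attempted.
        With ``max_leaders`` set, clustering stops once that many leaders
        exist — later candidates either join an existing cluster (and are
        dropped) or would rank beyond the K-best cut anyway.
        """
        ordered = sorted(subcomplexes, key=_sort_key)
        if not ordered:
            return []
        n_inst = ordered[0].size
        profile_bound = 2.0 * math.sqrt(n_inst) * self.params.rmsd_cluster + 1.0
        leaders: list[Subcomplex] = []
        for cand in ordered:
            merged = False
            for leader in leaders:
                if (
                    cand.dist_profile is not None
                    and leader.dist_profile is not None
                    and cand.dist_profile.size
                    and np.abs(cand.dist_profile - leader.dist_profile).max()
                    > profile_bound
                ):
                    continue
                if self._within_threshold(cand, leader, self.params.rmsd_cluster):
                    merged = True
                    break
            if not merged:
                leaders.append(cand)
                if max_leaders is not None and len(leaders) >= max_leaders:
                    break
        return leaders

    def _within_threshold(self, a: Subcomplex, b: Subcomplex, thr: float) -> bool:
        """Is the copy-aware CA RMSD of two same-composition subcomplexes
        below ``thr``?  Correspondence between identical copies is found by
        iterating centroid superposition with optimal per-type assignment
        (equivalent in outcome to the pairwise-swap descent, but cheaper).
        """
        arr_a, arr_b = self._placed(a), self._placed(b)
        cents_a, cents_b = arr_a["cents"], arr_b["cents"]
        n = len(a.instances)
        comp = a.composition
        groups = _type_groups(comp)
        mapping, cent_lb = _icp_assign(cents_a, cents_b, groups, np.arange(n))
        stack_a = np.concatenate(arr_a["cas"])

        def ca_ok(m) -> bool:
            stack_b = np.concatenate([arr_b["cas"][j] for j in m])
            return _kabsch_rmsd(stack_b, stack_a) < thr

        equal_sizes = len({self._n_res[sid] for sid in comp}) == 1
        if cent_lb < thr and ca_ok(mapping):
            return True
        if not groups or n < 3 or cent_lb >= 4.0 * thr:
            # the centroid RMSD lower-bounds the CA RMSD for equal-size
            # copies, so a far centroid miss settles it
            if equal_sizes and cent_lb >= thr:
                return False
            return ca_ok(mapping)
        # close miss: the assignment may sit in a relabelling local
        # minimum (cyclic shifts or flips of symmetric arrangements)
        cands, best_cent = _candidate_mappings(comp, cents_a, cents_b)
        if equal_sizes and best_cent >= thr:
            return False
        return any(ca_ok(m) for m in cands)

    # -- the main loop -------------------------------------------------------

    def run(
        self,
        target_stoich: Mapping[str, int],
        seeds: Sequence[Subcomplex] = (),
        single_types: Iterable[str] | None = None,
    ) -> list[Subcomplex]:
        """Assemble toward ``target_stoich``; see module docstring.

        ``seeds`` inject pre-built subcomplexes (group stages) that enter
        the state frozen; ``single_types`` restricts which subunits also
        enter as monomers (default: all of the stoichiometry).
        """
        stoich = dict(target_stoich)
        unknown = [sid for sid in stoich if sid not in self.representatives]
        if unknown:
            raise ValueError(f"stoichiometry names unknown subunits: {unknown}")
        if any(c < 1 for c in stoich.values()):
            raise ValueError("copy counts must be positive")
        n_total = sum(stoich.values())
        target = Counter(stoich)

        state: dict[tuple[str, ...], list[Subcomplex]] = {}
        single_ids = sorted(single_types if single_types is not None else stoich)
        for sid in single_ids:
            state[(sid,)] = [self.monomer(sid)]
        for seed in seeds:
            state.setdefault(seed.composition, []).append(seed)

        self.iteration_stats = []
        for i in range(2, n_total + 1):
            stats = {
                "size": i,
                "generated": 0,
                "dedup": 0,
                "clash": 0,
                "connectivity": 0,
                "restraints": 0,
                "kept": 0,
            }
            pools: dict[tuple[str, ...], dict[str, Subcomplex]] = {}
            rejected: dict[tuple[str, ...], set[str]] = {}
            comps = sorted(state)
            for comp_l in comps:
                k = len(comp_l)
                if k > i - k:
                    continue
                for comp_r in comps:
                    if len(comp_r) != i - k:
                        continue
                    if k == i - k and comp_l > comp_r:
                        continue
                    combined = Counter(comp_l) + Counter(comp_r)
                    if any(combined[sid] > target[sid] for sid in combined):
                        continue
                    if comp_l == comp_r:
                        pairs = itertools.combinations_with_replacement(
                            state[comp_l], 2
                        )
                    else:
                        pairs = itertools.product(state[comp_l], state[comp_r])
                    for left, right in pairs:
                        self._merge_into(left, right, stats, pools, rejected)
            for comp, pool in sorted(pools.items()):
                clustered = self.cluster(
                    list(pool.values()), max_leaders=self.params.k_best
                )
                if clustered:
                    state[comp] = clustered
                    stats["kept"] += len(state[comp])
            self.iteration_stats.append(stats)

        for size in range(n_total, 0, -1):
            final = [
                sub
                for comp, subs in state.items()
                if len(comp) == size
                for sub in subs
            ]
            if final:
                return sorted(final, key=_sort_key)
        return []

    def run_staged(self, target_stoich: Mapping[str, int]) -> list[Subcomplex]:
        """Honor assembly-order groups: assemble each group first, then
        combine the frozen group results with the remaining subunits."""
        plan = apply_groups(target_stoich, self.constraints.groups)
        seeds: list[Subcomplex] = []
        for stage in plan.group_stages:
            stage_results = self.run(stage)
            want = sum(stage.values())
            full = [s for s in stage_results if s.size == want] or stage_results
            seeds.extend(full[: self.params.k_best])
        return self.run(plan.full, seeds=seeds, single_types=sorted(plan.remaining))


# ---------------------------------------------------------------------------
# module-level surface


def assemble(
    library: TransformationLibrary,
    target_stoich: Mapping[str, int],
    params: AssemblyParams | None = None,
    constraints: ConstraintSet | None = None,
) -> list[Subcomplex]:
    """Assemble the target stoichiometry; returns the largest achieved
    subcomplexes, best score first (partial when the full size is
    unreachable with the given transforms)."""
    if sum(target_stoich.values()) < 2:
        raise ValueError("need at least two subunit copies to assemble")
    asm = Assembler(library, params, constraints)
    if asm.constraints.groups:
        return asm.run_staged(target_stoich)
    return asm.run(target_stoich)


def expand(
    left: Subcomplex,
    right: Subcomplex,
    library: TransformationLibrary,
    params: AssemblyParams | None = None,
) -> list[Subcomplex]:
    """All unfiltered merge candidates of two disjoint subcomplexes."""
    asm = Assembler(library, params)
    return asm.expand_candidates(left, right)


def cluster(
    subcomplexes: Sequence[Subcomplex],
    params: AssemblyParams,
    representatives: Mapping[str, SubunitStructure],
) -> list[Subcomplex]:
    """Greedy leader clustering of same-composition subcomplexes."""
    if not subcomplexes:
        return []
    comps = {s.composition for s in subcomplexes}
    if len(comps) != 1:
        raise ValueError("clustering requires identical compositions")
    ordered = sorted(subcomplexes, key=_sort_key)
    leaders: list[Subcomplex] = []
    for cand in ordered:
        if any(
            copy_aware_rmsd(cand, leader, representatives) < params.rmsd_cluster
            for leader in leaders
        ):
            continue
        leaders.append(cand)
    return leaders


def retain_top_k(
    per_composition: Mapping[tuple[str, ...], Sequence[Subcomplex]],
    params: AssemblyParams,
) -> dict[tuple[str, ...], list[Subcomplex]]:
    """Keep at most K best subcomplexes per composition (ties by
    canonical id, so the cut is deterministic)."""
    return {
        comp: sorted(subs, key=_sort_key)[: params.k_best]
        for comp, subs in per_composition.items()
    }
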