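"""Exhaustive assembly-tree enumeration: an independent oracle for the
hierarchical K-best search on tiny problems.

Every binary assembly tree over labelled subunit copies is enumerated
recursively — all fragment pairs, all anchor instance pairs, all library
transforms — with no clustering, no K-truncation and no deduplication.
The tree score is recomputed here from the weighted-mean definition
(including the symmetry reward) rather than taken from the package.  Only
the per-pair clash filter primitive is shared with the implementation,
since the filters have their own dedicated tests.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from multifold.assembler import AssemblyParams
from multifold.constraints import ClashChecker
from multifold.model_io import RigidTransform


def tree_score(usages, composition, params: AssemblyParams) -> float:
    """Weighted mean of transform scores, symmetry reward included.

    ``usages`` are (transform_id, (from, to), score, n_left, n_right).
    """
    counts = Counter(composition)
    rewarded: set[str] = set()
    for sid, copies in counts.items():
        if copies < params.symmetry_min_copies:
            continue
        self_usages = [u for u in usages if u[1] == (sid, sid)]
        ids = {u[0] for u in self_usages}
        if len(self_usages) >= copies - 1 and len(ids) == 1:
            rewarded |= ids
    num = den = 0.0
    for tid, pair, s, n_left, n_right in usages:
        if tid in rewarded and pair[0] == pair[1]:
            s = s + s * (100.0 - s) / 100.0
        w = n_left + n_right
        num += w * s
        den += w
    return num / den if den else 100.0


def brute_force_assemblies(library, stoich, params: AssemblyParams | None = None):
    """All full assemblies reachable by any binary merge tree.

    Returns a list of (score, members) where members maps a copy label to
    (subunit_id, rotation, translation).  Intended for N <= 4 with a
    handful of transforms per pair; complexity is exponential.
    """
    params = params or AssemblyParams()
    checker = ClashChecker(library.representatives, params)
    n_res = {sid: rep.n_residues for sid, rep in library.representatives.items()}

    fragments = []
    label = 0
    for sid in sorted(stoich):
        for _ in range(stoich[sid]):
            fragments.append(
                ({label: (sid, np.eye(3), np.zeros(3))}, ())
            )
            label += 1

    results: list[tuple[float, dict]] = []

    def cross_clash_free(members_a, members_b) -> bool:
        for sa, ra, ta in members_a.values():
            pa = RigidTransform(ra, ta)
            for sb, rb, tb in members_b.values():
                if not checker.pair_keep(sa, pa, sb, RigidTransform(rb, tb)):
                    return False
        return True

    def recurse(frags):
        if len(frags) == 1:
            members, usages = frags[0]
            comp = sorted(s for s, _, _ in members.values())
            results.append((tree_score(usages, comp, params), members))
            return
        for i in range(len(frags)):
            for j in range(i + 1, len(frags)):
                (mem_l, us_l), (mem_r, us_r) = frags[i], frags[j]
                rest = [frags[k] for k in range(len(frags)) if k not in (i, j)]
                nl = sum(n_res[s] for s, _, _ in mem_l.values())
                nr = sum(n_res[s] for s, _, _ in mem_r.values())
                for sa, ra, ta in mem_l.values():
                    for sb, rb, tb in mem_r.values():
                        for tid, x, score in library.directed(sa, sb):
                            # move = P_a ∘ X ∘ P_b⁻¹
                            rax = ra @ x.rotation
                            rot = rax @ rb.T
                            trans = rax @ (-rb.T @ tb) + ra @ x.translation + ta
                            moved = {
                                lab: (s2, rot @ r2, rot @ t2 + trans)
                                for lab, (s2, r2, t2) in mem_r.items()
                            }
                            if not cross_clash_free(mem_l, moved):
                                continue
                            merged = dict(mem_l)
                            merged.update(moved)
                            usage = (tid, (sa, sb), score, nl, nr)
                            recurse(rest + [(merged, us_l + us_r + (usage,))])

    recurse(fragments)
    return results


def brute_force_best(library, stoich, params: AssemblyParams | None = None):
    """(best score, best members) over all assembly trees."""
    results = brute_force_assemblies(library, stoich, params)
    if not results:
        return None, None
    return max(results, key=lambda r: r[0])


def members_ca_coords(members, representatives):
    """Per-instance (type, CA array) in deterministic label order."""
    out = []
    for label in sorted(members):
        sid, rot, trans = members[label]
        out.append((sid, representatives[sid].ca_coords @ rot.T + trans))
    return out
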