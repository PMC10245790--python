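"""Filters applied inside the assembly loop.

Three hard filters decide whether a freshly merged subcomplex survives:

* steric clashes between the two merged sides (backbone atoms of
  confidently modelled residues, sphere-overlap depth beyond a threshold);
* sequence connectivity between subunits cut from the same chain (the gap
  a linker of L residues can span is taken as L x 3 Å, floored at 4 Å so a
  zero-length linker keeps the peptide-bond CA-CA distance of ~3.8 Å
  satisfiable);
* crosslink-derived maximum CA-CA distance restraints, discarding a
  candidate once a configurable fraction (default 70%) of its applicable
  restraints is violated.  A restraint ambiguous across copies is satisfied
  if any copy pairing satisfies it.

Assembly-order groups (known subcomplexes) are expressed as a staged plan:
each group is assembled to completion first and its results become frozen
building blocks for the final stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model_io import RigidTransform, SubunitStructure

__all__ = [
    "Restraint",
    "ConstraintSet",
    "StagedPlan",
    "ClashChecker",
    "clash_filter",
    "connectivity_filter",
    "restraint_filter",
    "apply_groups",
    "load_crosslinks",
]

#: Van der Waals radii (Å) for backbone elements; CA counts as carbon.
VDW_RADII = {"N": 1.55, "CA": 1.70, "C": 1.70, "O": 1.52}
#: Distance floor (Å) for zero-length linkers (peptide-bond CA-CA ~ 3.8 Å).
LINKER_FLOOR = 4.0
LINKER_PER_RESIDUE = 3.0


@dataclass(frozen=True)
class Restraint:
    """A maximum CA-CA distance between two residues (crosslink-derived)."""

    subunit_a: str
    res_a: int
    subunit_b: str
    res_b: int
    max_dist: float
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.max_dist <= 0:
            raise ValueError("max_dist must be positive")
        if self.res_a < 1 or self.res_b < 1:
            raise ValueError("residue indices are 1-based")


@dataclass
class ConstraintSet:
    """Everything the assembly loop filters on besides clashes.

    ``chain_links`` are (subunit, successor, linker_len) triples for
    subunits cut from one parent chain; ``groups`` are disjoint subunit-id
    sets assembled separately before the final stage.
    """

    restraints: list[Restraint] = field(default_factory=list)
    chain_links: list[tuple[str, str, int]] = field(default_factory=list)
    groups: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.groups = [frozenset(g) for g in self.groups]
        seen: set[str] = set()
        for g in self.groups:
            if seen & g:
                raise ValueError("assembly groups must be pairwise disjoint")
            seen |= g

    @staticmethod
    def empty() -> "ConstraintSet":
        return ConstraintSet()


@dataclass(frozen=True)
class StagedPlan:
    """Assembly order: each group stage runs to completion, then the final
    stage combines group results with the remaining subunits."""

    group_stages: tuple[dict[str, int], ...]
    remaining: dict[str, int]
    full: dict[str, int]


# ---------------------------------------------------------------------------
# steric clashes


class ClashChecker:
    """Precomputed clash probes per subunit type.

    Only backbone atoms of residues with plDDT above the threshold are
    considered: disordered regions are static copies of the representative
    and would clash spuriously.  An atom clashes when it penetrates more
    than ``clash_penetration`` into another atom's van der Waals sphere,
    i.e. ``(r_i + r_j) - d > clash_penetration``.
    """

    def __init__(self, representatives: Mapping[str, SubunitStructure], params) -> None:
        self.params = params
        self._coords: dict[str, np.ndarray] = {}
        self._radii: dict[str, np.ndarray] = {}
        self._center: dict[str, np.ndarray] = {}
        self._bound: dict[str, float] = {}
        for sid, rep in representatives.items():
            mask = rep.plddt > params.plddt_clash_min
            coords = []
            radii = []
            for i in np.nonzero(mask)[0]:
                for k, aname in enumerate(("N", "CA", "C", "O")):
                    xyz = rep.coords[i, k]
                    if np.isfinite(xyz).all():
                        coords.append(xyz)
                        radii.append(VDW_RADII[aname])
            coords = np.asarray(coords).reshape(-1, 3)
            radii = np.asarray(radii)
            self._coords[sid] = coords
            self._radii[sid] = radii
            if coords.size:
                center = coords.mean(axis=0)
                bound = float(np.linalg.norm(coords - center, axis=1).max())
            else:
                center, bound = np.zeros(3), 0.0
            self._center[sid] = center
            self._bound[sid] = bound

    def pair_keep(
        self,
        type_a: str,
        place_a: RigidTransform,
        type_b: str,
        place_b: RigidTransform,
    ) -> bool:
        """True if this instance pair is clash-acceptable."""
        coords_a, coords_b = self._coords[type_a], self._coords[type_b]
        if coords_a.size == 0 or coords_b.size == 0:
            return True
        # bounding-sphere prune: deepest possible overlap still below threshold
        max_contact = 2 * max(VDW_RADII.values()) - self.params.clash_penetration
        gap = float(
            np.linalg.norm(
                place_a.apply(self._center[type_a]) - place_b.apply(self._center[type_b])
            )
        )
        if gap > self._bound[type_a] + self._bound[type_b] + max_contact:
            return True
        a = place_a.apply(coords_a)
        b = place_b.apply(coords_b)
        pen = (self._radii[type_a][:, None] + self._radii[type_b][None, :]) - cdist(a, b)
        clash = pen > self.params.clash_penetration
        frac_a = float(clash.any(axis=1).mean())
        frac_b = float(clash.any(axis=0).mean())
        return frac_a <= self.params.clash_fraction and frac_b <= self.params.clash_fraction


def clash_filter(
    candidate,
    new_pairing: tuple[Sequence, Sequence],
    representatives: Mapping[str, SubunitStructure],
    params,
    checker: ClashChecker | None = None,
) -> bool:
    """Keep/discard on steric clashes across the two newly merged sides.

    Checks every cross pair (one instance from each side); within-side
    pairs passed this filter when their side was built.  Discards when any
    instance has more than ``clash_fraction`` of its considered backbone
    atoms clashing with some single partner instance.
    """
    if checker is None:
        checker = ClashChecker(representatives, params)
    left, right = new_pairing
    for a in left:
        for b in right:
            if not checker.pair_keep(
                a[0], candidate.placements[a], b[0], candidate.placements[b]
            ):
                return False
    return True


# ---------------------------------------------------------------------------
# chain connectivity


def linker_bound(linker_len: int) -> float:
    """Maximum CA-CA gap (Å) a linker of ``linker_len`` residues may span."""
    return max(LINKER_FLOOR, LINKER_PER_RESIDUE * linker_len)


def connectivity_filter(
    candidate,
    chain_links: Sequence[tuple[str, str, int]],
    representatives: Mapping[str, SubunitStructure],
) -> bool:
    """Keep/discard on sequence connectivity of split chains.

    For each link whose two subunits are both present, the CA of the
    predecessor's last residue must lie within the linker bound of the CA of
    the successor's first residue.  With multiple copies, the copies are
    matched greedily by minimum gap distance (each copy used once); any
    matched pair over the bound discards the candidate.
    """
    by_type: dict[str, list] = {}
    for inst in candidate.instances:
        by_type.setdefault(inst[0], []).append(inst)
    for pred, succ, linker_len in chain_links:
        if pred not in by_type or succ not in by_type:
            continue
        bound = linker_bound(linker_len)
        tails = np.array(
            [
                candidate.placements[i].apply(representatives[pred].ca_coords[-1])
                for i in by_type[pred]
            ]
        )
        heads = np.array(
            [
                candidate.placements[i].apply(representatives[succ].ca_coords[0])
                for i in by_type[succ]
            ]
        )
        gaps = cdist(tails, heads)
        n_match = min(len(tails), len(heads))
        used_r, used_c = set(), set()
        for _ in range(n_match):
            best = None
            for r in range(gaps.shape[0]):
                if r in used_r:
                    continue
                for c in range(gaps.shape[1]):
                    if c in used_c:
                        continue
                    if best is None or gaps[r, c] < best[0]:
                        best = (gaps[r, c], r, c)
            used_r.add(best[1])
            used_c.add(best[2])
            if best[0] > bound:
                return False
    return True


# ---------------------------------------------------------------------------
# distance restraints


def restraint_filter(
    candidate,
    restraints: Sequence[Restraint],
    representatives: Mapping[str, SubunitStructure],
    params,
) -> bool:
    """Keep/discard on crosslink restraint violations.

    Only restraints with both endpoint subunit types present are counted.
    A restraint is satisfied if the minimum CA-CA distance over all copy
    pairings is within its bound (ambiguity resolved optimistically).  The
    candidate is discarded when the violated fraction reaches
    ``restraint_violation_fraction``.
    """
    by_type: dict[str, list] = {}
    for inst in candidate.instances:
        by_type.setdefault(inst[0], []).append(inst)
    considered = 0
    violated = 0
    for r in restraints:
        if r.subunit_a not in by_type or r.subunit_b not in by_type:
            continue
        rep_a, rep_b = representatives[r.subunit_a], representatives[r.subunit_b]
        if r.res_a > rep_a.n_residues or r.res_b > rep_b.n_residues:
            raise ValueError(f"restraint references residue outside subunit: {r}")
        considered += 1
        best = np.inf
        for ia in by_type[r.subunit_a]:
            pa = candidate.placements[ia].apply(rep_a.ca_coords[r.res_a - 1])
            for ib in by_type[r.subunit_b]:
                pb = candidate.placements[ib].apply(rep_b.ca_coords[r.res_b - 1])
                best = min(best, float(np.linalg.norm(pa - pb)))
        if not best <= r.max_dist:
            violated += 1
    if considered == 0:
        return True
    return violated / considered < params.restraint_violation_fraction


# ---------------------------------------------------------------------------
# assembly-order groups


def apply_groups(
    stoich: Mapping[str, int], groups: Sequence[Iterable[str]]
) -> StagedPlan:
    """Turn known subcomplex groups into a staged assembly plan.

    Each group is assembled to completion on its own; its best results are
    then frozen and combined with the remaining subunits.  Groups must be
    disjoint subsets of the stoichiometry.
    """
    stoich = dict(stoich)
    seen: set[str] = set()
    stages = []
    for g in groups:
        g = frozenset(g)
        if seen & g:
            raise ValueError("assembly groups overlap")
        unknown = g - stoich.keys()
        if unknown:
            raise ValueError(f"group subunits not in stoichiometry: {sorted(unknown)}")
        seen |= g
        stages.append({sid: stoich[sid] for sid in sorted(g)})
    remaining = {sid: n for sid, n in sorted(stoich.items()) if sid not in seen}
    return StagedPlan(group_stages=tuple(stages), remaining=remaining, full=stoich)


def chain_links_from_catalog(catalog) -> list[tuple[str, str, int]]:
    """Derive sequence-connectivity links from a subunit catalog: subunits
    sharing a parent chain are linked in start-residue order, with the
    predecessor's ``linker_to_next`` as the linker length."""
    by_parent: dict[str, list] = {}
    for sub in catalog:
        if sub.parent_chain is not None:
            by_parent.setdefault(sub.parent_chain, []).append(sub)
    links = []
    for parent in sorted(by_parent):
        segs = sorted(by_parent[parent], key=lambda s: s.start_res)
        for pred, succ in zip(segs, segs[1:]):
            links.append((pred.subunit_id, succ.subunit_id, pred.linker_to_next))
    return links


def load_crosslinks(path: str | Path, copy_counts: Mapping[str, int] | None = None) -> list[Restraint]:
    """Read a crosslink table (CSV/TSV: subunit_a, res_a, subunit_b, res_b,
    max_dist) into restraints; separator is sniffed from the header line."""
    path = Path(path)
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep)
    required = ["subunit_a", "res_a", "subunit_b", "res_b", "max_dist"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"crosslink table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        ambiguous = False
        if copy_counts is not None:
            ambiguous = (
                copy_counts.get(row.subunit_a, 1) > 1
                or copy_counts.get(row.subunit_b, 1) > 1
            )
        out.append(
            Restraint(
                subunit_a=str(row.subunit_a),
                res_a=int(row.res_a),
                subunit_b=str(row.subunit_b),
                res_b=int(row.res_b),
                max_dist=float(row.max_dist),
                ambiguous=ambiguous,
            )
        )
    return out
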