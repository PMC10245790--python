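"""Representative subunit structures and scored pairwise transformations.

Every predicted multimer model places its subunits in its own arbitrary
frame.  To make the assembly stage tractable, a single *representative*
structure is chosen per subunit (highest mean plDDT over all models) and
every observed interface is converted into a rigid transform between
representatives:

* ``T1`` superposes representative A' onto the model's copy of A, ``T2``
  superposes B' onto B, both over confidently modelled residues only
  (plDDT > 80, or the best-half fallback).
* The stored transform is ``T1⁻¹ ∘ T2``: with A' at the identity, it places
  B' so that the pair reproduces the model's relative pose.  This anchor
  convention (A' fixed at identity) is used everywhere.

Each transform is scored from the model's predicted aligned error:
``score = max(1, 100 − P²/4)`` where P is the mean PAE over the two
inter-subunit blocks.  The quadratic shape makes small differences at low
PAE meaningful while flattening the hopeless high-PAE regime; scores live
in [1, 100].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .model_io import (
    ModelInstance,
    PAEMatrix,
    PredictedModel,
    RigidTransform,
    SubunitStructure,
)

__all__ = [
    "PairwiseTransformation",
    "TransformationLibrary",
    "mean_plddt",
    "select_representative",
    "detect_interactions",
    "alignment_subset",
    "superpose",
    "score_transformation",
    "extract_pair_transformation",
    "build_library",
]

#: CA-CA distance (Å) below which two subunits count as interacting (strict <).
INTERACTION_CUTOFF = 8.0
#: plDDT above which a residue joins the alignment subset outright.
ALIGNMENT_PLDDT = 80.0
#: Default duplicate-transform tolerances (rotation angle, translation).
DEDUP_ROT_DEG = 5.0
DEDUP_TRANS = 1.0


@dataclass(frozen=True)
class PairwiseTransformation:
    """A scored rigid transform placing ``to_subunit``'s representative
    relative to ``from_subunit``'s representative held at the identity."""

    transform_id: str
    from_subunit: str
    to_subunit: str
    transform: RigidTransform
    score: float
    source_model: str
    avg_pae: float

    def __post_init__(self) -> None:
        expected = score_transformation(self.avg_pae)
        if abs(self.score - expected) > 1e-9:
            raise ValueError("score inconsistent with avg_pae")

    def inverted(self) -> "PairwiseTransformation":
        return replace(
            self,
            from_subunit=self.to_subunit,
            to_subunit=self.from_subunit,
            transform=self.transform.inverse(),
        )


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class TransformationLibrary:
    """All pairwise transforms, keyed by unordered subunit-type pair.

    Copies of a subunit share one representative and one transform list per
    type pair: a transform between types (X, Y) may be applied between any
    copy of X and any copy of Y.
    """

    representatives: dict[str, SubunitStructure]
    by_pair: dict[tuple[str, str], list[PairwiseTransformation]] = field(
        default_factory=dict
    )

    def add(self, t: PairwiseTransformation) -> None:
        self.by_pair.setdefault(_pair_key(t.from_subunit, t.to_subunit), []).append(t)

    def transforms(self, a: str, b: str) -> list[PairwiseTransformation]:
        return self.by_pair.get(_pair_key(a, b), [])

    def directed(self, from_id: str, to_id: str) -> list[tuple[str, RigidTransform, float]]:
        """Transforms placing ``to_id``'s representative relative to a fixed
        copy of ``from_id``, as (transform_id, transform, score).

        Heterotypic entries stored in the opposite direction are inverted on
        the fly (same id and score: one interface, two anchors).  Homotypic
        entries are returned as stored — both extraction directions of a
        homodimer interface enter the library separately.
        """
        out = []
        for t in self.transforms(from_id, to_id):
            if t.from_subunit == from_id and t.to_subunit == to_id:
                out.append((t.transform_id, t.transform, t.score))
            elif t.from_subunit == to_id and t.to_subunit == from_id and from_id != to_id:
                out.append((t.transform_id, t.transform.inverse(), t.score))
        return out

    @property
    def n_transforms(self) -> int:
        return sum(len(v) for v in self.by_pair.values())


def mean_plddt(structure: SubunitStructure) -> float:
    """Arithmetic mean of per-residue plDDT."""
    if structure.n_residues == 0:
        raise ValueError("structure has no residues")
    return float(structure.plddt.mean())


def select_representative(
    candidates: Sequence[tuple[str, str, SubunitStructure]],
) -> SubunitStructure:
    """Pick the candidate with maximal mean plDDT.

    ``candidates`` are (model_id, copy_label, structure); ties are broken by
    (model_id, copy_label) lexicographic order for determinism.
    """
    if not candidates:
        raise ValueError("no candidate structures to choose from")
    best = min(candidates, key=lambda c: (-mean_plddt(c[2]), c[0], c[1]))
    return best[2]


def detect_interactions(
    model: PredictedModel, cutoff: float = INTERACTION_CUTOFF
) -> list[tuple[int, int]]:
    """Instance index pairs with any CA-CA distance strictly below cutoff."""
    pairs = []
    cas = [inst.structure.ca_coords for inst in model.instances]
    for i, j in combinations(range(len(model.instances)), 2):
        if cdist(cas[i], cas[j]).min() < cutoff:
            pairs.append((i, j))
    return pairs


def alignment_subset(structure: SubunitStructure) -> np.ndarray:
    """0-based indices of residues used for superposition.

    Residues with plDDT > 80; if fewer than half the residues qualify, the
    best half (ceil(n/2), ties by residue order) is used instead, so that a
    disordered region folded differently in each model cannot dominate the
    alignment.
    """
    n = structure.n_residues
    if n < 2:
        raise ValueError("need at least 2 residues")
    high = np.nonzero(structure.plddt > ALIGNMENT_PLDDT)[0]
    half = math.ceil(n / 2)
    if high.size >= half:
        return high
    order = np.argsort(-structure.plddt, kind="stable")
    return np.sort(order[:half])


def superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of *mobile* onto *target* (Kabsch).

    Returns the proper rigid transform T with T(mobile) ≈ target and the
    residual RMSD.  Degenerate point sets (fewer than three points, or all
    collinear) are rejected; reflection solutions cannot occur (the rotation
    is constrained to det = +1).
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if mobile.shape != target.shape:
        raise ValueError("point sets must have equal shapes")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    a = mobile - cm
    sv = np.linalg.svd(a, compute_uv=False)
    if sv[1] < 1e-8 * max(1.0, sv[0]):
        raise ValueError("degenerate (collinear) point set")
    return _lsq_fit(mobile, target)


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Raw Kabsch fit: (rotation, translation, rmsd), no validation.

    Internal fast path; det = +1 is enforced by flipping the smallest
    singular direction, so reflections never leak out.
    """
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    a = mobile - cm
    b = target - ct
    u, s, vt = np.linalg.svd(a.T @ b)
    d = 1.0 if np.linalg.det(vt.T @ u.T) >= 0 else -1.0
    rot = (vt.T * np.array([1.0, 1.0, d])) @ u.T
    e = float((a * a).sum() + (b * b).sum() - 2.0 * (s[0] + s[1] + d * s[2]))
    rmsd = math.sqrt(max(e, 0.0) / mobile.shape[0])
    return rot, ct - rot @ cm, rmsd


def _kabsch_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    return _kabsch(mobile, target)[2]


def _lsq_fit(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Superposition without degeneracy checks (internal, RMSD-only uses)."""
    rot, trans, rmsd = _kabsch(mobile, target)
    return RigidTransform(rot, trans), rmsd


def score_transformation(avg_pae: float) -> float:
    """PAE-based transform confidence: ``max(1, 100 − P²/4)``, in [1, 100]."""
    if avg_pae < 0:
        raise ValueError("average PAE must be non-negative")
    return max(1.0, 100.0 - avg_pae**2 / 4.0)


def average_interface_pae(
    pae: PAEMatrix, i: int, j: int, mode: str = "full_average"
) -> float:
    """Mean PAE over the two inter-subunit blocks (rows i × cols j and
    rows j × cols i); intra-subunit blocks are excluded.

    ``mode``: ``full_average`` (default, the variant that performed best),
    ``min`` (minimum inter-block entry) — kept as a config switch.
    """
    block_ij = pae.inter_block(i, j)
    block_ji = pae.inter_block(j, i)
    if mode == "full_average":
        return float((block_ij.sum() + block_ji.sum()) / (block_ij.size + block_ji.size))
    if mode == "min":
        return float(min(block_ij.min(), block_ji.min()))
    raise ValueError(f"unknown PAE aggregation mode {mode!r}")


def extract_pair_transformation(
    model: PredictedModel,
    pair: tuple[int, int],
    representatives: Mapping[str, SubunitStructure],
    pae_mode: str = "full_average",
) -> PairwiseTransformation | None:
    """Extract the scored transform for one interacting instance pair.

    Returns None (with a warning) when either alignment subset has fewer
    than three residues, which makes the superposition ill-defined.
    """
    i, j = pair
    inst_a, inst_b = model.instances[i], model.instances[j]
    rep_a = representatives[inst_a.subunit_id]
    rep_b = representatives[inst_b.subunit_id]
    sub_a = alignment_subset(inst_a.structure)
    sub_b = alignment_subset(inst_b.structure)
    if sub_a.size < 3 or sub_b.size < 3:
        warnings.warn(
            f"{model.model_id}: alignment subset below 3 residues for pair "
            f"({inst_a.copy_label}, {inst_b.copy_label}); skipped"
        )
        return None
    t1, _ = superpose(rep_a.ca_coords[sub_a], inst_a.structure.ca_coords[sub_a])
    t2, _ = superpose(rep_b.ca_coords[sub_b], inst_b.structure.ca_coords[sub_b])
    transform = t1.inverse().compose(t2)
    if model.pae is None:
        raise ValueError(f"model {model.model_id} has no PAE matrix attached")
    avg_pae = average_interface_pae(model.pae, i, j, mode=pae_mode)
    return PairwiseTransformation(
        transform_id=f"{model.model_id}/{inst_a.copy_label}-{inst_b.copy_label}",
        from_subunit=inst_a.subunit_id,
        to_subunit=inst_b.subunit_id,
        transform=transform,
        score=score_transformation(avg_pae),
        source_model=model.model_id,
        avg_pae=avg_pae,
    )


def _dedup(
    transforms: list[PairwiseTransformation],
    rot_tol: float = DEDUP_ROT_DEG,
    trans_tol: float = DEDUP_TRANS,
) -> list[PairwiseTransformation]:
    """Greedy duplicate removal, keeping the higher score.

    Two transforms of the same direction are duplicates when they differ by
    less than ``rot_tol`` degrees of rotation and ``trans_tol`` Å of
    translation.  Without this, homomeric libraries explode combinatorially.
    """
    ordered = sorted(transforms, key=lambda t: (-t.score, t.transform_id))
    kept: list[PairwiseTransformation] = []
    for t in ordered:
        duplicate = False
        for k in kept:
            if (t.from_subunit, t.to_subunit) != (k.from_subunit, k.to_subunit):
                continue
            if (
                t.transform.rotation_angle_to(k.transform) < rot_tol
                and t.transform.translation_distance_to(k.transform) < trans_tol
            ):
                duplicate = True
                break
        if not duplicate:
            kept.append(t)
    return kept


def save_library(library: TransformationLibrary, path) -> None:
    """Persist a library: representatives as single-chain PDB references
    (plDDT in B-factor), transforms as 12 reals plus score and provenance."""
    import json
    from pathlib import Path

    from .model_io import write_instances

    path = Path(path)
    rep_dir = path.parent / f"{path.stem}_representatives"
    rep_dir.mkdir(parents=True, exist_ok=True)
    reps = {}
    for sid, rep in sorted(library.representatives.items()):
        fname = f"{sid}.pdb"
        write_instances([ModelInstance(sid, "A", rep)], rep_dir / fname)
        reps[sid] = {"file": f"{rep_dir.name}/{fname}", "sequence": rep.sequence}
    payload = {
        "representatives": reps,
        "transforms": [
            {
                "id": t.transform_id,
                "from": t.from_subunit,
                "to": t.to_subunit,
                "rotation": np.round(t.transform.rotation, 9).reshape(9).tolist(),
                "translation": np.round(t.transform.translation, 6).tolist(),
                "score": t.score,
                "avg_pae": t.avg_pae,
                "source_model": t.source_model,
            }
            for key in sorted(library.by_pair)
            for t in library.by_pair[key]
        ],
    }
    path.write_text(json.dumps(payload, indent=1))


def load_library(path) -> TransformationLibrary:
    """Load a library written by :func:`save_library`."""
    import json
    from pathlib import Path

    from .model_io import read_model

    path = Path(path)
    raw = json.loads(path.read_text())

    class _Entry:
        def __init__(self, sid, seq):
            self.subunit_id = sid
            self.sequence = seq
            self.chain_names = ()

    reps = {}
    for sid, info in raw["representatives"].items():
        catalog = [_Entry(sid, info["sequence"])]
        model = read_model(path.parent / info["file"], catalog, model_id=sid)
        reps[sid] = model.instances[0].structure
    lib = TransformationLibrary(representatives=reps)
    for t in raw["transforms"]:
        lib.add(
            PairwiseTransformation(
                transform_id=t["id"],
                from_subunit=t["from"],
                to_subunit=t["to"],
                transform=RigidTransform(
                    np.array(t["rotation"]).reshape(3, 3),
                    np.array(t["translation"]),
                ),
                score=score_transformation(t["avg_pae"]),
                source_model=t["source_model"],
                avg_pae=t["avg_pae"],
            )
        )
    for key in lib.by_pair:
        lib.by_pair[key].sort(key=lambda t: (-t.score, t.transform_id))
    return lib


def build_library(
    models: Sequence[PredictedModel],
    interaction_cutoff: float = INTERACTION_CUTOFF,
    pae_mode: str = "full_average",
    dedup_rot_deg: float = DEDUP_ROT_DEG,
    dedup_trans: float = DEDUP_TRANS,
) -> TransformationLibrary:
    """Build the full transformation library from all predicted models.

    Representatives are chosen first (max mean plDDT across all models) and
    used for every extraction.  All interacting pairs of all models are
    processed; homotypic pairs are extracted in both directions (identical
    chains can form asymmetric interfaces).  Per-pair lists are deduplicated
    and sorted by score descending.
    """
    if not models:
        raise ValueError("no models provided")
    candidates: dict[str, list[tuple[str, str, SubunitStructure]]] = {}
    for model in models:
        for inst in model.instances:
            candidates.setdefault(inst.subunit_id, []).append(
                (model.model_id, inst.copy_label, inst.structure)
            )
    representatives = {
        sid: select_representative(cands) for sid, cands in sorted(candidates.items())
    }
    lib = TransformationLibrary(representatives=representatives)
    raw: dict[tuple[str, str], list[PairwiseTransformation]] = {}
    for model in models:
        for i, j in detect_interactions(model, cutoff=interaction_cutoff):
            directions = [(i, j)]
            if model.instances[i].subunit_id == model.instances[j].subunit_id:
                directions.append((j, i))
            for a, b in directions:
                t = extract_pair_transformation(
                    model, (a, b), representatives, pae_mode=pae_mode
                )
                if t is not None:
                    raw.setdefault(
                        _pair_key(t.from_subunit, t.to_subunit), []
                    ).append(t)
    for key, transforms in sorted(raw.items()):
        deduped = _dedup(transforms, rot_tol=dedup_rot_deg, trans_tol=dedup_trans)
        lib.by_pair[key] = sorted(deduped, key=lambda t: (-t.score, t.transform_id))
    return lib
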