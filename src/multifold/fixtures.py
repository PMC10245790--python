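"""Synthetic complexes and noisy "predicted" models for end-to-end testing.

The generator builds rigid toy subunits (idealized helical or globular
backbone traces), places copies into clash-free ground-truth architectures
(rings, chains, custom placements), and derives per-interface pair models
the way a structure predictor would produce them: the true relative pose
perturbed by a random rotation/translation, with synthetic PAE whose
magnitude grows with the injected perturbation and synthetic plDDT marking
confident cores and disordered tails.  Noise acts on the relative pose, not
per atom, so the assembler's rigid-body assumptions hold exactly;
``atom_jitter`` adds optional per-atom noise for robustness tests.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assembler import AssemblyParams
from .constraints import ClashChecker
from .job_planner import SubunitDefinition, save_catalog
from .model_io import (
    ModelInstance,
    PAEMatrix,
    PredictedModel,
    RigidTransform,
    SubunitStructure,
    write_instances,
)
from .transform_library import detect_interactions

__all__ = [
    "NoiseSpec",
    "GroundTruth",
    "make_subunit",
    "make_ground_truth",
    "make_ring",
    "make_chain",
    "make_pair_models",
    "make_crosslinks",
    "write_fixture_dir",
]

#: Maximum value of a (synthetic) PAE entry, matching predictor output.
PAE_MAX = 31.75
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class NoiseSpec:
    """How far synthetic pair models deviate from the truth.

    ``rot_sigma``/``trans_sigma`` perturb the relative pose (half-normal
    rotation angle in degrees, normal translation in Å).  Inter-subunit PAE
    blocks are ``pae_base + pae_per_deg × angle`` (plus ``pae_jitter``
    noise, clipped to [0, 31.75]); intra blocks stay small.  plDDT is
    ``plddt_core`` on confident residues and ``plddt_tail`` on tails.
    """

    rot_sigma: float = 0.0
    trans_sigma: float = 0.0
    pae_base: float = 2.0
    pae_per_deg: float = 1.0
    pae_jitter: float = 0.25
    plddt_core: float = 90.0
    plddt_tail: float = 50.0
    decoy_pae: float = 28.0
    atom_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rot_sigma < 0 or self.trans_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if not 0 <= self.plddt_core <= 100 or not 0 <= self.plddt_tail <= 100:
            raise ValueError("plDDT levels must lie in [0, 100]")


@dataclass
class GroundTruth:
    """A reference complex with known placements and adjacency."""

    subunits: dict[str, SubunitStructure]  # canonical (representative) frames
    instances: tuple[ModelInstance, ...]  # placed copies
    placements: tuple[RigidTransform, ...]
    adjacency: tuple[tuple[int, int], ...]

    @property
    def stoichiometry(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for inst in self.instances:
            out[inst.subunit_id] = out.get(inst.subunit_id, 0) + 1
        return out

    @property
    def total_residues(self) -> int:
        return sum(inst.structure.n_residues for inst in self.instances)


# ---------------------------------------------------------------------------
# subunits


def _backbone_from_ca(ca: np.ndarray) -> np.ndarray:
    """Idealized N/CA/C/O positions around a CA trace (plausible local
    geometry; only relative magnitudes matter downstream)."""
    n = ca.shape[0]
    coords = np.full((n, 4, 3), np.nan)
    coords[:, 1] = ca
    for i in range(n):
        prev_ca = ca[max(i - 1, 0)]
        next_ca = ca[min(i + 1, n - 1)]
        t = next_ca - prev_ca
        t /= max(np.linalg.norm(t), 1e-9)
        curv = prev_ca + next_ca - 2 * ca[i]
        curv = curv - np.dot(curv, t) * t
        norm = np.linalg.norm(curv)
        if norm < 1e-6:  # straight stretch: pick any perpendicular
            ref = np.array([0.0, 0.0, 1.0])
            if abs(np.dot(ref, t)) > 0.9:
                ref = np.array([1.0, 0.0, 0.0])
            curv = ref - np.dot(ref, t) * t
            norm = np.linalg.norm(curv)
        u = curv / norm
        b = np.cross(t, u)
        coords[i, 0] = ca[i] - 1.17 * t + 0.87 * u  # N
        coords[i, 2] = ca[i] + 1.22 * t + 0.91 * u  # C
        coords[i, 3] = coords[i, 2] + 1.23 * b  # O
    return coords


def make_subunit(
    n_res: int,
    shape: str = "helix",
    seed: int = 0,
    subunit_id: str | None = None,
    plddt_core: float = 90.0,
    tail_len: int = 0,
    plddt_tail: float = 50.0,
) -> SubunitStructure:
    """A rigid toy subunit: helical or compact random-walk backbone trace.

    Consecutive CA distances are ~3.8 Å; the last ``tail_len`` residues get
    ``plddt_tail`` (a synthetic disordered tail), the rest ``plddt_core``.
    """
    if n_res < 10:
        raise ValueError("subunits need at least 10 residues")
    rng = np.random.default_rng(seed)
    if shape == "helix":
        radius, rise, dphi = 2.3, 1.5, math.radians(100.0)
        idx = np.arange(n_res)
        ca = np.stack(
            [
                radius * np.cos(dphi * idx),
                radius * np.sin(dphi * idx),
                rise * idx,
            ],
            axis=1,
        )
    elif shape == "globule":
        step = 3.8
        pts = [np.zeros(3)]
        direction = np.array([1.0, 0.0, 0.0])
        for _ in range(n_res - 1):
            turn = rng.normal(0, 0.6, 3)
            center_pull = -0.08 * pts[-1] / max(np.linalg.norm(pts[-1]), 1.0)
            direction = direction + turn + center_pull
            direction /= np.linalg.norm(direction)
            pts.append(pts[-1] + step * direction)
        ca = np.array(pts)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    ca = ca - ca.mean(axis=0)
    plddt = np.full(n_res, float(plddt_core))
    if tail_len:
        plddt[-tail_len:] = plddt_tail
    sequence = "".join(rng.choice(list(AA_LETTERS), size=n_res))
    return SubunitStructure(
        subunit_id=subunit_id or f"su{seed}",
        sequence=sequence,
        coords=_backbone_from_ca(ca),
        plddt=plddt,
    )


# ---------------------------------------------------------------------------
# ground truth architectures


def _rot_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _min_ca_distance(a: SubunitStructure, b: SubunitStructure) -> float:
    from scipy.spatial.distance import cdist

    return float(cdist(a.ca_coords, b.ca_coords).min())


#: Packing margin (Å) added to the tightest clash-free fixture geometry,
#: so the ground truth never sits on the clash-filter boundary and pose
#: noise cannot flip legitimate merges into rejections.
PACKING_MARGIN = 1.0

# strict construction criterion: not a single clashing atom
_STRICT_CLASH = AssemblyParams(clash_fraction=1e-9)


def _finalize_ground_truth(
    subunits: dict[str, SubunitStructure],
    placed: list[tuple[str, str, RigidTransform]],
    interaction_cutoff: float = 8.0,
    params: AssemblyParams | None = None,
) -> GroundTruth:
    """Validate clash-freedom and derive adjacency from the geometry."""
    params = params or AssemblyParams()
    checker = ClashChecker(subunits, params)
    instances = tuple(
        ModelInstance(sid, label, subunits[sid].transformed(place))
        for sid, label, place in placed
    )
    for i in range(len(placed)):
        for j in range(i + 1, len(placed)):
            if not checker.pair_keep(
                placed[i][0], placed[i][2], placed[j][0], placed[j][2]
            ):
                raise ValueError(
                    f"requested architecture self-clashes: instances "
                    f"{placed[i][1]} and {placed[j][1]}"
                )
    pseudo = PredictedModel(model_id="ground_truth", instances=instances)
    adjacency = tuple(detect_interactions(pseudo, cutoff=interaction_cutoff))
    return GroundTruth(
        subunits=subunits,
        instances=instances,
        placements=tuple(place for _, _, place in placed),
        adjacency=adjacency,
    )


def make_ring(
    subunit: SubunitStructure,
    n_copies: int,
    allow_dimer: bool = False,
) -> GroundTruth:
    """A Cn ring of one subunit: copies on a circle about the z axis.

    The ring radius is the smallest (0.25 Å grid) at which the clash filter
    passes for all copy pairs; adjacent copies must still interact
    (CA-CA < 8 Å) there, or the subunit is too small/large for a ring of
    this order and an error is raised.
    """
    if n_copies < 2 or (n_copies == 2 and not allow_dimer):
        raise ValueError("a ring needs at least 3 copies (or allow_dimer=True)")
    subunits = {subunit.subunit_id: subunit}
    step = 2 * math.pi / n_copies

    def ring_at(radius):
        placed = []
        for k in range(n_copies):
            base = RigidTransform(np.eye(3), np.array([radius, 0.0, 0.0]))
            place = RigidTransform(_rot_z(step * k), np.zeros(3)).compose(base)
            placed.append((subunit.subunit_id, f"c{k}", place))
        return placed

    for radius in np.arange(2.0, 120.0, 0.25):
        # tightest radius without a single clashing atom, plus a packing
        # margin so the ground truth sits clear of the filter boundary
        try:
            _finalize_ground_truth(subunits, ring_at(radius), params=_STRICT_CLASH)
        except ValueError:
            continue
        gt = _finalize_ground_truth(subunits, ring_at(radius + PACKING_MARGIN))
        adj_set = set(gt.adjacency)
        if all(
            ((k, (k + 1) % n_copies) in adj_set or ((k + 1) % n_copies, k) in adj_set)
            for k in range(n_copies if n_copies > 2 else 1)
        ):
            return gt
        raise ValueError(
            "no ring radius is both clash-free and in contact for this subunit"
        )
    raise ValueError("could not find a clash-free ring radius")


def make_chain(subunits: Sequence[SubunitStructure]) -> GroundTruth:
    """A linear A-B-C-... arrangement along x with adjacent contacts only."""
    if len(subunits) < 2:
        raise ValueError("a chain needs at least 2 subunits")
    catalog = {s.subunit_id: s for s in subunits}
    if len(catalog) != len(subunits):
        raise ValueError("chain subunits must be distinct types")
    placed: list[tuple[str, str, RigidTransform]] = [
        (subunits[0].subunit_id, "c0", RigidTransform.identity())
    ]
    placed_structs = [subunits[0]]
    x = 0.0
    for prev, cur in zip(subunits, subunits[1:]):
        for offset in np.arange(2.0, 120.0, 0.25):
            # tightest offset without a single clashing atom + margin
            probe = cur.transformed(
                RigidTransform(np.eye(3), np.array([x + offset, 0.0, 0.0]))
            )
            checker = ClashChecker({"a": placed_structs[-1], "b": probe}, _STRICT_CLASH)
            ident = RigidTransform.identity()
            if not checker.pair_keep("a", ident, "b", ident):
                continue
            place = RigidTransform(
                np.eye(3), np.array([x + offset + PACKING_MARGIN, 0.0, 0.0])
            )
            moved = cur.transformed(place)
            # contact with the predecessor, clear separation from the rest
            if _min_ca_distance(placed_structs[-1], moved) >= 8.0:
                raise ValueError(
                    f"could not place {cur.subunit_id} in contact with "
                    f"{prev.subunit_id} without clashes"
                )
            if any(
                _min_ca_distance(earlier, moved) < 9.0
                for earlier in placed_structs[:-1]
            ):
                continue
            placed.append((cur.subunit_id, "c0", place))
            placed_structs.append(moved)
            x += offset + PACKING_MARGIN
            break
        else:
            raise ValueError(
                f"could not place {cur.subunit_id} in contact with {prev.subunit_id}"
            )
    return _finalize_ground_truth(catalog, placed)


def make_ground_truth(
    architecture: str | Sequence[RigidTransform],
    subunits: SubunitStructure | Sequence[SubunitStructure],
) -> GroundTruth:
    """Dispatch on an architecture spec: ``"ring:N"``, ``"chain"``, or an
    explicit list of placements (one per subunit, custom mode)."""
    if isinstance(architecture, str):
        if architecture.startswith("ring:"):
            n = int(architecture.split(":", 1)[1])
            sub = subunits if isinstance(subunits, SubunitStructure) else subunits[0]
            return make_ring(sub, n)
        if architecture == "chain":
            return make_chain(list(subunits))
        raise ValueError(f"unknown architecture {architecture!r}")
    placements = list(architecture)
    subs = list(subunits)
    if len(placements) != len(subs):
        raise ValueError("need one placement per subunit")
    catalog: dict[str, SubunitStructure] = {}
    placed = []
    counts: dict[str, int] = {}
    for sub, place in zip(subs, placements):
        catalog.setdefault(sub.subunit_id, sub)
        k = counts.get(sub.subunit_id, 0)
        counts[sub.subunit_id] = k + 1
        placed.append((sub.subunit_id, f"c{k}", place))
    return _finalize_ground_truth(catalog, placed)


# ---------------------------------------------------------------------------
# noisy pair models


def _random_rotation(rng: np.random.Generator, angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(math.radians(angle_deg) * axis).as_matrix()


def _perturbation(
    rng: np.random.Generator, noise: NoiseSpec, about: np.ndarray
) -> tuple[RigidTransform, float]:
    """A small rigid motion about a pivot, plus the rotation angle drawn."""
    angle = abs(rng.normal(0.0, noise.rot_sigma)) if noise.rot_sigma > 0 else 0.0
    shift = (
        rng.normal(0.0, noise.trans_sigma, 3) if noise.trans_sigma > 0 else np.zeros(3)
    )
    rot = _random_rotation(rng, angle) if angle > 0 else np.eye(3)
    # rotate about the pivot, then translate
    trans = about - rot @ about + shift
    return RigidTransform(rot, trans), angle


def _noisy_plddt(base: SubunitStructure, noise: NoiseSpec) -> np.ndarray:
    tail = base.plddt < 80.0
    return np.where(tail, noise.plddt_tail, noise.plddt_core)


def _pae_blocks(
    rng: np.random.Generator,
    n_a: int,
    n_b: int,
    inter_level: float,
    jitter: float,
) -> np.ndarray:
    """Asymmetric PAE: independent noise per direction; small intra blocks."""
    pae = np.zeros((n_a + n_b, n_a + n_b))
    intra_level = min(2.0, inter_level)
    for sl in (slice(0, n_a), slice(n_a, n_a + n_b)):
        block = np.full((sl.stop - sl.start, sl.stop - sl.start), intra_level)
        if jitter > 0:
            block = block + np.abs(rng.normal(0, jitter, block.shape))
        pae[sl, sl] = block
    for rows, cols in ((slice(0, n_a), slice(n_a, n_a + n_b)), (slice(n_a, n_a + n_b), slice(0, n_a))):
        block = np.full((rows.stop - rows.start, cols.stop - cols.start), inter_level)
        if jitter > 0:
            block = block + rng.normal(0, jitter, block.shape)
        pae[rows, cols] = block
    return np.clip(pae, 0.0, PAE_MAX)


def _jittered(structure: SubunitStructure, rng: np.random.Generator, sigma: float) -> SubunitStructure:
    if sigma <= 0:
        return structure
    coords = structure.coords + rng.normal(0, sigma, structure.coords.shape)
    return SubunitStructure(
        subunit_id=structure.subunit_id,
        sequence=structure.sequence,
        coords=coords,
        plddt=structure.plddt,
        residue_ids=structure.residue_ids,
    )


def make_pair_models(
    ground_truth: GroundTruth,
    noise: NoiseSpec | None = None,
    include_decoys: bool = True,
) -> list[PredictedModel]:
    """Synthetic predictor output: one model per adjacent instance pair.

    The second subunit's pose is the true pose perturbed per the noise
    spec; inter-subunit PAE grows linearly with the drawn rotation angle,
    so PAE magnitude correlates with pose error by construction.
    Non-adjacent pairs optionally get decoy models: a touching but wrong
    pose with near-maximal PAE, emulating a predictor's low-confidence
    guesses.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    models: list[PredictedModel] = []

    def build_model(i: int, j: int, inter_level: float, perturb: bool) -> PredictedModel:
        u, v = ground_truth.instances[i], ground_truth.instances[j]
        rep_v = ground_truth.subunits[v.subunit_id]
        place_u = ground_truth.placements[i]
        place_v = ground_truth.placements[j]
        angle = 0.0
        if perturb:
            pivot = place_v.apply(rep_v.centroid())
            d, angle = _perturbation(rng, noise, pivot)
            place_v = d.compose(place_v)
        struct_u = SubunitStructure(
            subunit_id=u.subunit_id,
            sequence=u.structure.sequence,
            coords=u.structure.coords,
            plddt=_noisy_plddt(ground_truth.subunits[u.subunit_id], noise),
        )
        struct_v_raw = rep_v.transformed(place_v)
        struct_v = SubunitStructure(
            subunit_id=v.subunit_id,
            sequence=struct_v_raw.sequence,
            coords=struct_v_raw.coords,
            plddt=_noisy_plddt(rep_v, noise),
        )
        struct_u = _jittered(struct_u, rng, noise.atom_jitter)
        struct_v = _jittered(struct_v, rng, noise.atom_jitter)
        level = np.clip(inter_level + noise.pae_per_deg * angle, 0.0, PAE_MAX)
        n_u, n_v = struct_u.n_residues, struct_v.n_residues
        pae = PAEMatrix(
            values=_pae_blocks(rng, n_u, n_v, float(level), noise.pae_jitter),
            offsets=(0, n_u),
            sizes=(n_u, n_v),
        )
        model_id = f"pair_{u.subunit_id}.{u.copy_label}_{v.subunit_id}.{v.copy_label}"
        return PredictedModel(
            model_id=model_id,
            instances=(
                ModelInstance(u.subunit_id, "A", struct_u),
                ModelInstance(v.subunit_id, "B", struct_v),
            ),
            pae=pae,
            source="fixture",
        )

    seen_pairs: set[tuple[int, int]] = set()
    for i, j in ground_truth.adjacency:
        models.append(build_model(i, j, noise.pae_base, perturb=True))
        seen_pairs.add((i, j))
    if include_decoys:
        n = len(ground_truth.instances)
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in seen_pairs:
                    continue
                models.append(_decoy_model(ground_truth, i, j, noise, rng))
    return models


def _decoy_model(
    gt: GroundTruth, i: int, j: int, noise: NoiseSpec, rng: np.random.Generator
) -> PredictedModel:
    """A touching but wrong pose for a non-adjacent pair, at high PAE."""
    u, v = gt.instances[i], gt.instances[j]
    rep_u = gt.subunits[u.subunit_id]
    rep_v = gt.subunits[v.subunit_id]
    struct_u = SubunitStructure(
        subunit_id=u.subunit_id,
        sequence=rep_u.sequence,
        coords=rep_u.coords,
        plddt=_noisy_plddt(rep_u, noise),
    )
    direction = np.array([1.0, 0.0, 0.0])
    start = float(
        np.linalg.norm(rep_u.ca_coords - rep_u.centroid(), axis=1).max()
        + np.linalg.norm(rep_v.ca_coords - rep_v.centroid(), axis=1).max()
        + 10.0
    )
    for sep in np.arange(start, 2.0, -0.5):
        shift = rep_u.centroid() + sep * direction - rep_v.centroid()
        moved = rep_v.transformed(RigidTransform(np.eye(3), shift))
        if _min_ca_distance(struct_u, moved) < 7.0:
            break
    struct_v = SubunitStructure(
        subunit_id=v.subunit_id,
        sequence=moved.sequence,
        coords=moved.coords,
        plddt=_noisy_plddt(rep_v, noise),
    )
    n_u, n_v = struct_u.n_residues, struct_v.n_residues
    pae = PAEMatrix(
        values=_pae_blocks(rng, n_u, n_v, noise.decoy_pae, noise.pae_jitter),
        offsets=(0, n_u),
        sizes=(n_u, n_v),
    )
    return PredictedModel(
        model_id=f"decoy_{u.subunit_id}.{u.copy_label}_{v.subunit_id}.{v.copy_label}",
        instances=(
            ModelInstance(u.subunit_id, "A", struct_u),
            ModelInstance(v.subunit_id, "B", struct_v),
        ),
        pae=pae,
        source="fixture-decoy",
    )


# ---------------------------------------------------------------------------
# crosslinks


def make_crosslinks(
    ground_truth: GroundTruth,
    n: int,
    max_dist: float = 25.0,
    frac_decoy: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a synthetic crosslink restraint table from the ground truth.

    ``n − ceil(frac_decoy·n)`` restraints come from residue pairs truly
    within ``max_dist`` (CA-CA, over the best copy pairing, as the filter
    evaluates them); the rest are decoys beyond it.  The default 25 Å bound
    emulates a DSS-like crosslinker.
    """
    if n < 1:
        raise ValueError("need n >= 1 restraints")
    rng = np.random.default_rng(seed)
    n_decoy = math.ceil(frac_decoy * n)
    n_true = n - n_decoy
    instances = ground_truth.instances

    def min_pair_distance(sid_a: str, res_a: int, sid_b: str, res_b: int) -> float:
        best = np.inf
        for ia in instances:
            if ia.subunit_id != sid_a:
                continue
            for ib in instances:
                if ib.subunit_id != sid_b:
                    continue
                if ia is ib and sid_a == sid_b and res_a == res_b:
                    continue
                d = float(
                    np.linalg.norm(
                        ia.structure.ca_coords[res_a - 1]
                        - ib.structure.ca_coords[res_b - 1]
                    )
                )
                best = min(best, d)
        return best

    rows = []
    counts = ground_truth.stoichiometry
    budget = 20000 * n
    want = [(True, n_true), (False, n_decoy)]
    for is_true, quota in want:
        made = 0
        while made < quota and budget > 0:
            budget -= 1
            ia, ib = rng.choice(len(instances), size=2, replace=False)
            a, b = instances[int(ia)], instances[int(ib)]
            res_a = int(rng.integers(1, a.structure.n_residues + 1))
            res_b = int(rng.integers(1, b.structure.n_residues + 1))
            d = min_pair_distance(a.subunit_id, res_a, b.subunit_id, res_b)
            if is_true and d <= max_dist or (not is_true and d > max_dist):
                rows.append(
                    {
                        "subunit_a": a.subunit_id,
                        "res_a": res_a,
                        "subunit_b": b.subunit_id,
                        "res_b": res_b,
                        "max_dist": max_dist,
                        "decoy": not is_true,
                        "ambiguous": counts[a.subunit_id] > 1
                        or counts[b.subunit_id] > 1,
                    }
                )
                made += 1
        if made < quota:
            raise ValueError(
                "could not sample the requested restraints from this geometry"
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk fixture sets


def write_fixture_dir(
    ground_truth: GroundTruth,
    models: Sequence[PredictedModel],
    out_dir: str | Path,
    crosslinks: pd.DataFrame | None = None,
) -> Path:
    """Write a complete fixture set: catalog JSON, ground-truth structure,
    per-model PDB + PAE JSON, and an optional crosslink CSV."""
    out = Path(out_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    counts = ground_truth.stoichiometry
    catalog = [
        SubunitDefinition(
            subunit_id=sid,
            sequence=ground_truth.subunits[sid].sequence,
            copy_count=counts[sid],
        )
        for sid in sorted(ground_truth.subunits)
    ]
    save_catalog(catalog, out / "catalog.json")
    dialect = "pdb" if len(ground_truth.instances) <= 62 else "mmcif"
    suffix = "pdb" if dialect == "pdb" else "cif"
    write_instances(
        ground_truth.instances, out / f"ground_truth.{suffix}", dialect=dialect
    )
    for model in models:
        write_instances(model.instances, out / "models" / f"{model.model_id}.pdb")
        payload = {"predicted_aligned_error": np.round(model.pae.values, 2).tolist()}
        (out / "models" / f"{model.model_id}_pae.json").write_text(
            json.dumps(payload)
        )
    if crosslinks is not None:
        crosslinks.drop(columns=["decoy", "ambiguous"], errors="ignore").to_csv(
            out / "crosslinks.csv", index=False
        )
    return out
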