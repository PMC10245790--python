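"""Accuracy and diagnosability metrics.

* A backbone-only DockQ score for pairwise subunit poses (native-contact
  fraction plus interface and ligand RMSD terms; the 0.23 gate marks an
  acceptable pose).  Full-atom DockQ uses side chains; this package carries
  only backbone atoms, which is adequate here because the score gates a
  graph edge rather than serving as a benchmark number.
* Pairwise connectivity: the residue-weighted fraction of a reference
  complex covered by the largest connected component of the graph whose
  edges are acceptably accurate library transforms.  A ratio of 1.0 means
  the library can in principle assemble the whole complex; multiple
  components mean it cannot.
* Copy-aware comparison of an assembled model against a reference complex.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .assembler import Subcomplex, _copy_aware_alignment
from .model_io import ModelInstance, RigidTransform, SubunitStructure
from .transform_library import TransformationLibrary, _lsq_fit

__all__ = [
    "DockQUndefinedError",
    "ConnectivityReport",
    "dockq",
    "pairwise_connectivity",
    "compare_assembly",
]

#: DockQ constants from its publication: contact cutoff (Å), interface
#: neighbourhood (Å), and the two RMSD scaling lengths.
CONTACT_CUTOFF = 5.0
INTERFACE_CUTOFF = 10.0
IRMS_SCALE = 1.5
LRMS_SCALE = 8.5
ACCEPTABLE_DOCKQ = 0.23


class DockQUndefinedError(ValueError):
    """Raised when the reference pair has no interface contacts."""


@dataclass
class ConnectivityReport:
    """Connectivity of the transform-coverage graph over a reference."""

    nodes: tuple[tuple[str, str], ...]  # (subunit_id, copy_label)
    edges: tuple[tuple[int, int], ...]
    component_sizes: tuple[int, ...]  # residues per component, descending
    ratio: float


def _backbone(structure: SubunitStructure) -> tuple[np.ndarray, np.ndarray]:
    """Finite backbone atoms as (coords (m,3), residue index per atom)."""
    n = structure.n_residues
    flat = structure.coords.reshape(-1, 3)
    res_of_atom = np.repeat(np.arange(n), 4)
    finite = np.isfinite(flat).all(axis=1)
    return flat[finite], res_of_atom[finite]


def _pair_dockq(
    model: tuple[SubunitStructure, SubunitStructure],
    reference: tuple[SubunitStructure, SubunitStructure],
) -> float:
    ref_a, ref_b = reference
    mod_a, mod_b = model
    if (mod_a.n_residues, mod_b.n_residues) != (ref_a.n_residues, ref_b.n_residues):
        raise ValueError("model and reference subunits must have mapped residues")
    ra_xyz, ra_res = _backbone(ref_a)
    rb_xyz, rb_res = _backbone(ref_b)
    d_ref = cdist(ra_xyz, rb_xyz)

    # Fnat: residue-level contacts (any backbone atom pair < 5 Å)
    contact_mask = d_ref < CONTACT_CUTOFF
    ref_contacts = {
        (int(ra_res[i]), int(rb_res[j])) for i, j in zip(*np.nonzero(contact_mask))
    }
    if not ref_contacts:
        raise DockQUndefinedError("reference pair has no interface contacts")
    ma_xyz, ma_res = _backbone(mod_a)
    mb_xyz, mb_res = _backbone(mod_b)
    d_mod = cdist(ma_xyz, mb_xyz)
    mod_contacts = {
        (int(ma_res[i]), int(mb_res[j]))
        for i, j in zip(*np.nonzero(d_mod < CONTACT_CUTOFF))
    }
    fnat = len(ref_contacts & mod_contacts) / len(ref_contacts)

    # iRMS: backbone RMSD over interface residues after interface superposition
    near = d_ref < INTERFACE_CUTOFF
    int_res_a = np.unique(ra_res[near.any(axis=1)])
    int_res_b = np.unique(rb_res[near.any(axis=0)])
    mask_a = np.isin(ra_res, int_res_a)
    mask_b = np.isin(rb_res, int_res_b)
    ref_iface = np.concatenate([ra_xyz[mask_a], rb_xyz[mask_b]])
    mod_iface = np.concatenate([ma_xyz[np.isin(ma_res, int_res_a)], mb_xyz[np.isin(mb_res, int_res_b)]])
    _, irms = _lsq_fit(mod_iface, ref_iface)

    # LRMS: superpose on the larger subunit, RMSD over the smaller
    if ref_a.n_residues >= ref_b.n_residues:
        rec_ref, rec_mod, lig_ref, lig_mod = ra_xyz, ma_xyz, rb_xyz, mb_xyz
    else:
        rec_ref, rec_mod, lig_ref, lig_mod = rb_xyz, mb_xyz, ra_xyz, ma_xyz
    fit, _ = _lsq_fit(rec_mod, rec_ref)
    moved = fit.apply(lig_mod)
    lrms = float(np.sqrt(((moved - lig_ref) ** 2).sum(axis=1).mean()))

    return (
        fnat
        + 1.0 / (1.0 + (irms / IRMS_SCALE) ** 2)
        + 1.0 / (1.0 + (lrms / LRMS_SCALE) ** 2)
    ) / 3.0


def dockq(
    model_pair: tuple[SubunitStructure, SubunitStructure],
    reference_pair: tuple[SubunitStructure, SubunitStructure],
) -> float:
    """Backbone DockQ of a model pair against a reference pair, in [0, 1].

    When the two subunits are copies of the same type, both copy
    correspondences are scored and the better one returned.
    """
    score = _pair_dockq(model_pair, reference_pair)
    mod_a, mod_b = model_pair
    if mod_a.subunit_id == mod_b.subunit_id:
        score = max(score, _pair_dockq((mod_b, mod_a), reference_pair))
    return score


def pairwise_connectivity(
    library: TransformationLibrary,
    reference: Sequence[ModelInstance],
    acceptance: float = ACCEPTABLE_DOCKQ,
) -> ConnectivityReport:
    """Transform-coverage graph of a reference complex.

    Nodes are the reference's subunit instances.  An edge joins (u, v) when
    some library transform between their types, applied to the
    representatives, reproduces the reference pair with DockQ above the
    acceptance gate.  Each transform is anchored at both ordered instance
    pairs and the best DockQ taken, since library transforms are type-level
    while reference instances are copies.
    """
    reps = library.representatives
    g = nx.Graph()
    weights = []
    for idx, inst in enumerate(reference):
        g.add_node(idx)
        weights.append(inst.structure.n_residues)
    for i, j in combinations(range(len(reference)), 2):
        u, v = reference[i], reference[j]
        ref_pair = (u.structure, v.structure)
        best = 0.0
        for anchor, mobile, flip in (
            (u.subunit_id, v.subunit_id, False),
            (v.subunit_id, u.subunit_id, True),
        ):
            for _, x, _ in library.directed(anchor, mobile):
                placed = reps[mobile].transformed(x)
                pair = (placed, reps[anchor]) if flip else (reps[anchor], placed)
                try:
                    best = max(best, dockq(pair, ref_pair))
                except DockQUndefinedError:
                    continue
                if best > acceptance:
                    break
            if best > acceptance:
                break
        if best > acceptance:
            g.add_edge(i, j)
    comps = sorted(
        (sum(weights[n] for n in comp) for comp in nx.connected_components(g)),
        reverse=True,
    )
    total = sum(weights)
    return ConnectivityReport(
        nodes=tuple((inst.subunit_id, inst.copy_label) for inst in reference),
        edges=tuple(sorted(g.edges)),
        component_sizes=tuple(comps),
        ratio=comps[0] / total,
    )


def compare_assembly(
    model: Subcomplex,
    reference: Sequence[ModelInstance],
    representatives: Mapping[str, SubunitStructure],
) -> tuple[float, dict[tuple[str, int], tuple[str, str]]]:
    """Copy-aware CA RMSD of an assembled model against a reference.

    Returns (RMSD, mapping) where the mapping sends each model instance to
    the (subunit_id, copy_label) of the reference instance it matched.
    """
    model_comp = tuple(sorted(sid for sid, _ in model.instances))
    ref_sorted = sorted(range(len(reference)), key=lambda k: (reference[k].subunit_id, reference[k].copy_label))
    ref_comp = tuple(reference[k].subunit_id for k in ref_sorted)
    if model_comp != ref_comp:
        raise ValueError(
            f"composition mismatch: model {model_comp} vs reference {ref_comp}"
        )
    types = [sid for sid, _ in model.instances]
    cas_a = [
        representatives[i[0]].transformed(model.placements[i]).ca_coords
        for i in model.instances
    ]
    cas_b = [reference[k].structure.ca_coords for k in ref_sorted]
    rmsd, mapping = _copy_aware_alignment(types, cas_a, cas_b)
    assignment = {
        model.instances[i]: (
            reference[ref_sorted[mapping[i]]].subunit_id,
            reference[ref_sorted[mapping[i]]].copy_label,
        )
        for i in range(len(types))
    }
    return rmsd, assignment
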