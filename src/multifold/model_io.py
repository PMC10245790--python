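"""Structure and confidence I/O plus the core geometric data types.

Conventions used throughout the package:

* Rigid transforms act on column vectors, ``x' = R x + t``; the global frame
  is the frame of the representative subunit structures.
* Residues are renumbered 1-based and contiguous within each subunit,
  whatever the author numbering in the source file (the original numbering
  is kept as metadata).
* Per-residue plDDT (0-100) is carried in the B-factor column, following the
  convention of structure predictors; an optional JSON side-channel is
  supported for files whose B-factors hold something else.
* Only backbone atoms (N, CA, C, O) participate in any algorithm; side
  chains, ligands and altlocs are not modelled.
"""

from __future__ import annotations

import json
import math
import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "BACKBONE_ATOMS",
    "CA_INDEX",
    "RigidTransform",
    "SubunitStructure",
    "ModelInstance",
    "PAEMatrix",
    "PredictedModel",
    "read_model",
    "read_pae",
    "write_assembly",
    "write_instances",
]

#: Backbone atom names in storage order; index 1 is the alpha carbon.
BACKBONE_ATOMS = ("N", "CA", "C", "O")
CA_INDEX = 1

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}

# 62 one-character chain IDs usable in the PDB dialect.
_PDB_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body motion ``x' = R x + t`` (rotation + translation, Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    _TOL = 1e-6

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        trans = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-5):
            raise ValueError("rotation matrix is not orthonormal")
        if abs(float(np.linalg.det(rot)) - 1.0) > 1e-5:
            raise ValueError("rotation matrix must have determinant +1 (no reflection)")
        rot.setflags(write=False)
        trans.setflags(write=False)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", trans)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @classmethod
    def _unsafe(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        """Skip validation: internal hot paths composing already-valid
        transforms (closed under composition/inversion)."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "rotation", rotation)
        object.__setattr__(obj, "translation", translation)
        return obj

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of coordinates."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply *other* first, then *self*."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    __matmul__ = compose

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        cos = (float(np.trace(self.rotation)) - 1.0) / 2.0
        return math.degrees(math.acos(min(1.0, max(-1.0, cos))))

    def rotation_angle_to(self, other: "RigidTransform") -> float:
        return self.inverse().compose(other).rotation_angle_deg()

    def translation_distance_to(self, other: "RigidTransform") -> float:
        return float(np.linalg.norm(self.translation - other.translation))

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-6) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=tol)
            and np.allclose(self.translation, other.translation, atol=tol)
        )


@dataclass(frozen=True)
class SubunitStructure:
    """Backbone trace of one subunit instance with per-residue confidence.

    ``coords`` has shape ``(n_residues, 4, 3)`` with atoms ordered N, CA, C, O;
    missing N/C/O entries are NaN (a missing CA is an error).
    """

    subunit_id: str
    sequence: str
    coords: np.ndarray
    plddt: np.ndarray
    residue_ids: np.ndarray | None = None
    author_numbering: tuple | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (4, 3):
            raise ValueError("coords must have shape (n, 4, 3)")
        n = coords.shape[0]
        plddt = np.asarray(self.plddt, dtype=float).reshape(n)
        if np.any(plddt < 0) or np.any(plddt > 100):
            raise ValueError("plDDT values must lie in [0, 100]")
        if self.residue_ids is None:
            rid = np.arange(1, n + 1)
        else:
            rid = np.asarray(self.residue_ids, dtype=int).reshape(n)
            if np.any(np.diff(rid) <= 0):
                raise ValueError("residue indices must be strictly increasing")
        missing_ca = np.nonzero(~np.isfinite(coords[:, CA_INDEX]).all(axis=1))[0]
        if missing_ca.size:
            raise ValueError(
                f"residues without CA atom in {self.subunit_id!r}: "
                f"{[int(rid[i]) for i in missing_ca]}"
            )
        if len(self.sequence) != n:
            raise ValueError("sequence length must equal residue count")
        coords.setflags(write=False)
        plddt.setflags(write=False)
        rid.setflags(write=False)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "plddt", plddt)
        object.__setattr__(self, "residue_ids", rid)

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def ca_coords(self) -> np.ndarray:
        return self.coords[:, CA_INDEX, :]

    def backbone_coords(self, residue_mask: np.ndarray | None = None) -> np.ndarray:
        """Finite backbone atom coordinates, flattened to (m, 3)."""
        coords = self.coords if residue_mask is None else self.coords[residue_mask]
        flat = coords.reshape(-1, 3)
        return flat[np.isfinite(flat).all(axis=1)]

    def centroid(self) -> np.ndarray:
        return self.ca_coords.mean(axis=0)

    def transformed(self, transform: RigidTransform) -> "SubunitStructure":
        coords = self.coords.copy()
        finite = np.isfinite(coords).all(axis=2)
        coords[finite] = transform.apply(coords[finite])
        return SubunitStructure(
            subunit_id=self.subunit_id,
            sequence=self.sequence,
            coords=coords,
            plddt=self.plddt,
            residue_ids=self.residue_ids,
            author_numbering=self.author_numbering,
        )


@dataclass(frozen=True)
class ModelInstance:
    """One placed copy of a subunit inside a predicted model (or a reference)."""

    subunit_id: str
    copy_label: str
    structure: SubunitStructure


@dataclass
class PAEMatrix:
    """Predicted aligned error, Å; square over all residues of one model.

    ``pae[i, j]`` estimates the error of residue j when the model is aligned
    on residue i — the matrix is asymmetric by construction and is stored
    unchanged.  ``offsets[k]`` is the first row/column of instance ``k``.
    """

    values: np.ndarray
    offsets: tuple[int, ...]
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("PAE matrix must be square")
        if np.any(values < 0):
            raise ValueError("PAE values must be non-negative")
        self.values = values
        total = sum(self.sizes)
        if total != values.shape[0]:
            raise ValueError(
                f"PAE size {values.shape[0]} does not match residue count {total}"
            )

    def row_index(self, instance_index: int, residue_index: int) -> int:
        """Matrix row for (instance, 1-based residue index)."""
        if not 1 <= residue_index <= self.sizes[instance_index]:
            raise IndexError("residue index out of range")
        return self.offsets[instance_index] + residue_index - 1

    def inter_block(self, i: int, j: int) -> np.ndarray:
        """Rows of instance i against columns of instance j."""
        si, sj = self.offsets[i], self.offsets[j]
        return self.values[si : si + self.sizes[i], sj : sj + self.sizes[j]]


@dataclass
class PredictedModel:
    """One multimer prediction: placed subunit instances plus confidence."""

    model_id: str
    instances: tuple[ModelInstance, ...]
    pae: PAEMatrix | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.instances = tuple(self.instances)
        if self.pae is not None:
            counts = tuple(inst.structure.n_residues for inst in self.instances)
            if counts != self.pae.sizes:
                raise ValueError("PAE block sizes do not match instance residue counts")

    @property
    def total_residues(self) -> int:
        return sum(inst.structure.n_residues for inst in self.instances)


# ---------------------------------------------------------------------------
# readers


def _chain_to_arrays(chain: gemmi.Chain):
    """Extract sequence, backbone coords, plDDT and author numbering."""
    seq: list[str] = []
    coords: list[np.ndarray] = []
    plddt: list[float] = []
    author: list[int] = []
    missing_ca: list[int] = []
    for res in chain:
        if gemmi.find_tabulated_residue(res.name) is not None and not gemmi.find_tabulated_residue(res.name).is_amino_acid():
            continue
        row = np.full((4, 3), np.nan)
        b = None
        for atom in res:
            if atom.name in BACKBONE_ATOMS:
                k = BACKBONE_ATOMS.index(atom.name)
                row[k] = (atom.pos.x, atom.pos.y, atom.pos.z)
                if atom.name == "CA":
                    b = atom.b_iso
        if b is None:
            missing_ca.append(res.seqid.num)
            continue
        seq.append(_one_letter(res.name))
        coords.append(row)
        plddt.append(float(b))
        author.append(res.seqid.num)
    if missing_ca:
        raise ValueError(
            f"chain {chain.name!r}: residues missing CA atom: {missing_ca}"
        )
    return "".join(seq), np.array(coords).reshape(-1, 4, 3), np.array(plddt), tuple(author)


def _match_subunit(chain_name: str, chain_seq: str, catalog) -> str:
    """Map a chain to a catalog subunit by chain ID, then by sequence."""
    for sub in catalog:
        if chain_name in tuple(getattr(sub, "chain_names", ()) or ()):
            return sub.subunit_id
    for sub in catalog:
        if chain_seq == sub.sequence:
            return sub.subunit_id
    for sub in catalog:
        if chain_seq in sub.sequence or sub.sequence in chain_seq:
            return sub.subunit_id
    raise ValueError(
        f"chain {chain_name!r} (length {len(chain_seq)}) matches no catalog subunit"
    )


def read_model(
    path: str | Path,
    subunit_catalog,
    model_id: str | None = None,
    plddt_json: str | Path | None = None,
) -> PredictedModel:
    """Read a PDB/mmCIF multimer prediction and map its chains to subunits.

    Chains are mapped to catalog entries by chain ID first, then by exact
    sequence (sub)match.  plDDT comes from the CA B-factor unless
    ``plddt_json`` (a ``{chain: [per-residue values]}`` file) is given.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    side_plddt: Mapping[str, Sequence[float]] = {}
    if plddt_json is not None:
        side_plddt = json.loads(Path(plddt_json).read_text())
    instances = []
    for chain in st[0]:
        seq, coords, plddt, author = _chain_to_arrays(chain)
        if not seq:
            continue
        sid = _match_subunit(chain.name, seq, subunit_catalog)
        if chain.name in side_plddt:
            plddt = np.asarray(side_plddt[chain.name], dtype=float)
        plddt = np.clip(plddt, 0.0, 100.0)
        instances.append(
            ModelInstance(
                subunit_id=sid,
                copy_label=chain.name,
                structure=SubunitStructure(
                    subunit_id=sid,
                    sequence=seq,
                    coords=coords,
                    plddt=plddt,
                    author_numbering=author,
                ),
            )
        )
    if not instances:
        raise ValueError(f"no protein chains found in {path}")
    return PredictedModel(
        model_id=model_id or path.stem,
        instances=tuple(instances),
        source=str(path),
    )


def read_pae(path: str | Path, model: PredictedModel) -> PAEMatrix:
    """Read a ColabFold-style PAE JSON and align it to the model's residues.

    Keys tried in order: ``predicted_aligned_error``, ``pae``.  The matrix is
    stored as-is; no symmetrization is applied.
    """
    raw = json.loads(Path(path).read_text())
    if isinstance(raw, list):  # AFDB style: a one-element list of dicts
        raw = raw[0]
    arr = None
    for key in ("predicted_aligned_error", "pae"):
        if key in raw:
            arr = np.asarray(raw[key], dtype=float)
            break
    if arr is None:
        raise ValueError(f"{path}: no 'predicted_aligned_error' or 'pae' key")
    n = model.total_residues
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.shape[0] != n:
        raise ValueError(
            f"{path}: PAE matrix of size {arr.shape} does not match "
            f"model residue count {n}"
        )
    sizes = tuple(inst.structure.n_residues for inst in model.instances)
    offsets = tuple(np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(int).tolist())
    return PAEMatrix(values=arr, offsets=offsets, sizes=sizes)


def attach_pae(model: PredictedModel, path: str | Path) -> PredictedModel:
    """Return the model with the PAE at *path* attached."""
    model.pae = read_pae(path, model)
    return model


# ---------------------------------------------------------------------------
# writers


def _mmcif_chain_ids(n: int) -> list[str]:
    ids = list(_PDB_CHAIN_IDS)
    letters = string.ascii_uppercase
    while len(ids) < n:
        k = len(ids) - len(_PDB_CHAIN_IDS)
        ids.append(letters[k // 26] + letters[k % 26])
    return ids[:n]


def write_instances(
    instances: Sequence[ModelInstance],
    path: str | Path,
    dialect: str = "auto",
) -> Path:
    """Write placed instances as a PDB or mmCIF file, one chain each.

    Chains are labelled A, B, C, ... (then two-letter IDs, mmCIF only);
    plDDT goes to the B-factor column.  ``dialect`` is ``"pdb"``, ``"mmcif"``
    or ``"auto"`` (chosen from the file suffix).  Requesting the PDB dialect
    for more than 62 chains is an error.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if dialect == "pdb" and len(instances) > len(_PDB_CHAIN_IDS):
        raise ValueError(
            f"{len(instances)} chains exceed the 62-chain PDB limit; "
            "use the mmCIF dialect"
        )
    chain_ids = _mmcif_chain_ids(len(instances))
    st = gemmi.Structure()
    st.name = path.stem
    model = gemmi.Model("1")
    for cid, inst in zip(chain_ids, instances):
        chain = gemmi.Chain(cid)
        s = inst.structure
        for i in range(s.n_residues):
            res = gemmi.Residue()
            res.name = _AA3.get(s.sequence[i], "UNK")
            res.seqid = gemmi.SeqId(int(s.residue_ids[i]), " ")
            for k, aname in enumerate(BACKBONE_ATOMS):
                xyz = s.coords[i, k]
                if not np.isfinite(xyz).all():
                    continue
                atom = gemmi.Atom()
                atom.name = aname
                atom.pos = gemmi.Position(*xyz)
                atom.element = gemmi.Element(aname[0])
                atom.b_iso = float(s.plddt[i])
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if dialect == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
    return path


def write_assembly(
    subcomplex,
    representatives: Mapping[str, SubunitStructure],
    path: str | Path,
    dialect: str = "auto",
) -> Path:
    """Write an assembled subcomplex: each placed instance becomes a chain.

    Coordinates are the instance placement applied to the subunit's
    representative structure.
    """
    instances = []
    for inst in sorted(subcomplex.instances):
        sid, copy_idx = inst
        placed = representatives[sid].transformed(subcomplex.placements[inst])
        instances.append(
            ModelInstance(subunit_id=sid, copy_label=f"{sid}.{copy_idx}", structure=placed)
        )
    return write_instances(instances, path, dialect=dialect)
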