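"""Shared synthetic fixtures; session-scoped where construction is costly."""

from __future__ import annotations

import numpy as np
import pytest

from multifold import (
    NoiseSpec,
    build_library,
    make_chain,
    make_pair_models,
    make_ring,
    make_subunit,
)
from multifold.model_io import SubunitStructure


def line_structure(
    subunit_id: str,
    n_res: int = 20,
    spacing: float = 10.0,
    plddt: float = 90.0,
) -> SubunitStructure:
    """Residues on a straight line, backbone atoms collapsed near each CA.

    The wide spacing isolates residues so clash/contact counts are exact,
    which the threshold-straddling filter tests rely on.
    """
    coords = np.zeros((n_res, 4, 3))
    for i in range(n_res):
        base = np.array([i * spacing, 0.0, 0.0])
        coords[i, 0] = base + [-0.5, 0.0, 0.0]  # N
        coords[i, 1] = base  # CA
        coords[i, 2] = base + [0.5, 0.0, 0.0]  # C
        coords[i, 3] = base + [0.5, 0.6, 0.0]  # O
    return SubunitStructure(
        subunit_id=subunit_id,
        sequence="A" * n_res,
        coords=coords,
        plddt=np.full(n_res, plddt),
    )


@pytest.fixture(scope="session")
def chain3():
    """Hetero trimer chain ground truth (30-residue helices)."""
    subs = [make_subunit(30, seed=k, subunit_id=f"su{k}") for k in range(3)]
    return make_chain(subs)


@pytest.fixture(scope="session")
def chain3_library(chain3):
    """Exact (zero-noise) transform library for the trimer chain."""
    models = make_pair_models(
        chain3, NoiseSpec(pae_base=2.0, pae_jitter=0.0, seed=5), include_decoys=False
    )
    return build_library(models)


@pytest.fixture(scope="session")
def chain6():
    """Hetero hexamer chain ground truth."""
    subs = [make_subunit(30, seed=k, subunit_id=f"su{k}") for k in range(6)]
    return make_chain(subs)


@pytest.fixture(scope="session")
def chain6_library(chain6):
    models = make_pair_models(
        chain6, NoiseSpec(pae_base=2.0, pae_jitter=0.0, seed=5), include_decoys=False
    )
    return build_library(models)


@pytest.fixture(scope="session")
def ring8():
    """C8 homomeric ring ground truth (32-residue helix subunit)."""
    return make_ring(make_subunit(32, seed=7, subunit_id="su0"), 8)


@pytest.fixture(scope="session")
def ring8_library(ring8):
    models = make_pair_models(
        ring8, NoiseSpec(pae_base=2.0, pae_jitter=0.0, seed=11), include_decoys=False
    )
    return build_library(models)
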