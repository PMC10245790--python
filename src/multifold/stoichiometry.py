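"""Stoichiometry enumeration over a fixed transformation library.

The expensive predictor runs are done once; enumerating copy counts of one
subunit is then just repeated (fast, deterministic) assembly runs over the
same library.  Two signals identify the right stoichiometry: the predicted
confidence profile spikes at geometrically consistent copy counts, and
counts that cannot be assembled at all (every candidate clashes) are ruled
out outright.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .assembler import AssemblyParams, assemble
from .constraints import ConstraintSet
from .transform_library import TransformationLibrary

__all__ = ["scan", "MAX_SUBUNITS"]

#: Hard cap on total subunit copies per assembly run.
MAX_SUBUNITS = 64


def scan(
    library: TransformationLibrary,
    base_stoich: Mapping[str, int],
    variable_subunit: str,
    copy_range: range,
    params: AssemblyParams | None = None,
    constraints: ConstraintSet | None = None,
) -> pd.DataFrame:
    """Profile assemblability and confidence over copy counts.

    For each count in ``copy_range``, runs an independent assembly with the
    variable subunit at that count (all other counts fixed) and records
    whether a full-size complex survived filtering and the best final
    confidence.  Returns a DataFrame with columns ``copies``, ``assembled``,
    ``confidence``, ``achieved_size``, ``target_size``.
    """
    if variable_subunit not in library.representatives:
        raise ValueError(f"unknown subunit {variable_subunit!r}")
    rows = []
    for copies in copy_range:
        if not 1 <= copies <= MAX_SUBUNITS:
            raise ValueError(f"copy count {copies} outside [1, {MAX_SUBUNITS}]")
        stoich = dict(base_stoich)
        stoich[variable_subunit] = copies
        target_size = sum(stoich.values())
        results = assemble(library, stoich, params=params, constraints=constraints)
        achieved = results[0].size if results else 0
        assembled = achieved == target_size
        rows.append(
            {
                "copies": copies,
                "assembled": assembled,
                "confidence": results[0].score if assembled else float("nan"),
                "achieved_size": achieved,
                "target_size": target_size,
            }
        )
    return pd.DataFrame(rows)
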