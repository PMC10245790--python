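"""Subunit definitions and enumeration of prediction jobs.

A *subunit* is the atomic unit of assembly: a full chain or a user-defined
segment of one.  Chains too long for the predictor's length cap are divided
evenly into segments.  The planner then enumerates the predictor jobs whose
outputs feed the rest of the pipeline: all subunit pairs, plus a few larger
groups (3-5 subunits) per subunit built from its best-scoring partners, to
capture intertwined multi-subunit folds that no pair model can show.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SubunitDefinition",
    "PredictionJob",
    "divide_chain",
    "enumerate_pair_jobs",
    "select_group_jobs",
    "load_catalog",
    "save_catalog",
    "write_job_fasta",
]

#: Total sequence length (residues) a standard GPU prediction job can take.
DEFAULT_LENGTH_CAP = 1800


@dataclass(frozen=True)
class SubunitDefinition:
    """A named sequence segment with its copy count in the target complex.

    ``parent_chain``/``start_res``/``linker_to_next`` describe how segments
    of one chain tile it; ``linker_to_next`` counts unmodelled residues
    between this segment and its successor on the same chain and feeds the
    sequence-connectivity constraint during assembly.
    """

    subunit_id: str
    sequence: str
    copy_count: int = 1
    parent_chain: str | None = None
    start_res: int = 1
    linker_to_next: int = 0
    chain_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if self.copy_count < 1:
            raise ValueError("copy_count must be >= 1")
        if self.start_res < 1:
            raise ValueError("start_res is 1-based")
        if self.linker_to_next < 0:
            raise ValueError("linker_to_next must be >= 0")
        object.__setattr__(self, "chain_names", tuple(self.chain_names))

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PredictionJob:
    """A single predictor run over a multiset of subunits."""

    job_id: str
    members: tuple[str, ...]
    total_length: int
    over_cap: bool = False


def divide_chain(
    sequence: str,
    max_len: int,
    base_id: str = "seg",
    parent_chain: str | None = None,
    copy_count: int = 1,
) -> list[SubunitDefinition]:
    """Divide a chain evenly into the minimal number of segments <= max_len.

    Segment lengths differ by at most one residue; order is preserved and
    consecutive segments carry a zero-length linker (they are contiguous).
    """
    if max_len < 50:
        raise ValueError("max_len must be >= 50 residues")
    n = len(sequence)
    m = max(1, math.ceil(n / max_len))
    q, r = divmod(n, m)
    lengths = [q + 1] * r + [q] * (m - r)
    pieces = []
    start = 0
    for i, length in enumerate(lengths):
        pieces.append(
            SubunitDefinition(
                subunit_id=base_id if m == 1 else f"{base_id}_{i + 1}",
                sequence=sequence[start : start + length],
                copy_count=copy_count,
                parent_chain=parent_chain or base_id,
                start_res=start + 1,
                linker_to_next=0,
            )
        )
        start += length
    return pieces


def enumerate_pair_jobs(
    catalog: Sequence[SubunitDefinition],
    cap: int = DEFAULT_LENGTH_CAP,
) -> list[PredictionJob]:
    """All unordered pairs of distinct subunits, plus homodimers for copies.

    Jobs longer than the cap are emitted flagged rather than dropped, so the
    user can split subunits instead of silently losing an interaction.
    """
    subs = sorted(catalog, key=lambda s: s.subunit_id)
    jobs: list[PredictionJob] = []
    for i, a in enumerate(subs):
        if a.copy_count >= 2:
            total = 2 * a.length
            jobs.append(
                PredictionJob(
                    job_id=f"pair_{a.subunit_id}_{a.subunit_id}",
                    members=(a.subunit_id, a.subunit_id),
                    total_length=total,
                    over_cap=total > cap,
                )
            )
        for b in subs[i + 1 :]:
            total = a.length + b.length
            jobs.append(
                PredictionJob(
                    job_id=f"pair_{a.subunit_id}_{b.subunit_id}",
                    members=(a.subunit_id, b.subunit_id),
                    total_length=total,
                    over_cap=total > cap,
                )
            )
    jobs.sort(key=lambda j: j.job_id)
    return jobs


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def select_group_jobs(
    catalog: Sequence[SubunitDefinition],
    pair_scores: Mapping[tuple[str, str], float],
    cap: int = DEFAULT_LENGTH_CAP,
    groups_per_subunit: int = 3,
) -> list[PredictionJob]:
    """Greedy 3-5-subunit group jobs around each subunit's best partners.

    For each subunit, groups of sizes 3, 4 and 5 (up to ``groups_per_subunit``
    of them) are grown greedily: at each step add the partner with the best
    pair score against any current member (ties by subunit id), while the
    total length stays under the cap and copy counts are respected.
    Duplicate member multisets are removed globally.
    """
    by_id = {s.subunit_id: s for s in catalog}
    scores = {_pair_key(*k): float(v) for k, v in pair_scores.items()}
    sizes = (3, 4, 5)[:groups_per_subunit]
    seen: set[tuple[str, ...]] = set()
    jobs: list[PredictionJob] = []
    for seed in sorted(by_id):
        for size in sizes:
            members = [seed]
            total = by_id[seed].length
            while len(members) < size:
                counts = Counter(members)
                best: tuple[float, str] | None = None
                for cand in sorted(by_id):
                    if counts[cand] >= by_id[cand].copy_count:
                        continue
                    if total + by_id[cand].length > cap:
                        continue
                    cand_score = max(
                        (
                            scores[_pair_key(m, cand)]
                            for m in set(members)
                            if _pair_key(m, cand) in scores
                        ),
                        default=None,
                    )
                    if cand_score is None:
                        continue
                    if best is None or (-cand_score, cand) < best:
                        best = (-cand_score, cand)
                if best is None:
                    break
                members.append(best[1])
                total += by_id[best[1]].length
            if len(members) < size:
                continue
            key = tuple(sorted(members))
            if key in seen:
                continue
            seen.add(key)
            jobs.append(
                PredictionJob(
                    job_id="group_" + "_".join(key),
                    members=key,
                    total_length=total,
                    over_cap=False,
                )
            )
    jobs.sort(key=lambda j: j.job_id)
    return jobs


# ---------------------------------------------------------------------------
# catalog persistence

def load_catalog(path: str | Path) -> list[SubunitDefinition]:
    """Load a subunit catalog JSON: {"subunits": [{name, sequence, ...}]}."""
    raw = json.loads(Path(path).read_text())
    subs = []
    for entry in raw["subunits"]:
        subs.append(
            SubunitDefinition(
                subunit_id=entry["name"],
                sequence=entry["sequence"],
                copy_count=int(entry.get("copies", len(entry.get("chain_names", [])) or 1)),
                parent_chain=entry.get("parent_chain"),
                start_res=int(entry.get("start_res", 1)),
                linker_to_next=int(entry.get("linker_to_next", 0)),
                chain_names=tuple(entry.get("chain_names", ())),
            )
        )
    return subs


def save_catalog(catalog: Sequence[SubunitDefinition], path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "subunits": [
            {
                "name": s.subunit_id,
                "sequence": s.sequence,
                "copies": s.copy_count,
                "chain_names": list(s.chain_names),
                "start_res": s.start_res,
                "parent_chain": s.parent_chain,
                "linker_to_next": s.linker_to_next,
            }
            for s in catalog
        ]
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def write_job_fasta(
    job: PredictionJob,
    catalog: Sequence[SubunitDefinition],
    path: str | Path,
) -> Path:
    """Write one FASTA record per member copy of a prediction job."""
    by_id = {s.subunit_id: s for s in catalog}
    lines = []
    for i, member in enumerate(job.members):
        lines.append(f">{job.job_id}|{member}|{i + 1}")
        lines.append(by_id[member].sequence)
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)
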