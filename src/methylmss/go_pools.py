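"""GO-term subpools: partition of the differential pool with replacement.

A probe annotated with several GO terms belongs to each corresponding
subpool ("partition with replacement"); only terms reaching ``min_size``
pool members yield a subpool, since a 30-probe signature cannot be drawn
from fewer than 31 candidates with any redundancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .dm_analysis import ProbePool
from .synthetic_cohort import ProbeAnnotation

#: smallest subpool a 30-probe signature can meaningfully be drawn from
DEFAULT_MIN_SIZE = 31


@dataclass
class GOSubpool:
    go_term: str
    label: str
    probe_ids: list

    def __len__(self) -> int:
        return len(self.probe_ids)


def partition_subpools(
    pool: ProbePool,
    ann: ProbeAnnotation,
    min_size: int = DEFAULT_MIN_SIZE,
    labels: dict | None = None,
) -> list:
    """One subpool per GO term with >= min_size pool members.

    Subpools are ordered by GO accession; members keep the pool's order.
    Pool probes lacking any GO term are excluded with a warning; pool
    probes absent from the annotation are an error.
    """
    missing = [p for p in pool.probe_ids if p not in ann.table.index]
    if missing:
        raise KeyError(f"pool probes missing from annotation: {missing}")
    go_map = ann.go_map()
    uncovered = [p for p in pool.probe_ids if not go_map[p]]
    if uncovered:
        warnings.warn(f"{len(uncovered)} pool probes carry no GO term and are excluded: {uncovered[:10]}", stacklevel=2)
    index: dict = {}
    for pid in pool.probe_ids:
        for term in go_map[pid]:
            index.setdefault(term, []).append(pid)
    labels = labels or {}
    return [
        GOSubpool(go_term=term, label=labels.get(term, term), probe_ids=members)
        for term, members in sorted(index.items())
        if len(members) >= min_size
    ]
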