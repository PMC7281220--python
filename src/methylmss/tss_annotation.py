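"""Probe-to-TSS distances.

The transcription start site supplied per probe is an interval; its
midpoint represents the TSS location, and the probe's distance is the
absolute bp separation between probe position and that midpoint.
Coordinates are 1-based; distances are unsigned (strand ignored).
"""

from __future__ import annotations

import pandas as pd

from .mss_screen import Signature
from .synthetic_cohort import ProbeAnnotation


def tss_midpoint(tss_start: int, tss_end: int) -> int:
    """Midpoint of a TSS interval; half-base midpoints round down."""
    if tss_start > tss_end:
        raise ValueError(f"tss_start ({tss_start}) > tss_end ({tss_end})")
    return (int(tss_start) + int(tss_end)) // 2


def probe_tss_distance(row) -> int:
    """Absolute bp distance from a probe to its TSS midpoint.

    ``row`` is one annotation row (a mapping with position, tss_start,
    tss_end, and optionally tss_chromosome alongside chromosome).
    """
    if "tss_chromosome" in row and row["tss_chromosome"] != row["chromosome"]:
        raise ValueError(
            f"probe on {row['chromosome']} but TSS on {row['tss_chromosome']}; distance undefined"
        )
    return abs(int(row["position"]) - tss_midpoint(row["tss_start"], row["tss_end"]))


def tss_distance_report(ann: ProbeAnnotation, probe_ids=None) -> pd.DataFrame:
    """Per-probe TSS midpoints and distances (all probes by default)."""
    table = ann.table if probe_ids is None else ann.table.loc[list(probe_ids)]
    mids = [tss_midpoint(s, e) for s, e in zip(table["tss_start"], table["tss_end"])]
    dist = [abs(int(p) - m) for p, m in zip(table["position"], mids)]
    return pd.DataFrame({"tss_midpoint": mids, "distance": dist}, index=table.index)


def signature_mean_tss_distance(signature: Signature, ann: ProbeAnnotation) -> float:
    """Mean probe-to-TSS distance (bp) over exactly the signature's probes."""
    missing = [p for p in signature.probe_ids if p not in ann.table.index]
    if missing:
        raise KeyError(f"signature probes missing from annotation: {missing}")
    report = tss_distance_report(ann, signature.probe_ids)
    return float(report["distance"].mean())
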