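"""Normalization: beta/M conversion, 27k filtering, per-cohort z-scoring.

Methylation beta values (methylated fraction, in (0,1)) are mapped to
M values, M = log2(beta / (1 - beta)), the scale on which array noise is
approximately Gaussian.  Batch effects between cohorts are addressed by
z-scoring each probe within each cohort.  All downstream screening runs
on z-scored M values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_cohort import MethylationCohort, ProbeAnnotation


@dataclass
class NormalizedMatrix:
    """Probes x samples matrix of z-scored M values plus provenance."""

    values: pd.DataFrame
    provenance: list = field(default_factory=list)

    @property
    def probe_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)


def beta_to_m(beta):
    """M = log2(beta / (1 - beta)); strictly increasing bijection (0,1) -> R."""
    arr = np.asarray(beta, dtype=float)
    if arr.size and not ((arr > 0).all() and (arr < 1).all()):
        raise ValueError("beta values must lie strictly in (0, 1)")
    out = np.log2(arr / (1.0 - arr))
    return out if isinstance(beta, np.ndarray) or out.ndim else float(out)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`."""
    arr = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-arr))
    return out if isinstance(m, np.ndarray) or out.ndim else float(out)


def filter_to_27k(cohort: MethylationCohort, ann: ProbeAnnotation) -> MethylationCohort:
    """Restrict a cohort to the probes flagged as 27k-array members.

    Probe order is preserved; the sample axis is untouched even when no
    probe survives.  Probes absent from the annotation are an error.
    """
    missing = [p for p in cohort.beta.index if p not in ann.table.index]
    if missing:
        raise KeyError(f"probes missing from annotation: {missing[:10]}{'...' if len(missing) > 10 else ''}")
    keep = ann.table.loc[cohort.beta.index, "on_27k"].astype(bool).to_numpy()
    return MethylationCohort(beta=cohort.beta.loc[keep], samples=cohort.samples)


def zscore_by_cohort(matrix: pd.DataFrame, cohort_id) -> NormalizedMatrix:
    """Z-score each probe within each cohort (ddof=1).

    Rows constant within a cohort map to zeros there rather than NaN.
    Cohorts of a single sample are rejected: their standard deviation is
    undefined and silent NaN propagation would poison everything downstream.
    """
    cohort_id = pd.Series(cohort_id, index=matrix.columns) if not isinstance(cohort_id, pd.Series) else cohort_id
    cohort_id = cohort_id.loc[matrix.columns]
    out = np.empty(matrix.shape)
    values = matrix.to_numpy(dtype=float)
    for c in pd.unique(cohort_id):
        cols = (cohort_id == c).to_numpy()
        if cols.sum() < 2:
            raise ValueError(f"cohort {c!r} has fewer than 2 samples; sd is undefined")
        block = values[:, cols]
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        centred = block - mean
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, centred / sd, 0.0)
        out[:, cols] = z
    return NormalizedMatrix(
        values=pd.DataFrame(out, index=matrix.index, columns=matrix.columns),
        provenance=["zscore_by_cohort"],
    )


def normalize_cohort(cohort: MethylationCohort, ann: ProbeAnnotation | None = None, *, filter_27k: bool = True) -> NormalizedMatrix:
    """Full normalization: optional 27k filter, beta -> M, per-cohort z-score."""
    steps = []
    if filter_27k:
        if ann is None:
            raise ValueError("annotation required for the 27k filter")
        cohort = filter_to_27k(cohort, ann)
        steps.append("filter_to_27k")
    m = pd.DataFrame(beta_to_m(cohort.beta.to_numpy()), index=cohort.beta.index, columns=cohort.beta.columns)
    steps.append("beta_to_m")
    norm = zscore_by_cohort(m, cohort.cohort_id)
    norm.provenance = steps + norm.provenance
    return norm
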