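"""Probe-wise moderated-t differential methylation and pool selection.

The moderated t-statistic shrinks each probe's pooled two-sample variance
toward a prior estimated from all probes (empirical Bayes).  The prior
(d0, s0^2) is fitted by the method of moments on the log pooled variances:
with d residual degrees of freedom per probe, e_g = log s_g^2
- digamma(d/2) + log(d/2) has mean log s0^2 - digamma(d0/2) + log(d0/2)
and excess variance trigamma(d0/2) beyond trigamma(d/2), which pins down
d0 via the trigamma inverse.  The posterior variance is the precision-
weighted blend s~^2 = (d0 s0^2 + d s^2) / (d0 + d) and the moderated t is
referenced to a t distribution on d0 + d degrees of freedom.

"Fold change" for methylation is defined on the analysis scale as
fc = 2^|delta|, delta being the difference of class means, so the fc > 3
filter is direction-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix
from .synthetic_cohort import EC, GC


@dataclass
class ProbePool:
    """Ordered unique probes passing the differential-methylation filter."""

    probe_ids: list
    filter_params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.probe_ids)

    def __contains__(self, probe_id) -> bool:
        return probe_id in set(self.probe_ids)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple:
    """Moment fit of the scaled inverse-chi-square variance prior.

    Returns ``(d0, s0_sq)``; ``d0`` is ``inf`` when the observed spread of
    log variances does not exceed what df residual degrees of freedom
    already imply (all shrinkage, common variance).
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 0.0)
    if s2.size == 0:
        return np.inf, np.nan
    if s2.size == 1:
        return 0.0, float(s2[0])
    m = float(np.median(s2))
    if m == 0.0:
        warnings.warn("more than half of residual variances are exactly zero; moderation unreliable", stacklevel=2)
        m = 1.0
    s2 = np.maximum(s2, 1e-5 * m)  # offset exact zeros away from log(0)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(s2.mean())
    d0 = 2.0 * trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t(matrix, class_label, *, prior_df: float | None = None) -> pd.DataFrame:
    """Moderated two-sample t-test of GC vs. EC for every probe.

    Parameters
    ----------
    matrix
        ``NormalizedMatrix`` or probes x samples DataFrame (M-value scale).
    class_label
        Per-sample labels, ``EC`` or ``GC``, aligned with the columns.
    prior_df
        Force the prior degrees of freedom d0 instead of fitting them;
        ``prior_df=0`` recovers the ordinary pooled two-sample t-test.

    Returns a DataFrame indexed by probe_id with columns ``t_mod``,
    ``delta_m`` (mean GC - mean EC), ``fc`` (= 2^|delta_m|), ``p`` and
    ``fdr`` (Benjamini-Hochberg), with the fitted ``d0``/``s0_sq``/``df``
    stored in ``.attrs``.
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    labels = pd.Series(np.asarray(class_label, dtype=object), index=values.columns) if not isinstance(class_label, pd.Series) else class_label.loc[values.columns]
    unknown = set(labels) - {EC, GC}
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    gc_cols = (labels == GC).to_numpy()
    ec_cols = (labels == EC).to_numpy()
    n1, n2 = int(gc_cols.sum()), int(ec_cols.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both classes need >= 2 samples (GC={n1}, EC={n2})")

    x = values.to_numpy(dtype=float)
    g, e = x[:, gc_cols], x[:, ec_cols]
    delta = g.mean(axis=1) - e.mean(axis=1)
    df_resid = n1 + n2 - 2
    s2 = ((n1 - 1) * g.var(axis=1, ddof=1) + (n2 - 1) * e.var(axis=1, ddof=1)) / df_resid

    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        s0_sq = fit_variance_prior(s2, df_resid)[1] if d0 > 0 else 0.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mod = np.where(se > 0, delta / se, np.where(delta == 0, 0.0, np.sign(delta) * np.inf))
    df_total = d0 + df_resid
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    fdr = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame(
        {"t_mod": t_mod, "delta_m": delta, "fc": np.exp2(np.abs(delta)), "p": p, "fdr": fdr},
        index=values.index,
    )
    out.attrs.update({"d0": d0, "s0_sq": s0_sq, "df_resid": df_resid, "n_gc": n1, "n_ec": n2})
    return out


def _ordered(dm: pd.DataFrame, mask: np.ndarray) -> list:
    sub = dm.loc[mask]
    order = sub.sort_values(["fdr", "fc"], ascending=[True, False], kind="mergesort")
    # stable sort + index tie-break: ascending fdr, descending fc, then id
    order = order.loc[
        sorted(order.index, key=lambda pid: (order.at[pid, "fdr"], -order.at[pid, "fc"], pid))
    ]
    return list(order.index)


def select_pool(dm: pd.DataFrame, fdr_max: float = 1e-4, fc_min: float = 3.0) -> ProbePool:
    """Probes with fdr < fdr_max and fc > fc_min (strict inequalities).

    Ordered by ascending fdr, ties by descending fc then probe_id.  An
    empty pool is valid but flagged with a warning.
    """
    if fdr_max <= 0 or fc_min <= 0:
        raise ValueError("thresholds must be positive")
    if fdr_max > 1:
        raise ValueError("fdr_max must be <= 1")
    mask = ((dm["fdr"] < fdr_max) & (dm["fc"] > fc_min)).to_numpy()
    ids = _ordered(dm, mask)
    if not ids:
        warnings.warn("no probe passed the differential-methylation filter; pool is empty", stacklevel=2)
    return ProbePool(probe_ids=ids, filter_params={"fdr_max": fdr_max, "fc_min": fc_min})


def select_top_n(dm: pd.DataFrame, n: int) -> ProbePool:
    """Alternative pool rule: the n most significant probes by p-value."""
    if n <= 0:
        raise ValueError("n must be positive")
    order = sorted(dm.index, key=lambda pid: (dm.at[pid, "p"], -dm.at[pid, "fc"], pid))
    return ProbePool(probe_ids=order[:n], filter_params={"top_n": n})
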