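"""Seeded synthetic methylation cohorts.

Emulates the statistical structure of a two-class (esophageal vs. gastric
adenocarcinoma) methylation-array study: beta values in (0,1), a set of
"planted" probes carrying a true class effect, four gastric molecular
subtypes (EBV / MSI / GS / CIN) with subtype-specific nuisance shifts,
multiple cohorts with additive batch offsets, promoter-proximal probe
annotations with TSS coordinates, and overlapping GO-term memberships.

Generation happens on the M-value scale (Gaussian noise is natural there),
then maps back to beta through the logistic inverse of M = log2(b/(1-b)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EC = "EC"
GC = "GC"
GC_SUBTYPES = ("EBV", "MSI", "GS", "CIN")

ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "OpenSea")
REGULATORY_GROUPS = ("PromoterAssociated", "GeneAssociated", "GeneAssociatedCellSpecific", "Other")

# Category frequencies for differentially methylated probes on a promoter-
# centric array: islands dominate, and >80% of probes are promoter-associated.
_ISLAND_PROBS = {"Island": 0.550, "OpenSea": 0.184, "N_Shore": 0.115, "S_Shore": 0.097}
_REGULATORY_PROBS = {
    "PromoterAssociated": 0.813,
    "GeneAssociated": 0.0025,
    "GeneAssociatedCellSpecific": 0.0055,
    "Other": 0.179,
}

#: Default GO vocabulary: process-centric terms typical of tumor methylation
#: signature studies.  The first two are the "signal" terms into which
#: planted probes are concentrated by default.
DEFAULT_GO_TERMS = {
    "GO:0005515": "protein binding",
    "GO:0010467": "gene expression",
    "GO:0071840": "cellular component organization or biogenesis",
    "GO:0044237": "cellular metabolic process",
    "GO:0007049": "cell cycle",
    "GO:0000278": "mitotic cell cycle",
    "GO:0033554": "cellular response to stress",
    "GO:0006974": "cellular response to DNA damage stimulus",
    "GO:0016567": "protein ubiquitination",
    "GO:0019900": "kinase binding",
    "GO:0015630": "microtubule cytoskeleton",
    "GO:2001233": "regulation of apoptotic signaling pathway",
}

_BETA_CLIP = 1e-6


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-class methylation cohort.

    Beta-scale parameters (``effect_size``, ``subtype_shift``) are expressed
    as methylation-fraction shifts; noise and batch parameters are standard
    deviations on the M-value (log2-odds) scale.
    """

    n_ec: int = 200
    n_gc_per_subtype: int = 50
    n_probes: int = 2000
    n_planted: int = 50
    effect_size: float = 0.3
    subtype_shift: float = 0.1
    n_cohorts: int = 3
    batch_sd: float = 0.4
    noise_sd: float = 0.35
    frac_27k: float = 0.85
    seed: int = 0
    #: fraction of planted probes hypermethylated in GC (the rest are
    #: hypomethylated); 1.0 keeps the planted class-mean beta difference
    #: equal to +effect_size.
    planted_frac_hyper: float = 1.0
    #: fraction of probes carrying a nuisance shift for each gastric subtype
    subtype_marker_frac: float = 0.05
    #: GO accession -> label; planted probes are concentrated into signal_terms
    go_terms: dict = field(default_factory=lambda: dict(DEFAULT_GO_TERMS))
    signal_terms: tuple = ("GO:0005515", "GO:0010467")
    #: probability that a planted probe is annotated with each signal term
    signal_enrichment: float = 0.9

    def validate(self) -> None:
        for name in ("n_ec", "n_gc_per_subtype", "n_probes", "n_planted", "n_cohorts"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if not 0.0 <= self.effect_size < 1.0:
            raise ValueError(f"effect_size must be in [0, 1), got {self.effect_size!r}")
        if not 0.0 <= self.subtype_shift < 0.5:
            raise ValueError(f"subtype_shift must be in [0, 0.5), got {self.subtype_shift!r}")
        for name in ("batch_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)!r}")
        for name in ("frac_27k", "planted_frac_hyper", "subtype_marker_frac", "signal_enrichment"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.n_planted > self.n_probes:
            raise ValueError(f"n_planted ({self.n_planted}) exceeds n_probes ({self.n_probes})")
        unknown = [t for t in self.signal_terms if t not in self.go_terms]
        if unknown:
            raise ValueError(f"signal_terms not in go_terms: {unknown}")


@dataclass
class MethylationCohort:
    """Beta-value matrix (probes x samples) with per-sample metadata.

    ``samples`` is indexed by sample_id with columns ``class_label``
    (EC or GC), ``gc_subtype`` (one of EBV/MSI/GS/CIN for GC, missing for
    EC) and ``cohort_id``.
    """

    beta: pd.DataFrame
    samples: pd.DataFrame

    def validate(self) -> None:
        if self.beta.index.duplicated().any():
            raise ValueError("duplicated probe_ids")
        if self.beta.columns.duplicated().any():
            raise ValueError("duplicated sample_ids")
        if list(self.beta.columns) != list(self.samples.index):
            raise ValueError("beta columns and sample metadata index disagree")
        vals = self.beta.to_numpy()
        if vals.size and not ((vals > 0).all() and (vals < 1).all()):
            raise ValueError("beta values must lie strictly in (0, 1)")
        bad = set(self.samples["class_label"]) - {EC, GC}
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        gc = self.samples["class_label"] == GC
        if self.samples.loc[gc, "gc_subtype"].isna().any():
            raise ValueError("every GC sample needs a gc_subtype")
        if self.samples.loc[~gc, "gc_subtype"].notna().any():
            raise ValueError("EC samples must not carry a gc_subtype")

    @property
    def probe_ids(self) -> list:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list:
        return list(self.beta.columns)

    @property
    def class_label(self) -> pd.Series:
        return self.samples["class_label"]

    @property
    def cohort_id(self) -> pd.Series:
        return self.samples["cohort_id"]


@dataclass
class ProbeAnnotation:
    """Per-probe annotation table, indexed by probe_id.

    Columns: gene_symbol, chromosome, position (1-based bp), tss_start,
    tss_end, island_relation, regulatory_group, go_terms (frozenset of GO
    accessions) and on_27k (bool).
    """

    table: pd.DataFrame

    def validate(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise ValueError("duplicated probe_ids in annotation")
        if (t["tss_start"] > t["tss_end"]).any():
            raise ValueError("tss_start must be <= tss_end")
        if (t["position"] < 1).any():
            raise ValueError("positions are 1-based; found position < 1")
        bad = set(t["island_relation"]) - set(ISLAND_RELATIONS)
        if bad:
            raise ValueError(f"unknown island_relation values: {sorted(bad)}")
        bad = set(t["regulatory_group"]) - set(REGULATORY_GROUPS)
        if bad:
            raise ValueError(f"unknown regulatory_group values: {sorted(bad)}")

    def go_map(self) -> dict:
        """probe_id -> frozenset of GO accessions."""
        return {pid: frozenset(ts) for pid, ts in self.table["go_terms"].items()}

    def on_27k_ids(self) -> set:
        return set(self.table.index[self.table["on_27k"].astype(bool)])


def _logit2(beta):
    return np.log2(beta / (1.0 - beta))


def _expit2(m):
    return 1.0 / (1.0 + np.exp2(-np.asarray(m, dtype=float)))


def _mean_corrected_m(target_beta, sd, n_nodes=31):
    """M-value class means whose expected beta under N(0, sd) M-noise hits target.

    The logistic map is concave/convex away from beta = 0.5, so Gaussian
    M-noise biases the realized mean beta toward 0.5; solving
    E[expit2(m + eps)] = target (Gauss-Hermite quadrature, bisection)
    removes that bias so planted class-mean beta differences equal the
    requested effect size.
    """
    target = np.asarray(target_beta, dtype=float)
    if sd == 0:
        return _logit2(target)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    shift = np.sqrt(2.0) * sd * nodes
    w = weights / np.sqrt(np.pi)

    def expected_beta(m):
        return _expit2(m[:, None] + shift[None, :]) @ w

    lo = np.full(target.shape, -30.0)
    hi = np.full(target.shape, 30.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_low = expected_beta(mid) < target
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def generate_cohort(spec: CohortSpec, cohort_seed: int | None = None):
    """Generate a seeded synthetic cohort, its annotation and the truth set.

    Returns ``(cohort, annotation, truth)`` where ``truth`` is the set of
    planted probe_ids carrying a genuine class effect.  Per-sample M values
    are drawn as class/subtype/batch means plus Gaussian noise and mapped
    back to beta, clipped away from {0, 1} so M stays finite.  Deterministic
    for a fixed spec (including its seed).

    Probe-level structure (planted set, baselines, annotation, subtype
    marker probes) is driven by ``spec.seed`` alone; ``cohort_seed``
    reseeds only the sample-level draws (cohort assignment, batch offsets,
    noise), yielding an independent validation cohort that measures the
    same probe universe with the same truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rng_samples = np.random.default_rng(spec.seed if cohort_seed is None else cohort_seed)

    n_gc = 4 * spec.n_gc_per_subtype
    n_samples = spec.n_ec + n_gc
    probe_ids = np.array([f"cg{i:08d}" for i in range(spec.n_probes)])

    sample_ids = [f"EC-{i:04d}" for i in range(spec.n_ec)]
    class_label = [EC] * spec.n_ec
    gc_subtype: list = [None] * spec.n_ec
    for st in GC_SUBTYPES:
        for i in range(spec.n_gc_per_subtype):
            sample_ids.append(f"GC-{st}-{i:04d}")
            class_label.append(GC)
            gc_subtype.append(st)

    # stratified round-robin cohort assignment: every cohort sees every
    # class/subtype in near-equal proportion, so per-cohort z-scoring does
    # not erase the class signal.
    cohort_id = np.empty(n_samples, dtype=object)
    if spec.n_cohorts > 0:
        strata = [range(spec.n_ec)]
        for k in range(4):
            lo = spec.n_ec + k * spec.n_gc_per_subtype
            strata.append(range(lo, lo + spec.n_gc_per_subtype))
        for stratum in strata:
            idx = rng_samples.permutation(np.fromiter(stratum, dtype=int))
            for j, s in enumerate(idx):
                cohort_id[s] = f"cohort{j % spec.n_cohorts}"
    samples = pd.DataFrame(
        {"class_label": class_label, "gc_subtype": gc_subtype, "cohort_id": cohort_id},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    planted_idx = np.sort(rng.choice(spec.n_probes, size=spec.n_planted, replace=False))
    planted_mask = np.zeros(spec.n_probes, dtype=bool)
    planted_mask[planted_idx] = True

    # baseline beta per probe; planted probes get a class-dependent mean
    base_ec = rng.uniform(0.05, 0.95, size=spec.n_probes)
    base_gc = base_ec.copy()
    n_hyper = int(round(spec.planted_frac_hyper * spec.n_planted))
    hyper = planted_idx[:n_hyper]
    hypo = planted_idx[n_hyper:]
    margin = 0.05
    base_ec[hyper] = rng.uniform(margin, 1.0 - margin - spec.effect_size, size=hyper.size)
    base_gc[hyper] = base_ec[hyper] + spec.effect_size
    base_ec[hypo] = rng.uniform(margin + spec.effect_size, 1.0 - margin, size=hypo.size)
    base_gc[hypo] = base_ec[hypo] - spec.effect_size

    marginal_sd = float(np.hypot(spec.noise_sd, spec.batch_sd))
    m_ec = _mean_corrected_m(base_ec, marginal_sd)
    m_gc = _mean_corrected_m(base_gc, marginal_sd)

    # subtype nuisance shifts: a random subset of marker probes per subtype,
    # shifted on the M scale with random sign; magnitude corresponds to a
    # +/- subtype_shift beta change at the beta = 0.5 midpoint
    m_sub_mag = _logit2(0.5 + spec.subtype_shift) if spec.subtype_shift > 0 else 0.0
    n_marker = int(round(spec.subtype_marker_frac * spec.n_probes))
    subtype_offsets = {}
    for st in GC_SUBTYPES:
        off = np.zeros(spec.n_probes)
        if n_marker and m_sub_mag:
            marker = rng.choice(spec.n_probes, size=n_marker, replace=False)
            off[marker] = rng.choice([-1.0, 1.0], size=n_marker) * m_sub_mag
        subtype_offsets[st] = off

    cohorts = sorted(set(cohort_id)) if n_samples else []
    batch_offsets = {c: rng_samples.normal(0.0, spec.batch_sd, size=spec.n_probes) for c in cohorts}

    m = np.empty((spec.n_probes, n_samples))
    for j, sid in enumerate(sample_ids):
        cls = class_label[j]
        mu = m_gc.copy() if cls == GC else m_ec.copy()
        if cls == GC:
            mu += subtype_offsets[gc_subtype[j]]
        mu += batch_offsets[cohort_id[j]]
        m[:, j] = mu
    m += rng_samples.normal(0.0, spec.noise_sd, size=m.shape)

    beta = np.clip(_expit2(m), _BETA_CLIP, 1.0 - _BETA_CLIP)
    cohort = MethylationCohort(
        beta=pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids),
        samples=samples,
    )
    cohort.validate()

    ann = _generate_annotation(spec, rng, probe_ids, planted_mask)
    truth = set(probe_ids[planted_mask])
    return cohort, ann, truth


def _generate_annotation(spec, rng, probe_ids, planted_mask) -> ProbeAnnotation:
    n = probe_ids.size
    chrom = np.array([f"chr{c}" for c in rng.integers(1, 23, size=n)])
    position = rng.integers(10_000, 200_000_000, size=n)
    # TSS midpoint placed downstream of the probe at a promoter-proximal
    # distance, uniform over 150-290 bp (mean 220)
    dist = rng.integers(150, 291, size=n)
    half_width = rng.integers(0, 101, size=n)
    midpoint = position + dist
    tss_start = midpoint - half_width
    tss_end = midpoint + half_width

    island = rng.choice(
        list(_ISLAND_PROBS), size=n, p=np.array(list(_ISLAND_PROBS.values())) / sum(_ISLAND_PROBS.values())
    )
    regulatory = rng.choice(
        list(_REGULATORY_PROBS),
        size=n,
        p=np.array(list(_REGULATORY_PROBS.values())) / sum(_REGULATORY_PROBS.values()),
    )

    on_27k = rng.random(n) < spec.frac_27k
    on_27k[planted_mask] = True  # planted probes must survive the 27k filter

    terms = list(spec.go_terms)
    nonsignal = [t for t in terms if t not in spec.signal_terms]
    go_col = []
    for i in range(n):
        k = int(rng.integers(1, 4))
        if planted_mask[i]:
            chosen = {t for t in spec.signal_terms if rng.random() < spec.signal_enrichment}
            extra_pool = nonsignal if chosen else terms
            while len(chosen) < k and extra_pool:
                chosen.add(extra_pool[int(rng.integers(len(extra_pool)))])
            if not chosen:
                chosen = {spec.signal_terms[0]}
        else:
            chosen = set(rng.choice(terms, size=min(k, len(terms)), replace=False))
        go_col.append(frozenset(chosen))

    table = pd.DataFrame(
        {
            "gene_symbol": [f"GENE{i:05d}" for i in range(n)],
            "chromosome": chrom,
            "position": position.astype(np.int64),
            "tss_start": tss_start.astype(np.int64),
            "tss_end": tss_end.astype(np.int64),
            "island_relation": island,
            "regulatory_group": regulatory,
            "go_terms": go_col,
            "on_27k": on_27k,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    ann = ProbeAnnotation(table)
    ann.validate()
    return ann
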