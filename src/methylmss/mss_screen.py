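"""The optimized Multiple Survival Screening (MSS) core.

For each GO-defined subpool of differentially methylated probes the screen
draws many random gene sets (RGS).  A collection of balanced random
patient sets (RPS) — each 1:1 gastric : esophageal with the gastric half
stratified evenly over the four molecular subtypes (EBV/MSI/GS/CIN) — is
reduced to its most mutually dissimilar members by greedy max-min
selection under Jaccard distance.  Every RGS is scored against every
retained RPS with a one-sided Fisher's exact test asking whether the RGS
is enriched in that RPS's top differentially methylated probes; the
reciprocal of the mean Fisher p across RPSs is the RGS's enrichment
score.  The top-scoring RGSs per GO term are "gilded", and the probes
appearing most frequently across the gilded RGSs form the term's
signature (30 unique probes by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dm_analysis import ProbePool, moderated_t, select_pool, select_top_n
from .go_pools import DEFAULT_MIN_SIZE, GOSubpool, partition_subpools
from .preprocess import NormalizedMatrix, normalize_cohort
from .synthetic_cohort import EC, GC, GC_SUBTYPES, MethylationCohort, ProbeAnnotation


@dataclass(frozen=True)
class RGS:
    """Random gene set: a fixed-size subset of one GO subpool."""

    rgs_id: str
    go_term: str
    probe_ids: tuple

    def __len__(self) -> int:
        return len(self.probe_ids)


@dataclass(frozen=True)
class RPS:
    """Random patient set: class-balanced, subtype-stratified samples."""

    rps_id: str
    sample_ids: tuple

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def sample_set(self) -> frozenset:
        return frozenset(self.sample_ids)


@dataclass
class EnrichmentRecord:
    rgs_id: str
    p_values: tuple
    score: float
    gilded: bool


@dataclass
class Signature:
    """A GO term's signature: its most frequent gilded-RGS probes.

    ``probe_ids`` is the canonical order (descending gilded frequency,
    ties by probe_id); ``frequencies`` maps every probe seen in a gilded
    RGS to its appearance count.
    """

    go_term: str
    probe_ids: tuple
    frequencies: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.probe_ids)


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_rgs(subpool: GOSubpool, n_sets: int, m: int, seed) -> list:
    """Draw n_sets random gene sets of m unique probes from a subpool."""
    if m > len(subpool):
        raise ValueError(f"RGS size {m} exceeds subpool {subpool.go_term} size {len(subpool)}")
    rng = _rng(seed)
    members = np.asarray(subpool.probe_ids, dtype=object)
    return [
        RGS(
            rgs_id=f"{subpool.go_term}:rgs{i:05d}",
            go_term=subpool.go_term,
            probe_ids=tuple(rng.choice(members, size=m, replace=False)),
        )
        for i in range(n_sets)
    ]


def sample_rps(samples: pd.DataFrame, n_per_subtype: int = 25, n_ec: int = 100, seed=None, rps_id: str = "rps") -> RPS:
    """One balanced RPS: n_per_subtype gastric samples from each of the four
    subtypes plus n_ec esophageal samples (200 at defaults, ratio 1:1)."""
    rng = _rng(seed)
    chosen = []
    for st in GC_SUBTYPES:
        ids = samples.index[(samples["class_label"] == GC) & (samples["gc_subtype"] == st)].to_numpy()
        if ids.size < n_per_subtype:
            raise ValueError(f"subtype {st} has {ids.size} samples, need {n_per_subtype}")
        chosen.extend(rng.choice(ids, size=n_per_subtype, replace=False))
    ec_ids = samples.index[samples["class_label"] == EC].to_numpy()
    if ec_ids.size < n_ec:
        raise ValueError(f"class EC has {ec_ids.size} samples, need {n_ec}")
    chosen.extend(rng.choice(ec_ids, size=n_ec, replace=False))
    return RPS(rps_id=rps_id, sample_ids=tuple(chosen))


def sample_rps_candidates(samples: pd.DataFrame, n_candidates: int, n_per_subtype: int = 25, n_ec: int = 100, seed=None) -> list:
    rng = _rng(seed)
    return [
        sample_rps(samples, n_per_subtype=n_per_subtype, n_ec=n_ec, seed=rng, rps_id=f"rps{i:06d}")
        for i in range(n_candidates)
    ]


def _membership_matrix(candidates: list) -> tuple:
    universe = sorted({s for rps in candidates for s in rps.sample_ids})
    pos = {s: i for i, s in enumerate(universe)}
    m = np.zeros((len(candidates), len(universe)), dtype=np.float32)
    for i, rps in enumerate(candidates):
        m[i, [pos[s] for s in rps.sample_set]] = 1.0
    return m, np.asarray([len(rps.sample_set) for rps in candidates], dtype=np.float64)


def _jaccard_block(m, sizes, rows) -> np.ndarray:
    """Jaccard distances of the given candidate rows against all candidates."""
    inter = m[rows] @ m.T
    union = sizes[rows][:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return 1.0 - sim


def select_dissimilar_rps(candidates: list, k: int, block: int = 512) -> list:
    """Greedy max-min (farthest-point) selection of k mutually dissimilar RPSs.

    Seeded with the globally most distant pair under Jaccard distance on
    sample-id sets, then repeatedly adds the candidate whose minimum
    distance to the selected set is largest.  Deterministic for a fixed
    candidate order: every tie is broken toward the lower candidate index.
    """
    n = len(candidates)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} candidates")
    if k < 2:
        raise ValueError("k must be >= 2 (a dissimilarity selection needs a pair)")
    m, sizes = _membership_matrix(candidates)

    best = (-1.0, 0, 1)
    for lo in range(0, n, block):
        rows = np.arange(lo, min(lo + block, n))
        d = _jaccard_block(m, sizes, rows)
        for ri, i in enumerate(rows):
            if i + 1 >= n:
                continue
            j = int(np.argmax(d[ri, i + 1 :])) + i + 1
            if d[ri, j] > best[0]:
                best = (float(d[ri, j]), int(i), j)
    _, i0, j0 = best

    selected = [i0, j0]
    mindist = np.minimum(_jaccard_block(m, sizes, [i0])[0], _jaccard_block(m, sizes, [j0])[0])
    mindist[selected] = -np.inf
    while len(selected) < k:
        nxt = int(np.argmax(mindist))  # first occurrence -> lowest index on ties
        selected.append(nxt)
        mindist = np.minimum(mindist, _jaccard_block(m, sizes, [nxt])[0])
        mindist[nxt] = -np.inf
    return [candidates[i] for i in selected]


def default_top_d(pool_size: int, top_d: int | None = None) -> int:
    """Differential-set size per RPS: 300 at full scale, else half the pool."""
    return top_d if top_d is not None else min(300, max(1, pool_size // 2))


def rps_differential_set(rps: RPS, matrix: NormalizedMatrix, class_label: pd.Series, pool: ProbePool, q: int) -> frozenset:
    """The RPS's top-q pool probes by |moderated t| (GC vs EC within the RPS)."""
    if q > len(pool):
        raise ValueError(f"q={q} exceeds pool size {len(pool)}")
    sub = matrix.values.loc[pool.probe_ids, list(rps.sample_ids)]
    dm = moderated_t(sub, class_label.loc[list(rps.sample_ids)])
    order = sorted(dm.index, key=lambda pid: (-abs(dm.at[pid, "t_mod"]), pid))
    return frozenset(order[:q])


def fisher_enrichment_p(overlap, pool_size, d_size, rgs_size):
    """One-sided Fisher (hypergeometric tail) P(X >= overlap)."""
    return stats.hypergeom.sf(np.asarray(overlap) - 1, pool_size, d_size, rgs_size)


def fisher_enrichment(rgs: RGS, rps: RPS, matrix: NormalizedMatrix, class_label: pd.Series, pool: ProbePool, q: int) -> float:
    """Fisher's exact test (enrichment alternative) of RGS membership against
    the RPS's differential set, over the pool universe."""
    d = rps_differential_set(rps, matrix, class_label, pool, q)
    overlap = len(d & set(rgs.probe_ids))
    return float(fisher_enrichment_p(overlap, len(pool), len(d), len(rgs)))


def score_and_gild(records, top_k: int = 50) -> list:
    """Score RGSs (reciprocal mean Fisher p) and gild the top_k.

    ``records`` is an iterable of (rgs_id, p_values) pairs or a mapping.
    Descending score, ties broken by rgs_id; the first top_k are gilded.
    """
    items = list(records.items()) if isinstance(records, dict) else list(records)
    out = []
    for rgs_id, ps in items:
        ps = tuple(float(p) for p in ps)
        if not ps:
            raise ValueError(f"RGS {rgs_id} has no p-values")
        out.append(EnrichmentRecord(rgs_id=rgs_id, p_values=ps, score=1.0 / float(np.mean(ps)), gilded=False))
    out.sort(key=lambda r: (-r.score, r.rgs_id))
    for r in out[:top_k]:
        r.gilded = True
    return out


def derive_signature(gilded: list, size: int = 30, go_term: str | None = None) -> Signature:
    """The `size` probes appearing most frequently across gilded RGSs.

    Ties at the cutoff go to the lexicographically smallest probe_id.
    """
    counts: dict = {}
    for rgs in gilded:
        for pid in rgs.probe_ids:
            counts[pid] = counts.get(pid, 0) + 1
    if len(counts) < size:
        raise ValueError(f"gilded RGSs cover only {len(counts)} unique probes, need {size}")
    order = sorted(counts, key=lambda pid: (-counts[pid], pid))
    term = go_term if go_term is not None else (gilded[0].go_term if gilded else "")
    return Signature(go_term=term, probe_ids=tuple(order[:size]), frequencies=counts)


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable parameters of the MSS screen (full-study defaults)."""

    rgs_per_term: int = 500
    rgs_size: int = 10
    rps_candidates: int = 10_000
    rps_keep: int = 200
    per_subtype: int = 25
    ec_per_rps: int = 100
    top_d: int | None = None
    gild_top: int = 50
    signature_size: int = 30
    min_subpool: int = DEFAULT_MIN_SIZE
    fdr_max: float = 1e-4
    fc_min: float = 3.0
    top_n_pool: int | None = None

    def scaled(self, **overrides) -> "ScreenConfig":
        from dataclasses import replace

        return replace(self, **overrides)


#: desk-scale parameters used by the analysis scripts and acceptance runs
SCALED_OVERRIDES = dict(rps_candidates=200, rps_keep=50, rgs_per_term=100)


@dataclass
class DiscoveryResult:
    signatures: dict
    scoreboard: pd.DataFrame
    pool: ProbePool
    dm: pd.DataFrame
    subpools: list
    rps_list: list
    n_fisher_tests: int
    n_iterations: int


def discover_signatures(
    cohort: MethylationCohort,
    ann: ProbeAnnotation,
    config: ScreenConfig = ScreenConfig(),
    seed: int = 0,
    matrix: NormalizedMatrix | None = None,
) -> DiscoveryResult:
    """Run the full discovery pipeline on one cohort.

    Normalization (27k filter, M values, per-cohort z-score), moderated-t
    pool selection, GO subpooling, RPS candidate generation and max-min
    reduction, Fisher enrichment scoring of every RGS against every
    retained RPS, gilding and signature extraction.  All randomness flows
    from ``seed``.
    """
    rng = _rng(seed)
    if matrix is None:
        matrix = normalize_cohort(cohort, ann)
    labels = cohort.class_label

    dm = moderated_t(matrix, labels)
    if config.top_n_pool is not None:
        pool = select_top_n(dm, config.top_n_pool)
    else:
        pool = select_pool(dm, fdr_max=config.fdr_max, fc_min=config.fc_min)
    if len(pool) == 0:
        raise ValueError("empty differential pool; nothing to screen")

    subpools = partition_subpools(pool, ann, min_size=config.min_subpool)
    subpools = [sp for sp in subpools if len(sp) >= config.rgs_size]

    candidates = sample_rps_candidates(
        cohort.samples, config.rps_candidates, n_per_subtype=config.per_subtype, n_ec=config.ec_per_rps, seed=rng
    )
    rps_list = select_dissimilar_rps(candidates, config.rps_keep) if config.rps_keep < len(candidates) else candidates

    q = default_top_d(len(pool), config.top_d)
    pool_index = {pid: i for i, pid in enumerate(pool.probe_ids)}
    d_matrix = np.zeros((len(rps_list), len(pool)), dtype=np.float32)
    for i, rps in enumerate(rps_list):
        for pid in rps_differential_set(rps, matrix, labels, pool, q):
            d_matrix[i, pool_index[pid]] = 1.0

    signatures: dict = {}
    rows = []
    n_fisher = 0
    for sp in subpools:
        rgs_list = sample_rgs(sp, config.rgs_per_term, config.rgs_size, rng)
        rgs_matrix = np.zeros((len(rgs_list), len(pool)), dtype=np.float32)
        for i, rgs in enumerate(rgs_list):
            rgs_matrix[i, [pool_index[pid] for pid in rgs.probe_ids]] = 1.0
        overlap = rgs_matrix @ d_matrix.T  # n_rgs x n_rps
        pvals = fisher_enrichment_p(overlap, len(pool), q, config.rgs_size)
        n_fisher += pvals.size
        records = score_and_gild(
            [(rgs.rgs_id, pvals[i]) for i, rgs in enumerate(rgs_list)], top_k=config.gild_top
        )
        by_id = {rgs.rgs_id: rgs for rgs in rgs_list}
        gilded = [by_id[r.rgs_id] for r in records if r.gilded]
        try:
            signatures[sp.go_term] = derive_signature(gilded, size=config.signature_size, go_term=sp.go_term)
        except ValueError:
            continue  # subpool too small to yield a full signature
        for r in records:
            rows.append(
                {
                    "go_term": sp.go_term,
                    "rgs_id": r.rgs_id,
                    "score": r.score,
                    "mean_p": 1.0 / r.score,
                    "gilded": r.gilded,
                }
            )

    scoreboard = pd.DataFrame(rows, columns=["go_term", "rgs_id", "score", "mean_p", "gilded"])
    return DiscoveryResult(
        signatures=signatures,
        scoreboard=scoreboard,
        pool=pool,
        dm=dm,
        subpools=subpools,
        rps_list=rps_list,
        n_fisher_tests=n_fisher,
        n_iterations=sum(1 for _ in subpools) * config.rgs_per_term,
    )
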