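"""Preranked gene-set enrichment analysis (weighted Kolmogorov-Smirnov
statistic, permutation null, NES, FDR) and the hypergeometric
over-representation test.

The enrichment score walks the ranked gene list: genes in the set add
|metric|^weight normalized by the total hit weight, genes outside subtract
1/(N - N_hits); ES is the signed maximum deviation of this running sum from
zero.  The null distribution comes from phenotype (label) permutations by
default, falling back to gene-set resampling when the groups are too small;
NES divides each ES by the mean magnitude of same-sign null scores, and the
FDR q-value is the classic ratio of null-to-observed NES tail fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionStudy, GeneSetCollection
from .signature import StrataAssignment

log = logging.getLogger(__name__)

__all__ = [
    "RankedGeneList",
    "EnrichmentResult",
    "HypergeomResult",
    "rank_genes",
    "enrichment_score",
    "gsea",
    "hypergeom_enrichment",
]

EPS = 1e-8


@dataclass
class RankedGeneList:
    """Genes in descending order of a ranking metric (ties by gene id)."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    """Per-set ES/NES/p/q table plus leading-edge genes."""

    table: pd.DataFrame  # index: set name; es, nes, p, fdr_q, size, leading_edge

    def __len__(self) -> int:
        return len(self.table)

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.sort_values("nes", ascending=False).head(n)


@dataclass
class HypergeomResult:
    table: pd.DataFrame  # index: term; overlap, query_size, term_size, universe_size, p


def _log2_values(study: ExpressionStudy, samples, pseudocount: float = 1.0) -> np.ndarray:
    return np.log2(study.values[list(samples)].to_numpy(dtype=float) + pseudocount)


def _signal_to_noise(
    mh: np.ndarray, ml: np.ndarray, sh: np.ndarray, sl: np.ndarray
) -> np.ndarray:
    return (mh - ml) / (sh + sl + EPS)


def _order_genes(genes: np.ndarray, metric: np.ndarray) -> np.ndarray:
    """Indices sorting by descending metric, ties by ascending gene id."""
    return np.lexsort((genes, -metric))


def rank_genes(
    study: ExpressionStudy,
    strata: StrataAssignment,
    metric: str = "signal2noise",
    groups: tuple[str, str] = ("high", "low"),
    pseudocount: float = 1.0,
) -> RankedGeneList:
    """Rank genes by a two-group metric on log2(x + c) values.

    ``signal2noise``: (mean_high - mean_low) / (sd_high + sd_low + eps) with
    sample standard deviations (ddof=1) and no sd floor.  Genes constant in
    both groups get metric 0.
    """
    if metric != "signal2noise":
        raise ValueError(f"unknown ranking metric {metric!r}")
    high = [s for s in strata.samples_in(groups[0]) if s in study.values.columns]
    low = [s for s in strata.samples_in(groups[1]) if s in study.values.columns]
    if len(high) < 2 or len(low) < 2:
        raise ValueError("each group needs >=2 samples for the ranking metric")
    lh = _log2_values(study, high, pseudocount)
    ll = _log2_values(study, low, pseudocount)
    m = _signal_to_noise(
        lh.mean(axis=1), ll.mean(axis=1), lh.std(axis=1, ddof=1), ll.std(axis=1, ddof=1)
    )
    genes = np.asarray(study.gene_ids)
    order = _order_genes(genes, m)
    return RankedGeneList(genes=list(genes[order]), metric=m[order])


def enrichment_score(
    ranked: RankedGeneList, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted-KS enrichment score and the full running sum.

    Hits add |metric|^weight / sum over hits of |metric|^weight; misses
    subtract 1/(N - N_hits).  ES is the running-sum value of largest
    magnitude (positive preferred on an exact tie).
    """
    gene_set = set(gene_set)
    hits = np.array([g in gene_set for g in ranked.genes])
    n = len(ranked)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the whole ranked list; ES undefined")
    w = np.abs(ranked.metric) ** weight
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit metrics exactly zero: fall back to equal weights
        hit_w = hits.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~hits) / (n - n_hits)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    return float(np.clip(es, -1.0, 1.0)), running


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n: int
) -> float:
    """ES computed from sorted hit positions (0-based ranks) and their
    weights, without materializing the full running sum."""
    m = len(positions)
    denom = weights.sum()
    if denom == 0:
        weights = np.ones(m)
        denom = float(m)
    hit_cum = np.cumsum(weights) / denom
    miss = 1.0 / (n - m)
    idx = np.arange(m)
    # Running sum at each hit, and immediately before each hit (local minima).
    at_hit = hit_cum - (positions + 1 - (idx + 1)) * miss
    before_hit = (hit_cum - weights / denom) - (positions - idx) * miss
    hi = at_hit.max()
    lo = min(before_hit.min(), 0.0)
    return float(np.clip(hi if hi >= -lo else lo, -1.0, 1.0))


def _null_es_phenotype(
    lvals: np.ndarray,
    n_high: int,
    set_indices: list[np.ndarray],
    weight: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null ES matrix (n_sets x n_perm) from label permutations."""
    n_genes, n_samples = lvals.shape
    # Permuted group indicators, then group means/sds via matrix products.
    perm_high = np.zeros((n_samples, n_perm))
    for j in range(n_perm):
        perm_high[rng.permutation(n_samples)[:n_high], j] = 1.0
    perm_low = 1.0 - perm_high
    n_low = n_samples - n_high
    s_h = lvals @ perm_high
    s_l = lvals @ perm_low
    q_h = (lvals**2) @ perm_high
    q_l = (lvals**2) @ perm_low
    mh = s_h / n_high
    ml = s_l / n_low
    var_h = np.maximum(q_h - n_high * mh**2, 0.0) / (n_high - 1)
    var_l = np.maximum(q_l - n_low * ml**2, 0.0) / (n_low - 1)
    metric = _signal_to_noise(mh, ml, np.sqrt(var_h), np.sqrt(var_l))
    null = np.empty((len(set_indices), n_perm))
    gene_arr = np.arange(n_genes)
    for j in range(n_perm):
        mj = metric[:, j]
        order = np.lexsort((gene_arr, -mj))
        rank_of = np.empty(n_genes, dtype=np.int64)
        rank_of[order] = np.arange(n_genes)
        wj = np.abs(mj) ** weight
        for si, idx in enumerate(set_indices):
            pos = np.sort(rank_of[idx])
            null[si, j] = _es_from_positions(pos, wj[idx][np.argsort(rank_of[idx])], n_genes)
    return null


def _null_es_geneset(
    ranked_metric: np.ndarray,
    set_sizes: list[int],
    weight: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null ES from random gene sets drawn from the observed ranking."""
    n = len(ranked_metric)
    w = np.abs(ranked_metric) ** weight
    null = np.empty((len(set_sizes), n_perm))
    for si, m in enumerate(set_sizes):
        for j in range(n_perm):
            pos = np.sort(rng.choice(n, m, replace=False))
            null[si, j] = _es_from_positions(pos, w[pos], n)
    return null


def _nes_and_p(es: float, null_row: np.ndarray) -> tuple[float, float]:
    same_sign = null_row[null_row >= 0] if es >= 0 else null_row[null_row < 0]
    if len(same_sign) == 0:
        return np.nan, 1.0 / 1.0
    mean_mag = np.abs(same_sign).mean()
    nes = es / mean_mag if mean_mag > 0 else np.nan
    p = float((np.abs(same_sign) >= abs(es)).sum()) / len(same_sign)
    return nes, max(p, 0.0)


def _fdr_q(nes: np.ndarray, null_nes_pool: np.ndarray) -> np.ndarray:
    """Classic GSEA FDR: ratio of the null and observed NES tail fractions,
    computed separately on each sign, clipped to [0, 1] and made monotone
    from the most extreme NES inward."""
    q = np.full(len(nes), np.nan)
    for sign in (1, -1):
        obs_mask = (nes >= 0) if sign > 0 else (nes < 0)
        null_side = null_nes_pool[null_nes_pool >= 0] if sign > 0 else null_nes_pool[null_nes_pool < 0]
        obs_side = nes[obs_mask]
        if not obs_mask.any():
            continue
        for i in np.flatnonzero(obs_mask):
            v = nes[i]
            if np.isnan(v):
                q[i] = 1.0
                continue
            if len(null_side) == 0:
                q[i] = 0.0
                continue
            null_frac = (np.abs(null_side) >= abs(v)).mean()
            obs_frac = (np.abs(obs_side) >= abs(v)).mean()
            q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    return q


def gsea(
    study: ExpressionStudy,
    strata: StrataAssignment,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    perm_type: str = "phenotype",
    weight: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
    groups: tuple[str, str] = ("high", "low"),
    pseudocount: float = 1.0,
) -> EnrichmentResult:
    """Run GSEA for every set in the collection.

    Sets are intersected with the study's genes and filtered to sizes in
    [min_size, max_size].  Phenotype permutation shuffles the group labels;
    if either group has fewer than 7 samples the null switches to gene-set
    resampling with a warning.  Deterministic for a fixed seed.
    """
    if len(collection) == 0:
        raise ValueError("empty gene set collection")
    if n_perm < 100:
        log.warning("n_perm=%d is small; p and q values will be coarse", n_perm)
    high = [s for s in strata.samples_in(groups[0]) if s in study.values.columns]
    low = [s for s in strata.samples_in(groups[1]) if s in study.values.columns]
    if perm_type == "phenotype" and (len(high) < 7 or len(low) < 7):
        log.warning(
            "groups too small for phenotype permutation (%d vs %d); "
            "switching to gene_set permutation",
            len(high),
            len(low),
        )
        perm_type = "gene_set"
    ranked = rank_genes(study, strata, groups=groups, pseudocount=pseudocount)
    gene_index = {g: i for i, g in enumerate(study.gene_ids)}
    names, set_indices, kept_sets = [], [], []
    for name in collection.names:
        members = [g for g in collection[name] if g in gene_index]
        if not (min_size <= len(members) <= max_size):
            continue
        names.append(name)
        kept_sets.append(set(members))
        set_indices.append(np.array([gene_index[g] for g in members]))
    if not names:
        raise ValueError("no gene set passed the size filter")
    es_obs = np.empty(len(names))
    leading = []
    for i, members in enumerate(kept_sets):
        es, running = enrichment_score(ranked, members, weight=weight)
        es_obs[i] = es
        hits = [g for g in ranked.genes if g in members]
        if es >= 0:
            peak = int(np.argmax(running))
            lead = [g for g in ranked.genes[: peak + 1] if g in members]
        else:
            peak = int(np.argmin(running))
            lead = [g for g in ranked.genes[peak:] if g in members]
        leading.append(",".join(lead))
        del hits
    rng = np.random.default_rng(seed)
    if perm_type == "phenotype":
        lvals = _log2_values(study, high + low, pseudocount)
        null = _null_es_phenotype(lvals, len(high), set_indices, weight, n_perm, rng)
    elif perm_type == "gene_set":
        null = _null_es_geneset(
            ranked.metric, [len(s) for s in kept_sets], weight, n_perm, rng
        )
    else:
        raise ValueError(f"unknown perm_type {perm_type!r}")
    nes = np.empty(len(names))
    pvals = np.empty(len(names))
    null_nes_pool = []
    for i in range(len(names)):
        nes[i], pvals[i] = _nes_and_p(es_obs[i], null[i])
        row = null[i]
        pos = row[row >= 0]
        neg = row[row < 0]
        normed = np.concatenate(
            [
                pos / pos.mean() if len(pos) and pos.mean() > 0 else np.empty(0),
                neg / np.abs(neg).mean() if len(neg) and np.abs(neg).mean() > 0 else np.empty(0),
            ]
        )
        null_nes_pool.append(normed)
    qvals = _fdr_q(nes, np.concatenate(null_nes_pool))
    table = pd.DataFrame(
        {
            "size": [len(s) for s in kept_sets],
            "es": es_obs,
            "nes": nes,
            "p": pvals,
            "fdr_q": qvals,
            "leading_edge": leading,
        },
        index=pd.Index(names, name="gene_set"),
    )
    return EnrichmentResult(table=table)


def hypergeom_enrichment(
    query, annotation: GeneSetCollection, universe
) -> HypergeomResult:
    """One-sided hypergeometric over-representation test per annotation term.

    p = P(X >= k) for overlap k between the query and each term, drawn from
    the given universe.  Term genes outside the universe are dropped with a
    warning; a query outside the universe is an error.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:10]}")
    rows = []
    for name in annotation.names:
        term = set(annotation[name])
        inside = term & universe
        if len(inside) < len(term):
            log.warning(
                "term %r: dropping %d genes outside the universe",
                name,
                len(term) - len(inside),
            )
        if not inside:
            continue
        k = len(query & inside)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(inside), len(query)))
        rows.append((name, k, len(query), len(inside), len(universe), p))
    table = pd.DataFrame(
        rows,
        columns=["term", "overlap", "query_size", "term_size", "universe_size", "p"],
    ).set_index("term")
    return HypergeomResult(table=table)
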