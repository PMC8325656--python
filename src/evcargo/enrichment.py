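"""Gene-set enrichment statistics: weighted running-sum GSEA and hypergeometric ORA.

The enrichment score (ES) of a gene set S in a ranked list of N genes is
the maximal deviation from zero of a running sum that increments by
|r_i|^p / sum_{S}|r|^p at each set member ("hit") and decrements by
1 / (N - |S|) at each non-member. Significance comes from a permutation
null: by default random gene sets of the same size (gene-label
permutation), with the same-sign add-one-smoothed p-value convention and
the standard NES-pooled FDR q.

Over-representation analysis (ORA) is the upper-tail hypergeometric test of
the overlap between a selected list and each set, within a stated universe,
with Benjamini-Hochberg correction across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .config import EnrichmentConfig
from .nanostring import NormalizedMatrix


class EnrichmentError(ValueError):
    pass


@dataclass
class EsResult:
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]


def rank_genes(
    norm: NormalizedMatrix | pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Rank genes by log2 fold change of group means of normalized counts.

    Returns a Series (index = gene id, values = signed metric) sorted in
    descending order, ties broken by gene id so the ranking is deterministic.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise EnrichmentError("both groups must contain at least one sample")
    missing = [s for s in group_a + group_b if s not in values.columns]
    if missing:
        raise EnrichmentError(f"samples not in matrix: {missing}")
    mean_a = values[group_a].mean(axis=1)
    mean_b = values[group_b].mean(axis=1)
    if pseudocount <= 0 and ((mean_a <= 0) | (mean_b <= 0)).any():
        raise EnrichmentError("non-positive group mean requires a positive pseudocount")
    metric = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    if not np.isfinite(metric).all():
        raise EnrichmentError("ranking metric contains non-finite values")
    # stable sort on gene id first, then descending metric -> deterministic ties
    metric = metric.sort_index()
    return metric.sort_values(ascending=False, kind="mergesort")


def enrichment_score(
    ranked: pd.Series, gene_set: Iterable[str], p: float = 1.0
) -> EsResult:
    """Classic weighted Kolmogorov-Smirnov-like running-sum enrichment score."""
    genes = ranked.index
    members = set(gene_set) & set(genes)
    if not members:
        raise EnrichmentError("gene set is disjoint from the ranked list")
    n = len(genes)
    hit = genes.isin(members)
    n_hit = int(hit.sum())
    weights = np.abs(ranked.to_numpy()) ** p
    wsum = weights[hit].sum()
    if wsum == 0:
        # degenerate all-zero metric inside the set: fall back to equal weights
        inc = hit / n_hit
    else:
        inc = np.where(hit, weights / wsum, 0.0)
    if n_hit == n:
        running = np.cumsum(inc)  # no misses: the sum climbs monotonically to 1
    else:
        dec = (~hit) / (n - n_hit)
        running = np.cumsum(inc - dec)
    # extremum of |running sum|; ties (within fp tolerance) go to the
    # earliest position, matching a literal left-to-right scan
    absrun = np.abs(running)
    idx = int(np.flatnonzero(absrun >= absrun.max() - 1e-12)[0])
    es = float(running[idx])
    if es >= 0:
        leading = [g for i, g in enumerate(genes) if hit[i] and i <= idx]
    else:
        leading = [g for i, g in enumerate(genes) if hit[i] and i >= idx]
    return EsResult(es=es, running_sum=running, leading_edge=leading)


def _es_for_position_sets(weights: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Vectorised ES for many same-size hit-position sets over one ranked list.

    ``weights`` = |metric|^p in ranked order (length N); ``positions`` is a
    (K, h) integer array of 0-based hit positions. The running-sum extrema
    can only occur at a hit (maxima) or immediately before one (minima), so
    only those candidate values are evaluated.
    """
    n = weights.shape[0]
    k, h = positions.shape
    if h == n:
        return np.ones(k)
    s = np.sort(positions, axis=1)
    w = weights[s]
    wsum = w.sum(axis=1, keepdims=True)
    uniform = wsum == 0
    safe = np.where(uniform, 1.0, wsum)
    cw = np.where(uniform, (np.arange(1, h + 1) / h)[None, :], np.cumsum(w, axis=1) / safe)
    inc = np.where(uniform, 1.0 / h, w / safe)
    miss = (s - np.arange(h)[None, :]) / (n - h)
    at_hit = cw - miss
    before_hit = at_hit - inc
    rows = np.arange(k)
    i_hi = np.argmax(at_hit, axis=1)
    hi = at_hit[rows, i_hi]
    hi_pos = s[rows, i_hi]
    i_lo = np.argmin(before_hit, axis=1)
    lo = np.minimum(before_hit[rows, i_lo], 0.0)
    lo_pos = s[rows, i_lo] - 1
    # |hi| vs |lo| with the same earliest-position tie-break as the scan
    tol = 1e-12
    es = np.where(hi > -lo + tol, hi, lo)
    tie = np.abs(hi + lo) <= tol
    return np.where(tie & (hi_pos <= lo_pos), hi, es)


def _exhaustive_positions(n: int, h: int, limit: int = 500_000) -> np.ndarray:
    total = comb(n, h)
    if total > limit:
        raise EnrichmentError(
            f"exhaustive null of C({n},{h}) = {total} placements exceeds the {limit} limit"
        )
    return np.array(list(combinations(range(n), h)), dtype=int)


def gsea(
    ranked: pd.Series,
    sets: Mapping[str, Iterable[str]],
    config: EnrichmentConfig | None = None,
    exhaustive: bool = False,
    phenotype_ranker=None,
) -> pd.DataFrame:
    """Permutation GSEA over a collection of gene sets.

    Gene-label permutation (the default) draws random same-size gene sets
    against the fixed ranked list; with ``exhaustive=True`` every placement
    is enumerated (tiny lists only) and the p-value is exact. Phenotype
    permutation requires ``phenotype_ranker``, a callable taking a seeded
    ``numpy.random.Generator`` and returning a permuted-label ranked Series.

    Returns one row per set: es, nes, nominal p, FDR q, leading edge,
    significance at the configured cutoffs, and a degenerate-null flag.
    """
    config = config or EnrichmentConfig()
    rng = np.random.default_rng(config.seed)
    n = len(ranked)
    weights = np.abs(ranked.to_numpy()) ** config.weight
    rows = []
    perm_nes_pool: list[np.ndarray] = []
    for name in sorted(sets):
        members = set(sets[name]) & set(ranked.index)
        if not members:
            raise EnrichmentError(f"gene set {name!r} is disjoint from the ranked list")
        obs = enrichment_score(ranked, members, p=config.weight)
        h = len(members)
        if config.permutation_mode == "phenotype":
            if phenotype_ranker is None:
                raise EnrichmentError("phenotype permutation requires a phenotype_ranker")
            es_perm = np.array(
                [
                    enrichment_score(phenotype_ranker(rng), members, p=config.weight).es
                    for _ in range(config.n_permutations)
                ]
            )
        elif exhaustive:
            es_perm = _es_for_position_sets(weights, _exhaustive_positions(n, h))
        else:
            draws = np.argsort(
                rng.random((config.n_permutations, n)), axis=1, kind="stable"
            )[:, :h]
            es_perm = _es_for_position_sets(weights, draws)
        sign = 1.0 if obs.es >= 0 else -1.0
        same = es_perm[es_perm * sign > 0]
        degenerate = len(same) == 0
        if degenerate:
            p_nom = 1.0 / (len(es_perm) + 1)
            nes = np.nan
        elif exhaustive:
            p_nom = float((np.abs(same) >= abs(obs.es) - 1e-12).sum() / len(same))
            nes = obs.es / np.abs(same).mean()
        else:
            p_nom = float((1 + (np.abs(same) >= abs(obs.es) - 1e-12).sum()) / (1 + len(same)))
            nes = obs.es / np.abs(same).mean()
        # normalise the permutation ES by the same-sign means for the FDR pool
        pos_mean = np.abs(es_perm[es_perm > 0]).mean() if (es_perm > 0).any() else np.nan
        neg_mean = np.abs(es_perm[es_perm < 0]).mean() if (es_perm < 0).any() else np.nan
        nes_perm = np.where(es_perm >= 0, es_perm / pos_mean, es_perm / neg_mean)
        perm_nes_pool.append(nes_perm[np.isfinite(nes_perm)])
        rows.append(
            {
                "set": name,
                "size": h,
                "es": obs.es,
                "nes": nes,
                "p_nominal": p_nom,
                "degenerate_null": degenerate,
                "leading_edge": ",".join(obs.leading_edge),
            }
        )
    result = pd.DataFrame(rows).set_index("set")
    pool = np.concatenate(perm_nes_pool) if perm_nes_pool else np.array([])
    obs_nes = result["nes"].to_numpy()
    qs = np.full(len(result), np.nan)
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            num_den = (pool >= 0).sum()
            num = (pool >= nes).sum() / num_den if num_den else np.nan
            obs_den = (obs_nes[np.isfinite(obs_nes)] >= 0).sum()
            obs_frac = (obs_nes[np.isfinite(obs_nes)] >= nes).sum() / obs_den if obs_den else np.nan
        else:
            num_den = (pool < 0).sum()
            num = (pool <= nes).sum() / num_den if num_den else np.nan
            obs_den = (obs_nes[np.isfinite(obs_nes)] < 0).sum()
            obs_frac = (obs_nes[np.isfinite(obs_nes)] <= nes).sum() / obs_den if obs_den else np.nan
        if obs_frac and np.isfinite(obs_frac) and np.isfinite(num):
            qs[i] = min(1.0, num / obs_frac)
        elif np.isfinite(num):
            qs[i] = np.nan
    result["fdr_q"] = qs
    result["significant"] = (result["p_nominal"] < config.nominal_p_cutoff) & (
        result["fdr_q"] < config.fdr_q_cutoff
    )
    return result


def ora(
    selected: Iterable[str],
    universe: Iterable[str],
    sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test with BH correction.

    Sets are intersected with the universe before testing; the p-value is
    P(overlap >= observed) drawing |selected| genes from the universe.
    """
    selected, universe = frozenset(selected), frozenset(universe)
    if not selected <= universe:
        raise EnrichmentError(
            f"selected list is not contained in the universe "
            f"({len(selected - universe)} ids outside)"
        )
    m = len(universe)
    n_sel = len(selected)
    rows = []
    for name in sorted(sets):
        members = frozenset(sets[name]) & universe
        if not members:
            raise EnrichmentError(f"gene set {name!r} is empty after universe intersection")
        k = len(members & selected)
        p = float(hypergeom.sf(k - 1, m, len(members), n_sel))
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": len(members),
                "selected_size": n_sel,
                "universe_size": m,
                "p_value": p,
            }
        )
    result = pd.DataFrame(rows).set_index("set")
    result["fdr_q"] = bh_adjust(result["p_value"].to_numpy())
    return result


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise EnrichmentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
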