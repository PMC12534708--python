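"""Probe-set enrichment statistics.

One-sided hypergeometric (Fisher) tests of probe sets against named
annotation sets, interval-overlap colocalization with symmetric expansion
(GWAS SNP style), an unweighted rank-based set-enrichment statistic with a
membership-permutation null, a tissue mean-rank context analysis
(Kruskal-Wallis + Dunn post hoc), and CpG-to-gene linking / correlation.

All multiple-testing corrections are Benjamini-Hochberg, applied within each
family of annotations per query.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from methylcode.io import BetaMatrix, GenomicIntervalSet, ProbeManifest

__all__ = [
    "fisher_set_enrichment",
    "interval_colocalization",
    "ranked_set_enrichment",
    "tissue_rank_context",
    "link_probes_to_genes",
    "cpg_gene_correlation",
]

_ENRICH_COLUMNS = [
    "query",
    "annotation",
    "a",
    "b",
    "c",
    "d",
    "odds_ratio",
    "log2_or",
    "p_value",
    "q_value",
]


def _one_table(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """(OR, log2 OR, one-sided hypergeometric p) for a 2x2 overlap table.

    a = query & annotation, b = query only, c = annotation only, d = neither.
    A 0.5 continuity correction enters the OR (not the p) when any cell is 0.
    Degenerate margins (annotation or query covering the whole universe or
    none of it) carry no association: OR = 1 by convention.
    """
    n_tot = a + b + c + d
    if (a + c) in (0, n_tot) or (a + b) in (0, n_tot):
        p = float(stats.hypergeom.sf(a - 1, n_tot, a + c, a + b))
        return 1.0, 0.0, min(p, 1.0)
    if min(a, b, c, d) == 0:
        orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orat = (a * d) / (b * c)
    n = a + b + c + d
    # P(X >= a) with X ~ Hypergeom(N=n, K=a+c annotation, n draws=a+b query)
    p = float(stats.hypergeom.sf(a - 1, n, a + c, a + b))
    return float(orat), float(np.log2(orat)), min(p, 1.0)


def fisher_set_enrichment(
    query: set | list,
    annotations: dict[str, set | list],
    universe: set | list,
    query_name: str = "query",
) -> pd.DataFrame:
    """One-sided over-representation of a probe set in each annotation set.

    The query must be drawn from the universe (typically all probes on the
    array); annotations are intersected with the universe first. BH q-values
    are computed across the annotation family.
    """
    universe = set(universe)
    q = set(query) & universe
    if set(query) - universe:
        raise ValueError("query contains probes outside the universe")
    if not q:
        raise ValueError("query is empty after universe intersection")
    n = len(universe)
    rows = []
    for name, ann in annotations.items():
        a_set = set(ann) & universe
        a = len(q & a_set)
        b = len(q) - a
        c = len(a_set) - a
        d = n - a - b - c
        orat, l2, p = _one_table(a, b, c, d)
        rows.append((query_name, name, a, b, c, d, orat, l2, p, np.nan))
    out = pd.DataFrame(rows, columns=_ENRICH_COLUMNS)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def _build_trees(ivs: GenomicIntervalSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in ivs.table.groupby("chrom"):
        tree = IntervalTree()
        for s, e in zip(sub["start"], sub["end"]):
            if e > s:
                tree.addi(int(s), int(e))
        trees[str(chrom)] = tree
    return trees


def _overlap_flags(queries: GenomicIntervalSet, features: GenomicIntervalSet) -> np.ndarray:
    """True where a query interval shares >= 1 base with any feature (half-open)."""
    trees = _build_trees(features)
    flags = np.zeros(len(queries), dtype=bool)
    t = queries.table
    for i, (chrom, s, e) in enumerate(zip(t["chrom"], t["start"], t["end"])):
        tree = trees.get(str(chrom))
        if tree is not None and e > s and tree.overlaps(int(s), int(e)):
            flags[i] = True
    return flags


def interval_colocalization(
    query_intervals: GenomicIntervalSet,
    feature_intervals: dict[str, GenomicIntervalSet],
    universe_intervals: GenomicIntervalSet,
    expand_bp: int = 5000,
    query_name: str = "query",
) -> pd.DataFrame:
    """Colocalization of query intervals (e.g. tissue-marker CpGs) with features.

    Both sides are expanded by ``expand_bp`` upstream and downstream (starts
    clamped at 0) and overlap means any shared base under half-open
    semantics. Per feature set, the 2x2 table counts universe intervals
    (the background, e.g. all tissue-signature CpG intervals) that are in the
    query and/or overlap the feature; the hypergeometric machinery of
    :func:`fisher_set_enrichment` supplies OR and p.
    """
    uni_chroms = set(universe_intervals.table["chrom"].astype(str))
    q_exp = query_intervals.expand(expand_bp)
    uni_exp = universe_intervals.expand(expand_bp)
    # queries are identified within the universe by their (chrom,start,end,name)
    key = lambda t: list(zip(t["chrom"].astype(str), t["start"], t["end"], t["name"]))
    uni_keys = key(universe_intervals.table)
    q_keys = set(key(query_intervals.table))
    in_query = np.array([k in q_keys for k in uni_keys])
    rows = []
    for fname, fiv in feature_intervals.items():
        f_chroms = set(fiv.table["chrom"].astype(str))
        if uni_chroms and f_chroms and not (uni_chroms & f_chroms):
            raise ValueError(
                f"no shared chromosome names between universe and {fname!r}: "
                f"{sorted(uni_chroms)[:3]} vs {sorted(f_chroms)[:3]}"
            )
        hits = _overlap_flags(uni_exp, fiv.expand(expand_bp))
        a = int(np.sum(in_query & hits))
        b = int(np.sum(in_query & ~hits))
        c = int(np.sum(~in_query & hits))
        d = int(np.sum(~in_query & ~hits))
        orat, l2, p = _one_table(a, b, c, d)
        rows.append((query_name, fname, a, b, c, d, orat, l2, p, np.nan))
    out = pd.DataFrame(rows, columns=_ENRICH_COLUMNS)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def enrichment_score(is_hit: np.ndarray) -> float:
    """Signed maximum deviation of the running sum (unweighted KS form).

    +1/|Q| at query hits, -1/(N-|Q|) at misses, walked along the ranking.
    """
    n = len(is_hit)
    nq = int(is_hit.sum())
    if nq == 0 or nq == n:
        raise ValueError("query must be a proper non-empty subset of the ranking")
    step = np.where(is_hit, 1.0 / nq, -1.0 / (n - nq))
    running = np.cumsum(step)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


@dataclass
class SeaResult:
    query: str
    es: float
    p_value: float
    n_permutations: int


def ranked_set_enrichment(
    ranked_probes: list[str],
    query: set | list,
    n_permutations: int = 1000,
    seed: int = 0,
    query_name: str = "query",
) -> SeaResult:
    """Rank-based set enrichment of a probe set against an ordered probe list.

    ES is the signed maximum running-sum deviation; the null permutes query
    membership uniformly over positions and
    ``p = (1 + #{|ES*| >= |ES|}) / (n_permutations + 1)``.
    """
    ranked = list(ranked_probes)
    n = len(ranked)
    qset = set(query)
    if not qset <= set(ranked):
        raise ValueError("query must be a subset of the ranked list")
    nq = len(qset)
    if nq == 0 or nq == n:
        raise ValueError("query size must be in (0, N)")
    is_hit = np.fromiter((p in qset for p in ranked), dtype=bool, count=n)
    es = enrichment_score(is_hit)

    rng = np.random.default_rng(seed)
    # vectorized permutation null: random membership positions per permutation
    step_hit, step_miss = 1.0 / nq, -1.0 / (n - nq)
    null_abs = np.empty(n_permutations)
    perm_block = np.argsort(rng.random((n_permutations, n)), axis=1) < nq
    steps = np.where(perm_block, step_hit, step_miss)
    running = np.cumsum(steps, axis=1)
    null_abs = np.max(np.abs(running), axis=1)
    p = (1.0 + float(np.sum(null_abs >= abs(es) - 1e-12))) / (n_permutations + 1.0)
    return SeaResult(query_name, es, p, n_permutations)


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks with tie correction, BH-adjusted."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    # tie correction term for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    mean_ranks, sizes = {}, {}
    start = 0
    for g in labels:
        m = len(groups[g])
        mean_ranks[g] = float(ranks[start : start + m].mean())
        sizes[g] = m
        start += m
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            gi, gj = labels[i], labels[j]
            se = np.sqrt(
                (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[gi] + 1.0 / sizes[gj])
            )
            z = (mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((gi, gj, z, p))
    out = pd.DataFrame(rows, columns=["group1", "group2", "z", "p_value"])
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def tissue_rank_context(
    bm: BetaMatrix,
    trait_probes: set | list,
    groups: pd.Series,
) -> dict:
    """Which tissues carry a trait's methylation signal, by mean beta rank.

    For every trait CpG the samples are ranked by beta (midranks for ties);
    each tissue's mean rank over its samples is recorded, and the per-CpG
    tissue mean-ranks are pooled into per-tissue distributions. Differences
    across tissues are tested by Kruskal-Wallis (tie-corrected) with Dunn's
    post hoc pairwise z-tests (BH-adjusted).

    Returns {"mean_ranks": DataFrame (CpG x tissue), "kruskal_h", "kruskal_p",
    "dunn": DataFrame}.
    """
    groups = groups.dropna()
    samples = [s for s in groups.index if s in bm.sample_ids]
    labels = groups.loc[samples]
    tissues = [t for t in pd.unique(labels) if (labels == t).sum() > 0]
    probes = [p for p in trait_probes if p in bm.probe_ids]
    if not probes:
        raise ValueError("no trait probes present in matrix")
    sub = bm.data.loc[probes, samples].to_numpy()
    rank_rows = []
    for row in sub:
        obs = ~np.isnan(row)
        ranks = np.full(len(row), np.nan)
        ranks[obs] = stats.rankdata(row[obs])
        rank_rows.append(ranks)
    R = np.asarray(rank_rows)
    mean_ranks = pd.DataFrame(index=probes, columns=tissues, dtype=float)
    for t in tissues:
        cols = [i for i, s in enumerate(samples) if labels[s] == t]
        mean_ranks[t] = np.nanmean(R[:, cols], axis=1)
    dists = {t: mean_ranks[t].dropna().to_numpy() for t in tissues}
    dists = {t: v for t, v in dists.items() if len(v) > 0}
    h, p = stats.kruskal(*dists.values())
    return {
        "mean_ranks": mean_ranks,
        "kruskal_h": float(h),
        "kruskal_p": float(p),
        "dunn": _dunn_posthoc(dists),
    }


def link_probes_to_genes(
    manifest: ProbeManifest,
    genes: GenomicIntervalSet,
    window_bp: int = 10_000,
) -> pd.DataFrame:
    """Probe-gene pairs by interval overlap within a symmetric window.

    A probe links to every gene whose interval overlaps the probe interval
    expanded by ``window_bp`` on each side; many-to-many links are allowed.
    """
    probe_ivs = manifest.intervals().expand(window_bp)
    gene_trees: dict[str, IntervalTree] = {}
    gt = genes.sorted().table
    for chrom, sub in gt.groupby("chrom"):
        tree = IntervalTree()
        for s, e, name in zip(sub["start"], sub["end"], sub["name"]):
            if e > s:
                tree.addi(int(s), int(e), name)
        gene_trees[str(chrom)] = tree
    rows = []
    t = probe_ivs.table
    for chrom, s, e, pid in zip(t["chrom"], t["start"], t["end"], t["name"]):
        tree = gene_trees.get(str(chrom))
        if tree is None or e <= s:
            continue
        for hit in sorted(tree.overlap(int(s), int(e)), key=lambda h: (h.begin, h.data)):
            rows.append((pid, hit.data))
    return pd.DataFrame(rows, columns=["probe_id", "gene"])


def cpg_gene_correlation(
    beta_by_group: pd.DataFrame,
    expr: pd.DataFrame,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation of per-tissue mean beta with gene expression.

    ``beta_by_group``: probes x tissues mean betas; ``expr``: genes x tissues;
    ``pairs``: frame with probe_id and gene columns. Correlations use the
    shared tissues with both values non-NA; pairs with fewer than 3 points or
    zero variance are emitted with NA statistics.
    """
    shared = [t for t in beta_by_group.columns if t in expr.columns]
    rows = []
    for probe, gene in zip(pairs["probe_id"], pairs["gene"]):
        if probe not in beta_by_group.index or gene not in expr.index:
            rows.append((probe, gene, np.nan, np.nan, 0))
            continue
        x = beta_by_group.loc[probe, shared].to_numpy(dtype=float)
        y = expr.loc[gene, shared].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        n = int(ok.sum())
        if n < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            rows.append((probe, gene, np.nan, np.nan, n))
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append((probe, gene, float(r), float(p), n))
    return pd.DataFrame(rows, columns=["probe_id", "gene", "r", "p_value", "n_tissues"])
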