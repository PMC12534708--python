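"""One-vs-rest marker discovery and methylation-level screens.

Markers discriminating one cell/tissue type against the pooled remainder are
found per CpG by two-sided Wilcoxon rank-sum testing, with AUC = U/(n1*n2) as
the discrimination measure and delta-beta (difference of group means) as the
effect size. The same machinery applies to any numeric feature table, e.g.
per-tissue TPM expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from methylcode.io import BetaMatrix

__all__ = [
    "MarkerThresholds",
    "one_vs_rest_markers",
    "hierarchical_contrasts",
    "constitutive_screen",
    "intermediate_screen",
    "variability_rank",
    "tissue_specific_features",
]


@dataclass
class MarkerThresholds:
    """Selection thresholds for one-vs-rest marker discovery.

    ``min_auc`` is applied as distance from 0.5, so hypomethylated markers
    (AUC <= 1 - min_auc) qualify symmetrically. NA caps follow the array
    convention: a CpG is dropped when its NA fraction exceeds 10% of the
    target group or 50% of the out-group.
    """

    min_auc: float = 0.8
    min_delta: float = 0.2
    max_na_target: float = 0.10
    max_na_rest: float = 0.50


_RESULT_COLUMNS = [
    "probe_id",
    "contrast",
    "U",
    "p_value",
    "q_value",
    "auc",
    "delta_beta",
    "direction",
    "n_target_used",
    "n_rest_used",
]


def _rank_stats(target: np.ndarray, rest: np.ndarray) -> tuple[float, float, float]:
    """(U_target, AUC, two-sided p) with midranks for ties.

    Exact null distribution when both sides have <= 10 observations and no
    ties occur; otherwise normal approximation with tie and continuity
    corrections (delegated to scipy).
    """
    n1, n2 = len(target), len(rest)
    pooled = np.concatenate([target, rest])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (n1 <= 10 and n2 <= 10 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(target, rest, alternative="two-sided", method=method)
    u = float(res.statistic)
    return u, u / (n1 * n2), float(res.pvalue)


def one_vs_rest_markers(
    bm: BetaMatrix,
    groups: pd.Series,
    target: str,
    thresholds: MarkerThresholds | None = None,
    cap: int | None = None,
    min_n: int = 2,
    return_all: bool = False,
) -> pd.DataFrame:
    """Per-CpG one-vs-rest marker statistics and selection for one contrast.

    Parameters
    ----------
    bm
        Beta (or any numeric feature) matrix, probes x samples.
    groups
        sample_id -> group label; samples absent from ``groups`` are ignored.
    target
        Group label forming the target side; all other labelled samples form
        the out-group.
    thresholds
        Selection thresholds; defaults to AUC >= 0.8 and \\|delta beta\\| >= 0.2.
    cap
        Optional maximum number of markers per contrast. Candidates are
        ordered by (distance of AUC from 0.5 desc, \\|delta\\| desc, probe_id)
        and hyper/hypo directions are balanced by alternating picks while
        both lists are non-empty.
    min_n
        Minimum usable samples per side for a CpG to be tested.
    return_all
        Return statistics for every tested CpG (with a ``selected`` column)
        instead of only the selected markers.

    Returns
    -------
    DataFrame with columns probe_id, contrast, U, p_value, q_value (BH over
    tested CpGs), auc, delta_beta, direction, n_target_used, n_rest_used.
    """
    th = thresholds or MarkerThresholds()
    groups = groups.dropna()
    if target not in set(groups):
        raise ValueError(f"target label {target!r} not present in groups")
    samples = [s for s in groups.index if s in bm.sample_ids]
    labels = groups.loc[samples]
    t_cols = [s for s in samples if labels[s] == target]
    r_cols = [s for s in samples if labels[s] != target]
    if len(t_cols) < min_n or len(r_cols) < min_n:
        warnings.warn(
            f"contrast {target!r} skipped: fewer than {min_n} samples on one side",
            stacklevel=2,
        )
        return pd.DataFrame(columns=_RESULT_COLUMNS)

    tmat = bm.data[t_cols].to_numpy()
    rmat = bm.data[r_cols].to_numpy()
    t_na = np.isnan(tmat).mean(axis=1)
    r_na = np.isnan(rmat).mean(axis=1)
    rows = []
    for i, probe in enumerate(bm.probe_ids):
        if t_na[i] > th.max_na_target or r_na[i] > th.max_na_rest:
            continue
        tv = tmat[i][~np.isnan(tmat[i])]
        rv = rmat[i][~np.isnan(rmat[i])]
        if len(tv) < min_n or len(rv) < min_n:
            continue
        if np.all(tv == tv[0]) and np.all(rv == rv[0]) and tv[0] == rv[0]:
            continue  # constant CpG carries no contrast information
        u, auc, p = _rank_stats(tv, rv)
        delta = float(tv.mean() - rv.mean())
        rows.append(
            (
                probe,
                target,
                u,
                p,
                np.nan,
                auc,
                delta,
                "hyper" if delta > 0 else "hypo",
                len(tv),
                len(rv),
            )
        )
    table = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    if table.empty:
        return table
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]

    keep = ((table["auc"] >= th.min_auc) | (table["auc"] <= 1 - th.min_auc)) & (
        table["delta_beta"].abs() >= th.min_delta
    )
    table["selected"] = keep
    selected = table[keep]
    if cap is not None and len(selected) > cap:
        chosen = _apply_cap(selected, cap)
        table["selected"] = table["probe_id"].isin(chosen)
        selected = table[table["selected"]]
    if return_all:
        return table.reset_index(drop=True)
    return selected.drop(columns="selected").reset_index(drop=True)


def _sort_candidates(df: pd.DataFrame) -> pd.DataFrame:
    return df.assign(
        _dist=(df["auc"] - 0.5).abs(), _adelta=df["delta_beta"].abs()
    ).sort_values(["_dist", "_adelta", "probe_id"], ascending=[False, False, True])


def _apply_cap(selected: pd.DataFrame, cap: int) -> list[str]:
    """Deterministic truncation to ``cap`` markers, balancing hyper and hypo."""
    hyper = _sort_candidates(selected[selected["direction"] == "hyper"])["probe_id"].tolist()
    hypo = _sort_candidates(selected[selected["direction"] == "hypo"])["probe_id"].tolist()
    chosen: list[str] = []
    while len(chosen) < cap and (hyper or hypo):
        if hyper:
            chosen.append(hyper.pop(0))
        if len(chosen) < cap and hypo:
            chosen.append(hypo.pop(0))
    return chosen


def one_vs_rest_all_contrasts(
    bm: BetaMatrix,
    groups: pd.Series,
    thresholds: MarkerThresholds | None = None,
    cap: int | None = None,
) -> pd.DataFrame:
    """Run :func:`one_vs_rest_markers` for every group label; concatenated result."""
    parts = [
        one_vs_rest_markers(bm, groups, target, thresholds=thresholds, cap=cap)
        for target in pd.unique(groups.dropna())
    ]
    parts = [p for p in parts if not p.empty]
    if not parts:
        return pd.DataFrame(columns=_RESULT_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def hierarchical_contrasts(
    bm: BetaMatrix,
    tree: pd.DataFrame,
    thresholds: MarkerThresholds | None = None,
    cap: int | None = None,
) -> dict[tuple, pd.DataFrame]:
    """One-vs-rest marker discovery at every node of a label hierarchy.

    ``tree`` is a sample-indexed frame whose columns are hierarchy levels
    (major type first, subtypes after). At level 0 each label is contrasted
    against all other samples; at deeper levels each label is contrasted only
    against its siblings (samples sharing the parent labels). Nodes with an
    empty sibling out-group are skipped.

    Returns a dict keyed by (level, parent-labels tuple, target label).
    """
    if tree.index.has_duplicates:
        raise ValueError("tree index (sample IDs) must be unique")
    results: dict[tuple, pd.DataFrame] = {}
    levels = list(tree.columns)
    for li, level in enumerate(levels):
        parents = levels[:li]
        parent_groups = (
            tree.groupby(parents, sort=False).groups if parents else {(): tree.index}
        )
        for parent_key, samples in parent_groups.items():
            key = parent_key if isinstance(parent_key, tuple) else (parent_key,)
            labels = tree.loc[samples, level].dropna()
            uniq = pd.unique(labels)
            if len(uniq) < 2:
                continue  # no sibling out-group at this node
            for target in uniq:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = one_vs_rest_markers(
                        bm, labels, target, thresholds=thresholds, cap=cap
                    )
                results[(li, key, target)] = res
    return results


def constitutive_screen(
    bm: BetaMatrix, lo: float = 0.2, hi: float = 0.8
) -> tuple[list[str], list[str]]:
    """Probes consistently unmodified (every beta < lo) or modified (> hi).

    NA cells are skipped; all-NA probes are excluded from both lists.
    """
    vals = bm.data.to_numpy()
    any_obs = ~np.all(np.isnan(vals), axis=1)
    with np.errstate(invalid="ignore"):
        all_lo = np.all(np.isnan(vals) | (vals < lo), axis=1) & any_obs
        all_hi = np.all(np.isnan(vals) | (vals > hi), axis=1) & any_obs
    probes = np.asarray(bm.probe_ids)
    return probes[all_lo].tolist(), probes[all_hi].tolist()


def intermediate_screen(
    bm: BetaMatrix,
    lo: float = 0.3,
    hi: float = 0.7,
    min_frac_samples: float = 1.0,
    min_n_samples: int | None = None,
    use_row_means: bool = False,
) -> list[str]:
    """Probes with intermediate methylation, candidates for monoallelic loci.

    Default: a probe is retained when the required fraction of its non-NA
    betas lies strictly inside (lo, hi). The design-time variant
    (``use_row_means=True`` with ``min_n_samples``) instead asks for the
    per-sample value to be inside the band in at least ``min_n_samples``
    samples, e.g. 140 of 180.
    """
    vals = bm.data.to_numpy()
    with np.errstate(invalid="ignore"):
        inside = (vals > lo) & (vals < hi)
    n_obs = np.sum(~np.isnan(vals), axis=1)
    n_inside = np.sum(inside & ~np.isnan(vals), axis=1)
    if min_n_samples is not None:
        keep = n_inside >= min_n_samples
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            keep = (n_obs > 0) & (n_inside >= min_frac_samples * n_obs)
    if use_row_means and min_n_samples is None:
        means = np.nanmean(vals, axis=1)
        keep = (n_obs > 0) & (means > lo) & (means < hi)
    return np.asarray(bm.probe_ids)[keep].tolist()


def variability_rank(
    bm: BetaMatrix, chrom_by_probe: pd.Series | None = None, autosomes_only: bool = False
) -> pd.DataFrame:
    """Probes ordered by cross-sample variability (sample SD, n-1).

    Descending SD, ties broken by probe_id. With ``autosomes_only`` the sex
    chromosomes (chrX/chrY/X/Y) are removed first (requires
    ``chrom_by_probe``).
    """
    data = bm.data
    if autosomes_only:
        if chrom_by_probe is None:
            raise ValueError("autosome filter requires chrom_by_probe")
        chroms = chrom_by_probe.reindex(data.index)
        sex = chroms.isin(["chrX", "chrY", "X", "Y"])
        data = data.loc[~sex.to_numpy()]
    vals = data.to_numpy()
    n = np.sum(~np.isnan(vals), axis=1)
    with np.errstate(invalid="ignore"):
        sd = np.where(n >= 2, np.nanstd(vals, axis=1, ddof=1), np.nan)
    out = pd.DataFrame({"probe_id": data.index, "sd": sd})
    return (
        out.sort_values(["sd", "probe_id"], ascending=[False, True], na_position="last")
        .reset_index(drop=True)
    )


def tissue_specific_features(
    expr: pd.DataFrame,
    thresholds: MarkerThresholds | None = None,
    groups: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Group-biased features from any numeric table (e.g. genes x tissues TPM).

    Identical machinery to one-vs-rest marker discovery; delta is on the
    table's own scale. When ``groups`` is omitted every column is its own
    single-observation group (AUC computed over per-group values), matching
    the median-per-tissue expression use case.

    Defaults follow the expression convention AUC > 0.8, delta > 1.0.
    """
    th = thresholds or MarkerThresholds(min_auc=0.8, min_delta=1.0, max_na_target=1.0, max_na_rest=1.0)
    if groups is None:
        groups = pd.Series(expr.columns, index=expr.columns)
    bm = BetaMatrix.__new__(BetaMatrix)  # feature tables need no [0,1] validation
    bm.data = expr.astype(float)
    out: dict[str, pd.DataFrame] = {}
    for target in pd.unique(groups.dropna()):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = one_vs_rest_markers(bm, groups, target, thresholds=th, min_n=1)
        out[target] = res
    return out
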