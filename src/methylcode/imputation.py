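"""Cross-platform nearest-neighbor probe imputation.

A condensed array drops many legacy probes. For each dropped (query) site, a
neighbor is found among retained sites by Euclidean distance across a
reference methylome collection; neighbors whose cross-sample Pearson
correlation exceeds a gate (default r > 0.5, strict) may substitute for the
missing probe when applying legacy models to new-platform data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from methylcode.io import BetaMatrix

__all__ = ["build_neighbor_map", "substitute_betas"]


def _complete_vectors(ref: pd.DataFrame, probes: list[str]) -> np.ndarray:
    """Per-probe mean imputation of NA cells (distances need complete vectors)."""
    a = ref.loc[probes].to_numpy(dtype=float)
    row_mean = np.nanmean(a, axis=1)
    idx = np.where(np.isnan(a))
    a[idx] = np.take(row_mean, idx[0])
    return a


def build_neighbor_map(
    reference: BetaMatrix,
    retained_sites: list[str],
    query_sites: list[str],
    k: int = 50,
    r_min: float = 0.5,
) -> pd.DataFrame:
    """Nearest retained site for every query site over the reference samples.

    Distances are Euclidean over per-probe mean-imputed sample vectors; among
    the ``k`` nearest candidates the single lowest-distance site is recorded
    (ties broken by higher Pearson r, then probe_id) together with its
    cross-sample Pearson r; ``retained`` = (r > r_min), strict. The search is
    exhaustive, which is exactly equivalent to a k-NN graph query followed by
    a lowest-distance pick. Query sites absent from the reference are listed
    in the ``skipped`` attribute of the result and omitted.

    Returns a frame indexed by query probe with columns neighbor, distance,
    r, retained.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if reference.shape[1] < 3:
        raise ValueError("need at least 3 reference samples")
    ref = reference.data
    retained = [p for p in retained_sites if p in ref.index]
    missing_ret = sorted(set(retained_sites) - set(retained))
    if not retained:
        raise ValueError("no retained sites present in reference")
    queries = [p for p in query_sites if p in ref.index]
    skipped = sorted(set(query_sites) - set(queries))

    R = _complete_vectors(ref, retained)  # n_retained x n_samples
    Q = _complete_vectors(ref, queries)

    # standardized copies for Pearson r
    def _std(a: np.ndarray) -> np.ndarray:
        c = a - a.mean(axis=1, keepdims=True)
        n = np.linalg.norm(c, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, c / n, 0.0)

    Rs, Qs = _std(R), _std(Q)
    ret_ids = np.asarray(retained)
    ret_pos = {p: i for i, p in enumerate(retained)}
    rows = []
    block = 256  # bound the distance-matrix memory
    r_norm2 = np.einsum("ij,ij->i", R, R)
    for b0 in range(0, len(queries), block):
        qb = Q[b0 : b0 + block]
        d2 = (
            np.einsum("ij,ij->i", qb, qb)[:, None]
            - 2.0 * qb @ R.T
            + r_norm2[None, :]
        )
        np.maximum(d2, 0.0, out=d2)
        rb = Qs[b0 : b0 + block] @ Rs.T
        for i in range(qb.shape[0]):
            qid = queries[b0 + i]
            di, ri = d2[i], rb[i]
            if qid in ret_pos:  # self-match = pass-through, not imputation
                best = ret_pos[qid]
            else:
                order = np.lexsort((ret_ids, -ri, di))  # distance, then higher r, then id
                best = order[0]
            # recompute directly: the expanded-norm identity loses ~1e-8 to
            # cancellation, which matters for exact-copy queries
            dist = float(np.linalg.norm(qb[i] - R[best]))
            r = float(ri[best])
            rows.append((qid, ret_ids[best], dist, r, r > r_min))
    out = pd.DataFrame(
        rows, columns=["query", "neighbor", "distance", "r", "retained"]
    ).set_index("query")
    out.attrs["skipped"] = skipped
    out.attrs["missing_retained"] = missing_ret
    return out


def substitute_betas(
    target: BetaMatrix,
    neighbor_map: pd.DataFrame,
    wanted: list[str],
) -> tuple[BetaMatrix, dict]:
    """Reconstruct a legacy probe space from new-platform betas.

    Wanted probes present on the new platform pass through unchanged;
    otherwise the retained neighbor's beta is emitted under the legacy
    probe's ID; probes with no retained neighbor come back as all-NA columns
    (rows). Returns the legacy-space matrix and a tally report.
    """
    data = target.data
    cols = data.columns
    out = {}
    tally = {"pass_through": 0, "substituted": 0, "na": 0}
    for probe in wanted:
        if probe in data.index:
            out[probe] = data.loc[probe].to_numpy()
            tally["pass_through"] += 1
            continue
        if probe in neighbor_map.index:
            rec = neighbor_map.loc[probe]
            if bool(rec["retained"]) and rec["neighbor"] in data.index:
                out[probe] = data.loc[rec["neighbor"]].to_numpy()
                tally["substituted"] += 1
                continue
        out[probe] = np.full(len(cols), np.nan)
        tally["na"] += 1
    df = pd.DataFrame.from_dict(out, orient="index", columns=cols)
    return BetaMatrix(df, validate=False), tally
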