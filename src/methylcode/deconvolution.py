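"""Reference-based cell-type deconvolution of bulk methylation profiles.

A reference panel holds mean betas of marker CpGs per cell type; bulk
proportions are estimated by regressing the bulk betas on the panel columns.
The primary solver follows the robust-partial-correlations contract: Huber
robust linear regression (no intercept), negative coefficients truncated to
zero, and renormalization to a probability vector. A non-negative
least-squares solver is provided as an independent cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import nnls

from methylcode.io import BetaMatrix

__all__ = ["ReferencePanel", "build_reference", "rpc_deconvolve", "nnls_deconvolve"]


@dataclass
class ReferencePanel:
    """Markers x cell types table of mean betas."""

    table: pd.DataFrame  # index: marker probe IDs; columns: cell types

    def __post_init__(self):
        vals = self.table.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 1) & ~np.isnan(vals)):
                raise ValueError("panel values outside [0, 1]")
        all_na = np.all(np.isnan(vals), axis=1)
        if all_na.any():
            raise ValueError(
                f"all-NA marker rows in panel: {list(self.table.index[all_na][:5])}"
            )

    @property
    def celltype_ids(self) -> pd.Index:
        return self.table.columns

    @property
    def marker_ids(self) -> pd.Index:
        return self.table.index


def build_reference(
    refs: BetaMatrix,
    markers: pd.DataFrame | list[pd.DataFrame],
    groups: pd.Series | None = None,
) -> ReferencePanel:
    """Reference panel from archetype/sorted-cell betas at marker CpGs.

    ``markers`` is one or several marker tables (needing a ``probe_id``
    column); the union of their probes, deduplicated, forms the panel rows.
    When ``groups`` maps samples to cell types, panel cells are the mean beta
    over each type's replicate samples (NA-skipping); otherwise ``refs``
    columns are taken as cell types directly. Marker probes absent from
    ``refs`` are dropped with a warning.
    """
    if isinstance(markers, pd.DataFrame):
        markers = [markers]
    wanted: list[str] = []
    seen = set()
    for m in markers:
        for p in m["probe_id"]:
            if p not in seen:
                seen.add(p)
                wanted.append(p)
    present = [p for p in wanted if p in refs.probe_ids]
    missing = sorted(set(wanted) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} marker probes absent from reference; dropped", stacklevel=2)
    if not present:
        raise ValueError("no marker probes present in reference")
    sub = refs.data.loc[present]
    if groups is not None:
        cols = {}
        for ct in pd.unique(groups.dropna()):
            members = [s for s in groups.index[groups == ct] if s in sub.columns]
            cols[ct] = sub[members].mean(axis=1)
        sub = pd.DataFrame(cols)
    return ReferencePanel(sub)


def _proportions_frame(
    rows: list[tuple], celltypes: pd.Index
) -> pd.DataFrame:
    recs = []
    for sid, p, resid, n_used, converged in rows:
        rec = {"sample_id": sid, **dict(zip(celltypes, p))}
        rec["residual_norm"] = resid
        rec["n_markers_used"] = n_used
        rec["converged"] = converged
        recs.append(rec)
    return pd.DataFrame(recs).set_index("sample_id")


def _finalize(coef: np.ndarray) -> np.ndarray:
    p = np.where(coef < 0, 0.0, coef)
    total = p.sum()
    if total <= 0:
        return np.full_like(p, 1.0 / len(p))
    return p / total


def rpc_deconvolve(
    bulk: BetaMatrix,
    panel: ReferencePanel,
    huber_c: float = 1.345,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Robust-partial-correlations deconvolution of each bulk sample.

    Per sample: Huber IRLS regression (tuning constant ``huber_c``, 95%
    Gaussian efficiency; no intercept) of the bulk betas on the panel
    columns over pairwise-complete markers, then truncation of negative
    coefficients to 0 and renormalization to sum 1.

    Returns a frame indexed by sample with one column per cell type plus
    ``residual_norm``, ``n_markers_used`` and ``converged``.
    """
    X_full = panel.table.to_numpy(dtype=float)
    k = X_full.shape[1]
    if np.linalg.matrix_rank(np.nan_to_num(X_full)) < k:
        corr = np.corrcoef(np.nan_to_num(X_full).T)
        pairs = [
            (panel.celltype_ids[i], panel.celltype_ids[j])
            for i in range(k)
            for j in range(i + 1, k)
            if abs(corr[i, j]) > 1 - 1e-9
        ]
        raise ValueError(f"rank-deficient reference panel; collinear cell types: {pairs}")
    shared = [p for p in panel.marker_ids if p in bulk.probe_ids]
    if len(shared) < k:
        raise ValueError("fewer shared markers than cell types")
    y_all = bulk.data.loc[shared]
    X_shared = panel.table.loc[shared].to_numpy(dtype=float)
    rows = []
    for sid in bulk.sample_ids:
        y = y_all[sid].to_numpy(dtype=float)
        ok = ~np.isnan(y) & ~np.isnan(X_shared).any(axis=1)
        if ok.sum() < k:
            raise ValueError(f"sample {sid!r}: fewer usable markers than cell types")
        X, yv = X_shared[ok], y[ok]
        ols_coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
        converged = True
        if np.linalg.norm(yv - X @ ols_coef) < 1e-9 * max(1.0, np.linalg.norm(yv)):
            coef = ols_coef  # consistent system: IRLS scale would degenerate
        else:
            model = sm.RLM(yv, X, M=sm.robust.norms.HuberT(t=huber_c))
            try:
                fit = model.fit(maxiter=max_iter, tol=tol)
                coef = np.asarray(fit.params)
            except Exception:  # pragma: no cover - IRLS breakdown fallback
                coef = ols_coef
                converged = False
        p = _finalize(coef)
        resid = float(np.linalg.norm(yv - X @ coef))
        rows.append((sid, p, resid, int(ok.sum()), converged))
    return _proportions_frame(rows, panel.celltype_ids)


def nnls_deconvolve(bulk: BetaMatrix, panel: ReferencePanel) -> pd.DataFrame:
    """Non-negative least-squares deconvolution (cross-check solver)."""
    shared = [p for p in panel.marker_ids if p in bulk.probe_ids]
    X_shared = panel.table.loc[shared].to_numpy(dtype=float)
    k = X_shared.shape[1]
    if len(shared) < k:
        raise ValueError("fewer shared markers than cell types")
    y_all = bulk.data.loc[shared]
    rows = []
    for sid in bulk.sample_ids:
        y = y_all[sid].to_numpy(dtype=float)
        ok = ~np.isnan(y) & ~np.isnan(X_shared).any(axis=1)
        if ok.sum() == 0:
            raise ValueError(f"sample {sid!r}: no usable markers after NA removal")
        if ok.sum() < k:
            raise ValueError(f"sample {sid!r}: fewer usable markers than cell types")
        coef, rnorm = nnls(X_shared[ok], y[ok])
        rows.append((sid, _finalize(coef), float(rnorm), int(ok.sum()), True))
    return _proportions_frame(rows, panel.celltype_ids)
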