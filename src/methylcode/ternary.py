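"""Ternary decomposition of matched 5modC / 5hmC beta matrices.

Standard bisulfite conversion measures total modification (5modC = 5mC +
5hmC); a matched APOBEC-based experiment measures 5hmC directly. Subtracting
the two yields a per-CpG ternary code (5mC, 5hmC, unmodified C) summing to 1.
Measurement noise can push 5modC - 5hmC below zero; such cells are clamped to
0 and flagged rather than renormalized, so the 5hmC reading is preserved and
the violation stays auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from methylcode.io import BetaMatrix, SampleSheet

__all__ = ["TernaryProfile", "decompose", "global_ternary_means", "ratio_by_hmc_bin"]


@dataclass
class TernaryProfile:
    """Per-CpG decomposition into 5mC, 5hmC and unmodified C.

    All three component frames share probe/sample axes; for every non-NA cell
    the components are non-negative and sum to 1 within 1e-9. ``clamped_mask``
    marks cells where 5modC - 5hmC was negative before clamping.
    """

    five_mC: pd.DataFrame
    five_hmC: pd.DataFrame
    unmod_C: pd.DataFrame
    clamped_mask: pd.DataFrame

    @property
    def clamped_fraction(self) -> float:
        valid = ~np.isnan(self.five_mC.to_numpy())
        n = valid.sum()
        return float(self.clamped_mask.to_numpy()[valid].sum() / n) if n else float("nan")


def decompose(modc: BetaMatrix, hmc: BetaMatrix, pairs: pd.DataFrame | None = None) -> TernaryProfile:
    """Decompose matched 5modC and 5hmC matrices into the ternary code.

    Parameters
    ----------
    modc, hmc
        Beta matrices on the same probes. Samples are matched positionally by
        identical IDs, or explicitly through ``pairs``.
    pairs
        Optional two-column frame (``modc_sample``, ``hmc_sample``) pairing a
        5modC sample with its matched 5hmC sample (same donor, two
        chemistries). Output columns use the 5modC sample IDs.

    Returns
    -------
    TernaryProfile
        5mC = max(0, 5modC - 5hmC); unmodified C = 1 - 5modC. NA in either
        input propagates to all components of that cell.
    """
    if not modc.probe_ids.equals(hmc.probe_ids):
        common = modc.probe_ids.intersection(hmc.probe_ids)
        if len(common) == 0:
            raise ValueError("5modC and 5hmC matrices share no probes")
        modc = modc.subset_probes(common)
        hmc = hmc.subset_probes(common)
    if pairs is None:
        unpaired = modc.sample_ids.symmetric_difference(hmc.sample_ids)
        if len(unpaired):
            raise ValueError(f"unpaired samples between 5modC and 5hmC: {list(unpaired[:10])}")
        hmc_cols = modc.sample_ids
        out_cols = modc.sample_ids
        m = modc.data.to_numpy()
        h = hmc.data.loc[:, hmc_cols].to_numpy()
    else:
        missing_m = set(pairs["modc_sample"]) - set(modc.sample_ids)
        missing_h = set(pairs["hmc_sample"]) - set(hmc.sample_ids)
        if missing_m or missing_h:
            raise ValueError(
                f"pairing refers to absent samples: {sorted(missing_m | missing_h)[:10]}"
            )
        out_cols = pd.Index(pairs["modc_sample"])
        m = modc.data.loc[:, out_cols].to_numpy()
        h = hmc.data.loc[:, pairs["hmc_sample"]].to_numpy()

    na = np.isnan(m) | np.isnan(h)
    with np.errstate(invalid="ignore"):
        raw_mc = m - h
        clamped = (raw_mc < 0) & ~na
        mc = np.where(clamped, 0.0, raw_mc)
        c = np.maximum(1.0 - m, 0.0)
    mc[na] = np.nan
    hm = h.copy()
    hm[na] = np.nan
    c[na] = np.nan
    # closure: where 5mC was clamped, 5hmC + C may exceed 1; rescale only C so
    # the flagged 5hmC reading is kept as measured
    over = clamped & ((hm + c) > 1.0)
    c[over] = 1.0 - hm[over]
    idx, cols = modc.probe_ids, out_cols
    as_df = lambda a: pd.DataFrame(a, index=idx, columns=cols)
    return TernaryProfile(as_df(mc), as_df(hm), as_df(c), as_df(clamped).astype(bool))


def global_ternary_means(
    tp: TernaryProfile, sheet: SampleSheet, group_by: str = "tissue"
) -> pd.DataFrame:
    """Mean 5mC / 5hmC / unmodified C per sample group, over non-NA cells.

    Groups without samples in the profile are omitted with a warning. The
    three means sum to 1 for each group (non-NA cells coincide across
    components by construction).
    """
    groups = sheet.groups(group_by)
    rows = []
    for label in pd.unique(groups):
        samples = [s for s in groups.index[groups == label] if s in tp.five_mC.columns]
        if not samples:
            warnings.warn(f"group {label!r} has no samples in profile; omitted", stacklevel=2)
            continue
        mc = tp.five_mC[samples].to_numpy()
        rows.append(
            (
                label,
                float(np.nanmean(mc)),
                float(np.nanmean(tp.five_hmC[samples].to_numpy())),
                float(np.nanmean(tp.unmod_C[samples].to_numpy())),
                len(samples),
            )
        )
    return pd.DataFrame(rows, columns=["group", "mean_5mC", "mean_5hmC", "mean_C", "n_samples"])


def ratio_by_hmc_bin(tp: TernaryProfile, bins: np.ndarray | list[float]) -> pd.DataFrame:
    """Mean 5mC / (5mC + unmodified C) within bins of the 5hmC level.

    Bins are left-closed right-open over [0, 1], the last bin closed. Cells
    where 5mC + C = 0 have an undefined ratio and are excluded. A rising
    profile indicates 5hmC concentrating on methylated background.
    """
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing with >= 2 edges")
    hm = tp.five_hmC.to_numpy().ravel()
    mc = tp.five_mC.to_numpy().ravel()
    c = tp.unmod_C.to_numpy().ravel()
    valid = ~np.isnan(hm) & ~np.isnan(mc) & ~np.isnan(c) & ((mc + c) > 0)
    hm, mc, c = hm[valid], mc[valid], c[valid]
    ratio = mc / (mc + c)
    which = np.digitize(hm, edges, right=False) - 1
    which[hm == edges[-1]] = len(edges) - 2  # last bin closed on the right
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        rows.append(
            (
                edges[b],
                edges[b + 1],
                int(sel.sum()),
                float(ratio[sel].mean()) if sel.any() else float("nan"),
            )
        )
    return pd.DataFrame(rows, columns=["bin_left", "bin_right", "n_cells", "mean_ratio"])
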