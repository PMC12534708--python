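"""Per-CpG EWAS linear models, elastic-net age clocks, and sex scoring.

The EWAS fits, per CpG, ordinary least squares of beta on Age + Sex + Tissue
(categoricals dummy-coded against a reference level) with two-sided t-tests
and BH q-values per coefficient family. Age clocks are trained by
leave-one-out cross-validation with feature selection strictly inside each
fold: for every held-out sample, an EWAS on the remaining samples picks the
CpGs with the smallest age p-values, and an elastic net (mixing parameter
alpha, penalty chosen by seeded inner cross-validation minimizing squared
error) predicts the held-out age from those betas alone.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from methylcode.io import BetaMatrix, SampleSheet

__all__ = [
    "build_design",
    "fit_linear_ewas",
    "ClockModel",
    "loocv_clock",
    "apply_clock",
    "sex_score",
]


def build_design(
    sheet: SampleSheet,
    covariates: tuple[str, ...] = ("age", "sex", "tissue"),
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Design matrix with intercept; categoricals dummy-coded, first level reference."""
    t = sheet.table.set_index("sample_id")
    if samples is not None:
        t = t.loc[samples]
    cols = {"intercept": np.ones(len(t))}
    for cov in covariates:
        if cov not in t.columns:
            raise ValueError(f"covariate {cov!r} absent from sample sheet")
        if cov == "age":
            cols["age"] = t["age"].to_numpy(dtype=float)
        else:
            levels = sorted(pd.unique(t[cov].dropna()))
            for lev in levels[1:]:  # first level is the reference
                cols[f"{cov}[{lev}]"] = (t[cov] == lev).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=t.index)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing covariate values in design columns {bad}")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _aliased_columns(X.to_numpy(), list(X.columns))
        raise ValueError(f"collinear design; aliased columns: {aliased}")
    return X


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    aliased, kept = [], []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) < len(kept) + 1:
            aliased.append(names[j])
        else:
            kept.append(j)
    return aliased


def fit_linear_ewas(
    bm: BetaMatrix,
    sheet: SampleSheet,
    covariates: tuple[str, ...] = ("age", "sex", "tissue"),
) -> pd.DataFrame:
    """Per-CpG OLS of beta on the covariates; BH q-values per coefficient.

    CpGs with fewer than rank(design) + 2 non-NA samples come back as all-NA
    rows; CpGs with zero residual variance get NA p-values (not 0). Output
    columns: coef_/se_/t_/p_/q_ per design column plus n_used.
    """
    X_full = build_design(sheet, covariates)
    samples = [s for s in X_full.index if s in bm.sample_ids]
    X_full = X_full.loc[samples]
    Y = bm.data[samples].to_numpy()
    Xv = X_full.to_numpy()
    names = list(X_full.columns)
    p_cols = len(names)
    n_probes = Y.shape[0]
    rank = np.linalg.matrix_rank(Xv)
    floor = rank + 2

    coefs = np.full((n_probes, p_cols), np.nan)
    ses = np.full((n_probes, p_cols), np.nan)
    tstats = np.full((n_probes, p_cols), np.nan)
    pvals = np.full((n_probes, p_cols), np.nan)
    n_used = np.zeros(n_probes, dtype=int)

    na_mask = np.isnan(Y)
    # group probes by NA pattern so each distinct design solve is vectorized
    pattern_ids = {}
    pattern_of = np.empty(n_probes, dtype=int)
    for i in range(n_probes):
        key = na_mask[i].tobytes()
        pattern_of[i] = pattern_ids.setdefault(key, len(pattern_ids))
    for pid in range(len(pattern_ids)):
        rows = np.flatnonzero(pattern_of == pid)
        obs = ~na_mask[rows[0]]
        n_obs = int(obs.sum())
        n_used[rows] = n_obs
        if n_obs < floor:
            continue
        Xs = Xv[obs]
        if np.linalg.matrix_rank(Xs) < p_cols:
            continue
        Ys = Y[np.ix_(rows, obs)]
        XtX_inv = np.linalg.inv(Xs.T @ Xs)
        B = XtX_inv @ Xs.T @ Ys.T  # p_cols x n_rows
        resid = Ys.T - Xs @ B
        dof = n_obs - p_cols
        s2 = np.sum(resid**2, axis=0) / dof
        se = np.sqrt(np.outer(np.diag(XtX_inv), s2))
        coefs[rows] = B.T
        ses[rows] = se.T
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se.T > 0, B.T / se.T, np.nan)
        # zero residual variance: a perfect fit gives t = +/-inf (p = 0) for
        # nonzero coefficients, but a constant row (0/0) has no inference
        degenerate = s2 <= 1e-28
        if degenerate.any():
            coef_deg = B.T[degenerate, :]
            t_deg = np.where(np.abs(coef_deg) > 1e-10, np.inf * np.sign(coef_deg), np.nan)
            t[degenerate, :] = t_deg
        tstats[rows] = t
        pvals[rows] = 2.0 * stats.t.sf(np.abs(t), dof)

    out = pd.DataFrame(index=bm.probe_ids)
    for j, name in enumerate(names):
        out[f"coef_{name}"] = coefs[:, j]
        out[f"se_{name}"] = ses[:, j]
        out[f"t_{name}"] = tstats[:, j]
        out[f"p_{name}"] = pvals[:, j]
        pj = pvals[:, j]
        q = np.full_like(pj, np.nan)
        ok = ~np.isnan(pj)
        if ok.any():
            q[ok] = multipletests(pj[ok], method="fdr_bh")[1]
        out[f"q_{name}"] = q
    out["n_used"] = n_used
    out.attrs["design_columns"] = names
    out.attrs["dof"] = int(len(samples) - rank)
    return out


# ---------------------------------------------------------------------------
# clocks


@dataclass
class ClockModel:
    """Linear age predictor: intercept + sum(w_i * beta_i).

    ``training_means`` are per-probe mean betas from training, used by the
    mean-impute missing policy. ``transform`` tags an optional user-supplied
    invertible response transform applied at training time; prediction
    applies its inverse.
    """

    weights: pd.Series  # probe -> weight, beta scale
    intercept: float
    training_means: pd.Series
    transform: str = "identity"
    inverse_transform: object = None  # callable for non-identity transforms
    metadata: dict = field(default_factory=dict)

    def predict(self, betas: pd.DataFrame) -> pd.Series:
        """Predict from a probes x samples frame covering all clock probes."""
        X = betas.loc[self.weights.index]
        raw = X.T @ self.weights + self.intercept
        if self.transform != "identity":
            if self.inverse_transform is None:
                raise ValueError(f"no inverse supplied for transform {self.transform!r}")
            raw = raw.map(self.inverse_transform)
        return raw

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.weights.rename("weight").rename_axis("probe_id").to_csv(
            prefix.with_suffix(".weights.csv")
        )
        header = {
            "intercept": float(self.intercept),
            "transform": self.transform,
            "training_means": {str(k): float(v) for k, v in self.training_means.items()},
            "metadata": {k: (v if isinstance(v, (int, float, str, bool)) else str(v)) for k, v in self.metadata.items()},
        }
        prefix.with_suffix(".model.yaml").write_text(yaml.safe_dump(header))

    @classmethod
    def load(cls, prefix: str | Path) -> "ClockModel":
        prefix = Path(prefix)
        w = pd.read_csv(prefix.with_suffix(".weights.csv"), index_col=0)["weight"]
        header = yaml.safe_load(prefix.with_suffix(".model.yaml").read_text())
        return cls(
            weights=w,
            intercept=float(header["intercept"]),
            training_means=pd.Series(header["training_means"]),
            transform=header.get("transform", "identity"),
            metadata=header.get("metadata", {}),
        )


def _fold_seed(seed: int, sample_id: str) -> int:
    """Deterministic per-fold RNG seed keyed by held-out sample ID, not position."""
    return (seed * 1_000_003 + zlib.crc32(sample_id.encode())) % (2**31)


def _select_age_features(
    bm: BetaMatrix, sheet: SampleSheet, samples: list[str], n_features: int,
    covariates: tuple[str, ...],
) -> list[str]:
    sub_sheet = SampleSheet(
        sheet.table[sheet.table["sample_id"].isin(samples)].sort_values("sample_id")
    )
    res = fit_linear_ewas(bm.subset_samples(samples), sub_sheet, covariates)
    ps = res["p_age"].dropna()
    order = sorted(ps.index, key=lambda probe: (ps[probe], probe))  # p, then probe_id
    return order[:n_features]


def _fit_elastic_net(
    X: np.ndarray, y: np.ndarray, alpha: float, inner_folds: int, rng_seed: int
) -> tuple[np.ndarray, float]:
    """Standardized elastic net, penalty by inner CV; weights on the input scale."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    cv = KFold(n_splits=min(inner_folds, len(y)), shuffle=True, random_state=rng_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        enet = ElasticNetCV(l1_ratio=alpha, cv=cv, alphas=60, max_iter=5000)
        enet.fit(Xs, y)
    w = enet.coef_ / sd
    b0 = float(enet.intercept_ - np.sum(enet.coef_ * mu / sd))
    return w, b0


def loocv_clock(
    bm: BetaMatrix,
    sheet: SampleSheet,
    n_features: int = 50,
    alpha: float = 0.5,
    inner_folds: int = 10,
    seed: int = 0,
    covariates: tuple[str, ...] = ("age", "sex", "tissue"),
) -> dict:
    """Leave-one-out elastic-net age clock with in-fold feature selection.

    For each held-out sample: EWAS on the remaining samples, the
    ``n_features`` CpGs with the smallest age p-values (ties broken by
    probe_id) become predictors, and a seeded inner-CV elastic net
    (mixing ``alpha``) predicts the held-out age. Only CpG betas enter the
    elastic net; sex/tissue covariates act solely in feature selection.
    Training-set NA betas are mean-imputed per probe.

    Returns {"predictions": DataFrame(sample_id, age, predicted), "mae",
    "pearson_r", "model": final ClockModel retrained on all samples}.
    """
    t = sheet.table
    if t["age"].isna().any():
        raise ValueError("all samples need a non-NA age for clock training")
    # canonical sample order: fold assignment and float reductions then do
    # not depend on how the caller ordered the cohort
    samples = sorted(s for s in t["sample_id"] if s in bm.sample_ids)
    if len(samples) < 10:
        raise ValueError("need at least 10 samples for LOOCV clock training")
    ages = t.set_index("sample_id")["age"].astype(float)

    preds = {}
    for held in samples:
        train = [s for s in samples if s != held]
        feats = _select_age_features(bm, sheet, train, n_features, covariates)
        if len(feats) < n_features:
            warnings.warn(
                f"fold {held!r}: only {len(feats)} usable CpGs for selection",
                stacklevel=2,
            )
        if not feats:
            preds[held] = float(ages.loc[train].mean())
            continue
        Xtr = bm.data.loc[feats, train].T.to_numpy()
        col_mean = np.nanmean(Xtr, axis=0)
        inds = np.where(np.isnan(Xtr))
        Xtr[inds] = np.take(col_mean, inds[1])
        w, b0 = _fit_elastic_net(
            Xtr, ages.loc[train].to_numpy(), alpha, inner_folds, _fold_seed(seed, held)
        )
        xh = bm.data.loc[feats, held].to_numpy(dtype=float)
        xh = np.where(np.isnan(xh), col_mean, xh)
        preds[held] = float(xh @ w + b0)

    pred_df = pd.DataFrame(
        {"age": ages.loc[samples], "predicted": [preds[s] for s in samples]},
        index=pd.Index(samples, name="sample_id"),
    )
    err = pred_df["predicted"] - pred_df["age"]
    mae = float(err.abs().mean())
    r = float(np.corrcoef(pred_df["age"], pred_df["predicted"])[0, 1])

    # final model: same recipe on all samples
    feats = _select_age_features(bm, sheet, samples, n_features, covariates)
    Xall = bm.data.loc[feats, samples].T.to_numpy()
    col_mean = np.nanmean(Xall, axis=0)
    inds = np.where(np.isnan(Xall))
    Xall[inds] = np.take(col_mean, inds[1])
    w, b0 = _fit_elastic_net(
        Xall, ages.loc[samples].to_numpy(), alpha, inner_folds, _fold_seed(seed, "__final__")
    )
    model = ClockModel(
        weights=pd.Series(w, index=feats, name="weight"),
        intercept=b0,
        training_means=pd.Series(col_mean, index=feats),
        metadata={"alpha": alpha, "inner_folds": inner_folds, "seed": seed,
                  "n_features": n_features, "fold_scheme": "loocv"},
    )
    return {"predictions": pred_df, "mae": mae, "pearson_r": r, "model": model}


def apply_clock(
    bm: BetaMatrix,
    model: ClockModel,
    missing_policy: str = "error",
    neighbor_map: pd.DataFrame | None = None,
) -> pd.Series:
    """Apply a clock to a beta matrix under a policy for absent probes.

    ``error`` refuses when any clock probe is absent; ``mean_impute`` fills
    absent probes (and NA cells) with stored training means; ``neighbor_map``
    substitutes retained nearest-neighbor probes first (cross-platform use)
    and then mean-imputes what remains.
    """
    from methylcode.imputation import substitute_betas

    wanted = list(model.weights.index)
    data = bm.data
    if missing_policy == "neighbor_map":
        if neighbor_map is None:
            raise ValueError("neighbor_map policy requires a neighbor map")
        sub, _ = substitute_betas(bm, neighbor_map, wanted)
        data = sub.data
        missing_policy = "mean_impute"
    absent = [p for p in wanted if p not in data.index]
    if missing_policy == "error":
        if absent:
            raise KeyError(f"clock probes absent from matrix: {absent[:10]}")
        X = data.loc[wanted]
    elif missing_policy == "mean_impute":
        X = data.reindex(wanted)
        means = model.training_means.reindex(wanted)
        X = X.apply(lambda col: col.fillna(means), axis=0)
    else:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    return model.predict(X)


def sex_score(
    bm: BetaMatrix,
    male_hyper: list | set,
    male_hypo: list | set,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Sex score: mean beta over male-hyper CpGs minus mean over male-hypo CpGs.

    Predicted male iff score > threshold (strict; a score exactly at the
    threshold is called female).
    """
    hyper = [p for p in male_hyper if p in bm.probe_ids]
    hypo = [p for p in male_hypo if p in bm.probe_ids]
    if not hyper and not hypo:
        raise ValueError("no sex-associated probes present in matrix")
    hyper_mean = (
        bm.data.loc[hyper].mean(axis=0, skipna=True) if hyper else pd.Series(0.0, index=bm.sample_ids)
    )
    hypo_mean = (
        bm.data.loc[hypo].mean(axis=0, skipna=True) if hypo else pd.Series(0.0, index=bm.sample_ids)
    )
    score = hyper_mean - hypo_mean
    return pd.DataFrame(
        {
            "score": score,
            "predicted_sex": np.where(score > threshold, "M", "F"),
        },
        index=bm.sample_ids,
    )
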