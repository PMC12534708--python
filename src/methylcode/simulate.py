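"""Synthetic beta-value data with full ground truth.

Generates the statistical structure the analysis stages assume: bimodal
tissue-structured betas, planted cell-type markers, Dirichlet bulk mixtures,
linear age effects, sex effects, an additive 5hmC layer bounded by total
modification, a two-platform probe split with correlated neighbors, and
annotation probe sets with planted odds ratios.

Noise model: Gaussian noise on the logit scale,
``beta' = logistic(logit(beta) + eps)``, which keeps values in [0, 1] and
mimics the heteroskedastic error of array betas (small variance near 0/1,
larger in the middle). Betas exactly at 0/1 are nudged by 1e-6 before the
logit. Missingness is injected completely at random. Every stochastic call
takes a mandatory seed and uses a single RNG stream, so identical seeds give
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from methylcode.io import BetaMatrix, ProbeManifest, SampleSheet, GenomicIntervalSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "logit_noise",
    "simulate_references",
    "simulate_group_samples",
    "simulate_mixtures",
    "simulate_cohort",
    "simulate_two_platform",
    "simulate_annotations",
    "manifest_for_probes",
]

_EPS = 1e-6
_LOW_MODE = 0.1
_HIGH_MODE = 0.9


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the effect sizes the downstream thresholds are built
    around: planted marker delta-beta 0.4 against logit-scale noise 0.5,
    per-year age slopes of 0.003-0.005 beta, a sex offset of 0.5 beta at
    sex-CpGs, group-dependent 5hmC fractions concentrated on methylated
    background, and uniform Dirichlet mixing.
    """

    n_probes: int = 5000
    n_celltypes: int = 5
    n_samples: int = 40
    n_markers_per_type: int = 20  # half hyper, half hypo
    marker_delta: float = 0.4
    noise_sd: float = 0.5  # logit-scale
    age_slope_range: tuple[float, float] = (0.003, 0.005)  # beta per year
    frac_age_cpgs: float = 0.02
    n_sex_cpgs: int = 20
    sex_delta: float = 0.5
    frac_imprinted: float = 0.01  # stable intermediate (monoallelic-like) loci
    hmc_fraction_by_group: dict = field(
        default_factory=lambda: {"high": 0.25, "low": 0.02}
    )
    proliferation_range: tuple[float, float] = (0.3, 1.0)
    dirichlet_alpha: float = 1.0
    age_range: tuple[float, float] = (20.0, 80.0)
    na_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.marker_delta <= 0:
            raise ValueError("marker_delta must be positive")
        if self.n_celltypes < 2:
            raise ValueError("need at least 2 cell types")
        for frac in (self.frac_age_cpgs, self.na_rate):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure, addressable by ID, for recovery tests."""

    marker_ids: dict | None = None  # celltype -> DataFrame(probe_id, direction)
    mixture_proportions: pd.DataFrame | None = None  # samples x cell types
    age_cpgs: pd.DataFrame | None = None  # probe_id, slope
    sex_cpgs: dict | None = None  # {"male_hyper": [...], "male_hypo": [...]}
    imprinted_cpgs: list | None = None  # stable-intermediate loci near 0.5
    hmc_fraction: pd.Series | None = None  # per-probe 5hmC share of 5modC
    proliferation: pd.Series | None = None  # per-sample global 5hmC scalar
    hmc_pre_noise: pd.DataFrame | None = None
    archetypes: pd.DataFrame | None = None  # probes x cell types noiseless means
    neighbor_map: pd.Series | None = None  # query probe -> generator probe
    annotation_query: list | None = None
    annotation_or: dict | None = None

    def to_json(self, path: str | Path) -> None:
        def conv(v):
            if isinstance(v, pd.DataFrame):
                return v.to_dict(orient="list") | {"_index": list(map(str, v.index))}
            if isinstance(v, pd.Series):
                return {str(k): (None if pd.isna(x) else float(x) if np.isreal(x) else str(x)) for k, x in v.items()}
            if isinstance(v, dict):
                return {str(k): conv(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [conv(x) for x in v]
            return v

        dense = {"hmc_pre_noise", "archetypes"}  # full matrices stay out of the sidecar
        payload = {
            k: conv(v) for k, v in asdict(self).items() if v is not None and k not in dense
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


def logit_noise(values: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Apply Gaussian noise on the logit scale; sd=0 returns values unchanged."""
    values = np.asarray(values, dtype=float)
    if sd == 0:
        return values.copy()
    clipped = np.clip(values, _EPS, 1 - _EPS)
    return expit(logit(clipped) + rng.normal(0.0, sd, size=values.shape))


def _inject_na(values: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return values
    mask = rng.random(values.shape) < rate
    out = values.copy()
    out[mask] = np.nan
    return out


def simulate_references(cfg: SimulationConfig) -> tuple[BetaMatrix, GroundTruth]:
    """Cell-type archetype betas with planted one-vs-rest markers.

    Background probes sit at a bimodal baseline (low mode 0.1, high mode 0.9,
    jittered on the logit scale by ``noise_sd``/2 but shared across cell
    types, so non-markers carry no contrast). Each cell type receives
    ``n_markers_per_type`` markers — hyper markers raised by ``marker_delta``
    above a low background, hypo markers lowered below a high background —
    giving an exact one-vs-rest mean difference of ``marker_delta`` in the
    noiseless archetypes.
    """
    rng = np.random.default_rng(cfg.seed)
    probes = [f"cg{i:07d}" for i in range(cfg.n_probes)]
    types = [f"CT{k}" for k in range(cfg.n_celltypes)]
    n_markers_total = cfg.n_markers_per_type * cfg.n_celltypes
    if n_markers_total > cfg.n_probes:
        raise ValueError("more planted markers than probes")

    high = rng.random(cfg.n_probes) < 0.5
    base = np.where(high, _HIGH_MODE, _LOW_MODE)
    base = logit_noise(base, cfg.noise_sd / 2, rng)  # probe-level jitter
    arch = np.tile(base[:, None], (1, cfg.n_celltypes))

    marker_probes = rng.choice(cfg.n_probes, size=n_markers_total, replace=False)
    marker_ids: dict[str, pd.DataFrame] = {}
    half = cfg.n_markers_per_type // 2
    for k, ct in enumerate(types):
        mine = marker_probes[k * cfg.n_markers_per_type : (k + 1) * cfg.n_markers_per_type]
        recs = []
        for j, p in enumerate(mine):
            if j < cfg.n_markers_per_type - half:  # hyper
                lo = _LOW_MODE
                arch[p, :] = lo
                arch[p, k] = min(lo + cfg.marker_delta, 1 - _EPS)
                recs.append((probes[p], "hyper"))
            else:  # hypo
                hi = _HIGH_MODE
                arch[p, :] = hi
                arch[p, k] = max(hi - cfg.marker_delta, _EPS)
                recs.append((probes[p], "hypo"))
        marker_ids[ct] = pd.DataFrame(recs, columns=["probe_id", "direction"])

    bm = BetaMatrix(pd.DataFrame(arch, index=probes, columns=types), validate=False)
    return bm, GroundTruth(marker_ids=marker_ids)


def simulate_group_samples(
    refs: BetaMatrix,
    n_per_type: int,
    noise_sd: float,
    seed: int,
    na_rate: float = 0.0,
) -> tuple[BetaMatrix, pd.Series]:
    """Replicate samples around each archetype column with logit-scale noise.

    Returns the sample matrix and a sample_id -> cell type labelling.
    """
    rng = np.random.default_rng(seed)
    cols, labels = [], {}
    arr = refs.data.to_numpy()
    for k, ct in enumerate(refs.sample_ids):
        for r in range(n_per_type):
            sid = f"{ct}_s{r}"
            col = logit_noise(arr[:, k], noise_sd, rng)
            cols.append(_inject_na(col, na_rate, rng))
            labels[sid] = ct
    data = pd.DataFrame(
        np.column_stack(cols), index=refs.probe_ids, columns=list(labels)
    )
    return BetaMatrix(data, validate=False), pd.Series(labels, name="celltype")


def simulate_mixtures(
    refs: BetaMatrix,
    props: pd.DataFrame | np.ndarray | None = None,
    n_samples: int = 50,
    dirichlet_alpha: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    na_rate: float = 0.0,
) -> tuple[BetaMatrix, GroundTruth]:
    """Bulk betas as convex mixtures of archetype columns plus logit noise.

    ``props`` rows (samples x cell types) must be non-negative and sum to 1;
    when omitted, proportions are drawn from Dirichlet(``dirichlet_alpha``).
    """
    rng = np.random.default_rng(seed)
    k = refs.shape[1]
    if props is None:
        props = rng.dirichlet(np.full(k, float(dirichlet_alpha)), size=n_samples)
    props = np.asarray(props, dtype=float) if not isinstance(props, pd.DataFrame) else props.to_numpy()
    if props.ndim != 2 or props.shape[1] != k:
        raise ValueError(f"proportions must be n_samples x {k}")
    if (props < 0).any():
        raise ValueError("negative mixture proportion")
    if not np.allclose(props.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("proportion rows must sum to 1")
    mean = refs.data.to_numpy() @ props.T
    noisy = logit_noise(mean, noise_sd, rng)
    noisy = _inject_na(noisy, na_rate, rng)
    samples = [f"bulk{i:03d}" for i in range(props.shape[0])]
    bm = BetaMatrix(pd.DataFrame(noisy, index=refs.probe_ids, columns=samples), validate=False)
    gt = GroundTruth(
        mixture_proportions=pd.DataFrame(props, index=samples, columns=refs.sample_ids)
    )
    return bm, gt


def _safe_choice(rng: np.random.Generator, pool: list, size: int) -> np.ndarray:
    size = min(size, len(pool))
    if size == 0:
        return np.array([], dtype=int)
    return rng.choice(pool, size=size, replace=False)


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[BetaMatrix, BetaMatrix, SampleSheet, GroundTruth]:
    """Tissue cohort with matched 5modC / 5hmC matrices and full ground truth.

    Tissue structure comes from :func:`simulate_references` (tissues =
    archetypes, samples assigned round-robin). Age-CpGs gain beta linearly
    with age from the low end of ``age_range``; sex-CpGs are offset by
    ``sex_delta`` in males. The 5hmC layer is a per-probe fraction of total
    modification (high on methylated background, low elsewhere), scaled per
    sample by a "proliferation" scalar, so 0 <= 5hmC <= 5modC holds for every
    cell before noise; independent measurement noise on the two matrices can
    and deliberately does violate the bound afterwards.
    """
    rng = np.random.default_rng(cfg.seed)
    refs, gt = simulate_references(
        SimulationConfig(**{**asdict(cfg), "seed": int(rng.integers(2**31))})
    )
    probes = refs.probe_ids
    types = list(refs.sample_ids)
    n = cfg.n_samples
    samples = [f"S{i:03d}" for i in range(n)]
    tissues = [types[i % len(types)] for i in range(n)]
    ages = rng.uniform(*cfg.age_range, size=n)
    sexes = np.where(np.arange(n) % 2 == 0, "F", "M")

    arch = refs.data.to_numpy()
    t_index = {t: j for j, t in enumerate(types)}
    mean = np.column_stack([arch[:, t_index[t]] for t in tissues])

    # age effects on low-background, non-marker probes
    marker_set = set()
    for df in gt.marker_ids.values():
        marker_set.update(df["probe_id"])
    base_low = [i for i, p in enumerate(probes) if arch[i].mean() < 0.5 and p not in marker_set]
    n_age = int(round(cfg.frac_age_cpgs * cfg.n_probes))
    age_idx = _safe_choice(rng, base_low, n_age)
    slopes = rng.uniform(*cfg.age_slope_range, size=len(age_idx))
    age_offset = np.outer(slopes, ages - cfg.age_range[0])
    mean[age_idx, :] = np.clip(mean[age_idx, :] + age_offset, _EPS, 1 - _EPS)

    # sex effects: male-hyper CpGs rise from a low background, male-hypo CpGs
    # fall from a high background, so a hyper-minus-hypo score separates at 0
    base_high = [i for i, p in enumerate(probes) if arch[i].mean() >= 0.5 and p not in marker_set]
    remaining_low = [i for i in base_low if i not in set(age_idx)]
    n_hyper = cfg.n_sex_cpgs - cfg.n_sex_cpgs // 2
    n_hypo = cfg.n_sex_cpgs // 2
    sex_hyper_idx = _safe_choice(rng, remaining_low, n_hyper)
    sex_hypo_idx = _safe_choice(rng, base_high, n_hypo)
    male = (sexes == "M").astype(float)
    mean[sex_hyper_idx, :] = np.clip(
        mean[sex_hyper_idx, :] + cfg.sex_delta * male[None, :], _EPS, 1 - _EPS
    )
    mean[sex_hypo_idx, :] = np.clip(
        mean[sex_hypo_idx, :] - cfg.sex_delta * male[None, :], _EPS, 1 - _EPS
    )

    # imprinted-like loci: stable intermediate methylation near 0.5 in every
    # sample and tissue, as at imprinting control regions
    used = set(age_idx) | set(sex_hyper_idx) | set(sex_hypo_idx)
    imprint_pool = [i for i, p in enumerate(probes)
                    if p not in marker_set and i not in used]
    imprint_idx = _safe_choice(rng, imprint_pool, int(round(cfg.frac_imprinted * cfg.n_probes)))
    mean[imprint_idx, :] = 0.5

    # 5hmC layer: fraction of 5modC, high on methylated background
    probe_high = arch.mean(axis=1) >= 0.5
    h_frac = np.where(
        probe_high,
        cfg.hmc_fraction_by_group.get("high", 0.25),
        cfg.hmc_fraction_by_group.get("low", 0.02),
    )
    prolif = rng.uniform(*cfg.proliferation_range, size=n)
    hmc_mean = mean * h_frac[:, None] * prolif[None, :]

    modc = _inject_na(logit_noise(mean, cfg.noise_sd, rng), cfg.na_rate, rng)
    hmc = _inject_na(logit_noise(hmc_mean, cfg.noise_sd, rng), cfg.na_rate, rng)

    modc_bm = BetaMatrix(pd.DataFrame(modc, index=probes, columns=samples), validate=False)
    hmc_bm = BetaMatrix(pd.DataFrame(hmc, index=probes, columns=samples), validate=False)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": samples,
                "tissue": tissues,
                "age": np.round(ages, 2),
                "sex": sexes,
                "modality": "5modC",
            }
        )
    )
    gt.age_cpgs = pd.DataFrame(
        {"probe_id": [probes[i] for i in age_idx], "slope": slopes}
    )
    gt.sex_cpgs = {
        "male_hyper": [probes[i] for i in sex_hyper_idx],
        "male_hypo": [probes[i] for i in sex_hypo_idx],
    }
    gt.imprinted_cpgs = [probes[i] for i in imprint_idx]
    gt.hmc_fraction = pd.Series(h_frac, index=probes, name="hmc_fraction")
    gt.proliferation = pd.Series(prolif, index=samples, name="proliferation")
    gt.hmc_pre_noise = pd.DataFrame(hmc_mean, index=probes, columns=samples)
    gt.archetypes = refs.data
    return modc_bm, hmc_bm, sheet, gt


def simulate_two_platform(
    refs: BetaMatrix,
    n_query: int,
    rho: float,
    seed: int,
    query_prefix: str = "q",
) -> tuple[BetaMatrix, BetaMatrix, GroundTruth]:
    """Two-platform probe split: query sites as noisy copies of retained sites.

    Every input probe is a retained site. Each of ``n_query`` new query sites
    copies a randomly chosen retained site across samples with additive noise
    calibrated so that the expected cross-sample Pearson correlation is
    approximately ``rho`` (exactly the site for rho=1; an independent bimodal
    draw for rho=0). Values are clipped to [0, 1].
    """
    if not (-1 < rho <= 1):
        raise ValueError("rho must be in (-1, 1]")
    rng = np.random.default_rng(seed)
    vals = refs.data.to_numpy().copy()
    # NA cells would propagate into every derived query; fill with row means
    row_mean = np.nanmean(np.where(np.isnan(vals).all(axis=1)[:, None], 0.5, vals), axis=1)
    ii, jj = np.where(np.isnan(vals))
    vals[ii, jj] = row_mean[ii]
    n_ret, n_samp = vals.shape
    neighbor_idx = rng.integers(0, n_ret, size=n_query)
    out = np.empty((n_query, n_samp))
    for i, j in enumerate(neighbor_idx):
        v = vals[j]
        if rho == 1:
            out[i] = v
            continue
        if rho == 0:
            mode = _HIGH_MODE if rng.random() < 0.5 else _LOW_MODE
            out[i] = logit_noise(np.full(n_samp, mode), 0.5, rng)
            continue
        m, sd = v.mean(), v.std()
        if sd == 0:
            out[i] = np.clip(v + rng.normal(0, 0.05, n_samp), 0, 1)
            continue
        sigma = sd * np.sqrt(1.0 / rho**2 - 1.0)
        signed = m + np.sign(rho) * (v - m)
        out[i] = np.clip(signed + rng.normal(0.0, sigma, n_samp), 0, 1)
    query_ids = [f"{query_prefix}{i:06d}" for i in range(n_query)]
    query = BetaMatrix(
        pd.DataFrame(out, index=query_ids, columns=refs.sample_ids), validate=False
    )
    gt = GroundTruth(
        neighbor_map=pd.Series(
            [refs.probe_ids[j] for j in neighbor_idx], index=query_ids, name="neighbor"
        )
    )
    return refs, query, gt


def manifest_for_probes(
    probe_ids: list[str],
    chrom: str = "chr1",
    spacing: int = 1000,
    replicate_prefixes: dict | None = None,
) -> ProbeManifest:
    """Minimal synthetic manifest: evenly spaced 2-bp CpG intervals on one chromosome."""
    starts = np.arange(len(probe_ids)) * spacing
    t = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chrom,
            "start": starts,
            "end": starts + 2,
        }
    )
    if replicate_prefixes:
        t["replicate_prefix"] = [replicate_prefixes.get(p, p) for p in probe_ids]
    return ProbeManifest(t)


def simulate_annotations(
    manifest: ProbeManifest,
    n_sets: int,
    enrichment_factor: float,
    seed: int,
    query_frac: float = 0.1,
    base_rate: float = 0.1,
) -> tuple[list[str], dict[str, list[str]], GenomicIntervalSet, GroundTruth]:
    """Annotation probe sets with one set planted at a target odds ratio.

    A query set (``query_frac`` of the universe) is drawn; the first
    annotation set includes probes inside the query with odds
    ``enrichment_factor`` times the outside odds ``base_rate/(1-base_rate)``;
    the remaining sets are planted at OR = 1. Interval records mirror the
    probe sets through the manifest coordinates.

    Returns (query set, {set name: probe list}, intervals, ground truth).
    """
    if enrichment_factor <= 0:
        raise ValueError("enrichment_factor must be positive")
    rng = np.random.default_rng(seed)
    universe = list(manifest.probe_ids)
    n = len(universe)
    q_idx = rng.choice(n, size=max(1, int(round(query_frac * n))), replace=False)
    in_query = np.zeros(n, dtype=bool)
    in_query[q_idx] = True
    query = [universe[i] for i in q_idx]

    odds_out = base_rate / (1 - base_rate)
    p_in_enriched = (enrichment_factor * odds_out) / (1 + enrichment_factor * odds_out)
    sets: dict[str, list[str]] = {}
    true_or: dict[str, float] = {}
    for s in range(n_sets):
        name = f"set{s:02d}"
        p_in = p_in_enriched if s == 0 else base_rate
        draw = rng.random(n)
        member = np.where(in_query, draw < p_in, draw < base_rate)
        sets[name] = [universe[i] for i in np.flatnonzero(member)]
        true_or[name] = enrichment_factor if s == 0 else 1.0

    mt = manifest.table.set_index("probe_id")
    records = []
    for name, members in sets.items():
        sub = mt.loc[members]
        for pid, row in sub.iterrows():
            records.append((row["chrom"], row["start"], row["end"], name))
    ivs = GenomicIntervalSet(
        pd.DataFrame(records, columns=["chrom", "start", "end", "name"])
    ).sorted()
    gt = GroundTruth(annotation_query=query, annotation_or=true_or)
    return query, sets, ivs, gt
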