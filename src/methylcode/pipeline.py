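"""End-to-end synthetic replay pipeline.

Runs the stages in dependency order — simulate -> ternary -> markers ->
deconvolution / imputation / enrichment / EWAS / clock / sex — on a
fully synthetic cohort, writing every stage's tables plus a machine-readable
summary into a run directory. A single global seed is expanded into
per-stage seeds by a fixed derivation, so stages can be rerun in isolation
and identical configs give bit-identical exact stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from methylcode import io as mio
from methylcode import simulate as sim
from methylcode import ternary as tern
from methylcode import markers as mk
from methylcode import deconvolution as dec
from methylcode import imputation as imp
from methylcode import enrichment as enr
from methylcode import ewas as ew

log = logging.getLogger("methylcode.pipeline")

_STAGES = ("simulate", "ternary", "markers", "deconv", "impute", "enrich", "ewas", "clock", "sex")


@dataclass
class PipelineConfig:
    """Validated configuration for the replay pipeline; unknown keys rejected."""

    out_dir: str = "results/run"
    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    # simulation scale
    n_probes: int = 2000
    n_celltypes: int = 5
    n_samples: int = 40
    noise_sd: float = 0.5
    marker_delta: float = 0.4
    # thresholds
    min_auc: float = 0.8
    min_delta: float = 0.2
    cap: int | None = None
    n_mixtures: int = 25
    mixture_noise_sd: float = 0.3
    n_query_sites: int = 500
    neighbor_rho: float = 0.9
    r_min: float = 0.5
    knn_k: int = 50
    n_annotation_sets: int = 4
    enrichment_factor: float = 4.0
    expand_bp: int = 5000
    n_permutations: int = 500
    clock_n_features: int = 50
    clock_alpha: float = 0.5
    clock_inner_folds: int = 10

    def __post_init__(self):
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: crc32 of the stage name folded with the global seed."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the toggled stages in dependency order; return the summary dict.

    Every output table lands under ``config.out_dir`` tagged with the config
    hash; a resolved-config echo (``config.yaml``) and ``summary.json`` are
    always written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    summary: dict = {"config_hash": chash, "seed": config.seed, "stages": {}}
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict() | {"config_hash": chash}))
    stages = set(config.stages)
    if not stages:
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        return summary

    need_sim = stages & set(_STAGES)  # every stage consumes the simulation
    if not need_sim:
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        return summary

    cfg = sim.SimulationConfig(
        n_probes=config.n_probes,
        n_celltypes=config.n_celltypes,
        n_samples=config.n_samples,
        noise_sd=config.noise_sd,
        marker_delta=config.marker_delta,
        seed=stage_seed(config.seed, "simulate"),
    )
    modc, hmc, sheet, gt = sim.simulate_cohort(cfg)
    refs = mio.BetaMatrix(gt.archetypes, validate=False)  # the cohort's own archetypes
    manifest = sim.manifest_for_probes(list(modc.probe_ids))
    if "simulate" in stages:
        mio.write_beta_matrix(modc, out / "betas_5modC.tsv")
        mio.write_beta_matrix(hmc, out / "betas_5hmC.tsv")
        mio.write_sample_sheet(sheet, out / "samples.csv")
        mio.write_manifest(manifest, out / "manifest.tsv")
        gt.to_json(out / "ground_truth.json")
        summary["stages"]["simulate"] = {
            "n_probes": modc.shape[0],
            "n_samples": modc.shape[1],
        }
        log.info("simulate: %s probes x %s samples", *modc.shape)

    if "ternary" in stages:
        tp = tern.decompose(modc, hmc)
        mio.write_beta_matrix(mio.BetaMatrix(tp.five_mC, validate=False), out / "ternary_5mC.tsv")
        mio.write_beta_matrix(mio.BetaMatrix(tp.unmod_C, validate=False), out / "ternary_C.tsv")
        tp.clamped_mask.astype(int).to_csv(out / "ternary_clamped.tsv", sep="\t")
        gmeans = tern.global_ternary_means(tp, sheet)
        gmeans.to_csv(out / "ternary_group_means.csv", index=False)
        closure = tp.five_mC + tp.five_hmC + tp.unmod_C
        dev = float(np.nanmax(np.abs(closure.to_numpy() - 1.0)))
        summary["stages"]["ternary"] = {
            "max_closure_deviation": dev,
            "clamped_fraction": tp.clamped_fraction,
        }
        log.info("ternary: closure deviation %.2e", dev)

    markers_df = None
    if "markers" in stages:
        groups = sheet.groups("tissue")
        markers_df = mk.one_vs_rest_all_contrasts(
            modc,
            groups,
            thresholds=mk.MarkerThresholds(min_auc=config.min_auc, min_delta=config.min_delta),
            cap=config.cap,
        )
        markers_df.to_csv(out / "markers.tsv", sep="\t", index=False)
        truth = {
            (ct, p) for ct, df in gt.marker_ids.items() for p in df["probe_id"]
        }
        found = set(zip(markers_df["contrast"], markers_df["probe_id"]))
        tp_n = len(found & truth)
        precision = tp_n / len(found) if found else float("nan")
        recall = tp_n / len(truth) if truth else float("nan")
        summary["stages"]["markers"] = {
            "n_selected": int(len(markers_df)),
            "precision": precision,
            "recall": recall,
        }
        log.info("markers: %d selected, precision %.3f recall %.3f", len(markers_df), precision, recall)

    if "deconv" in stages:
        if markers_df is None or markers_df.empty:
            raise RuntimeError("deconv stage requires markers stage output")
        panel = dec.build_reference(refs, markers_df)
        bulks, mix_gt = sim.simulate_mixtures(
            refs,
            n_samples=config.n_mixtures,
            noise_sd=config.mixture_noise_sd,
            seed=stage_seed(config.seed, "deconv"),
        )
        props = dec.rpc_deconvolve(bulks, panel)
        props.to_csv(out / "proportions.csv")
        est = props[panel.celltype_ids].to_numpy()
        true = mix_gt.mixture_proportions.to_numpy()
        rmse = float(np.sqrt(np.mean((est - true) ** 2)))
        summary["stages"]["deconv"] = {"rmse": rmse, "n_bulks": int(len(props))}
        log.info("deconv: RMSE %.4f over %d bulks", rmse, len(props))

    if "impute" in stages:
        retained, query, imp_gt = sim.simulate_two_platform(
            modc, config.n_query_sites, config.neighbor_rho,
            seed=stage_seed(config.seed, "impute"),
        )
        reference = mio.BetaMatrix(
            pd.concat([retained.data, query.data]), validate=False
        )
        nmap = imp.build_neighbor_map(
            reference,
            list(retained.probe_ids),
            list(query.probe_ids),
            k=config.knn_k,
            r_min=config.r_min,
        )
        nmap.to_csv(out / "neighbor_map.tsv", sep="\t")
        correct = float(
            np.mean(nmap["neighbor"].to_numpy() == imp_gt.neighbor_map.loc[nmap.index].to_numpy())
        )
        summary["stages"]["impute"] = {
            "neighbor_accuracy": correct,
            "retained_fraction": float(nmap["retained"].mean()),
        }
        log.info("impute: %.1f%% neighbors correct", 100 * correct)

    if "enrich" in stages:
        eseed = stage_seed(config.seed, "enrich")
        query, sets, ivs, ann_gt = sim.simulate_annotations(
            manifest, config.n_annotation_sets, config.enrichment_factor, seed=eseed
        )
        fisher = enr.fisher_set_enrichment(query, sets, list(manifest.probe_ids))
        fisher.to_csv(out / "enrichment_fisher.tsv", sep="\t", index=False)
        sd_rank = mk.variability_rank(modc)
        sea = enr.ranked_set_enrichment(
            sd_rank["probe_id"].tolist(),
            query,
            n_permutations=config.n_permutations,
            seed=eseed,
        )
        summary["stages"]["enrich"] = {
            "planted_or": config.enrichment_factor,
            "estimated_or_enriched": float(fisher.loc[fisher["annotation"] == "set00", "odds_ratio"].iloc[0]),
            "sea_es": sea.es,
            "sea_p": sea.p_value,
        }
        log.info("enrich: planted OR %.1f estimated %.2f",
                 config.enrichment_factor, summary["stages"]["enrich"]["estimated_or_enriched"])

    ewas_res = None
    if "ewas" in stages:
        ewas_res = ew.fit_linear_ewas(modc, sheet)
        ewas_res.to_csv(out / "ewas.tsv", sep="\t")
        age_q = ewas_res["q_age"]
        hits = set(ewas_res.index[age_q < 0.05])
        truth_age = set(gt.age_cpgs["probe_id"])
        recall = len(hits & truth_age) / len(truth_age) if truth_age else float("nan")
        summary["stages"]["ewas"] = {
            "n_age_hits_q05": int(len(hits)),
            "age_cpg_recall": recall,
        }
        log.info("ewas: %d age hits, recall %.3f", len(hits), recall)

    if "clock" in stages:
        # train on an informative subset for speed: age CpGs + background
        rng = np.random.default_rng(stage_seed(config.seed, "clock"))
        probes = list(gt.age_cpgs["probe_id"])
        background = [p for p in modc.probe_ids if p not in set(probes)]
        extra = rng.choice(len(background), size=min(400, len(background)), replace=False)
        subset = probes + [background[i] for i in sorted(extra)]
        res = ew.loocv_clock(
            modc.subset_probes(subset),
            sheet,
            n_features=config.clock_n_features,
            alpha=config.clock_alpha,
            inner_folds=config.clock_inner_folds,
            seed=stage_seed(config.seed, "clock"),
        )
        res["predictions"].to_csv(out / "clock_predictions.csv")
        res["model"].save(out / "clock")
        summary["stages"]["clock"] = {"mae": res["mae"], "pearson_r": res["pearson_r"]}
        log.info("clock: LOOCV r %.3f MAE %.2f", res["pearson_r"], res["mae"])

    if "sex" in stages:
        scores = ew.sex_score(modc, gt.sex_cpgs["male_hyper"], gt.sex_cpgs["male_hypo"])
        scores.to_csv(out / "sex_scores.csv")
        truth_sex = sheet.table.set_index("sample_id")["sex"]
        acc = float((scores["predicted_sex"] == truth_sex.loc[scores.index]).mean())
        summary["stages"]["sex"] = {"accuracy": acc}
        log.info("sex: accuracy %.3f", acc)

    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
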