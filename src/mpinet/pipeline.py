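"""End-to-end orchestration with a provenance manifest.

Stage order: build/load network -> preprocess cohort -> subtype model ->
RF importance + GL1 -> C1-vs-C2 differential -> gene GSEA -> immune score ->
deltaM + metabolite GSEA -> link prediction -> optional TME sub-clustering
+ GL2 -> survival comparison. Each stage writes plain-text outputs and is
recorded (path, wall time, checksum) in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "synthetic": True,
    "synth": {},
    "max_met_degree": 200,
    "core_min_degree": 4,
    "consensus_reps": 250,
    "subsample_fraction": 0.8,
    "final_k": 2,
    "n_trees": 300,
    "top_k_genes": 30,
    "gsea_permutations": 500,
    "link": {"n_trees": 200, "cv_folds": 5, "threshold": 0.9, "max_pairs": 400},
    "tme": {"enabled": True},
    "log2fc_mode": "mean_of_logs",
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seeds: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    version: str = ""

    def record(self, stage: str, outputs: dict, elapsed: float) -> None:
        self.stages.append(
            {
                "stage": stage,
                "outputs": {
                    name: {"path": str(p), "sha256": _sha256(Path(p))}
                    for name, p in outputs.items()
                },
                "seconds": round(elapsed, 3),
            }
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "config": self.config,
                    "seeds": self.seeds,
                    "stages": self.stages,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def run_full_pipeline(config: dict, out_dir) -> RunManifest:
    """Run every stage on synthetic (or provided) inputs; see module docstring."""
    from mpinet import __version__, network as netmod
    from mpinet.deltam import delta_m, metabolite_gsea
    from mpinet.enrichment import RankedList, build_immune_gene_list, gsea, sample_set_score
    from mpinet.mpi_predict import predict_high_confidence, train_link_model
    from mpinet.stats import ExpressionCohort, logrank, unpaired_differential, zscore_normalize
    from mpinet.subtyping import (
        fit_subtype_model,
        rf_gene_importance,
        sub_cluster_tme,
        top_genes,
        train_classifier,
    )
    from mpinet import synth

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, version=__version__)
    seed = int(config["seed"])
    manifest.seeds["root"] = seed

    def stage(name):
        logger.info("stage: %s", name)
        return time.perf_counter()

    # ------------------------------------------------------------ network
    t0 = stage("network")
    if config.get("synthetic", True):
        scfg = synth.SynthConfig(seed=seed, **config.get("synth", {}))
        net, net_truth = synth.gen_mpi_network(scfg)
    else:
        net = netmod.MPINetwork.from_tsv(config["network_tsv"])
        net_truth = {}
        scfg = synth.SynthConfig(seed=seed, **config.get("synth", {}))
    net = netmod.remove_common_metabolites(net, config["max_met_degree"])
    net = netmod.prune_isolated_proteins(net)
    net_path = out / "network.tsv"
    net.to_tsv(net_path)
    manifest.record("network", {"network": net_path}, time.perf_counter() - t0)

    # ------------------------------------------------------------- cohort
    t0 = stage("cohort")
    if config.get("synthetic", True):
        cohort, truth_labels, cohort_truth = synth.gen_cohort(scfg, net)
        markers = set(cohort_truth["marker_genes"])
        truth_labels.to_csv(out / "true_labels.tsv", sep="\t")
    else:
        cohort = ExpressionCohort.from_tsv(config["expression_tsv"], config.get("clinical_tsv"))
        markers = set(config["marker_genes"])
        truth_labels = None
    zx = zscore_normalize(cohort.expression)
    zcohort = ExpressionCohort(zx, cohort.clinical)
    expr_path = out / "expression.tsv"
    cohort.to_tsv(expr_path, out / "clinical.tsv")
    manifest.record(
        "cohort", {"expression": expr_path, "clinical": out / "clinical.tsv"},
        time.perf_counter() - t0,
    )

    # ------------------------------------------------------------ subtype
    t0 = stage("subtype")
    model = fit_subtype_model(
        zcohort,
        net,
        markers,
        k=config["final_k"],
        reps=config["consensus_reps"],
        subsample_fraction=config["subsample_fraction"],
        seed=seed,
        core_min_degree=config["core_min_degree"],
    )
    labels_path = out / "subtype_labels.tsv"
    model.labels.to_csv(labels_path, sep="\t")
    model.consensus.consensus_matrix.to_csv(out / "consensus_matrix.tsv", sep="\t")
    manifest.record(
        "subtype",
        {"labels": labels_path, "consensus": out / "consensus_matrix.tsv"},
        time.perf_counter() - t0,
    )

    # --------------------------------------------- RF importance + GL1
    t0 = stage("classifier")
    imp = rf_gene_importance(zx, model.labels, n_trees=config["n_trees"], seed=seed)
    gl1_genes = top_genes(imp, config["top_k_genes"])
    gl1 = train_classifier(zx.loc[gl1_genes], model.labels, seed=seed)
    imp.head(200).to_csv(out / "gene_importance.tsv", sep="\t", index=False)
    gl1.to_json(out / "gl1.json")
    manifest.record(
        "classifier",
        {"importance": out / "gene_importance.tsv", "gl1": out / "gl1.json"},
        time.perf_counter() - t0,
    )

    # -------------------------------------------------- differential + GSEA
    t0 = stage("differential")
    clin = cohort.clinical.copy() if len(cohort.clinical) else pd.DataFrame(
        index=pd.Index(cohort.samples, name="sample_id")
    )
    clin["group"] = model.labels.reindex(clin.index)
    tagged = ExpressionCohort(cohort.expression, clin)
    de = unpaired_differential(tagged, "C1", "C2")
    de_path = out / "differential_c1_vs_c2.tsv"
    de.to_csv(de_path, sep="\t")
    ranked = RankedList.from_scores(de["log2FC"])
    gene_sets = synth.gen_pathway_sets(list(zx.index), n_sets=8, set_size=20, seed=seed)
    gsea_table = gsea(
        ranked, gene_sets, n_permutations=config["gsea_permutations"], seed=seed
    )
    gsea_table.to_csv(out / "gene_gsea.tsv", sep="\t", index=False)
    manifest.record(
        "differential",
        {"differential": de_path, "gene_gsea": out / "gene_gsea.tsv"},
        time.perf_counter() - t0,
    )

    # -------------------------------------------------------- immune score
    t0 = stage("immune")
    immune_sets = synth.gen_pathway_sets(
        list(zx.index), n_sets=3, set_size=40, seed=seed + 11, prefix="IMMUNE"
    )
    immune_genes = build_immune_gene_list(tagged, model.labels, immune_sets)
    if len(immune_genes) >= 3:
        immu = sample_set_score(cohort.expression, immune_genes)
    else:
        logger.warning("immune gene list too small (%d); scoring all immune-set genes",
                       len(immune_genes))
        immu = sample_set_score(cohort.expression, immune_sets.all_members())
    immu_path = out / "immune_scores.tsv"
    immu.to_csv(immu_path, sep="\t")
    manifest.record("immune", {"scores": immu_path}, time.perf_counter() - t0)

    # ------------------------------------------------- deltaM + metabolite GSEA
    t0 = stage("deltam")
    log2fc = de["log2FC"].to_dict()
    acc = delta_m(net, log2fc)
    acc_path = out / "deltam.tsv"
    acc.to_csv(acc_path, sep="\t")
    met_sets = synth.gen_pathway_sets(
        net.metabolites, n_sets=6, set_size=15, seed=seed + 7, prefix="METSET"
    )
    if len(acc):
        met_gsea = metabolite_gsea(
            acc, met_sets, n_permutations=config["gsea_permutations"], seed=seed
        )
        met_gsea.to_csv(out / "metabolite_gsea.tsv", sep="\t", index=False)
    manifest.record(
        "deltam",
        {"deltam": acc_path, "metabolite_gsea": out / "metabolite_gsea.tsv"},
        time.perf_counter() - t0,
    )

    # ------------------------------------------------------ link prediction
    t0 = stage("link_prediction")
    link_cfg = config["link"]
    lcfg = synth.SynthConfig(
        seed=seed,
        n_metabolites=60,
        n_proteins=80,
        n_blocks=3,
        p_within=0.3,
        p_between=0.02,
    )
    lnet, lpos, lcand, ltruth = synth.gen_link_instance(lcfg)
    rng = np.random.default_rng(seed)
    max_pairs = int(link_cfg.get("max_pairs", 400))
    pos = lpos if len(lpos) <= max_pairs else [
        lpos[i] for i in sorted(rng.choice(len(lpos), size=max_pairs, replace=False))
    ]
    from mpinet.mpi_predict import sample_negative_pairs

    neg = sample_negative_pairs(lnet, len(pos), seed=seed, exclude=set(lcand))
    link_model = train_link_model(
        pos, neg, lnet,
        n_trees=link_cfg.get("n_trees", 200),
        cv_folds=link_cfg.get("cv_folds", 5),
        seed=seed,
    )
    preds = predict_high_confidence(
        link_model, lcand, lnet, threshold=link_cfg.get("threshold", 0.9)
    )
    preds_path = out / "mpi_predictions.tsv"
    preds.to_csv(preds_path, sep="\t", index=False)
    with open(out / "link_model_metrics.json", "w") as fh:
        json.dump({"auroc": link_model.auroc, "n_pos": len(pos), "n_neg": len(neg)}, fh)
    manifest.record(
        "link_prediction",
        {"predictions": preds_path, "metrics": out / "link_model_metrics.json"},
        time.perf_counter() - t0,
    )

    # ----------------------------------------------- TME sub-clustering + GL2
    if config.get("tme", {}).get("enabled", True):
        t0 = stage("tme")
        c1 = set(model.labels.index[model.labels == "C1"])
        if len(c1) >= 10:
            planted = pd.Series(
                {s: ("S1" if i % 2 == 0 else "S2") for i, s in enumerate(sorted(c1))}
            )
            tme, _ = synth.gen_tme_matrix(sorted(c1), planted, seed=seed + 5)
            survival = cohort.clinical[["time", "event"]] if {
                "time", "event"
            } <= set(cohort.clinical.columns) else None
            s_labels = sub_cluster_tme(tme, c1, survival=survival, seed=seed, reps=100)
            s_labels.to_csv(out / "s1_s2_labels.tsv", sep="\t")
            if s_labels.value_counts().min() >= 20:
                imp2 = rf_gene_importance(
                    zx[s_labels.index], s_labels, n_trees=config["n_trees"], seed=seed
                )
                gl2_genes = top_genes(imp2, config["top_k_genes"])
                gl2 = train_classifier(zx.loc[gl2_genes, s_labels.index], s_labels, seed=seed)
                gl2.to_json(out / "gl2.json")
            manifest.record("tme", {"s_labels": out / "s1_s2_labels.tsv"},
                            time.perf_counter() - t0)
        else:
            logger.info("TME stage skipped: fewer than 10 C1 samples")
    else:
        logger.info("TME stage skipped by config")

    # ------------------------------------------------------------ survival
    t0 = stage("survival")
    if {"time", "event"} <= set(cohort.clinical.columns):
        tumor = cohort.clinical.dropna(subset=["time"])
        surv_cohort = ExpressionCohort(
            cohort.expression[list(tumor.index)], tumor
        )
        try:
            stat, p = logrank(surv_cohort, model.labels.reindex(tumor.index).dropna())
            with open(out / "survival.json", "w") as fh:
                json.dump({"logrank_statistic": stat, "logrank_p": p}, fh)
            manifest.record("survival", {"survival": out / "survival.json"},
                            time.perf_counter() - t0)
        except ValueError as exc:
            logger.warning("survival comparison skipped: %s", exc)

    manifest.write(out / "manifest.json")
    return manifest
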