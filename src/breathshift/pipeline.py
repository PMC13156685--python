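"""End-to-end pipeline orchestration with a machine-readable run report.

Stage order mirrors the analysis: simulate (or load) the two cohort
tables, preprocess (sparsity filter, ROS imputation, AUC aggregation),
paired differential statistics with cross-cohort overlap, correlation-
network concordance, pathway annotation/enrichment, and the grouped
classifier.  A fixed global seed makes every stage, and therefore every
written artifact, reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierConfig, cluster_probability_profiles, train_evaluate
from .diffstats import (
    classify_volcano,
    cross_cohort_overlap,
    paired_differential,
    volcano_counts,
)
from .network import (
    build_correlation_network,
    cross_site_similarity,
    topology_profile,
    write_edge_list_tsv,
    write_graphml,
)
from .pathways import annotate_features, mummichog_enrichment, pathway_degree_analysis
from .preprocess import aggregate_auc, filter_sparse_features, impute_ros
from .synthetic import StudyDesignConfig, generate_cohort_pair, generate_compound_library

logger = logging.getLogger("breathshift")

REPORT_SCHEMA_ID = "breathshift-run-report/1"

_STAGES = ("simulate", "preprocess", "diff", "network", "pathways", "classify")

_DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "breathshift_run",
    "stages": {name: True for name in _STAGES},
    "simulate": {
        "n_subjects_per_cohort": [12, 12],
        "n_features": 800,
        "frac_affected": 0.1,
        "effect_log2fc_range": [1.5, 2.5],
        "noise_sd_log10": 0.15,
        "n_blocks": 10,
        "block_rho": 0.6,
        "censor_quantile": 0.05,
        "frac_annotatable": 0.5,
    },
    "preprocess": {"max_zero_frac": 0.5},
    "diff": {"fc_cut": 1.5, "fdr_cut": 0.01},
    "network": {"cutoff": 0.7, "cutoffs": [0.1, 0.3, 0.5, 0.7, 0.9],
                "subset": "significant"},
    "pathways": {
        "n_compounds": 60,
        "n_pathways": 12,
        "min_features": 5,
        "n_perm": 100,
        "overlap_weight": 0.001,
    },
    "classify": {"pca_components": 16, "hidden_sizes": [32, 32], "n_repeats": 10},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-backed key-value tree)."""

    seed: int = 0
    output_dir: str = "breathshift_run"
    stages: dict = field(default_factory=lambda: dict(_DEFAULTS["stages"]))
    params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {"seed", "output_dir", "stages"} | set(_STAGES)
        for key in raw:
            if key not in known:
                raise ValueError(f"unknown configuration key: {key!r}")
        stages = dict(_DEFAULTS["stages"])
        stages.update(raw.get("stages", {}))
        for key in stages:
            if key not in _STAGES:
                raise ValueError(f"unknown stage toggle: {key!r}")
        params = {}
        for stage in _STAGES:
            block = dict(_DEFAULTS.get(stage, {}))
            overrides = raw.get(stage, {})
            for key in overrides:
                if key not in block:
                    raise ValueError(f"unknown key {key!r} in stage {stage!r}")
            block.update(overrides)
            params[stage] = block
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", _DEFAULTS["output_dir"])),
            stages=stages,
            params=params,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunReport:
    schema_id: str
    package_version: str
    seed: int
    stages: list = field(default_factory=list)  # dicts: name, params, outputs, counts

    def add_stage(self, name: str, params: dict, outputs: dict[str, str],
                  counts: dict, warnings_: list[str] | None = None) -> None:
        self.stages.append(
            {
                "name": name,
                "params": params,
                "outputs": outputs,
                "counts": counts,
                "warnings": warnings_ or [],
            }
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(report: RunReport, path) -> None:
    payload = asdict(report)
    _validate_report_payload(payload)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_report(path) -> RunReport:
    with open(path) as fh:
        payload = json.load(fh)
    _validate_report_payload(payload)
    return RunReport(
        schema_id=payload["schema_id"],
        package_version=payload["package_version"],
        seed=payload["seed"],
        stages=payload["stages"],
    )


def _validate_report_payload(payload: dict) -> None:
    if payload.get("schema_id") != REPORT_SCHEMA_ID:
        raise ValueError(f"unsupported report schema: {payload.get('schema_id')!r}")
    for key in ("package_version", "seed", "stages"):
        if key not in payload:
            raise ValueError(f"report missing required key {key!r}")
    for stage in payload["stages"]:
        for key in ("name", "params", "outputs", "counts", "warnings"):
            if key not in stage:
                raise ValueError(f"stage entry missing key {key!r}")


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order.

    Artifacts are written under ``config.output_dir``; the returned report
    lists, per stage, the parameters used, sha256 digests of the outputs,
    and headline counts.  Reruns with the same config and seed reproduce
    identical artifacts.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("breathshift %s | seed=%d | output=%s", __version__, config.seed, out)
    report = RunReport(schema_id=REPORT_SCHEMA_ID, package_version=__version__,
                       seed=config.seed)

    state: dict = {}

    def run_stage(name, fn):
        if not config.stages.get(name, True):
            logger.info("stage %s: skipped", name)
            return
        logger.info("stage %s: running", name)
        try:
            fn()
        except Exception as exc:
            for f in out.glob("*.tmp"):
                f.rename(f.with_suffix(f.suffix + ".partial"))
            raise PipelineError(name, exc) from exc

    # -- simulate ---------------------------------------------------------
    def stage_simulate():
        p = config.params["simulate"]
        pw = config.params["pathways"]
        library = generate_compound_library(pw["n_compounds"], pw["n_pathways"],
                                            seed=config.seed)
        state["library"] = library
        design = StudyDesignConfig(
            n_subjects_per_cohort=tuple(p["n_subjects_per_cohort"]),
            n_features=p["n_features"],
            frac_affected=p["frac_affected"],
            effect_log2fc_range=tuple(p["effect_log2fc_range"]),
            noise_sd_log10=p["noise_sd_log10"],
            n_blocks=p["n_blocks"],
            block_rho=p["block_rho"],
            censor_quantile=p["censor_quantile"],
            seed=config.seed,
        )
        from .pathways import adduct_mz_pool

        ta, tb, truth = generate_cohort_pair(
            design, mz_pool=adduct_mz_pool(library),
            frac_from_pool=p["frac_annotatable"],
        )
        paths = {}
        for label, tab in (("discovery", ta), ("validation", tb)):
            path = out / f"table_{label}.tsv"
            tab.to_tsv(path)
            paths[f"table_{label}"] = _digest(path)
        truth_path = out / "ground_truth.json"
        truth.to_json(truth_path)
        paths["ground_truth"] = _digest(truth_path)
        state.update(tables={"discovery": ta, "validation": tb}, truth=truth)
        report.add_stage("simulate", p, paths,
                         {"n_features": design.n_features,
                          "n_affected": len(truth.affected_feature_ids)})

    # -- preprocess -------------------------------------------------------
    def stage_preprocess():
        p = config.params["preprocess"]
        paired, filtered = {}, {}
        paths, counts = {}, {}
        for label, tab in state["tables"].items():
            filt = filter_sparse_features(tab, p["max_zero_frac"])
            imputed = impute_ros(filt)
            paired[label] = aggregate_auc(imputed)
            filtered[label] = imputed
            path = out / f"table_{label}_imputed.tsv"
            imputed.to_tsv(path)
            paths[f"table_{label}_imputed"] = _digest(path)
            counts[f"{label}_features_in"] = tab.n_features
            counts[f"{label}_features_out"] = filt.n_features
        state.update(paired=paired, imputed=filtered)
        report.add_stage("preprocess", p, paths, counts)

    # -- differential -----------------------------------------------------
    def stage_diff():
        p = config.params["diff"]
        stats, paths, counts = {}, {}, {}
        for label, pr in state["paired"].items():
            st = classify_volcano(paired_differential(pr), p["fc_cut"], p["fdr_cut"])
            stats[label] = st
            path = out / f"stats_{label}.tsv"
            st.to_csv(path, sep="\t")
            paths[f"stats_{label}"] = _digest(path)
            counts.update({f"{label}_{k}": v for k, v in volcano_counts(st).items()})
        shared = sorted(set(stats["discovery"].index) & set(stats["validation"].index))
        up_a = set(stats["discovery"].index[stats["discovery"]["volcano_class"] == "up"])
        up_b = set(stats["validation"].index[stats["validation"]["volcano_class"] == "up"])
        overlap = cross_cohort_overlap(up_a & set(shared), up_b & set(shared), len(shared))
        counts["overlap_up"] = overlap.n_overlap
        counts["overlap_p"] = overlap.hypergeom_p
        state.update(stats=stats, shared_features=shared)
        report.add_stage("diff", p, paths, counts)

    # -- network ----------------------------------------------------------
    def stage_network():
        p = config.params["network"]
        shared = state["shared_features"]
        if p["subset"] == "significant":
            # restrict to features regulated in either cohort (the displayed-
            # network convention); topology on the full shared set scales
            # quadratically and is available via subset="shared"
            sig = sorted(
                set().union(
                    *(
                        set(st.index[st["volcano_class"] != "ns"])
                        for st in state["stats"].values()
                    )
                )
                & set(shared)
            )
            if len(sig) >= 10:
                shared = sig
        nets = {
            label: build_correlation_network(
                state["imputed"][label], feature_subset=shared,
                cutoff=p["cutoff"], stats=state["stats"][label],
            )
            for label in ("discovery", "validation")
        }
        sim = cross_site_similarity(nets["discovery"], nets["validation"], p["cutoffs"])
        topo = {label: topology_profile(net, p["cutoffs"]) for label, net in nets.items()}
        paths = {}
        for label, net in nets.items():
            gpath = out / f"network_{label}.graphml"
            write_graphml(net, gpath)
            epath = out / f"edges_{label}.tsv"
            write_edge_list_tsv(net, epath)
            paths[f"network_{label}"] = _digest(gpath)
            paths[f"edges_{label}"] = _digest(epath)
            tpath = out / f"topology_{label}.tsv"
            topo[label].to_csv(tpath, sep="\t")
            paths[f"topology_{label}"] = _digest(tpath)
        spath = out / "similarity.tsv"
        sim.per_cutoff.to_csv(spath, sep="\t")
        paths["similarity"] = _digest(spath)
        state.update(networks=nets, similarity=sim)
        report.add_stage(
            "network", p, paths,
            {"trace_similarity": sim.trace_similarity,
             "eigenvalue_corr": sim.eigenvalue_corr,
             "edges_discovery": nets["discovery"].graph.number_of_edges(),
             "edges_validation": nets["validation"].graph.number_of_edges()},
        )

    # -- pathways ---------------------------------------------------------
    def stage_pathways():
        p = config.params["pathways"]
        library = state.get("library") or generate_compound_library(
            p["n_compounds"], p["n_pathways"], seed=config.seed
        )
        lib_path = out / "compound_library.json"
        library.to_json(lib_path)
        shared = state["shared_features"]
        mz = state["imputed"]["discovery"].feature_mz[shared]
        annotations = annotate_features(mz, library)
        ann_path = out / "annotations.tsv"
        annotations.to_csv(ann_path, sep="\t", index=False)
        degree = pathway_degree_analysis(
            state["stats"]["discovery"], state["stats"]["validation"],
            state["networks"]["discovery"], state["networks"]["validation"],
            annotations, library, min_features=p["min_features"],
        )
        deg_path = out / "pathway_degree.tsv"
        degree.stats.to_csv(deg_path, sep="\t")
        sig = set(
            state["stats"]["discovery"].index[
                state["stats"]["discovery"]["volcano_class"] != "ns"
            ]
        ) & set(shared)
        enrich = mummichog_enrichment(
            sig, set(shared), annotations, library,
            n_perm=p["n_perm"], overlap_weight=p["overlap_weight"], seed=config.seed,
        )
        enr_path = out / "enrichment.tsv"
        enrich.to_csv(enr_path, sep="\t", index=False)
        report.add_stage(
            "pathways", p,
            {name: _digest(path) for name, path in
             (("compound_library", lib_path), ("annotations", ann_path),
              ("pathway_degree", deg_path), ("enrichment", enr_path))},
            {"n_annotated_features": int(annotations["feature_id"].nunique()),
             "n_pathways_tested": len(enrich)},
        )

    # -- classify ---------------------------------------------------------
    def stage_classify():
        p = config.params["classify"]
        ta = state["tables"]["discovery"]
        tb = state["tables"]["validation"]
        from .tables import FeatureTable

        table = FeatureTable(
            pd.concat([ta.samples, tb.samples]),
            pd.concat([ta.intensities, tb.intensities]),
        )
        cfg = ClassifierConfig(
            pca_components=p["pca_components"],
            hidden_sizes=tuple(p["hidden_sizes"]),
            n_repeats=p["n_repeats"],
            seed=config.seed,
        )
        rep = train_evaluate(table, config=cfg)
        pm = rep.probability_matrix
        if not pm.isna().all(axis=1).any() and pm.shape[0] >= 3:
            labels, _ = cluster_probability_profiles(pm.dropna(how="all"), k=3)
        else:
            labels = None
        path = out / "classifier_report.json"
        payload = {
            "roc_auc": rep.roc_auc,
            "roc_auc_mean_over_repeats": rep.roc_auc_mean_over_repeats,
            "accuracy": rep.accuracy,
            "per_measurement_accuracy": rep.per_measurement_accuracy,
            "cluster_labels": labels.to_dict() if labels is not None else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        pm_path = out / "probability_matrix.tsv"
        pm.to_csv(pm_path, sep="\t")
        report.add_stage(
            "classify", p,
            {"classifier_report": _digest(path), "probability_matrix": _digest(pm_path)},
            {"roc_auc": rep.roc_auc, "accuracy": rep.accuracy},
        )

    run_stage("simulate", stage_simulate)
    run_stage("preprocess", stage_preprocess)
    run_stage("diff", stage_diff)
    run_stage("network", stage_network)
    run_stage("pathways", stage_pathways)
    run_stage("classify", stage_classify)

    write_report(report, out / "run_report.json")
    logger.info("pipeline complete: %d stage(s)", len(report.stages))
    return report
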