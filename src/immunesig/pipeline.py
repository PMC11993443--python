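"""Config-driven end-to-end orchestration of the analysis.

One :func:`run_pipeline` call reads expression + clinical files, aggregates
probes, scales per dataset, scores the immune signature (adapting it when a
platform lacks some signature genes), assigns intrinsic and immune
subtypes, runs the per-dataset / pooled / meta response statistics, the
RI-score quadrant analysis and ROC comparisons, and the survival
stratification — writing a machine-readable JSON report plus CSV artifacts.
Every sample exclusion (unknown pCR, missing RS, unclassifiable profile) is
counted in the report's ``exclusions`` section; nothing is silently imputed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from . import reference, signature, simulate, stats, subtype as subtyping
from .discrimination import delong_test, roc_auc
from .matrix import ExpressionMatrix, ProbeGeneMap
from .survival import km_estimate, logrank, median_followup

__all__ = ["PipelineConfig", "run_pipeline", "make_fixture"]

logger = logging.getLogger(__name__)

REPORT_SECTIONS = ("config", "exclusions", "scoring", "subtype", "response", "roc", "survival")


@dataclasses.dataclass
class PipelineConfig:
    """Paths, preprocessing choices and analysis toggles for one run."""

    expression: str
    clinical: str
    probe_map: str | None = None
    model: str | None = None
    centroids: str | None = None
    feature_kind: str = "gene"
    scaling: str = "zscale"          # zscale | center | none
    aggregation: str = "mean"        # mean | median
    min_features: int = 16
    cutoffs: stats.CutoffConfig = dataclasses.field(default_factory=stats.CutoffConfig)
    run_subtype: bool = True
    run_meta: bool = True
    run_roc: bool = True
    run_survival: bool = True
    outdir: str = "immunesig_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        cutoffs = stats.CutoffConfig(**raw.pop("cutoffs", {}))
        return cls(cutoffs=cutoffs, **raw)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as handle:
            yaml.safe_dump(payload, handle, sort_keys=False)


def _scale_per_dataset(
    matrix: ExpressionMatrix, clinical: eio.ClinicalTable, mode: str
) -> ExpressionMatrix:
    """Apply the scaling mode within each dataset (platforms differ by dataset)."""
    if mode == "none":
        return matrix
    if "dataset" not in clinical.data.columns or clinical.data["dataset"].nunique() <= 1:
        return eio.preprocess(matrix, mode)
    pieces = []
    by_dataset = clinical.data.groupby("dataset")["sample_id"]
    for _, ids in by_dataset:
        cols = [s for s in ids if s in matrix.data.columns]
        if not cols:
            continue
        block = matrix.replace(data=matrix.data[cols])
        pieces.append(eio.preprocess(block, mode).data)
    merged = pd.concat(pieces, axis=1)[matrix.samples]
    return matrix.replace(data=merged, centered=True, zscaled=(mode == "zscale"))


def _score_stage(matrix, clinical, config, exclusions):
    model = (
        signature.DLDASignatureResults.from_json(config.model)
        if config.model
        else reference.reference_model()
    )
    missing = [f for f in model.features if f not in matrix.data.index]
    if missing:
        train_X, train_labels, _, _ = reference.reference_training_cohort()
        model = model.adapt(
            matrix.features, train_X, train_labels, min_features=config.min_features
        )
        exclusions["signature_features_dropped"] = len(missing)
    scaled = _scale_per_dataset(matrix, clinical, config.scaling)
    return model, model.score(scaled), scaled


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every enabled stage; returns (and writes) the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exclusions: dict[str, int] = {}
    report: dict = {"config": dataclasses.asdict(config), "exclusions": exclusions}

    # --- read -----------------------------------------------------------
    matrix = eio.read_series_matrix(config.expression, feature_kind=config.feature_kind)
    clinical = eio.read_clinical(config.clinical)
    if matrix.feature_kind == "probe":
        if not config.probe_map:
            raise ValueError("probe-level expression requires a probe_map")
        probe_map = ProbeGeneMap.read_tsv(config.probe_map)
        unannotated = sum(1 for p in matrix.features if p not in probe_map)
        matrix = eio.aggregate_probes(matrix, probe_map, method=config.aggregation)
        exclusions["unannotated_probes"] = unannotated
    shared = [s for s in clinical.sample_ids if s in matrix.data.columns]
    exclusions["samples_without_expression"] = len(clinical) - len(shared)
    clinical = clinical.subset(shared)
    matrix = matrix.replace(data=matrix.data[shared])

    # --- score ----------------------------------------------------------
    model, scores, scaled = _score_stage(matrix, clinical, config, exclusions)
    scores.write_csv(outdir / "scores.csv")
    gp_r_fraction = float((scores.group == "Gp-R").mean())
    report["scoring"] = {
        "n_samples": len(scores),
        "n_features": len(model.features),
        "gp_r_fraction": gp_r_fraction,
        "gp_nr_fraction": 1.0 - gp_r_fraction,
        "mean_is": float(scores.is_score.mean()),
    }

    # --- subtype ---------------------------------------------------------
    calls = None
    if config.run_subtype:
        centroids = (
            subtyping.CentroidSet.from_json(config.centroids)
            if config.centroids
            else subtyping.CentroidSet(simulate.subtype_centroids(), source="built-in")
        )
        calls = subtyping.assign_nearest_centroid(scaled, centroids)
        calls = subtyping.pamir_label(calls, scores)
        calls.to_csv(outdir / "subtype.csv", index=False)
        exclusions["unclassified_samples"] = int((calls["pam50"] == "unclassified").sum())
        report["subtype"] = {
            "pam50_counts": calls["pam50"].value_counts().to_dict(),
            "pamir_counts": calls["pamir"].value_counts().to_dict(),
        }

    # --- response statistics ---------------------------------------------
    data = clinical.data.set_index("sample_id")
    outcome = data["pcr"]
    exclusions["unknown_pcr"] = int(outcome.isna().sum())
    group = scores.group
    per_dataset: list[stats.ContingencyTable2x2] = []
    dataset_rows = []
    for ds, ids in data.groupby("dataset").groups.items():
        known = [s for s in ids if not pd.isna(outcome.loc[s])]
        if not known:
            continue
        table = stats.make_table(
            group.reindex(known), outcome.reindex(known).astype(bool), dataset=str(ds)
        )
        if min(table.row_margins) == 0:
            logger.info("dataset %s has an empty group; kept for pooling only", ds)
        per_dataset.append(table)
        p, test = stats.auto_test(table)
        or_, ci = stats.odds_ratio(table, haldane=True)
        r1, r2 = stats.rates(table) if min(table.row_margins) > 0 else (np.nan, np.nan)
        dataset_rows.append(
            {
                "dataset": str(ds), "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                "gp_r_rate_pct": stats.percent(r1) if np.isfinite(r1) else None,
                "gp_nr_rate_pct": stats.percent(r2) if np.isfinite(r2) else None,
                "or": or_, "ci_low": ci[0], "ci_high": ci[1], "p": p, "test": test,
            }
        )
    pooled = stats.pool_tables(per_dataset)
    pooled_rates = stats.rates(pooled)
    pooled_p, pooled_test = stats.auto_test(pooled)
    pooled_or, pooled_ci = stats.odds_ratio(pooled, haldane=True)
    response: dict = {
        "per_dataset": dataset_rows,
        "pooled": {
            "a": pooled.a, "b": pooled.b, "c": pooled.c, "d": pooled.d,
            "gp_r_rate_pct": stats.percent(pooled_rates[0]),
            "gp_nr_rate_pct": stats.percent(pooled_rates[1]),
            "or": pooled_or, "ci_low": pooled_ci[0], "ci_high": pooled_ci[1],
            "p": pooled_p, "test": pooled_test,
        },
    }
    if config.run_meta and len(per_dataset) >= 2:
        meta = stats.mh_meta(per_dataset)
        response["meta"] = {
            "method": meta.method,
            "pooled_or": meta.pooled_or,
            "ci_low": meta.pooled_ci[0],
            "ci_high": meta.pooled_ci[1],
            "studies": meta.studies.to_dict(orient="records"),
        }
    screen = stats.univariate_screen(clinical, scores, config.cutoffs)
    screen.to_csv(outdir / "univariate_screen.csv", index=False)
    response["univariate_screen"] = screen.to_dict(orient="records")
    if "rs" in data.columns and data["rs"].notna().any():
        ri = signature.ri_score(data["rs"], scores.is_score)
        exclusions["missing_rs_or_is"] = len(data) - len(ri)
        quadrant_rows = []
        for quadrant in signature.RI_QUADRANTS:
            ids = ri.index[ri["quadrant"] == quadrant]
            known = outcome.reindex(ids).dropna()
            if len(known) == 0:
                continue
            quadrant_rows.append(
                {
                    "quadrant": quadrant,
                    "n": int(len(known)),
                    "pcr_rate_pct": stats.percent(float(known.astype(bool).mean())),
                }
            )
        response["ri_quadrants"] = quadrant_rows
    report["response"] = response

    # --- ROC --------------------------------------------------------------
    if config.run_roc:
        known = outcome.dropna()
        y = known.astype(bool).to_numpy()
        roc: dict = {}
        if y.any() and not y.all():
            is_known = scores.is_score.reindex(known.index).to_numpy()
            roc["is"] = {"auc": roc_auc(is_known, y, name="IS").auc}
            if "rs" in data.columns and data["rs"].notna().all():
                rs_known = data["rs"].reindex(known.index).to_numpy(dtype=float)
                roc["rs"] = {"auc": roc_auc(rs_known, y, name="RS").auc}
                ri_known = rs_known + is_known
                roc["ri"] = {"auc": roc_auc(ri_known, y, name="RI").auc}
                auc_ri, auc_rs, z, p = delong_test(ri_known, rs_known, y)
                roc["delong_ri_vs_rs"] = {"auc_a": auc_ri, "auc_b": auc_rs, "z": z, "p": p}
        report["roc"] = roc

    # --- survival ----------------------------------------------------------
    if config.run_survival and {"time", "event"} <= set(data.columns) and data["time"].notna().any():
        times = data["time"].to_numpy(dtype=float)
        events = data["event"].fillna(False).to_numpy(dtype=bool)
        surv: dict = {"median_followup": median_followup(times, events)}
        if calls is not None:
            labels = (
                calls.set_index("sample_id")["pamir_merged"].reindex(data.index).to_numpy()
            )
            usable = labels != "unclassified"
            if pd.unique(labels[usable]).size >= 2 and events[usable].any():
                chi2, p = logrank(times[usable], events[usable], labels[usable])
                surv["logrank"] = {"chi2": chi2, "p": p, "df": int(pd.unique(labels[usable]).size - 1)}
            curves = km_estimate(times[usable], events[usable], labels[usable])
            surv["groups"] = {
                name: {"n": int((labels[usable] == name).sum()),
                       "final_survival": float(curve.table["survival"].iloc[-1])}
                for name, curve in curves.items()
            }
            pd.concat(
                [curve.table.assign(group=name) for name, curve in curves.items()]
            ).to_csv(outdir / "km_curves.csv", index=False)
        report["survival"] = surv

    eio.write_report(report, outdir / "report.json")
    return report


def make_fixture(outdir, seed: int = 0, n_samples: int = 300) -> dict[str, str]:
    """Write a small self-contained demo dataset (expression, probes, clinical,
    truth, signature model, centroids, pipeline config) and return its paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = simulate.SyntheticConfig(n_samples=n_samples, n_datasets=3, seed=seed)
    matrix, clinical, truth = simulate.simulate_cohort(config)
    clinical = simulate.simulate_survival(clinical, truth, config)
    probes, probe_map = simulate.expand_probes(matrix, 2, seed=seed + 1)

    paths = {
        "expression": str(outdir / "expression.tsv"),
        "probes": str(outdir / "probes.tsv"),
        "probe_map": str(outdir / "probe_map.tsv"),
        "clinical": str(outdir / "clinical.csv"),
        "truth": str(outdir / "truth.csv"),
        "model": str(outdir / "model.json"),
        "centroids": str(outdir / "centroids.json"),
        "config": str(outdir / "pipeline.yaml"),
    }
    eio.write_series_matrix(matrix, paths["expression"])
    eio.write_series_matrix(probes, paths["probes"])
    probe_map.write_tsv(paths["probe_map"])
    clinical.write_csv(paths["clinical"])
    truth.to_csv(paths["truth"], index=False)
    reference.reference_model().to_json(paths["model"])
    subtyping.CentroidSet(simulate.subtype_centroids(), source="built-in").to_json(
        paths["centroids"]
    )
    PipelineConfig(
        expression=paths["expression"],
        clinical=paths["clinical"],
        model=paths["model"],
        centroids=paths["centroids"],
        outdir=str(outdir / "out"),
        seed=seed,
    ).to_yaml(paths["config"])
    return paths
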