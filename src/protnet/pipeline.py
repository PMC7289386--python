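"""End-to-end orchestration: raw matrix to prognostic validation.

Stages run in order — preprocess, learn, components, annotate/activity,
compare, survival — writing every intermediate as TSV (re-readable by the
package's own readers) plus SIF/GraphML graph exports and a machine-readable
JSON manifest.  The manifest echoes all parameters and seeds and carries the
run's edge and component census; it contains no timestamps, so a rerun with
the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path

import pandas as pd

from . import annotation as ann
from . import components as comp
from . import group_stats as gs
from . import pc_stable, preprocess, survival
from .config import PipelineConfig
from .errors import ProtnetError

logger = logging.getLogger(__name__)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    Stage failures raise with a stage-named message; outputs of completed
    stages are left in place.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "protnet",
        "version": _pkg_version("protnet"),
        "config": config.to_dict(),
        "stages": {},
    }

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("preprocess")
        raw = preprocess.read_expression_tsv(config.matrix, stage="raw")
        counts_df = pd.read_csv(config.peptide_counts, sep="\t", index_col=0)
        peptide_counts = counts_df.iloc[:, 0].astype(int).to_dict()
        groups_df = pd.read_csv(config.groups, sep="\t", index_col=0)
        groups = groups_df.iloc[:, 0].astype(str).to_dict()
        rule = preprocess.QuantifiabilityRule(
            config.min_unique_peptides, config.min_detect_fraction
        )
        filtered = preprocess.filter_quantifiable(raw, peptide_counts, groups, rule)
        z = preprocess.zscore(
            preprocess.impute_missing(
                preprocess.log2_transform(filtered),
                config.width_factor,
                config.downshift_factor,
                seed=config.seed,
            )
        )
        z.to_tsv(outdir / "zscored.tsv")
        manifest["stages"]["preprocess"] = {
            "proteins_in": raw.n_proteins,
            "proteins_kept": z.n_proteins,
            "samples": z.n_samples,
        }
    except Exception as exc:
        raise ProtnetError(f"[preprocess] {exc}") from exc

    try:
        _stage("learn")
        g = pc_stable.learn_cpdag(
            z, alpha=config.alpha, max_cond_size=config.max_cond_size,
            corr_method=config.corr_method,
        )
        g.write_graphml(outdir / "graph.graphml")
        g.write_sif(outdir / "graph.sif")
        census = g.edge_census()
        pd.DataFrame(
            [
                {"edge_type": "guided", "count": census["directed"]},
                {"edge_type": "undetermined", "count": census["undirected"]},
                {"edge_type": "total", "count": census["total"]},
            ]
        ).to_csv(outdir / "edge_census.tsv", sep="\t", index=False)
        manifest["stages"]["learn"] = {
            "alpha": config.alpha,
            "edges_total": census["total"],
            "edges_guided": census["directed"],
            "edges_undetermined": census["undirected"],
            "n_ci_tests": g.meta.get("n_ci_tests"),
            "n_ci_skipped": g.meta.get("n_ci_skipped"),
        }
    except Exception as exc:
        raise ProtnetError(f"[learn] {exc}") from exc

    try:
        _stage("components")
        all_comps = comp.connected_components(g)
        dist = comp.size_distribution(all_comps)
        kept = comp.filter_components(
            all_comps, config.min_component_size, config.max_component_size
        )
        comp.components_to_frame(all_comps).to_csv(
            outdir / "components.tsv", sep="\t", index=False
        )
        comp.size_distribution_to_frame(dist).to_csv(outdir / "size_census.tsv", sep="\t")
        manifest["stages"]["components"] = {
            "n_components": len(all_comps),
            "n_kept": len(kept),
            "size_distribution": {str(k): v for k, v in dist.items()},
        }
    except Exception as exc:
        raise ProtnetError(f"[components] {exc}") from exc

    try:
        _stage("annotate/activity")
        table = ann.load_annotation_tsv(config.annotation, config.annotation_background)
        annotated = []
        for c in kept:
            enriched = ann.enrich_terms(c, table)
            annotated.append(ann.assign_major_function(c, enriched))
        activities = ann.activity_matrix(annotated, z, table)
        activities.to_csv(outdir / "activities.tsv", sep="\t")
        pd.DataFrame(
            [
                {
                    "component_id": c.id,
                    "n_nodes": c.n_nodes,
                    "major_function": c.major_function,
                    "source": c.function_source,
                }
                for c in annotated
            ]
        ).to_csv(outdir / "component_functions.tsv", sep="\t", index=False)
        manifest["stages"]["activity"] = {"n_components_scored": len(annotated)}
    except Exception as exc:
        raise ProtnetError(f"[annotate/activity] {exc}") from exc

    try:
        _stage("compare")
        clinical = gs.read_clinical_tsv(config.clinical)
        comparisons = gs.compare_all(activities, clinical)
        comparisons.to_csv(outdir / "comparisons.tsv", sep="\t", index=False)
        manifest["stages"]["compare"] = {"n_rows": int(len(comparisons))}
    except Exception as exc:
        raise ProtnetError(f"[compare] {exc}") from exc

    try:
        _stage("survival")
        ranking = survival.rank_components_by_survival(
            activities, clinical, config.threshold_percentile
        )
        ranking.to_csv(outdir / "survival_ranking.tsv", sep="\t", index=False)
        scan = tuple(config.scan) if config.scan is not None else None
        results = survival.loo_permutation_validate(
            activities, clinical,
            B=config.permutations, seed=config.seed,
            threshold_percentile=config.threshold_percentile, scan=scan,
        )
        rows = []
        for r in results:
            rows.append(
                {
                    "component_id": r.component_id,
                    "hazard_ratio": r.hazard_ratio,
                    "coef": r.coef,
                    "cox_p": r.cox_p,
                    "km_logrank_p": r.km_logrank_p,
                    "risk_threshold": r.risk_threshold,
                    "permutation_p": r.permutation_p,
                    "observed_statistic": r.observed_statistic,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "survival_validation.tsv", sep="\t", index=False)
        if results:
            best = min(results, key=lambda r: r.permutation_p)
            best.risk_labels.rename("risk").to_csv(
                outdir / "risk_labels.tsv", sep="\t", index_label="sample_id"
            )
            survival.risk_by_subtype(best, clinical).to_csv(
                outdir / "risk_by_subtype.tsv", sep="\t"
            )
            _write_km_curves(best, clinical, outdir / "km_curves.tsv")
            manifest["stages"]["survival"] = {
                "n_components_validated": len(results),
                "best_component": best.component_id,
                "best_permutation_p": best.permutation_p,
                "best_hazard_ratio": best.hazard_ratio,
            }
        else:
            manifest["stages"]["survival"] = {"n_components_validated": 0}
    except Exception as exc:
        raise ProtnetError(f"[survival] {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _write_km_curves(result, clinical, path) -> None:
    """Kaplan-Meier coordinates per risk group, for external plotting."""
    from lifelines import KaplanMeierFitter

    df = clinical.df.loc[result.risk_labels.index]
    rows = []
    for group in ("low", "high"):
        mask = (result.risk_labels == group).to_numpy()
        if mask.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(df["time"][mask], df["event"][mask], label=group)
        sf = kmf.survival_function_
        for t, s in zip(sf.index, sf[group]):
            rows.append({"risk_group": group, "time": float(t), "survival": float(s)})
    pd.DataFrame(rows, columns=["risk_group", "time", "survival"]).to_csv(
        path, sep="\t", index=False
    )
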