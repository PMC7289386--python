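"""Offline functional annotation and component-activity scoring.

Each network component is assigned a *major biological function* by
hypergeometric over-representation of annotation terms from a packaged
flat-file table (protein_id, gene_symbol, term_id, term_label, source), with
an override hook for manually curated labels.  A component's per-sample
*activity* is then the mean z-score of its member proteins annotated to that
major function — a one-number functional readout per component and sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .components import Component
from .errors import LabellingError
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["protein_id", "gene_symbol", "term_id", "term_label", "source"]


@dataclass
class AnnotationTable:
    """Flat protein-to-term annotation with a fixed background size.

    ``background`` is the total number of annotated genes in the reference
    population (the hypergeometric urn size N).  Term "descendant closure" is
    assumed to be precomputed into the rows: a protein annotated to a
    descendant of term T also carries a row for T.
    """

    df: pd.DataFrame
    background: int

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.df.columns]
        if missing:
            raise LabellingError(f"annotation table missing columns: {missing}")
        if self.df.duplicated(["protein_id", "term_id"]).any():
            dupes = self.df[self.df.duplicated(["protein_id", "term_id"])]
            raise LabellingError(
                f"duplicate (protein_id, term_id) pairs, e.g. "
                f"{dupes.iloc[0][['protein_id', 'term_id']].tolist()}"
            )
        if self.background < self.df["protein_id"].nunique():
            raise ValueError("background smaller than the number of annotated proteins")

    def proteins_for_term(self, term_id: str) -> set[str]:
        return set(self.df.loc[self.df["term_id"] == term_id, "protein_id"])

    def annotated(self) -> set[str]:
        return set(self.df["protein_id"])

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def load_annotation_tsv(path, background: int) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return AnnotationTable(df, background)


def enrich_terms(component: Component, table: AnnotationTable) -> pd.DataFrame:
    """Term over-representation in a component (one-sided hypergeometric).

    For each term with at least one member overlap: overlap ``k``, annotated
    component size ``m``, term size ``K``, background ``N``; the p-value is
    the upper tail P(X >= k) of Hypergeometric(N, K, m).  Rows are ranked by
    raw p, then overlap (descending), then term_id; a Benjamini-Hochberg q is
    reported alongside but does not drive the ranking.
    """
    members = set(component.members)
    annotated_members = members & table.annotated()
    m = len(annotated_members)
    if m == 0:
        logger.warning("component %s has no annotated member", component.id)
        return pd.DataFrame(
            columns=["term_id", "term_label", "source", "k", "m", "K", "N",
                     "p_value", "q_value"]
        )
    N = table.background
    sub = table.df[table.df["protein_id"].isin(annotated_members)]
    rows = []
    for term_id, grp in sub.groupby("term_id"):
        k = grp["protein_id"].nunique()
        K = int((table.df["term_id"] == term_id).sum())
        p = float(stats.hypergeom.sf(k - 1, N, K, m))
        rows.append(
            {
                "term_id": term_id,
                "term_label": grp["term_label"].iloc[0],
                "source": grp["source"].iloc[0],
                "k": k, "m": m, "K": K, "N": N,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out = out.sort_values(
        ["p_value", "k", "term_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return out


def assign_major_function(
    component: Component,
    enriched: pd.DataFrame | None = None,
    override: str | None = None,
) -> Component:
    """Set the component's major function from enrichment or a curated label.

    An explicit ``override`` wins over any ranking (major-function labels are
    often curated summaries rather than single ontology terms).  Otherwise the
    top-ranked enriched term's label is used.  With neither, the component is
    returned unassigned and flagged in the log.
    """
    if override is not None:
        return replace(component, major_function=override, function_source="override")
    if enriched is not None and len(enriched):
        top = enriched.iloc[0]
        return replace(
            component,
            major_function=str(top["term_label"]),
            function_source=f"enrichment:{top['term_id']}",
        )
    logger.warning("component %s left without a major function", component.id)
    return replace(component, major_function=None, function_source=None)


@dataclass
class ActivityVector:
    """Per-sample activity of one component (mean z-score units)."""

    component_id: str
    values: pd.Series  # indexed by sample id
    contributing: tuple[str, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(float)).all():
            raise ValueError(f"non-finite activity for {self.component_id}")


def component_activity(
    component: Component,
    matrix: ExpressionMatrix,
    table: AnnotationTable | None = None,
    allow_fallback: bool = True,
) -> ActivityVector:
    """Mean z-score, per sample, of the members carrying the major function.

    The contributing set is the members annotated (in ``table``) to the
    component's major-function term; when the component has no major function
    or no member is annotated to it, all members contribute (logged fallback)
    unless ``allow_fallback`` is false.
    """
    if matrix.stage != "zscored":
        raise LabellingError("component_activity requires a z-scored matrix")
    members = [p for p in component.members if p in matrix.data.index]
    if len(members) < len(component.members):
        missing = set(component.members) - set(members)
        raise LabellingError(f"members absent from matrix: {sorted(missing)[:5]}")
    contributing = list(component.members)
    if component.major_function is not None and table is not None:
        term_ids = set(
            table.df.loc[
                table.df["term_label"] == component.major_function, "term_id"
            ]
        )
        if component.function_source and component.function_source.startswith(
            "enrichment:"
        ):
            term_ids.add(component.function_source.split(":", 1)[1])
        carriers = set(
            table.df.loc[table.df["term_id"].isin(term_ids), "protein_id"]
        )
        annotated = [p for p in component.members if p in carriers]
        if annotated:
            contributing = annotated
        elif allow_fallback:
            logger.info(
                "component %s: no member annotated to %r; all members contribute",
                component.id, component.major_function,
            )
        else:
            raise LabellingError(
                f"component {component.id}: empty contributing set and fallback disabled"
            )
    values = matrix.data.loc[contributing].mean(axis=0)
    return ActivityVector(
        component_id=component.id,
        values=values,
        contributing=tuple(contributing),
    )


def activity_matrix(
    components: list[Component],
    matrix: ExpressionMatrix,
    table: AnnotationTable | None = None,
) -> pd.DataFrame:
    """Stack component activities into a components-by-samples DataFrame."""
    rows = {
        c.id: component_activity(c, matrix, table).values for c in components
    }
    out = pd.DataFrame(rows).T
    out.index.name = "component_id"
    return out
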