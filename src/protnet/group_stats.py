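"""Subtype comparisons of component activities (Mann-Whitney).

Activities are compared between tumour subtype groups (e.g. ER-true vs
TN-like vs TNBC) with the two-sided Mann-Whitney rank-sum test — exact for
small tie-free samples, normal approximation with tie and continuity
correction otherwise.  Raw p-values drive interpretation; Benjamini-Hochberg
q-values across the whole comparison table are reported alongside.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import ActivityVector
from .errors import LabellingError

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ["subtype", "time", "event"]


@dataclass
class ClinicalTable:
    """Per-sample subtype label plus follow-up time and event indicator.

    ``df`` is indexed by sample id with columns subtype (str), time
    (nonnegative, months) and event (bool; distant metastasis observed).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise LabellingError(f"clinical table missing columns: {missing}")
        if self.df.index.has_duplicates:
            raise LabellingError("duplicate sample ids in clinical table")
        if self.df["subtype"].isna().any():
            raise LabellingError("null subtype label")
        if (self.df["time"].astype(float) < 0).any():
            raise ValueError("negative follow-up time")
        self.df = self.df.assign(
            time=self.df["time"].astype(float), event=self.df["event"].astype(bool)
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def subtypes(self) -> list[str]:
        return sorted(self.df["subtype"].unique())

    def samples_in(self, subtype: str) -> list[str]:
        return list(self.df.index[self.df["subtype"] == subtype])

    def check_samples(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.df.index]
        if missing:
            raise LabellingError(f"samples missing from clinical table: {missing[:5]}")

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out["event"] = out["event"].astype(int)
        out.to_csv(path, sep="\t", index_label="sample_id")


def read_clinical_tsv(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return ClinicalTable(df)


def mann_whitney_compare(
    activity: ActivityVector | pd.Series,
    clinical: ClinicalTable,
    group_a: str,
    group_b: str,
    exact_threshold: int = 20,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney comparison of one activity between two subtypes.

    Returns (U, p) where U is the rank-sum statistic of ``group_a``.  The
    exact null distribution is used when the combined sample size is at most
    ``exact_threshold`` and there are no ties; otherwise the normal
    approximation with midrank tie correction and continuity correction.
    """
    values = activity.values if isinstance(activity, ActivityVector) else activity
    a = values.loc[[s for s in clinical.samples_in(group_a) if s in values.index]]
    b = values.loc[[s for s in clinical.samples_in(group_b) if s in values.index]]
    if len(a) == 0 or len(b) == 0:
        raise LabellingError(
            f"empty group in comparison {group_a!r} vs {group_b!r}"
        )
    if len(a) == 1 or len(b) == 1:
        logger.warning(
            "group of size 1 in %s vs %s; p-value approximation unreliable",
            group_a, group_b,
        )
    pooled = np.concatenate([a.to_numpy(float), b.to_numpy(float)])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= exact_threshold and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a.to_numpy(float), b.to_numpy(float), alternative="two-sided", method=method
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_all(
    activities: pd.DataFrame,
    clinical: ClinicalTable,
    pairs: list[tuple[str, str]] | None = None,
    exact_threshold: int = 20,
) -> pd.DataFrame:
    """All requested pairwise subtype comparisons for every component.

    ``activities`` is components x samples.  Returns a long table with one
    row per (component, pair): U, raw p and a BH-adjusted q computed across
    the whole table.
    """
    if pairs is None:
        pairs = list(itertools.combinations(clinical.subtypes(), 2))
    rows = []
    for cid, values in activities.iterrows():
        for ga, gb in pairs:
            u, p = mann_whitney_compare(values, clinical, ga, gb, exact_threshold)
            rows.append(
                {
                    "component_id": cid,
                    "group_a": ga,
                    "group_b": gb,
                    "U": u,
                    "p_value": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
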