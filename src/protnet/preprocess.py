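"""Preprocessing of label-free quantification matrices.

A raw LFQ intensity matrix (proteins x samples, with missing values where a
protein was not detected in a run) is turned into the filtered, log2-scaled,
imputed, per-protein z-scored matrix that downstream correlation-based network
learning consumes.  The four stages are explicit and ordered:

    raw -> (quantifiability filter) -> log2 -> imputed -> zscored

Missing values in label-free MS are predominantly left-censored (low-abundance
proteins drop below the detection limit), so imputation draws from a
down-shifted, shrunken normal distribution fitted per sample column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    EmptyResultError,
    InsufficientDataError,
    LabellingError,
    StageError,
)

logger = logging.getLogger(__name__)

STAGES = ("raw", "log2", "imputed", "zscored")

_ZSCORE_TOL = 1e-9


@dataclass
class ExpressionMatrix:
    """Protein-by-sample expression matrix with an explicit processing stage.

    ``data`` is a pandas DataFrame with protein identifiers on the index and
    sample identifiers on the columns; ``NaN`` marks missing values.  The
    ``stage`` tag enforces the preprocessing order: operations check it and
    refuse matrices at the wrong stage.
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise LabellingError(f"duplicate protein ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise LabellingError(f"duplicate sample ids: {dups[:5]}")
        if self.stage in ("imputed", "zscored") and self.data.isna().any().any():
            raise StageError(f"stage {self.stage!r} must not contain missing values")
        if self.stage == "zscored" and len(self.data.columns) > 0:
            vals = self.data.to_numpy(float)
            if vals.size and vals.shape[1] > 1:
                means = vals.mean(axis=1)
                sd0 = vals.std(axis=1, ddof=0)
                sd1 = vals.std(axis=1, ddof=1)
                sd_off = np.minimum(np.abs(sd0 - 1.0), np.abs(sd1 - 1.0))
                if np.abs(means).max() > _ZSCORE_TOL or sd_off.max() > 1e-6:
                    raise StageError(
                        "stage 'zscored' requires per-protein mean 0 and sd 1"
                    )

    # -- convenience views ------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.data.isna().to_numpy()

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.stage)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="protein_id", na_rep="NA")


@dataclass(frozen=True)
class QuantifiabilityRule:
    """Which proteins count as reliably quantified.

    A protein is kept when it shows at least ``min_unique_peptides`` unique
    peptides and was detected in at least ``min_detect_fraction`` of the
    samples of at least one sample group (e.g. receptor-defined tumour types).
    """

    min_unique_peptides: int = 2
    min_detect_fraction: float = 0.75

    def __post_init__(self) -> None:
        if not (0.0 < self.min_detect_fraction <= 1.0):
            raise ValueError("min_detect_fraction must be in (0, 1]")
        if self.min_unique_peptides < 0:
            raise ValueError("min_unique_peptides must be nonnegative")


def read_expression_tsv(
    path,
    stage: str = "raw",
    missing_tokens: tuple[str, ...] = ("", "NA", "NaN", "nan"),
    zero_is_missing: bool = True,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a tab-separated quantification matrix.

    First column holds protein ids, the header row sample ids. Empty cells and
    the tokens in ``missing_tokens`` are treated as missing; with
    ``zero_is_missing`` (the default for raw intensity matrices) exact zeros
    are treated as not-detected, as LFQ tools emit them.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=list(missing_tokens),
        keep_default_na=False,
    )
    df = df.astype(float)
    if zero_is_missing and stage == "raw":
        df = df.mask(df == 0.0)
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, stage=stage)


def filter_quantifiable(
    matrix: ExpressionMatrix,
    peptide_counts: Mapping[str, int],
    groups: Mapping[str, str],
    rule: QuantifiabilityRule = QuantifiabilityRule(),
) -> ExpressionMatrix:
    """Keep proteins satisfying the quantifiability rule.

    Retains exactly the proteins with peptide count >= rule.min_unique_peptides
    whose non-missing fraction reaches rule.min_detect_fraction within at least
    one sample group.  Protein order and the sample axis are preserved, so the
    operation is idempotent.
    """
    missing_p = [p for p in matrix.protein_ids if p not in peptide_counts]
    if missing_p:
        raise LabellingError(f"no peptide count for proteins: {missing_p[:5]}")
    missing_s = [s for s in matrix.sample_ids if s not in groups]
    if missing_s:
        raise LabellingError(f"no group label for samples: {missing_s[:5]}")

    detected = ~matrix.data.isna()
    group_series = pd.Series({s: groups[s] for s in matrix.sample_ids})
    frac_by_group = detected.T.groupby(group_series).mean().T  # proteins x groups
    best_frac = frac_by_group.max(axis=1)
    counts = pd.Series({p: int(peptide_counts[p]) for p in matrix.protein_ids})
    keep = (counts >= rule.min_unique_peptides) & (
        best_frac >= rule.min_detect_fraction
    )
    if not keep.any():
        raise EmptyResultError("quantifiability filter removed every protein")
    kept = matrix.data.loc[keep[keep].index]
    logger.info(
        "quantifiability filter: kept %d / %d proteins", kept.shape[0], matrix.n_proteins
    )
    return ExpressionMatrix(kept, stage=matrix.stage)


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform all non-missing intensities (stage raw -> log2)."""
    if matrix.stage != "raw":
        raise StageError(f"log2_transform expects stage 'raw', got {matrix.stage!r}")
    vals = matrix.data.to_numpy(float)
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DomainError(
            f"non-positive intensity for protein {matrix.protein_ids[i]!r} "
            f"in sample {matrix.sample_ids[j]!r}"
        )
    out = pd.DataFrame(
        np.log2(vals), index=matrix.data.index, columns=matrix.data.columns
    )
    return ExpressionMatrix(out, stage="log2")


def impute_missing(
    matrix: ExpressionMatrix,
    width_factor: float = 0.3,
    downshift_factor: float = 1.8,
    seed: int = 0,
) -> ExpressionMatrix:
    """Replace missing values by draws from a down-shifted normal, per column.

    For each sample column, missing entries are drawn from
    ``N(mean_obs - downshift_factor * sd_obs, (width_factor * sd_obs)^2)``
    where mean_obs / sd_obs are computed on the observed values of that column.
    This emulates left-censored label-free missingness: imputed values sit in
    the low-abundance tail.  Deterministic given ``seed``.
    """
    if matrix.stage != "log2":
        raise StageError(f"impute_missing expects stage 'log2', got {matrix.stage!r}")
    rng = np.random.default_rng(seed)
    out = matrix.data.copy()
    for col in out.columns:
        column = out[col]
        miss = column.isna()
        if not miss.any():
            continue
        obs = column[~miss]
        if len(obs) < 3:
            raise InsufficientDataError(
                f"sample {col!r} has only {len(obs)} observed values; "
                "cannot estimate an imputation distribution"
            )
        mu = obs.mean()
        sd = obs.std(ddof=1)
        draws = rng.normal(
            loc=mu - downshift_factor * sd,
            scale=width_factor * sd,
            size=int(miss.sum()),
        )
        out.loc[miss, col] = draws
    return ExpressionMatrix(out, stage="imputed")


def zscore(matrix: ExpressionMatrix, ddof: int = 0) -> ExpressionMatrix:
    """Center and scale each protein row to mean 0, sd 1 (population sd).

    Accepts stage 'imputed' or 'zscored' (the operation is idempotent within
    tolerance).  ``ddof=0`` (population denominator) is the default; set
    ``ddof=1`` for the sample-sd convention.
    """
    if matrix.stage not in ("imputed", "zscored"):
        raise StageError(
            f"zscore expects stage 'imputed' (or 'zscored'), got {matrix.stage!r}"
        )
    vals = matrix.data.to_numpy(float)
    sds = vals.std(axis=1, ddof=ddof)
    zero = np.where(sds == 0)[0]
    if zero.size:
        raise DomainError(
            f"zero-variance protein row(s): {[matrix.protein_ids[i] for i in zero[:5]]}"
        )
    z = (vals - vals.mean(axis=1, keepdims=True)) / sds[:, None]
    out = pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(out, stage="zscored")
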