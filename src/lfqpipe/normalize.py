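"""Quantification chain: retention filter, detection-limit imputation,
peptide-count normalization and fraction-of-total scaling.

The chain mirrors common label-free practice: proteins must carry more
than one unique peptide and be observed in at least one replicate of some
group; missing values (left-censored non-detections) are replaced by
draws from a down-shifted normal on the log2 scale (mean shifted
``shift`` run-SDs below the run mean, width ``width`` run-SDs); areas are
divided by each protein's theoretical peptide count; and each run is
rescaled to fractions of its total so that runs are directly comparable.
All downstream statistics consume the log2 fractions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import AreaMatrix, NormalizedMatrix, SchemaError, validate_design

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationParams:
    """Down-shifted-normal imputation parameters (log2 scale, per run)."""

    shift: float = 1.8
    width: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")


def filter_proteins(
    matrix: AreaMatrix,
    design: pd.DataFrame,
    min_replicates_present: int = 1,
    min_unique_peptides: int = 2,
) -> AreaMatrix:
    """Retention filter.

    Keeps proteins with ``unique_peptides >= min_unique_peptides``
    (default: more than one unique peptide) that are observed in at least
    ``min_replicates_present`` runs of at least one group.  Row order is
    preserved.
    """
    validate_design(design, matrix.run_ids)
    observed = matrix.areas.notna()
    present_somewhere = pd.Series(False, index=matrix.areas.index)
    for group in design["group"].unique():
        runs = design.index[design["group"] == group]
        present_somewhere |= observed[list(runs)].sum(axis=1) >= min_replicates_present
    keep = (matrix.unique_peptides >= min_unique_peptides) & present_somewhere
    dropped = int((~keep).sum())
    logger.info(
        "retention filter: kept %d / %d proteins (dropped %d; >=%d unique peptides, "
        "present in >=%d replicate(s) of some group)",
        int(keep.sum()), len(keep), dropped, min_unique_peptides, min_replicates_present,
    )
    return AreaMatrix(matrix.areas.loc[keep].copy(), matrix.unique_peptides.loc[keep].copy())


class DetectionLimitImputer(BaseEstimator, TransformerMixin):
    """Impute left-censored missing values from a down-shifted normal.

    For each run (column), the observed areas' log2 mean ``m`` and
    standard deviation ``s`` (ddof=1) are estimated at ``fit`` time;
    ``transform`` replaces each missing cell with ``2**x`` where
    ``x ~ Normal(m - shift*s, (width*s)**2)``, simulating expression
    below the detection limit.  Observed cells are never altered.

    Parameters
    ----------
    shift : float, default 1.8
        Down-shift of the imputation mean, in run-SD multiples.
    width : float, default 0.3
        SD of the imputation distribution, in run-SD multiples.
    random_state : int, default 0
        Seed; identical seed and input give identical output.

    Attributes
    ----------
    run_log2_mean_, run_log2_sd_ : pandas.Series
        Per-run observed-value statistics on the log2 scale.
    imputed_mask_ : pandas.DataFrame
        After ``transform``: True where a value was drawn.
    """

    def __init__(self, shift: float = 1.8, width: float = 0.3, random_state: int = 0):
        self.shift = shift
        self.width = width
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        ImputationParams(self.shift, self.width, self.random_state)  # validate
        log2 = np.log2(X.where(X > 0))
        empty = log2.notna().sum(axis=0) == 0
        if empty.any():
            bad = list(X.columns[empty])
            raise ValueError(f"run(s) with no observed values cannot be imputed: {bad}")
        self.run_log2_mean_ = log2.mean(axis=0, skipna=True)
        self.run_log2_sd_ = log2.std(axis=0, ddof=1, skipna=True).fillna(0.0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        rng = np.random.default_rng(self.random_state)
        out = X.copy()
        mask = X.isna()
        for run in X.columns:
            n_missing = int(mask[run].sum())
            if n_missing == 0:
                continue
            m = self.run_log2_mean_[run]
            s = self.run_log2_sd_[run]
            draws = rng.normal(m - self.shift * s, self.width * s, n_missing)
            out.loc[mask[run], run] = np.exp2(draws)
        self.imputed_mask_ = mask
        return out


def impute_missing(matrix: AreaMatrix, params: ImputationParams = ImputationParams()) -> AreaMatrix:
    """Complete an area matrix by detection-limit imputation.

    Returns a new :class:`AreaMatrix` whose ``imputed_mask`` records cell
    provenance; observed cells are bit-identical to the input.  A matrix
    without missing cells is returned unchanged (mask all-False).
    """
    imputer = DetectionLimitImputer(params.shift, params.width, params.seed)
    filled = imputer.fit_transform(matrix.areas)
    return AreaMatrix(filled, matrix.unique_peptides.copy(), imputer.imputed_mask_)


def normalize(matrix: AreaMatrix, peptide_counts: pd.DataFrame) -> NormalizedMatrix:
    """Peptide-count normalization followed by fraction-of-total scaling.

    ``value1 = area / n_theoretical_peptides``; ``fraction`` is value1's
    share of the run total; ``log2_fractions`` feeds the statistics.
    Proteins with a zero peptide count are dropped with a warning.
    """
    counts = peptide_counts["n_theoretical_peptides"].reindex(matrix.areas.index)
    if counts.isna().any():
        missing = list(matrix.areas.index[counts.isna()])[:5]
        raise SchemaError(f"no peptide count for accession(s): {missing}")
    zero = counts == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} protein(s) with zero theoretical peptides",
            stacklevel=2,
        )
        logger.warning("dropped %d zero-peptide-count proteins", int(zero.sum()))
    areas = matrix.areas.loc[~zero]
    if areas.isna().any().any():
        raise ValueError("normalize() requires a complete (imputed) matrix")
    value1 = areas.div(counts[~zero], axis=0)
    totals = value1.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero total normalized area in run(s): {bad}")
    fractions = value1.div(totals, axis=1)
    mask = (
        matrix.imputed_mask.loc[~zero]
        if matrix.imputed_mask is not None
        else pd.DataFrame(False, index=fractions.index, columns=fractions.columns)
    )
    return NormalizedMatrix(fractions, np.log2(fractions), mask)


def group_summary(norm: NormalizedMatrix, design: pd.DataFrame) -> pd.DataFrame:
    """Per-protein, per-group mean and SD of log2 fractions.

    Returns a long table keyed (accession, group) with columns ``mean``,
    ``sd`` and ``n_runs``; SD is NaN-flagged for single-run groups.
    """
    validate_design(design, norm.run_ids)
    records = []
    for group in design["group"].unique():
        runs = list(design.index[design["group"] == group])
        sub = norm.log2_fractions[runs]
        records.append(
            pd.DataFrame(
                {
                    "accession": sub.index,
                    "group": group,
                    "mean": sub.mean(axis=1).to_numpy(),
                    "sd": sub.std(axis=1, ddof=1).to_numpy(),
                    "n_runs": len(runs),
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def group_mean_matrix(summary: pd.DataFrame, groups) -> pd.DataFrame:
    """Pivot a group summary to an accession x group matrix of means."""
    wide = summary.pivot(index="accession", columns="group", values="mean")
    return wide[list(groups)]
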