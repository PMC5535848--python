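"""Core in-memory containers shared across pipeline stages.

The pipeline's entry point is a protein x run matrix of MS1 precursor-ion
areas with missing entries (below-detection-limit non-detections), plus a
design table mapping each MS run to its experimental group and biological
replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """Raised when an input table does not match the expected schema."""


@dataclass
class AreaMatrix:
    """Protein x run precursor-area matrix.

    Parameters
    ----------
    areas : pandas.DataFrame
        Rows indexed by protein accession, columns by run id.  Values are
        non-negative precursor-ion areas; ``NaN`` marks a missing
        (non-detected) entry.  Zero areas are treated as non-detections
        and coerced to ``NaN`` on construction.
    unique_peptides : pandas.Series
        Per-accession count of unique identified peptides, used by the
        retention filter (proteins with more than one unique peptide are
        kept by default).
    imputed_mask : pandas.DataFrame or None
        Boolean mask aligned with ``areas``; ``True`` where the value was
        drawn by the detection-limit imputer rather than observed.
    """

    areas: pd.DataFrame
    unique_peptides: pd.Series
    imputed_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.areas.index.has_duplicates:
            dups = self.areas.index[self.areas.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate accessions in area matrix: {dups}")
        if self.areas.columns.has_duplicates:
            raise SchemaError("duplicate run ids in area matrix")
        vals = self.areas.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative precursor areas are not allowed")
        # a recorded zero area is a non-detection
        self.areas = self.areas.where(self.areas > 0)
        self.unique_peptides = self.unique_peptides.reindex(self.areas.index)
        if self.unique_peptides.isna().any():
            missing = self.unique_peptides.index[self.unique_peptides.isna()].tolist()
            raise SchemaError(f"missing unique-peptide counts for: {missing[:5]}")

    @property
    def accessions(self) -> list[str]:
        return list(self.areas.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.areas.columns)

    @property
    def observed_mask(self) -> pd.DataFrame:
        """True where an area was measured (and not imputed)."""
        obs = self.areas.notna()
        if self.imputed_mask is not None:
            obs &= ~self.imputed_mask
        return obs

    def copy(self) -> "AreaMatrix":
        return AreaMatrix(
            self.areas.copy(),
            self.unique_peptides.copy(),
            None if self.imputed_mask is None else self.imputed_mask.copy(),
        )


@dataclass
class NormalizedMatrix:
    """Fraction-of-total normalized matrix.

    ``fractions`` holds each protein's share of the summed
    peptide-count-normalized area within a run (columns sum to 1);
    ``log2_fractions`` is its log2, the scale on which all downstream
    statistics run.  ``imputed_mask`` records cell provenance.
    """

    fractions: pd.DataFrame
    log2_fractions: pd.DataFrame
    imputed_mask: pd.DataFrame

    @property
    def accessions(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.fractions.columns)


def validate_design(design: pd.DataFrame, run_ids=None) -> pd.DataFrame:
    """Check a design table (index run_id, columns ``group``/``replicate``).

    When ``run_ids`` is given, require the design to cover exactly those runs.
    """
    for col in ("group", "replicate"):
        if col not in design.columns:
            raise SchemaError(f"design table lacks required column '{col}'")
    if design.index.has_duplicates:
        raise SchemaError("duplicate run ids in design table")
    if run_ids is not None:
        missing = set(run_ids) - set(design.index)
        extra = set(design.index) - set(run_ids)
        if missing or extra:
            raise SchemaError(
                f"design/matrix run mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
    return design


def runs_of_group(design: pd.DataFrame, group: str) -> list[str]:
    runs = list(design.index[design["group"] == group])
    if not runs:
        raise SchemaError(f"unknown group label: {group!r}")
    return runs
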