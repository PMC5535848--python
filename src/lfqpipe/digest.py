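"""In-silico tryptic digestion and theoretical peptide counting.

Trypsin cleaves C-terminal to lysine (K) or arginine (R); cleavage is
suppressed when the following residue is proline (the classical "no K/R
before P" specificity rule, toggleable).  The theoretical peptide count of
a protein — the number of fully-cleaved peptides within a length window —
is the per-protein denominator of the quantification normalization, the
same role the count plays in iBAQ-style normalization.

Two parameter conventions are exposed:

* ``SEARCH_PARAMS``: up to 2 missed cleavages, length >= 7, matching a
  typical database-search configuration.
* ``COUNTING_PARAMS``: 0 missed cleavages, length 7-30, the convention
  used for the normalization denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DigestParams:
    """Tryptic digest parameters.

    max_peptide_length may be ``None`` for no upper bound.
    """

    max_missed_cleavages: int = 2
    min_peptide_length: int = 7
    max_peptide_length: int | None = 30
    proline_rule: bool = True

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_peptide_length < 1:
            raise ValueError("min_peptide_length must be >= 1")
        if (
            self.max_peptide_length is not None
            and self.max_peptide_length < self.min_peptide_length
        ):
            raise ValueError("max_peptide_length must be >= min_peptide_length")


#: database-search emulation: <=2 missed cleavages, peptides of >=7 residues
SEARCH_PARAMS = DigestParams(max_missed_cleavages=2, min_peptide_length=7, max_peptide_length=None)
#: counting convention for the normalization denominator: fully cleaved, 7-30 residues
COUNTING_PARAMS = DigestParams(max_missed_cleavages=0, min_peptide_length=7, max_peptide_length=30)


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """Return cut positions: index i means a cut between residue i-1 and i."""
    sites = []
    n = len(sequence)
    for i, res in enumerate(sequence):
        if res in "KR" and i < n - 1:
            if proline_rule and sequence[i + 1] == "P":
                continue
            sites.append(i + 1)
    return sites


def _validate_sequence(sequence: str) -> None:
    for off, res in enumerate(sequence):
        if res not in VALID_RESIDUES:
            raise ValueError(
                f"illegal residue {res!r} at offset {off}: sequence must use the 20-letter alphabet"
            )


def digest(sequence: str, params: DigestParams = DigestParams()) -> list[str]:
    """Enumerate tryptic peptides of ``sequence`` under ``params``.

    Peptides are returned in N- to C-terminal order of their start
    position; repeated subsequences occurring at distinct positions are
    kept as distinct entries.  An empty sequence yields an empty list.
    """
    _validate_sequence(sequence)
    if not sequence:
        return []
    bounds = [0] + cleavage_sites(sequence, params.proline_rule) + [len(sequence)]
    lo, hi = params.min_peptide_length, params.max_peptide_length
    peptides = []
    for i in range(len(bounds) - 1):
        # peptide spanning fragments i .. j-1 has j-1-i internal (missed) sites
        for j in range(i + 1, min(i + 2 + params.max_missed_cleavages, len(bounds))):
            length = bounds[j] - bounds[i]
            if length < lo:
                continue
            if hi is not None and length > hi:
                break
            peptides.append(sequence[bounds[i] : bounds[j]])
    return peptides


def count_theoretical_peptides(
    proteome: dict[str, str], params: DigestParams = COUNTING_PARAMS
) -> pd.DataFrame:
    """Theoretical peptide count per protein.

    Parameters
    ----------
    proteome : dict
        Mapping accession -> amino-acid sequence.
    params : DigestParams
        Digest convention; defaults to the counting convention
        (0 missed cleavages, length 7-30).

    Returns
    -------
    pandas.DataFrame
        Indexed by accession with columns ``n_theoretical_peptides`` and
        ``zero_count`` (flagging proteins the normalization must drop).

    Raises
    ------
    ValueError
        If the proteome is empty or contains duplicate accessions.
    """
    if not proteome:
        raise ValueError("proteome is empty")
    accs = list(proteome)
    if len(set(accs)) != len(accs):
        dups = sorted({a for a in accs if accs.count(a) > 1})
        raise ValueError(f"duplicate accessions: {dups}")
    counts = {acc: len(digest(seq, params)) for acc, seq in proteome.items()}
    table = pd.DataFrame(
        {"n_theoretical_peptides": pd.Series(counts, dtype=int)}
    ).rename_axis("accession")
    table["zero_count"] = table["n_theoretical_peptides"] == 0
    return table
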