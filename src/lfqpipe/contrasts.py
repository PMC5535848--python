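"""Per-protein pairwise group contrasts.

Each contrast is a two-sample t-test on log2 fractions (pooled-variance
Student's t by default, Welch by flag), flagged significant at raw
P < alpha.  No multiple-testing correction is applied by default — the
selection rule the pipeline reproduces thresholds raw P-values — but a
Benjamini-Hochberg column can be requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import NormalizedMatrix, validate_design


@dataclass(frozen=True)
class ContrastSpec:
    """One pairwise comparison between group labels."""

    name: str
    group_a: str
    group_b: str
    alpha: float = 0.05
    two_sided: bool = True

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("group_a and group_b must differ")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def t_test_contrast(
    norm: NormalizedMatrix,
    design: pd.DataFrame,
    spec: ContrastSpec,
    equal_var: bool = True,
    add_bh: bool = False,
) -> pd.DataFrame:
    """Per-protein t-test for one contrast.

    Returns one row per protein with group means, log2 fold change
    (mean_b - mean_a), t statistic, degrees of freedom, p-value and the
    significance flag (p < alpha).  When both groups are constant and
    equal the convention t = 0, p = 1 applies; constant but unequal
    groups get p = 0.
    """
    validate_design(design, norm.run_ids)
    runs_a = list(design.index[design["group"] == spec.group_a])
    runs_b = list(design.index[design["group"] == spec.group_b])
    for label, runs in ((spec.group_a, runs_a), (spec.group_b, runs_b)):
        if len(runs) < 2:
            raise ValueError(f"group {label!r} has {len(runs)} run(s); need >= 2 for a t-test")
    a = norm.log2_fractions[runs_a].to_numpy()
    b = norm.log2_fractions[runs_b].to_numpy()
    alternative = "two-sided" if spec.two_sided else "greater"
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant rows trigger scipy's precision-loss warning; the
        # degenerate cases are handled by convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=equal_var, alternative=alternative)
    if equal_var:
        df = np.full(t.shape, a.shape[1] + b.shape[1] - 2, dtype=float)
    else:  # Welch-Satterthwaite
        va, vb = a.var(axis=1, ddof=1) / a.shape[1], b.var(axis=1, ddof=1) / b.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            df = (va + vb) ** 2 / (va**2 / (a.shape[1] - 1) + vb**2 / (b.shape[1] - 1))
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    # zero pooled variance: equal means -> t=0, p=1; unequal -> infinitely strong
    degenerate = np.isnan(t)
    equal_means = np.isclose(mean_a, mean_b)
    signed_inf = np.where(mean_b - mean_a > 0, np.inf, -np.inf)
    t = np.where(degenerate, np.where(equal_means, 0.0, signed_inf), t)
    p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    out = pd.DataFrame(
        {
            "contrast": spec.name,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fold_change": mean_b - mean_a,
            "t_statistic": t,
            "degrees_of_freedom": df,
            "p_value": p,
        },
        index=norm.log2_fractions.index.rename("accession"),
    )
    out["significant"] = out["p_value"] < spec.alpha
    if add_bh:
        out["q_bh"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out


def significant_union(results: list[pd.DataFrame]) -> tuple[set[str], pd.DataFrame, pd.DataFrame]:
    """Union of significant proteins over contrasts.

    Returns ``(union_set, per_contrast_counts, membership)`` where
    ``membership`` is an accession x contrast boolean table.  Contrasts
    computed over different protein sets trigger a warning and are
    reduced to the intersection of tested proteins.
    """
    if not results:
        raise ValueError("need at least one contrast result")
    common = results[0].index
    for res in results[1:]:
        if not res.index.equals(common):
            warnings.warn(
                "contrast results cover different protein sets; using their intersection",
                stacklevel=2,
            )
            common = common.intersection(res.index)
    membership = pd.DataFrame(
        {res["contrast"].iloc[0]: res.loc[common, "significant"] for res in results}
    )
    union = set(membership.index[membership.any(axis=1)])
    counts = pd.DataFrame(
        {
            "n_significant": membership.sum(axis=0),
            "n_tested": len(common),
        }
    ).rename_axis("contrast")
    return union, counts, membership


def volcano_table(result: pd.DataFrame) -> pd.DataFrame:
    """(log2 fold change, -log10 p, significance) table for plotting."""
    if result.empty:
        raise ValueError("empty contrast result")
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(result["p_value"].to_numpy())
    return pd.DataFrame(
        {
            "log2_fold_change": result["log2_fold_change"],
            "neg_log10_p": neg_log10_p,
            "significant": result["significant"],
        },
        index=result.index,
    )
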