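"""Offline term enrichment, common-pathway intersection, the candidate
funnel, and orthogonal-validation (Western-blot) concordance.

Enrichment is the upper-tail hypergeometric test of a selected protein
set against a background, per GMT term, with Benjamini-Hochberg adjusted
values reported alongside (raw P drives pathway selection, matching the
selection rule being reproduced).  The funnel conjoins: significance in
at least one contrast, a qualifying trend (monotone in the injury phase
or biphasic in the repair phase), membership in the extracellular-region
localization term, and membership in at least one pathway enriched in
both phases.
"""

from __future__ import annotations

import importlib.resources
import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .trends import classify_trend

EXTRACELLULAR_TERM = "extracellular_region"
#: funnel-qualifying trends per phase
INJURY_TRENDS = frozenset({"up", "down"})
REPAIR_TRENDS = frozenset({"up_down", "down_up"})


def enrich(
    selected: set[str],
    background: set[str],
    terms: dict[str, set[str]],
    namespace: str = "",
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``selected`` within ``background``.

    For each term with background overlap K, selected overlap k, selected
    size n and background size N, ``p_hyper`` is the upper-tail
    probability P(X >= k) of the hypergeometric distribution; ``q_bh`` is
    the Benjamini-Hochberg adjustment across the table.  Rows are sorted
    by p.
    """
    if not background:
        raise ValueError("background is empty")
    stray = selected - background
    if stray:
        raise ValueError(f"selected proteins not in background: {sorted(stray)[:10]}")
    N, n = len(background), len(selected)
    rows = []
    for term, members in terms.items():
        bg_members = members & background
        K = len(bg_members)
        k = len(bg_members & selected)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p_hyper"])
    if namespace:
        table.insert(1, "namespace", namespace)
    if len(table):
        table["q_bh"] = multipletests(table["p_hyper"].to_numpy(), method="fdr_bh")[1]
        table = table.sort_values("p_hyper", kind="stable").reset_index(drop=True)
    return table


def common_pathways(
    enrichment_a: pd.DataFrame, enrichment_b: pd.DataFrame, alpha: float = 0.05
) -> set[str]:
    """Terms enriched (raw p < alpha) in both phases."""
    sig_a = set(enrichment_a.loc[enrichment_a["p_hyper"] < alpha, "term_id"])
    sig_b = set(enrichment_b.loc[enrichment_b["p_hyper"] < alpha, "term_id"])
    common = sig_a & sig_b
    if not common:
        warnings.warn("no pathway enriched in both phases; the funnel will be empty", stacklevel=2)
    return common


def candidate_funnel(
    sig_membership: pd.DataFrame,
    injury_trends: pd.Series,
    repair_trends: pd.Series,
    cc_terms: dict[str, set[str]],
    kegg_terms: dict[str, set[str]],
    common_pathway_set: set[str],
    extracellular_term: str = EXTRACELLULAR_TERM,
) -> pd.DataFrame:
    """Apply the conjunctive candidate-selection rule.

    Parameters
    ----------
    sig_membership : DataFrame
        Accession x contrast boolean table of per-contrast significance.
    injury_trends, repair_trends : Series
        Trend labels per accession for the injury (first three groups)
        and repair (last three groups) phases; proteins absent from a
        phase simply cannot qualify through it.
    cc_terms, kegg_terms : dict
        GMT term -> member sets for localization and pathway namespaces.
    common_pathway_set : set
        Pathways enriched in both phases (see :func:`common_pathways`).

    Returns
    -------
    DataFrame with one row per tested accession and a ``passes_funnel``
    flag; passing requires >=1 significant contrast AND a qualifying
    trend (monotone injury or biphasic repair) AND extracellular-region
    membership AND membership in >=1 common pathway.
    """
    if extracellular_term not in cc_terms:
        raise KeyError(
            f"annotation fixture lacks the {extracellular_term!r} localization term"
        )
    ecr = cc_terms[extracellular_term]
    accs = sig_membership.index
    inj = injury_trends.reindex(accs)
    rep = repair_trends.reindex(accs)
    rows = []
    for acc in accs:
        sig_contrasts = set(sig_membership.columns[sig_membership.loc[acc]])
        trend_ok = (inj.get(acc) in INJURY_TRENDS) or (rep.get(acc) in REPAIR_TRENDS)
        pathways = {t for t, members in kegg_terms.items() if acc in members}
        rows.append(
            {
                "accession": acc,
                "n_significant_contrasts": len(sig_contrasts),
                "significant_contrasts": ";".join(sorted(sig_contrasts)),
                "injury_trend": inj.get(acc),
                "repair_trend": rep.get(acc),
                "qualifying_trend": bool(trend_ok),
                "in_extracellular_region": acc in ecr,
                "pathways": ";".join(sorted(pathways)),
                "in_common_pathway": bool(pathways & common_pathway_set),
            }
        )
    table = pd.DataFrame(rows).set_index("accession")
    table["passes_funnel"] = (
        (table["n_significant_contrasts"] >= 1)
        & table["qualifying_trend"]
        & table["in_extracellular_region"]
        & table["in_common_pathway"]
    )
    return table


# ------------------------------------------------------- WB concordance

WB_GROUPS = ("Sham", "MCAO", "DHI")


def load_reference_wb_table() -> pd.DataFrame:
    """Packaged densitometric reference table (12 candidates x 3 groups).

    Columns: protein, group (Sham/MCAO/DHI), mean, sd, n (five blot
    repeats per group).
    """
    with importlib.resources.files("lfqpipe.data").joinpath("wb_densitometry.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def _mean_triples(wb: pd.DataFrame, groups=WB_GROUPS) -> pd.DataFrame:
    wide = wb.pivot(index="protein", columns="group", values="mean")
    missing = [g for g in groups if g not in wide.columns]
    if missing:
        raise ValueError(f"WB table lacks group(s): {missing}")
    return wide[list(groups)]


def wb_concordance(
    wb: pd.DataFrame,
    label_free_means: pd.DataFrame,
    tolerance: float = 0.05,
    name_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Compare WB and label-free trends over (Sham, MCAO, DHI).

    Both mean triples are trend-classified; a protein is concordant when
    the labels agree.  The summary also counts proteins whose MCAO WB
    mean strictly exceeds both the Sham and DHI means (the
    "MCAO-elevated" count), and lists proteins that could not be mapped
    between the tables.
    """
    wb_means = _mean_triples(wb)
    lf = label_free_means.copy()
    if name_map:
        lf.index = [name_map.get(a, a) for a in lf.index]
    unmapped = sorted(set(wb_means.index) - set(lf.index))
    shared = [p for p in wb_means.index if p in set(lf.index)]
    rows = []
    for prot in shared:
        wb_trend = classify_trend(wb_means.loc[prot].to_numpy(), tolerance)
        lf_trend = classify_trend(lf.loc[prot].to_numpy()[:3], tolerance)
        rows.append((prot, wb_trend, lf_trend, wb_trend == lf_trend))
    table = pd.DataFrame(rows, columns=["protein", "wb_trend", "label_free_trend", "concordant"])
    m = wb_means
    elevated = int(((m["MCAO"] > m["Sham"]) & (m["MCAO"] > m["DHI"])).sum())
    summary = {
        "n_compared": len(table),
        "n_concordant": int(table["concordant"].sum()),
        "mcao_elevated_count": elevated,
        "unmapped": unmapped,
    }
    return table, summary


def mcao_elevated_count(wb: pd.DataFrame) -> int:
    """Count proteins whose MCAO mean strictly exceeds Sham and DHI means."""
    m = _mean_triples(wb)
    return int(((m["MCAO"] > m["Sham"]) & (m["MCAO"] > m["DHI"])).sum())
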