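"""Hypergeometric enrichment, common pathways, funnel, WB concordance."""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from lfqpipe import (
    candidate_funnel,
    common_pathways,
    enrich,
    load_reference_wb_table,
    mcao_elevated_count,
    wb_concordance,
)


def exhaustive_upper_tail(N, K, n, k):
    """P(overlap >= k) by exact enumeration over all C(N, n) selections."""
    population = list(range(N))
    in_term = set(range(K))
    hits = total = 0
    for sel in itertools.combinations(population, n):
        total += 1
        if len(in_term & set(sel)) >= k:
            hits += 1
    return Fraction(hits, total)


class TestEnrich:
    def _acc(self, n):
        return {f"P{i}" for i in range(n)}

    def test_printed_formula_toy_case(self):
        """N=20, K=5, n=5, k=4 -> 76/15504."""
        background = self._acc(20)
        term = {f"P{i}" for i in range(5)}
        selected = {"P0", "P1", "P2", "P3", "P10"}  # overlap 4
        table = enrich(selected, background, {"term": term})
        assert table.loc[0, "p_hyper"] == pytest.approx(76 / 15504, rel=1e-12)

    def test_disjoint_term_p_one(self):
        background = self._acc(10)
        table = enrich({"P0", "P1"}, background, {"t": {"P8", "P9"} , "u": {"P0"}})
        row = table.set_index("term_id").loc["t"]
        assert row["k"] == 0 and row["p_hyper"] == 1.0

    def test_matches_exhaustive_enumeration(self):
        """Exact agreement with a combinatorial oracle on small instances."""
        rng = np.random.default_rng(2)
        for N, K, n in [(8, 3, 4), (10, 5, 5), (12, 6, 4), (12, 4, 6)]:
            background = self._acc(N)
            term = {f"P{i}" for i in range(K)}
            sel = set(rng.choice(sorted(background), size=n, replace=False))
            k = len(sel & term)
            table = enrich(sel, background, {"t": term})
            expected = float(exhaustive_upper_tail(N, K, n, k))
            assert abs(table.loc[0, "p_hyper"] - expected) < 1e-12

    def test_upper_tail_from_zero_sums_to_one(self):
        from scipy.stats import hypergeom

        N, K, n = 30, 10, 8
        pmf_total = sum(hypergeom.pmf(k, N, K, n) for k in range(0, min(K, n) + 1))
        assert pmf_total == pytest.approx(1.0, abs=1e-12)
        assert hypergeom.sf(-1, N, K, n) == pytest.approx(1.0)

    def test_selected_outside_background_rejected(self):
        with pytest.raises(ValueError, match="not in background"):
            enrich({"X"}, self._acc(5), {"t": {"P0"}})

    def test_bh_is_monotone_in_p_rank(self):
        rng = np.random.default_rng(1)
        background = self._acc(50)
        sel = set(rng.choice(sorted(background), 10, replace=False))
        terms = {
            f"t{i}": set(rng.choice(sorted(background), rng.integers(3, 20), replace=False))
            for i in range(12)
        }
        table = enrich(sel, background, terms)
        assert (table["q_bh"].diff().dropna() >= -1e-12).all()
        assert (table["q_bh"] <= 1.0).all()
        assert (table["q_bh"] >= table["p_hyper"] - 1e-12).all()


class TestCommonPathways:
    def _table(self, ps):
        return pd.DataFrame({"term_id": list(ps), "p_hyper": list(ps.values())})

    def test_identical_tables(self):
        t = self._table({"WNT": 0.001, "MAPK": 0.2})
        assert common_pathways(t, t) == {"WNT"}

    def test_planted_three_pathways(self):
        t1 = self._table({"WNT": 0.001, "MAPK": 0.002, "AMPK": 0.01, "other": 0.5})
        t2 = self._table({"WNT": 0.04, "MAPK": 0.001, "AMPK": 0.02, "other": 0.03})
        assert common_pathways(t1, t2) == {"WNT", "MAPK", "AMPK"}

    def test_alpha_zero_empty_with_warning(self):
        t = self._table({"WNT": 0.001})
        with pytest.warns(UserWarning):
            assert common_pathways(t, t, alpha=0.0) == set()


class TestFunnel:
    def _inputs(self):
        membership = pd.DataFrame(
            {"c1": [True, True, False, True], "c2": [False, True, False, False]},
            index=["cand", "flat", "unsig", "noecr"],
        )
        injury = pd.Series({"cand": "up", "flat": "flat_mixed", "noecr": "down"})
        repair = pd.Series({"cand": "up_down", "flat": "flat_mixed", "noecr": "down_up"})
        cc = {"extracellular_region": {"cand", "flat", "unsig"}}
        kegg = {"WNT": {"cand", "noecr", "unsig"}, "MAPK": {"flat"}}
        return membership, injury, repair, cc, kegg

    def test_conjunctive_rule(self):
        membership, injury, repair, cc, kegg = self._inputs()
        table = candidate_funnel(membership, injury, repair, cc, kegg, {"WNT"})
        assert list(table.index[table["passes_funnel"]]) == ["cand"]
        # significant but flat trend: excluded
        assert not table.loc["flat", "passes_funnel"]
        # qualifying in every way except localization: excluded
        assert not table.loc["noecr", "passes_funnel"]
        # never significant: excluded
        assert not table.loc["unsig", "passes_funnel"]

    def test_empty_annotation_namespace_errors(self):
        membership, injury, repair, _, kegg = self._inputs()
        with pytest.raises(KeyError):
            candidate_funnel(membership, injury, repair, {}, kegg, {"WNT"})

    def test_monotone_in_significance_and_terms(self):
        """Enlarging the significant set or a term never removes candidates."""
        membership, injury, repair, cc, kegg = self._inputs()
        base = candidate_funnel(membership, injury, repair, cc, kegg, {"WNT"})
        bigger = membership.copy()
        bigger.loc["noecr", "c2"] = True
        cc2 = {"extracellular_region": cc["extracellular_region"] | {"noecr"}}
        out = candidate_funnel(bigger, injury, repair, cc2, kegg, {"WNT"})
        passed_before = set(base.index[base["passes_funnel"]])
        passed_after = set(out.index[out["passes_funnel"]])
        assert passed_before <= passed_after
        assert "noecr" in passed_after


class TestWBConcordance:
    def test_reference_table_mcao_elevated_count(self):
        """Nine of the twelve validated proteins peak in the MCAO group."""
        wb = load_reference_wb_table()
        assert len(wb) == 36
        assert mcao_elevated_count(wb) == 9

    def test_identical_triples_fully_concordant(self):
        wb = load_reference_wb_table()
        lf = wb.pivot(index="protein", columns="group", values="mean")[["Sham", "MCAO", "DHI"]]
        table, summary = wb_concordance(wb, lf)
        assert summary["n_compared"] == 12
        assert summary["n_concordant"] == 12
        assert summary["unmapped"] == []

    def test_gsk3b_trend_is_biphasic(self):
        wb = load_reference_wb_table()
        lf = wb.pivot(index="protein", columns="group", values="mean")[["Sham", "MCAO", "DHI"]]
        table, _ = wb_concordance(wb, lf)
        assert table.set_index("protein").loc["Gsk-3b", "wb_trend"] == "up_down"

    def test_unmapped_proteins_listed(self):
        wb = load_reference_wb_table()
        lf = wb.pivot(index="protein", columns="group", values="mean")[["Sham", "MCAO", "DHI"]]
        lf = lf.drop(index=["Apc"])
        table, summary = wb_concordance(wb, lf)
        assert summary["unmapped"] == ["Apc"]
        assert summary["n_compared"] == 11
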