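"""End-to-end orchestration: fixture (or user) inputs to candidate report.

Stage order: digest -> retention filter -> detection-limit imputation ->
peptide-count / fraction-of-total normalization -> per-contrast t-tests
-> phase trend clustering -> pathway enrichment -> common-pathway
intersection -> candidate funnel -> orthogonal (WB) concordance.

A single config seed fans out to per-stage seeds (stage-name hashing) so
stages are independently reproducible; identical inputs and seed give
byte-identical outputs.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .containers import AreaMatrix, validate_design
from .contrasts import ContrastSpec, significant_union, t_test_contrast, volcano_table
from .digest import COUNTING_PARAMS, DigestParams, count_theoretical_peptides
from .enrichment import (
    candidate_funnel,
    common_pathways,
    enrich,
    wb_concordance,
)
from .normalize import (
    ImputationParams,
    filter_proteins,
    group_mean_matrix,
    group_summary,
    impute_missing,
    normalize,
)
from .simulate import SyntheticConfig, write_bundle
from .trends import ClusteringParams, hierarchical_cluster, pearson_distance, trend_profiles

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    return (seed ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Inputs and parameters for a full run.

    Either ``synthetic`` is set (a fixture bundle is generated into
    ``outdir/bundle``) or the five input paths are given.
    """

    outdir: Path = Path("lfq_out")
    synthetic: SyntheticConfig | None = None
    fasta: Path | None = None
    areas: Path | None = None
    design: Path | None = None
    go_cc: Path | None = None
    kegg: Path | None = None
    wb_table: Path | None = None
    digest_params: DigestParams = COUNTING_PARAMS
    imputation: ImputationParams = ImputationParams()
    alpha: float = 0.05
    enrich_alpha: float = 0.05
    min_unique_peptides: int = 2
    min_replicates_present: int = 1
    injury_clustering: ClusteringParams = ClusteringParams(k=3)
    repair_clustering: ClusteringParams = ClusteringParams(k=4)
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.synthetic is None:
            needed = ("fasta", "areas", "design", "go_cc", "kegg")
            missing = [n for n in needed if getattr(self, n) is None]
            if missing:
                raise ValueError(f"non-synthetic run needs input paths: {missing}")


def _phase_groups(groups: list[str]) -> tuple[list[str], list[str]]:
    """Injury phase = first three groups; repair phase = last three."""
    if len(groups) < 3:
        raise ValueError("need >= 3 ordered groups for phase analysis")
    return list(groups[:3]), list(groups[-3:])


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; write outputs and return the run report."""
    t0 = time.monotonic()
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "params": {"alpha": config.alpha, "seed": config.seed}}

    # ---- inputs -------------------------------------------------------
    if config.synthetic is not None:
        syn = config.synthetic
        paths = write_bundle(syn, out / "bundle")
        proteome = io.read_fasta(paths["fasta"])
        matrix = io.read_area_matrix(paths["areas"])
        design = io.read_design(paths["design"])
        cc_terms = io.read_gmt(paths["go_cc"])
        kegg_terms = io.read_gmt(paths["kegg"])
        wb = io.read_table(paths["wb"])
    else:
        proteome = io.read_fasta(config.fasta)
        matrix = io.read_area_matrix(config.areas)
        design = io.read_design(config.design)
        cc_terms = io.read_gmt(config.go_cc)
        kegg_terms = io.read_gmt(config.kegg)
        wb = io.read_table(config.wb_table) if config.wb_table else None
    validate_design(design, matrix.run_ids)
    groups = list(dict.fromkeys(design["group"]))
    report["stages"]["input"] = {"n_proteins": len(matrix.accessions), "n_runs": len(matrix.run_ids)}

    # ---- digest -------------------------------------------------------
    counts = count_theoretical_peptides(proteome, config.digest_params)
    io.write_table(counts.reset_index(), out / "peptide_counts.tsv")
    report["stages"]["digest"] = {
        "n_proteins": len(counts),
        "n_zero_count": int(counts["zero_count"].sum()),
    }

    # ---- filter / impute / normalize ---------------------------------
    filtered = filter_proteins(
        matrix, design, config.min_replicates_present, config.min_unique_peptides
    )
    dropped_filter = sorted(set(matrix.accessions) - set(filtered.accessions))
    impute_params = ImputationParams(
        config.imputation.shift, config.imputation.width, stage_seed(config.seed, "impute")
    )
    completed = impute_missing(filtered, impute_params)
    zero_count = set(counts.index[counts["zero_count"]])
    norm = normalize(
        AreaMatrix(
            completed.areas.loc[[a for a in completed.accessions if a not in zero_count]],
            completed.unique_peptides,
            completed.imputed_mask.loc[[a for a in completed.accessions if a not in zero_count]],
        ),
        counts,
    )
    io.write_table(norm.log2_fractions.reset_index(), out / "log2_fractions.tsv")
    report["stages"]["filter"] = {
        "n_retained": len(filtered.accessions),
        "n_dropped": len(dropped_filter),
    }
    report["stages"]["normalize"] = {
        "n_proteins": len(norm.accessions),
        "n_imputed_cells": int(norm.imputed_mask.to_numpy().sum()),
    }
    report["ledger"] = {
        "input": len(matrix.accessions),
        "dropped_filter": len(dropped_filter),
        "dropped_zero_peptide_count": len(set(filtered.accessions) & zero_count),
        "quantified": len(norm.accessions),
    }

    # ---- group summary & contrasts -----------------------------------
    summary = group_summary(norm, design)
    io.write_table(summary, out / "group_summary.tsv")
    means = group_mean_matrix(summary, groups)

    contrast_specs = [
        ContrastSpec(f"{a}_vs_{b}", a, b, alpha=config.alpha)
        for a, b in zip(groups[:-1], groups[1:])
    ]
    results = [t_test_contrast(norm, design, spec) for spec in contrast_specs]
    all_results = pd.concat([r.reset_index() for r in results], ignore_index=True)
    io.write_table(all_results, out / "contrast_results.tsv")
    union, counts_table, membership = significant_union(results)
    io.write_table(counts_table.reset_index(), out / "significant_counts.tsv")
    for res in results:
        name = res["contrast"].iloc[0]
        io.write_table(volcano_table(res).reset_index(), out / f"volcano_{name}.tsv")
    report["stages"]["contrasts"] = {
        "n_tested": len(norm.accessions),
        "n_significant_union": len(union),
        "per_contrast": {c: int(n) for c, n in counts_table["n_significant"].items()},
    }

    # ---- phase trends -------------------------------------------------
    injury_groups, repair_groups = _phase_groups(groups)
    phase_cfg = {
        "injury": (injury_groups, contrast_specs[:2], config.injury_clustering),
        "repair": (repair_groups, contrast_specs[-2:], config.repair_clustering),
    }
    phase_out = {}
    for phase, (pgroups, specs, cparams) in phase_cfg.items():
        spec_names = [s.name for s in specs]
        phase_sig = sorted(
            membership.index[membership[spec_names].any(axis=1)]
        )
        cparams = ClusteringParams(
            k=cparams.k,
            linkage=cparams.linkage,
            n_restarts=cparams.n_restarts,
            trend_tolerance=cparams.trend_tolerance,
            seed=stage_seed(config.seed, f"kmeans_{phase}"),
        )
        phase_means = means.loc[phase_sig, pgroups]
        if len(phase_sig) >= max(cparams.k, 2):
            profiles = trend_profiles(phase_means, cparams)
            dist, _ = pearson_distance(phase_means)
            hier, _ = hierarchical_cluster(dist, cparams.k, cparams.linkage)
            profiles["hier_cluster"] = hier
        else:
            profiles = pd.DataFrame(
                {"trend_label": [], "kmeans_cluster": [], "hier_cluster": []}
            )
        io.write_table(profiles.reset_index(names="accession"), out / f"trends_{phase}.tsv")
        phase_out[phase] = (phase_sig, profiles)
        report["stages"][f"trends_{phase}"] = {
            "n_significant": len(phase_sig),
            "trend_counts": profiles["trend_label"].value_counts().to_dict()
            if len(profiles)
            else {},
        }

    # ---- enrichment & common pathways --------------------------------
    observed = matrix.areas.notna()
    quantified = set(norm.accessions)
    enrich_tables = {}
    for phase, (pgroups, _, _) in phase_cfg.items():
        in_all_groups = pd.Series(True, index=matrix.areas.index)
        for g in pgroups:
            runs = list(design.index[design["group"] == g])
            in_all_groups &= observed[runs].any(axis=1)
        background = set(matrix.areas.index[in_all_groups]) & quantified
        phase_sig, profiles = phase_out[phase]
        qualifying = {"injury": {"up", "down"}, "repair": {"up_down", "down_up"}}[phase]
        if len(profiles):
            selected = set(profiles.index[profiles["trend_label"].isin(qualifying)])
        else:
            selected = set()
        selected &= background
        enrich_tables[phase] = enrich(selected, background, kegg_terms, namespace="KEGG")
        io.write_table(enrich_tables[phase], out / f"enrichment_{phase}.tsv")
        report["stages"][f"enrichment_{phase}"] = {
            "n_selected": len(selected),
            "n_background": len(background),
            "n_terms_sub_alpha": int(
                (enrich_tables[phase]["p_hyper"] < config.enrich_alpha).sum()
            ),
        }
    common = common_pathways(
        enrich_tables["injury"], enrich_tables["repair"], config.enrich_alpha
    )
    report["stages"]["common_pathways"] = {"terms": sorted(common)}

    # ---- candidate funnel --------------------------------------------
    injury_profiles = phase_out["injury"][1]
    repair_profiles = phase_out["repair"][1]
    funnel = candidate_funnel(
        membership,
        injury_profiles["trend_label"] if len(injury_profiles) else pd.Series(dtype=object),
        repair_profiles["trend_label"] if len(repair_profiles) else pd.Series(dtype=object),
        cc_terms,
        kegg_terms,
        common,
    )
    candidates = sorted(funnel.index[funnel["passes_funnel"]])
    io.write_table(funnel.reset_index(), out / "candidates.tsv")
    report["stages"]["funnel"] = {"n_candidates": len(candidates), "candidates": candidates}

    # ---- WB concordance ----------------------------------------------
    if wb is not None and len(wb):
        repair_means = means[repair_groups]
        conc, conc_summary = wb_concordance(wb, repair_means)
        io.write_table(conc, out / "wb_concordance.tsv")
        report["stages"]["wb_concordance"] = conc_summary

    # ---- consistency checks ------------------------------------------
    led = report["ledger"]
    assert led["input"] == led["dropped_filter"] + led["dropped_zero_peptide_count"] + led["quantified"]
    assert report["stages"]["contrasts"]["n_tested"] == led["quantified"]
    for phase in ("injury", "repair"):
        assert report["stages"][f"trends_{phase}"]["n_significant"] <= len(union)
    report["ledger"]["consistent"] = True
    report["elapsed_seconds"] = round(time.monotonic() - t0, 3)
    io.write_json(report, out / "report.json")
    logger.info("pipeline finished in %.1f s; %d candidate(s)", report["elapsed_seconds"], len(candidates))
    return report
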