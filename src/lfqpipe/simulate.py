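"""Synthetic fixture bundles with known ground truth.

Emulates the statistical structure of a 4-group (Naive, Sham, MCAO,
MCAO_DHI) x 3-replicate label-free experiment: log-normal protein
abundances, planted group effects in the three adjacent contrasts,
intensity-dependent (left-censored, MNAR) missingness, and annotation
fixtures containing an ``extracellular_region`` localization term and
WNT/MAPK/AMPK-like pathway terms.

Planted effects come in three shapes, mirroring the trend clusters the
study design produces:

* *ramp* proteins: mean shifts ``(0, ±e, ±2e, ±2e)`` across the four
  groups — differential in the first two contrasts and monotone
  (up/down) across the injury phase;
* *spike* proteins (the planted funnel candidates): mean shifts
  ``±effect_log2`` in the MCAO group only — differential in both
  Sham-vs-MCAO and MCAO-vs-DHI with a biphasic (up-then-down /
  down-then-up) repair-phase trend.  Spikes are planted in the upper
  half of the abundance distribution: funnel candidates model proteins
  from the commonly-quantified core proteome, which left-censoring
  cannot push below the detection limit;
* *late-step* proteins: mean shifts ``±effect_log2`` in the last group
  only — differential in the treatment contrast alone.

The linear-scale area of a protein is ``2**log2_abundance`` multiplied by
its theoretical peptide count, which makes the peptide-count
normalization exactly invertible on noise-free data and turns the
generator into an oracle for the normalization chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AreaMatrix
from .digest import COUNTING_PARAMS, DigestParams, count_theoretical_peptides
from . import io

DEFAULT_GROUPS = ("Naive", "Sham", "MCAO", "MCAO_DHI")

#: the study's three adjacent contrasts: (name, group_a, group_b)
DEFAULT_CONTRASTS = (
    ("Naive_vs_Sham", "Naive", "Sham"),
    ("Sham_vs_MCAO", "Sham", "MCAO"),
    ("MCAO_vs_DHI", "MCAO", "MCAO_DHI"),
)

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_KR_IDX = np.array([_AMINO_ACIDS.tolist().index(a) for a in "KR"])


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults reproduce the study design at desk scale."""

    n_proteins: int = 3000
    groups: tuple[str, ...] = DEFAULT_GROUPS
    replicates_per_group: int = 3
    base_log2_abundance_mean: float = 20.0
    base_log2_abundance_sd: float = 2.0
    replicate_log2_sd: float = 0.3
    de_fraction_per_contrast: float = 0.04
    candidate_fraction: float = 0.004
    effect_log2: float = 1.0
    censor_quantile: float = 0.25
    kr_density: float = 0.11
    min_seq_length: int = 50
    max_seq_length: int = 600
    annotation_term_count: int = 20
    term_size_range: tuple[int, int] = (20, 200)
    annotation_background_rate: float = 0.1
    planted_pathway_rate: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise InvalidConfigError("n_proteins must be >= 1")
        if len(self.groups) < 2:
            raise InvalidConfigError("need at least 2 groups")
        if self.replicates_per_group < 1:
            raise InvalidConfigError("replicates_per_group must be >= 1")
        for name in ("de_fraction_per_contrast", "candidate_fraction", "censor_quantile",
                     "kr_density", "annotation_background_rate", "planted_pathway_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        if not 1 <= self.min_seq_length <= self.max_seq_length:
            raise InvalidConfigError("require 1 <= min_seq_length <= max_seq_length")
        lo, hi = self.term_size_range
        if not 1 <= lo <= hi:
            raise InvalidConfigError("term_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_proteins:
            raise InvalidConfigError("term_size_range exceeds n_proteins")
        if self.replicate_log2_sd < 0 or self.base_log2_abundance_sd < 0:
            raise InvalidConfigError("standard deviations must be >= 0")

    @property
    def run_ids(self) -> list[str]:
        return [f"{g}_r{r}" for g in self.groups for r in range(1, self.replicates_per_group + 1)]

    def design(self) -> pd.DataFrame:
        rows = [
            (f"{g}_r{r}", g, r)
            for g in self.groups
            for r in range(1, self.replicates_per_group + 1)
        ]
        return pd.DataFrame(rows, columns=["run_id", "group", "replicate"]).set_index("run_id")

    def contrasts(self) -> list[tuple[str, str, str]]:
        return [
            (f"{a}_vs_{b}".replace("MCAO_DHI", "DHI"), a, b)
            for a, b in zip(self.groups[:-1], self.groups[1:])
        ]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated bundle: the recovery oracle."""

    planted_up: dict[str, set[str]] = field(default_factory=dict)
    planted_down: dict[str, set[str]] = field(default_factory=dict)
    planted_candidates: set[str] = field(default_factory=set)
    censor_threshold_per_run: dict[str, float] = field(default_factory=dict)
    true_group_log2: pd.DataFrame | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "planted_up": {c: sorted(s) for c, s in self.planted_up.items()},
            "planted_down": {c: sorted(s) for c, s in self.planted_down.items()},
            "planted_candidates": sorted(self.planted_candidates),
            "censor_threshold_per_run": self.censor_threshold_per_run,
            "seed": self.seed,
        }


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def generate_proteome(config: SyntheticConfig) -> dict[str, str]:
    """Random amino-acid sequences with controllable K/R density.

    Residues are drawn i.i.d.; K and R each carry probability
    ``kr_density / 2`` and the 18 other residues share the remainder
    uniformly, so the theoretical-peptide-count distribution widens with
    ``kr_density``.  Deterministic under the config seed.
    """
    rng = _rng(config, 0)
    probs = np.full(20, (1.0 - config.kr_density) / 18.0)
    probs[_KR_IDX] = config.kr_density / 2.0
    lengths = rng.integers(config.min_seq_length, config.max_seq_length + 1, config.n_proteins)
    width = len(str(config.n_proteins))
    proteome = {}
    for i, length in enumerate(lengths):
        seq = "".join(rng.choice(_AMINO_ACIDS, size=length, p=probs))
        proteome[f"SYN{i + 1:0{width}d}"] = seq
    return proteome


def _plant_effects(
    config: SyntheticConfig,
    eligible: np.ndarray,
    high_abundance: set[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Assign per-(protein, group) log2 shifts and record the truth."""
    groups = list(config.groups)
    contrasts = config.contrasts()
    e = config.effect_log2
    n_spike = int(round(config.candidate_fraction * config.n_proteins))
    n_step = int(round(config.de_fraction_per_contrast * config.n_proteins))
    spike_pool = np.array([a for a in eligible if a in high_abundance])
    if n_spike > len(spike_pool):
        raise InvalidConfigError(
            f"not enough high-abundance eligible proteins ({len(spike_pool)}) "
            f"to plant {n_spike} candidates"
        )
    spikes = rng.choice(spike_pool, size=n_spike, replace=False)
    rest_pool = np.array([a for a in eligible if a not in set(spikes)])
    need = 2 * n_step
    if need > len(rest_pool):
        raise InvalidConfigError(
            f"not enough eligible proteins ({len(rest_pool)}) to plant {need} effects"
        )
    rest = rng.choice(rest_pool, size=need, replace=False)
    ramps, late_steps = rest[:n_step], rest[n_step:]

    truth = SyntheticTruth(seed=config.seed)
    delta = pd.DataFrame(0.0, index=eligible, columns=groups)
    for name, _, _ in contrasts:
        truth.planted_up[name] = set()
        truth.planted_down[name] = set()
    c1, c2, c3 = contrasts[0][0], contrasts[1][0], contrasts[-1][0]

    # spikes: +/- e in the second-to-last (injured, untreated) group only
    spike_group = groups[-2]
    for j, acc in enumerate(spikes):
        sign = 1.0 if j % 2 == 0 else -1.0
        delta.loc[acc, spike_group] = sign * e
        (truth.planted_up if sign > 0 else truth.planted_down)[c2].add(acc)
        (truth.planted_down if sign > 0 else truth.planted_up)[c3].add(acc)
    truth.planted_candidates = set(spikes)

    # ramps: (0, +/-e, +/-2e, +/-2e) — monotone across the injury phase
    for j, acc in enumerate(ramps):
        sign = 1.0 if j % 2 == 0 else -1.0
        delta.loc[acc, groups[1]] = sign * e
        delta.loc[acc, groups[2:]] = sign * 2 * e
        (truth.planted_up if sign > 0 else truth.planted_down)[c1].add(acc)
        (truth.planted_up if sign > 0 else truth.planted_down)[c2].add(acc)

    # late steps: +/- e in the final (treated) group only
    for j, acc in enumerate(late_steps):
        sign = 1.0 if j % 2 == 0 else -1.0
        delta.loc[acc, groups[-1]] = sign * e
        (truth.planted_up if sign > 0 else truth.planted_down)[c3].add(acc)
    return delta, truth


def generate_area_matrix(
    config: SyntheticConfig,
    proteome: dict[str, str],
    counting_params: DigestParams = COUNTING_PARAMS,
) -> tuple[AreaMatrix, SyntheticTruth]:
    """Simulate the precursor-area matrix and its ground truth.

    Per protein: true log2 abundance = base draw + planted group effect +
    replicate noise; linear area = 2**log2 x theoretical peptide count.
    Entries whose log2 area falls below the per-run ``censor_quantile``
    quantile are recorded missing (left-censoring).
    """
    if not proteome:
        raise InvalidConfigError("proteome is empty")
    if config.censor_quantile >= 1.0:
        raise InvalidConfigError("censor_quantile = 1 would censor every observation")
    counts = count_theoretical_peptides(proteome, counting_params)
    accs = np.array(list(proteome))
    n = len(accs)
    design = config.design()
    runs = list(design.index)
    group_of_run = design["group"]

    rng = _rng(config, 1)
    base = rng.normal(config.base_log2_abundance_mean, config.base_log2_abundance_sd, n)

    # plant effects only on proteins that survive the unique-peptide filter;
    # candidates additionally come from the upper abundance half
    npep = counts["n_theoretical_peptides"].reindex(accs).to_numpy()
    eligible = accs[npep >= 2]
    high = set(accs[base >= np.median(base)])
    delta, truth = _plant_effects(config, eligible, high, rng)
    delta_full = delta.reindex(accs).fillna(0.0)

    group_log2 = pd.DataFrame(
        base[:, None] + delta_full.to_numpy(), index=accs, columns=list(config.groups)
    )
    truth.true_group_log2 = group_log2

    noise = rng.normal(0.0, config.replicate_log2_sd, (n, len(runs)))
    log2_abund = group_log2[group_of_run.loc[runs]].to_numpy() + noise

    areas = np.exp2(log2_abund) * npep[:, None]
    log2_area = np.full_like(areas, -np.inf)
    np.log2(areas, out=log2_area, where=areas > 0)

    mat = pd.DataFrame(areas, index=accs, columns=runs)
    if config.censor_quantile > 0:
        for j, run in enumerate(runs):
            col = log2_area[:, j]
            finite = col[np.isfinite(col)]
            thr = float(np.quantile(finite, config.censor_quantile))
            truth.censor_threshold_per_run[run] = thr
            mat.loc[col < thr, run] = np.nan
    else:
        for run in runs:
            truth.censor_threshold_per_run[run] = float("-inf")

    unique_peptides = counts["n_theoretical_peptides"].reindex(accs)
    return AreaMatrix(mat, unique_peptides), truth


def generate_annotations(
    config: SyntheticConfig, proteome: dict[str, str], truth: SyntheticTruth
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """GO-CC and KEGG-like GMT fixtures tied to the planted truth.

    The CC fixture contains an ``extracellular_region`` term holding every
    planted candidate plus background members at
    ``annotation_background_rate``.  The KEGG fixture contains WNT, MAPK
    and AMPK terms: every candidate belongs to at least one of the three,
    planted differential proteins join each of the three at
    ``planted_pathway_rate`` (so the fixture genuinely plants pathway
    enrichment in both phases, as the funnel requires), and non-planted
    proteins join at the background rate.  Remaining terms are random
    background sets with sizes drawn from ``term_size_range``.
    """
    rng = _rng(config, 2)
    accs = np.array(list(proteome))
    candidates = sorted(truth.planted_candidates)
    planted_all = set().union(*truth.planted_up.values(), *truth.planted_down.values())
    non_candidates = np.array([a for a in accs if a not in truth.planted_candidates])
    unplanted = np.array([a for a in accs if a not in planted_all])
    planted_non_candidates = np.array(sorted(planted_all - truth.planted_candidates))
    rate = config.annotation_background_rate

    def sample(pool: np.ndarray, p: float) -> set[str]:
        if p == 0 or len(pool) == 0:
            return set()
        keep = rng.random(len(pool)) < p
        return set(pool[keep])

    go_cc: dict[str, set[str]] = {}
    go_cc["extracellular_region"] = set(candidates) | sample(non_candidates, rate)
    pathways = ("WNT", "MAPK", "AMPK")
    kegg: dict[str, set[str]] = {
        p: sample(unplanted, rate) | sample(planted_non_candidates, config.planted_pathway_rate)
        for p in pathways
    }
    for i, acc in enumerate(candidates):
        kegg[pathways[i % 3]].add(acc)

    lo, hi = config.term_size_range
    n_extra = max(config.annotation_term_count - 1, 0)
    for i in range(n_extra):
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(accs, size=size, replace=False))
        target = go_cc if i % 2 == 0 else kegg
        prefix = "CC_term" if i % 2 == 0 else "pathway"
        target[f"{prefix}_{i // 2 + 1:02d}"] = members
    # GMT members must be nonempty
    for d in (go_cc, kegg):
        for term in list(d):
            if not d[term]:
                d[term] = {str(accs[int(rng.integers(0, len(accs)))])}
    return go_cc, kegg


def generate_wb_table(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    n_replicates: int = 5,
    noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Orthogonal-validation (Western-blot style) mean table for candidates.

    Relative densitometric levels per group are the true relative linear
    abundances of each planted candidate over the repair-phase groups
    (Sham, MCAO, DHI-treated), scaled to a unit mean, with small
    multiplicative noise.
    """
    rng = _rng(config, 3)
    groups = list(config.groups[-3:])
    out_groups = ["Sham", "MCAO", "DHI"] if groups == ["Sham", "MCAO", "MCAO_DHI"] else groups
    rows = []
    for acc in sorted(truth.planted_candidates):
        log2 = truth.true_group_log2.loc[acc, groups].to_numpy()
        rel = np.exp2(log2 - log2.mean())
        rel = rel * np.exp2(rng.normal(0.0, noise_sd, rel.shape))
        for g, m in zip(out_groups, rel):
            rows.append((acc, g, float(m), float(abs(rng.normal(0.15 * m, 0.05 * m))), n_replicates))
    return pd.DataFrame(rows, columns=["protein", "group", "mean", "sd", "n"])


def write_bundle(config: SyntheticConfig, outdir) -> dict[str, Path]:
    """Generate a complete fixture bundle and write it to ``outdir``.

    Returns the mapping of artifact name -> path.  Byte-identical for
    identical config (seed included).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteome = generate_proteome(config)
    matrix, truth = generate_area_matrix(config, proteome)
    go_cc, kegg = generate_annotations(config, proteome, truth)
    wb = generate_wb_table(config, truth)

    paths = {
        "fasta": outdir / "proteome.fasta",
        "areas": outdir / "areas.tsv",
        "design": outdir / "design.tsv",
        "go_cc": outdir / "go_cc.gmt",
        "kegg": outdir / "kegg.gmt",
        "wb": outdir / "wb_means.tsv",
        "truth": outdir / "truth.json",
    }
    io.write_fasta(proteome, paths["fasta"])
    io.write_area_matrix(matrix, paths["areas"])
    io.write_design(config.design(), paths["design"])
    io.write_gmt(go_cc, paths["go_cc"])
    io.write_gmt(kegg, paths["kegg"])
    io.write_table(wb, paths["wb"])
    io.write_json(truth.to_dict(), paths["truth"])
    return paths
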