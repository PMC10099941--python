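"""Synthetic experiment generator with per-gene ground truth.

Emulates the 7-group factorial design (two diploid parents, their diploid
hybrid, two autotetraploids, and two allotetraploids), 2 tissues x 6 lines
with one sequenced individual per line (84 expression samples) and 6
phenotyped individuals per line (252 plants).

Gene counts follow a negative-binomial model realized as a gamma-weighted
multinomial: each sample draws a library size, each feature an intensity
(expected group mean x per-gene gamma noise with per-gene dispersion), and
reads are allocated multinomially.  Marginally each gene is approximately
NB with the configured dispersion while sample totals match the drawn
library sizes exactly.

The ground truth encodes the central biological null of the design: by
default whole-genome duplication leaves relative expression unchanged
(``wgd_effect_fraction = 0``), so the expected expression vectors satisfy
Co4 = Co2, Cg4 = Cg2 and F2 = Allo-d = Allo-h, while hybridization acts
through the per-gene hybrid mode (additive, expression-level dominance
toward either parent, or transgressive expression beyond both).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from allohybrid.core import (
    GROUPS,
    HYBRID_GROUPS,
    TETRAPLOID_GROUPS,
    TE_CLASSES,
    TISSUES,
    CountMatrix,
    group_is_hybrid,
    group_ploidy,
    validate_feature_table,
    validate_sample_table,
)

HYBRID_MODES = ("additive", "ELD_P1", "ELD_P2", "TRE_up", "TRE_down", "conserved")

#: P1 is the maternal parent *C. orientalis* (Co), P2 is *C. grandiflora* (Cg).
P1_GROUP, P2_GROUP = "Co2", "Cg2"


def _simplex(d: Mapping[str, float], keys: Sequence[str], what: str) -> dict:
    out = {k: float(d.get(k, 0.0)) for k in keys}
    if any(v < 0 or v > 1 for v in out.values()):
        raise ValueError(f"{what} entries must lie in [0, 1]")
    if abs(sum(out.values()) - 1.0) > 1e-9:
        raise ValueError(f"{what} must sum to 1 (got {sum(out.values()):.12f})")
    return out


@dataclass
class SimulationConfig:
    """All generator parameters; defaults reproduce the study conditions."""

    n_genes: int = 10_000
    n_te: int = 400
    te_class_weights: dict = field(
        default_factory=lambda: {
            "LTR": 0.45, "Helitron": 0.20, "SINE": 0.10, "LINE": 0.15, "other": 0.10,
        }
    )
    groups: tuple = GROUPS
    lines_per_group: int = 6
    individuals_per_line: int = 6          # phenotyped; one per line is sequenced
    tissues: tuple = TISSUES

    # expression model (log2 scale)
    baseline_logmean_mu: float = 4.0
    baseline_logmean_sd: float = 2.0
    dispersion_logmean: float = float(np.log(0.05))
    dispersion_logsd: float = 0.5
    pi_ped: float = 0.25                   # fraction of genes diverged between parents
    ped_logfc_sd: float = 1.5              # N(0, sd) truncated to |logFC| >= ped_logfc_min
    ped_logfc_min: float = 1.0
    hybrid_mode_fractions: dict = field(
        default_factory=lambda: {
            "additive": 0.17, "ELD_P1": 0.03, "ELD_P2": 0.03,
            "TRE_up": 0.0001, "TRE_down": 0.0001, "conserved": 0.7698,
        }
    )
    tre_shift: float = 1.5                 # log2 offset beyond the extreme parent
    wgd_effect_fraction: float = 0.0
    wgd_logfc: float = 1.5
    tissue_logfc_sd: float = 1.0           # per-gene leaf-vs-flower offset
    line_effect_sd: float = 0.0            # optional per-line random effect

    # sequencing
    library_size_logmean: float = float(np.log(2e7))
    library_size_logsd: float = 0.15
    lanes: tuple = ("lane1", "lane2", "lane3")
    te_fraction_by_lane: dict = field(
        default_factory=lambda: {"lane1": 0.053, "lane2": 0.015, "lane3": 0.048}
    )

    # phenotypes
    pheno_viability_by_group: dict = field(
        default_factory=lambda: {
            "Cg2": 0.966, "Co2": 0.985, "F2": 0.827, "Allo-d": 0.813,
            "Allo-h": 0.878, "Co4": 0.831, "Cg4": 0.914,
        }
    )
    pheno_normal_seed_by_group: dict = field(
        default_factory=lambda: {
            "F2": 0.57, "Allo-h": 0.78, "Allo-d": 0.70,
            "Co2": 0.95, "Cg2": 0.93, "Co4": 0.80, "Cg4": 0.85,
        }
    )
    stem_cm_by_group: dict = field(
        default_factory=lambda: {
            "Co2": 25.0, "Cg2": 55.0, "F2": 40.0, "Co4": 33.0,
            "Cg4": 63.0, "Allo-d": 48.0, "Allo-h": 48.0,
        }
    )
    flowering_days_by_group: dict = field(
        default_factory=lambda: {
            "Co2": 30.0, "Cg2": 55.0, "F2": 42.0, "Co4": 34.0,
            "Cg4": 59.0, "Allo-d": 51.0, "Allo-h": 46.0,
        }
    )
    pollen_count_by_group: dict = field(
        default_factory=lambda: {
            "Co2": 2500.0, "Cg2": 9000.0, "F2": 5500.0, "Co4": 2600.0,
            "Cg4": 7500.0, "Allo-d": 5600.0, "Allo-h": 5700.0,
        }
    )
    stem_sd: float = 5.0
    flowering_sd: float = 4.0
    pollen_count_sd: float = 800.0
    pollen_grains_examined: int = 300      # minimum per flower; 2 flowers scored
    flowers_per_individual: int = 2
    fruits_per_individual: int = 10
    seeds_per_fruit_mean: float = 20.0
    pheno_overdispersion_rho: float = 0.02  # beta-binomial intra-class correlation

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_te < 0:
            raise ValueError("n_genes must be >= 1 and n_te >= 0")
        if not self.groups:
            raise ValueError("groups must be non-empty")
        if not 0 <= self.pi_ped <= 1 or not 0 <= self.wgd_effect_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        self.hybrid_mode_fractions = _simplex(
            self.hybrid_mode_fractions, HYBRID_MODES, "hybrid_mode_fractions"
        )
        self.te_class_weights = _simplex(self.te_class_weights, TE_CLASSES, "te_class_weights")
        for name in ("pheno_viability_by_group", "pheno_normal_seed_by_group"):
            m = getattr(self, name)
            missing = set(self.groups) - set(m)
            if missing:
                raise ValueError(f"{name} missing groups: {sorted(missing)}")
            if any(not 0 <= v <= 1 for v in m.values()):
                raise ValueError(f"{name} proportions must lie in [0, 1]")
        if not 0 <= self.pheno_overdispersion_rho < 1:
            raise ValueError("pheno_overdispersion_rho must lie in [0, 1)")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SimulatedExperiment:
    counts: CountMatrix
    features: pd.DataFrame
    samples: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: pd.DataFrame


def _truncated_normal_min_abs(rng, n: int, sd: float, min_abs: float) -> np.ndarray:
    """Draw N(0, sd) conditioned on |x| >= min_abs (rejection sampling)."""
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.normal(0.0, sd, todo.size)
        ok = np.abs(draw) >= min_abs
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def assign_gene_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-gene hybrid modes, parental divergence, and expected means.

    Hybrid-mode fractions are interpreted over all genes.  Modes that require
    the parents to differ (additive and both dominance modes) force the gene
    to be parentally diverged; the remaining genes are diverged with the
    residual probability so that the overall diverged fraction matches
    ``pi_ped``.  Transgressive genes shift beyond the more extreme parent by
    ``tre_shift`` whether or not the parents differ.
    """
    n = config.n_genes
    gene_ids = np.array([f"gene{i:05d}" for i in range(n)])
    fracs = config.hybrid_mode_fractions
    modes = rng.choice(HYBRID_MODES, size=n, p=[fracs[m] for m in HYBRID_MODES])

    forced = np.isin(modes, ["additive", "ELD_P1", "ELD_P2"])
    p_forced = fracs["additive"] + fracs["ELD_P1"] + fracs["ELD_P2"]
    if p_forced > config.pi_ped > 0 or config.pi_ped == 0:
        # pi_ped cannot accommodate all divergence-requiring modes: demote
        # the excess to conserved so the overall diverged fraction matches
        keep_p = 0.0 if config.pi_ped == 0 else config.pi_ped / p_forced
        demote = forced & (rng.random(n) >= keep_p)
        modes[demote] = "conserved"
        forced &= ~demote
        p_forced = min(p_forced, config.pi_ped)
    p_rest = 1.0 - p_forced
    p_extra = 0.0 if p_rest <= 0 else min(max((config.pi_ped - p_forced) / p_rest, 0.0), 1.0)
    ped = forced | (~forced & (rng.random(n) < p_extra))

    d = np.zeros(n)
    d[ped] = _truncated_normal_min_abs(rng, int(ped.sum()), config.ped_logfc_sd,
                                       config.ped_logfc_min)

    b = rng.normal(config.baseline_logmean_mu, config.baseline_logmean_sd, n)
    p1 = b + d / 2.0   # Co (maternal)
    p2 = b - d / 2.0   # Cg

    hybrid = (p1 + p2) / 2.0  # additive / conserved: midparent on the log2 scale
    hybrid[modes == "ELD_P1"] = p1[modes == "ELD_P1"]
    hybrid[modes == "ELD_P2"] = p2[modes == "ELD_P2"]
    up = modes == "TRE_up"
    dn = modes == "TRE_down"
    hybrid[up] = np.maximum(p1, p2)[up] + config.tre_shift
    hybrid[dn] = np.minimum(p1, p2)[dn] - config.tre_shift

    wgd_shifted = rng.random(n) < config.wgd_effect_fraction

    truth = pd.DataFrame({
        "feature_id": gene_ids,
        "parental_log2fc": d,
        "hybrid_mode": modes,
        "wgd_shifted": wgd_shifted,
        "dispersion": np.exp(rng.normal(config.dispersion_logmean,
                                        config.dispersion_logsd, n)),
        "tissue_log2fc": rng.normal(0.0, config.tissue_logfc_sd, n),
    })
    for g in config.groups:
        if g == P1_GROUP:
            mu = p1.copy()
        elif g == P2_GROUP:
            mu = p2.copy()
        elif group_is_hybrid(g):
            mu = hybrid.copy()
        elif g.startswith("Co"):
            mu = p1.copy()
        else:
            mu = p2.copy()
        if group_ploidy(g) == 4:
            mu = mu + np.where(wgd_shifted, config.wgd_logfc, 0.0)
        truth[f"log2_mean_{g}"] = mu
    return truth.set_index("feature_id", drop=False)


def _sample_design(config: SimulationConfig) -> pd.DataFrame:
    """One sequenced sample per (group, tissue, line), lanes in balanced blocks.

    Within each group x tissue, the six lines are spread over the three lanes
    so that every cell has two samples on each lane.
    """
    rows = []
    lanes = config.lanes
    for g in config.groups:
        for t in config.tissues:
            for line in range(1, config.lines_per_group + 1):
                rows.append({
                    "sample_id": f"{g}_L{line}_{t}",
                    "group": g,
                    "tissue": t,
                    "line": line,
                    "lane": lanes[(line - 1) % len(lanes)],
                })
    return validate_sample_table(pd.DataFrame(rows))


def _make_features(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    gene_ids = [f"gene{i:05d}" for i in range(config.n_genes)]
    gene_len = np.round(np.exp(rng.normal(np.log(1500), 0.6, config.n_genes))).astype(int)
    gene_len = np.maximum(gene_len, 100)
    te_ids = [f"te{i:04d}" for i in range(config.n_te)]
    w = config.te_class_weights
    te_class = rng.choice(TE_CLASSES, size=config.n_te, p=[w[c] for c in TE_CLASSES])
    te_len = np.round(np.exp(rng.normal(np.log(800), 0.8, config.n_te))).astype(int)
    te_len = np.maximum(te_len, 50)
    feats = pd.DataFrame({
        "feature_id": gene_ids + te_ids,
        "feature_kind": ["gene"] * config.n_genes + ["TE"] * config.n_te,
        "te_class": [""] * config.n_genes + list(te_class),
        "length_bp": np.concatenate([gene_len, te_len]),
    })
    return validate_feature_table(feats)


def simulate_counts(
    config: SimulationConfig,
    truth: pd.DataFrame,
    features: pd.DataFrame,
    samples: pd.DataFrame,
    rng: np.random.Generator,
) -> CountMatrix:
    """Gamma-multinomial count generation; totals equal drawn library sizes."""
    gene_mask = (features["feature_kind"] == "gene").to_numpy()
    gene_ids = features.index[gene_mask]
    te_ids = features.index[~gene_mask]
    truth = truth.loc[gene_ids]

    n_samples = len(samples)
    lib_sizes = np.round(np.exp(rng.normal(
        config.library_size_logmean, config.library_size_logsd, n_samples))).astype(np.int64)

    gene_disp = truth["dispersion"].to_numpy()
    te_disp = np.exp(rng.normal(config.dispersion_logmean, config.dispersion_logsd,
                                len(te_ids)))
    te_base = np.exp(rng.normal(0.0, 1.0, len(te_ids)))  # per-TE abundance weight

    line_eff = {}
    if config.line_effect_sd > 0:
        for g in config.groups:
            for line in range(1, config.lines_per_group + 1):
                line_eff[(g, line)] = rng.normal(0.0, config.line_effect_sd, len(gene_ids))

    cols = np.empty((len(features), n_samples), dtype=np.int64)
    ref_tissue = config.tissues[0]
    for j, (_, s) in enumerate(samples.iterrows()):
        log2mu = truth[f"log2_mean_{s['group']}"].to_numpy().copy()
        if s["tissue"] != ref_tissue:
            log2mu = log2mu + truth["tissue_log2fc"].to_numpy()
        if config.line_effect_sd > 0:
            log2mu = log2mu + line_eff[(s["group"], s["line"])]
        gene_w = np.exp2(log2mu)
        gene_gamma = rng.gamma(1.0 / gene_disp, gene_disp)
        gene_int = gene_w * gene_gamma

        if len(te_ids):
            f = config.te_fraction_by_lane.get(s["lane"], 0.0)
            te_scale = (f / (1.0 - f)) * gene_w.sum() / te_base.sum()
            te_gamma = rng.gamma(1.0 / te_disp, te_disp)
            te_int = te_base * te_scale * te_gamma
            intensity = np.concatenate([gene_int, te_int])
        else:
            intensity = gene_int
        cols[:, j] = rng.multinomial(lib_sizes[j], intensity / intensity.sum())

    values = pd.DataFrame(cols, index=features.index, columns=samples.index)
    return CountMatrix(values, features, samples)


def _beta_binomial(rng, n: np.ndarray, p: np.ndarray, rho: float) -> np.ndarray:
    """Binomial with beta-distributed success probability (ICC rho)."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n)
    if rho <= 0:
        return rng.binomial(n, p)
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    # degenerate proportions stay deterministic
    pp = np.where((p <= 0) | (p >= 1), p, rng.beta(np.maximum(a, 1e-12),
                                                   np.maximum(b, 1e-12)))
    return rng.binomial(n, pp)


def simulate_phenotypes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-individual phenotypes for groups x lines x individuals.

    Pollen viability and normal-seed counts are beta-binomial around the
    configured group proportions (mild overdispersion so a quasi-binomial
    fit sees dispersion > 1); quantitative traits are normal around group
    means ordered Co < hybrids < Cg with a tetraploid offset.
    """
    rows = []
    for g in config.groups:
        for line in range(1, config.lines_per_group + 1):
            for ind in range(1, config.individuals_per_line + 1):
                rows.append({"individual_id": f"{g}_L{line}_I{ind}",
                             "group": g, "line": line})
    df = pd.DataFrame(rows)
    n = len(df)
    groups = df["group"].to_numpy()

    df["stem_length"] = rng.normal(
        [config.stem_cm_by_group[g] for g in groups], config.stem_sd)
    df["flowering_time"] = rng.normal(
        [config.flowering_days_by_group[g] for g in groups], config.flowering_sd)
    df["pollen_per_flower"] = np.maximum(np.round(rng.normal(
        [config.pollen_count_by_group[g] for g in groups],
        config.pollen_count_sd)), 0).astype(int)

    viab = np.array([config.pheno_viability_by_group[g] for g in groups])
    examined = np.zeros(n, dtype=int)
    viable = np.zeros(n, dtype=int)
    for _ in range(config.flowers_per_individual):
        ex = config.pollen_grains_examined + rng.poisson(30, n)
        vi = _beta_binomial(rng, ex, viab, config.pheno_overdispersion_rho)
        examined += ex
        viable += vi
    df["pollen_examined"] = examined
    df["pollen_viable"] = viable

    seeds_total = rng.poisson(config.seeds_per_fruit_mean,
                              (n, config.fruits_per_individual)).sum(axis=1)
    norm_p = np.array([config.pheno_normal_seed_by_group[g] for g in groups])
    df["seeds_total"] = seeds_total
    df["seeds_normal"] = _beta_binomial(rng, seeds_total, norm_p,
                                        config.pheno_overdispersion_rho)
    # Cg is an obligate outcrosser; selfed lineages set seed on their own
    df["selfed_seed_set"] = ~np.isin(groups, ["Cg2", "Cg4"])
    return df


def simulate_experiment(config: SimulationConfig | None = None) -> SimulatedExperiment:
    """Generate the full synthetic study: counts, metadata, phenotypes, truth."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.rng_seed)
    truth = assign_gene_truth(config, rng)
    features = _make_features(config, rng)
    samples = _sample_design(config)
    counts = simulate_counts(config, truth, features, samples, rng)
    phenotypes = simulate_phenotypes(config, rng)
    return SimulatedExperiment(counts, features, samples, phenotypes, truth)


def write_experiment(exp: SimulatedExperiment, outdir) -> dict:
    """Write counts.tsv, features.tsv, samples.tsv, phenotypes.tsv, truth.tsv."""
    from pathlib import Path

    from allohybrid.core import write_count_matrix, write_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "features": outdir / "features.tsv",
        "samples": outdir / "samples.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_count_matrix(exp.counts, paths["counts"])
    write_table(exp.features.reset_index(drop=True), paths["features"])
    write_table(exp.samples.reset_index(drop=True), paths["samples"])
    write_table(exp.phenotypes, paths["phenotypes"])
    write_table(exp.truth.reset_index(drop=True), paths["truth"])
    return {k: str(v) for k, v in paths.items()}
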