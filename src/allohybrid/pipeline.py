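"""End-to-end orchestration: simulate/load -> normalize -> DE -> classify ->
extreme -> TE -> phenotypes -> ordination, with a hashed output manifest.

A single global seed fans out to per-stage seeds as
``(seed * 1000003 + crc32(stage_name)) mod 2^31`` so each stage is
individually reproducible.  Every stage writes TSV outputs under the run
directory; the manifest records a SHA-256 content hash per file, and a rerun
with the same config and seed reproduces the hashes bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from allohybrid import core, diffexpr, eld, extreme, normalize, ordination, phenostats, te
from allohybrid.core import AnalysisThresholds, CountMatrix
from allohybrid.simulate import SimulationConfig, simulate_experiment, write_experiment

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "normalize", "de", "classify", "extreme",
              "te", "phenotypes", "ordination")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    outdir: str | Path = "results/run"
    seed: int = 0
    simulate: dict | None = None          # SimulationConfig overrides
    paths: dict | None = None             # counts/features/samples/phenotypes
    thresholds: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)   # stage -> bool
    downsample: bool = True               # equalize group mean library sizes

    def __post_init__(self) -> None:
        if (self.simulate is not None) == (self.paths is not None):
            raise ValueError("exactly one of simulate block or input paths required")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.paths is not None:
            missing = {"counts", "features", "samples"} - set(self.paths)
            if missing:
                raise ValueError(f"missing input paths: {sorted(missing)}")
            for p in self.paths.values():
                if not Path(p).exists():
                    raise ValueError(f"input path does not exist: {p}")

    def enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages in dependency order and return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = AnalysisThresholds(**config.thresholds)
    outputs: dict[str, Path] = {}
    stage = "init"
    try:
        if config.simulate is not None:
            stage = "simulate"
            sim_cfg = SimulationConfig(
                **{**config.simulate, "rng_seed": stage_seed(config.seed, "simulate")})
            exp = simulate_experiment(sim_cfg)
            counts, phenotypes, truth = exp.counts, exp.phenotypes, exp.truth
            if config.enabled("simulate"):
                for name, p in write_experiment(exp, outdir / "data").items():
                    outputs[f"data/{name}"] = Path(p)
        else:
            stage = "load"
            features = core.read_feature_table(config.paths["features"])
            samples = core.read_sample_table(config.paths["samples"])
            counts = core.read_count_matrix(config.paths["counts"], features, samples)
            phenotypes = (pd.read_csv(config.paths["phenotypes"], sep="\t")
                          if "phenotypes" in config.paths else None)

        if config.downsample:
            stage = "downsample"
            counts = normalize.downsample_to_group_mean(
                counts, stage_seed(config.seed, "downsample"))

        stage = "normalize"
        tpm = normalize.compute_tpm(counts)
        expressed = normalize.filter_expressed(
            tpm, thresholds.min_tpm, thresholds.min_tpm_samples)
        if config.enabled("normalize"):
            factors = normalize.tmm_factors(counts, thresholds)
            core.write_table(factors.reset_index().rename(
                columns={"index": "sample_id"}), outdir / "tmm_factors.tsv")
            outputs["tmm_factors"] = outdir / "tmm_factors.tsv"
            core.write_table(
                pd.DataFrame({"feature_id": expressed}), outdir / "expressed_genes.tsv")
            outputs["expressed_genes"] = outdir / "expressed_genes.tsv"

        tissues = list(counts.samples["tissue"].unique())
        de_results: dict[str, dict] = {}
        if config.enabled("de") or config.enabled("classify") or config.enabled("extreme"):
            stage = "de"
            for t in tissues:
                disp = diffexpr.estimate_dispersions(
                    counts, tissue=t, thresholds=thresholds, gene_ids=expressed)
                de_results[t] = diffexpr.all_pairwise_contrasts(
                    counts, t, disp, thresholds)
            if config.enabled("de"):
                summary = pd.concat([diffexpr.deg_summary(v) for v in de_results.values()],
                                    ignore_index=True)
                core.write_table(summary, outdir / "deg_summary.tsv")
                outputs["deg_summary"] = outdir / "deg_summary.tsv"

        if config.enabled("classify") and de_results:
            stage = "classify"
            groups = set(counts.samples["group"].unique())
            hybrids = [g for g in ("F2", "Allo-d", "Allo-h") if g in groups]
            rows = []
            for t in tissues:
                nonadd: dict[str, set] = {}
                for h in hybrids:
                    res = eld.classify_hybrid_group(
                        de_results[t][_pair(de_results[t], h, "Co2")],
                        de_results[t][_pair(de_results[t], h, "Cg2")],
                        de_results[t][_pair(de_results[t], "Co2", "Cg2")],
                        hybrid_group=h)
                    core.write_table(res.table.reset_index(drop=True),
                                     outdir / f"categories_{h}_{t}.tsv")
                    outputs[f"categories_{h}_{t}"] = outdir / f"categories_{h}_{t}.tsv"
                    rows.append({"tissue": t, "hybrid": h,
                                 "eld": res.eld_proportion,
                                 "tre": res.tre_proportion,
                                 "nonadditive": res.nonadditive_proportion})
                    nonadd[h] = set(res.table.index[
                        res.table["category"].isin(eld.NONADDITIVE_CATEGORIES)])
                ped_res = de_results[t][_pair(de_results[t], "Co2", "Cg2")]
                nonadd["PED"] = set(ped_res.table.index[ped_res.table["status"] != "ns"])
                if 2 <= len(nonadd) <= 4:
                    core.write_table(eld.overlap_analysis(nonadd),
                                     outdir / f"overlap_{t}.tsv")
                    outputs[f"overlap_{t}"] = outdir / f"overlap_{t}.tsv"
            core.write_table(pd.DataFrame(rows), outdir / "category_proportions.tsv")
            outputs["category_proportions"] = outdir / "category_proportions.tsv"

        if config.enabled("extreme"):
            stage = "extreme"
            cpm = normalize.compute_cpm(counts)
            for t in tissues:
                sub = counts.samples[counts.samples["tissue"] == t]
                cpm_t = normalize.NormalizedMatrix(cpm.values[sub.index], "CPM")
                kept = normalize.filter_expressed(
                    normalize.NormalizedMatrix(cpm_t.values.loc[counts.gene_ids], "CPM"),
                    thresholds.min_cpm, thresholds.min_cpm_samples)
                ex = extreme.rank_extremes(
                    cpm_t, counts.samples, tissue=t,
                    gene_set=kept, seed=stage_seed(config.seed, f"extreme_{t}"))
                if de_results:
                    nonped = extreme.nonped_gene_set(
                        de_results[t][_pair(de_results[t], "Co2", "Cg2")], thresholds)
                    ex_np = extreme.rank_extremes(
                        cpm_t, counts.samples, tissue=t,
                        gene_set=kept.intersection(nonped),
                        seed=stage_seed(config.seed, f"extreme_{t}"))
                    ex = ex.join(ex_np[["n_extreme"]].rename(
                        columns={"n_extreme": "n_extreme_nonped"}))
                core.write_table(ex.reset_index(drop=True),
                                 outdir / f"extreme_{t}.tsv")
                outputs[f"extreme_{t}"] = outdir / f"extreme_{t}.tsv"

        if config.enabled("te"):
            stage = "te"
            rows = []
            for t in tissues:
                obs = te.te_proportions(counts, tissue=t)
                core.write_table(obs.reset_index(drop=True),
                                 outdir / f"te_proportions_{t}.tsv")
                outputs[f"te_proportions_{t}"] = outdir / f"te_proportions_{t}.tsv"
                include_lane = obs["lane"].nunique() > 1
                fit = te.te_glm(obs, include_lane=include_lane)
                at = fit.anova_table.copy()
                at.insert(0, "tissue", t)
                at.insert(1, "dispersion", fit.dispersion)
                rows.append(at)
            core.write_table(pd.concat(rows, ignore_index=True),
                             outdir / "te_glm.tsv")
            outputs["te_glm"] = outdir / "te_glm.tsv"

        if config.enabled("phenotypes") and phenotypes is not None:
            stage = "phenotypes"
            report = phenostats.phenotype_report(phenotypes, thresholds.alpha_phenotype)
            rows = []
            for trait, res in report["anova"].items():
                for g, m in res.group_means.items():
                    rows.append({"trait": trait, "group": g, "mean": m,
                                 "letters": res.letters.get(g, ""),
                                 "F": res.F, "pvalue": res.pvalue})
            for trait, fit in report["glm"].items():
                for r in fit.anova_table.itertuples():
                    rows.append({"trait": trait, "group": f"term:{r.term}",
                                 "mean": np.nan, "letters": "",
                                 "F": r.F, "pvalue": r.pvalue})
            core.write_table(pd.DataFrame(rows), outdir / "phenotype_stats.tsv")
            outputs["phenotype_stats"] = outdir / "phenotype_stats.tsv"

        if config.enabled("ordination"):
            stage = "ordination"
            eff = normalize.effective_library_sizes(counts, thresholds)
            sub = counts.subset_features(expressed)
            logcpm = normalize.compute_cpm(sub, prior=thresholds.cpm_prior_count,
                                           effective_sizes=eff, log=True)
            coords = ordination.mds(logcpm, top=min(thresholds.mds_top_genes,
                                                    len(expressed))).coordinates
            core.write_table(coords.reset_index().rename(columns={"index": "sample_id"}),
                             outdir / "mds_coordinates.tsv")
            outputs["mds_coordinates"] = outdir / "mds_coordinates.tsv"

    except Exception as exc:  # pragma: no cover - error path exercised in tests
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)}
                    for k, p in sorted(outputs.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _pair(results: dict, a: str, b: str):
    """Locate the contrast key for an unordered group pair."""
    if (a, b) in results:
        return (a, b)
    if (b, a) in results:
        return (b, a)
    raise KeyError(f"no contrast for pair ({a}, {b})")
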