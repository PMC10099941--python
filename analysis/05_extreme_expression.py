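"""Count extremely expressed genes (rank 1 or rank 42 by CPM among the 42
individuals of a tissue) per individual, with and without restriction to
genes not differentially expressed between the parents (FC < 1.2 or
FDR > 0.05), and compare the seven groups by one-way ANOVA + Tukey HSD.

Expected picture: no excess of extreme expression in hybrids or
polyploids — individual-level dysregulation is absent, contradicting a
TE-driven genomic-shock scenario.

Writes per-individual extreme counts and the group comparison under
results/extreme/.
"""

import pandas as pd
from _shared import RESULTS, load_experiment, read_de_result

from allohybrid import core, normalize
from allohybrid.core import AnalysisThresholds
from allohybrid.extreme import extreme_group_test, nonped_gene_set, rank_extremes

DE = RESULTS / "de"
OUT = RESULTS / "extreme"


def main(seed: int = 20233) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts, _, _ = load_experiment()
    thr = AnalysisThresholds()
    cpm = normalize.compute_cpm(counts)
    for tissue in ("flower", "leaf"):
        sub = counts.samples[counts.samples["tissue"] == tissue]
        cpm_t = normalize.NormalizedMatrix(
            cpm.values[sub.index].loc[counts.gene_ids], "CPM")
        kept = normalize.filter_expressed(cpm_t, thr.min_cpm, thr.min_cpm_samples)
        parents = read_de_result(DE / f"de_Co2_vs_Cg2_{tissue}.tsv",
                                 "Co2", "Cg2", tissue)
        nonped = kept.intersection(nonped_gene_set(parents, thr))

        full = rank_extremes(cpm_t, counts.samples, tissue=tissue,
                             gene_set=kept, seed=seed)
        restricted = rank_extremes(cpm_t, counts.samples, tissue=tissue,
                                   gene_set=nonped, seed=seed)
        table = full.join(restricted[["n_extreme"]].rename(
            columns={"n_extreme": "n_extreme_nonped"}))
        core.write_table(table.reset_index(drop=True),
                         OUT / f"extreme_{tissue}.tsv")

        for label, res in (("all genes", full), ("non-PED genes", restricted)):
            test = extreme_group_test(res)
            means = res.groupby("group")["n_extreme"].mean().round(1)
            print(f"{tissue} ({label}, G={res['n_genes'].iloc[0]}): "
                  f"F{test.df_between},{test.df_within} = {test.F:.2f}, "
                  f"P = {test.pvalue:.3f}; group means {means.to_dict()}")


if __name__ == "__main__":
    main()
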