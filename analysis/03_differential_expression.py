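"""Negative-binomial differential expression: all 21 pairwise group
contrasts per tissue at FC > 2 and BH FDR < 0.05.

Expected picture: hundreds of DEGs in every hybrid-parent and
parent-parent contrast, and almost none between a diploid group and its
autotetraploid (the WGD null) or among the three hybrid groups.

Writes the per-contrast DEG summary and the contrast tables needed by the
downstream classification and extreme-expression steps under results/de/.
"""

import pandas as pd
from _shared import RESULTS, load_experiment, write_de_result

from allohybrid import core, diffexpr, normalize
from allohybrid.core import AnalysisThresholds

OUT = RESULTS / "de"

# contrasts consumed downstream (hybrid vs each parent, parents)
KEY_CONTRASTS = [("F2", "Co2"), ("F2", "Cg2"),
                 ("Allo-d", "Co2"), ("Allo-d", "Cg2"),
                 ("Allo-h", "Co2"), ("Allo-h", "Cg2"),
                 ("Co2", "Cg2")]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts, _, _ = load_experiment()
    thr = AnalysisThresholds()

    summaries = []
    for tissue in ("flower", "leaf"):
        tpm = normalize.compute_tpm(
            counts.subset_samples(counts.samples["tissue"] == tissue))
        expressed = normalize.filter_expressed(
            tpm, thr.min_tpm, thr.min_tpm_samples)
        disp = diffexpr.estimate_dispersions(
            counts, tissue=tissue, thresholds=thr, gene_ids=expressed)
        results = diffexpr.all_pairwise_contrasts(counts, tissue, disp, thr)
        summary = diffexpr.deg_summary(results)
        summaries.append(summary)
        for (a, b) in KEY_CONTRASTS:
            key = (a, b) if (a, b) in results else (b, a)
            res = results[key] if key == (a, b) else results[key].swap()
            write_de_result(res, OUT / f"de_{a}_vs_{b}_{tissue}.tsv")

        wgd_pairs = {("Co2", "Co4"), ("Co4", "Co2"), ("Cg2", "Cg4"),
                     ("Cg4", "Cg2")}
        wgd = summary[[tuple(x) in wgd_pairs
                       for x in zip(summary["group_a"], summary["group_b"])]]
        hyb_par = summary[
            (summary["group_a"].isin(["F2", "Allo-d", "Allo-h"])
             & summary["group_b"].isin(["Co2", "Cg2"]))
            | (summary["group_b"].isin(["F2", "Allo-d", "Allo-h"])
               & summary["group_a"].isin(["Co2", "Cg2"]))]
        print(f"{tissue}: {len(expressed)} genes tested; "
              f"WGD contrasts {wgd['total'].tolist()} DEGs; "
              f"hybrid-parent contrasts "
              f"{hyb_par['total'].min()}-{hyb_par['total'].max()} DEGs")

    core.write_table(pd.concat(summaries, ignore_index=True),
                     OUT / "deg_summary.tsv")


if __name__ == "__main__":
    main()
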