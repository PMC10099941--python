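"""TE transcript abundance: the proportion of annotated reads mapped to TE
features per sample (total and per TE class), tested for hybridization, WGD
and their interaction with quasi-binomial GLMs that include the sequencing
lane as a batch factor, after downsampling so all groups share a similar
average library size.

Expected picture: a strong lane effect (TE share ~5.3%, 1.5%, 4.8% by
lane) but no hybridization, WGD, or interaction effect, overall or in any
TE class — no transcriptome-level TE reactivation.

Writes per-sample proportions and GLM tables under results/te/.
"""

import pandas as pd
from _shared import RESULTS, load_experiment

from allohybrid import core, normalize, te
from allohybrid.core import TE_CLASSES

OUT = RESULTS / "te"


def main(seed: int = 20236) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts, _, _ = load_experiment()
    counts = normalize.downsample_to_group_mean(counts, seed=seed)
    glm_rows = []
    for tissue in ("flower", "leaf"):
        obs = te.te_proportions(counts, tissue=tissue)
        core.write_table(obs.reset_index(drop=True),
                         OUT / f"te_proportions_{tissue}.tsv")
        by_lane = obs.groupby("lane")["proportion"].mean()
        print(f"{tissue}: mean TE share {100 * obs['proportion'].mean():.1f}% "
              f"(by lane: " +
              ", ".join(f"{k} {100 * v:.1f}%" for k, v in by_lane.items()) + ")")
        for te_class in (None, *TE_CLASSES):
            o = obs if te_class is None else te.te_proportions(
                counts, te_class=te_class, tissue=tissue)
            if (o["numerator"] == 0).all():
                continue
            fit = te.te_glm(o, include_lane=True)
            at = fit.anova_table.copy()
            at.insert(0, "tissue", tissue)
            at.insert(1, "te_class", te_class or "all")
            at.insert(2, "dispersion", fit.dispersion)
            glm_rows.append(at)
            p = at.set_index("term")["pvalue"]
            label = te_class or "all TEs"
            print(f"  {label}: P(hybridization) = {p['is_hybrid']:.2f}, "
                  f"P(WGD) = {p['is_tetraploid']:.2f}, "
                  f"P(interaction) = {p['is_hybrid:is_tetraploid']:.2f}, "
                  f"P(lane) = {p['lane']:.2e}")
    core.write_table(pd.concat(glm_rows, ignore_index=True),
                     OUT / "te_glm.tsv")


if __name__ == "__main__":
    main()
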