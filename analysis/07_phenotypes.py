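"""Phenotype statistics for the 252 plants: one-way ANOVA with Tukey HSD
compact letters for stem length, flowering time, and pollen number;
hybridization x WGD quasi-binomial GLMs for pollen viability and the
proportion of normal seeds; and the targeted hybridization-first
allotetraploid (Allo-h) vs diploid hybrid (F2) viability contrast.

Expected picture: parents at the trait extremes with hybrids intermediate;
both hybridization and WGD depress pollen viability with a positive
interaction (WGD is less deleterious in hybrids); WGD raises the normal-
seed proportion of hybrids while lowering it in nonhybrids.

Writes one summary table per trait family under results/phenotypes/.
"""

import pandas as pd
from _shared import RESULTS, load_experiment

from allohybrid import core
from allohybrid.phenostats import phenotype_report

OUT = RESULTS / "phenotypes"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    _, phenotypes, _ = load_experiment()
    report = phenotype_report(phenotypes)

    anova_rows = []
    for trait, res in report["anova"].items():
        print(f"{trait}: F{res.df_between},{res.df_within} = {res.F:.1f}, "
              f"P = {res.pvalue:.2e}; letters " +
              ", ".join(f"{g}={res.letters[g]}" for g in res.group_means.index))
        for g in res.group_means.index:
            anova_rows.append({"trait": trait, "group": g,
                               "mean": res.group_means[g],
                               "letters": res.letters[g],
                               "F": res.F, "pvalue": res.pvalue})
    core.write_table(pd.DataFrame(anova_rows), OUT / "anova_tukey.tsv")

    glm_rows = []
    for trait, fit in report["glm"].items():
        terms = fit.anova_table.copy()
        terms.insert(0, "trait", trait)
        terms.insert(1, "dispersion", fit.dispersion)
        glm_rows.append(terms)
        detail = ", ".join(f"{r.term}: F={r.F:.2f} P={r.pvalue:.3g}"
                           for r in fit.anova_table.itertuples())
        print(f"{trait} (phi = {fit.dispersion:.1f}): {detail}")
    core.write_table(pd.concat(glm_rows, ignore_index=True),
                     OUT / "glm_tests.tsv")

    props = phenotypes.groupby("group").apply(
        lambda d: pd.Series({
            "viability": d["pollen_viable"].sum() / d["pollen_examined"].sum(),
            "normal_seeds": d["seeds_normal"].sum() / d["seeds_total"].sum(),
        }), include_groups=False)
    core.write_table(props.reset_index(), OUT / "group_proportions.tsv")
    print("group proportions:\n", props.round(3))


if __name__ == "__main__":
    main()
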