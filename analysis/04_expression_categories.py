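"""Classify hybrid gene expression into the 10 additive/nonadditive
categories for each hybrid group (F2, Allo-d, Allo-h) and tissue, and
intersect the proven-nonadditive sets (complete ELD or TRE) with each other
and with the parental expression-differential (PED) genes.

Expected picture: a few percent of genes show complete expression-level
dominance, transgressive expression is essentially absent, and nonadditive
genes are highly shared among hybrid groups and with PED genes — hybrid
expression change is deterministic, not stochastic.

Writes per-gene category tables, category proportions, and Venn region
counts under results/categories/.
"""

import pandas as pd
from _shared import RESULTS, read_de_result

from allohybrid import core, eld

DE = RESULTS / "de"
OUT = RESULTS / "categories"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for tissue in ("flower", "leaf"):
        parents = read_de_result(DE / f"de_Co2_vs_Cg2_{tissue}.tsv",
                                 "Co2", "Cg2", tissue)
        nonadditive = {}
        for hybrid in ("F2", "Allo-d", "Allo-h"):
            res = eld.classify_hybrid_group(
                read_de_result(DE / f"de_{hybrid}_vs_Co2_{tissue}.tsv",
                               hybrid, "Co2", tissue),
                read_de_result(DE / f"de_{hybrid}_vs_Cg2_{tissue}.tsv",
                               hybrid, "Cg2", tissue),
                parents, hybrid_group=hybrid)
            core.write_table(res.table.reset_index(drop=True),
                             OUT / f"categories_{hybrid}_{tissue}.tsv")
            rows.append({"tissue": tissue, "hybrid": hybrid,
                         "complete_eld": res.eld_proportion,
                         "tre": res.tre_proportion,
                         "nonadditive": res.nonadditive_proportion})
            nonadditive[hybrid] = set(res.table.index[
                res.table["category"].isin(eld.NONADDITIVE_CATEGORIES)])
            print(f"{tissue} {hybrid}: complete ELD "
                  f"{100 * res.eld_proportion:.1f}%, "
                  f"TRE {100 * res.tre_proportion:.3f}%")
        nonadditive["PED"] = set(parents.table.index[
            parents.table["status"] != "ns"])
        venn = eld.overlap_analysis(nonadditive)
        core.write_table(venn, OUT / f"venn_{tissue}.tsv")
        shared3 = venn[venn["F2"] & venn["Allo-d"] & venn["Allo-h"]]["count"].sum()
        union3 = venn[venn[["F2", "Allo-d", "Allo-h"]].any(axis=1)]["count"].sum()
        in_ped = venn[venn[["F2", "Allo-d", "Allo-h"]].any(axis=1)
                      & venn["PED"]]["count"].sum()
        print(f"{tissue}: {shared3}/{union3} nonadditive genes shared by all "
              f"three hybrid groups; {in_ped}/{union3} overlap PED genes")
    core.write_table(pd.DataFrame(rows), OUT / "category_proportions.tsv")


if __name__ == "__main__":
    main()
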