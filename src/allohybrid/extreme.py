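"""Per-individual counts of genome-wide extreme expression ranks.

Within one tissue the N sequenced individuals (42 in the reference design:
7 groups x 6 lines) are ranked per gene by CPM; ranks 1 and N are "extreme".
Under exchangeability each individual expects 2G/N extreme genes, so an
excess in hybrids or polyploids would indicate individual-specific
dysregulation (e.g. TE-mediated genomic shock).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from allohybrid.core import AnalysisThresholds
from allohybrid.diffexpr import DEResult
from allohybrid.normalize import NormalizedMatrix


def rank_extremes(
    cpm: NormalizedMatrix,
    samples: pd.DataFrame,
    tissue: str | None = None,
    gene_set: pd.Index | None = None,
    seed: int = 0,
    drop_ties: bool = False,
) -> pd.DataFrame:
    """Count rank-1 and rank-N genes per individual.

    Ties are broken by a per-gene seeded random permutation so that ranks
    form a strict total order and the counts conserve exactly
    (sum of rank-1 counts = sum of rank-N counts = number of genes).  With
    ``drop_ties`` genes whose extreme value is tied are skipped instead
    (sensitivity mode; conservation then holds only over untied genes).
    """
    cols = samples.index if tissue is None else samples.index[samples["tissue"] == tissue]
    if len(cols) < 2:
        raise ValueError("need at least 2 individuals to rank")
    vals = cpm.values[cols]
    if gene_set is not None:
        vals = vals.loc[vals.index.intersection(gene_set)]
    arr = vals.to_numpy(dtype=float)
    g, n = arr.shape
    rng = np.random.default_rng(seed)
    # random jitter ordering: argsort on (value, per-gene random key)
    tiebreak = rng.random((g, n))
    order = np.lexsort((tiebreak, arr), axis=1)
    lowest = order[:, 0]
    highest = order[:, -1]
    if drop_ties:
        srt = np.take_along_axis(arr, order, axis=1)
        low_tied = srt[:, 0] == srt[:, 1]
        high_tied = srt[:, -1] == srt[:, -2]
    else:
        low_tied = np.zeros(g, dtype=bool)
        high_tied = np.zeros(g, dtype=bool)
    n_low = np.bincount(lowest[~low_tied], minlength=n)
    n_high = np.bincount(highest[~high_tied], minlength=n)
    out = pd.DataFrame({
        "individual_id": cols,
        "n_rank_low": n_low,
        "n_rank_high": n_high,
        "n_extreme": n_low + n_high,
        "n_individuals": n,
        "n_genes": g,
    }).set_index("individual_id", drop=False)
    out["group"] = samples.loc[cols, "group"].to_numpy()
    return out


def nonped_gene_set(de_parents: DEResult,
                    thresholds: AnalysisThresholds | None = None) -> pd.Index:
    """Genes not differentially expressed between the parents under the
    relaxed screen: |FC| < 1.2 or FDR > 0.05.

    Genes never tested for significance (no q-value) count as FDR > 0.05.
    """
    thresholds = thresholds or AnalysisThresholds()
    t = de_parents.table
    log2_relaxed = np.log2(thresholds.ped_relaxed_fc)
    q = t["qvalue"].fillna(1.0)
    keep = (t["log2fc"].abs() < log2_relaxed) | (q > thresholds.fdr_alpha)
    return t.index[keep]


def extreme_group_test(extreme_counts: pd.DataFrame):
    """One-way ANOVA + Tukey letters on per-individual extreme-gene counts."""
    from allohybrid.phenostats import anova_tukey

    return anova_tukey(extreme_counts["n_extreme"].to_numpy(dtype=float),
                       extreme_counts["group"].to_numpy())
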