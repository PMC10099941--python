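"""Transposable-element transcript abundance and its GLM tests.

The TE abundance of a sample is the proportion of annotated reads mapped to
TE features (reads on TEs / reads on TEs or genes), optionally restricted to
one TE class (LTR, Helitron, SINE, LINE, other).  Hybridization, whole-
genome duplication, and their interaction are tested with a quasi-binomial
logit GLM; the sequencing lane is included as a batch factor because TE
proportions carry a strong lane effect in the reference design.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from allohybrid.core import CountMatrix, group_is_hybrid, group_ploidy
from allohybrid.phenostats import GLMFit, quasibinomial_glm

logger = logging.getLogger(__name__)


def te_proportions(counts: CountMatrix, te_class: str | None = None,
                   tissue: str | None = None) -> pd.DataFrame:
    """Per-sample TE read proportions with design covariates.

    Numerator: reads on TE features (one class if given); denominator: reads
    on all genes and TEs.  Returns one observation per sample with columns
    ``numerator``, ``denominator``, ``proportion`` and the factors used by
    the GLM stage.
    """
    if tissue is not None:
        counts = counts.subset_samples(counts.samples["tissue"] == tissue)
    te_mask = counts.features["feature_kind"] == "TE"
    if te_class is not None:
        te_mask &= counts.features["te_class"] == te_class
    if not te_mask.any():
        logger.warning("no TE features%s; proportions are 0",
                       f" of class {te_class}" if te_class else "")
    num = counts.values.loc[counts.features.index[te_mask]].sum(axis=0)
    den = counts.values.sum(axis=0)
    s = counts.samples
    return pd.DataFrame({
        "unit_id": s.index,
        "numerator": num.astype(int),
        "denominator": den.astype(int),
        "proportion": np.where(den > 0, num / den.replace(0, 1), 0.0),
        "is_hybrid": s["group"].map(group_is_hybrid),
        "is_tetraploid": s["group"].map(lambda g: group_ploidy(g) == 4),
        "lane": s["lane"],
        "group": s["group"],
        "tissue": s["tissue"],
    }).set_index("unit_id", drop=False)


def te_glm(obs: pd.DataFrame, include_lane: bool = True) -> GLMFit:
    """Quasi-binomial test of hybridization, WGD, and their interaction.

    ``include_lane`` adds the sequencing lane as an additional main effect;
    it requires at least two lane levels in the observations.
    """
    terms = ["is_hybrid", "is_tetraploid"]
    if include_lane:
        if obs["lane"].nunique() < 2:
            raise ValueError("lane factor has a single level")
        terms.append("lane")
    terms.append("is_hybrid:is_tetraploid")
    return quasibinomial_glm(obs, terms)
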