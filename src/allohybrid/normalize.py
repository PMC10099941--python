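"""Within- and between-sample normalization and expression filtering.

Implements transcripts-per-million (length-normalized), counts-per-million
(library-size normalized, with an optional stabilizing prior count), trimmed
mean of M-values (TMM) scaling factors, the strict expression filters
(value > threshold in at least k samples), and binomial downsampling of
counts so that all groups share a similar average library size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from allohybrid.core import AnalysisThresholds, CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame
    method: str                                # TPM | CPM | logCPM
    tmm_factors: pd.Series | None = None
    effective_library_sizes: pd.Series | None = None


def compute_tpm(counts: CountMatrix, include_te: bool = False) -> NormalizedMatrix:
    """Transcripts per million: rate_g = c_g / length_g, scaled to 1e6 per sample.

    TE features are excluded by default so gene TPM is comparable across
    samples with different TE loads.
    """
    ids = counts.features.index if include_te else counts.gene_ids
    sub = counts.values.loc[ids]
    lengths = counts.features.loc[ids, "length_bp"].to_numpy(dtype=float)
    rate = sub.to_numpy(dtype=float) / lengths[:, None]
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        logger.warning("TPM: %d all-zero samples get zero columns", int(zero.sum()))
        denom[zero] = 1.0
    tpm = 1e6 * rate / denom
    return NormalizedMatrix(pd.DataFrame(tpm, index=sub.index, columns=sub.columns), "TPM")


def _adjusted_cpm(values: np.ndarray, lib: np.ndarray, prior: float,
                  log: bool) -> np.ndarray:
    """CPM with a library-size-scaled prior count.

    The prior added to each count is ``prior * lib_s / mean(lib)`` and the
    library size grows by twice that amount, so samples with larger libraries
    receive proportionally larger priors (keeping log-CPM comparable).  With
    ``prior = 0`` this is plain counts-per-million and columns sum to 1e6.
    """
    if prior < 0:
        raise ValueError("prior count must be non-negative")
    lib = lib.astype(float)
    adj_prior = prior * lib / lib.mean() if prior > 0 else np.zeros_like(lib)
    safe_lib = np.where(lib + 2 * adj_prior == 0, 1.0, lib + 2 * adj_prior)
    cpm = 1e6 * (values + adj_prior[None, :]) / safe_lib[None, :]
    return np.log2(cpm) if log else cpm


def compute_cpm(
    counts: CountMatrix,
    prior: float = 0.0,
    effective_sizes: pd.Series | None = None,
    log: bool = False,
) -> NormalizedMatrix:
    """Counts per million over all features (genes + TEs).

    ``effective_sizes`` (e.g. TMM-scaled library sizes) replace the raw
    column sums when supplied.
    """
    lib = (effective_sizes.loc[counts.values.columns].to_numpy()
           if effective_sizes is not None
           else counts.values.sum(axis=0).to_numpy())
    vals = _adjusted_cpm(counts.values.to_numpy(dtype=float), lib, prior, log)
    return NormalizedMatrix(
        pd.DataFrame(vals, index=counts.values.index, columns=counts.values.columns),
        "logCPM" if log else "CPM",
        effective_library_sizes=pd.Series(lib, index=counts.values.columns),
    )


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
                     logratio_trim: float, abs_trim: float) -> float:
    """Two-sample TMM factor: weighted mean of doubly-trimmed M-values."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        logger.warning("TMM: no co-expressed genes with reference; factor set to 1")
        return 1.0
    o = obs[keep].astype(float)
    r = ref[keep].astype(float)
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    # inverse asymptotic binomial variance weights
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = len(m)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not sel.any() or w[sel].sum() == 0:
        return 1.0
    f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    counts: CountMatrix,
    thresholds: AnalysisThresholds | None = None,
) -> pd.Series:
    """TMM scaling factors, rescaled to geometric mean 1.

    The reference sample is the one whose upper-quartile/library-size ratio is
    closest to the mean of that ratio across samples.  M-values are trimmed by
    ``tmm_logratio_trim`` from each tail (default 0.3, keeping the central 40%)
    and A-values by ``tmm_abs_trim`` from each tail (default 0.05), and the
    surviving M-values are averaged with inverse-variance weights.
    """
    thresholds = thresholds or AnalysisThresholds()
    vals = counts.values.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = vals.sum(axis=0)
    f75 = np.quantile(vals, 0.75, axis=0) / np.where(lib == 0, 1.0, lib)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array([
        _tmm_pair_factor(vals[:, j], vals[:, ref_idx], lib[j], lib[ref_idx],
                         thresholds.tmm_logratio_trim, thresholds.tmm_abs_trim)
        for j in range(vals.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.values.columns, name="tmm_factor")


def effective_library_sizes(counts: CountMatrix,
                            thresholds: AnalysisThresholds | None = None) -> pd.Series:
    """Library sizes multiplied by TMM factors."""
    factors = tmm_factors(counts, thresholds)
    return counts.values.sum(axis=0) * factors


def filter_expressed(norm: NormalizedMatrix, min_value: float,
                     min_samples: int) -> pd.Index:
    """Features with value strictly greater than ``min_value`` in at least
    ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    n_over = (norm.values > min_value).sum(axis=1)
    return norm.values.index[n_over >= min_samples]


def downsample_to_group_mean(counts: CountMatrix, seed: int) -> CountMatrix:
    """Binomially thin counts so every group's mean library size matches the
    smallest group mean.

    Each cell of a sample in group g is thinned with keep probability
    ``target / mean_library(g)`` (capped at 1), so thinning never increases a
    count and preserves expected proportions within a sample.
    """
    lib = counts.values.sum(axis=0)
    group_mean = lib.groupby(counts.samples["group"]).mean()
    if (group_mean <= 0).any():
        raise ValueError("zero mean library size in a group")
    target = group_mean.min()
    keep_p = (target / group_mean).clip(upper=1.0)
    rng = np.random.default_rng(seed)
    out = counts.values.copy()
    for sample_id in out.columns:
        p = keep_p[counts.samples.loc[sample_id, "group"]]
        if p < 1.0:
            out[sample_id] = rng.binomial(out[sample_id].to_numpy(), p)
    return CountMatrix(out, counts.features, counts.samples)
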