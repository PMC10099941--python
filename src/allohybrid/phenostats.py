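"""Statistical engines for phenotype and proportion data.

One-way ANOVA with Tukey HSD compact-letter display for quantitative traits
(stem length, flowering time, pollen number, extreme-gene counts), and
quasi-binomial logit GLMs with type II analysis-of-deviance F-tests for
proportion traits (pollen viability, normal seeds, TE read proportions),
with hybridization, whole-genome duplication, and their interaction as
factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

from allohybrid.core import group_is_hybrid, group_ploidy

logger = logging.getLogger(__name__)


@dataclass
class AnovaTukeyResult:
    F: float
    df_between: int
    df_within: int
    pvalue: float
    group_means: pd.Series
    pairwise: pd.DataFrame           # group1, group2, diff, pvalue
    letters: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.05


def one_way_anova(values: np.ndarray, groups: np.ndarray) -> AnovaTukeyResult:
    """Classical fixed-effects one-way ANOVA (between/within decomposition)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    k = len(labels)
    n = len(values)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if n - k < 1:
        raise ValueError("need at least 1 residual degree of freedom")
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    means = {}
    for g in labels:
        v = values[groups == g]
        means[g] = v.mean()
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    df_b, df_w = k - 1, n - k
    if ss_within == 0 and ss_between == 0:
        raise ValueError("zero variance both between and within groups; F undefined")
    ms_w = ss_within / df_w
    F = np.inf if ms_w == 0 else (ss_between / df_b) / ms_w
    p = float(f_dist.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    return AnovaTukeyResult(float(F), df_b, df_w, p,
                            pd.Series(means), pd.DataFrame(), {})


def _tukey_pairwise(values, groups, labels, df_w, ms_w, alpha,
                    with_pvalues=True) -> pd.DataFrame:
    """Tukey-Kramer pairwise tests via the studentized range distribution.

    Significance is decided against the alpha critical value of the
    studentized range (one quantile evaluation); p-values are reported for
    the table and are the same test inverted.
    """
    k = len(labels)
    crit = studentized_range.isf(alpha, k, df_w)
    rows = []
    for g1, g2 in combinations(labels, 2):
        v1 = values[groups == g1]
        v2 = values[groups == g2]
        diff = v1.mean() - v2.mean()
        se = np.sqrt(ms_w / 2.0 * (1.0 / len(v1) + 1.0 / len(v2)))
        q = np.abs(diff) / se if se > 0 else np.inf
        p = (float(studentized_range.sf(q, k, df_w))
             if with_pvalues and np.isfinite(q) else (0.0 if q > crit else np.nan))
        rows.append({"group1": g1, "group2": g2, "diff": diff,
                     "q": q, "pvalue": p, "significant": bool(q > crit)})
    return pd.DataFrame(rows)


def tukey_rejections(values: np.ndarray, groups: np.ndarray, alpha: float = 0.05,
                     crit: float | None = None) -> np.ndarray:
    """Boolean vector of pairwise Tukey rejections (no p-values computed).

    ``crit`` may be supplied to reuse a precomputed critical value across
    repeated calls with the same design (e.g. calibration studies).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    k = len(labels)
    n = len(values)
    df_w = n - k
    means = np.array([values[groups == g].mean() for g in labels])
    counts = np.array([(groups == g).sum() for g in labels])
    ms_w = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum()
               for g in labels) / df_w
    if crit is None:
        crit = studentized_range.isf(alpha, k, df_w)
    out = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(ms_w / 2.0 * (1.0 / counts[i] + 1.0 / counts[j]))
        q = np.abs(means[i] - means[j]) / se if se > 0 else np.inf
        out.append(q > crit)
    return np.array(out)


def _compact_letters(labels_by_mean: list, sig_pairs: set) -> dict[str, str]:
    """Insert-absorb compact letter display.

    Starts from one letter covering all groups; each significantly different
    pair splits every letter containing both; letters fully contained in
    another are absorbed.  Letters are named a, b, c, ... in order of the
    highest-mean group they contain, so the display is deterministic.
    """
    letters: list[set] = [set(labels_by_mean)]
    for g1, g2 in sig_pairs:
        for s in [s for s in letters if g1 in s and g2 in s]:
            letters.remove(s)
            a, b = s - {g1}, s - {g2}
            for cand in (a, b):
                if not any(cand <= other for other in letters):
                    letters.append(cand)
    letters = [s for s in letters if s and
               not any(s < other for other in letters)]
    rank = {g: i for i, g in enumerate(labels_by_mean)}
    letters.sort(key=lambda s: min(rank[g] for g in s))
    out = {g: "" for g in labels_by_mean}
    for ch, s in zip("abcdefghijklmnopqrstuvwxyz", letters):
        for g in s:
            out[g] += ch
    return {g: "".join(sorted(v)) for g, v in out.items()}


def tukey_hsd_letters(values: np.ndarray, groups: np.ndarray,
                      alpha: float = 0.05) -> AnovaTukeyResult:
    """ANOVA plus Tukey HSD pairwise tests and a compact letter display.

    Groups sharing no letter differ significantly at ``alpha``; the letter
    assignment is a deterministic function of the pairwise significance
    matrix (groups ordered by mean descending).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    res = one_way_anova(values, groups)
    labels = list(res.group_means.index)
    if len(labels) == 1:
        res.letters = {labels[0]: "a"}
        return res
    ms_w = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum()
               for g in labels) / res.df_within
    pairwise = _tukey_pairwise(values, groups, labels, res.df_within, ms_w, alpha)
    sig = {(r.group1, r.group2) for r in pairwise.itertuples() if r.significant}
    by_mean = list(res.group_means.sort_values(ascending=False).index)
    res.pairwise = pairwise
    res.letters = _compact_letters(by_mean, sig)
    res.alpha = alpha
    return res


@dataclass
class GLMFit:
    """Quasi-binomial logit fit with type II analysis-of-deviance F-tests."""

    coefficients: pd.Series
    std_errors: pd.Series            # quasi (scaled by sqrt(dispersion))
    dispersion: float                # Pearson chi^2 / residual df
    deviance: float
    df_resid: int
    anova_table: pd.DataFrame        # term, df, F, pvalue
    anova_type: str = "II"


def _design_columns(obs: pd.DataFrame, term: str) -> pd.DataFrame:
    """Design-matrix columns for a main effect or ':'-interaction term."""
    if ":" in term:
        parts = term.split(":")
        cols = [_design_columns(obs, p) for p in parts]
        out = cols[0]
        for c in cols[1:]:
            prod = pd.DataFrame({
                f"{a}:{b}": out[a] * c[b] for a in out.columns for b in c.columns
            })
            out = prod
        return out
    col = obs[term]
    if col.dtype == bool or set(pd.unique(col)) <= {0, 1, True, False}:
        return pd.DataFrame({term: col.astype(float)})
    levels = sorted(pd.unique(col.astype(str)))
    if len(levels) < 2:
        raise ValueError(f"factor {term!r} has a single level")
    return pd.DataFrame({
        f"{term}[{lv}]": (col.astype(str) == lv).astype(float) for lv in levels[1:]
    })


def _fit_binomial(obs: pd.DataFrame, terms: list[str]):
    X = pd.concat([pd.Series(1.0, index=obs.index, name="Intercept")]
                  + [_design_columns(obs, t) for t in terms], axis=1)
    endog = np.column_stack([
        obs["numerator"].to_numpy(dtype=float),
        (obs["denominator"] - obs["numerator"]).to_numpy(dtype=float),
    ])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"rank-deficient design for terms {terms}")
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    res = model.fit()
    mu = res.fittedvalues
    if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
        logger.warning("quasi-binomial fit near separation; estimates capped by IRLS")
    return res, X


def quasibinomial_glm(obs: pd.DataFrame, formula_terms: list[str]) -> GLMFit:
    """Quasi-binomial GLM on numerator/denominator proportion observations.

    ``formula_terms`` is an ordered list of factor names present in ``obs``
    (booleans or categoricals), with interactions written ``a:b``.  The point
    estimates are those of the plain binomial fit; only standard errors and
    tests are scaled by the Pearson dispersion.  Type II analysis of
    deviance: each main effect is tested against the model containing the
    other main effects, interactions are tested last against the full model,
    F = (change in deviance / change in df) / dispersion, with the full
    model's dispersion and residual df.
    """
    if (obs["denominator"] <= 0).any():
        raise ValueError("denominators must be positive")
    if ((obs["numerator"] < 0) | (obs["numerator"] > obs["denominator"])).any():
        raise ValueError("numerators must lie in [0, denominator]")
    full_res, X = _fit_binomial(obs, formula_terms)
    df_resid = int(full_res.df_resid)
    phi = float(full_res.pearson_chi2 / df_resid)

    rows = []
    for term in formula_terms:
        # type II: exclude the term and every higher-order term containing it
        excluded = [t for t in formula_terms
                    if t == term or (":" in t and term in t.split(":"))]
        base = [t for t in formula_terms if t not in excluded]
        with_term = base + [term]
        res_with, Xw = _fit_binomial(obs, with_term)
        res_base, Xb = _fit_binomial(obs, base)
        ddev = res_base.deviance - res_with.deviance
        ddf = Xw.shape[1] - Xb.shape[1]
        F = (ddev / ddf) / phi
        rows.append({
            "term": term, "df": ddf, "F": float(F),
            "pvalue": float(f_dist.sf(F, ddf, df_resid)),
        })
    return GLMFit(
        coefficients=pd.Series(full_res.params, index=X.columns),
        std_errors=pd.Series(full_res.bse * np.sqrt(phi), index=X.columns),
        dispersion=phi,
        deviance=float(full_res.deviance),
        df_resid=df_resid,
        anova_table=pd.DataFrame(rows),
    )


def _proportion_obs(pheno: pd.DataFrame, num: str, den: str) -> pd.DataFrame:
    obs = pd.DataFrame({
        "numerator": pheno[num],
        "denominator": pheno[den],
        "is_hybrid": pheno["group"].map(group_is_hybrid),
        "is_tetraploid": pheno["group"].map(lambda g: group_ploidy(g) == 4),
        "group": pheno["group"],
    })
    return obs[obs["denominator"] > 0]


def phenotype_report(pheno: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Full phenotype statistics bundle.

    ANOVA + Tukey letters for stem length, flowering time, and pollen number;
    hybridization x WGD quasi-binomial GLMs for pollen viability and
    normal-seed proportion; the targeted hybridization-first allotetraploid
    (Allo-h) vs diploid hybrid (F2) viability contrast; and descriptive
    selfed-seed-set rates.
    """
    report: dict = {"anova": {}, "glm": {}}
    for trait in ("stem_length", "flowering_time", "pollen_per_flower"):
        sub = pheno.dropna(subset=[trait])
        report["anova"][trait] = tukey_hsd_letters(
            sub[trait].to_numpy(dtype=float), sub["group"].to_numpy(), alpha)

    viab = _proportion_obs(pheno, "pollen_viable", "pollen_examined")
    seeds = _proportion_obs(pheno, "seeds_normal", "seeds_total")
    terms = ["is_hybrid", "is_tetraploid", "is_hybrid:is_tetraploid"]
    report["glm"]["pollen_viability"] = quasibinomial_glm(viab, terms)
    report["glm"]["normal_seeds"] = quasibinomial_glm(seeds, terms)

    pair = viab[viab["group"].isin(["Allo-h", "F2"])].copy()
    pair["is_alloh"] = pair["group"] == "Allo-h"
    report["glm"]["alloh_vs_f2_viability"] = quasibinomial_glm(pair, ["is_alloh"])

    if "selfed_seed_set" in pheno.columns:
        report["selfed_seed_set"] = pheno.groupby("group")["selfed_seed_set"].mean()
    return report


def anova_tukey(values: np.ndarray, groups: np.ndarray,
                alpha: float = 0.05) -> AnovaTukeyResult:
    """Convenience alias: ANOVA F plus Tukey letters."""
    return tukey_hsd_letters(values, groups, alpha)
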