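"""Shared domain types, validation, and TSV/MTX readers and writers.

The experimental design is a 7-group factorial: the two diploid parents
(Co2 = *C. orientalis*, Cg2 = *C. grandiflora*), the diploid hybrid (F2),
the two autotetraploids (Co4, Cg4), and the allotetraploids formed
duplication-first (Allo-d) or hybridization-first (Allo-h).  Ploidy and
hybrid state are pure functions of the group label and are derived, never
stored independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical group order used throughout (parents, diploid hybrid, autopolyploids,
#: allopolyploids).
GROUPS = ("Co2", "Cg2", "F2", "Co4", "Cg4", "Allo-d", "Allo-h")
TETRAPLOID_GROUPS = frozenset({"Co4", "Cg4", "Allo-d", "Allo-h"})
HYBRID_GROUPS = frozenset({"F2", "Allo-d", "Allo-h"})
TISSUES = ("flower", "leaf")
TE_CLASSES = ("LTR", "Helitron", "SINE", "LINE", "other")


def group_ploidy(group: str) -> int:
    """Ploidy level (2 or 4) implied by the group label."""
    if group not in GROUPS:
        raise ValueError(f"unknown group label: {group!r}")
    return 4 if group in TETRAPLOID_GROUPS else 2


def group_is_hybrid(group: str) -> bool:
    """Whether the group carries both parental subgenomes."""
    if group not in GROUPS:
        raise ValueError(f"unknown group label: {group!r}")
    return group in HYBRID_GROUPS


@dataclass(frozen=True)
class AnalysisThresholds:
    """All numeric thresholds used by the analysis stages.

    Defaults follow the study design: genes are kept when TPM > 2 in at least
    three samples (expression filter before ordination and DE), CPM > 1 in at
    least two individuals (extreme-expression ranking), DEGs require linear
    fold-change > 2 at BH FDR < 0.05, and the relaxed parental-difference
    screen uses FC < 1.2 or FDR > 0.05.
    """

    min_tpm: float = 2.0
    min_tpm_samples: int = 3
    min_cpm: float = 1.0
    min_cpm_samples: int = 2
    fc_threshold: float = 2.0        # linear scale
    fdr_alpha: float = 0.05
    ped_relaxed_fc: float = 1.2      # linear scale
    alpha_phenotype: float = 0.05
    mds_top_genes: int = 500
    tmm_logratio_trim: float = 0.3
    tmm_abs_trim: float = 0.05
    cpm_prior_count: float = 0.5

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be strictly positive")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")


def validate_feature_table(features: pd.DataFrame) -> pd.DataFrame:
    """Validate a feature annotation table (genes + TEs).

    Required columns: ``feature_id``, ``feature_kind`` in {gene, TE},
    ``te_class`` (one of LTR/Helitron/SINE/LINE/other for TEs, empty for
    genes) and ``length_bp`` (required and >= 1 for genes).
    Returns a copy indexed by feature_id, sorted lexicographically.
    """
    required = {"feature_id", "feature_kind"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    if features["feature_id"].duplicated().any():
        dups = features.loc[features["feature_id"].duplicated(), "feature_id"]
        raise ValueError(f"duplicated feature ids: {sorted(set(dups))[:5]}")
    bad_kind = ~features["feature_kind"].isin(["gene", "TE"])
    if bad_kind.any():
        raise ValueError(
            f"invalid feature_kind values: {sorted(set(features.loc[bad_kind, 'feature_kind']))}"
        )
    out = features.copy()
    if "te_class" not in out.columns:
        out["te_class"] = ""
    out["te_class"] = out["te_class"].fillna("")
    is_te = out["feature_kind"] == "TE"
    bad_class = is_te & ~out["te_class"].isin(TE_CLASSES)
    if bad_class.any():
        raise ValueError("TE features must carry a te_class in "
                         f"{TE_CLASSES}; offending ids: "
                         f"{out.loc[bad_class, 'feature_id'].tolist()[:5]}")
    if (~is_te & (out["te_class"] != "")).any():
        raise ValueError("te_class must be empty for gene features")
    if "length_bp" in out.columns:
        genes = out.loc[~is_te]
        if genes["length_bp"].isna().any() or (genes["length_bp"] < 1).any():
            raise ValueError("length_bp must be >= 1 for every gene")
    elif (~is_te).any():
        raise ValueError("feature table must provide length_bp for genes")
    return out.set_index("feature_id", drop=False).sort_index()


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate sample metadata and derive ploidy / is_hybrid from group.

    Required columns: ``sample_id``, ``group``, ``tissue``, ``line``,
    ``lane``.  If ploidy or is_hybrid columns are present they are checked
    against the group-derived values and an inconsistency raises.
    """
    required = {"sample_id", "group", "tissue", "line", "lane"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicated sample ids")
    bad = ~samples["group"].isin(GROUPS)
    if bad.any():
        raise ValueError(f"unknown group labels: {sorted(set(samples.loc[bad, 'group']))}")
    bad_t = ~samples["tissue"].isin(TISSUES)
    if bad_t.any():
        raise ValueError(f"unknown tissue labels: {sorted(set(samples.loc[bad_t, 'tissue']))}")
    out = samples.copy()
    derived_ploidy = out["group"].map(group_ploidy)
    derived_hybrid = out["group"].map(group_is_hybrid)
    if "ploidy" in out.columns and not (out["ploidy"].astype(int) == derived_ploidy).all():
        rows = out.loc[out["ploidy"].astype(int) != derived_ploidy, "sample_id"]
        raise ValueError(f"ploidy inconsistent with group for samples: {rows.tolist()[:5]}")
    if "is_hybrid" in out.columns and not (out["is_hybrid"].astype(bool) == derived_hybrid).all():
        raise ValueError("is_hybrid inconsistent with group")
    out["ploidy"] = derived_ploidy
    out["is_hybrid"] = derived_hybrid
    dup = out.duplicated(subset=["group", "tissue", "line"])
    if dup.any():
        raise ValueError("duplicate (group, tissue, line) combinations")
    return out.set_index("sample_id", drop=False).sort_index()


@dataclass
class CountMatrix:
    """Feature x sample matrix of non-negative integer read-pair counts.

    Rows are bound to a validated feature table and columns to a validated
    sample table; both are canonicalized to lexicographic id order so that
    downstream results never depend on input file order.
    """

    values: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.features = (
            self.features
            if self.features.index.name == "feature_id"
            else validate_feature_table(self.features)
        )
        self.samples = (
            self.samples
            if self.samples.index.name == "sample_id"
            else validate_sample_table(self.samples)
        )
        vals = self.values
        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(arr != np.round(arr))[0]
                raise ValueError(
                    f"non-integer count at feature {vals.index[bad[0]]!r}, "
                    f"sample {vals.columns[bad[1]]!r}"
                )
            vals = vals.round().astype(np.int64)
        if (vals.to_numpy() < 0).any():
            bad = np.argwhere(vals.to_numpy() < 0)[0]
            raise ValueError(
                f"negative count at feature {vals.index[bad[0]]!r}, "
                f"sample {vals.columns[bad[1]]!r}"
            )
        missing_f = set(self.features.index) - set(vals.index)
        if missing_f:
            raise ValueError(f"count matrix missing {len(missing_f)} annotated features")
        missing_s = set(self.samples.index) - set(vals.columns)
        if missing_s:
            raise ValueError(f"count matrix missing {len(missing_s)} samples")
        extra = set(vals.index) - set(self.features.index)
        if extra:
            logger.warning("dropping %d unannotated features from count matrix", len(extra))
        self.values = vals.loc[self.features.index, self.samples.index]

    @property
    def gene_ids(self) -> pd.Index:
        return self.features.index[self.features["feature_kind"] == "gene"]

    @property
    def te_ids(self) -> pd.Index:
        return self.features.index[self.features["feature_kind"] == "TE"]

    def subset_samples(self, mask: pd.Series | np.ndarray) -> "CountMatrix":
        sub = self.samples.loc[mask]
        return CountMatrix(self.values[sub.index], self.features, sub)

    def subset_features(self, ids) -> "CountMatrix":
        feats = self.features.loc[self.features.index.intersection(ids)]
        return CountMatrix(self.values.loc[feats.index], feats, self.samples)


# ---------------------------------------------------------------------------
# I/O

def read_feature_table(path: str | Path) -> pd.DataFrame:
    return validate_feature_table(pd.read_csv(path, sep="\t", dtype={"feature_id": str}))


def read_sample_table(path: str | Path) -> pd.DataFrame:
    return validate_sample_table(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def read_count_matrix(
    path: str | Path,
    features: pd.DataFrame,
    samples: pd.DataFrame,
) -> CountMatrix:
    """Read a TSV (features x samples) or MatrixMarket count file.

    A ``.mtx`` path expects sidecar files ``<stem>.features.txt`` and
    ``<stem>.samples.txt`` holding row and column ids, one per line.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = mmread(path).toarray()
        row_ids = Path(path.with_suffix("")).parent / (path.stem + ".features.txt")
        col_ids = Path(path.with_suffix("")).parent / (path.stem + ".samples.txt")
        rows = row_ids.read_text().split()
        cols = col_ids.read_text().split()
        values = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
    return CountMatrix(values, features, samples)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(path), csr_matrix(matrix.values.to_numpy()))
        (path.parent / (path.stem + ".features.txt")).write_text(
            "\n".join(matrix.values.index) + "\n"
        )
        (path.parent / (path.stem + ".samples.txt")).write_text(
            "\n".join(matrix.values.columns) + "\n"
        )
    else:
        out = matrix.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as deterministic TSV (UTF-8, 6 significant digits)."""
    records.to_csv(path, sep="\t", index=False, float_format="%.6g", encoding="utf-8")


def validate_design(samples: pd.DataFrame) -> pd.DataFrame:
    """Summarize samples per group x tissue and flag unbalanced cells.

    The reference design has 6 lines sequenced per group and tissue, i.e.
    84 samples = 7 groups x 6 lines x 2 tissues.  Returns a table with one
    row per (group, tissue) holding the sample count and a ``balanced``
    flag (count equal to the modal count).
    """
    samples = validate_sample_table(samples.reset_index(drop=True))
    cells = (
        samples.groupby(["group", "tissue"], observed=True)
        .size()
        .rename("n_samples")
        .reset_index()
    )
    # include empty cells for groups/tissues present in the table
    full = pd.MultiIndex.from_product(
        [sorted(samples["group"].unique()), sorted(samples["tissue"].unique())],
        names=["group", "tissue"],
    )
    cells = (
        cells.set_index(["group", "tissue"])
        .reindex(full, fill_value=0)
        .reset_index()
    )
    mode = cells["n_samples"].mode().iloc[0]
    cells["balanced"] = cells["n_samples"] == mode
    return cells
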