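"""Helpers shared by the numbered analysis drivers."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from allohybrid import core
from allohybrid.diffexpr import DEResult

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"


def load_experiment():
    features = core.read_feature_table(DATA / "features.tsv")
    samples = core.read_sample_table(DATA / "samples.tsv")
    counts = core.read_count_matrix(DATA / "counts.tsv", features, samples)
    phenotypes = pd.read_csv(DATA / "phenotypes.tsv", sep="\t")
    truth = pd.read_csv(DATA / "truth.tsv", sep="\t").set_index(
        "feature_id", drop=False)
    return counts, phenotypes, truth


def write_de_result(res: DEResult, path: Path) -> None:
    core.write_table(res.table.reset_index(drop=True), path)


def read_de_result(path: Path, group_a: str, group_b: str,
                   tissue: str) -> DEResult:
    table = pd.read_csv(path, sep="\t").set_index("feature_id", drop=False)
    n_tested = int(table["qvalue"].notna().sum())
    return DEResult(group_a, group_b, tissue, table, n_tested, "bh_then_fc")
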