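"""Additive/nonadditive classification of hybrid gene expression.

Each gene in a hybrid group is classified from three differential-expression
statuses: hybrid vs parent 1 (Co2, *C. orientalis*), hybrid vs parent 2
(Cg2, *C. grandiflora*), and parent 1 vs parent 2.  The ten categories
distinguish no change, strict additive (intermediate) expression,
complete expression-level dominance toward either parent in either
direction, transgressive expression above or below both parents, an
unresolved parental difference (parents differ but the hybrid resolves
against neither), and ambiguous (status triples that are incoherent under
test noise; reported, never dropped).

Complete ELD and TRE together constitute "proven nonadditive" expression.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from allohybrid.diffexpr import DEResult

STATUSES = ("up", "down", "ns")

CATEGORIES = (
    "no_change",
    "additive_intermediate",
    "ELD_P1_high",
    "ELD_P1_low",
    "ELD_P2_high",
    "ELD_P2_low",
    "transgressive_up",
    "transgressive_down",
    "unresolved_parental_difference",
    "ambiguous",
)
ELD_CATEGORIES = frozenset({"ELD_P1_high", "ELD_P1_low", "ELD_P2_high", "ELD_P2_low"})
TRE_CATEGORIES = frozenset({"transgressive_up", "transgressive_down"})
NONADDITIVE_CATEGORIES = ELD_CATEGORIES | TRE_CATEGORIES

# Decision table on (hybrid vs P1, hybrid vs P2, P1 vs P2).  Kept as a single
# explicit constant so an alternative category scheme can be swapped in.
# Rules: hybrid above both parents -> transgressive up (and symmetrically
# down); hybrid equal to one parent and shifted in the direction of that
# parent's difference from the other -> complete dominance of the matched
# parent; hybrid strictly between two differing parents -> additive;
# parents differ but the hybrid differs from neither -> unresolved.
_TABLE: dict[tuple[str, str, str], str] = {}
for _c12 in STATUSES:
    _TABLE[("up", "up", _c12)] = "transgressive_up"
    _TABLE[("down", "down", _c12)] = "transgressive_down"
_TABLE[("ns", "ns", "ns")] = "no_change"
_TABLE[("ns", "ns", "up")] = "unresolved_parental_difference"
_TABLE[("ns", "ns", "down")] = "unresolved_parental_difference"
_TABLE[("ns", "up", "up")] = "ELD_P1_high"      # hybrid = P1, P1 above P2
_TABLE[("ns", "down", "down")] = "ELD_P1_low"   # hybrid = P1, P1 below P2
_TABLE[("up", "ns", "down")] = "ELD_P2_high"    # hybrid = P2, P2 above P1
_TABLE[("down", "ns", "up")] = "ELD_P2_low"     # hybrid = P2, P2 below P1
_TABLE[("up", "down", "down")] = "additive_intermediate"   # P2 > hybrid > P1
_TABLE[("down", "up", "up")] = "additive_intermediate"     # P1 > hybrid > P2
for _t in itertools.product(STATUSES, repeat=3):
    _TABLE.setdefault(_t, "ambiguous")


def classify_triple(c1: str, c2: str, c12: str) -> str:
    """Category for one status triple (hybrid vs P1, hybrid vs P2, P1 vs P2)."""
    for s in (c1, c2, c12):
        if s not in STATUSES:
            raise ValueError(f"invalid status: {s!r}")
    return _TABLE[(c1, c2, c12)]


@dataclass
class CategoryResult:
    hybrid_group: str
    tissue: str | None
    table: pd.DataFrame          # feature_id, c1, c2, c12, category
    proportions: pd.Series       # per category, over the shared gene universe

    @property
    def eld_proportion(self) -> float:
        return float(self.proportions[list(ELD_CATEGORIES)].sum())

    @property
    def tre_proportion(self) -> float:
        return float(self.proportions[list(TRE_CATEGORIES)].sum())

    @property
    def nonadditive_proportion(self) -> float:
        return self.eld_proportion + self.tre_proportion


def classify_hybrid_group(
    de_h_p1: DEResult,
    de_h_p2: DEResult,
    de_p1_p2: DEResult,
    hybrid_group: str | None = None,
) -> CategoryResult:
    """Classify every gene of a hybrid group from its three contrasts.

    Contrast orientation is normalized internally: ``de_h_p1`` and
    ``de_h_p2`` are re-oriented to hybrid-relative-to-parent and
    ``de_p1_p2`` to P1 (Co2) relative to P2 (Cg2), so callers may pass
    results from either direction.
    """
    def oriented(res: DEResult, first: str) -> DEResult:
        return res if res.group_a == first else res.swap()

    hybrid_group = hybrid_group or (
        de_h_p1.group_a if de_h_p1.group_a not in ("Co2", "Cg2") else de_h_p1.group_b)
    c1 = oriented(de_h_p1, hybrid_group)
    c2 = oriented(de_h_p2, hybrid_group)
    c12 = oriented(de_p1_p2, c1.group_b)

    universes = [set(r.table.index) for r in (c1, c2, c12)]
    if universes[0] != universes[1] or universes[0] != universes[2]:
        diff = (universes[0] ^ universes[1]) | (universes[0] ^ universes[2])
        raise ValueError(f"contrasts disagree on {len(diff)} genes")

    genes = c1.table.index
    s1 = c1.table["status"].to_numpy()
    s2 = c2.table.loc[genes, "status"].to_numpy()
    s12 = c12.table.loc[genes, "status"].to_numpy()
    cats = np.array([_TABLE[(a, b, c)] for a, b, c in zip(s1, s2, s12)])
    table = pd.DataFrame({
        "feature_id": genes, "c1": s1, "c2": s2, "c12": s12, "category": cats,
    }).set_index("feature_id", drop=False)
    props = (table["category"].value_counts().reindex(CATEGORIES, fill_value=0)
             / len(table))
    return CategoryResult(hybrid_group, c1.tissue, table, props)


def overlap_analysis(sets: dict[str, set]) -> pd.DataFrame:
    """Counts for every intersection region of 2-4 named sets (Venn regions).

    Regions partition the union: each element is counted in exactly the
    region given by its membership pattern.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError("overlap_analysis takes 2-4 named sets")
    names = list(sets)
    universe = set().union(*sets.values())
    counts: dict[tuple[bool, ...], int] = {}
    for el in universe:
        key = tuple(el in sets[n] for n in names)
        counts[key] = counts.get(key, 0) + 1
    rows = []
    for pattern in itertools.product([True, False], repeat=len(names)):
        if not any(pattern):
            continue
        rows.append({
            **{n: inc for n, inc in zip(names, pattern)},
            "count": counts.get(pattern, 0),
        })
    return pd.DataFrame(rows)
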