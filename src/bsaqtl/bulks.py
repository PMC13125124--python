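"""Selection of low/high phenotypic bulks per trait.

RILs are ranked within each context — each environment's stage-1 BLUPs
plus the across-environment GEI BLUP — and a RIL's composite score is the
mean of its (ascending) ranks across contexts.  The bulk_size lowest
composite scores form the low bulk and the bulk_size highest form the
high bulk.  Mean-of-ranks is a scale-free consensus over all the stated
screening inputs; ``ranking="gei_only"`` ranks on the GEI BLUP alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .pheno import BlupTable

__all__ = ["BulkPair", "composite_ranking", "select_bulks"]


@dataclass
class BulkPair:
    trait: str
    low: list[str]
    high: list[str]
    bulk_size: int
    scores: pd.Series

    def __post_init__(self) -> None:
        if len(self.low) != self.bulk_size or len(self.high) != self.bulk_size:
            raise ValueError("bulk sizes do not match bulk_size")
        if set(self.low) & set(self.high):
            raise ValueError("low and high bulks overlap")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"trait": self.trait, "bulk": bulk, "ril": ril, "composite": self.scores[ril]}
            for bulk, members in (("low", self.low), ("high", self.high))
            for ril in members
        ]
        return pd.DataFrame(rows)


def composite_ranking(
    blups: BlupTable, trait: str, ranking: str = "mean_rank"
) -> pd.Series:
    """Per-RIL composite score for one trait (lower = lower trait value).

    ``mean_rank`` averages ascending ranks over every environmental BLUP
    column plus the GEI BLUP; ``gei_only`` uses the GEI BLUP rank alone.
    RILs missing from a context are ranked over the contexts they have.
    """
    env = blups.env_blups(trait)
    gei = blups.gei_blups(trait)
    if ranking == "gei_only":
        contexts = gei.to_frame("GEI")
    elif ranking == "mean_rank":
        contexts = env.join(gei.rename("GEI"), how="outer")
    else:
        raise ValueError(f"unknown ranking rule {ranking!r}")
    ranks = contexts.rank(axis=0, method="average", na_option="keep")
    score = ranks.mean(axis=1, skipna=True)
    score.index = score.index.astype(str)
    return score.rename(trait)


def select_bulks(scores: pd.Series, bulk_size: int = 20, trait: str | None = None) -> BulkPair:
    """Split the composite ranking into low/high bulks of ``bulk_size``.

    Ties in the composite score are broken lexicographically by RIL id so
    selection is deterministic.
    """
    n = len(scores)
    if 2 * bulk_size > n:
        raise ValueError(f"2*bulk_size={2 * bulk_size} exceeds number of RILs ({n})")
    ordered = scores.to_frame("score").reset_index(names="ril")
    ordered["ril"] = ordered["ril"].astype(str)
    ordered = ordered.sort_values(["score", "ril"], kind="mergesort")
    low = ordered["ril"].head(bulk_size).tolist()
    high = ordered["ril"].tail(bulk_size).tolist()
    return BulkPair(
        trait=trait or str(scores.name),
        low=low,
        high=high,
        bulk_size=bulk_size,
        scores=scores,
    )
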