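"""Sulphur-isotope residency analysis.

Tissue d34S separates marine from freshwater residency: marine fish
typically fall between +13 and +18 permil, freshwater fish between -8 and
+8 permil, and fish moving between the habitats show intermediate values.
Group comparisons (e.g. migratory vs non-migratory species, river vs
estuary fish) use the non-parametric Kruskal-Wallis rank-sum test, which
suits the very small sample sizes typical of sulphur subsamples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

__all__ = [
    "BandConfig",
    "ResidencyCall",
    "KWResult",
    "classify_d34s",
    "kruskal_wallis",
]


@dataclass(frozen=True)
class BandConfig:
    """d34S band edges (permil), inclusive.  Defaults are the published
    typical ranges for freshwater and marine fish."""

    freshwater_low: float = -8.0
    freshwater_high: float = 8.0
    marine_low: float = 13.0
    marine_high: float = 18.0

    def __post_init__(self) -> None:
        if not (
            self.freshwater_low
            <= self.freshwater_high
            < self.marine_low
            <= self.marine_high
        ):
            raise ValueError("band edges must be ordered: freshwater below marine")


@dataclass(frozen=True)
class ResidencyCall:
    record_id: str
    d34S: float
    band: str  # freshwater | intermediate | marine
    out_of_band: bool = False  # value fell outside [fw_low, marine_high]


def classify_d34s(
    record_id: str, d34S: float, bands: BandConfig | None = None
) -> ResidencyCall:
    """Classify a d34S value into freshwater / intermediate / marine.

    Values between the bands are intermediate (mixed residency); values
    below the freshwater band or above the marine band map to the nearest
    extreme with an out-of-band note.
    """
    if not math.isfinite(d34S):
        raise ValueError("d34S must be finite")
    bands = bands or BandConfig()
    if d34S < bands.freshwater_low:
        return ResidencyCall(record_id, d34S, "freshwater", out_of_band=True)
    if d34S <= bands.freshwater_high:
        return ResidencyCall(record_id, d34S, "freshwater")
    if d34S < bands.marine_low:
        return ResidencyCall(record_id, d34S, "intermediate")
    if d34S <= bands.marine_high:
        return ResidencyCall(record_id, d34S, "marine")
    return ResidencyCall(record_id, d34S, "marine", out_of_band=True)


@dataclass(frozen=True)
class KWResult:
    """Kruskal-Wallis rank-sum test: tie-corrected H, chi-square p."""

    statistic: float
    df: int
    p_value: float
    group_sizes: tuple[int, ...]
    tie_corrected: bool = True  # mid-ranks with the standard tie correction

    def __post_init__(self) -> None:
        if self.statistic < -1e-12 or self.df < 1:
            raise ValueError("invalid Kruskal-Wallis result")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Tie-corrected Kruskal-Wallis test across >= 2 groups.

    Mid-ranks are assigned to ties; the p-value uses the chi-square
    approximation with df = groups - 1.  All-identical data leave H
    undefined and raise.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    sizes = tuple(len(g) for g in groups)
    if any(s == 0 for s in sizes):
        raise ValueError("every group must be non-empty")
    if sum(sizes) < 3:
        raise ValueError("need >= 3 observations in total")
    pooled = [v for g in groups for v in g]
    if len(set(pooled)) == 1:
        raise ValueError("Kruskal-Wallis H undefined: all values identical")
    res = stats.kruskal(*[list(g) for g in groups])
    if not math.isfinite(res.statistic):
        raise ValueError("Kruskal-Wallis H undefined for this data")
    return KWResult(
        statistic=float(res.statistic),
        df=len(groups) - 1,
        p_value=float(res.pvalue),
        group_sizes=sizes,
    )
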