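"""Three-way promoter classification from H3K4me3 and H3K27me3 intensities.

Promoters below the first quartile (Q1) of the catalog-wide H3K4me3
intensity are H3K4me3-Low. Among the remaining (H3K4me3-High) promoters,
those above the third quartile (Q3) of the catalog-wide H3K27me3 intensity
are bivalent; the rest are H3K4me3-Only. Both thresholds are computed over
the whole catalog — which is why the bivalent fraction is not 25% of the
High subset — and both comparisons are strict.

Quantiles use linear interpolation at rank h = 1 + (N - 1) q. With N
distinct values and (N - 1) q non-integer the strictly-below count is
exactly floor(h), which pins the classifier's behavior on catalogs of any
size.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import List, Sequence

import numpy as np


class PromoterClass(str, Enum):
    H3K4ME3_LOW = "H3K4me3_LOW"
    H3K4ME3_ONLY = "H3K4me3_ONLY"
    BIVALENT = "BIVALENT"


@dataclass(frozen=True)
class ClassifierParams:
    low_quantile: float = 0.25
    high_quantile: float = 0.75

    def __post_init__(self) -> None:
        if not (0 < self.low_quantile < self.high_quantile < 1):
            raise ValueError("require 0 < low_quantile < high_quantile < 1")


def quantile(values: Sequence[float], q: float) -> float:
    """Linear-interpolation quantile at rank ``h = 1 + (N - 1) q``."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("quantile of empty values is undefined")
    if not 0 <= q <= 1:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    return float(np.quantile(arr, q, method="linear"))


def classify_promoters(
    h3k4me3: Sequence[float],
    h3k27me3: Sequence[float],
    params: ClassifierParams = ClassifierParams(),
) -> List[PromoterClass]:
    """Label every promoter; the three labels partition the catalog."""
    k4 = np.asarray(h3k4me3, dtype=float)
    k27 = np.asarray(h3k27me3, dtype=float)
    if k4.shape != k27.shape or k4.ndim != 1:
        raise ValueError(
            f"intensity lists must be 1-D and aligned: {k4.shape} vs {k27.shape}"
        )
    if k4.size == 0:
        return []
    t_low = quantile(k4, params.low_quantile)
    t_high = quantile(k27, params.high_quantile)
    labels: List[PromoterClass] = []
    for a, b in zip(k4, k27):
        if a < t_low:
            labels.append(PromoterClass.H3K4ME3_LOW)
        elif b > t_high:
            labels.append(PromoterClass.BIVALENT)
        else:
            labels.append(PromoterClass.H3K4ME3_ONLY)
    return labels
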