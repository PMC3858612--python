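"""Directional percent overlap between home-range polygons.

Percent overlap of range A by range B is 100 * area(A n B) / area(A) — the
share of A's area that falls inside B. It is directional: when a small
female range nests inside a larger male range the female-side percentage
exceeds the male-side one even though the shared area is identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .home_range_kde import RangePolygon

__all__ = ["OverlapResult", "percent_overlap", "overlap_matrix", "overlap_table"]

#: Ranges whose polygons lie within this distance (m) count as neighbors.
DEFAULT_ADJACENCY_M = 50.0


@dataclass
class OverlapResult:
    id_a: str
    id_b: str
    overlap_a_by_b: float  # percent of A's area inside B
    overlap_b_by_a: float
    area_a_ha: float
    area_b_ha: float
    intersection_ha: float


def percent_overlap(a: RangePolygon, b: RangePolygon) -> OverlapResult:
    """Directional percent overlap between two range polygons.

    Multi-ring ranges contribute their summed ring areas; the intersection
    area is computed once and used for both directions.
    """
    area_a = a.geometry.area
    area_b = b.geometry.area
    if area_a <= 0 or area_b <= 0:
        raise ValueError("zero-area range polygon")
    inter = a.geometry.intersection(b.geometry).area
    return OverlapResult(
        a.individual_id or "A",
        b.individual_id or "B",
        100.0 * inter / area_a,
        100.0 * inter / area_b,
        area_a / 1e4,
        area_b / 1e4,
        inter / 1e4,
    )


def overlap_matrix(polygons: list[RangePolygon], neighbors_only: bool = False,
                   adjacency_m: float = DEFAULT_ADJACENCY_M) -> list[OverlapResult]:
    """Directional overlap for all unordered pairs of ranges.

    With ``neighbors_only`` the pair set is restricted to ranges whose
    polygons lie within ``adjacency_m`` of each other (the summaries over
    "neighboring" same-sex individuals use this restriction).
    """
    if len(polygons) < 2:
        raise ValueError("need at least two polygons")
    out = []
    for a, b in combinations(polygons, 2):
        if neighbors_only and a.geometry.distance(b.geometry) > adjacency_m:
            continue
        out.append(percent_overlap(a, b))
    return out


def overlap_table(results: list[OverlapResult]) -> pd.DataFrame:
    """Tabular view matching the TSV report layout."""
    return pd.DataFrame(
        [
            {
                "id_a": r.id_a,
                "id_b": r.id_b,
                "pct_a_in_b": round(r.overlap_a_by_b, 2),
                "pct_b_in_a": round(r.overlap_b_by_a, 2),
                "area_a_ha": round(r.area_a_ha, 4),
                "area_b_ha": round(r.area_b_ha, 4),
            }
            for r in results
        ]
    )
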