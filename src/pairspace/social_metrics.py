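"""Social-interaction classification, hourly rates, and sleeping-site tallies.

Interactions between pair partners are classed as *agonistic* (any
aggressive or submissive behavior code), *affiliative* (grooming, or sitting
within 1 m), or *neutral* (within 5 m without agonistic or affiliative
behavior); approaches beyond 5 m are not scored as interactions. Rates are
events per hour the focal animals were actually in sight.

Sleeping-site records (one tree per individual per day) are tallied per
dyad into exclusively used trees, trees shared with the pair partner on any
date, and days of simultaneous use of the same tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "classify_event",
    "interaction_rates",
    "rate_summary",
    "sleeping_tally",
    "read_interactions_csv",
    "read_sleeping_csv",
    "AGONISTIC_CODES",
    "AFFILIATIVE_CODES",
]

#: Aggressive or submissive behavior codes (either side scores agonistic).
AGONISTIC_CODES = frozenset(
    {"chase", "charge", "bite", "grab", "flee", "displace", "jump_away"}
)
AFFILIATIVE_CODES = frozenset({"groom"})
KNOWN_CODES = AGONISTIC_CODES | AFFILIATIVE_CODES

AFFILIATIVE_MAX_M = 1.0
NEUTRAL_MAX_M = 5.0

CLASSES = ["neutral", "agonistic", "affiliative"]


@dataclass
class RateTable:
    """Per-dyad hourly interaction rates plus across-dyad means and SDs."""

    per_dyad: pd.DataFrame  # index: dyad; columns: neutral, agonistic, affiliative, total
    means: pd.Series
    sds: pd.Series


def classify_event(codes=(), distance_m: float | None = None) -> str | None:
    """Classify one interaction record from behavior codes and/or distance.

    Agonistic codes dominate; otherwise grooming or distance <= 1 m is
    affiliative; otherwise distance <= 5 m is neutral; beyond 5 m the record
    is no interaction (returns None). A record carrying neither codes nor a
    distance, or an unknown code, is rejected rather than guessed.
    """
    codes = {str(c).strip().lower().replace(" ", "_") for c in codes if str(c).strip()}
    unknown = codes - KNOWN_CODES
    if unknown:
        raise ValueError(f"unknown behavior code(s): {sorted(unknown)}")
    if not codes and distance_m is None:
        raise ValueError("record has neither behavior codes nor a distance")
    if codes & AGONISTIC_CODES:
        return "agonistic"
    if codes & AFFILIATIVE_CODES:
        return "affiliative"
    if distance_m is not None:
        if distance_m <= AFFILIATIVE_MAX_M:
            return "affiliative"
        if distance_m <= NEUTRAL_MAX_M:
            return "neutral"
    return None


def _dyad_key(a: str, b: str) -> str:
    return "-".join(sorted((str(a), str(b))))


def interaction_rates(events: pd.DataFrame, hours_in_sight: dict[str, float],
                      round_dp: int = 2) -> RateTable:
    """Hourly interaction rates per dyad and per class.

    ``events`` needs columns ``actor_id, receiver_id, klass``;
    ``hours_in_sight`` maps the dyad key (sorted ids joined by '-') to the
    simultaneous in-sight observation hours of that dyad. Rates are rounded
    to ``round_dp`` decimals for report parity; the across-dyad means are
    unweighted means of the (rounded) per-dyad rates.
    """
    for dyad, hours in hours_in_sight.items():
        if hours <= 0:
            raise ValueError(f"nonpositive observation hours for dyad {dyad}")
    if len(events):
        keys = [_dyad_key(a, b) for a, b in zip(events["actor_id"], events["receiver_id"])]
        counts = (
            events.assign(dyad=keys)
            .groupby(["dyad", "klass"])
            .size()
            .unstack(fill_value=0)
        )
    else:
        counts = pd.DataFrame()
    rows = {}
    for dyad, hours in hours_in_sight.items():
        row, total = {}, 0
        for klass in CLASSES:
            c = counts.loc[dyad, klass] if (dyad in counts.index and klass in counts) else 0
            total += c
            row[klass] = round(c / hours, round_dp)
        # total from unrounded counts, so it can differ from the sum of the
        # rounded class rates by one unit in the last place
        row["total"] = round(total / hours, round_dp)
        rows[dyad] = row
    per_dyad = pd.DataFrame.from_dict(rows, orient="index")[CLASSES + ["total"]]
    return RateTable(per_dyad, per_dyad.mean(), per_dyad.std(ddof=1))


def rate_summary(per_dyad_rates: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Unweighted across-dyad means and SDs of already-tabulated rates."""
    return per_dyad_rates.mean(), per_dyad_rates.std(ddof=1)


def sleeping_tally(records: pd.DataFrame, dyads: list[tuple[str, str]]) -> pd.DataFrame:
    """Per-dyad sleeping-tree tallies.

    ``records`` needs columns ``date, individual_id, tree_id`` with at most
    one record per individual per date. For each (male, female) dyad the
    tally reports: dates with records for both partners (observation_days),
    trees used by exactly one partner (exclusive_m / exclusive_f), trees
    used by both on any dates (shared_trees), and dates on which both slept
    in the same tree (simultaneous_days).
    """
    dup = records.duplicated(subset=["date", "individual_id"])
    if dup.any():
        raise ValueError("multiple sleeping records for one individual on one date")
    rows = []
    for male, female in dyads:
        rm = records[records["individual_id"] == male]
        rf = records[records["individual_id"] == female]
        trees_m = set(rm["tree_id"])
        trees_f = set(rf["tree_id"])
        merged = rm.merge(rf, on="date", suffixes=("_m", "_f"))
        rows.append(
            {
                "male_id": male,
                "female_id": female,
                "observation_days": len(merged),
                "exclusive_m": len(trees_m - trees_f),
                "exclusive_f": len(trees_f - trees_m),
                "shared_trees": len(trees_m & trees_f),
                "simultaneous_days": int((merged["tree_id_m"] == merged["tree_id_f"]).sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

def read_interactions_csv(path) -> pd.DataFrame:
    """Read and classify an interaction-event CSV.

    Columns: ``timestamp, actor_id, receiver_id, codes, distance_m``;
    ``codes`` is a semicolon-separated behavior-code list (may be empty when
    a distance is given). Records classifying to no interaction (> 5 m,
    no codes) are dropped; invalid records raise.
    """
    df = pd.read_csv(path)
    required = ["timestamp", "actor_id", "receiver_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    klasses = []
    for _, row in df.iterrows():
        raw = row.get("codes", "")
        codes = [] if pd.isna(raw) or raw == "" else str(raw).split(";")
        dist = row.get("distance_m", None)
        dist = None if dist is None or pd.isna(dist) else float(dist)
        klasses.append(classify_event(codes, dist))
    df = df.assign(klass=klasses)
    return df[df["klass"].notna()].reset_index(drop=True)


def read_sleeping_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["date", "individual_id", "tree_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    return df
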