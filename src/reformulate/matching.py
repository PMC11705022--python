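"""Cross-year product matching, exclusion cascade and per-100 normalization.

Products are matched one-to-one on exact equality of (product code,
retailer, container size, container unit); a key occurring more than
once within either year is ambiguous and excluded.  Container-size
changes ("shrinkflation") therefore break the match by design.  After
matching, four exclusion stages mirror the study flow: drop TRA
categories W/X, drop pairs without valid price, drop pairs with
incomplete core nutrition, and drop pairs unusable by the FSANZ scorer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .records import CORE_NUTRIENTS, FoodDatabase, NUTRIENT_KEYS, ProductRecord


class MatchingError(ValueError):
    pass


@dataclass
class MatchedPair:
    """One product observed at both time points, with per-100 values and deltas."""

    key: tuple
    record_y1: ProductRecord
    record_y2: ProductRecord
    price_per100_y1: Optional[float] = None
    price_per100_y2: Optional[float] = None
    nutrients_per100_y1: dict = field(default_factory=dict)
    nutrients_per100_y2: dict = field(default_factory=dict)
    delta_price: Optional[float] = None
    delta_nutrients: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)
    fsanz_y1: object = None
    fsanz_y2: object = None
    fsanz_score_change: Optional[int] = None


@dataclass
class ExclusionEntry:
    stage: str
    criterion: str
    n_in: int
    n_removed: int
    n_out: int


@dataclass
class ExclusionLog:
    """Ordered audit trail of the matching and exclusion cascade."""

    entries: list = field(default_factory=list)

    def add(self, stage: str, criterion: str, n_in: int, n_removed: int) -> None:
        n_out = n_in - n_removed
        assert n_out >= 0
        self.entries.append(ExclusionEntry(stage, criterion, n_in, n_removed, n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": e.stage,
                    "criterion": e.criterion,
                    "n_in": e.n_in,
                    "n_removed": e.n_removed,
                    "n_out": e.n_out,
                }
                for e in self.entries
            ],
            columns=["stage", "criterion", "n_in", "n_removed", "n_out"],
        )


def per_hundred(amount, basis_size):
    """Scale an amount to per-100 using the given basis (g or ml).

    Price uses the container size as basis, nutrients the serving size.
    ``None`` amounts propagate; a nonpositive basis is a hard error.
    """
    if basis_size is None or basis_size <= 0:
        raise MatchingError(f"basis size must be positive, got {basis_size!r}")
    if amount is None:
        return None
    return amount * 100.0 / basis_size


def _per100_nutrients(rec: ProductRecord) -> dict:
    out = {}
    if rec.serving_size is None or rec.serving_size <= 0:
        return {k: None for k in NUTRIENT_KEYS}
    for key in NUTRIENT_KEYS:
        amount = rec.nutrients.get(key)
        out[key] = None if amount is None else per_hundred(amount, rec.serving_size)
    return out


def compute_deltas(pair: MatchedPair) -> MatchedPair:
    """Fill per-100 fields and year2-minus-year1 deltas; missing propagates."""
    pair.price_per100_y1 = pair.record_y1.price_per100()
    pair.price_per100_y2 = pair.record_y2.price_per100()
    pair.nutrients_per100_y1 = _per100_nutrients(pair.record_y1)
    pair.nutrients_per100_y2 = _per100_nutrients(pair.record_y2)
    if pair.price_per100_y1 is not None and pair.price_per100_y2 is not None:
        pair.delta_price = pair.price_per100_y2 - pair.price_per100_y1
    else:
        pair.delta_price = None
    pair.delta_nutrients = {}
    for key in NUTRIENT_KEYS:
        a = pair.nutrients_per100_y1.get(key)
        b = pair.nutrients_per100_y2.get(key)
        pair.delta_nutrients[key] = None if a is None or b is None else b - a
    return pair


def match_products(db1: FoodDatabase, db2: FoodDatabase):
    """One-to-one match on (code, retailer, container size, unit).

    Returns (pairs sorted by key, ExclusionLog).  Ambiguous keys —
    duplicated within a year — are excluded and logged; unmatched
    records are counted.  Databases must carry distinct year labels.
    """
    if db1.year_label == db2.year_label:
        raise MatchingError(
            f"both databases have year label {db1.year_label!r}; refusing to self-match"
        )

    def index(db):
        by_key: dict = {}
        for rec in db.records:
            by_key.setdefault(rec.key(), []).append(rec)
        ambiguous = {k for k, v in by_key.items() if len(v) > 1}
        return by_key, ambiguous

    by1, amb1 = index(db1)
    by2, amb2 = index(db2)
    ambiguous = amb1 | amb2
    shared = (set(by1) & set(by2)) - ambiguous
    n_amb_shared = len((set(by1) & set(by2)) & ambiguous)

    pairs = []
    for key in sorted(shared, key=lambda k: tuple(str(p) for p in k)):
        pair = MatchedPair(key=key, record_y1=by1[key][0], record_y2=by2[key][0])
        pairs.append(compute_deltas(pair))

    log = ExclusionLog()
    log.add("input_y1", f"records in {db1.year_label}", len(db1.records), 0)
    log.add("input_y2", f"records in {db2.year_label}", len(db2.records), 0)
    log.add(
        "ambiguous_keys",
        "duplicate match key within a year",
        len(set(by1) & set(by2)),
        n_amb_shared,
    )
    n_unmatched_y1 = sum(len(v) for k, v in by1.items() if k not in shared)
    n_unmatched_y2 = sum(len(v) for k, v in by2.items() if k not in shared)
    log.add("unmatched_y1", "year-1 records without a year-2 match", len(db1.records), n_unmatched_y1)
    log.add("unmatched_y2", "year-2 records without a year-1 match", len(db2.records), n_unmatched_y2)
    log.add("matched", "one-to-one matched pairs", len(pairs), 0)
    return pairs, log


EXCLUSION_STAGES = ("category_WX", "invalid_price", "incomplete_nutrition", "fsanz_ineligible")

#: TRA categories whose FSANZ scoring requires a calcium value (cheese
#: candidates within Dairy).  Configurable per call.
DEFAULT_CHEESE_CATEGORIES = frozenset({"D"})


def _valid_price(rec: ProductRecord) -> bool:
    return (
        rec.price is not None
        and rec.price >= 0
        and rec.container_size is not None
        and rec.container_size > 0
    )


def _complete_nutrition(rec: ProductRecord) -> bool:
    return (
        rec.serving_size is not None
        and rec.serving_size > 0
        and all(rec.nutrients.get(k) is not None for k in CORE_NUTRIENTS)
    )


def _fsanz_ready(rec: ProductRecord, cheese_categories) -> bool:
    if rec.nutrients.get("fibre_g") is None or rec.fvnl_percent is None:
        return False
    if rec.tra_category in cheese_categories and rec.nutrients.get("calcium_mg") is None:
        return False
    return True


def apply_exclusions(pairs, stage: str, cheese_categories=DEFAULT_CHEESE_CATEGORIES):
    """Apply one named exclusion stage; returns (kept pairs, ExclusionEntry)."""
    if stage == "category_WX":
        def keep(p):
            return p.record_y1.tra_category not in ("W", "X")
        criterion = "TRA category W or X"
    elif stage == "invalid_price":
        def keep(p):
            return _valid_price(p.record_y1) and _valid_price(p.record_y2)
        criterion = "missing or invalid price/container size in either year"
    elif stage == "incomplete_nutrition":
        def keep(p):
            return _complete_nutrition(p.record_y1) and _complete_nutrition(p.record_y2)
        criterion = "incomplete core nutrition in either year"
    elif stage == "fsanz_ineligible":
        def keep(p):
            return _fsanz_ready(p.record_y1, cheese_categories) and _fsanz_ready(
                p.record_y2, cheese_categories
            )
        criterion = "missing fibre/fvnl (or calcium for cheese candidates)"
    else:
        raise MatchingError(f"unknown exclusion stage {stage!r}")

    kept = [p for p in pairs if keep(p)]
    entry = ExclusionEntry(stage, criterion, len(pairs), len(pairs) - len(kept), len(kept))
    return kept, entry
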