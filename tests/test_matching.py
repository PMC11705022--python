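import dataclasses
import random

import pytest
from hypothesis import given, strategies as st

from reformulate.matching import (
    MatchingError,
    apply_exclusions,
    compute_deltas,
    match_products,
    per_hundred,
    MatchedPair,
)
from reformulate.records import FoodDatabase, ProductRecord


def _rec(code, year, retailer="R1", container=500.0, category="A", price=3.0,
         serving=50.0, sodium=150.0, **kw):
    nutrients = {
        "energy_kcal": 100.0, "fat_g": 5.0, "satfat_g": 1.0, "carb_g": 10.0,
        "sugars_g": 2.0, "fibre_g": 1.0, "protein_g": 3.0,
        "sodium_mg": sodium, "calcium_mg": 50.0,
    }
    nutrients.update(kw.pop("nutrients", {}))
    return ProductRecord(
        product_code=code, retailer_id=retailer, tra_category=category,
        container_size=container, serving_size=serving, serving_unit="g",
        price=price, nutrients=nutrients, fvnl_percent=0.0, year_label=year, **kw,
    )


class TestPerHundred:
    def test_price_basis_container(self):
        assert per_hundred(3.00, 300.0) == pytest.approx(1.00)

    def test_sodium_basis_serving(self):
        assert per_hundred(240.0, 30.0) == pytest.approx(800.0)

    def test_zero_basis_is_error(self):
        with pytest.raises(MatchingError):
            per_hundred(1.0, 0.0)

    def test_missing_amount_propagates(self):
        assert per_hundred(None, 100.0) is None

    @given(
        amount=st.floats(0, 1e4, allow_nan=False),
        size=st.floats(0.01, 1e4, allow_nan=False),
        k=st.floats(0.01, 1e3, allow_nan=False),
    )
    def test_scale_invariance(self, amount, size, k):
        assert per_hundred(k * amount, k * size) == pytest.approx(
            per_hundred(amount, size), rel=1e-9, abs=1e-9
        )


class TestMatchProducts:
    def test_self_match_copy_all_deltas_zero(self):
        recs = [_rec(f"P{i}", "2017") for i in range(10)]
        db1 = FoodDatabase(recs, "2017")
        db2 = FoodDatabase(
            [dataclasses.replace(r, year_label="2020") for r in recs], "2020"
        )
        pairs, log = match_products(db1, db2)
        assert len(pairs) == 10
        for p in pairs:
            assert p.delta_price == 0.0
            assert all(v == 0.0 for v in p.delta_nutrients.values())

    def test_shrinkflation_breaks_the_size_key(self):
        db1 = FoodDatabase([_rec("061234500012", "2017", container=500.0)], "2017")
        db2 = FoodDatabase([_rec("061234500012", "2020", container=450.0)], "2020")
        pairs, log = match_products(db1, db2)
        assert pairs == []
        flow = {e.stage: e for e in log.entries}
        assert flow["unmatched_y1"].n_removed == 1
        assert flow["unmatched_y2"].n_removed == 1

    def test_hand_enumerated_fixture(self):
        # 5 shared keys, 2 only-y1, 3 only-y2, 1 shared key duplicated in y2
        shared = [f"S{i}" for i in range(5)]
        y1 = [_rec(c, "2017") for c in shared] + [_rec("A1", "2017"), _rec("A2", "2017")]
        y2 = [_rec(c, "2020") for c in shared] + [
            _rec("B1", "2020"), _rec("B2", "2020"), _rec("B3", "2020"),
            _rec("S0", "2020", price=9.9),  # duplicate key for S0
        ]
        pairs, log = match_products(FoodDatabase(y1, "2017"), FoodDatabase(y2, "2020"))
        assert len(pairs) == 4
        assert {p.key[0] for p in pairs} == {"S1", "S2", "S3", "S4"}
        flow = {e.stage: e for e in log.entries}
        assert flow["ambiguous_keys"].n_removed == 1

    def test_identical_year_labels_refused(self):
        db = FoodDatabase([_rec("P1", "2017")], "2017")
        with pytest.raises(MatchingError, match="self-match"):
            match_products(db, db)

    def test_row_order_does_not_change_content(self):
        recs1 = [_rec(f"P{i}", "2017", sodium=100.0 + i) for i in range(20)]
        recs2 = [_rec(f"P{i}", "2020", sodium=90.0 + i) for i in range(20)]
        pairs_a, _ = match_products(FoodDatabase(recs1, "2017"), FoodDatabase(recs2, "2020"))
        rng = random.Random(0)
        shuffled1, shuffled2 = recs1[:], recs2[:]
        rng.shuffle(shuffled1)
        rng.shuffle(shuffled2)
        pairs_b, _ = match_products(FoodDatabase(shuffled1, "2017"), FoodDatabase(shuffled2, "2020"))
        assert [p.key for p in pairs_a] == [p.key for p in pairs_b]
        assert [p.delta_nutrients["sodium_mg"] for p in pairs_a] == [
            p.delta_nutrients["sodium_mg"] for p in pairs_b
        ]


class TestComputeDeltas:
    def test_sodium_decrease(self):
        pair = MatchedPair(
            key=("P", "R1", 500.0, "g"),
            record_y1=_rec("P", "2017", sodium=400.0),   # 800 per 100
            record_y2=_rec("P", "2020", sodium=340.0),   # 680 per 100
        )
        compute_deltas(pair)
        assert pair.delta_nutrients["sodium_mg"] == pytest.approx(-120.0)

    def test_price_increase(self):
        pair = MatchedPair(
            key=("P", "R1", 500.0, "g"),
            record_y1=_rec("P", "2017", price=5.00),
            record_y2=_rec("P", "2020", price=7.60),
        )
        compute_deltas(pair)
        assert pair.price_per100_y1 == pytest.approx(1.00)
        assert pair.delta_price == pytest.approx(0.52)

    def test_missing_inputs_propagate(self):
        pair = MatchedPair(
            key=("P", "R1", 500.0, "g"),
            record_y1=_rec("P", "2017", price=None),
            record_y2=_rec("P", "2020"),
        )
        compute_deltas(pair)
        assert pair.delta_price is None


def _pair(code, category="A", price_y2=3.0, missing_y2=(), **kw):
    r1 = _rec(code, "2017", category=category, **kw)
    r2 = _rec(code, "2020", category=category, price=price_y2, **kw)
    for name in missing_y2:
        if name == "price":
            r2.price = None
        else:
            r2.nutrients[name] = None
    return compute_deltas(MatchedPair(key=r1.key(), record_y1=r1, record_y2=r2))


class TestExclusionCascade:
    def test_category_wx_removed(self):
        pairs = [_pair("P1", category="W"), _pair("P2", category="A")]
        kept, entry = apply_exclusions(pairs, "category_WX")
        assert [p.key[0] for p in kept] == ["P2"]
        assert entry.n_removed == 1

    def test_missing_price_survives_wx_then_dies_at_price_stage(self):
        pair = _pair("P1", category="A", missing_y2=("price",))
        kept, _ = apply_exclusions([pair], "category_WX")
        assert kept == [pair]
        kept, entry = apply_exclusions(kept, "invalid_price")
        assert kept == []
        assert entry.n_removed == 1

    def test_hand_counted_cascade_10_8_7_4(self):
        pairs = (
            [_pair(f"W{i}", category="W" if i == 0 else "X") for i in range(2)]
            + [_pair("NP", missing_y2=("price",))]
            + [_pair(f"NS{i}", missing_y2=("sodium_mg",)) for i in range(3)]
            + [_pair(f"OK{i}") for i in range(4)]
        )
        assert len(pairs) == 10
        step1, e1 = apply_exclusions(pairs, "category_WX")
        step2, e2 = apply_exclusions(step1, "invalid_price")
        step3, e3 = apply_exclusions(step2, "incomplete_nutrition")
        assert (len(step1), len(step2), len(step3)) == (8, 7, 4)
        assert (e1.n_out, e2.n_out, e3.n_out) == (8, 7, 4)

    def test_fsanz_stage_requires_fibre_fvnl_and_cheese_calcium(self):
        ok = _pair("OK")
        no_fibre = _pair("NF", missing_y2=("fibre_g",))
        cheese_no_ca = _pair("CH", category="D", missing_y2=("calcium_mg",))
        other_no_ca = _pair("OC", category="A", missing_y2=("calcium_mg",))
        no_fvnl = _pair("NV")
        no_fvnl.record_y2.fvnl_percent = None
        kept, entry = apply_exclusions(
            [ok, no_fibre, cheese_no_ca, other_no_ca, no_fvnl], "fsanz_ineligible"
        )
        assert {p.key[0] for p in kept} == {"OK", "OC"}
        assert entry.n_removed == 3

    def test_stage_idempotent(self):
        pairs = [_pair("P1", category="W"), _pair("P2"), _pair("P3", missing_y2=("price",))]
        once, e1 = apply_exclusions(pairs, "category_WX")
        twice, e2 = apply_exclusions(once, "category_WX")
        assert once == twice
        assert e2.n_removed == 0

    def test_unknown_stage_is_error(self):
        with pytest.raises(MatchingError):
            apply_exclusions([], "bogus_stage")


def test_exclusion_log_reconciles_at_every_stage(small_supply):
    db1, db2, _ = small_supply
    pairs, log = match_products(db1, db2)
    for entry in log.entries:
        assert entry.n_in - entry.n_removed == entry.n_out
    for stage in ("category_WX", "invalid_price", "incomplete_nutrition", "fsanz_ineligible"):
        n_before = len(pairs)
        pairs, entry = apply_exclusions(pairs, stage)
        assert entry.n_in == n_before
        assert entry.n_out == len(pairs) <= n_before
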