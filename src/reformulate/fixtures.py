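"""Checked-in style example databases with hand-verified expected outputs.

:func:`make_fixtures` writes a deterministic 60-product two-year fixture
pair that exercises every exclusion branch (categories W/X, missing
price, incomplete nutrition, nutrient-profiling ineligibility, ambiguous
duplicate keys, shrinkflation, one-year-only products), every one of the
five reformulation groups for sodium (including the exact -15 % and +5 %
band edges against the 2300 mg sodium DV), and all three NPSC
categories.  The companion ``expected.json`` freezes hand-computed
outputs; ``EXPECTED`` is the same object in code.
"""

from __future__ import annotations

import json
from pathlib import Path

from .io import write_food_db
from .records import FoodDatabase, ProductRecord

#: Per-100 g profile shared by ordinary fixture products.  NPSC walk:
#: energy 200 kcal = 836.8 kJ -> 2 pts; satfat 2 -> 1; sugars 4 -> 0;
#: sodium 300 -> 3; baseline 6; fibre 2 -> F 2; protein 6 -> P 3;
#: score 1; category 2 pass.
BULK_PER100 = {
    "energy_kcal": 200.0,
    "fat_g": 5.0,
    "satfat_g": 2.0,
    "carb_g": 30.0,
    "sugars_g": 4.0,
    "fibre_g": 2.0,
    "protein_g": 6.0,
    "sodium_mg": 300.0,
    "calcium_mg": 100.0,
}

_BULK_CATEGORIES = "ACEFGIJKLMNOPQRSTUV"
_BRAND_CYCLE = (
    "multinational",
    "domestic_or_other",
    "private_label_premium",
    "private_label_discount",
)

#: Hand-verified expected outputs for the fixture run (sodium DV 2300 mg,
#: packaged NPSC tables).  Derivations are in the docstrings/comments of
#: this module; each number was worked out by hand once and frozen.
EXPECTED = {
    "flow": {
        "n_y1": 60,
        "n_y2": 61,
        "n_matched": 53,
        "n_ambiguous": 1,
        "category_WX": 50,
        "invalid_price": 48,
        "incomplete_nutrition": 45,
        "fsanz_ineligible": 42,
    },
    # 45 classified pairs: P13/P18 large dec, P14/P26 medium dec,
    # P16/P19 medium inc, P17 large inc, the rest unchanged.
    "sodium_groups": {
        "large_decrease": 2,
        "medium_decrease": 2,
        "little_change": 38,
        "medium_increase": 2,
        "large_increase": 1,
    },
    # brand_type -> [reformulated, little_change] over the 45 pairs
    "contingency_sodium": {
        "private_label_premium": [2, 7],
        "private_label_discount": [1, 8],
        "multinational": [3, 15],
        "domestic_or_other": [1, 8],
    },
    # year-1 NPSC scores, hand-computed from the packaged tables
    "fsanz_scores_y1": {"P13": 6, "P14": 3, "P20": 2, "P21": 0, "P22": 21, "P23": 21, "P24": 27},
    "fsanz_categories": {"P20": "cat1", "P21": "cat1", "P22": "cat3", "P23": "cat2", "P24": "cat3"},
    "npsc_pass_y1_total": 38,
    "npsc_pass_y2_total": 39,
    "score_changes": {
        "P13": -4,
        "P14": -2,
        "P16": 2,
        "P17": 4,
        "P18": -3,
        "P19": 1,
        "P25": -1,
        "P26": -1,
    },
}


def _record(
    code,
    year,
    category="A",
    brand_type="multinational",
    per100=None,
    fvnl=0.0,
    price_per100=1.5,
    container=400.0,
    serving=50.0,
    retailer="R1",
    missing=(),
):
    unit = "ml" if category == "B" else "g"
    profile = {**BULK_PER100, **(per100 or {})}
    nutrients = {
        key: (None if key in missing else value * serving / 100.0)
        for key, value in profile.items()
    }
    return ProductRecord(
        product_code=code,
        retailer_id=retailer,
        brand=f"Brand-{code}",
        brand_type=brand_type,
        tra_category=category,
        container_size=container,
        container_unit=unit,
        serving_size=serving,
        serving_unit=unit,
        price=None if "price" in missing else round(price_per100 * container / 100.0, 4),
        nutrients=nutrients,
        fvnl_percent=None if "fvnl" in missing else fvnl,
        year_label=year,
    )


def build_fixture_databases():
    """Return (year-1 db, year-2 db) of the 60-product fixture."""
    y1, y2 = [], []

    def pair(code, y1_kwargs=None, y2_kwargs=None, **common):
        y1.append(_record(code, "2017", **{**common, **(y1_kwargs or {})}))
        y2.append(_record(code, "2020", **{**common, **(y2_kwargs or {})}))

    # excluded categories (matched, otherwise complete)
    pair("P01", category="W")
    pair("P02", category="W")
    pair("P03", category="X")
    # invalid price
    pair("P04", y2_kwargs={"missing": ("price",)})
    pair("P05", y1_kwargs={"missing": ("price",)})
    # ordinary survivor
    pair("P06")
    # incomplete core nutrition
    pair("P07", y2_kwargs={"missing": ("sodium_mg",)})
    pair("P08", y1_kwargs={"missing": ("protein_g",)})
    pair("P09", y2_kwargs={"missing": ("energy_kcal",)})
    # NPSC-ineligible (classified, but unscoreable)
    pair("P10", y1_kwargs={"missing": ("fibre_g",)})
    pair("P11", y2_kwargs={"missing": ("fvnl",)})
    pair(
        "P12",
        category="D",
        per100={"calcium_mg": 400.0},
        y2_kwargs={"per100": {"calcium_mg": 400.0}, "missing": ("calcium_mg",)},
    )
    # sodium reformulation groups (DV 2300 mg per 100 g)
    pair(  # -400 -> -17.39 % DV: large decrease
        "P13",
        brand_type="private_label_premium",
        y1_kwargs={"per100": {"sodium_mg": 800.0}},
        y2_kwargs={"per100": {"sodium_mg": 400.0}},
    )
    pair(  # -200 -> -8.70 %: medium decrease
        "P14",
        y1_kwargs={"per100": {"sodium_mg": 500.0}},
        y2_kwargs={"per100": {"sodium_mg": 300.0}},
    )
    pair("P15")  # little change
    pair(  # +200 -> +8.70 %: medium increase
        "P16",
        brand_type="domestic_or_other",
        y1_kwargs={"per100": {"sodium_mg": 300.0}},
        y2_kwargs={"per100": {"sodium_mg": 500.0}},
    )
    pair(  # +400 -> +17.39 %: large increase
        "P17",
        brand_type="private_label_discount",
        y1_kwargs={"per100": {"sodium_mg": 300.0}},
        y2_kwargs={"per100": {"sodium_mg": 700.0}},
    )
    pair(  # -345 -> exactly -15.0 %: large decrease (band edge)
        "P18",
        brand_type="private_label_premium",
        y1_kwargs={"per100": {"sodium_mg": 800.0}},
        y2_kwargs={"per100": {"sodium_mg": 455.0}},
    )
    pair(  # +115 -> exactly +5.0 %: medium increase (band edge)
        "P19",
        y1_kwargs={"per100": {"sodium_mg": 300.0}},
        y2_kwargs={"per100": {"sodium_mg": 415.0}},
    )
    # NPSC categories: beverages, cheese, margarine
    pair(
        "P20",
        category="B",
        per100={
            "energy_kcal": 44.0,
            "fat_g": 0.0,
            "satfat_g": 0.0,
            "carb_g": 11.0,
            "sugars_g": 10.0,
            "fibre_g": 0.0,
            "protein_g": 0.5,
            "sodium_mg": 10.0,
            "calcium_mg": 0.0,
        },
    )
    pair(
        "P21",
        category="B",
        per100={k: 0.0 for k in BULK_PER100},
    )
    pair(  # cheese, calcium 700 > 320 -> category 3
        "P22",
        category="D",
        brand_type="private_label_discount",
        per100={
            "energy_kcal": 400.0,
            "fat_g": 33.0,
            "satfat_g": 20.0,
            "carb_g": 2.0,
            "sugars_g": 1.0,
            "fibre_g": 0.0,
            "protein_g": 25.0,
            "sodium_mg": 600.0,
            "calcium_mg": 700.0,
        },
    )
    pair(  # calcium exactly 320 -> stays category 2
        "P23",
        category="D",
        brand_type="private_label_discount",
        per100={
            "energy_kcal": 350.0,
            "fat_g": 30.0,
            "satfat_g": 18.0,
            "carb_g": 2.0,
            "sugars_g": 1.0,
            "fibre_g": 0.0,
            "protein_g": 24.0,
            "sodium_mg": 700.0,
            "calcium_mg": 320.0,
        },
    )
    pair(  # margarine -> category 3, score 27 sits just under the <28 bound
        "P24",
        category="H",
        per100={
            "energy_kcal": 700.0,
            "fat_g": 80.0,
            "satfat_g": 15.0,
            "carb_g": 0.5,
            "sugars_g": 0.0,
            "fibre_g": 0.0,
            "protein_g": 0.5,
            "sodium_mg": 600.0,
            "calcium_mg": 0.0,
        },
    )
    pair(  # -114 -> -4.957 %: still little change (just inside the band)
        "P25",
        brand_type="domestic_or_other",
        y1_kwargs={"per100": {"sodium_mg": 414.0}},
        y2_kwargs={"per100": {"sodium_mg": 300.0}},
    )
    pair(  # -116 -> -5.043 %: medium decrease (just outside)
        "P26",
        y1_kwargs={"per100": {"sodium_mg": 416.0}},
        y2_kwargs={"per100": {"sodium_mg": 300.0}},
    )
    # bulk survivors P27..P53
    for i in range(27, 54):
        pair(
            f"P{i:02d}",
            category=_BULK_CATEGORIES[(i - 27) % len(_BULK_CATEGORIES)],
            brand_type=_BRAND_CYCLE[(i - 27) % 4],
        )
    # ambiguous duplicate key in year 2
    y1.append(_record("P54", "2017"))
    y2.append(_record("P54", "2020"))
    y2.append(_record("P54", "2020", price_per100=1.6))
    # year-1-only products
    for i in (55, 56, 57):
        y1.append(_record(f"P{i}", "2017"))
    # shrinkflation: container shrinks, match key breaks
    for i in (58, 59, 60):
        y1.append(_record(f"P{i}", "2017", container=400.0))
        y2.append(_record(f"P{i}", "2020", container=360.0))
    # year-2-only products
    for i in (61, 62, 63):
        y2.append(_record(f"P{i}", "2020"))

    db1 = FoodDatabase(records=y1, year_label="2017", provenance="fixture")
    db2 = FoodDatabase(records=y2, year_label="2020", provenance="fixture")
    return db1, db2


def make_fixtures(out_dir):
    """Write fixture_y1.csv, fixture_y2.csv and expected.json to out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    db1, db2 = build_fixture_databases()
    write_food_db(db1, out_dir / "fixture_y1.csv")
    write_food_db(db2, out_dir / "fixture_y2.csv")
    (out_dir / "expected.json").write_text(json.dumps(EXPECTED, indent=2, sort_keys=True))
    return out_dir
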