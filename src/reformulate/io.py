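"""Read, write and validate CSV food-label databases.

Dialect: comma-separated, UTF-8, one header row, empty string means
missing.  The column dictionary ships with the package in
``data/column_dictionary.md``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from .records import (
    BRAND_TYPES,
    FoodDatabase,
    NUTRIENT_KEYS,
    ProductRecord,
    TRA_CATEGORIES,
)

#: Columns that must be present in any input file.
MANDATORY_COLUMNS = ("product_code", "retailer_id", "tra_category", "container_size")

#: Full column order used when writing.
ALL_COLUMNS = (
    "product_code",
    "retailer_id",
    "brand",
    "brand_type",
    "tra_category",
    "container_size",
    "container_unit",
    "serving_size",
    "serving_unit",
    "price",
    *NUTRIENT_KEYS,
    "fvnl_percent",
)

NUMERIC_COLUMNS = ("container_size", "serving_size", "price", *NUTRIENT_KEYS, "fvnl_percent")


class FoodDBError(ValueError):
    """Hard error while reading or writing a food database."""


def _parse_float(cell: str):
    """Return (value, ok). Empty string is missing-but-ok."""
    cell = cell.strip()
    if cell == "":
        return None, True
    try:
        return float(cell), True
    except ValueError:
        return None, False


def read_food_db(path, year_label: str) -> FoodDatabase:
    """Read a CSV food database.

    Unparseable numeric cells become missing values and are counted per
    column in ``db.parse_report``.  Row order is preserved.

    Raises
    ------
    FoodDBError
        If the file is empty or a mandatory column is absent.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FoodDBError(f"empty food database file: {path}") from None
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise FoodDBError(
            f"missing mandatory column(s) {', '.join(missing)} in {path}"
        )

    parse_report: dict = {}
    records = []
    for _, row in frame.iterrows():
        rec_kwargs = {
            "product_code": str(row.get("product_code", "")).strip(),
            "retailer_id": str(row.get("retailer_id", "")).strip(),
            "brand": str(row.get("brand", "")).strip(),
            "year_label": year_label,
        }
        bt = str(row.get("brand_type", "")).strip()
        rec_kwargs["brand_type"] = bt if bt else None
        tra = str(row.get("tra_category", "")).strip().upper()
        rec_kwargs["tra_category"] = tra if tra else None
        cu = str(row.get("container_unit", "")).strip().lower()
        rec_kwargs["container_unit"] = cu if cu else "g"
        su = str(row.get("serving_unit", "")).strip().lower()
        rec_kwargs["serving_unit"] = su if su else None

        nutrients = {}
        for col in NUMERIC_COLUMNS:
            if col not in frame.columns:
                continue
            value, ok = _parse_float(str(row[col]))
            if not ok:
                parse_report[col] = parse_report.get(col, 0) + 1
            if col in NUTRIENT_KEYS:
                nutrients[col] = value
            else:
                rec_kwargs[col] = value
        rec_kwargs["nutrients"] = nutrients
        records.append(ProductRecord(**rec_kwargs))

    return FoodDatabase(
        records=records,
        year_label=year_label,
        provenance=f"read from {path}",
        parse_report=parse_report,
    )


def _format_number(x) -> str:
    if x is None:
        return ""
    return repr(float(x))


def write_food_db(db: FoodDatabase, path) -> None:
    """Write a database as CSV; read_food_db round-trips all fields.

    Missing values are written as empty strings; numbers use full repr
    precision (>= 10 significant digits).
    """
    rows = []
    for rec in db.records:
        row = {
            "product_code": rec.product_code,
            "retailer_id": rec.retailer_id,
            "brand": rec.brand,
            "brand_type": rec.brand_type or "",
            "tra_category": rec.tra_category or "",
            "container_size": _format_number(rec.container_size),
            "container_unit": rec.container_unit,
            "serving_size": _format_number(rec.serving_size),
            "serving_unit": rec.serving_unit or "",
            "price": _format_number(rec.price),
            "fvnl_percent": _format_number(rec.fvnl_percent),
        }
        for key in NUTRIENT_KEYS:
            row[key] = _format_number(rec.nutrients.get(key))
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(ALL_COLUMNS))
    try:
        frame.to_csv(path, index=False)
    except OSError as exc:
        raise FoodDBError(f"cannot write food database to {path}: {exc}") from exc


@dataclass
class ValidationReport:
    """Per-rule lists of offending record keys.  Reporting only."""

    duplicate_keys: list = field(default_factory=list)
    nonpositive_sizes: list = field(default_factory=list)
    satfat_exceeds_fat: list = field(default_factory=list)
    sugars_exceed_carb: list = field(default_factory=list)
    fvnl_out_of_range: list = field(default_factory=list)
    invalid_brand_type: list = field(default_factory=list)
    invalid_category: list = field(default_factory=list)

    RULES = (
        "duplicate_keys",
        "nonpositive_sizes",
        "satfat_exceeds_fat",
        "sugars_exceed_carb",
        "fvnl_out_of_range",
        "invalid_brand_type",
        "invalid_category",
    )

    def is_clean(self) -> bool:
        return all(not getattr(self, rule) for rule in self.RULES)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": rule, "record_key": "|".join(str(p) for p in key)}
            for rule in self.RULES
            for key in getattr(self, rule)
        ]
        return pd.DataFrame(rows, columns=["rule", "record_key"])

    def to_text(self) -> str:
        lines = []
        for rule in self.RULES:
            keys = getattr(self, rule)
            lines.append(f"{rule}: {len(keys)}")
            for key in keys:
                lines.append(f"  {key}")
        return "\n".join(lines)


def validate_db(db: FoodDatabase) -> ValidationReport:
    """Check label-consistency rules without mutating the database."""
    report = ValidationReport()
    seen: dict = {}
    for rec in db.records:
        key = rec.key()
        seen.setdefault(key, []).append(rec)
    for key, recs in seen.items():
        if len(recs) > 1:
            report.duplicate_keys.append(key)

    for rec in db.records:
        key = rec.key()
        if (rec.container_size is not None and rec.container_size <= 0) or (
            rec.serving_size is not None and rec.serving_size <= 0
        ):
            report.nonpositive_sizes.append(key)
        fat = rec.nutrients.get("fat_g")
        satfat = rec.nutrients.get("satfat_g")
        if fat is not None and satfat is not None and satfat > fat:
            report.satfat_exceeds_fat.append(key)
        carb = rec.nutrients.get("carb_g")
        sugars = rec.nutrients.get("sugars_g")
        if carb is not None and sugars is not None and sugars > carb:
            report.sugars_exceed_carb.append(key)
        if rec.fvnl_percent is not None and not (0.0 <= rec.fvnl_percent <= 100.0):
            report.fvnl_out_of_range.append(key)
        if rec.brand_type is not None and rec.brand_type not in BRAND_TYPES:
            report.invalid_brand_type.append(key)
        if rec.tra_category is not None and rec.tra_category not in TRA_CATEGORIES:
            report.invalid_category.append(key)
    return report
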