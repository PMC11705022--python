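"""Core domain types: single-time-point product records and whole databases.

A :class:`ProductRecord` is one packaged food or beverage observed at one
time point, carrying identity (product code + retailer), classification
(TRA letter category, brand type), pack geometry (container and serving
size), shelf price, per-serving nutrient amounts and the
fruit/vegetable/nut/legume percentage used by the nutrient-profiling
scorer.  A :class:`FoodDatabase` is an ordered collection of records that
share a year label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: The four recognised brand types.
BRAND_TYPES = (
    "private_label_premium",
    "private_label_discount",
    "multinational",
    "domestic_or_other",
)

#: TRA major food-category letters.  A-V are analysed; W (food for
#: children under 4) and X (meal replacements/substitutes) are excluded
#: by the matching cascade but are valid input categories.
TRA_CATEGORIES = tuple("ABCDEFGHIJKLMNOPQRSTUVWX")
ANALYSED_CATEGORIES = tuple("ABCDEFGHIJKLMNOPQRSTUV")

#: All nutrient columns carried per serving.
NUTRIENT_KEYS = (
    "energy_kcal",
    "fat_g",
    "satfat_g",
    "carb_g",
    "sugars_g",
    "fibre_g",
    "protein_g",
    "sodium_mg",
    "calcium_mg",
)

#: The seven core Nutrition Facts nutrients that define "complete
#: nutrition" for the reformulation analysis.
CORE_NUTRIENTS = (
    "energy_kcal",
    "fat_g",
    "satfat_g",
    "carb_g",
    "sugars_g",
    "protein_g",
    "sodium_mg",
)

#: Nutrients run through the five-group reformulation classifier.
CLASSIFIED_NUTRIENTS = CORE_NUTRIENTS

VALID_UNITS = ("g", "ml")


@dataclass
class ProductRecord:
    """One labelled product at one time point.

    Numeric fields other than ``container_size`` may be ``None``
    (missing); validation of label-consistency rules (e.g. saturated fat
    not exceeding total fat) is performed by
    :func:`reformulate.io.validate_db`, never at construction, so that
    file round-trips are lossless.
    """

    product_code: str
    retailer_id: str
    brand: str = ""
    brand_type: Optional[str] = None
    tra_category: Optional[str] = None
    container_size: Optional[float] = None
    container_unit: str = "g"
    serving_size: Optional[float] = None
    serving_unit: Optional[str] = None
    price: Optional[float] = None
    nutrients: dict = field(default_factory=dict)
    fvnl_percent: Optional[float] = None
    year_label: str = ""

    def key(self) -> tuple:
        """Cross-year match key: code, retailer, container size and unit."""
        return (
            self.product_code,
            self.retailer_id,
            self.container_size,
            self.container_unit,
        )

    def nutrient(self, name: str) -> Optional[float]:
        return self.nutrients.get(name)

    def per100(self, name: str) -> Optional[float]:
        """Nutrient amount per 100 g (or ml), using the serving size as basis."""
        amount = self.nutrients.get(name)
        if amount is None or self.serving_size is None or self.serving_size <= 0:
            return None
        return amount * 100.0 / self.serving_size

    def price_per100(self) -> Optional[float]:
        """Price per 100 g (or ml), using the container size as basis."""
        if self.price is None or self.container_size is None or self.container_size <= 0:
            return None
        return self.price * 100.0 / self.container_size


@dataclass
class FoodDatabase:
    """Ordered collection of :class:`ProductRecord` sharing a year label."""

    records: list
    year_label: str
    provenance: str = ""
    parse_report: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]
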