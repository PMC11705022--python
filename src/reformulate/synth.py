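"""Synthetic two-year food-supply generator with known ground truth.

Emulates the structure of a branded label-and-price database pair:
several retailers, the 22 analysed TRA categories, four brand types,
partial cross-year overlap, missing price/nutrition cells, shrinkflation
and configurable reformulation events.  Nutrient and price baselines are
lognormal (positive, right-skewed, as label data are).  Reformulation
magnitudes are drawn as a percentage of the Daily Value and mapped back
to absolute per-100 deltas, so the truth group of every event follows by
construction under the default classifier.  Year-2 price is
multiplicative inflation on year-1 price plus an additive injected
effect for products in a targeted (category, nutrient, group) cell plus
noise — which makes the inflation-cancellation property of the exposure
models exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .classifier import DVTable, ReformulationGroup, classify, load_dv_table
from .records import (
    ANALYSED_CATEGORIES,
    BRAND_TYPES,
    CLASSIFIED_NUTRIENTS,
    FoodDatabase,
    ProductRecord,
)


class ConfigError(ValueError):
    pass


def _uniform_weights(keys):
    return {k: 1.0 / len(keys) for k in keys}


#: Default per-100 g arithmetic (mean, sd) of the lognormal nutrient
#: baselines, loosely shaped like packaged-food label data.
DEFAULT_NUTRIENT_BASELINES = {
    "energy_kcal": (250.0, 150.0),
    "fat_g": (10.0, 8.0),
    "satfat_g": (3.0, 2.5),
    "carb_g": (30.0, 20.0),
    "sugars_g": (8.0, 7.0),
    "fibre_g": (3.0, 2.0),
    "protein_g": (8.0, 6.0),
    "sodium_mg": (400.0, 350.0),
    "calcium_mg": (120.0, 130.0),
}

#: Default event prevalence per classified nutrient; sodium is the most
#: frequently changed nutrient, around one matched product in six.
DEFAULT_PREVALENCE = {
    "energy_kcal": 0.10,
    "fat_g": 0.10,
    "satfat_g": 0.10,
    "carb_g": 0.12,
    "sugars_g": 0.11,
    "protein_g": 0.09,
    "sodium_mg": 0.18,
}

_CONTAINER_CHOICES = (100.0, 200.0, 250.0, 300.0, 400.0, 500.0, 750.0, 1000.0)


@dataclass
class SupplyConfig:
    """Knobs for one paired-database generation run."""

    n_products: int = 1000
    n_retailers: int = 3
    category_weights: dict = field(default_factory=lambda: _uniform_weights(ANALYSED_CATEGORIES))
    brand_type_weights: dict = field(
        default_factory=lambda: {
            "private_label_premium": 0.10,
            "private_label_discount": 0.15,
            "multinational": 0.45,
            "domestic_or_other": 0.30,
        }
    )
    nutrient_baselines: dict = field(default_factory=lambda: dict(DEFAULT_NUTRIENT_BASELINES))
    price_baseline: tuple = (1.5, 1.2)  # per-100 mean, sd
    reformulation_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    reformulation_direction_up: dict = field(default_factory=dict)  # default 0.5
    reformulation_magnitude: dict = field(default_factory=dict)  # nutrient -> (mean, sd) %DV
    price_effect_beta: dict = field(default_factory=dict)  # (cat|'*', nutrient, group) -> $
    inflation_rate: float = 0.02
    retailer_price_offsets: dict = field(default_factory=dict)
    price_noise_sd: float = 0.05
    shrinkflation_prob: float = 0.0
    unmatched_frac: float = 0.2
    missing_price_frac: float = 0.0
    missing_nutrition_frac: float = 0.0
    seed: int = 0
    year1_label: str = "Y1"
    year2_label: str = "Y2"

    DEFAULT_MAGNITUDE = (15.0, 10.0)  # % of DV

    def validate(self) -> None:
        if self.n_products < 1:
            raise ConfigError("n_products must be >= 1")
        if self.n_retailers < 1:
            raise ConfigError("n_retailers must be >= 1")
        for name in (
            "inflation_rate",
            "price_noise_sd",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        for name in ("shrinkflation_prob", "unmatched_frac", "missing_price_frac", "missing_nutrition_frac"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        for label, weights in (("category_weights", self.category_weights), ("brand_type_weights", self.brand_type_weights)):
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{label} must sum to 1, got {total}")
            if any(w < 0 for w in weights.values()):
                raise ConfigError(f"{label} must be non-negative")
        for nutrient, prob in self.reformulation_prevalence.items():
            if not 0.0 <= prob <= 1.0:
                raise ConfigError(f"prevalence for {nutrient} must lie in [0, 1]")

    def to_dict(self) -> dict:
        raw = asdict(self)
        raw["price_effect_beta"] = {
            "|".join(str(p) for p in key): value for key, value in self.price_effect_beta.items()
        }
        return raw

    @classmethod
    def from_dict(cls, raw: dict) -> "SupplyConfig":
        raw = dict(raw)
        beta = {}
        for key, value in (raw.pop("price_effect_beta", None) or {}).items():
            parts = key.split("|") if isinstance(key, str) else list(key)
            if len(parts) != 3:
                raise ConfigError(f"price_effect_beta key must be category|nutrient|group: {key!r}")
            beta[(parts[0], parts[1], parts[2])] = float(value)
        cfg = cls(**raw)
        cfg.price_effect_beta = beta
        return cfg


@dataclass
class SupplyTruth:
    """Ground truth for the matched portion of a generated supply."""

    groups: pd.DataFrame  # product_code, retailer_id, nutrient, group, realized_pct
    price_effects: pd.DataFrame  # product_code, retailer_id, injected_effect
    inflation_rate: float
    n_matched: int
    n_only_year1: int
    n_only_year2: int
    n_shrinkflation: int


def _lognormal(rng, mean, sd, size=None):
    """Lognormal draws with the requested arithmetic mean and sd."""
    if mean <= 0:
        raise ConfigError(f"lognormal mean must be positive, got {mean}")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _weighted_choice(rng, weights: dict):
    keys = sorted(weights)
    probs = np.array([weights[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def generate_supply(config: SupplyConfig, dv: Optional[DVTable] = None):
    """Generate (year-1 database, year-2 database, SupplyTruth).

    Deterministic given ``config.seed``.  Matched year-2 records share
    the match key with year-1 unless a shrinkflation event shrank the
    container; nutrient deltas equal the truth deltas exactly; year-2
    price per 100 is ``y1 * (1 + inflation) + injected effect + noise``.
    """
    config.validate()
    if dv is None:
        dv = load_dv_table()
    rng = np.random.default_rng(config.seed)

    retailers = [f"R{i + 1}" for i in range(config.n_retailers)]
    offsets = dict(config.retailer_price_offsets)
    for i, retailer in enumerate(retailers):
        offsets.setdefault(retailer, 0.05 * ((i % 3) - 1))

    y1_records, y2_records = [], []
    truth_rows, effect_rows = [], []
    n_matched = n_only1 = n_only2 = n_shrink = 0

    for i in range(config.n_products):
        code = f"{i:012d}"
        retailer = retailers[int(rng.integers(config.n_retailers))]
        category = _weighted_choice(rng, config.category_weights)
        brand_type = _weighted_choice(rng, config.brand_type_weights)
        unit = "ml" if category == "B" else "g"
        container = float(_CONTAINER_CHOICES[int(rng.integers(len(_CONTAINER_CHOICES)))])
        serving = float(min(container, np.round(rng.uniform(20, 200))))
        if serving <= 0:
            serving = 30.0

        per100 = {}
        for nutrient in DEFAULT_NUTRIENT_BASELINES:
            mean, sd = config.nutrient_baselines.get(
                (category, nutrient),
                config.nutrient_baselines.get(nutrient, DEFAULT_NUTRIENT_BASELINES[nutrient]),
            )
            per100[nutrient] = float(_lognormal(rng, mean, sd))
        # keep label-consistency: satfat <= fat, sugars <= carb
        per100["satfat_g"] = min(per100["satfat_g"], per100["fat_g"])
        per100["sugars_g"] = min(per100["sugars_g"], per100["carb_g"])
        fvnl = float(np.round(rng.beta(1.2, 4.0) * 100.0, 1))

        price_mean, price_sd = config.price_baseline
        price100 = float(_lognormal(rng, price_mean, price_sd)) + offsets[retailer]
        price100 = max(price100, 0.05)

        def build(year_label, container_size, per100_map, price_per100):
            nutrients = {k: v * serving / 100.0 for k, v in per100_map.items()}
            return ProductRecord(
                product_code=code,
                retailer_id=retailer,
                brand=f"Brand{i % 40:02d}",
                brand_type=brand_type,
                tra_category=category,
                container_size=container_size,
                container_unit=unit,
                serving_size=serving,
                serving_unit=unit,
                price=round(price_per100 * container_size / 100.0, 4),
                nutrients={k: round(v, 6) for k, v in nutrients.items()},
                fvnl_percent=fvnl,
                year_label=year_label,
            )

        # membership: matched, only-year-1 or only-year-2
        u = rng.random()
        if u < config.unmatched_frac:
            if rng.random() < 0.5:
                y1_records.append(build(config.year1_label, container, per100, price100))
                n_only1 += 1
            else:
                y2_records.append(
                    build(config.year2_label, container, per100, price100 * (1 + config.inflation_rate))
                )
                n_only2 += 1
            continue

        rec1 = build(config.year1_label, container, per100, price100)

        # reformulation events drawn as % of DV, mapped to absolute deltas
        per100_y2 = dict(per100)
        injected = 0.0
        for nutrient in CLASSIFIED_NUTRIENTS:
            prevalence = config.reformulation_prevalence.get(nutrient, 0.0)
            event = rng.random() < prevalence
            if event:
                up = rng.random() < config.reformulation_direction_up.get(nutrient, 0.5)
                mag_mean, mag_sd = config.reformulation_magnitude.get(
                    nutrient, SupplyConfig.DEFAULT_MAGNITUDE
                )
                pct = float(_lognormal(rng, mag_mean, mag_sd))
                delta = (pct if up else -pct) / 100.0 * dv[nutrient]
                per100_y2[nutrient] = max(0.0, per100[nutrient] + delta)
            realized = per100_y2[nutrient] - per100[nutrient]
            realized_pct = 100.0 * realized / dv[nutrient]
            group = classify(realized_pct)
            truth_rows.append(
                {
                    "product_code": code,
                    "retailer_id": retailer,
                    "tra_category": category,
                    "nutrient": nutrient,
                    "group": group.name,
                    "realized_pct": realized_pct,
                }
            )
            for cat_key in (category, "*"):
                injected += config.price_effect_beta.get((cat_key, nutrient, group.name), 0.0)

        noise = float(rng.normal(0.0, config.price_noise_sd)) if config.price_noise_sd > 0 else 0.0
        price100_y2 = price100 * (1.0 + config.inflation_rate) + injected + noise
        price100_y2 = max(price100_y2, 0.01)

        shrunk = rng.random() < config.shrinkflation_prob
        container2 = round(container * 0.9, 4) if shrunk else container
        rec2 = build(config.year2_label, container2, per100_y2, price100_y2)

        # missingness injections (year chosen at random)
        if config.missing_price_frac and rng.random() < config.missing_price_frac:
            (rec1 if rng.random() < 0.5 else rec2).price = None
        if config.missing_nutrition_frac and rng.random() < config.missing_nutrition_frac:
            target = rec1 if rng.random() < 0.5 else rec2
            victim = ["sodium_mg", "protein_g", "fibre_g", "energy_kcal", "calcium_mg"][
                int(rng.integers(5))
            ]
            target.nutrients[victim] = None

        y1_records.append(rec1)
        y2_records.append(rec2)
        effect_rows.append(
            {"product_code": code, "retailer_id": retailer, "injected_effect": injected}
        )
        if shrunk:
            n_shrink += 1
        else:
            n_matched += 1

    db1 = FoodDatabase(records=y1_records, year_label=config.year1_label, provenance="synthetic")
    db2 = FoodDatabase(records=y2_records, year_label=config.year2_label, provenance="synthetic")
    truth = SupplyTruth(
        groups=pd.DataFrame(
            truth_rows,
            columns=["product_code", "retailer_id", "tra_category", "nutrient", "group", "realized_pct"],
        ),
        price_effects=pd.DataFrame(
            effect_rows, columns=["product_code", "retailer_id", "injected_effect"]
        ),
        inflation_rate=config.inflation_rate,
        n_matched=n_matched,
        n_only_year1=n_only1,
        n_only_year2=n_only2,
        n_shrinkflation=n_shrink,
    )
    return db1, db2, truth


def truth_summary(truth: SupplyTruth) -> pd.DataFrame:
    """Group counts per nutrient over intended-matched products.

    Counts for each nutrient sum to the number of generated matched
    products (including those later broken by shrinkflation).
    """
    group_names = [g.name for g in ReformulationGroup]
    frame = truth.groups
    if frame.empty:
        return pd.DataFrame(0, index=pd.Index([], name="nutrient"), columns=group_names)
    table = (
        frame.groupby(["nutrient", "group"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=group_names, fill_value=0)
    )
    table.index.name = "nutrient"
    return table
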