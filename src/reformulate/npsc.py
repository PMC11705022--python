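"""Table-driven FSANZ Nutrient Profiling Scoring Criterion scorer.

Baseline points accrue from energy (kJ), saturated fat, total sugars and
sodium per 100 g (or ml); modifying points from fruit/vegetable/nut/
legume content (V), protein (P, subject to the baseline gate) and fibre
(F).  Final score = baseline - V - P - F; a lower score is healthier.
Health-claim eligibility: category 1 (beverages) passes below 1,
category 2 (other foods) below 4, category 3 (cheese, oils, spreads)
below 28.

Every threshold, cap, the protein gate and the pass bounds live in a
versioned YAML file (see ``data/npsc_tables.yml``); this module only
interprets it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import yaml

from .records import ProductRecord

CATEGORIES = ("cat1", "cat2", "cat3")

#: Default mapping of TRA letters to FSANZ categories: B (beverages) is
#: category 1; H (fats and oils) is category 3; Dairy (D) products are
#: category-3 *candidates*, promoted only when calcium exceeds the
#: cheese cut-off; everything else is category 2.
DEFAULT_BEVERAGE_CATEGORIES = frozenset({"B"})
DEFAULT_FATS_OILS_CATEGORIES = frozenset({"H"})
DEFAULT_CHEESE_CANDIDATE_CATEGORIES = frozenset({"D"})
CHEESE_CALCIUM_CUTOFF_MG = 320.0  # strictly greater than -> category 3


class NpscError(ValueError):
    pass


@dataclass(frozen=True)
class ComponentSteps:
    """Monotone step function: points of the highest threshold satisfied."""

    name: str
    steps: tuple  # of (threshold, points, inclusive)
    max_points: int

    def lookup(self, value: float) -> int:
        if value is None:
            raise NpscError(f"missing value for NPSC component {self.name}")
        if value < 0:
            raise NpscError(f"negative value {value!r} for NPSC component {self.name}")
        points = 0
        for threshold, pts, inclusive in self.steps:
            if value > threshold or (inclusive and value == threshold):
                points = pts
            else:
                break
        return min(points, self.max_points)


def _parse_steps(name: str, spec: dict, extra: Optional[dict] = None) -> ComponentSteps:
    raw = list(spec["steps"])
    max_points = int(spec["max_points"])
    if extra is not None:
        raw += list(extra["steps"])
        max_points = int(extra["max_points"])
    steps = []
    for step in raw:
        if "gt" in step:
            steps.append((float(step["gt"]), int(step["points"]), False))
        elif "ge" in step:
            steps.append((float(step["ge"]), int(step["points"]), True))
        else:
            raise NpscError(f"step in component {name} needs a gt or ge threshold")
    thresholds = [s[0] for s in steps]
    points = [s[1] for s in steps]
    if thresholds != sorted(thresholds) or len(set(thresholds)) != len(thresholds):
        raise NpscError(f"thresholds for {name} must be strictly increasing")
    if points != sorted(points) or len(set(points)) != len(points):
        raise NpscError(f"points for {name} must be strictly increasing")
    return ComponentSteps(name=name, steps=tuple(steps), max_points=max_points)


BASELINE_COMPONENTS = ("energy_kj", "satfat_g", "sugars_g", "sodium_mg")
MODIFYING_COMPONENTS = ("fvnl_pct", "protein_g", "fibre_g")


@dataclass(frozen=True)
class NpscTables:
    """Validated, immutable point tables for the three NPSC categories."""

    version: str
    kj_per_kcal: float
    pass_below: dict  # category -> int
    baseline: dict  # (category, component) -> ComponentSteps
    modifying: dict  # component -> ComponentSteps
    protein_gate_baseline: int
    protein_gate_v_waiver: int
    protein_gate_exempt: frozenset

    def component(self, category: str, name: str) -> ComponentSteps:
        return self.baseline[(category, name)]


def load_npsc_tables(path=None) -> NpscTables:
    """Load and validate NPSC point tables from YAML (default: packaged file)."""
    if path is None:
        text = resources.files("reformulate.data").joinpath("npsc_tables.yml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)

    baseline = {}
    for comp in BASELINE_COMPONENTS:
        spec = raw["baseline_components"][comp]
        base = _parse_steps(comp, spec)
        for cat in ("cat1", "cat2"):
            baseline[(cat, comp)] = base
        baseline[("cat3", comp)] = _parse_steps(comp, spec, spec.get("cat3_extension"))
    modifying = {
        comp: _parse_steps(comp, raw["modifying_components"][comp])
        for comp in MODIFYING_COMPONENTS
    }
    gate = raw["protein_gate"]
    return NpscTables(
        version=str(raw.get("version", "unversioned")),
        kj_per_kcal=float(raw["kj_per_kcal"]),
        pass_below={cat: int(raw["categories"][cat]["pass_below"]) for cat in CATEGORIES},
        baseline=baseline,
        modifying=modifying,
        protein_gate_baseline=int(gate["baseline_at_least"]),
        protein_gate_v_waiver=int(gate["v_points_waiver"]),
        protein_gate_exempt=frozenset(gate.get("exempt_categories", ())),
    )


@dataclass(frozen=True)
class FsanzResult:
    category: str
    baseline_points: int
    v_points: int
    p_points: int
    f_points: int
    score: int
    npsc_pass: bool


def lookup_points(value, steps: ComponentSteps) -> int:
    """Points of the highest step satisfied; 0 below the first threshold."""
    return steps.lookup(value)


def assign_category(
    record: ProductRecord,
    calcium_per100=None,
    beverage_categories=DEFAULT_BEVERAGE_CATEGORIES,
    fats_oils_categories=DEFAULT_FATS_OILS_CATEGORIES,
    cheese_candidate_categories=DEFAULT_CHEESE_CANDIDATE_CATEGORIES,
) -> str:
    """Map a product to its NPSC category (cat1/cat2/cat3).

    Cheese candidates need a per-100 calcium amount; it defaults to the
    record's own per-100 value.
    """
    tra = record.tra_category
    if tra is None:
        raise NpscError("record has no TRA category; cannot assign NPSC category")
    if tra in beverage_categories:
        return "cat1"
    if tra in fats_oils_categories:
        return "cat3"
    if tra in cheese_candidate_categories:
        if calcium_per100 is None:
            calcium_per100 = record.per100("calcium_mg")
        if calcium_per100 is None:
            raise NpscError(
                f"cheese candidate {record.product_code} is missing calcium; "
                "exclude upstream (fsanz_ineligible stage)"
            )
        if calcium_per100 > CHEESE_CALCIUM_CUTOFF_MG:
            return "cat3"
    return "cat2"


def _per100_profile(record: ProductRecord, tables: NpscTables) -> dict:
    needed = {
        "energy_kcal": "energy",
        "satfat_g": "saturated fat",
        "sugars_g": "sugars",
        "sodium_mg": "sodium",
        "protein_g": "protein",
        "fibre_g": "fibre",
    }
    profile = {}
    for key, label in needed.items():
        value = record.per100(key)
        if value is None:
            raise NpscError(f"missing per-100 {label} for {record.product_code}")
        profile[key] = value
    if record.fvnl_percent is None:
        raise NpscError(f"missing fvnl_percent for {record.product_code}")
    profile["fvnl_pct"] = record.fvnl_percent
    profile["energy_kj"] = profile.pop("energy_kcal") * tables.kj_per_kcal
    return profile


def score_profile(profile: dict, category: str, tables: NpscTables) -> FsanzResult:
    """Score a per-100 profile dict (energy_kj, satfat_g, sugars_g,
    sodium_mg, fvnl_pct, protein_g, fibre_g) in the given category."""
    baseline = sum(
        tables.component(category, comp).lookup(profile[comp])
        for comp in BASELINE_COMPONENTS
    )
    v = tables.modifying["fvnl_pct"].lookup(profile["fvnl_pct"])
    f = tables.modifying["fibre_g"].lookup(profile["fibre_g"])
    p = tables.modifying["protein_g"].lookup(profile["protein_g"])
    gated = (
        category not in tables.protein_gate_exempt
        and baseline >= tables.protein_gate_baseline
        and v < tables.protein_gate_v_waiver
    )
    if gated:
        p = 0
    score = baseline - v - p - f
    return FsanzResult(
        category=category,
        baseline_points=baseline,
        v_points=v,
        p_points=p,
        f_points=f,
        score=score,
        npsc_pass=npsc_eligible(score, category, tables),
    )


def score_product(record: ProductRecord, tables: NpscTables, category=None) -> FsanzResult:
    """Score one product; missing required fields are hard errors."""
    if category is None:
        category = assign_category(record)
    if category not in CATEGORIES:
        raise NpscError(f"unknown NPSC category {category!r}")
    return score_profile(_per100_profile(record, tables), category, tables)


def npsc_eligible(score: int, category: str, tables: NpscTables) -> bool:
    """Health-claim eligibility: score strictly below the category bound."""
    return score < tables.pass_below[category]


def score_change(pair, tables: NpscTables):
    """Year-2 minus year-1 score; None (not an error) if either year is
    unscoreable.  Negative means the product got healthier."""
    try:
        r1 = score_product(pair.record_y1, tables)
        r2 = score_product(pair.record_y2, tables)
    except NpscError:
        pair.fsanz_score_change = None
        return None
    pair.fsanz_y1, pair.fsanz_y2 = r1, r2
    pair.fsanz_score_change = r2.score - r1.score
    return pair.fsanz_score_change
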