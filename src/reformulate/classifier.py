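"""Five-group reformulation classification of per-100 nutrient deltas.

A nutrient change is expressed as a signed percentage — by default as a
percentage of the nutrient's Daily Value (the labelling convention in
which 5 % DV is "a little" and 15 % DV is "a lot"), optionally relative
to the year-1 amount — and binned into five ordered groups:

    large_decrease  <= -15
    medium_decrease (-15, -5]
    little_change   (-5, +5)
    medium_increase [+5, +15)
    large_increase  >= +15

The printed band edges (-14.9, -4.9, +4.9, +14.9) are one-decimal
roundings; the implementation tiles the real line with +/-5 and +/-15
belonging to the larger-magnitude band.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .records import BRAND_TYPES, CLASSIFIED_NUTRIENTS


class ReformulationGroup(enum.IntEnum):
    """Ordered five-level reformulation outcome."""

    large_decrease = 0
    medium_decrease = 1
    little_change = 2
    medium_increase = 3
    large_increase = 4

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


GROUP_NAMES = tuple(g.name for g in ReformulationGroup)


@dataclass(frozen=True)
class DVTable:
    """Daily-Value reference amounts, loaded from a versioned data file."""

    values: dict
    version: str = "unversioned"

    def __getitem__(self, nutrient: str) -> float:
        try:
            return self.values[nutrient]
        except KeyError:
            raise KeyError(f"no Daily Value entry for nutrient {nutrient!r}") from None

    def __contains__(self, nutrient: str) -> bool:
        return nutrient in self.values


def load_dv_table(path=None) -> DVTable:
    """Load a DV table from YAML; default is the packaged Health Canada table."""
    if path is None:
        text = resources.files("reformulate.data").joinpath("daily_values.yml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    values = {k: float(v) for k, v in raw["values"].items()}
    if any(v <= 0 for v in values.values()):
        raise ValueError("Daily Values must all be positive")
    return DVTable(values=values, version=str(raw.get("version", "unversioned")))


def percent_change(
    delta_per100,
    nutrient: str,
    dv: DVTable,
    mode: str = "percent_of_dv",
    baseline_per100=None,
):
    """Signed percentage change for one nutrient delta.

    ``percent_of_dv`` divides by the Daily Value; ``relative_to_baseline``
    divides by the year-1 per-100 amount (``None`` when that baseline is
    zero, since relative change is then undefined).
    """
    if delta_per100 is None:
        return None
    if mode == "percent_of_dv":
        return 100.0 * delta_per100 / dv[nutrient]
    if mode == "relative_to_baseline":
        if baseline_per100 is None or baseline_per100 == 0:
            return None
        return 100.0 * delta_per100 / baseline_per100
    raise ValueError(f"unknown percent-change mode {mode!r}")


def classify(pct: float) -> ReformulationGroup:
    """Bin a signed percentage into the five reformulation groups."""
    if pct is None or not math.isfinite(pct):
        raise ValueError(f"cannot classify non-finite percentage {pct!r}")
    if pct <= -15:
        return ReformulationGroup.large_decrease
    if pct <= -5:
        return ReformulationGroup.medium_decrease
    if pct < 5:
        return ReformulationGroup.little_change
    if pct < 15:
        return ReformulationGroup.medium_increase
    return ReformulationGroup.large_increase


def classify_pairs(
    pairs,
    dv: DVTable,
    nutrients=CLASSIFIED_NUTRIENTS,
    mode: str = "percent_of_dv",
):
    """Populate ``pair.groups`` (nutrient -> ReformulationGroup) in place.

    Pairs missing a nutrient delta get no entry for that nutrient.
    Returns the same list for chaining.
    """
    for pair in pairs:
        groups = {}
        for nutrient in nutrients:
            delta = pair.delta_nutrients.get(nutrient)
            baseline = (pair.nutrients_per100_y1 or {}).get(nutrient)
            pct = percent_change(delta, nutrient, dv, mode=mode, baseline_per100=baseline)
            if pct is not None:
                groups[nutrient] = classify(pct)
        pair.groups = groups
    return pairs


def _cell_label(pair, by: str) -> str:
    if by == "overall":
        return "overall"
    if by == "tra_category":
        return pair.record_y1.tra_category or "?"
    if by == "brand_type":
        return pair.record_y1.brand_type or "?"
    raise ValueError(f"unknown grouping {by!r}")


def tabulate_groups(pairs, by: str = "overall", nutrients=CLASSIFIED_NUTRIENTS) -> pd.DataFrame:
    """Counts and proportions per (grouping cell, nutrient, group).

    Proportions sum to 1 over the five groups within each cell/nutrient.
    """
    counts: dict = {}
    for pair in pairs:
        cell = _cell_label(pair, by)
        for nutrient in nutrients:
            group = pair.groups.get(nutrient)
            if group is None:
                continue
            counts[(cell, nutrient, group.name)] = counts.get((cell, nutrient, group.name), 0) + 1
    rows = []
    cells = sorted({k[0] for k in counts})
    for cell in cells:
        for nutrient in nutrients:
            total = sum(counts.get((cell, nutrient, g), 0) for g in GROUP_NAMES)
            if total == 0:
                continue
            for g in GROUP_NAMES:
                n = counts.get((cell, nutrient, g), 0)
                rows.append(
                    {
                        "cell": cell,
                        "nutrient": nutrient,
                        "group": g,
                        "n": n,
                        "proportion": n / total,
                    }
                )
    return pd.DataFrame(rows, columns=["cell", "nutrient", "group", "n", "proportion"])


def brand_group_contingency(pairs, nutrient: str) -> pd.DataFrame:
    """4x2 brand-type contingency: any reformulation group vs little change."""
    table = pd.DataFrame(0, index=list(BRAND_TYPES), columns=["reformulated", "little_change"])
    for pair in pairs:
        group = pair.groups.get(nutrient)
        bt = pair.record_y1.brand_type
        if group is None or bt not in BRAND_TYPES:
            continue
        col = "little_change" if group == ReformulationGroup.little_change else "reformulated"
        table.loc[bt, col] += 1
    return table
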