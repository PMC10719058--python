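"""Market-level reports: per-subcategory pass proportions for every
requirement, high-sugar warning proportions among sugar-declaring
products, and median [IQR] nutrient summaries.

Conventions, fixed and documented:

* proportions are reported as ``% (n)`` with the denominator recorded
  explicitly; products for which a requirement is not applicable are
  excluded from that requirement's denominator;
* high-sugar denominators exclude products whose total sugar (or
  energy) is undeclared; median/IQR summaries cover declaring products
  only;
* display rounding is half-up to one decimal (matching the usual
  printed style); raw fractions are retained in the JSON output;
* quartiles use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .categorizer import Subcategory
from .labelling_assessor import (GROUPS, LabellingAssessment,
                                 LabellingRequirement)
from .nutrient_assessor import (HighSugar, NutrientAssessment, Requirement,
                                RequirementResult, Status)

NUTRIENT_COLUMNS = ("total_sugar_g", "sodium_mg", "protein_g", "total_fat_g")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (2.25 → 2.3), unlike banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def proportion_pct(n: int, denominator: int) -> Optional[float]:
    """% = round(100·n/denominator, 1) half-up; None for an empty denominator."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * n / denominator, 1)


def median_iqr(values: Iterable[float]) -> tuple[float, float, float]:
    """(median, q1, q3) with linear interpolation between order statistics."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr of an empty list is undefined")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# per-product record
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssessmentRecord:
    """Per-product bundle: subcategory, the six nutrient results plus
    overall and high-sugar state, and the 17 labelling results with group
    subtotals; plus the declared per-100 g panel values used by the
    nutrient summary table."""

    product_id: str
    subcategory: Subcategory
    nutrients: NutrientAssessment
    labelling: LabellingAssessment
    panel_values: dict[str, Optional[float]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "product_id": self.product_id,
            "subcategory": self.subcategory.value,
            "nutrients": {
                "results": {
                    k.value: {"status": v.status.value, "reason": v.reason,
                              "measured_value": v.measured_value, "unit": v.unit}
                    for k, v in self.nutrients.results.items()},
                "overall_pass": self.nutrients.overall_pass,
                "high_sugar": self.nutrients.high_sugar.value,
            },
            "labelling": {
                "results": {
                    k.value: {"status": v.status.value, "reason": v.reason}
                    for k, v in self.labelling.results.items()},
                "group_pass": dict(self.labelling.group_pass),
                "overall_pass": self.labelling.overall_pass,
            },
            "panel_values": dict(self.panel_values),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "AssessmentRecord":
        nut = d["nutrients"]
        nut_results = {
            Requirement(k): RequirementResult(
                Requirement(k), Status(v["status"]), reason=v.get("reason"),
                measured_value=v.get("measured_value"), unit=v.get("unit"))
            for k, v in nut["results"].items()}
        lab = d["labelling"]
        lab_results = {
            LabellingRequirement(k): RequirementResult(
                LabellingRequirement(k), Status(v["status"]),
                reason=v.get("reason"))
            for k, v in lab["results"].items()}
        return cls(
            product_id=d["product_id"],
            subcategory=Subcategory(d["subcategory"]),
            nutrients=NutrientAssessment(
                results=nut_results, overall_pass=nut["overall_pass"],
                high_sugar=HighSugar(nut["high_sugar"])),
            labelling=LabellingAssessment(
                results=lab_results, group_pass=dict(lab["group_pass"]),
                overall_pass=lab["overall_pass"]),
            panel_values=dict(d.get("panel_values", {})),
        )


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class Cell:
    """One % (n / denominator) cell with the raw fraction retained."""
    n: int
    denominator: int

    @property
    def pct(self) -> Optional[float]:
        return proportion_pct(self.n, self.denominator)

    @property
    def fraction(self) -> Optional[float]:
        return self.n / self.denominator if self.denominator else None

    def to_json_dict(self) -> dict:
        return {"pct": self.pct, "n": self.n, "denominator": self.denominator,
                "fraction": self.fraction}


@dataclass
class MarketReport:
    category_counts: dict[str, int]
    # nutrient_table[category][requirement or 'all'] -> Cell
    nutrient_table: dict[str, dict[str, Cell]]
    # labelling_table[category][requirement | 'subtotal:<group>' | 'all'] -> Cell
    labelling_table: dict[str, dict[str, Cell]]
    # high_sugar_table[category] -> {'declaring': int, 'warning': Cell}
    high_sugar_table: dict[str, dict]
    # nutrient_summary[category][nutrient] -> {'n', 'median', 'q1', 'q3'}
    nutrient_summary: dict[str, dict[str, dict]]

    def to_json_dict(self) -> dict:
        return {
            "category_counts": self.category_counts,
            "nutrient_table": {c: {k: v.to_json_dict() for k, v in row.items()}
                               for c, row in self.nutrient_table.items()},
            "labelling_table": {c: {k: v.to_json_dict() for k, v in row.items()}
                                for c, row in self.labelling_table.items()},
            "high_sugar_table": {
                c: {"declaring": row["declaring"],
                    "warning": row["warning"].to_json_dict()}
                for c, row in self.high_sugar_table.items()},
            "nutrient_summary": self.nutrient_summary,
        }

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Printed-table analogues as DataFrames (one per report table)."""
        def table_frame(table: dict[str, dict[str, Cell]]) -> pd.DataFrame:
            rows = {}
            for cat, row in table.items():
                rows[cat] = {k: (f"{c.pct} ({c.n})" if c.pct is not None else "NA")
                             for k, c in row.items()}
            return pd.DataFrame.from_dict(rows, orient="index")

        summary_rows = {}
        for cat, row in self.nutrient_summary.items():
            flat = {}
            for nut, stats in row.items():
                if stats["n"] == 0:
                    flat[nut] = "NA"
                else:
                    flat[nut] = (f"{stats['median']:.1f} "
                                 f"[{stats['q1']:.1f}-{stats['q3']:.1f}] "
                                 f"(n={stats['n']})")
            summary_rows[cat] = flat
        hs_rows = {}
        for cat, row in self.high_sugar_table.items():
            cell = row["warning"]
            hs_rows[cat] = {
                "declaring": row["declaring"],
                "warning_required": (f"{cell.pct} ({cell.n})"
                                     if cell.pct is not None else "NA"),
            }
        return {
            "nutrient_table": table_frame(self.nutrient_table),
            "labelling_table": table_frame(self.labelling_table),
            "high_sugar_table": pd.DataFrame.from_dict(hs_rows, orient="index"),
            "nutrient_summary": pd.DataFrame.from_dict(summary_rows, orient="index"),
        }


_ALL = "all_products"


def summarize(records: list[AssessmentRecord]) -> MarketReport:
    """Aggregate per-product assessments into the market report.

    An empty input yields an empty report, not an error.
    """
    cats = [c.value for c in Subcategory]
    by_cat: dict[str, list[AssessmentRecord]] = {c: [] for c in cats}
    for rec in records:
        by_cat[rec.subcategory.value].append(rec)
    groups_of = {c: by_cat[c] for c in cats}
    groups_of[_ALL] = list(records)

    category_counts = {c: len(by_cat[c]) for c in cats}
    category_counts[_ALL] = len(records)

    nutrient_table: dict[str, dict[str, Cell]] = {}
    labelling_table: dict[str, dict[str, Cell]] = {}
    high_sugar_table: dict[str, dict] = {}
    nutrient_summary: dict[str, dict[str, dict]] = {}

    for cat, recs in groups_of.items():
        # nutrient requirements
        row: dict[str, Cell] = {}
        for req in Requirement:
            applicable = [r for r in recs if r.nutrients[req].applicable]
            passed = sum(1 for r in applicable if r.nutrients[req].passed)
            row[req.value] = Cell(passed, len(applicable))
        row["all"] = Cell(sum(1 for r in recs if r.nutrients.overall_pass), len(recs))
        nutrient_table[cat] = row

        # labelling requirements + group subtotals
        lrow: dict[str, Cell] = {}
        for grp, reqs in GROUPS.items():
            for req in reqs:
                applicable = [r for r in recs if r.labelling[req].applicable]
                passed = sum(1 for r in applicable if r.labelling[req].passed)
                lrow[req.value] = Cell(passed, len(applicable))
            grp_applicable = [r for r in recs
                              if any(r.labelling[q].applicable for q in reqs)]
            grp_passed = sum(1 for r in grp_applicable if r.labelling.group_pass[grp])
            lrow[f"subtotal:{grp}"] = Cell(grp_passed, len(grp_applicable))
        lrow["all"] = Cell(sum(1 for r in recs if r.labelling.overall_pass), len(recs))
        labelling_table[cat] = lrow

        # high-sugar warning among declaring products
        declaring = [r for r in recs
                     if r.nutrients.high_sugar != HighSugar.sugar_undeclared]
        warning = sum(1 for r in declaring
                      if r.nutrients.high_sugar == HighSugar.warning_required)
        high_sugar_table[cat] = {"declaring": len(declaring),
                                 "warning": Cell(warning, len(declaring))}

        # nutrient summary (declaring products only)
        srow: dict[str, dict] = {}
        for nut in NUTRIENT_COLUMNS:
            vals = [r.panel_values.get(nut) for r in recs
                    if r.panel_values.get(nut) is not None]
            if vals:
                med, q1, q3 = median_iqr(vals)
                srow[nut] = {"n": len(vals), "median": med, "q1": q1, "q3": q3}
            else:
                srow[nut] = {"n": 0, "median": None, "q1": None, "q3": None}
        nutrient_summary[cat] = srow

    return MarketReport(category_counts=category_counts,
                        nutrient_table=nutrient_table,
                        labelling_table=labelling_table,
                        high_sugar_table=high_sugar_table,
                        nutrient_summary=nutrient_summary)
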