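"""Rounding and table output matching the published convention, plus golden
comparison against printed reference tables with erratum handling.

Printed counts are in thousands: values of 10 or more are rounded half-up to
the nearest integer, values under 10 to one decimal place.  Reference cells
keep the text exactly as printed (including typos); cells carrying an
erratum flag are reported in comparisons but can never fail them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .cascade import ImpactRow, ImpactTable

__all__ = [
    "ReferenceCell",
    "ReferenceTable",
    "CellComparison",
    "ComparisonReport",
    "format_count",
    "parse_printed",
    "split_printed_range",
    "render_table",
    "compare_to_reference",
    "load_reference_table",
]

COLUMNS = ("affected", "discontinue", "adverse_events")

_DASHES = "-–−"  # hyphen, en-dash, minus: the tables mix them


def format_count(x: float, thousands_sep: bool = False) -> str:
    """Format a count in thousands the way the published tables print them:
    >= 10 rounds half-up to an integer, < 10 keeps one decimal place."""
    if x < 0:
        raise ValueError(f"counts are nonnegative, got {x}")
    if x >= 10:
        q = Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
        return f"{int(q):,}" if thousands_sep else str(int(q))
    q = Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return str(q)


def parse_printed(text: str) -> float:
    """Parse one printed cell value; accepts comma separators and bare
    leading-dot decimals (the tables contain ``.04``)."""
    cleaned = text.strip().replace(",", "").replace(" ", "")
    if cleaned.startswith("."):
        cleaned = "0" + cleaned
    value = float(cleaned)
    if value < 0:
        raise ValueError(f"printed counts are nonnegative, got {text!r}")
    return value


def _decimals(text: str) -> int:
    cleaned = text.strip().replace(",", "")
    return len(cleaned.split(".")[1]) if "." in cleaned else 0


def split_printed_range(text: str) -> tuple[str, str]:
    """Split a printed 'low-high' cell, accepting hyphen or en-dash."""
    for dash in _DASHES:
        # skip a leading dash that would belong to the number (never occurs
        # in practice since counts are nonnegative)
        idx = text.find(dash, 1)
        if idx != -1:
            return text[:idx].strip(), text[idx + 1 :].strip()
    raise ValueError(f"not a printed range: {text!r}")


# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------


@dataclass
class ReferenceCell:
    """One printed low/high cell, kept verbatim as text."""

    formulary: str
    medication: str
    column: str  # affected | discontinue | adverse_events
    printed_low: str
    printed_high: str
    erratum_bound: Optional[str] = None  # low | high | both
    erratum_note: Optional[str] = None

    def is_erratum(self, bound: str) -> bool:
        return self.erratum_bound in (bound, "both")


@dataclass
class ReferenceTable:
    name: str
    cells: list[ReferenceCell] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def load_reference_table(path: Union[str, Path]) -> ReferenceTable:
    data = yaml.safe_load(Path(path).read_text())
    cells = []
    for c in data.get("cells", []):
        err = c.get("erratum") or {}
        low, high = str(c["low"]), str(c["high"])
        parse_printed(low), parse_printed(high)  # reject non-numeric cells early
        cells.append(
            ReferenceCell(
                formulary=str(c["formulary"]),
                medication=str(c["medication"]),
                column=str(c["column"]),
                printed_low=low,
                printed_high=high,
                erratum_bound=err.get("bound"),
                erratum_note=err.get("note"),
            )
        )
    return ReferenceTable(
        name=str(data.get("name", path)),
        cells=cells,
        notes=[str(n) for n in data.get("notes", [])],
    )


def reference_from_impact(t: ImpactTable) -> ReferenceTable:
    """Render an impact table back into reference form (used for
    self-comparison round trips)."""
    cells = []
    for r in t.rows:
        for column in COLUMNS:
            rng = getattr(r, column)
            cells.append(
                ReferenceCell(
                    formulary=r.formulary,
                    medication=r.medication,
                    column=column,
                    printed_low=format_count(rng.low),
                    printed_high=format_count(rng.high),
                )
            )
    return ReferenceTable(name=t.scenario_name, cells=cells)


# ---------------------------------------------------------------------------
# Comparison
# ---------------------------------------------------------------------------


@dataclass
class CellComparison:
    formulary: str
    medication: str
    column: str
    bound: str  # low | high
    printed: str
    computed: float
    computed_rounded: float
    delta_units: float  # |rounded - printed| in units of the printed precision
    status: str  # match | within_tolerance | mismatch | skipped_erratum
    erratum_note: Optional[str] = None


@dataclass
class ComparisonReport:
    scenario_name: str
    reference_name: str
    tolerance: int
    entries: list[CellComparison] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out = {"match": 0, "within_tolerance": 0, "mismatch": 0, "skipped_erratum": 0}
        for e in self.entries:
            out[e.status] += 1
        return out

    @property
    def n_mismatches(self) -> int:
        return self.counts["mismatch"]

    def passed(self) -> bool:
        """True when no non-erratum cell mismatches beyond tolerance."""
        return self.n_mismatches == 0

    def to_json(self) -> str:
        doc: dict[str, Any] = {
            "scenario": self.scenario_name,
            "reference": self.reference_name,
            "tolerance": self.tolerance,
            "summary": self.counts,
            "cells": [
                {
                    "formulary": e.formulary,
                    "medication": e.medication,
                    "column": e.column,
                    "bound": e.bound,
                    "printed": e.printed,
                    "computed": e.computed,
                    "computed_rounded": e.computed_rounded,
                    "delta_units": e.delta_units,
                    "status": e.status,
                    **({"erratum_note": e.erratum_note} if e.erratum_note else {}),
                }
                for e in self.entries
            ],
        }
        return json.dumps(doc, indent=2)


def _round_to_printed(x: float, printed: str) -> float:
    """Round a computed value half-up to the precision of the printed text."""
    nd = _decimals(printed)
    q = Decimal(repr(x)).quantize(Decimal(1).scaleb(-nd), rounding=ROUND_HALF_UP)
    return float(q)


def compare_to_reference(
    t: ImpactTable, ref: ReferenceTable, tol: int = 1
) -> ComparisonReport:
    """Compare computed impact against a printed reference table.

    Each bound of each reference cell is rounded-matched at the printed
    precision: equal after rounding → ``match``; within ``tol`` units of the
    printed last digit → ``within_tolerance``; otherwise ``mismatch``.
    Erratum-flagged bounds are reported as ``skipped_erratum`` and never
    fail.  A reference cell with no computed counterpart is an error.
    """
    report = ComparisonReport(
        scenario_name=t.scenario_name, reference_name=ref.name, tolerance=tol
    )
    for cell in ref.cells:
        try:
            row = t.row(cell.formulary, cell.medication)
        except KeyError as exc:
            raise KeyError(
                f"reference cell ({cell.formulary}, {cell.medication}, "
                f"{cell.column}) has no computed counterpart"
            ) from exc
        if cell.column not in COLUMNS:
            raise ValueError(f"unknown reference column {cell.column!r}")
        rng = getattr(row, cell.column)
        for bound, printed, computed in (
            ("low", cell.printed_low, rng.low),
            ("high", cell.printed_high, rng.high),
        ):
            unit = 10.0 ** -_decimals(printed)
            rounded = _round_to_printed(computed, printed)
            delta = abs(rounded - parse_printed(printed)) / unit
            delta = round(delta, 9)
            if cell.is_erratum(bound):
                status = "skipped_erratum"
            elif delta == 0:
                status = "match"
            elif delta <= tol:
                status = "within_tolerance"
            else:
                status = "mismatch"
            report.entries.append(
                CellComparison(
                    formulary=cell.formulary,
                    medication=cell.medication,
                    column=cell.column,
                    bound=bound,
                    printed=printed,
                    computed=computed,
                    computed_rounded=rounded,
                    delta_units=delta,
                    status=status,
                    erratum_note=cell.erratum_note if cell.is_erratum(bound) else None,
                )
            )
    return report


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_HEADERS = (
    "Medication",
    "Market Share %",
    "Potentially Affected",
    "Likely to Discontinue",
    "Adverse Events",
)


def _row_values(r: ImpactRow) -> tuple[str, ...]:
    return (
        r.medication,
        f"{r.share * 100:.2f}",
        f"{format_count(r.affected.low)}-{format_count(r.affected.high)}",
        f"{format_count(r.discontinue.low)}-{format_count(r.discontinue.high)}",
        f"{format_count(r.adverse_events.low)}-{format_count(r.adverse_events.high)}",
    )


def render_table(t: ImpactTable, style: str = "markdown") -> str:
    """Render an impact table, one block per formulary, as csv, tsv or
    markdown.  Column order is fixed: medication, market share, affected,
    discontinue, adverse events; counts print as 'low-high' in thousands."""
    if style not in ("csv", "tsv", "markdown"):
        raise ValueError(f"unknown style {style!r}; expected csv, tsv or markdown")
    formularies: list[str] = []
    for r in t.rows:
        if r.formulary not in formularies:
            formularies.append(r.formulary)
    lines: list[str] = []
    if style in ("csv", "tsv"):
        sep = "," if style == "csv" else "\t"

        def quote(v: str) -> str:
            if style == "csv" and ("," in v or '"' in v):
                return '"' + v.replace('"', '""') + '"'
            return v

        lines.append(sep.join(("Formulary",) + _HEADERS))
        for f in formularies:
            for r in t.rows:
                if r.formulary == f:
                    lines.append(sep.join(quote(v) for v in (f,) + _row_values(r)))
    else:
        header = "| " + " | ".join(_HEADERS) + " |"
        rule = "|" + "|".join(" --- " for _ in _HEADERS) + "|"
        for f in formularies:
            lines.append(f"### {f} — {t.scenario_name} (thousands)")
            lines.append("")
            lines.append(header)
            lines.append(rule)
            for r in t.rows:
                if r.formulary == f:
                    lines.append("| " + " | ".join(_row_values(r)) + " |")
            lines.append("")
    return "\n".join(lines).rstrip("\n") + "\n"
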