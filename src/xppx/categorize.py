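"""Functional-category summaries of differential calls.

Aggregates up/down calls into a per-category table (Increase, Decrease,
Total, Total %) of the kind used to summarize regulon-scale studies in
B. subtilis, with SubtiWiki-style category names. Percentages are taken
against the sum of the table's own Total column; shares of at least 1%
print as integers, smaller non-zero shares with one decimal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .differential import DOWN, UP, FoldChangeRecord

__all__ = [
    "UNKNOWN_CATEGORY",
    "CategoryRow",
    "CategorySummary",
    "summarize",
    "recompute_percentages",
    "format_pct",
    "read_category_map",
]

UNKNOWN_CATEGORY = "Unknown or poorly characterized proteins"


@dataclass(frozen=True)
class CategoryRow:
    category: str
    n_up: int
    n_down: int
    n_total: int
    pct: float

    def __post_init__(self) -> None:
        if self.n_total != self.n_up + self.n_down:
            raise ValueError(
                f"{self.category}: n_total must equal n_up + n_down"
            )


@dataclass(frozen=True)
class CategorySummary:
    rows: tuple[CategoryRow, ...]

    @property
    def total_up(self) -> int:
        return sum(r.n_up for r in self.rows)

    @property
    def total_down(self) -> int:
        return sum(r.n_down for r in self.rows)

    @property
    def total(self) -> int:
        return sum(r.n_total for r in self.rows)

    @property
    def categories(self) -> list[str]:
        return [r.category for r in self.rows]


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _pct_value(n: int, total: int) -> float:
    """Percentage of ``total`` under the mixed-precision printing rule.

    Shares rounding to >= 1% at one decimal are reported as integers
    (half away from zero); smaller non-zero shares keep one decimal so
    categories such as 8/1109 surface as 0.7 rather than 1.
    """
    if n == 0:
        return 0.0
    exact = 100.0 * n / total
    one_dec = _round_half_up(exact, 1)
    if one_dec < 1.0:
        return one_dec
    return _round_half_up(exact, 0)


def recompute_percentages(
    totals: Sequence[tuple[str, int]]
) -> list[tuple[str, float]]:
    """Per-category share of the summed Total column.

    ``pct_i = 100 * n_i / sum(n)`` rounded half away from zero; values
    below 1% carry one decimal. An all-zero input has no denominator and
    raises.
    """
    denom = sum(n for _, n in totals)
    if denom == 0:
        raise ValueError("cannot compute percentages: category totals sum to 0")
    if any(n < 0 for _, n in totals):
        raise ValueError("category totals must be nonnegative")
    return [(cat, _pct_value(n, denom)) for cat, n in totals]


def format_pct(pct: float) -> str:
    """Render a percentage: '24', '0.7', '0'."""
    if pct == int(pct):
        return str(int(pct))
    return f"{pct:.1f}"


def summarize(
    calls: Iterable[FoldChangeRecord],
    catmap: Mapping[str, str],
    category_order: Sequence[str] | None = None,
) -> CategorySummary:
    """Tabulate up/down calls per functional category.

    Unchanged features are excluded. Features missing from ``catmap``
    fall into the Unknown category. Row order follows ``category_order``
    when given, else first appearance in the category map (Unknown
    last); categories with no changed feature are kept only when an
    explicit order lists them. No calls at all yields an empty table.
    """
    up_counts: dict[str, int] = {}
    down_counts: dict[str, int] = {}
    seen_any = False
    for rec in calls:
        if rec.call not in (UP, DOWN):
            continue
        seen_any = True
        category = catmap.get(rec.feature_id, UNKNOWN_CATEGORY)
        bucket = up_counts if rec.call == UP else down_counts
        bucket[category] = bucket.get(category, 0) + 1
    if not seen_any:
        return CategorySummary(rows=())

    if category_order is not None:
        order = list(category_order)
    else:
        order = list(dict.fromkeys(catmap.values()))
    for extra in (*up_counts, *down_counts):
        if extra not in order:
            order.append(extra)
    # the Unknown fallback sorts last when it appears implicitly
    if UNKNOWN_CATEGORY in order and category_order is None and (
        UNKNOWN_CATEGORY not in catmap.values()
    ):
        order.remove(UNKNOWN_CATEGORY)
        order.append(UNKNOWN_CATEGORY)

    counted = [
        (cat, up_counts.get(cat, 0), down_counts.get(cat, 0))
        for cat in order
        if category_order is not None
        or up_counts.get(cat, 0) + down_counts.get(cat, 0) > 0
    ]
    pcts = dict(
        recompute_percentages([(cat, u + d) for cat, u, d in counted])
    )
    rows = tuple(
        CategoryRow(
            category=cat, n_up=u, n_down=d, n_total=u + d, pct=pcts[cat]
        )
        for cat, u, d in counted
    )
    return CategorySummary(rows=rows)


def read_category_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (feature_id, category); '#' lines are comments.

    Insertion order of categories is preserved and defines the default
    summary row order.
    """
    catmap: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].lower() in ("feature_id", "gene", "protein_id"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if row[0] in catmap:
                raise ValueError(f"{path}:{lineno}: duplicate feature {row[0]!r}")
            catmap[row[0]] = row[1]
    return catmap


def summary_to_rows(summary: CategorySummary) -> list[list[str]]:
    out = []
    for r in summary.rows:
        out.append(
            [r.category, str(r.n_up), str(r.n_down), str(r.n_total), format_pct(r.pct)]
        )
    return out


def write_summary(
    summary: CategorySummary, path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["category", "increase", "decrease", "total", "total_pct"])
        writer.writerows(summary_to_rows(summary))
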