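"""Descriptive summary tables for SCAR report sets and signal matrices.

All outputs are tabular (label, count, percent): yearly/reporter/country/
sex/age/outcome distributions, per-PT report counts, top-N reporting
proportions at drug or second-ATC-level class granularity, and the
distribution of positive-signal counts per drug.  Plotting is left to the
user.

Rounding conventions: one decimal for proportions, nearest integer for the
outcome percentages, always half away from zero.  Percent cells are always
re-derived from the count cells.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from ._util import percent
from .disproportionality import SMQ_SCOPE, SignalMatrix
from .normalize import CulpritDrug
from .report_model import ReportSet, Sex
from .smq import SMQDefinition, builtin_scar_smq, match_scar_pts

__all__ = [
    "SummaryTable",
    "descriptive_summary",
    "reporting_proportions",
    "positive_signal_distribution",
    "write_summary_tsv",
]


@dataclass
class SummaryTable:
    """An ordered (label, count, percent) table with its denominator.

    ``partition`` is False for tables whose rows do not partition the
    denominator (top-N truncations, multi-valued outcome counts).
    """

    name: str
    rows: list[tuple[str, int, float]]
    denominator: int
    partition: bool = True
    percent_decimals: int = 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["label", "count", "percent"])

    def counts(self) -> dict[str, int]:
        return {label: count for label, count, _ in self.rows}


def _table(
    name: str,
    counts: list[tuple[str, int]],
    denominator: int,
    partition: bool = True,
    decimals: int = 1,
) -> SummaryTable:
    rows = [
        (label, count, percent(count, denominator, decimals))
        for label, count in counts
    ]
    return SummaryTable(name, rows, denominator, partition, decimals)


_AGE_BIN_LABELS = [
    "0–10", "11–20", "21–30", "31–40", "41–50",
    "51–60", "61–70", "71–80", "81–90", ">90",
]


def _age_bin(age: float | None) -> str:
    """Decade bins 0–10, 11–20, …, 81–90, >90; first bin includes age 10."""
    if age is None:
        return "unknown"
    if age <= 10:
        return _AGE_BIN_LABELS[0]
    if age > 90:
        return ">90"
    return _AGE_BIN_LABELS[min(int(math.ceil(age) - 1) // 10, 8)]


def descriptive_summary(
    scar_set: ReportSet, smq: SMQDefinition | None = None
) -> dict[str, SummaryTable]:
    """Distribution tables over a deduplicated SCAR report set.

    Returns year, reporter, country (top 10, ties alphabetical), sex, age
    decade, outcome (multi-valued; percents of the report total, integer
    rounding) and per-PT report counts.
    """
    smq = smq or builtin_scar_smq()
    n = len(scar_set)

    years = Counter()
    reporters = Counter()
    countries = Counter()
    sexes = Counter()
    ages = Counter()
    outcomes = Counter()
    pt_counts = Counter({pt: 0 for pt in smq.pt_names})
    for report in scar_set:
        years[str(report.receive_date.year) if report.receive_date else "unknown"] += 1
        reporters[report.reporter.value] += 1
        countries[report.country or "unknown"] += 1
        sexes[report.sex.value] += 1
        ages[_age_bin(report.age_years)] += 1
        for o in report.outcomes:
            outcomes[o.value] += 1
        for pt in match_scar_pts(report, smq):
            pt_counts[pt] += 1

    year_rows = sorted(
        ((y, c) for y, c in years.items() if y != "unknown"), key=lambda t: t[0]
    )
    if "unknown" in years:
        year_rows.append(("unknown", years["unknown"]))

    top_countries = sorted(countries.items(), key=lambda t: (-t[1], t[0]))[:10]

    sex_rows = [(s.value, sexes.get(s.value, 0)) for s in Sex]
    age_rows = [
        (label, ages.get(label, 0)) for label in [*_AGE_BIN_LABELS, "unknown"]
    ]
    outcome_rows = sorted(outcomes.items(), key=lambda t: (-t[1], t[0]))
    pt_rows = sorted(pt_counts.items(), key=lambda t: (-t[1], t[0]))
    pt_rows.append((smq.name, n))

    return {
        "year": _table("year", year_rows, n),
        "reporter": _table("reporter", reporters.most_common(), n),
        "country_top10": _table("country_top10", top_countries, n, partition=False),
        "sex": _table("sex", sex_rows, n),
        "age_decade": _table("age_decade", age_rows, n),
        "outcome": _table("outcome", outcome_rows, n, partition=False, decimals=0),
        "pt_counts": _table("pt_counts", pt_rows, n, partition=False),
    }


def reporting_proportions(
    scar_set: ReportSet,
    culprits: list[CulpritDrug],
    level: str = "drug",
    top_n: int = 10,
    scope: str = SMQ_SCOPE,
    smq: SMQDefinition | None = None,
) -> SummaryTable:
    """Top-N reporting proportions at drug or second-ATC-class level.

    The denominator is the number of SCAR reports matching ``scope``.  A
    drug's count is the number of in-scope reports where it is primary
    suspect; a class's count uses distinct reports with at least one
    primary-suspect drug in the class (a report with two same-class suspects
    counts once).  Drugs with multiple ATC codes contribute to every class
    they belong to.  Rows sort by count descending, label ascending.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if level not in ("drug", "atc2"):
        raise ValueError(f"unknown level {level!r}")
    smq = smq or builtin_scar_smq()

    if scope == SMQ_SCOPE:
        in_scope = {r.report_id for r in scar_set}
    else:
        in_scope = {
            r.report_id for r in scar_set if scope in match_scar_pts(r, smq)
        }
    denominator = len(in_scope)

    counts: Counter[str] = Counter()
    if level == "drug":
        for drug in culprits:
            k = len(drug.scar_report_ids & in_scope)
            if k:
                counts[drug.canonical_name] = k
    else:
        class_reports: dict[str, set[str]] = {}
        for drug in culprits:
            classes = drug.atc2_classes or {"unclassified"}
            ids = drug.scar_report_ids & in_scope
            for cls in classes:
                class_reports.setdefault(cls, set()).update(ids)
        counts = Counter(
            {cls: len(ids) for cls, ids in class_reports.items() if ids}
        )

    rows = sorted(counts.items(), key=lambda t: (-t[1], t[0]))[:top_n]
    return _table(
        f"top{top_n}_{level}_{scope}", rows, denominator, partition=False
    )


def positive_signal_distribution(
    matrices: Mapping[str, SignalMatrix],
) -> tuple[SummaryTable, int]:
    """Drug counts by number of positive signals, plus the ≥1-positive scalar.

    Rows run from the maximum observed positive count down to 0 (every
    intermediate value included), followed by a Total row at 100.0%.
    """
    total = len(matrices)
    histogram = Counter(m.n_positive for m in matrices.values())
    max_k = max(histogram) if histogram else 0
    rows = [(str(k), histogram.get(k, 0)) for k in range(max_k, -1, -1)]
    table = _table("positive_signal_distribution", rows, total)
    table.rows.append(("Total", total, 100.0 if total else 0.0))
    n_ge1 = total - histogram.get(0, 0)
    return table, n_ge1


def write_summary_tsv(table: SummaryTable, path: str | Path) -> None:
    """Write a SummaryTable as TSV with a denominator header comment."""
    path = Path(path)
    header = (
        f"# table={table.name}\tdenominator={table.denominator}"
        f"\tpartition={table.partition}\n"
    )
    path.write_text(
        header + table.to_frame().to_csv(sep="\t", index=False), encoding="utf-8"
    )
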