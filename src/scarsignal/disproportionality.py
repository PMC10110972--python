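"""Reporting odds ratio (ROR) disproportionality analysis.

For a drug of interest and an event scope, reports are cross-classified in
the 2×2 table

=================  ================  ===========
.                  drug of interest  other drugs
event of interest          a               b
other events               c               d
=================  ================  ===========

and the reporting odds ratio is ``ROR = (a·d)/(b·c)`` with the Woolf
log-normal 95% interval ``exp(ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d))``.
A drug–scope pair is a *positive signal* when the interval's lower bound is
strictly above 1 and there are at least three case reports (a ≥ 3).

Each culprit drug is evaluated at 19 scopes: the whole SCAR SMQ plus the 18
narrow preferred terms, giving a 19-entry signal matrix per drug.  The
counting unit is the report: a report is "with drug" iff any primary-suspect
mention normalizes to the drug, and "with event" iff its reactions match the
scope (SMQ scope: any narrow PT; PT scope: that PT).

Zero cells make the ROR undefined; by default such results are *not
evaluable* (and therefore negative).  An optional Haldane–Anscombe mode adds
0.5 to all four cells of zero-cell tables, flagged as ``corrected`` in the
output.  The ≥3-case gate always applies to the raw a.  No multiple-testing
adjustment is applied anywhere: every interval is a plain unadjusted 95% CI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .normalize import CulpritDrug, IngredientMap, primary_suspect_drugs
from .report_model import ReportSet
from .smq import SMQDefinition, builtin_scar_smq, match_scar_pts

__all__ = [
    "SMQ_SCOPE",
    "Z_95",
    "ContingencyTable",
    "RorEstimate",
    "SignalResult",
    "SignalMatrix",
    "scope_order",
    "build_contingency",
    "compute_ror",
    "classify_signal",
    "signal_matrix",
    "screen_positive_drugs",
    "signal_frame",
]

#: Scope label for the SMQ-level (any narrow PT) analysis.
SMQ_SCOPE = "SMQ"

#: 95% normal quantile as conventionally hard-coded in the ROR formula.
Z_95 = 1.96


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts a/b/c/d of the drug × event 2×2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in ("a", "b", "c", "d"):
            value = getattr(self, cell)
            if value < 0:
                raise ValueError(f"cell {cell} is negative ({value})")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class RorEstimate:
    ror: float | None
    ci_low: float | None
    ci_high: float | None
    evaluable: bool
    corrected: bool = False


def compute_ror(t: ContingencyTable, zero_cell: str = "none") -> RorEstimate:
    """ROR point estimate and 95% CI for one contingency table.

    ``zero_cell="none"`` (default) declares tables with any empty cell not
    evaluable; ``"haldane"`` adds 0.5 to all four cells of such tables and
    flags the estimate as corrected.
    """
    if zero_cell not in ("none", "haldane"):
        raise ValueError(f"unknown zero_cell mode {zero_cell!r}")
    corrected = False
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if t.has_zero_cell:
        if zero_cell == "none":
            return RorEstimate(None, None, None, evaluable=False)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    ror = (a * d) / (b * c)
    half_width = Z_95 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return RorEstimate(
        ror=ror,
        ci_low=math.exp(log_ror - half_width),
        ci_high=math.exp(log_ror + half_width),
        evaluable=True,
        corrected=corrected,
    )


@dataclass(frozen=True)
class SignalResult:
    """ROR result for one (drug, scope) pair with its positivity call."""

    drug: str
    scope: str
    table: ContingencyTable
    ror: float | None
    ci_low: float | None
    ci_high: float | None
    evaluable: bool
    positive: bool
    corrected: bool = False


def classify_signal(res: SignalResult | RorEstimate, a: int | None = None) -> bool:
    """Positive-signal rule: evaluable, CI lower bound > 1 (strict), a ≥ 3.

    The case-count gate uses the raw cell a even under zero-cell correction.
    """
    if isinstance(res, SignalResult):
        a = res.table.a
    elif a is None:
        raise ValueError("raw case count a required with a bare RorEstimate")
    return bool(res.evaluable and res.ci_low is not None and res.ci_low > 1 and a >= 3)


@dataclass
class SignalMatrix:
    """The 19 signal results of one drug: SMQ first, then the 18 PTs."""

    drug: str
    results: list[SignalResult]

    def __post_init__(self) -> None:
        if len(self.results) != 19:
            raise ValueError(
                f"{self.drug}: expected 19 signal results, got {len(self.results)}"
            )

    @property
    def n_positive(self) -> int:
        return sum(r.positive for r in self.results)


def scope_order(smq: SMQDefinition | None = None) -> list[str]:
    """SMQ scope followed by the 18 narrow PTs in definition order."""
    smq = smq or builtin_scar_smq()
    return [SMQ_SCOPE, *smq.pt_names]


def _result(
    drug: str, scope: str, table: ContingencyTable, zero_cell: str
) -> SignalResult:
    est = compute_ror(table, zero_cell)
    res = SignalResult(
        drug=drug,
        scope=scope,
        table=table,
        ror=est.ror,
        ci_low=est.ci_low,
        ci_high=est.ci_high,
        evaluable=est.evaluable,
        positive=False,
        corrected=est.corrected,
    )
    positive = classify_signal(res)
    return SignalResult(**{**res.__dict__, "positive": positive})


def build_contingency(
    all_reports: ReportSet,
    drug: str,
    scope: str,
    smq: SMQDefinition | None = None,
    imap: IngredientMap | None = None,
) -> ContingencyTable:
    """Count the 2×2 table for one drug and scope over a deduplicated set.

    The background is the full report collection (SCAR and non-SCAR alike).
    Each report lands in exactly one cell.
    """
    smq = smq or builtin_scar_smq()
    imap = imap or IngredientMap()
    a = b = c = d = 0
    for report in all_reports:
        names, _ = primary_suspect_drugs(report, imap)
        with_drug = drug in names
        matched = match_scar_pts(report, smq)
        with_event = bool(matched) if scope == SMQ_SCOPE else scope in matched
        if with_drug and with_event:
            a += 1
        elif with_drug:
            b += 1
        elif with_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def _report_features(
    reports: Iterable, smq: SMQDefinition, imap: IngredientMap
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """One pass over reports → per-drug row indices and a boolean event matrix.

    The event matrix has one column per scope in :func:`scope_order`.
    """
    pt_col = {pt: j + 1 for j, pt in enumerate(smq.pt_names)}
    drug_rows: dict[str, list[int]] = {}
    event_rows: list[tuple[int, set[str]]] = []
    n = 0
    for i, report in enumerate(reports):
        n = i + 1
        names, _ = primary_suspect_drugs(report, imap)
        for name in names:
            drug_rows.setdefault(name, []).append(i)
        matched = match_scar_pts(report, smq)
        if matched:
            event_rows.append((i, matched))
    events = np.zeros((n, 19), dtype=bool)
    for i, matched in event_rows:
        events[i, 0] = True
        for pt in matched:
            events[i, pt_col[pt]] = True
    return {k: np.asarray(v, dtype=np.intp) for k, v in drug_rows.items()}, events


def signal_matrix(
    all_reports: ReportSet,
    culprits: list[CulpritDrug],
    smq: SMQDefinition | None = None,
    imap: IngredientMap | None = None,
    zero_cell: str = "none",
    background: str = "faers_background",
) -> dict[str, SignalMatrix]:
    """Compute all 19 signals for every culprit drug.

    ``background`` selects the denominator convention: the full report
    collection (``faers_background``, the default — all other drugs in the
    database form the comparator) or the SCAR subset only (``scar_only``).
    The result preserves the culprit-list drug order; scopes follow
    :func:`scope_order`.
    """
    if background not in ("faers_background", "scar_only"):
        raise ValueError(f"unknown background convention {background!r}")
    smq = smq or builtin_scar_smq()
    imap = imap or IngredientMap()

    reports = list(all_reports)
    drug_rows, events = _report_features(reports, smq, imap)
    if background == "scar_only":
        keep = np.flatnonzero(events[:, 0]) if len(events) else np.array([], dtype=np.intp)
        remap = {old: new for new, old in enumerate(keep)}
        events = events[keep]
        drug_rows = {
            name: np.asarray([remap[r] for r in rows if r in remap], dtype=np.intp)
            for name, rows in drug_rows.items()
        }
    n_total = events.shape[0] if background == "scar_only" else len(reports)
    event_totals = events.sum(axis=0)

    scopes = scope_order(smq)
    matrices: dict[str, SignalMatrix] = {}
    for culprit in culprits:
        rows = drug_rows.get(culprit.canonical_name, np.array([], dtype=np.intp))
        n_drug = len(rows)
        with_drug_events = events[rows].sum(axis=0)
        results = []
        for j, scope in enumerate(scopes):
            a = int(with_drug_events[j])
            table = ContingencyTable(
                a=a,
                b=n_drug - a,
                c=int(event_totals[j]) - a,
                d=n_total - n_drug - int(event_totals[j]) + a,
            )
            results.append(_result(culprit.canonical_name, scope, table, zero_cell))
        matrices[culprit.canonical_name] = SignalMatrix(culprit.canonical_name, results)
    return matrices


def screen_positive_drugs(
    matrices: Mapping[str, SignalMatrix],
) -> tuple[list[str], dict[int, int]]:
    """Drugs with ≥1 positive signal, plus the n_positive → drug-count histogram.

    Input (culprit-list) order is preserved in the returned list; the
    histogram covers every drug, including those with zero positives.
    """
    histogram: dict[int, int] = {}
    positives = []
    for drug, matrix in matrices.items():
        k = matrix.n_positive
        histogram[k] = histogram.get(k, 0) + 1
        if k >= 1:
            positives.append(drug)
    return positives, histogram


def signal_frame(matrices: Mapping[str, SignalMatrix]) -> pd.DataFrame:
    """Flatten signal matrices to one row per (drug, scope) for export.

    Full-precision columns plus 2-decimal display columns.
    """
    rows = []
    for matrix in matrices.values():
        for res in matrix.results:
            rows.append(
                {
                    "drug": res.drug,
                    "scope": res.scope,
                    "a": res.table.a,
                    "b": res.table.b,
                    "c": res.table.c,
                    "d": res.table.d,
                    "ror": res.ror,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "evaluable": res.evaluable,
                    "positive": res.positive,
                    "corrected": res.corrected,
                    "n_positive": matrix.n_positive,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "drug", "scope", "a", "b", "c", "d", "ror", "ci_low", "ci_high",
            "evaluable", "positive", "corrected", "n_positive",
        ],
    )
    for col in ("ror", "ci_low", "ci_high"):
        frame[f"{col}_2dp"] = frame[col].round(2)
    return frame
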