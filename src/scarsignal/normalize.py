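"""Primary-suspect drug extraction, name normalization and ATC classing.

Only drugs reported as *primary suspect* (role code 1) count as culprit
evidence.  Raw generic names are canonicalized (lowercased, trimmed,
internal whitespace collapsed) and then passed through a user-supplied
``IngredientMap`` that integrates different forms of the same active
ingredient (e.g. salt forms) — the configurable stand-in for manual
pharmacist curation.  Names can also be mapped to the ``AMBIGUOUS`` marker
to exclude them.  Exclusions (missing generic name, ambiguous, within-report
duplicates) are tallied, never silently dropped.

ATC codes attach per canonical ingredient via ``ATCMap``; the second ATC
level (first three characters, e.g. ``N03``) is the therapeutic-subgroup
granularity used in class summaries.  Ingredients without an ATC entry are
retained as unclassified so report totals are conserved.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._util import percent
from .report_model import AdverseEventReport, DrugRole, ReportSet
from .smq import SMQDefinition, builtin_scar_smq, match_scar_pts

__all__ = [
    "AMBIGUOUS",
    "IngredientMap",
    "ATCMap",
    "CulpritDrug",
    "canonicalize_name",
    "extract_primary_suspect_names",
    "normalize_name",
    "primary_suspect_drugs",
    "build_culprit_list",
    "culprit_counts_per_scope",
]

#: Marker for raw names that cannot be resolved to a single ingredient.
AMBIGUOUS = "__AMBIGUOUS__"

_ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")


def canonicalize_name(raw: str) -> str:
    """Lowercase, trim, collapse internal whitespace."""
    return " ".join(raw.casefold().split())


@dataclass
class IngredientMap:
    """Normalized raw name → canonical ingredient (or ``AMBIGUOUS``).

    Unmapped names pass through as their canonical form (identity fallback).
    """

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.entries.items():
            if key != canonicalize_name(key):
                raise ValueError(f"IngredientMap key {key!r} is not canonical")
            if not value:
                raise ValueError(f"IngredientMap entry for {key!r} is empty")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IngredientMap":
        """Read ``raw_name<TAB>canonical`` rows; ``AMBIGUOUS`` marks exclusions."""
        entries = {}
        for ln in Path(path).read_text(encoding="utf-8").splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            raw, canonical = ln.split("\t")
            entries[canonicalize_name(raw)] = canonical.strip()
        return cls(entries)

    def resolve(self, canonical_raw: str) -> str:
        return self.entries.get(canonical_raw, canonical_raw)


@dataclass
class ATCMap:
    """Canonical ingredient → full 7-character ATC codes (e.g. ``N03AX09``)."""

    entries: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ingredient, codes in self.entries.items():
            for code in codes:
                if not _ATC_RE.match(code):
                    raise ValueError(f"{ingredient!r}: invalid ATC code {code!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ATCMap":
        """Read ``canonical<TAB>atc_code[,atc_code...]`` rows."""
        entries = {}
        for ln in Path(path).read_text(encoding="utf-8").splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            ingredient, codes = ln.split("\t")
            entries[canonicalize_name(ingredient)] = [
                c.strip() for c in codes.split(",") if c.strip()
            ]
        return cls(entries)

    def codes_for(self, ingredient: str) -> list[str]:
        return self.entries.get(ingredient, [])


@dataclass
class CulpritDrug:
    """A drug that is primary suspect in at least one SCAR report."""

    canonical_name: str
    atc_codes: list[str]
    scar_report_ids: set[str]

    @property
    def atc2_classes(self) -> set[str]:
        """Second-level ATC classes (first three characters of each code)."""
        return {code[:3] for code in self.atc_codes}


def extract_primary_suspect_names(
    report: AdverseEventReport,
) -> tuple[list[str], dict[str, int]]:
    """Raw generic names of primary-suspect mentions, plus an exclusion tally.

    Primary-suspect mentions lacking a generic name are counted under
    ``missing_name`` rather than returned.
    """
    names, missing = [], 0
    for mention in report.drugs:
        if mention.role is not DrugRole.PRIMARY_SUSPECT:
            continue
        if mention.generic_name:
            names.append(mention.generic_name)
        else:
            missing += 1
    return names, {"missing_name": missing}


def normalize_name(raw: str, imap: IngredientMap) -> tuple[str | None, str | None]:
    """Resolve a raw name to ``(canonical, None)`` or ``(None, reason)``.

    ``reason`` is ``"ambiguous"`` for names mapped to :data:`AMBIGUOUS`.
    """
    resolved = imap.resolve(canonicalize_name(raw))
    if resolved == AMBIGUOUS:
        return None, "ambiguous"
    return resolved, None


def primary_suspect_drugs(
    report: AdverseEventReport, imap: IngredientMap
) -> tuple[set[str], dict[str, int]]:
    """Distinct canonical primary-suspect ingredients of one report.

    Within-report repeats of the same canonical ingredient collapse to one
    occurrence (the "duplicated" exclusion) and are tallied.
    """
    raw_names, tally = extract_primary_suspect_names(report)
    tally = dict(tally, ambiguous=0, within_report_duplicates=0)
    canonical: set[str] = set()
    for raw in raw_names:
        name, reason = normalize_name(raw, imap)
        if reason is not None:
            tally["ambiguous"] += 1
        elif name in canonical:
            tally["within_report_duplicates"] += 1
        else:
            canonical.add(name)
    return canonical, tally


def build_culprit_list(
    scar_set: ReportSet,
    imap: IngredientMap | None = None,
    atcmap: ATCMap | None = None,
) -> tuple[list[CulpritDrug], dict[str, int]]:
    """Compile the culprit-drug list from a deduplicated SCAR report set.

    Returns drugs sorted by number of SCAR reports (descending, ties by name
    ascending) together with the aggregate exclusion tallies.  Ingredients
    missing from the ATC map keep an empty code list and are counted under
    ``unmapped_atc``.
    """
    imap = imap or IngredientMap()
    atcmap = atcmap or ATCMap()
    totals = Counter()
    report_ids: dict[str, set[str]] = {}
    for report in scar_set:
        names, tally = primary_suspect_drugs(report, imap)
        totals.update(tally)
        for name in names:
            report_ids.setdefault(name, set()).add(report.report_id)

    culprits = [
        CulpritDrug(name, atcmap.codes_for(name), ids)
        for name, ids in report_ids.items()
    ]
    culprits.sort(key=lambda d: (-len(d.scar_report_ids), d.canonical_name))
    tallies = dict(totals)
    tallies["unmapped_atc"] = sum(1 for d in culprits if not d.atc_codes)
    return culprits, tallies


def culprit_counts_per_scope(
    culprits: list[CulpritDrug],
    scar_set: ReportSet,
    smq: SMQDefinition | None = None,
) -> pd.DataFrame:
    """Number of culprit drugs per narrow-PT subgroup, plus the SMQ total row.

    A drug counts in a PT subgroup if it is primary suspect in at least one
    SCAR report matching that PT, so a drug may appear in several subgroups.
    Percentages are of the total culprit count, one decimal, rounded half
    away from zero.  PT rows are sorted by count descending then name; the
    SMQ row (always 100.0% of the culprit list) comes last.
    """
    smq = smq or builtin_scar_smq()
    pts_by_report = {r.report_id: match_scar_pts(r, smq) for r in scar_set}
    drugs_per_pt: dict[str, set[str]] = {pt: set() for pt in smq.pt_names}
    for drug in culprits:
        for rid in drug.scar_report_ids:
            for pt in pts_by_report.get(rid, ()):
                drugs_per_pt[pt].add(drug.canonical_name)

    total = len(culprits)
    rows = [
        {"scope": pt, "n_drugs": len(names), "percent": percent(len(names), total)}
        for pt, names in drugs_per_pt.items()
    ]
    rows.sort(key=lambda r: (-r["n_drugs"], r["scope"]))
    rows.append(
        {"scope": smq.name, "n_drugs": total, "percent": 100.0 if total else 0.0}
    )
    return pd.DataFrame(rows, columns=["scope", "n_drugs", "percent"])
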