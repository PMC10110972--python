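"""Identification of SCAR-related reports via narrow-scope SMQ preferred terms.

A Standardized MedDRA Query (SMQ) groups preferred terms (PTs) around a
clinical concept; the *narrow* scope keeps only PTs highly likely to
represent it.  The built-in definition here is the severe-cutaneous-adverse-
reaction (SCAR) SMQ (code 20000020) with its 18 narrow-scope PTs, spanning
SJS, TEN, DRESS, AGEP and related dermatoses.  A report is SCAR-related iff
at least one of its reaction PTs matches one of the 18 names.

Matching is on the *normalized* PT name — case-insensitive, surrounding
whitespace stripped, internal whitespace collapsed, and hyphen/en-dash
variants unified — because the openFDA reaction field carries PT strings,
not MedDRA codes, and dash conventions drift between sources ("SJS–TEN
overlap" vs "SJS-TEN overlap").  Users may substitute any other SMQ via a
three-column TSV (name, code, scope).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

from .report_model import AdverseEventReport, PTTerm, ReportSet

__all__ = [
    "SCAR_SMQ_CODE",
    "SMQDefinition",
    "normalize_pt_name",
    "builtin_scar_smq",
    "load_smq_tsv",
    "match_scar_pts",
    "filter_scar_reports",
]

SCAR_SMQ_CODE = 20000020

_DASH_RE = re.compile(r"[‐‑‒–—−]")


def normalize_pt_name(name: str) -> str:
    """Canonical form used for PT matching."""
    return " ".join(_DASH_RE.sub("-", name).casefold().split())


@dataclass(frozen=True)
class SMQDefinition:
    """An SMQ restricted to its narrow-scope PT list."""

    name: str
    smq_code: int
    narrow_pts: tuple[PTTerm, ...]
    _lookup: dict[str, str] = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        lookup = {normalize_pt_name(pt.name): pt.name for pt in self.narrow_pts}
        if len(lookup) != len(self.narrow_pts):
            raise ValueError("narrow PT names collide after normalization")
        object.__setattr__(self, "_lookup", lookup)

    @property
    def pt_names(self) -> tuple[str, ...]:
        """Canonical narrow-PT names, in definition order."""
        return tuple(pt.name for pt in self.narrow_pts)

    def canonical_pt(self, reaction: str) -> str | None:
        """Canonical PT name for a reaction string, or None if not in scope."""
        return self._lookup.get(normalize_pt_name(reaction))


@lru_cache(maxsize=1)
def builtin_scar_smq() -> SMQDefinition:
    """The SCAR SMQ (20000020) with its 18 narrow-scope PTs (MedDRA 23.0)."""
    with resources.files("scarsignal.data").joinpath("scar_smq_narrow_pts.tsv").open(
        "r", encoding="utf-8"
    ) as fh:
        smq = _parse_smq_tsv(fh.read(), name="Severe cutaneous adverse reactions (SMQ)",
                             smq_code=SCAR_SMQ_CODE)
    if len(smq.narrow_pts) != 18:
        raise RuntimeError("built-in SCAR SMQ resource must list exactly 18 narrow PTs")
    return smq


def load_smq_tsv(path: str | Path, name: str, smq_code: int) -> SMQDefinition:
    """Load a user-supplied SMQ from a ``name<TAB>code<TAB>scope`` table.

    Only rows with scope ``narrow`` are kept.
    """
    return _parse_smq_tsv(Path(path).read_text(encoding="utf-8"), name, smq_code)


def _parse_smq_tsv(text: str, name: str, smq_code: int) -> SMQDefinition:
    pts = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:  # header row skipped
        pt_name, code, scope = ln.split("\t")
        if scope.strip() == "narrow":
            pts.append(PTTerm(pt_name.strip(), int(code)))
    return SMQDefinition(name=name, smq_code=smq_code, narrow_pts=tuple(pts))


def match_scar_pts(report: AdverseEventReport, smq: SMQDefinition | None = None) -> set[str]:
    """Narrow-PT names (canonical spelling) present among the report's reactions."""
    smq = smq or builtin_scar_smq()
    matched = set()
    for reaction in report.reactions:
        canonical = smq.canonical_pt(reaction)
        if canonical is not None:
            matched.add(canonical)
    return matched


def filter_scar_reports(
    rs: ReportSet, smq: SMQDefinition | None = None
) -> tuple[ReportSet, dict[str, int]]:
    """Split off SCAR-related reports and count reports per narrow PT.

    A report matching k of the 18 PTs contributes 1 to each of the k PT
    counts but only once to the SMQ-level total, which equals
    ``len(scar_set)``.  Expects a deduplicated input.
    """
    smq = smq or builtin_scar_smq()
    counts = {pt: 0 for pt in smq.pt_names}
    scar_reports = []
    for report in rs:
        matched = match_scar_pts(report, smq)
        if matched:
            scar_reports.append(report)
            for pt in matched:
                counts[pt] += 1
    scar_set = ReportSet(
        scar_reports,
        provenance=f"{rs.provenance} | scar({smq.smq_code})",
        skipped_no_reactions=rs.skipped_no_reactions,
    )
    return scar_set, counts
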