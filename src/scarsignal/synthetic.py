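"""Synthetic spontaneous-report generator with known drug→reaction effects.

The generator emulates the structure of openFDA drug-event data — one
primary-suspect drug per report, optional concomitant mentions, multiple
reactions per report, missing generic names, duplicated reports and
realistic demographic marginals — while keeping the drug→reaction
association structure fully known, so downstream disproportionality results
can be checked against ground truth.

Generative model, per report:

1. draw one primary-suspect drug from the catalog (``use_probability``);
2. for every SCAR preferred term p, include p independently with odds
   ``baseline_pt_odds[p] × m(drug, p)``, where the multiplier m comes from
   the configured effects (an SMQ-scope effect multiplies the odds of every
   narrow PT; multipliers default to 1);
3. draw filler (non-SCAR) reactions independently; if no reaction at all was
   drawn, the first filler is added so no report is empty;
4. demographics are drawn independently of drugs and reactions (the ROR
   method performs no adjustment, so no confounding is simulated);
5. with ``missing_name_probability`` the suspect's generic name is blanked
   (the raw product name remains), and with ``duplicate_probability`` an
   exact copy of the report — same report_id — is appended.

Because odds (not probabilities) are multiplied, the report-level odds ratio
of any single PT between the affected drug and the rest of the catalog
equals the configured multiplier exactly; SMQ-level (any narrow PT) effects
are marginals of the model, available from :func:`ground_truth`.
"""

from __future__ import annotations

import datetime as dt
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .report_model import (
    AdverseEventReport,
    DrugMention,
    DrugRole,
    Outcome,
    Reporter,
    ReportSet,
    Sex,
)
from .smq import SMQDefinition, builtin_scar_smq, normalize_pt_name

__all__ = [
    "DrugSpec",
    "EffectSpec",
    "Demographics",
    "SimulationConfig",
    "SMQ_EFFECT_SCOPE",
    "generate_reports",
    "ground_truth",
    "expected_case_counts",
    "default_study_config",
    "load_simulation_config",
]

#: Scope value marking an effect that multiplies the odds of all narrow PTs.
SMQ_EFFECT_SCOPE = "SMQ"


class DrugSpec(BaseModel):
    """A catalog entry: ingredient name, ATC codes, marginal use probability."""

    model_config = ConfigDict(extra="forbid")

    name: str
    atc_codes: list[str] = Field(min_length=1)
    use_probability: float = Field(gt=0, le=1)


class EffectSpec(BaseModel):
    """Ground-truth odds multiplier for one (drug, scope); 1 means null."""

    model_config = ConfigDict(extra="forbid")

    drug: str
    scope: str  # a PT name or SMQ_EFFECT_SCOPE
    odds_multiplier: float = Field(gt=0)


class Demographics(BaseModel):
    """Independent marginal distributions for report covariates."""

    model_config = ConfigDict(extra="forbid")

    sex: dict[str, float] = {"female": 0.55, "male": 0.40, "unknown": 0.05}
    age_mean: float = 58.0
    age_sd: float = 19.0
    age_unknown_probability: float = Field(default=0.15, ge=0, le=1)
    reporter: dict[str, float] = {
        "health_professional": 0.78,
        "consumer_or_lawyer": 0.17,
        "unknown": 0.05,
    }
    country: dict[str, float] = {
        "US": 0.40, "FR": 0.12, "JP": 0.08, "GB": 0.07, "DE": 0.06,
        "CN": 0.05, "IT": 0.04, "ES": 0.04, "CA": 0.03, "AU": 0.03,
        "unknown": 0.08,
    }
    # independent per-outcome probabilities
    outcome: dict[str, float] = {
        "death": 0.10,
        "life_threatening": 0.08,
        "hospitalization": 0.40,
        "disability": 0.03,
        "congenital_anomaly": 0.002,
        "other": 0.35,
    }
    year_range: tuple[int, int] = (2004, 2021)

    @field_validator("sex", "reporter", "country")
    @classmethod
    def _sums_to_one(cls, v: dict[str, float]) -> dict[str, float]:
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("category probabilities must sum to 1")
        if any(p < 0 for p in v.values()):
            raise ValueError("probabilities must be non-negative")
        return v


class SimulationConfig(BaseModel):
    """Full specification of one synthetic study."""

    model_config = ConfigDict(extra="forbid")

    n_reports: int = Field(ge=0)
    catalog: list[DrugSpec] = Field(min_length=1)
    baseline_pt_odds: dict[str, float]
    filler_reactions: list[tuple[str, float]] = Field(min_length=1)
    effects: list[EffectSpec] = []
    missing_name_probability: float = Field(default=0.0, ge=0, le=1)
    duplicate_probability: float = Field(default=0.0, ge=0, le=1)
    concomitant_probability: float = Field(default=0.0, ge=0, le=1)
    demographics: Demographics = Demographics()
    seed: int = 0

    @field_validator("baseline_pt_odds")
    @classmethod
    def _positive_odds(cls, v: dict[str, float]) -> dict[str, float]:
        for pt, odds in v.items():
            if odds <= 0:
                raise ValueError(f"baseline_pt_odds[{pt!r}] must be positive")
        return v

    @field_validator("filler_reactions")
    @classmethod
    def _filler_probs(cls, v):
        for name, p in v:
            if not 0 <= p <= 1:
                raise ValueError(f"filler_reactions[{name!r}] probability out of [0,1]")
        return v

    @model_validator(mode="after")
    def _cross_checks(self) -> "SimulationConfig":
        if abs(sum(d.use_probability for d in self.catalog) - 1.0) > 1e-9:
            raise ValueError("catalog use_probabilities must sum to 1")
        names = {d.name for d in self.catalog}
        if len(names) != len(self.catalog):
            raise ValueError("catalog drug names must be unique")
        pts = set(self.baseline_pt_odds)
        for eff in self.effects:
            if eff.drug not in names:
                raise ValueError(f"effects: drug {eff.drug!r} not in catalog")
            if eff.scope != SMQ_EFFECT_SCOPE and eff.scope not in pts:
                raise ValueError(
                    f"effects: scope {eff.scope!r} not in baseline_pt_odds"
                )
        return self


def _multiplier_matrix(config: SimulationConfig, smq: SMQDefinition) -> np.ndarray:
    """(n_drugs, n_pts) odds multipliers implied by the configured effects."""
    pt_names = list(config.baseline_pt_odds)
    narrow = {normalize_pt_name(p) for p in smq.pt_names}
    in_smq = np.array([normalize_pt_name(p) in narrow for p in pt_names])
    drug_index = {d.name: i for i, d in enumerate(config.catalog)}
    m = np.ones((len(config.catalog), len(pt_names)))
    pt_index = {p: j for j, p in enumerate(pt_names)}
    for eff in config.effects:
        i = drug_index[eff.drug]
        if eff.scope == SMQ_EFFECT_SCOPE:
            m[i, in_smq] *= eff.odds_multiplier
        else:
            m[i, pt_index[eff.scope]] *= eff.odds_multiplier
    return m


def _grouped_columns(mask: np.ndarray) -> list[np.ndarray]:
    """Row-wise true-column lists of a boolean matrix, cheaply."""
    rows, cols = np.nonzero(mask)
    boundaries = np.searchsorted(rows, np.arange(1, mask.shape[0]))
    return np.split(cols, boundaries)


def generate_reports(
    config: SimulationConfig, smq: SMQDefinition | None = None
) -> ReportSet:
    """Generate a synthetic ReportSet; identical config and seed → identical output."""
    smq = smq or builtin_scar_smq()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    if n == 0:
        return ReportSet([], provenance=f"synthetic(seed={config.seed})")

    catalog = config.catalog
    use_p = np.array([d.use_probability for d in catalog])
    use_p = use_p / use_p.sum()  # guard rounding drift
    drug_idx = rng.choice(len(catalog), size=n, p=use_p)

    pt_names = list(config.baseline_pt_odds)
    baseline = np.array([config.baseline_pt_odds[p] for p in pt_names])
    multipliers = _multiplier_matrix(config, smq)
    odds = baseline[None, :] * multipliers[drug_idx]
    pt_draws = rng.random((n, len(pt_names))) < odds / (1.0 + odds)

    filler_names = [name for name, _ in config.filler_reactions]
    filler_p = np.array([p for _, p in config.filler_reactions])
    filler_draws = rng.random((n, len(filler_names))) < filler_p[None, :]

    missing_mask = rng.random(n) < config.missing_name_probability
    concomitant_mask = rng.random(n) < config.concomitant_probability
    concomitant_idx = rng.choice(len(catalog), size=n, p=use_p)
    duplicate_mask = rng.random(n) < config.duplicate_probability

    demo = config.demographics
    sex_levels = list(demo.sex)
    sex_draw = rng.choice(len(sex_levels), size=n, p=list(demo.sex.values()))
    reporter_levels = list(demo.reporter)
    reporter_draw = rng.choice(
        len(reporter_levels), size=n, p=list(demo.reporter.values())
    )
    country_levels = list(demo.country)
    country_draw = rng.choice(
        len(country_levels), size=n, p=list(demo.country.values())
    )
    age_draw = np.clip(rng.normal(demo.age_mean, demo.age_sd, size=n), 0.0, 119.0)
    age_unknown = rng.random(n) < demo.age_unknown_probability

    outcome_levels = [Outcome(k) for k in demo.outcome]
    outcome_p = np.array(list(demo.outcome.values()))
    outcome_draws = rng.random((n, len(outcome_levels))) < outcome_p[None, :]

    # reporting volume grows over the years, mirroring real spontaneous data
    y0, y1 = demo.year_range
    year_weights = (np.arange(y0, y1 + 1) - y0 + 1.0) ** 1.5
    years = y0 + rng.choice(y1 - y0 + 1, size=n, p=year_weights / year_weights.sum())
    day_of_year = rng.integers(0, 365, size=n)

    pt_cols = _grouped_columns(pt_draws)
    filler_cols = _grouped_columns(filler_draws)
    outcome_cols = _grouped_columns(outcome_draws)

    sex_enum = [Sex(s) for s in sex_levels]
    reporter_enum = [Reporter(r) for r in reporter_levels]

    reports: list[AdverseEventReport] = []
    for i in range(n):
        reactions = [pt_names[j] for j in pt_cols[i]]
        reactions += [filler_names[j] for j in filler_cols[i]]
        if not reactions:
            reactions = [filler_names[0]]  # guaranteed filler

        suspect = catalog[drug_idx[i]]
        mentions = [
            DrugMention(
                role=DrugRole.PRIMARY_SUSPECT,
                generic_name=None if missing_mask[i] else suspect.name,
                raw_product_name=suspect.name.upper(),
            )
        ]
        if concomitant_mask[i]:
            other = catalog[concomitant_idx[i]]
            mentions.append(
                DrugMention(
                    role=DrugRole.CONCOMITANT,
                    generic_name=other.name,
                    raw_product_name=other.name.upper(),
                )
            )

        country = country_levels[country_draw[i]]
        reports.append(
            AdverseEventReport(
                report_id=f"R{i + 1:07d}",
                reactions=reactions,
                drugs=mentions,
                receive_date=dt.date(int(years[i]), 1, 1)
                + dt.timedelta(days=int(day_of_year[i])),
                reporter=reporter_enum[reporter_draw[i]],
                country=None if country == "unknown" else country,
                sex=sex_enum[sex_draw[i]],
                age_years=None if age_unknown[i] else float(round(age_draw[i], 1)),
                outcomes={outcome_levels[j] for j in outcome_cols[i]},
            )
        )

    # exact copies (same report_id) appended after the base reports
    for i in np.flatnonzero(duplicate_mask):
        src = reports[i]
        reports.append(
            AdverseEventReport(
                report_id=src.report_id,
                reactions=list(src.reactions),
                drugs=list(src.drugs),
                receive_date=src.receive_date,
                reporter=src.reporter,
                country=src.country,
                sex=src.sex,
                age_years=src.age_years,
                outcomes=set(src.outcomes),
            )
        )

    return ReportSet(reports, provenance=f"synthetic(seed={config.seed})")


def _scar_pt_mask(config: SimulationConfig, smq: SMQDefinition) -> np.ndarray:
    narrow = {normalize_pt_name(p) for p in smq.pt_names}
    return np.array(
        [normalize_pt_name(p) in narrow for p in config.baseline_pt_odds]
    )


def _marginal_smq_odds(baseline: np.ndarray, mult: np.ndarray) -> float:
    """Odds of 'any narrow PT present' under independent per-PT Bernoulli draws."""
    p_none = np.prod(1.0 / (1.0 + baseline * mult))
    p_any = 1.0 - p_none
    return p_any / p_none


def ground_truth(
    config: SimulationConfig, smq: SMQDefinition | None = None
) -> pd.DataFrame:
    """One row per (drug, scope) over catalog × (18 narrow PTs + SMQ).

    PT rows carry the exact configured odds multiplier (the per-PT report
    odds ratio of the generative model).  The SMQ row reports the *marginal*
    odds ratio of "any narrow PT" relative to a multiplier-1 drug, computed
    by enumeration over the model; its ``induced`` flag is True when that
    value is model-derived (any PT odds differ from baseline) rather than a
    trivially null 1.
    """
    smq = smq or builtin_scar_smq()
    pt_names = list(config.baseline_pt_odds)
    scar_mask = _scar_pt_mask(config, smq)
    baseline = np.array([config.baseline_pt_odds[p] for p in pt_names])[scar_mask]
    multipliers = _multiplier_matrix(config, smq)[:, scar_mask]
    scar_names = [p for p, keep in zip(pt_names, scar_mask) if keep]
    pt_mult = {p: j for j, p in enumerate(scar_names)}

    null_odds = _marginal_smq_odds(baseline, np.ones_like(baseline))
    rows = []
    for i, drug in enumerate(config.catalog):
        m = multipliers[i]
        smq_or = _marginal_smq_odds(baseline, m) / null_odds
        rows.append(
            {
                "drug": drug.name,
                "scope": SMQ_EFFECT_SCOPE,
                "odds_multiplier": smq_or,
                "induced": bool(np.any(m != 1.0)),
            }
        )
        for pt in smq.pt_names:
            j = pt_mult.get(pt)
            value = float(m[j]) if j is not None else 1.0
            rows.append(
                {"drug": drug.name, "scope": pt, "odds_multiplier": value,
                 "induced": False}
            )
    return pd.DataFrame(rows, columns=["drug", "scope", "odds_multiplier", "induced"])


def expected_case_counts(
    config: SimulationConfig, smq: SMQDefinition | None = None
) -> pd.DataFrame:
    """Expected cell-a count per (drug, scope) under the generative model.

    Counts refer to the deduplicated set (duplicates share report ids, so
    they vanish again downstream).
    """
    smq = smq or builtin_scar_smq()
    pt_names = list(config.baseline_pt_odds)
    scar_mask = _scar_pt_mask(config, smq)
    baseline = np.array([config.baseline_pt_odds[p] for p in pt_names])[scar_mask]
    multipliers = _multiplier_matrix(config, smq)[:, scar_mask]
    scar_names = [p for p, keep in zip(pt_names, scar_mask) if keep]
    pt_col = {p: j for j, p in enumerate(scar_names)}

    rows = []
    for i, drug in enumerate(config.catalog):
        n_drug = config.n_reports * drug.use_probability
        odds = baseline * multipliers[i]
        p = odds / (1.0 + odds)
        p_any = 1.0 - np.prod(1.0 - p)
        rows.append({"drug": drug.name, "scope": SMQ_EFFECT_SCOPE,
                     "expected_a": n_drug * p_any})
        for pt in smq.pt_names:
            j = pt_col.get(pt)
            rows.append(
                {"drug": drug.name, "scope": pt,
                 "expected_a": n_drug * float(p[j]) if j is not None else 0.0}
            )
    return pd.DataFrame(rows, columns=["drug", "scope", "expected_a"])


# --------------------------------------------------------------------------
# default study conditions
# --------------------------------------------------------------------------

_DEFAULT_CATALOG: list[tuple[str, str, float]] = [
    # (ingredient, ATC code, use probability)
    ("lamotrigine", "N03AX09", 0.055),
    ("carbamazepine", "N03AF01", 0.050),
    ("phenytoin", "N03AB02", 0.045),
    ("allopurinol", "M04AA01", 0.055),
    ("acetaminophen", "N02BE01", 0.075),
    ("sulfamethoxazole/trimethoprim", "J01EE01", 0.050),
    ("amoxicillin", "J01CA04", 0.065),
    ("ceftriaxone", "J01DD04", 0.045),
    ("vancomycin", "J01XA01", 0.040),
    ("furosemide", "C03CA01", 0.050),
    ("ibuprofen", "M01AE01", 0.065),
    ("naproxen", "M01AE02", 0.045),
    ("omeprazole", "A02BC01", 0.055),
    ("pembrolizumab", "L01FF02", 0.040),
    ("nivolumab", "L01FF01", 0.040),
    ("vemurafenib", "L01EC01", 0.030),
    ("metformin", "A10BA02", 0.060),
    ("lisinopril", "C09AA03", 0.050),
    ("amlodipine", "C08CA01", 0.045),
    ("atorvastatin", "C10AA05", 0.040),
]

# Baseline per-report odds of each narrow PT; SJS/TEN/DRESS most frequent,
# overall SCAR fraction ≈ 1.5% of reports (rare-event regime).
_DEFAULT_BASELINE_ODDS: dict[str, float] = {
    "Stevens–Johnson syndrome": 0.0030,
    "Toxic epidermal necrolysis": 0.0018,
    "Drug reaction with eosinophilia and systemic symptoms": 0.0016,
    "Erythema multiforme": 0.0014,
    "Dermatitis exfoliative": 0.0012,
    "Dermatitis bullous": 0.0010,
    "Toxic skin eruption": 0.0009,
    "Skin necrosis": 0.0008,
    "Exfoliative rash": 0.0008,
    "Acute generalized exanthematous pustulosis": 0.0007,
    "Dermatitis exfoliative generalized": 0.0006,
    "Cutaneous vasculitis": 0.0006,
    "Epidermal necrosis": 0.0005,
    "Oculomucocutaneous syndrome": 0.0005,
    "SJS–TEN overlap": 0.0004,
    "Bullous hemorrhagic dermatosis": 0.0004,
    "Target skin lesion": 0.0004,
    "Erythrodermic atopic dermatitis": 0.0004,
}

_DEFAULT_FILLERS: list[tuple[str, float]] = [
    ("Drug ineffective", 0.20),
    ("Nausea", 0.18),
    ("Headache", 0.15),
    ("Fatigue", 0.12),
    ("Pyrexia", 0.10),
    ("Diarrhoea", 0.10),
    ("Dizziness", 0.08),
    ("Vomiting", 0.08),
    ("Pruritus", 0.05),
    ("Rash", 0.05),
]


def default_study_config(
    n_reports: int = 200_000,
    seed: int = 0,
    effects: Sequence[EffectSpec] | Sequence[dict] = (),
) -> SimulationConfig:
    """The package's reference synthetic study.

    Twenty-drug catalog with realistic ATC classes, rare-event baseline odds
    for all 18 narrow PTs, 5% missing generic names, 2% duplicated reports,
    30% concomitant decorations, and demographic marginals matching large
    spontaneous-report databases (predominantly health-professional
    reporters, more female than male patients, ages centred in the sixth and
    seventh decades, ~10% fatal outcomes).
    """
    effects = [e if isinstance(e, EffectSpec) else EffectSpec(**e) for e in effects]
    return SimulationConfig(
        n_reports=n_reports,
        catalog=[
            DrugSpec(name=name, atc_codes=[atc], use_probability=p)
            for name, atc, p in _DEFAULT_CATALOG
        ],
        baseline_pt_odds=dict(_DEFAULT_BASELINE_ODDS),
        filler_reactions=list(_DEFAULT_FILLERS),
        effects=effects,
        missing_name_probability=0.05,
        duplicate_probability=0.02,
        concomitant_probability=0.30,
        seed=seed,
    )


def load_simulation_config(path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML (or JSON) file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return SimulationConfig(**data)


def default_atc_map() -> dict[str, list[str]]:
    """Ingredient → ATC codes table implied by the default catalog."""
    return {name: [atc] for name, atc, _ in _DEFAULT_CATALOG}
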