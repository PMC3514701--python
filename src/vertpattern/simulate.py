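"""Seeded synthetic-cohort generator with the study's statistical structure.

The generator draws a latent pattern class for each subject from an
eight-class multinomial, synthesises a concrete vertebral column that the
rule engine classifies back to exactly that class, and draws per-organ-system
malformation events from Bernoulli distributions whose log-odds are linear
in the severity score.  Sex and gestational age are generated with no effect
on the pattern, matching the study population.

Defaults encode the published cohort: the class frequencies observed among
the 1,062 analysable columns, the published per-system severity slopes, and
intercepts calibrated by root-finding so the expected case count per system
matches the published count at the reference cohort size.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .columns import (
    PatternClass,
    RibObservation,
    RibState,
    Side,
    Vertebra,
    VertebralColumn,
    severity,
    shift_flags,
)
from .malformations import ORGAN_SYSTEMS

#: Default eight-class frequencies (fractions).  The published composite
#: frequencies are split as documented in docs/methods.md: R 20.6 %,
#: LS 3.4 %, TL & TL_LS 8.6 % split evenly, C-T-involving 67.4 % of which
#: CT_TL & CT_TL_LS are 33.4 % and CT_TL_LS alone 10.6 %.
DEFAULT_PATTERN_PROBS: dict[str, float] = {
    "R": 0.206,
    "LS": 0.034,
    "TL": 0.043,
    "TL_LS": 0.043,
    "CT": 0.170,
    "CT_LS": 0.170,
    "CT_TL": 0.228,
    "CT_TL_LS": 0.106,
}

#: Published severity slope (log-odds per scale unit) and case count per
#: organ system, at the reference cohort of 1,062 analysable subjects.
DEFAULT_SYSTEM_PARAMS: dict[str, tuple[float, int]] = {
    "BP": (0.12, 68),
    "CV": (0.12, 216),
    "CF": (0.36, 64),
    "DS": (0.19, 110),
    "LD": (0.17, 146),
    "MS": (0.11, 28),
    "NS": (0.07, 121),
    "SK": (0.31, 115),
    "UG": (0.11, 168),
    "VBW": (0.18, 23),
}

#: Terms materialised for an event in each system (all map primarily to
#: that system and are never demoted by the secondary rules without context).
SYSTEM_TERMS: dict[str, list[str]] = {
    "BP": ["lung_hypoplasia", "bronchial_atresia", "lung_lobation_defect"],
    "CV": ["ventricular_septal_defect", "transposition_great_arteries",
           "hypoplastic_left_heart", "heterotaxy"],
    "CF": ["cleft_lip", "cleft_palate", "ear_anomaly", "micrognathia"],
    "DS": ["TE_fistula", "duodenal_atresia", "anal_atresia", "intestinal_malrotation"],
    "LD": ["limb_reduction", "polydactyly", "syndactyly"],
    "MS": ["diaphragmatic_hernia", "muscular_hypoplasia"],
    "NS": ["holoprosencephaly", "anencephaly", "spina_bifida", "hydrocephaly"],
    "SK": ["skeletal_dysplasia", "hemivertebrae", "fused_ribs", "vertebral_fusion"],
    "UG": ["renal_agenesis", "hydronephrosis", "hypospadias"],
    "VBW": ["omphalocele", "gastroschisis"],
}

PATTERN_ORDER = [p.value for p in PatternClass]


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """All tunable knobs of the cohort generator.

    Probabilities that shape rib synthesis within a class (laterality,
    rudimentary-versus-absent, anterior-versus-posterior realisation) change
    the morphology drawn but never the class, which is exact by
    construction.
    """

    n_subjects: int = 1062
    seed: int = 0
    pattern_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_PROBS)
    )
    system_params: dict[str, tuple[float, int]] = field(
        default_factory=lambda: dict(DEFAULT_SYSTEM_PARAMS)
    )
    #: cohort size at which the published per-system case counts were observed
    reference_n: int = 1062
    #: per-system probability of a "non-available" score (maceration /
    #: no autopsy), independent across systems
    missing_prob: float = 0.10
    #: P(both sides affected) for cervical / rudimentary rib synthesis
    bilateral_prob: float = 0.5
    #: P(rudimentary rather than absent) for first/twelfth-rib anomalies
    rudimentary_vs_absent_prob: float = 0.5
    #: share of C-T shifts realised as rudimentary/absent first ribs
    #: (published: 9.8 % of all cases within the 67.4 % C-T group)
    ct_posterior_prob: float = 0.098 / 0.674
    #: share of T-L shifts realised as lumbar ribs ("usually" twelfth-rib)
    tl_posterior_prob: float = 0.10
    #: within anterior C-T shifts: P(enlarged transverse process form) and
    #: P(full-length cervical rib, the rare full posteriorisation)
    c7_tp_enlarged_prob: float = 0.10
    c7_full_rib_prob: float = 0.02
    #: L-S realisation: flagged transitional vertebra vs changed count
    ls_flag_prob: float = 0.25
    male_prob: float = 589 / 1049
    ga_mean_weeks: float = 26.6
    ga_sd_weeks: float = 10.4
    ga_range_weeks: tuple[float, float] = (13.0, 92.0)

    def validate(self) -> None:
        probs = np.array([self.pattern_probs.get(p, 0.0) for p in PATTERN_ORDER])
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"pattern_probs must be a simplex over {PATTERN_ORDER}; sum={probs.sum()}"
            )
        for name in ("missing_prob", "bilateral_prob", "rudimentary_vs_absent_prob",
                     "ct_posterior_prob", "tl_posterior_prob", "ls_flag_prob",
                     "c7_tp_enlarged_prob", "c7_full_rib_prob", "male_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be >= 0")

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown generator config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def severity_distribution(pattern_probs: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    """Severity scale values and their probabilities under a class simplex."""
    values = np.array([severity(PatternClass(p)) for p in PATTERN_ORDER], dtype=float)
    probs = np.array([pattern_probs.get(p, 0.0) for p in PATTERN_ORDER])
    return values, probs


def calibrate_intercept(
    slope: float,
    target_count: float,
    reference_n: int,
    pattern_probs: dict[str, float] | None = None,
) -> float:
    """Solve for the logistic intercept giving the target expected case count.

    Finds ``a`` such that ``sum_s pi(s) * expit(a + slope*s) * reference_n``
    equals ``target_count``, where ``pi`` is the severity distribution
    implied by the pattern simplex.
    """
    values, probs = severity_distribution(pattern_probs or DEFAULT_PATTERN_PROBS)
    target_rate = target_count / reference_n
    if not 0.0 < target_rate < 1.0:
        raise ConfigError(f"target rate {target_rate} outside (0, 1)")

    def gap(a: float) -> float:
        return float(probs @ expit(a + slope * values)) - target_rate

    return brentq(gap, -50.0, 50.0, xtol=1e-12)


# ---------------------------------------------------------------------------
# morphology synthesis


def _rib(side: Side, state: RibState = RibState.ABSENT,
         ratio: float | None = None, tp_exceeds: bool = False) -> RibObservation:
    return RibObservation(side=side, state=state, length_ratio=ratio,
                          tp_exceeds_t1=tp_exceeds)


def _sides(rng: np.random.Generator, bilateral_prob: float) -> list[Side]:
    if rng.random() < bilateral_prob:
        return [Side.LEFT, Side.RIGHT]
    return [Side(rng.choice([Side.LEFT.value, Side.RIGHT.value]))]


def _short_ratio(rng: np.random.Generator) -> float:
    # strictly below the half-length threshold
    return float(rng.uniform(0.05, 0.45))


def _long_ratio(rng: np.random.Generator) -> float:
    return float(rng.uniform(0.55, 1.0))


def sample_pattern(config: GeneratorConfig, rng: np.random.Generator) -> PatternClass:
    """One multinomial draw from the configured class simplex."""
    probs = [config.pattern_probs.get(p, 0.0) for p in PATTERN_ORDER]
    return PatternClass(rng.choice(PATTERN_ORDER, p=probs))


def synthesize_morphology(
    pattern: PatternClass,
    config: GeneratorConfig,
    rng: np.random.Generator,
    subject_id: str = "synthetic",
) -> VertebralColumn:
    """Emit a concrete column whose classification is exactly ``pattern``.

    Within the class, laterality, rudimentary-versus-absent ribs and the
    anterior-versus-posterior realisation of each shift are randomised.
    """
    ct, tl, ls = shift_flags(PatternClass(pattern))

    n_lumbar = 5
    ls_flag = False
    if ls:
        if rng.random() < config.ls_flag_prob:
            ls_flag = True  # transitional lumbo-sacral vertebra, count unchanged
        else:
            n_lumbar = int(rng.choice([4, 6]))

    tl_posterior = tl and rng.random() < config.tl_posterior_prob
    presacral = 7 + 12 + n_lumbar

    # regular scaffold: full thoracic ribs at ordinals 8..19
    special: dict[int, tuple[RibObservation, RibObservation]] = {}

    def set_ribs(ordinal: int, per_side: dict[Side, RibObservation]) -> None:
        default = {
            Side.LEFT: _default_rib(ordinal, Side.LEFT),
            Side.RIGHT: _default_rib(ordinal, Side.RIGHT),
        }
        default.update(per_side)
        special[ordinal] = (default[Side.LEFT], default[Side.RIGHT])

    def _default_rib(ordinal: int, side: Side) -> RibObservation:
        if 8 <= ordinal <= 19:
            return _rib(side, RibState.PRESENT, 1.0)
        return _rib(side)

    if ct:
        if rng.random() < config.ct_posterior_prob:
            # rudimentary or absent first thoracic rib
            ribs = {}
            for side in _sides(rng, config.bilateral_prob):
                if rng.random() < config.rudimentary_vs_absent_prob:
                    ribs[side] = _rib(side, RibState.PRESENT, _short_ratio(rng))
                else:
                    ribs[side] = _rib(side, RibState.ABSENT)
            set_ribs(8, ribs)
        else:
            u = rng.random()
            ribs = {}
            for side in _sides(rng, config.bilateral_prob):
                if u < config.c7_tp_enlarged_prob:
                    ribs[side] = _rib(side, RibState.TP_ENLARGED, tp_exceeds=True)
                elif u < config.c7_tp_enlarged_prob + config.c7_full_rib_prob:
                    ribs[side] = _rib(side, RibState.PRESENT, _long_ratio(rng))
                else:
                    ribs[side] = _rib(side, RibState.PRESENT, _short_ratio(rng))
            set_ribs(7, ribs)

    if tl:
        if tl_posterior:
            # lumbar rib on the vertebra caudal to the twelve thoracic ones
            ribs = {}
            for side in _sides(rng, config.bilateral_prob):
                ratio = _long_ratio(rng) if rng.random() < 0.5 else _short_ratio(rng)
                ribs[side] = _rib(side, RibState.PRESENT, ratio)
            set_ribs(20, ribs)
        else:
            ribs = {}
            for side in _sides(rng, config.bilateral_prob):
                if rng.random() < config.rudimentary_vs_absent_prob:
                    ribs[side] = _rib(side, RibState.PRESENT, _short_ratio(rng))
                else:
                    ribs[side] = _rib(side, RibState.ABSENT)
            set_ribs(19, ribs)

    vertebrae = []
    for i in range(1, presacral + 1):
        ribs_pair = special.get(i) or (_default_rib(i, Side.LEFT), _default_rib(i, Side.RIGHT))
        vertebrae.append(
            Vertebra(
                ordinal=i,
                ribs=ribs_pair,
                ls_transitional=(ls_flag and i == presacral),
            )
        )
    return VertebralColumn(subject_id=subject_id, vertebrae=vertebrae)


# ---------------------------------------------------------------------------
# malformation events and cohort assembly


def sample_malformations(
    severity_value: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    subject_id: str = "synthetic",
) -> tuple[dict[str, int], dict[str, bool], list[dict]]:
    """Draw latent events, availability and observed finding rows for one subject.

    Returns ``(events, availability, finding_rows)`` where ``events`` holds
    the latent per-system Bernoulli indicators (before missingness) and
    ``finding_rows`` only the observable findings (available systems).
    """
    events: dict[str, int] = {}
    availability: dict[str, bool] = {}
    rows: list[dict] = []
    for sys in ORGAN_SYSTEMS:
        slope, target = config.system_params.get(sys, (0.0, 0))
        if target > 0:
            a = _cached_intercept(config, sys)
            p = float(expit(a + slope * severity_value))
        else:
            p = 0.0
        event = int(rng.random() < p)
        events[sys] = event
        available = rng.random() >= config.missing_prob
        availability[sys] = available
        if event and available:
            terms = SYSTEM_TERMS[sys]
            n_terms = 1 + int(rng.random() < 0.3)
            for term in rng.choice(terms, size=min(n_terms, len(terms)), replace=False):
                rows.append(
                    {"subject_id": subject_id, "term": str(term), "raw_system": sys,
                     "cause_context": ""}
                )
    return events, availability, rows


_INTERCEPT_CACHE: dict[tuple, dict[str, float]] = {}


def _cached_intercept(config: GeneratorConfig, system: str) -> float:
    key = (
        tuple(sorted(config.pattern_probs.items())),
        tuple(sorted(config.system_params.items())),
        config.reference_n,
    )
    per_system = _INTERCEPT_CACHE.setdefault(key, {})
    if system not in per_system:
        slope, target = config.system_params[system]
        per_system[system] = calibrate_intercept(
            slope, target, config.reference_n, config.pattern_probs
        )
    return per_system[system]


@dataclass
class RecoveryResult:
    """Monte-Carlo parameter-recovery summary for one outcome."""

    generating_slope: float
    intercept: float
    mean_slope: float
    mc_se: float
    slopes: np.ndarray
    n_replicates: int
    n_subjects: int


def slope_recovery(
    slope: float,
    target_count: float,
    n_replicates: int = 200,
    n_subjects: int = 1062,
    seed: int = 0,
    pattern_probs: dict[str, float] | None = None,
) -> RecoveryResult:
    """Recover a generating severity slope by repeated simulation + IRLS fit.

    Each replicate draws severities from the pattern multinomial, draws the
    binary outcome from the logistic model with the given slope and an
    intercept calibrated to the target case count, and refits the logit GLM.
    The Monte-Carlo standard error is the replicate SD of the estimate
    divided by sqrt(n_replicates).
    """
    from .glm import fit_severity_glm

    probs = pattern_probs or DEFAULT_PATTERN_PROBS
    values, weights = severity_distribution(probs)
    a = calibrate_intercept(slope, target_count, n_subjects, probs)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20200717]))
    slopes = np.empty(n_replicates)
    for i in range(n_replicates):
        s = rng.choice(values, p=weights, size=n_subjects)
        y = (rng.random(n_subjects) < expit(a + slope * s)).astype(float)
        slopes[i] = fit_severity_glm(y, s).coef_of("severity")
    return RecoveryResult(
        generating_slope=slope,
        intercept=a,
        mean_slope=float(slopes.mean()),
        mc_se=float(slopes.std(ddof=1) / np.sqrt(n_replicates)),
        slopes=slopes,
        n_replicates=n_replicates,
        n_subjects=n_subjects,
    )


@dataclass
class CohortTables:
    """Generated cohort: long morphology table, findings table, truth table."""

    morphology: pd.DataFrame
    findings: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig


def _morphology_rows(column: VertebralColumn) -> list[dict]:
    rows = []
    for v in column.vertebrae:
        for rib in v.ribs:
            rows.append(
                {
                    "subject_id": column.subject_id,
                    "vertebra_ordinal": v.ordinal,
                    "side": rib.side.value,
                    "rib_state": rib.state.value,
                    "length_ratio": "" if rib.length_ratio is None else rib.length_ratio,
                    "tp_exceeds_t1": int(rib.tp_exceeds_t1),
                    "sacral_attached": int(v.sacral_attached),
                    "ls_transitional_flag": int(v.ls_transitional),
                    "quality": column.quality.value,
                }
            )
    return rows


def generate_columns(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[tuple[PatternClass, VertebralColumn]]:
    """Draw latent classes and synthesise one column per subject."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    probs = [config.pattern_probs.get(p, 0.0) for p in PATTERN_ORDER]
    classes = rng.choice(PATTERN_ORDER, p=probs, size=config.n_subjects)
    out = []
    for i, cls in enumerate(classes):
        pattern = PatternClass(cls)
        col = synthesize_morphology(pattern, config, rng, subject_id=f"S{i:05d}")
        out.append((pattern, col))
    return out


def generate_cohort(config: GeneratorConfig) -> CohortTables:
    """Full cohort: morphology + findings CSV-shaped tables and a truth table."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_morph, rng_malf, rng_demo = (np.random.default_rng(s) for s in root.spawn(3))

    pairs = generate_columns(config, rng_morph)

    morph_rows: list[dict] = []
    finding_rows: list[dict] = []
    truth_rows: list[dict] = []

    n = config.n_subjects
    sexes = np.where(rng_demo.random(n) < config.male_prob, "M", "F") if n else np.array([])
    lo, hi = config.ga_range_weeks
    a = (lo - config.ga_mean_weeks) / config.ga_sd_weeks
    b = (hi - config.ga_mean_weeks) / config.ga_sd_weeks
    ga = (
        truncnorm.rvs(a, b, loc=config.ga_mean_weeks, scale=config.ga_sd_weeks,
                      size=n, random_state=rng_demo)
        if n
        else np.array([])
    )

    for i, (pattern, column) in enumerate(pairs):
        sev = severity(pattern)
        morph_rows.extend(_morphology_rows(column))
        events, availability, rows = sample_malformations(
            sev, config, rng_malf, subject_id=column.subject_id
        )
        finding_rows.extend(
            {**r, "autopsy_available": 1,
             **{f"avail_{s}": int(availability[s]) for s in ORGAN_SYSTEMS}}
            for r in rows
        )
        if not rows:
            finding_rows.append(
                {"subject_id": column.subject_id, "term": "", "raw_system": "",
                 "cause_context": "", "autopsy_available": 1,
                 **{f"avail_{s}": int(availability[s]) for s in ORGAN_SYSTEMS}}
            )
        truth_rows.append(
            {
                "subject_id": column.subject_id,
                "pattern": pattern.value,
                "severity": sev,
                "sex": sexes[i],
                "gestational_age_weeks": round(float(ga[i]), 2),
                **{f"event_{s}": events[s] for s in ORGAN_SYSTEMS},
                **{f"avail_{s}": int(availability[s]) for s in ORGAN_SYSTEMS},
            }
        )

    morph_cols = ["subject_id", "vertebra_ordinal", "side", "rib_state", "length_ratio",
                  "tp_exceeds_t1", "sacral_attached", "ls_transitional_flag", "quality"]
    find_cols = ["subject_id", "term", "raw_system", "cause_context", "autopsy_available",
                 *[f"avail_{s}" for s in ORGAN_SYSTEMS]]
    truth_cols = ["subject_id", "pattern", "severity", "sex", "gestational_age_weeks",
                  *[f"event_{s}" for s in ORGAN_SYSTEMS],
                  *[f"avail_{s}" for s in ORGAN_SYSTEMS]]
    return CohortTables(
        morphology=pd.DataFrame(morph_rows, columns=morph_cols),
        findings=pd.DataFrame(finding_rows, columns=find_cols),
        truth=pd.DataFrame(truth_rows, columns=truth_cols),
        config=config,
    )
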