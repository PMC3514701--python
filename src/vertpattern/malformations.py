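"""Malformation coding: primary/secondary attribution, germ layers, processes.

Autopsy findings are recorded as controlled-vocabulary terms.  Each term has
one primary organ system; a handful of causal rules demote specific findings
to secondary status so that no defect is counted in two systems.  Germ-layer
and morphogenetic-process involvement is derived from the coding map through
the primary findings only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import yaml

ORGAN_SYSTEMS = ["BP", "CV", "CF", "DS", "LD", "MS", "NS", "SK", "UG", "VBW"]
GERM_LAYERS = ["endoderm", "mesoderm", "ectoderm"]
PROCESSES = ["midline", "neural_crest", "left_right", "segmentation"]

#: context findings that render lung hypoplasia secondary
LUNG_HYPOPLASIA_CAUSES = {"skeletal_dysplasia", "diaphragmatic_hernia", "oligohydramnion"}
HYPOXIC_CONTEXT = "hypoxic_stress"


class SystemStatus(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    NON_AVAILABLE = "non_available"


class CodingError(ValueError):
    pass


@dataclass(frozen=True)
class Finding:
    """One autopsy finding for one subject."""

    subject_id: str
    term: str
    raw_system: str = ""
    cause_context: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.raw_system and self.raw_system not in ORGAN_SYSTEMS:
            raise CodingError(f"unknown organ system {self.raw_system!r}")
        object.__setattr__(self, "cause_context", frozenset(self.cause_context))


@dataclass(frozen=True)
class TermEntry:
    primary_system: str
    secondary_systems: frozenset[str] = frozenset()
    germ_layers: frozenset[str] = frozenset()
    processes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.primary_system not in ORGAN_SYSTEMS:
            raise CodingError(f"unknown primary system {self.primary_system!r}")
        object.__setattr__(self, "secondary_systems", frozenset(self.secondary_systems))
        object.__setattr__(self, "germ_layers", frozenset(self.germ_layers))
        object.__setattr__(self, "processes", frozenset(self.processes))
        for layer in self.germ_layers:
            if layer not in GERM_LAYERS:
                raise CodingError(f"unknown germ layer {layer!r}")
        for proc in self.processes:
            if proc not in PROCESSES:
                raise CodingError(f"unknown process {proc!r}")


def _e(primary, secondary=(), layers=(), processes=()) -> TermEntry:
    return TermEntry(primary, frozenset(secondary), frozenset(layers), frozenset(processes))


#: Default coding map.  The primary/secondary columns for the starred terms
#: follow the fixed causal rules (tracheo-esophageal fistula, skeletal
#: dysplasia, holoprosencephaly, limb reduction/polydactyly, lung
#: hypoplasia); germ-layer and process assignments are editorial defaults
#: and can be overridden from the run config.
DEFAULT_CODING_MAP: dict[str, TermEntry] = {
    # bronchopulmonary
    "lung_hypoplasia": _e("BP", layers=["endoderm"]),
    "bronchial_atresia": _e("BP", layers=["endoderm"]),
    "lung_lobation_defect": _e("BP", layers=["endoderm"], processes=["left_right"]),
    # cardiovascular
    "ventricular_septal_defect": _e("CV", layers=["mesoderm"]),
    "transposition_great_arteries": _e("CV", layers=["mesoderm"], processes=["left_right", "neural_crest"]),
    "hypoplastic_left_heart": _e("CV", layers=["mesoderm"]),
    "heterotaxy": _e("CV", layers=["mesoderm"], processes=["left_right"]),
    # craniofacial
    "cleft_lip": _e("CF", layers=["ectoderm"], processes=["neural_crest", "midline"]),
    "cleft_palate": _e("CF", layers=["ectoderm"], processes=["neural_crest"]),
    "ear_anomaly": _e("CF", layers=["ectoderm"], processes=["neural_crest"]),
    "micrognathia": _e("CF", layers=["ectoderm"], processes=["neural_crest"]),
    # digestive
    "TE_fistula": _e("DS", secondary=["BP"], layers=["endoderm"], processes=["midline"]),
    "duodenal_atresia": _e("DS", layers=["endoderm"]),
    "anal_atresia": _e("DS", layers=["endoderm"], processes=["midline"]),
    "intestinal_malrotation": _e("DS", layers=["endoderm"], processes=["left_right"]),
    # limbs
    "limb_reduction": _e("LD", secondary=["SK"], layers=["mesoderm"]),
    "polydactyly": _e("LD", secondary=["SK"], layers=["mesoderm"]),
    "syndactyly": _e("LD", layers=["mesoderm"]),
    # muscular
    "diaphragmatic_hernia": _e("MS", layers=["mesoderm"], processes=["midline"]),
    "muscular_hypoplasia": _e("MS", layers=["mesoderm"]),
    # nervous system
    "holoprosencephaly": _e("NS", secondary=["CF"], layers=["ectoderm"], processes=["midline", "neural_crest"]),
    "anencephaly": _e("NS", layers=["ectoderm"], processes=["midline"]),
    "spina_bifida": _e("NS", layers=["ectoderm"], processes=["midline"]),
    "hydrocephaly": _e("NS", layers=["ectoderm"]),
    # skeletal
    "skeletal_dysplasia": _e("SK", secondary=["LD", "CF"], layers=["mesoderm"]),
    "hemivertebrae": _e("SK", layers=["mesoderm"], processes=["segmentation"]),
    "fused_ribs": _e("SK", layers=["mesoderm"], processes=["segmentation"]),
    "vertebral_fusion": _e("SK", layers=["mesoderm"], processes=["segmentation"]),
    # urogenital
    "renal_agenesis": _e("UG", layers=["mesoderm"]),
    "hydronephrosis": _e("UG", layers=["mesoderm"]),
    "hypospadias": _e("UG", layers=["mesoderm"], processes=["midline"]),
    # ventral body wall
    "omphalocele": _e("VBW", layers=["mesoderm"], processes=["midline"]),
    "gastroschisis": _e("VBW", layers=["mesoderm"], processes=["midline"]),
}


def load_coding_map(source: dict | str | None = None) -> dict[str, TermEntry]:
    """Return the coding map, optionally overridden from YAML/dict config.

    ``source`` may be a mapping ``term -> {primary, secondary, germ_layers,
    processes}``, a path to a YAML file with such a mapping under the key
    ``coding_map`` (or at top level), or ``None`` for the shipped default.
    """
    if source is None:
        return dict(DEFAULT_CODING_MAP)
    if isinstance(source, str):
        with open(source, encoding="utf-8") as fh:
            source = yaml.safe_load(fh) or {}
    entries = source.get("coding_map", source)
    cmap = dict(DEFAULT_CODING_MAP)
    for term, entry in entries.items():
        cmap[term] = TermEntry(
            entry["primary"],
            frozenset(entry.get("secondary", [])),
            frozenset(entry.get("germ_layers", [])),
            frozenset(entry.get("processes", [])),
        )
    return cmap


@dataclass
class MalformationRecord:
    """Per-subject coded malformation status."""

    subject_id: str
    primary_flags: dict[str, SystemStatus]
    germ_layers: set[str] = field(default_factory=set)
    processes: set[str] = field(default_factory=set)

    @property
    def n_systems_affected(self) -> int:
        return sum(1 for s in self.primary_flags.values() if s is SystemStatus.AFFECTED)

    @property
    def available_systems(self) -> list[str]:
        return [k for k, s in self.primary_flags.items() if s is not SystemStatus.NON_AVAILABLE]

    @property
    def fully_non_available(self) -> bool:
        return not self.available_systems

    def affected(self, system: str) -> bool:
        return self.primary_flags[system] is SystemStatus.AFFECTED


def _is_secondary(finding: Finding) -> bool:
    """Causal demotion rules: a secondary finding is not counted anywhere."""
    if HYPOXIC_CONTEXT in finding.cause_context:
        return True
    if finding.term == "lung_hypoplasia" and finding.cause_context & LUNG_HYPOPLASIA_CAUSES:
        return True
    return False


def primary_findings(findings: list[Finding], coding_map: dict[str, TermEntry]) -> list[Finding]:
    """Findings that survive the primary/secondary causal rules."""
    for f in findings:
        if f.term not in coding_map:
            raise CodingError(f"unknown finding term {f.term!r}; add it to the coding map")
    return [f for f in findings if not _is_secondary(f)]


def apply_primary_secondary(
    findings: list[Finding],
    coding_map: dict[str, TermEntry] | None = None,
    availability: dict[str, bool] | None = None,
    subject_id: str | None = None,
) -> MalformationRecord:
    """Code one subject's findings into per-system primary flags.

    Each counted (primary) finding marks exactly its primary organ system as
    affected; systems listed as secondary for that term are never marked by
    it.  ``availability`` maps system code to observability (autopsy done,
    tissue not macerated); unavailable systems are flagged
    ``non_available`` and contribute to no counts.
    """
    coding_map = coding_map or DEFAULT_CODING_MAP
    if subject_id is None:
        subject_id = findings[0].subject_id if findings else ""
    availability = availability or {}
    flags = {
        sys: (
            SystemStatus.UNAFFECTED
            if availability.get(sys, True)
            else SystemStatus.NON_AVAILABLE
        )
        for sys in ORGAN_SYSTEMS
    }
    for f in primary_findings(findings, coding_map):
        sys = coding_map[f.term].primary_system
        if flags[sys] is not SystemStatus.NON_AVAILABLE:
            flags[sys] = SystemStatus.AFFECTED
    return MalformationRecord(subject_id=subject_id, primary_flags=flags)


def derive_layers_processes(
    record: MalformationRecord,
    findings: list[Finding],
    coding_map: dict[str, TermEntry] | None = None,
) -> MalformationRecord:
    """Attach germ-layer and process sets, attributed via primary findings only."""
    coding_map = coding_map or DEFAULT_CODING_MAP
    layers: set[str] = set()
    procs: set[str] = set()
    for f in primary_findings(findings, coding_map):
        entry = coding_map[f.term]
        if record.primary_flags[entry.primary_system] is SystemStatus.NON_AVAILABLE:
            continue
        layers |= entry.germ_layers
        procs |= entry.processes
    record.germ_layers = layers
    record.processes = procs
    return record


def code_subject(
    findings: list[Finding],
    coding_map: dict[str, TermEntry] | None = None,
    availability: dict[str, bool] | None = None,
    subject_id: str | None = None,
) -> MalformationRecord:
    """Full coding for one subject: flags plus germ layers and processes."""
    rec = apply_primary_secondary(findings, coding_map, availability, subject_id)
    return derive_layers_processes(rec, findings, coding_map)


N_AFFECTED_BANDS = ["0", "1", "2", "3", "4plus"]


def n_affected_band(record: MalformationRecord) -> str:
    """Band the count of affected organ systems: 0, 1, 2, 3 or 4plus."""
    n = record.n_systems_affected
    return "4plus" if n >= 4 else str(n)
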