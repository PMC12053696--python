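"""Disease codex: the map from diseases to bodily systems with ordered severity levels.

Each disease belongs to exactly one bodily system and carries an ordered set of
severity levels coded ``1..D`` where code 1 always means "no disease".  The
default codex covers 13 systems (11 organ systems plus stroke and cancer as
separate entities) and 26 conditions, the layout used throughout multimorbidity
scoring: cardiovascular, renal, metabolic, gastrointestinal/liver, respiratory,
thyroid, hematopoietic, periodontal, musculoskeletal, sensory, central nervous
system, stroke, and cancer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Disease",
    "DiseaseCodex",
    "default_codex",
    "generate_codex",
    "read_codex",
    "write_codex",
]


class CodexError(ValueError):
    """Invalid codex configuration."""


@dataclass(frozen=True)
class Disease:
    name: str
    system: str
    #: ordered severity labels; index 0 (code 1) is the disease-free reference
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise CodexError(
                f"disease {self.name!r} needs >= 2 levels (reference + at least one)"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class DiseaseCodex:
    """Ordered collection of diseases grouped into bodily systems."""

    diseases: tuple[Disease, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.diseases:
            raise CodexError("codex must contain at least one disease")
        names = [d.name for d in self.diseases]
        if len(set(names)) != len(names):
            raise CodexError("duplicate disease names in codex")

    @property
    def systems(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for d in self.diseases:
            seen.setdefault(d.system, None)
        return tuple(seen)

    @property
    def n_systems(self) -> int:
        return len(self.systems)

    @property
    def disease_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.diseases)

    def levels_per_disease(self) -> dict[str, int]:
        return {d.name: d.n_levels for d in self.diseases}

    def diseases_of(self, system: str) -> tuple[Disease, ...]:
        out = tuple(d for d in self.diseases if d.system == system)
        if not out:
            raise CodexError(f"unknown system {system!r}")
        return out

    def subset(self, system: str) -> "DiseaseCodex":
        """Codex restricted to one system (used for system-specific clocks)."""
        return DiseaseCodex(self.diseases_of(system))

    def n_deficit_items(self) -> int:
        """Total binary deficit items when every non-reference level is one item."""
        return sum(d.n_levels - 1 for d in self.diseases)

    def content_hash(self) -> str:
        import hashlib

        payload = repr(
            [(d.name, d.system, d.levels) for d in self.diseases]
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# The 13-system default layout: 11 organ systems extended with stroke and
# cancer as separate entities. Level tuples follow clinical severity ladders
# (e.g. hypertension: none / untreated / treated; eye disease: none /
# cataract / glaucoma / macular degeneration).
_DEFAULT_LAYOUT: list[tuple[str, str, tuple[str, ...]]] = [
    ("hypertension", "cardiovascular", ("none", "untreated", "treated")),
    ("ischemic_heart_disease", "cardiovascular", ("none", "angina", "myocardial_infarction")),
    ("congestive_heart_failure", "cardiovascular", ("none", "preserved_ef", "low_ef")),
    ("arrhythmia", "cardiovascular", ("none", "sinus_bradycardia", "long_qtc", "atrial_fibrillation")),
    ("peripheral_artery_disease", "cardiovascular", ("none", "present")),
    ("chronic_kidney_disease", "renal", ("none", "stage_1", "stage_2", "stage_3", "end_stage")),
    ("diabetes", "metabolic", ("none", "impaired_glucose_tolerance", "untreated", "treated")),
    ("hyperlipidemia", "metabolic", ("none", "untreated", "treated")),
    ("gastrointestinal_disease", "gastrointestinal_liver", ("none", "untreated", "treated")),
    ("liver_disease", "gastrointestinal_liver", ("none", "mild", "severe")),
    ("copd", "respiratory", ("none", "chronic_bronchitis", "emphysema")),
    ("asthma", "respiratory", ("none", "adult_onset")),
    ("hypothyroidism", "thyroid", ("none", "subclinical", "overt")),
    ("hyperthyroidism", "thyroid", ("none", "present")),
    ("anemia", "hematopoietic", ("none", "mild", "severe")),
    ("thrombocytopenia", "hematopoietic", ("none", "present")),
    ("oral_health", "periodontal", ("none", "gingivitis", "edentulous")),
    ("osteoarthritis", "musculoskeletal", ("none", "mild", "severe")),
    ("osteoporosis", "musculoskeletal", ("none", "osteopenia", "osteoporosis")),
    ("hearing", "sensory", ("none", "aided", "impaired")),
    ("eye_disease", "sensory", ("none", "cataract", "glaucoma", "macular_degeneration")),
    ("depression", "cns", ("none", "untreated", "treated")),
    ("parkinsons", "cns", ("none", "present")),
    ("cognition", "cns", ("none", "mild_impairment", "dementia")),
    ("stroke", "stroke", ("none", "tia", "stroke")),
    ("cancer", "cancer", ("none", "present")),
]


def default_codex() -> DiseaseCodex:
    """The 13-system, 26-disease default codex."""
    return DiseaseCodex(tuple(Disease(n, s, lv) for n, s, lv in _DEFAULT_LAYOUT))


def generate_codex(
    n_systems: int,
    diseases_per_system: int | list[int] = 2,
    levels_per_disease: int | list[int] = 3,
    seed: int = 0,
) -> DiseaseCodex:
    """Generate a synthetic codex with the given layout.

    Parameters
    ----------
    n_systems
        Number of bodily systems (>= 1).
    diseases_per_system
        Scalar or per-system list of disease counts (each >= 1).
    levels_per_disease
        Scalar or flat per-disease list of severity level counts (each >= 2,
        level 1 being "no disease"). When a scalar and ``seed`` controls
        nothing else, the codex is fully deterministic; a list must match the
        total number of diseases.
    seed
        Reserved for future randomized layouts; recorded for determinism.
    """
    if n_systems < 1:
        raise CodexError("n_systems must be >= 1")
    if np.isscalar(diseases_per_system):
        dps = [int(diseases_per_system)] * n_systems
    else:
        dps = [int(x) for x in diseases_per_system]
        if len(dps) != n_systems:
            raise CodexError("diseases_per_system length must equal n_systems")
    if any(x < 1 for x in dps):
        raise CodexError("each system needs >= 1 disease")
    n_total = sum(dps)
    if np.isscalar(levels_per_disease):
        lpd = [int(levels_per_disease)] * n_total
    else:
        lpd = [int(x) for x in levels_per_disease]
        if len(lpd) != n_total:
            raise CodexError("levels_per_disease length must equal total diseases")
    if any(x < 2 for x in lpd):
        raise CodexError("every disease needs >= 2 levels")

    diseases = []
    k = 0
    for s in range(n_systems):
        system = f"sys{s + 1:02d}"
        for j in range(dps[s]):
            levels = tuple(
                ["none"] + [f"level{lev}" for lev in range(2, lpd[k] + 1)]
            )
            diseases.append(Disease(f"d{k + 1:02d}_{system}", system, levels))
            k += 1
    return DiseaseCodex(tuple(diseases))


def write_codex(codex: DiseaseCodex, path) -> None:
    doc = {
        "schema": "octoclock-codex/1",
        "diseases": [
            {"name": d.name, "system": d.system, "levels": list(d.levels)}
            for d in codex.diseases
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_codex(path) -> DiseaseCodex:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "diseases" not in doc:
        raise CodexError(f"{path}: not a codex file")
    return DiseaseCodex(
        tuple(
            Disease(d["name"], d["system"], tuple(d["levels"]))
            for d in doc["diseases"]
        )
    )
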