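"""Concept codelists.

All phenotyping logic in this package runs on abstract *concepts* grouped
into *categories* (e.g. ``ms_diagnosis``, ``comorbidity:epilepsy``,
``medication:opioids``).  Per-dialect code strings (ICD-like for the claims
dialect, Read-like for the EMR dialect) are attached to each concept only
for realism in file I/O; they carry no logic.  A concept belongs to exactly
one category.  A concept with no code strings for a dialect is *inactive*
in that dialect and its events are ignored there (used e.g. for overdose,
which contributes to suicidal-behaviour ascertainment only in the EMR
dialect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml

__all__ = [
    "Concept",
    "Codelist",
    "default_codelist",
    # category name constants
    "CAT_MS",
    "CAT_DEMYELINATING",
    "CAT_DMT",
    "CAT_SYMPTOM",
    "CAT_SYMPT_TREAT",
    "CAT_HOSP_MARKER",
    "CAT_SUICIDAL",
    "EXCL_ALS",
    "EXCL_STROKE",
    "EXCL_TIA",
    "EXCL_ALTERNATE",
]

CAT_MS = "ms_diagnosis"
CAT_DEMYELINATING = "demyelinating_disease"
CAT_DMT = "dmt_or_dalfampridine"
CAT_SYMPTOM = "ms_symptom"
CAT_SYMPT_TREAT = "symptomatic_treatment"
CAT_HOSP_MARKER = "hospitalization_marker"
CAT_SUICIDAL = "suicidal_behavior"
EXCL_ALS = "exclusion:als"
EXCL_STROKE = "exclusion:stroke"
EXCL_TIA = "exclusion:tia"
EXCL_ALTERNATE = "exclusion:alternate"


@dataclass(frozen=True)
class Concept:
    name: str
    label: str
    category: str
    dod_codes: tuple[str, ...] = ()
    cprd_codes: tuple[str, ...] = ()

    def codes_for(self, dialect) -> tuple[str, ...]:
        from .records import Dialect  # local import to avoid cycle

        return self.dod_codes if dialect == Dialect.CLAIMS_DOD else self.cprd_codes


class Codelist:
    """Mapping of concept name -> :class:`Concept`, with category queries."""

    def __init__(self, concepts: Iterable[Concept]) -> None:
        self._concepts: dict[str, Concept] = {}
        self._by_category: dict[str, set[str]] = {}
        for c in concepts:
            if c.name in self._concepts:
                raise ValueError(f"duplicate concept {c.name!r}")
            self._concepts[c.name] = c
            self._by_category.setdefault(c.category, set()).add(c.name)

    def __contains__(self, concept: str) -> bool:
        return concept in self._concepts

    def __getitem__(self, concept: str) -> Concept:
        return self._concepts[concept]

    def __len__(self) -> int:
        return len(self._concepts)

    @property
    def concepts(self) -> dict[str, Concept]:
        return dict(self._concepts)

    @property
    def categories(self) -> frozenset[str]:
        return frozenset(self._by_category)

    def category_of(self, concept: str) -> Optional[str]:
        c = self._concepts.get(concept)
        return c.category if c else None

    def concepts_in(self, category: str, dialect=None) -> frozenset[str]:
        names = self._by_category.get(category, set())
        if dialect is None:
            return frozenset(names)
        return frozenset(n for n in names if self.active_in(n, dialect))

    def active_in(self, concept: str, dialect) -> bool:
        c = self._concepts.get(concept)
        return bool(c and c.codes_for(dialect))

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = [
            {
                "concept": c.name,
                "label": c.label,
                "category": c.category,
                "dod_codes": list(c.dod_codes),
                "cprd_codes": list(c.cprd_codes),
            }
            for c in self._concepts.values()
        ]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Codelist":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            Concept(
                d["concept"],
                d.get("label", d["concept"]),
                d["category"],
                tuple(d.get("dod_codes", ())),
                tuple(d.get("cprd_codes", ())),
            )
            for d in data
        )


def _c(name, label, category, dod, cprd) -> Concept:
    dod_t = tuple(dod.split(";")) if dod else ()
    cprd_t = tuple(cprd.split(";")) if cprd else ()
    return Concept(name, label, category, dod_t, cprd_t)


def default_codelist() -> Codelist:
    """The packaged illustrative codelist.

    Code strings are illustrative stand-ins in ICD-like / Read-like shapes,
    not real vocabulary entries; all logic uses the concept and category
    columns only.
    """
    concepts = [
        _c("ms", "Multiple sclerosis", CAT_MS, "ICD9:340;ICD10:G35", "READ:F20.."),
        _c(
            "demyelinating_disease",
            "Other CNS demyelinating disease",
            CAT_DEMYELINATING,
            "ICD9:341;ICD10:G36-G37",
            "READ:F21..",
        ),
        # disease-modifying treatments + dalfampridine
        _c("interferon_beta", "Interferon beta", CAT_DMT, "NDC:44087-0022", "GEM:78123"),
        _c("glatiramer", "Glatiramer acetate", CAT_DMT, "NDC:68546-0317", "GEM:81233"),
        _c("natalizumab", "Natalizumab", CAT_DMT, "NDC:59075-0730", "GEM:90011"),
        _c("fingolimod", "Fingolimod", CAT_DMT, "NDC:0078-0607", "GEM:93377"),
        _c("dalfampridine", "Dalfampridine", CAT_DMT, "NDC:10144-0427", "GEM:95520"),
        # MS symptoms (support codes in the EMR algorithm; descriptive rows)
        _c("optic_neuritis", "Optic neuritis", CAT_SYMPTOM, "ICD9:377.3", "READ:F48.."),
        _c("nerve_disorder", "Nerve disorder, unspecified", CAT_SYMPTOM, "ICD9:349.9", "READ:F2y.."),
        _c("paresis_weakness", "Paresis, plegia, paralysis, muscle weakness", CAT_SYMPTOM, "ICD9:344", "READ:F22.."),
        _c("vertigo", "Vestibular/labyrinthine disorder / vertigo", CAT_SYMPTOM, "ICD9:386", "READ:F53.."),
        _c("spasticity_ataxia", "Spasms, incoordination, gait abnormality / spasticity, ataxia", CAT_SYMPTOM, "ICD9:781.0", "READ:F13.."),
        _c("neuritis_neuralgia", "Neuritis and neuralgia", CAT_SYMPTOM, "ICD9:729.2", "READ:F26.."),
        _c("neuropathy", "Neuropathy", CAT_SYMPTOM, "ICD9:356", "READ:F35.."),
        _c("speech_disorder", "Speech disorder", CAT_SYMPTOM, "ICD9:784.5", "READ:1B9.."),
        _c("skin_sensation_disturbance", "Disturbance of skin sensation / paraesthesia", CAT_SYMPTOM, "ICD9:782.0", "READ:1B8.."),
        _c("dizziness", "Dizziness and giddiness", CAT_SYMPTOM, "ICD9:780.4", "READ:R008."),
        _c("malaise_fatigue", "Malaise and fatigue", CAT_SYMPTOM, "ICD9:780.7", "READ:R007."),
        _c("vision_symptoms", "Vision symptoms", CAT_SYMPTOM, "ICD9:368", "READ:F4K.."),
        _c("bladder_symptoms", "Bladder symptoms", CAT_SYMPTOM, "ICD9:788.3", "READ:R08.."),
        _c("bowel_dysfunction", "Bowel dysfunction", CAT_SYMPTOM, "ICD9:564.0", "READ:J57.."),
        _c("generalized_pain", "Pain, generalized", CAT_SYMPTOM, "ICD9:780.96", "READ:R005."),
        _c("itch", "Itch, unspecified", CAT_SYMPTOM, "ICD9:698.9", "READ:M18y."),
        # MS symptomatic treatments (support codes; not Table-style drug classes)
        _c("oxybutynin", "Oxybutynin (bladder symptoms)", CAT_SYMPT_TREAT, "NDC:0591-0897", "GEM:40122"),
        _c("modafinil", "Modafinil (fatigue)", CAT_SYMPT_TREAT, "NDC:63459-0101", "GEM:56719"),
        # chronic comorbidities
        _c("depression", "Depression diagnosis", "comorbidity:depression", "ICD9:296.2", "READ:E112."),
        _c("hypertension", "Hypertension diagnosis", "comorbidity:hypertension", "ICD9:401", "READ:G20.."),
        _c("diabetes_t2", "Type II diabetes diagnosis", "comorbidity:diabetes", "ICD9:250.0", "READ:C10F."),
        _c("epilepsy", "Epilepsy", "comorbidity:epilepsy", "ICD9:345", "READ:F25.."),
        _c("asthma_copd", "Asthma or COPD", "comorbidity:asthma_copd", "ICD9:493", "READ:H33.."),
        _c("autoimmune_disorder", "Autoimmune disorder", "comorbidity:autoimmune", "ICD9:710", "READ:N000."),
        _c("liver_disease", "Liver disease", "comorbidity:liver_disease", "ICD9:571", "READ:J61.."),
        _c("dyslipidemia", "Dyslipidemia", "comorbidity:dyslipidemia", "ICD9:272", "READ:C32.."),
        _c("fracture", "Fracture", "comorbidity:fracture", "ICD9:829", "READ:S3...."),
        _c("osteoporosis", "Osteoporosis", "comorbidity:osteoporosis", "ICD9:733.0", "READ:N330."),
        _c("cancer", "Cancer (primary diagnosis)", "comorbidity:cancer", "ICD9:199", "READ:B...."),
        _c("cancer_history", "History of cancer / secondary cancer", "comorbidity:cancer_history", "ICD9:V10;ICD9:196-198", "READ:ZV10."),
        # infections (acute, 1-year look-back)
        _c("urinary_infection", "Urinary and kidney infection", "infection:urinary", "ICD9:599.0", "READ:K190."),
        _c("skin_infection", "Skin infection", "infection:skin", "ICD9:686.9", "READ:M0...."),
        _c("respiratory_infection", "Respiratory and throat infection", "infection:respiratory", "ICD9:465", "READ:H05.."),
        _c("pneumonia_influenza", "Pneumonia and influenza", "infection:pneumonia_influenza", "ICD9:486", "READ:H2...."),
        _c("eye_ear_infection", "Eye and ear infection", "infection:eye_ear", "ICD9:372.0", "READ:F4C.."),
        _c("viral_infection", "Viral infectious disease", "infection:viral", "ICD9:079.9", "READ:A7...."),
        _c("fungal_infection", "Fungal infectious disease", "infection:fungal", "ICD9:117.9", "READ:AB...."),
        _c("meningitis", "Meningitis and encephalitis", "infection:meningitis", "ICD9:322.9", "READ:F00.."),
        # concomitant medication classes (1-year look-back)
        _c("antidepressant", "Antidepressants", "medication:antidepressants", "NDC:0049-4960", "GEM:11111"),
        _c("antihypertensive", "Antihypertensives", "medication:antihypertensives", "NDC:0071-0155", "GEM:11222"),
        _c("oral_hypoglycemic", "Oral hypoglycemics", "medication:oral_hypoglycemics", "NDC:0087-6060", "GEM:11333"),
        _c("opioid", "Opioids", "medication:opioids", "NDC:0406-0512", "GEM:11444"),
        _c("nsaid", "NSAIDs", "medication:nsaids", "NDC:0025-1520", "GEM:11555"),
        _c("steroid", "Steroids", "medication:steroids", "NDC:0054-4728", "GEM:11666"),
        _c("anticonvulsant", "Anticonvulsants", "medication:anticonvulsants", "NDC:0071-0401", "GEM:11777"),
        _c("spasticity_agent", "Spasticity treatments", "medication:spasticity_treatments", "NDC:0172-4096", "GEM:11888"),
        _c("antibiotic", "Antibiotics", "medication:antibiotics", "NDC:0093-4155", "GEM:11999"),
        _c("statin", "Statins", "medication:statins", "NDC:0071-0156", "GEM:12111"),
        # exclusion concepts
        _c("als", "Amyotrophic lateral sclerosis", EXCL_ALS, "ICD9:335.20", "READ:F152."),
        _c("stroke", "Stroke", EXCL_STROKE, "ICD9:434", "READ:G66.."),
        _c("tia", "Transient ischemic attack", EXCL_TIA, "ICD9:435", "READ:G65.."),
        _c("alternate_diagnosis", "Alternate (non-MS) diagnosis", EXCL_ALTERNATE, "ICD9:323.9", "READ:F03.."),
        # markers
        _c("hospital_admission", "Hospital admission marker", CAT_HOSP_MARKER, "CPT:99223", "READ:8H2.."),
        # suicidal behaviour; overdose is active only in the EMR dialect
        _c("self_harm", "Suicidal ideation / attempt / self-harm", CAT_SUICIDAL, "ICD9:E950", "READ:TK...."),
        _c("overdose", "Overdose", CAT_SUICIDAL, "", "READ:TK6.."),
    ]
    return Codelist(concepts)
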