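"""Synthetic discharge-summary corpus generator.

Emulates the structure the pipeline assumes of a real obesity/comorbidity
discharge-summary corpus: a master file of records separated by a literal
``[record_end]`` tag, sectioned notes with uppercase headings, disease
mentions realized under present/negated/uncertain contexts, abbreviations
that need expansion, family-history confounder mentions, and dual gold
labels (textual: what the note states; intuitive: what a clinician would
conclude).  Alongside the notes it emits the matching gazetteer, rule set,
abbreviation table, section dictionary and gold label table, so every
downstream stage is testable without any restricted data.

Category realizations are template sentences chosen so the textual gold
label is *derivable* by the rule cascade:

* Present      -> "The patient has {alias}."
* Absent       -> "No evidence of {alias}."
* Questionable -> "Possible {alias}."
* Unmentioned  -> the disease name never appears.

The intuitive label equals the textual one for mentioned diseases.  For
Unmentioned diseases it is sampled (configurable prior): an
intuitive-Present disease is betrayed only by clinical *marker* concepts
(disease-specific treatments, findings, symptoms) written into the note
without naming the disease — exactly the signal a bag-of-CUIs model must
pick up where rules cannot.  Family-history confounders are extra mentions
of a relative's disease placed strictly inside the family-history section;
they are only attached to diseases the cascade already judges mentioned, so
gold consistency survives (the cascade has no section awareness — filtering
family history is the feature filter's job, not the rule engine's).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .concepts import Gazetteer, write_gazetteer
from .prep import DEFAULT_END_TAG, write_section_dictionary
from .rules import RuleSet, default_ruleset, write_ruleset
from .types import (
    ABSENT,
    GoldLabel,
    PRESENT,
    QUESTIONABLE,
    SectionDictionary,
    TASK_INTUITIVE,
    TASK_TEXTUAL,
    UNMENTIONED,
)


@dataclass(frozen=True)
class DiseaseProfile:
    """Everything the generator knows about one phenotype."""

    name: str
    cui: str
    abbrev: str | None
    #: (term, cui, semantic_type) concepts that betray the disease without
    #: naming it: treatments, findings, symptoms.
    markers: tuple[tuple[str, str, str], ...]


#: Obesity and fifteen comorbidities commonly studied together in
#: discharge-summary phenotyping.  CUIs for the diseases are the standard
#: UMLS codes; marker concepts use a reserved synthetic C39xxxxx range.
DEFAULT_PROFILES: dict[str, DiseaseProfile] = {
    p.name: p
    for p in [
        DiseaseProfile(
            "obesity", "C0028754", None,
            (("morbid weight gain", "C3900011", "T033"),
             ("bariatric surgery", "C3900012", "T061")),
        ),
        DiseaseProfile(
            "coronary artery disease", "C0010054", "CAD",
            (("cardiac stent placement", "C3900021", "T061"),
             ("exertional angina", "C3900022", "T184")),
        ),
        DiseaseProfile(
            "congestive heart failure", "C0018802", "CHF",
            (("reduced ejection fraction", "C3900031", "T033"),
             ("furosemide", "C3900032", "T121")),
        ),
        DiseaseProfile(
            "diabetes mellitus", "C0011849", "DM",
            (("metformin", "C3900041", "T121"),
             ("elevated hemoglobin a1c", "C3900042", "T034")),
        ),
        DiseaseProfile(
            "hypertension", "C0020538", "HTN",
            (("lisinopril", "C3900051", "T121"),
             ("elevated blood pressure readings", "C3900052", "T033")),
        ),
        DiseaseProfile(
            "asthma", "C0004096", None,
            (("albuterol inhaler", "C3900061", "T121"),
             ("expiratory wheezing", "C3900062", "T184")),
        ),
        DiseaseProfile(
            "gastroesophageal reflux disease", "C0017168", "GERD",
            (("omeprazole", "C3900071", "T121"),
             ("nocturnal heartburn", "C3900072", "T184")),
        ),
        DiseaseProfile(
            "depression", "C0011570", None,
            (("sertraline", "C3900081", "T121"),
             ("depressed mood", "C3900082", "T184")),
        ),
        DiseaseProfile(
            "gallstones", "C0008350", None,
            (("cholecystectomy", "C3900091", "T061"),
             ("right upper quadrant pain", "C3900092", "T184")),
        ),
        DiseaseProfile(
            "gout", "C0018099", None,
            (("allopurinol", "C3900101", "T121"),
             ("elevated uric acid", "C3900102", "T034")),
        ),
        DiseaseProfile(
            "hypercholesterolemia", "C0020443", None,
            (("atorvastatin", "C3900111", "T121"),
             ("elevated ldl cholesterol", "C3900112", "T034")),
        ),
        DiseaseProfile(
            "hypertriglyceridemia", "C0020557", None,
            (("fenofibrate", "C3900121", "T121"),
             ("elevated triglyceride level", "C3900122", "T034")),
        ),
        DiseaseProfile(
            "obstructive sleep apnea", "C0520679", "OSA",
            (("nightly cpap use", "C3900131", "T061"),
             ("daytime somnolence", "C3900132", "T184")),
        ),
        DiseaseProfile(
            "osteoarthritis", "C0029408", "OA",
            (("degenerative joint changes", "C3900141", "T033"),
             ("knee replacement", "C3900142", "T061")),
        ),
        DiseaseProfile(
            "peripheral vascular disease", "C0085096", "PVD",
            (("claudication", "C3900151", "T184"),
             ("diminished pedal pulses", "C3900152", "T033")),
        ),
        DiseaseProfile(
            "venous insufficiency", "C0042485", None,
            (("lower extremity edema", "C3900161", "T184"),
             ("compression stockings", "C3900162", "T061")),
        ),
    ]
}

#: Fifteen discharge-summary section headings; FAMILY HISTORY is the one the
#: family-history feature filter targets.
DEFAULT_SECTION_HEADINGS = [
    "PRINCIPAL DIAGNOSIS",
    "HISTORY OF PRESENT ILLNESS",
    "PAST MEDICAL HISTORY",
    "FAMILY HISTORY",
    "SOCIAL HISTORY",
    "MEDICATIONS ON ADMISSION",
    "ALLERGIES",
    "PHYSICAL EXAMINATION",
    "LABORATORY DATA",
    "HOSPITAL COURSE",
    "REVIEW OF SYSTEMS",
    "DISCHARGE MEDICATIONS",
    "DISCHARGE DIAGNOSIS",
    "DISCHARGE INSTRUCTIONS",
    "FOLLOW-UP",
]
FAMILY_HISTORY_HEADING = "FAMILY HISTORY"

#: Generic concepts sprinkled as uninformative noise features.
FILLER_TERMS: Gazetteer = {
    "chest pain": ("C0008031", "T184"),
    "aspirin": ("C0004057", "T121"),
    "echocardiogram": ("C0013516", "T060"),
    "complete blood count": ("C0009555", "T059"),
}
# Filler sentences deliberately avoid every negation/uncertainty trigger.
_FILLER_SENTENCES = [
    "Vital signs were stable on admission.",
    "The patient reported intermittent chest pain.",
    "Aspirin was continued daily.",
    "An echocardiogram was obtained during the stay.",
    "Complete blood count was unremarkable.",
]


@dataclass
class CorpusConfig:
    """Stated world for one synthetic corpus.

    Category probabilities reflect a comorbidity-rich discharge-summary
    population: most diseases are either affirmed or never mentioned, clear
    negations are common, hedged mentions rare.
    """

    n_notes: int = 100
    diseases: list[str] = dc_field(default_factory=lambda: list(DEFAULT_PROFILES))
    section_headings: list[str] = dc_field(
        default_factory=lambda: list(DEFAULT_SECTION_HEADINGS)
    )
    p_present: float = 0.35
    p_absent: float = 0.25
    p_questionable: float = 0.10
    p_unmentioned: float = 0.30
    p_family_history_confounder: float = 0.10
    #: P(intuitive = Present | textual = Unmentioned): how often an
    #: unmentioned disease is nonetheless clinically inferable.
    p_intuitive_present_given_unmentioned: float = 0.5
    abbreviation_rate: float = 0.30
    seed: int = 0
    end_tag: str = DEFAULT_END_TAG
    profiles: dict[str, DiseaseProfile] = dc_field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )

    def __post_init__(self) -> None:
        probs = (self.p_present, self.p_absent, self.p_questionable, self.p_unmentioned)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(
                f"category probabilities must be non-negative and sum to 1, got {probs}"
            )
        if self.n_notes < 0:
            raise ValueError("n_notes must be >= 0")
        for rate in (
            self.p_family_history_confounder,
            self.p_intuitive_present_given_unmentioned,
            self.abbreviation_rate,
        ):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        unknown = [d for d in self.diseases if d not in self.profiles]
        if unknown:
            raise ValueError(f"no disease profile for: {unknown}")
        if FAMILY_HISTORY_HEADING not in self.section_headings:
            raise ValueError("section_headings must include the family-history section")


@dataclass
class SynthCorpus:
    """Generator output: the master file plus every configuration artifact."""

    master_text: str
    gold: list[GoldLabel]
    gazetteer: Gazetteer
    ruleset: RuleSet
    abbreviations: dict[str, str]
    section_dictionary: SectionDictionary
    config: CorpusConfig


def build_section_dictionary(headings: list[str]) -> SectionDictionary:
    entries = {h: i + 1 for i, h in enumerate(headings)}
    return SectionDictionary(
        entries=entries, family_history_id=entries.get(FAMILY_HISTORY_HEADING)
    )


def build_gazetteer(config: CorpusConfig) -> Gazetteer:
    gazetteer: Gazetteer = dict(FILLER_TERMS)
    for name in config.diseases:
        profile = config.profiles[name]
        gazetteer[profile.name] = (profile.cui, "T047")
        for term, cui, semtype in profile.markers:
            gazetteer[term] = (cui, semtype)
    return gazetteer


def build_abbreviations(config: CorpusConfig) -> dict[str, str]:
    return {
        config.profiles[name].abbrev: name
        for name in config.diseases
        if config.profiles[name].abbrev
    }


def generate_corpus(config: CorpusConfig) -> SynthCorpus:
    """Generate a full corpus; identical config means byte-identical output."""
    rng = random.Random(config.seed)
    sdict = build_section_dictionary(config.section_headings)
    gazetteer = build_gazetteer(config)
    abbreviations = build_abbreviations(config)
    ruleset = default_ruleset({name: [name] for name in config.diseases})

    records: list[str] = []
    gold: list[GoldLabel] = []
    for note_id in range(1, config.n_notes + 1):
        text, note_gold = _generate_note(note_id, config, rng)
        records.append(text)
        gold.extend(note_gold)

    master_text = "".join(r + config.end_tag + "\n" for r in records)
    return SynthCorpus(
        master_text=master_text,
        gold=gold,
        gazetteer=gazetteer,
        ruleset=ruleset,
        abbreviations=abbreviations,
        section_dictionary=sdict,
        config=config,
    )


def _mention_of(profile: DiseaseProfile, config: CorpusConfig, rng: random.Random) -> str:
    """The surface form of a mention: sometimes the raw abbreviation."""
    if profile.abbrev and rng.random() < config.abbreviation_rate:
        return profile.abbrev
    return profile.name


def _generate_note(
    note_id: int, config: CorpusConfig, rng: random.Random
) -> tuple[str, list[GoldLabel]]:
    hpi: list[str] = [rng.choice(_FILLER_SENTENCES)]
    pmh: list[str] = []
    family: list[str] = []
    gold: list[GoldLabel] = []

    for name in config.diseases:
        profile = config.profiles[name]
        category = rng.choices(
            (PRESENT, ABSENT, QUESTIONABLE, UNMENTIONED),
            weights=(
                config.p_present,
                config.p_absent,
                config.p_questionable,
                config.p_unmentioned,
            ),
        )[0]

        if category == PRESENT:
            pmh.append(f"The patient has {_mention_of(profile, config, rng)}.")
            intuitive = PRESENT
        elif category == ABSENT:
            pmh.append(f"No evidence of {_mention_of(profile, config, rng)}.")
            intuitive = ABSENT
        elif category == QUESTIONABLE:
            pmh.append(f"Possible {_mention_of(profile, config, rng)}.")
            intuitive = QUESTIONABLE
        else:
            intuitive = (
                PRESENT
                if rng.random() < config.p_intuitive_present_given_unmentioned
                else ABSENT
            )

        # Clinical markers appear whenever the disease is clinically present,
        # whether or not the note names it.
        if intuitive == PRESENT:
            m0, m1 = profile.markers[0][0], profile.markers[1][0]
            hpi.append(f"Treatment includes {m0}.")
            hpi.append(f"Notable for {m1}.")

        # A relative's disease, strictly inside the family-history section;
        # never attached to Unmentioned diseases so the cascade's textual
        # judgment stays derivable from the templates alone.
        if category != UNMENTIONED and rng.random() < config.p_family_history_confounder:
            family.append(f"Mother has a history of {profile.name}.")

        gold.append(GoldLabel(note_id, name, TASK_TEXTUAL, category))
        gold.append(GoldLabel(note_id, name, TASK_INTUITIVE, intuitive))

    if not family:
        family.append("Noncontributory.")

    parts = [f"Record {note_id} admitted for evaluation.\n"]
    parts.append("HISTORY OF PRESENT ILLNESS:\n" + " ".join(hpi) + "\n")
    parts.append("PAST MEDICAL HISTORY:\n" + (" ".join(pmh) or "Unremarkable.") + "\n")
    parts.append(FAMILY_HISTORY_HEADING + ":\n" + " ".join(family) + "\n")
    parts.append("HOSPITAL COURSE:\n" + rng.choice(_FILLER_SENTENCES) + "\n")
    return "\n".join(parts), gold


def write_corpus(corpus: SynthCorpus, out_dir: str | Path) -> dict[str, Path]:
    """Write every artifact as plain text; returns the path of each."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "master": out / "master.txt",
        "gold": out / "gold.tsv",
        "gazetteer": out / "gazetteer.tsv",
        "ruleset": out / "ruleset.yaml",
        "abbreviations": out / "abbreviations.tsv",
        "sections": out / "sections.yaml",
    }
    paths["master"].write_text(corpus.master_text, encoding="utf-8")
    write_gold(corpus.gold, paths["gold"])
    write_gazetteer(corpus.gazetteer, paths["gazetteer"])
    write_ruleset(corpus.ruleset, paths["ruleset"])
    paths["abbreviations"].write_text(
        "".join(f"{k}\t{v}\n" for k, v in corpus.abbreviations.items()),
        encoding="utf-8",
    )
    write_section_dictionary(corpus.section_dictionary, paths["sections"])
    return paths


def write_gold(gold: list[GoldLabel], path: str | Path) -> None:
    lines = ["note_id\tdisease\ttask\tjudgment"]
    lines += [f"{g.note_id}\t{g.disease}\t{g.task}\t{g.judgment}" for g in gold]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_gold(path: str | Path) -> list[GoldLabel]:
    gold = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        note_id, disease, task, judgment = line.split("\t")
        gold.append(GoldLabel(int(note_id), disease, task, judgment))
    return gold
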