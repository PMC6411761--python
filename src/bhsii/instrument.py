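"""Structure and scoring of the Bologna Healing Stifle Injury Index (BHSII).

The BHSII is a 34-item outcome instrument for dogs surgically treated for
cranial cruciate ligament (CCL) rupture.  It combines an owner questionnaire
(BHSII-OQ: Pain P1-P12, Stiffness S1-S5, Function F1-F7; 24 items) with a
clinical record filled in by the veterinarian (BHSII-CR: Visual examination
V1-V3, Manual examination M1-M7; 10 items).  Every item is answered on a
five-level Likert scale (0 = never ... 4 = always), higher values meaning
more severe signs.

Domain, section and total scores are normalized to a 0-100 scale with

    normalized = 100 - raw * 100 / max_raw

so that 100 means absence of any problem and 0 means severe stifle joint
problems.  Normalization follows the KOOS convention the instrument was
modelled on.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from .errors import MissingItemError, ValidationError

SECTION_OQ = "OQ"
SECTION_CR = "CR"

#: domain code -> (full name, section, number of items)
_DOMAIN_LAYOUT: Dict[str, Tuple[str, str, int]] = {
    "P": ("Pain", SECTION_OQ, 12),
    "S": ("Stiffness", SECTION_OQ, 5),
    "F": ("Function", SECTION_OQ, 7),
    "V": ("Visual examination", SECTION_CR, 3),
    "M": ("Manual examination", SECTION_CR, 7),
}

MISSING_POLICIES = ("strict", "prorate")

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ItemDef:
    """One multiple-choice item of the instrument."""

    item_id: str
    domain_code: str
    prompt: str
    min_value: int = 0
    max_value: int = 4

    def __post_init__(self) -> None:
        if self.min_value != 0 or self.max_value != 4:
            raise ValidationError(
                f"item {self.item_id}: BHSII items use a 0-4 Likert scale, "
                f"got [{self.min_value}, {self.max_value}]"
            )
        if self.domain_code not in _DOMAIN_LAYOUT:
            raise ValidationError(f"unknown domain code {self.domain_code!r}")


@dataclass(frozen=True)
class DomainDef:
    """An ordered group of items scored together (e.g. Pain)."""

    domain_code: str
    name: str
    section: str
    items: Tuple[ItemDef, ...]

    def __post_init__(self) -> None:
        if self.section not in (SECTION_OQ, SECTION_CR):
            raise ValidationError(f"unknown section {self.section!r}")
        for idx, item in enumerate(self.items, start=1):
            if item.domain_code != self.domain_code:
                raise ValidationError(
                    f"item {item.item_id} assigned to domain {self.domain_code}"
                )
            expected = f"{self.domain_code}{idx}"
            if item.item_id != expected:
                raise ValidationError(
                    f"item ids must be consecutive within a domain: "
                    f"expected {expected}, got {item.item_id}"
                )

    @property
    def max_raw(self) -> int:
        return sum(item.max_value for item in self.items)

    @property
    def item_ids(self) -> Tuple[str, ...]:
        return tuple(item.item_id for item in self.items)


@dataclass(frozen=True)
class InstrumentDefinition:
    """The full instrument: an ordered collection of domains."""

    name: str
    domains: Tuple[DomainDef, ...]

    def __post_init__(self) -> None:
        seen: set = set()
        for domain in self.domains:
            for item in domain.items:
                if item.item_id in seen:
                    raise ValidationError(f"duplicate item id {item.item_id}")
                seen.add(item.item_id)

    @property
    def items(self) -> Tuple[ItemDef, ...]:
        return tuple(i for d in self.domains for i in d.items)

    @property
    def item_ids(self) -> Tuple[str, ...]:
        return tuple(i.item_id for i in self.items)

    @property
    def total_max_raw(self) -> int:
        return sum(d.max_raw for d in self.domains)

    @property
    def item_map(self) -> Dict[str, ItemDef]:
        return {i.item_id: i for i in self.items}

    def domain(self, code: str) -> DomainDef:
        for d in self.domains:
            if d.domain_code == code:
                return d
        raise KeyError(code)

    def section_domains(self, section: str) -> Tuple[DomainDef, ...]:
        return tuple(d for d in self.domains if d.section == section)

    def section_max_raw(self, section: str) -> int:
        return sum(d.max_raw for d in self.section_domains(section))

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "domains": [
                {
                    "code": d.domain_code,
                    "name": d.name,
                    "section": d.section,
                    "items": [
                        {
                            "item_id": i.item_id,
                            "prompt": i.prompt,
                            "min_value": i.min_value,
                            "max_value": i.max_value,
                        }
                        for i in d.items
                    ],
                }
                for d in self.domains
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: Mapping) -> "InstrumentDefinition":
        if data.get("schema_version") != SCHEMA_VERSION:
            raise ValidationError(
                f"unsupported instrument schema version {data.get('schema_version')!r}"
            )
        domains = tuple(
            DomainDef(
                domain_code=d["code"],
                name=d["name"],
                section=d["section"],
                items=tuple(
                    ItemDef(
                        item_id=i["item_id"],
                        domain_code=d["code"],
                        prompt=i["prompt"],
                        min_value=i.get("min_value", 0),
                        max_value=i.get("max_value", 4),
                    )
                    for i in d["items"]
                ),
            )
            for d in data["domains"]
        )
        return cls(name=data["name"], domains=domains)

    @classmethod
    def from_json(cls, text: str) -> "InstrumentDefinition":
        return cls.from_dict(json.loads(text))


def load_default_instrument() -> InstrumentDefinition:
    """Return the canonical BHSII definition.

    34 items in five domains: Pain (12, max 48), Stiffness (5, max 20),
    Function (7, max 28), Visual examination (3, max 12), Manual
    examination (7, max 28); total maximum raw score 136.  Item prompts
    are placeholders describing the domain — the published questionnaire
    wording lives in supplementary material that scoring never depends on.
    """
    domains = []
    for code, (name, section, n_items) in _DOMAIN_LAYOUT.items():
        items = tuple(
            ItemDef(
                item_id=f"{code}{i}",
                domain_code=code,
                prompt=f"{name} item {i} (placeholder prompt)",
            )
            for i in range(1, n_items + 1)
        )
        domains.append(DomainDef(code, name, section, items))
    return InstrumentDefinition(name="BHSII", domains=tuple(domains))


@dataclass
class ResponseSheet:
    """One administration of the instrument for one subject.

    ``values`` maps item id to the recorded 0-4 answer; items may be
    missing (partial sheet).  ``timepoint`` is one of T0/T1/T3/T6 for
    surgical follow-up or test/retest for the control group.
    """

    subject_id: str
    timepoint: str
    values: Dict[str, int] = field(default_factory=dict)

    def validate(self, instrument: InstrumentDefinition) -> None:
        item_map = instrument.item_map
        for item_id, value in self.values.items():
            if item_id not in item_map:
                raise ValidationError(
                    f"sheet {self.subject_id}/{self.timepoint}: unknown item {item_id!r}"
                )
            item = item_map[item_id]
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ValidationError(
                    f"sheet {self.subject_id}/{self.timepoint}: item {item_id} "
                    f"value {value!r} is not an integer"
                )
            if not item.min_value <= value <= item.max_value:
                raise ValidationError(
                    f"sheet {self.subject_id}/{self.timepoint}: item {item_id} "
                    f"value {value} outside [{item.min_value}, {item.max_value}]"
                )

    def is_complete(self, instrument: InstrumentDefinition) -> bool:
        return all(i in self.values for i in instrument.item_ids)


@dataclass(frozen=True)
class SheetScores:
    """Raw sums and normalized 0-100 scores for one response sheet.

    Undefined aggregates (prorate policy with too few answered items)
    are NaN.
    """

    subject_id: str
    timepoint: str
    domain_raw: Dict[str, float]
    domain_score: Dict[str, float]
    oq_raw: float
    cr_raw: float
    oq_score: float
    cr_score: float
    total_raw: float
    total_score: float

    def as_row(self) -> Dict[str, float]:
        row: Dict[str, float] = {
            "subject_id": self.subject_id,
            "timepoint": self.timepoint,
        }
        row.update({code: self.domain_score[code] for code in self.domain_score})
        row["OQ"] = self.oq_score
        row["CR"] = self.cr_score
        row["total"] = self.total_score
        return row


def normalize(raw: float, max_raw: float) -> float:
    """Map a raw distress sum onto the 0-100 well-being scale."""
    return 100.0 - raw * 100.0 / max_raw


def score_domain(
    sheet: ResponseSheet,
    domain: DomainDef,
    missing_policy: str = "strict",
) -> Tuple[float, float]:
    """Score one domain of a sheet.

    Returns ``(raw, normalized)``.  Under ``strict`` every item of the
    domain must be present.  Under ``prorate`` (KOOS convention) a domain
    with at least half of its items answered substitutes the mean of the
    answered items for each missing one; with fewer answers the domain is
    undefined and ``(nan, nan)`` is returned.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValidationError(f"unknown missing policy {missing_policy!r}")
    values = []
    missing = []
    for item in domain.items:
        v = sheet.values.get(item.item_id)
        if v is None:
            missing.append(item.item_id)
            continue
        if not isinstance(v, int) or isinstance(v, bool):
            raise ValidationError(
                f"item {item.item_id}: value {v!r} is not an integer"
            )
        if not item.min_value <= v <= item.max_value:
            raise ValidationError(
                f"item {item.item_id}: value {v} outside "
                f"[{item.min_value}, {item.max_value}]"
            )
        values.append(v)
    if missing:
        if missing_policy == "strict":
            raise MissingItemError(
                f"sheet {sheet.subject_id}/{sheet.timepoint}: missing item(s) "
                f"{', '.join(missing)} in domain {domain.domain_code}"
            )
        if len(values) * 2 < len(domain.items):
            return (math.nan, math.nan)
        mean = sum(values) / len(values)
        raw = sum(values) + mean * len(missing)
    else:
        raw = float(sum(values))
    return (raw, normalize(raw, domain.max_raw))


def score_sheet(
    sheet: ResponseSheet,
    instrument: InstrumentDefinition,
    missing_policy: str = "strict",
) -> SheetScores:
    """Score all domains, both sections and the total of one sheet.

    Section scores use the same normalization as domains and the total:
    BHSII-OQ = 100 - (raw_P+raw_S+raw_F)*100/96 and
    BHSII-CR = 100 - (raw_V+raw_M)*100/40; the total is
    100 - total_raw*100/136.  An undefined domain makes every aggregate
    containing it undefined (NaN).
    """
    domain_raw: Dict[str, float] = {}
    domain_score: Dict[str, float] = {}
    for domain in instrument.domains:
        raw, norm = score_domain(sheet, domain, missing_policy)
        domain_raw[domain.domain_code] = raw
        domain_score[domain.domain_code] = norm

    def _section(section: str) -> Tuple[float, float]:
        codes = [d.domain_code for d in instrument.section_domains(section)]
        raw = sum(domain_raw[c] for c in codes)
        if math.isnan(raw):
            return (math.nan, math.nan)
        return (raw, normalize(raw, instrument.section_max_raw(section)))

    oq_raw, oq_score = _section(SECTION_OQ)
    cr_raw, cr_score = _section(SECTION_CR)
    total_raw = sum(domain_raw.values())
    total_score = (
        math.nan if math.isnan(total_raw)
        else normalize(total_raw, instrument.total_max_raw)
    )
    return SheetScores(
        subject_id=sheet.subject_id,
        timepoint=sheet.timepoint,
        domain_raw=domain_raw,
        domain_score=domain_score,
        oq_raw=oq_raw,
        cr_raw=cr_raw,
        oq_score=oq_score,
        cr_score=cr_score,
        total_raw=total_raw,
        total_score=total_score,
    )


def score_table(
    sheets: Iterable[ResponseSheet],
    instrument: Optional[InstrumentDefinition] = None,
    missing_policy: str = "strict",
):
    """Score many sheets into a tidy DataFrame.

    Columns: subject_id, timepoint, P, S, F, V, M, OQ, CR, total
    (normalized 0-100 scores).
    """
    import pandas as pd

    if instrument is None:
        instrument = load_default_instrument()
    rows: List[Dict[str, float]] = [
        score_sheet(sheet, instrument, missing_policy).as_row() for sheet in sheets
    ]
    columns = ["subject_id", "timepoint"] + [d.domain_code for d in instrument.domains]
    columns += ["OQ", "CR", "total"]
    return pd.DataFrame(rows, columns=columns)
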