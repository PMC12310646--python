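"""Controlled vocabularies: drug-name normalization, event grouping, severity.

Spontaneous reports carry verbatim drug names (brand names, generic names,
dosage suffixes) and MedDRA preferred terms (PTs).  Analyses need both
normalized: drug strings are resolved to ingredients through a synonym
dictionary, and PTs are folded into composite event categories — here the
neurological immune-mediated adverse-event (NAE) groups such as autoimmune
encephalitis (AIE), the Guillain-Barré spectrum, or the myasthenia gravis
spectrum.  Matching is exact after case/whitespace normalization: MedDRA is
a controlled vocabulary, so fuzzy matching would only add noise.

Severity follows the outcome-code convention used in SRS mortality
analyses: a report is SERIOUS iff its outcome set contains death (DE);
any other non-empty outcome set is NON_SERIOUS; an empty set is UNKNOWN.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .report_store import CaseReport, DrugEntry

import datetime as _dt

#: composite event-group labels (the NAE categories)
EVENT_GROUPS = (
    "AIE",
    "GBS_SPECTRUM",
    "CIDP",
    "MG_SPECTRUM",
    "IMMUNE_MYOPATHY",
    "MYELITIS",
    "CNS_DEMYELINATION",
    "NMOSD",
    "MOGAD",
    "MULTIPLE_SCLEROSIS",
    "ADEM",
    "ASEPTIC_MENINGITIS",
    "CNS_VASCULITIS",
)

SERIOUS = "SERIOUS"
NON_SERIOUS = "NON_SERIOUS"
UNKNOWN = "UNKNOWN"

_WS = re.compile(r"\s+")
# dosage/strength tokens appended to verbatim drug names, e.g. "200MG", "5 ML"
_DOSE_TOKEN = re.compile(r"^\d+(\.\d+)?(mg|mcg|ug|g|ml|l|iu|%)?$|^(mg|mcg|ug|ml|iu)$")
_PUNCT = re.compile(r"[.,;:!?/\\()\[\]{}'\"]+")


def normalize_pt(pt: str) -> str:
    """Case-fold, collapse whitespace, strip trailing periods."""
    return _WS.sub(" ", pt.strip().strip(".").casefold()).strip()


def clean_drug_name(raw: str) -> str:
    """Normalize a verbatim drug string for dictionary lookup.

    Trims, case-folds, strips punctuation, and drops dosage tokens
    (``"PEMBROLIZUMAB 200MG"`` -> ``"pembrolizumab"``).
    """
    s = _PUNCT.sub(" ", raw.casefold())
    tokens = [t for t in _WS.split(s.strip()) if t and not _DOSE_TOKEN.match(t)]
    return " ".join(tokens)


def _read_tsv(path_or_res) -> list[dict[str, str]]:
    with open(path_or_res, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pvsignals").joinpath("data", name)))


#: the seven checkpoint-inhibitor ingredients under study, in fixed order
TARGET_INGREDIENTS = (
    "ipilimumab",
    "pembrolizumab",
    "nivolumab",
    "cemiplimab",
    "atezolizumab",
    "durvalumab",
    "avelumab",
)


@dataclass
class DrugDictionary:
    """Ingredient -> synonym-set map with O(1) reverse lookup.

    Synonym sets must be pairwise disjoint (a verbatim name resolves to at
    most one ingredient).  The shipped default covers the seven checkpoint
    inhibitors plus tremelimumab, with common brand names.
    """

    synonyms: dict[str, set[str]] = field(default_factory=dict)
    target_ingredients: tuple[str, ...] = TARGET_INGREDIENTS

    def __post_init__(self) -> None:
        self._reverse: dict[str, str] = {}
        for ingredient, names in self.synonyms.items():
            names.add(ingredient)
            for name in names:
                key = clean_drug_name(name)
                other = self._reverse.get(key)
                if other is not None and other != ingredient:
                    raise ValueError(
                        f"synonym {name!r} claimed by both {other!r} and {ingredient!r}"
                    )
                self._reverse[key] = ingredient

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "DrugDictionary":
        """Load an (ingredient, synonym) two-column TSV."""
        syn: dict[str, set[str]] = {}
        for row in _read_tsv(path):
            syn.setdefault(row["ingredient"].strip().casefold(), set()).add(
                row["synonym"].strip()
            )
        return cls(synonyms=syn, **kwargs)

    @classmethod
    def default(cls) -> "DrugDictionary":
        return cls.from_tsv(_data_path("drug_synonyms.tsv"))

    def normalize(self, raw_name: str) -> str | None:
        """Resolve a verbatim drug string to an ingredient, or ``None``.

        The whole cleaned string is looked up first; on a miss, individual
        tokens are tried (verbatim names like ``"OPDIVO (NIVOLUMAB)"``
        carry brand and generic together) and accepted only when they all
        point at one ingredient.
        """
        cleaned = clean_drug_name(raw_name)
        hit = self._reverse.get(cleaned)
        if hit is not None:
            return hit
        token_hits = {
            self._reverse[t] for t in cleaned.split() if t in self._reverse
        }
        if len(token_hits) == 1:
            return token_hits.pop()
        return None


def normalize_drug_name(raw_name: str, dictionary: DrugDictionary) -> str | None:
    """Functional alias for :meth:`DrugDictionary.normalize`."""
    return dictionary.normalize(raw_name)


@dataclass
class EventGroupMap:
    """MedDRA PT -> composite event-group lookup.

    Each PT maps to exactly one group; matching is case- and
    whitespace-insensitive.  ``nae_groups`` is the umbrella of groups
    counted as neurological immune-mediated events.
    """

    pt_to_group: dict[str, str] = field(default_factory=dict)
    nae_groups: frozenset[str] = frozenset(EVENT_GROUPS)

    def __post_init__(self) -> None:
        self.pt_to_group = {normalize_pt(pt): g for pt, g in self.pt_to_group.items()}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EventGroupMap":
        """Load a (pt, group, nae_flag) TSV."""
        mapping: dict[str, str] = {}
        nae: set[str] = set()
        for row in _read_tsv(path):
            pt, group = row["pt"], row["group"].strip()
            if normalize_pt(pt) in mapping and mapping[normalize_pt(pt)] != group:
                raise ValueError(f"PT {pt!r} mapped to two groups")
            mapping[pt] = group
            if row.get("nae_flag", "1").strip() in ("1", "true", "True"):
                nae.add(group)
        return cls(pt_to_group=mapping, nae_groups=frozenset(nae))

    @classmethod
    def default(cls) -> "EventGroupMap":
        return cls.from_tsv(_data_path("event_groups.tsv"))

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.pt_to_group.values())))

    def group_of(self, pt: str) -> str | None:
        return self.pt_to_group.get(normalize_pt(pt))


def map_pt_to_group(pt: str, group_map: EventGroupMap) -> str | None:
    """Functional alias for :meth:`EventGroupMap.group_of`."""
    return group_map.group_of(pt)


def classify_outcome_severity(outcomes: Iterable[str]) -> str:
    """SERIOUS iff death (DE) reported; NON_SERIOUS otherwise; UNKNOWN if empty."""
    codes = set(outcomes)
    if not codes:
        return UNKNOWN
    return SERIOUS if "DE" in codes else NON_SERIOUS


def select_suspect_exposures(
    case: CaseReport,
    dictionary: DrugDictionary,
    roles: frozenset[str] | set[str] = frozenset({"PS"}),
) -> list[tuple[str, _dt.date | None]]:
    """Target-ingredient exposures of a case under the role filter.

    Returns one ``(ingredient, start_date)`` per matched target ingredient
    among drug entries whose role is in ``roles`` (default: primary suspect
    only).  Duplicate rows for the same ingredient collapse to the earliest
    known start date.  Order follows the dictionary's target list.
    """
    best: dict[str, _dt.date | None] = {}
    for entry in case.drugs:
        if entry.role not in roles:
            continue
        ingredient = entry.ingredient or dictionary.normalize(entry.raw_name)
        if ingredient is None or ingredient not in dictionary.target_ingredients:
            continue
        if ingredient not in best:
            best[ingredient] = entry.start_date
        elif entry.start_date is not None and (
            best[ingredient] is None or entry.start_date < best[ingredient]
        ):
            best[ingredient] = entry.start_date
    order = {ing: i for i, ing in enumerate(dictionary.target_ingredients)}
    return sorted(best.items(), key=lambda kv: order.get(kv[0], len(order)))


def annotate_store(
    cases: Iterable[CaseReport],
    dictionary: DrugDictionary | None = None,
    group_map: EventGroupMap | None = None,
) -> list[CaseReport]:
    """Fill ``DrugEntry.ingredient`` and ``ReactionEntry.group`` in place.

    Unmatched drug names fall back to their cleaned verbatim string so that
    all-drug rankings have a stable normalized key; unmatched PTs keep
    ``group=None``.  Returns the same list for chaining.
    """
    dictionary = dictionary or DrugDictionary.default()
    group_map = group_map or EventGroupMap.default()
    cases = list(cases)
    for case in cases:
        for drug in case.drugs:
            drug.ingredient = dictionary.normalize(drug.raw_name) or clean_drug_name(
                drug.raw_name
            )
        for reaction in case.reactions:
            reaction.group = group_map.group_of(reaction.pt)
    return cases


def case_groups(case: CaseReport, nae_only: bool = False,
                group_map: EventGroupMap | None = None) -> set[str]:
    """Distinct event groups present in a case (one per group, however many PTs).

    A case with two PTs in the same group contributes that group once — the
    counting unit everywhere in this package is the case, not the reaction
    row.
    """
    groups = {r.group for r in case.reactions if r.group is not None}
    if nae_only:
        gm = group_map or EventGroupMap.default()
        groups &= gm.nae_groups
    return groups
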