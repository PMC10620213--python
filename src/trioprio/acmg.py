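"""ACMG/AMP criteria combining and the PS2 de novo upgrade.

The 2015 ACMG/AMP framework scores a variant on 28 boolean evidence
criteria — 16 pathogenic (PVS1; PS1-4; PM1-6; PP1-5) and 12 benign
(BA1; BS1-4; BP1-7) — and combines them into one of five classes:
pathogenic (P), likely pathogenic (LP), uncertain significance (VUS),
likely benign (LB), benign (B).  The combining table ships as package
data (``data/acmg_rules.json``) so rule edits are data, not code.

PS2 is the "confirmed de novo" strong criterion.  External classifiers
typically cannot assign it (they see no pedigree), so trio-aware
pipelines add PS2 to every de novo record and recombine, promoting
qualifying VUS calls to LP/P.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import Iterable, Optional

from .models import ClassificationRecord, VariantKey
from .vcf_io import CRITERIA_VOCABULARY

log = logging.getLogger(__name__)

__all__ = [
    "CriteriaVector",
    "combine_criteria",
    "apply_ps2_upgrade",
    "CLASS_ORDER",
    "load_combining_rules",
]

#: Benign -> pathogenic ordering used for "never downgrade" guarantees.
CLASS_ORDER = ("B", "LB", "VUS", "LP", "P")
_CLASS_RANK = {c: i for i, c in enumerate(CLASS_ORDER)}

_TIER_OF = {}
_TIER_OF["PVS1"] = "pvs"
for _i in range(1, 5):
    _TIER_OF[f"PS{_i}"] = "ps"
for _i in range(1, 7):
    _TIER_OF[f"PM{_i}"] = "pm"
for _i in range(1, 6):
    _TIER_OF[f"PP{_i}"] = "pp"
_TIER_OF["BA1"] = "ba"
for _i in range(1, 5):
    _TIER_OF[f"BS{_i}"] = "bs"
for _i in range(1, 8):
    _TIER_OF[f"BP{_i}"] = "bp"


@dataclass(frozen=True)
class CriteriaVector:
    """A validated set of ACMG criterion flags."""

    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = self.flags - CRITERIA_VOCABULARY
        if unknown:
            raise ValueError(f"unknown ACMG criteria: {sorted(unknown)}")

    @classmethod
    def of(cls, *tags: str) -> "CriteriaVector":
        return cls(flags=frozenset(tags))

    @classmethod
    def from_string(cls, text: str) -> "CriteriaVector":
        return cls(flags=frozenset(t.strip() for t in text.split(";") if t.strip()))

    def tier_counts(self) -> dict[str, int]:
        counts = {"pvs": 0, "ps": 0, "pm": 0, "pp": 0, "ba": 0, "bs": 0, "bp": 0}
        for tag in self.flags:
            counts[_TIER_OF[tag]] += 1
        return counts

    def with_flag(self, tag: str) -> "CriteriaVector":
        return CriteriaVector(flags=self.flags | {tag})

    def __contains__(self, tag: object) -> bool:
        return tag in self.flags

    def __len__(self) -> int:
        return len(self.flags)


@lru_cache(maxsize=1)
def load_combining_rules() -> dict[str, list[dict[str, int]]]:
    text = resources.files("trioprio.data").joinpath("acmg_rules.json").read_text()
    raw = json.loads(text)
    return {k: v for k, v in raw.items() if k != "comment"}


def _any_rule_fires(counts: dict[str, int], rules: list[dict[str, int]]) -> bool:
    return any(all(counts[tier] >= n for tier, n in rule.items()) for rule in rules)


def combine_criteria(v: CriteriaVector | frozenset[str] | Iterable[str]) -> str:
    """Combine criterion flags into one of P, LP, VUS, LB, B.

    Pathogenic and benign sides are evaluated independently against the
    combining table; if both sides qualify the evidence conflicts and
    the class is VUS, and with no qualifying evidence on either side the
    class is likewise VUS.
    """
    if not isinstance(v, CriteriaVector):
        v = CriteriaVector(flags=frozenset(v))
    counts = v.tier_counts()
    rules = load_combining_rules()
    if _any_rule_fires(counts, rules["pathogenic"]):
        patho: Optional[str] = "P"
    elif _any_rule_fires(counts, rules["likely_pathogenic"]):
        patho = "LP"
    else:
        patho = None
    if _any_rule_fires(counts, rules["benign"]):
        benign: Optional[str] = "B"
    elif _any_rule_fires(counts, rules["likely_benign"]):
        benign = "LB"
    else:
        benign = None
    if patho and benign:
        return "VUS"  # conflicting evidence
    return patho or benign or "VUS"


def apply_ps2_upgrade(
    records: list[ClassificationRecord],
    denovo_keys: set[tuple[VariantKey, str]],
) -> list[ClassificationRecord]:
    """Assign PS2 to every de novo record and recombine its criteria.

    ``denovo_keys`` holds (variant_key, proband_id) pairs confirmed de
    novo from the pedigree.  PS2 is added to *all* matching records
    (idempotently), and the class is recomputed via
    :func:`combine_criteria`; a record never moves toward benign — if
    recombination lands below the tool's original call, the original
    label is kept.  The outcome is stored in
    ``classification_after_ps2``; non-de-novo records pass through with
    it set to their unchanged classification.  A de novo VUS with an
    empty criteria vector cannot be recombined meaningfully and is left
    unchanged with a warning.
    """
    out: list[ClassificationRecord] = []
    for r in records:
        if (r.variant_key, r.proband_id) not in denovo_keys:
            out.append(replace(r, classification_after_ps2=r.classification))
            continue
        if not r.criteria and r.classification == "VUS":
            log.warning(
                "de novo VUS %s/%s has no criteria vector; left unchanged",
                r.variant_key, r.proband_id,
            )
            out.append(replace(r, classification_after_ps2=r.classification))
            continue
        upgraded = frozenset(r.criteria) | {"PS2"}
        recombined = combine_criteria(upgraded)
        final = max(recombined, r.classification, key=_CLASS_RANK.__getitem__)
        out.append(replace(r, criteria=upgraded, classification_after_ps2=final))
    return out
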